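"""Weighted ssGWAS: backsolve, nonlinearA weights, iteration, windows."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import relmat
from ssgblup.mme_aireml import build_design, solve_mme
from ssgblup.qc_prep import allele_frequencies, impute_missing
from ssgblup.simdata import (
    make_phenotypes,
    plant_qtl,
    simulate_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
)
from ssgblup.types import RelationshipMatrix, SnpEffectSet, VarComp
from ssgblup.wssgwas import (
    GwasDataset,
    backsolve_snp_effects,
    nonlinearA_weights,
    run_wssgblup,
    window_variances,
)
from .conftest import make_genotypes


def _offcenter_setup(n=40, m=60, seed=2):
    """All-genotyped founder herd with off-centered frequencies.

    Centering at slightly perturbed frequencies keeps G full rank (exactly
    centered G always has the all-ones null vector), so the unblended
    projection identity Zc a_hat = u_hat holds exactly.
    """
    ped = simulate_pedigree(n, 0, seed=1)
    geno = simulate_genotypes(ped, m, 3, seed=seed)
    freqs = 0.9 * allele_frequencies(geno) + 0.03
    Zc = impute_missing(geno, freqs)
    lam = relmat.scaling_parameter(freqs)
    return ped, geno, freqs, Zc, lam


class TestBacksolve:
    def test_null_gebvs_give_null_effects(self):
        ped, geno, freqs, Zc, lam = _offcenter_setup()
        G = relmat.build_G(Zc, freqs, labels=geno.animal_ids)
        eff = backsolve_snp_effects(np.zeros(40), Zc, np.ones(60), G, lam)
        np.testing.assert_array_equal(eff.effects, 0.0)

    def test_projection_identity_unblended(self):
        ped, geno, freqs, Zc, lam = _offcenter_setup()
        rng = np.random.default_rng(5)
        u = rng.normal(0, 1, 40)
        G = relmat.build_G(Zc, freqs, labels=geno.animal_ids)
        eff = backsolve_snp_effects(u, Zc, np.ones(60), G, lam)
        np.testing.assert_allclose(Zc @ eff.effects, u, atol=1e-9)

    def test_matches_dense_ridge_solver_oracle(self):
        # ssGBLUP backsolve must reproduce the marker effects of the
        # equivalent ridge (SNP-BLUP) system solved densely
        ped, geno, freqs, Zc, lam = _offcenter_setup(n=4, m=6, seed=3)
        rng = np.random.default_rng(7)
        y = rng.normal(0, 2, 4)
        traits = pd.DataFrame(
            {
                "animal_id": geno.animal_ids,
                "birth_year": 2000,
                "age_at_slaughter": rng.normal(550, 40, 4),
                "MARB": y,
            }
        )
        design = build_design(traits, "MARB")
        su, se_ = 2.0, 3.0
        G = relmat.build_G(Zc, freqs, labels=geno.animal_ids)
        H = RelationshipMatrix(labels=geno.animal_ids, values=G.values, kind="H")
        sol = solve_mme(design, VarComp(sigma_u2=su, sigma_e2=se_), H)
        eff = backsolve_snp_effects(sol.u, Zc, np.ones(6), G, lam)
        X = design.X
        alpha = se_ / (su * lam)
        C = np.block(
            [[X.T @ X, X.T @ Zc], [Zc.T @ X, Zc.T @ Zc + alpha * np.eye(6)]]
        )
        rhs = np.concatenate([X.T @ y, Zc.T @ y])
        a_ridge = np.linalg.solve(C, rhs)[X.shape[1] :]
        np.testing.assert_allclose(eff.effects, a_ridge, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        ped, geno, freqs, Zc, lam = _offcenter_setup()
        G = relmat.build_G(Zc, freqs, labels=geno.animal_ids)
        with pytest.raises(ValueError):
            backsolve_snp_effects(np.zeros(10), Zc, np.ones(60), G, lam)


class TestNonlinearAWeights:
    def test_formula_values_and_cap(self):
        # craft an effect vector, then recompute the rule independently
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1.0, 500)
        m = len(a)
        d = nonlinearA_weights(a, ct=1.05, cap=10.0)
        sd = np.std(a)
        raw = np.minimum(1.05 ** (np.abs(a) / sd - 2.0), 10.0)
        np.testing.assert_allclose(d, raw * m / raw.sum(), rtol=1e-12)

    def test_exponent_zero_at_two_sigma(self):
        # pre-normalization weight is exactly 1 when |a| = 2 sd(a), and
        # ~0.95238 = 1.05^-1 when |a| = sd(a)
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1.0, 2000)
        sd = np.std(a)
        raw = 1.05 ** (np.abs(a) / sd - 2.0)
        j2 = np.argmin(np.abs(np.abs(a) - 2 * sd))
        j1 = np.argmin(np.abs(np.abs(a) - sd))
        assert raw[j2] == pytest.approx(1.0, abs=0.01)
        assert raw[j1] == pytest.approx(1.05 ** (-1), abs=0.01)
        assert 1.05 ** (-1) == pytest.approx(0.95238, abs=1e-5)

    def test_cap_binds_for_extreme_effect(self):
        # a single huge effect among many tiny ones exceeds 49 sd -> cap 10
        a = np.zeros(4000)
        a[:3999] = np.random.default_rng(13).normal(0, 1e-6, 3999)
        a[3999] = 1.0
        sd = np.std(a)
        assert abs(a[3999]) / sd > 49  # 1.05^49 > 10: the cap must bind
        d = nonlinearA_weights(a, ct=1.05, cap=10.0)
        raw_capped = 10.0
        raw_rest = 1.05 ** (np.abs(a[:3999]) / sd - 2.0)
        norm = 4000 / (raw_rest.sum() + raw_capped)
        assert d[3999] == pytest.approx(raw_capped * norm, rel=1e-10)

    def test_normalization_preserves_marker_count(self):
        for seed in range(5):
            a = np.random.default_rng(seed).normal(0, 2.0, 313)
            d = nonlinearA_weights(a)
            assert d.sum() == pytest.approx(313.0, abs=1e-9)
            assert np.all(d > 0)

    def test_all_zero_effects_reset_with_warning(self):
        with pytest.warns(UserWarning):
            d = nonlinearA_weights(np.zeros(10))
        np.testing.assert_array_equal(d, 1.0)


class TestWindowVariances:
    def test_hand_computed_single_marker_window(self):
        # Zc column {-1, 0, 1}, a = 1: population Var(w) = 2/3; sigma_u2 = 10
        # -> 6.67%
        Zc = np.array([[-1.0], [0.0], [1.0]])
        map_df = pd.DataFrame({"marker": ["SNP1"], "chrom": ["1"], "bp": [500_000]})
        eff = SnpEffectSet(
            trait="MARB", effects=np.array([1.0]), weights=np.ones(1),
            iteration=1, sigma_u2_used=10.0,
        )
        out = window_variances(eff, Zc, map_df, sigma_u2=10.0)
        assert len(out) == 1
        assert out.loc[0, "pct_var"] == pytest.approx(100.0 * (2.0 / 3.0) / 10.0)
        assert out.loc[0, "n_markers"] == 1

    def test_zero_effect_markers_give_zero_percent(self):
        Zc = np.random.default_rng(1).normal(0, 1, (10, 4))
        map_df = pd.DataFrame(
            {"marker": [f"S{i}" for i in range(4)], "chrom": "1",
             "bp": [1, 2, 1_000_001, 1_000_002]}
        )
        eff = SnpEffectSet("MARB", np.zeros(4), np.ones(4), 1, 1.0)
        out = window_variances(eff, Zc, map_df, sigma_u2=1.0)
        assert (out["pct_var"] == 0.0).all()

    def test_window_decomposition_sums_to_gebvs(self):
        # with D = I and no blending the per-window genetic values add up
        # exactly to Zc a_hat = u_hat over the genome
        ped, geno, freqs, Zc, lam = _offcenter_setup(n=30, m=80)
        rng = np.random.default_rng(15)
        u = rng.normal(0, 1, 30)
        G = relmat.build_G(Zc, freqs, labels=geno.animal_ids)
        eff = backsolve_snp_effects(u, Zc, np.ones(80), G, lam)
        total = np.zeros(30)
        out = window_variances(eff, Zc, geno.marker_map, sigma_u2=1.0)
        bp = geno.marker_map["bp"].to_numpy()
        chrom = geno.marker_map["chrom"].to_numpy()
        for row in out.itertuples(index=False):
            cols = np.flatnonzero(
                (chrom == row.chrom) & (bp >= row.start_bp) & (bp <= row.end_bp)
            )
            total += Zc[:, cols] @ eff.effects[cols]
        np.testing.assert_allclose(total, Zc @ eff.effects, atol=1e-10)
        np.testing.assert_allclose(total, u, atol=1e-8)

    def test_invariant_to_marker_order_within_window(self):
        rng = np.random.default_rng(17)
        Zc = rng.normal(0, 1, (12, 6))
        a = rng.normal(0, 1, 6)
        map_df = pd.DataFrame(
            {"marker": [f"S{i}" for i in range(6)], "chrom": "1",
             "bp": [10, 20, 30, 40, 50, 60]}
        )
        eff = SnpEffectSet("MARB", a, np.ones(6), 1, 1.0)
        base = window_variances(eff, Zc, map_df, 2.0)
        perm = rng.permutation(6)
        map_p = map_df.iloc[perm].sort_values("bp").reset_index(drop=True)
        order = np.argsort(map_df["bp"].to_numpy()[perm])
        eff_p = SnpEffectSet("MARB", a[perm][order], np.ones(6), 1, 1.0)
        out_p = window_variances(eff_p, Zc[:, perm][:, order], map_p, 2.0)
        np.testing.assert_allclose(base["pct_var"], out_p["pct_var"], atol=1e-12)

    def test_sliding_scheme_anchors_each_marker(self):
        Zc = np.random.default_rng(19).normal(0, 1, (8, 3))
        map_df = pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": "1", "bp": [1, 400_000, 2_000_000]}
        )
        eff = SnpEffectSet("MARB", np.ones(3), np.ones(3), 1, 1.0)
        out = window_variances(eff, Zc, map_df, 1.0, scheme="sliding")
        assert len(out) == 3
        assert list(out["n_markers"]) == [2, 1, 1]

    def test_bad_inputs_rejected(self):
        Zc = np.ones((2, 1))
        map_df = pd.DataFrame({"marker": ["a"], "chrom": "1", "bp": [1]})
        eff = SnpEffectSet("MARB", np.ones(1), np.ones(1), 1, 1.0)
        with pytest.raises(ValueError):
            window_variances(eff, Zc, map_df, sigma_u2=0.0)
        with pytest.raises(ValueError):
            window_variances(eff, Zc, map_df, 1.0, scheme="hexagonal")


class TestRunWssgblup:
    @pytest.fixture(scope="class")
    def planted_dataset(self):
        ped = simulate_pedigree(60, 1, 4, seed=41)  # 180 animals
        geno = simulate_genotypes(
            ped, 400, 4, chrom_length_bp=40_000_000, seed=42
        )
        names = ["MARB", "REA"]
        state = simulate_breeding_values(
            ped, np.diag([1.0, 1.0]), seed=43, trait_names=names
        )
        state = plant_qtl(
            geno, ("2", 10_000_001, 11_000_000), 10.0, ["MARB"], state, seed=44
        )
        traits, state = make_phenotypes(ped, state, np.diag([1.0, 1.0]), seed=43)
        return GwasDataset(ped, geno, traits, names), state

    def test_single_iteration_is_unweighted(self, planted_dataset):
        ds, state = planted_dataset
        res = run_wssgblup(ds, "MARB", n_iterations=1, conditional=False)
        assert len(res.iterations) == 1
        np.testing.assert_array_equal(res.final.weights, 1.0)

    def test_weights_evolve_and_iterations_recorded(self, planted_dataset):
        ds, state = planted_dataset
        res = run_wssgblup(ds, "MARB", n_iterations=3, conditional=False)
        assert [e.iteration for e in res.iterations] == [1, 2, 3]
        assert res.iterations[1].weights.sum() == pytest.approx(400.0)
        assert res.iterations[1].weights.std() > 0

    def test_qtl_rank_improves_or_holds_with_iteration(self):
        # Monte-Carlo property: reweighting should not push a strong planted
        # QTL marker down the |a_hat| ranking
        hold = 0
        n_rep = 8
        for rep in range(n_rep):
            ped = simulate_pedigree(50, 1, 4, seed=100 + rep)
            geno = simulate_genotypes(ped, 300, 3, chrom_length_bp=40_000_000,
                                      seed=200 + rep)
            state = simulate_breeding_values(
                ped, np.array([[1.0]]), seed=300 + rep, trait_names=["MARB"]
            )
            state = plant_qtl(
                geno, ("2", 1, 40_000_000), 20.0, ["MARB"], state, seed=400 + rep
            )
            j = np.flatnonzero(state.qtl_effects[:, 0])[0]
            traits, state = make_phenotypes(ped, state, np.array([[1.0]]),
                                            seed=300 + rep)
            ds = GwasDataset(ped, geno, traits, ["MARB"])
            res = run_wssgblup(ds, "MARB", n_iterations=3, conditional=False)
            ranks = [
                int((np.abs(e.effects) >= abs(e.effects[j])).sum())
                for e in res.iterations
            ]
            if ranks[-1] <= ranks[0]:
                hold += 1
        assert hold >= int(0.75 * n_rep)

    def test_conditional_design_contains_other_traits(self, planted_dataset):
        ds, state = planted_dataset
        res = run_wssgblup(ds, "MARB", n_iterations=1, conditional=True)
        assert "REA" in res.design.column_names

    def test_conditioning_removes_mediated_signal(self):
        # a QTL acting on trait A only, with trait B = A + noise downstream:
        # the unconditional scan of B sees the QTL window, the conditional
        # scan (B adjusted for A) suppresses it
        rng = np.random.default_rng(55)
        ped = simulate_pedigree(80, 1, 4, seed=56)  # 240 animals
        geno = simulate_genotypes(ped, 300, 3, chrom_length_bp=40_000_000, seed=57)
        state = simulate_breeding_values(
            ped, np.array([[1.0]]), seed=58, trait_names=["MARB"]
        )
        state = plant_qtl(geno, ("2", 1, 40_000_000), 30.0, ["MARB"], state, seed=59)
        traits, state = make_phenotypes(ped, state, np.array([[0.3]]), seed=58)
        traits["JUIC"] = traits["MARB"] + rng.normal(0, 0.3, len(traits))
        ds = GwasDataset(ped, geno, traits, ["MARB", "JUIC"])
        j = np.flatnonzero(state.qtl_effects[:, 0])[0]
        freqs, Zc = ds._genomic()
        out = {}
        for conditional in (False, True):
            res = run_wssgblup(ds, "JUIC", n_iterations=2, conditional=conditional)
            w = window_variances(res.final, Zc, geno.marker_map, res.vc.sigma_u2)
            chrom = geno.marker_map["chrom"].iloc[j]
            bp = geno.marker_map["bp"].iloc[j]
            sel = (
                (w["chrom"] == chrom)
                & (w["start_bp"] <= bp)
                & (w["end_bp"] >= bp)
            )
            out[conditional] = float(w.loc[sel, "pct_var"].iloc[0])
        assert out[True] < 0.5 * out[False]

    def test_bad_iteration_count(self, planted_dataset):
        ds, _ = planted_dataset
        with pytest.raises(ValueError):
            run_wssgblup(ds, "MARB", n_iterations=0)
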