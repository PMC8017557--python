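"""Synthetic multibreed beef-cattle population generator.

Emulates the statistical structure the downstream single-step analysis
assumes: a multigeneration pedigree whose animals carry a breed fraction
between 0 (pure breed A, e.g. Angus) and 1 (pure breed B, e.g. Brahman),
genotypes produced by gene dropping along the pedigree with Haldane
recombination at 1 cM/Mb, multi-trait phenotypes generated under the animal
model with an additive (co)variance matrix T and residual (co)variance R,
year-of-birth class effects and an age-at-slaughter covariate, and optionally
a planted QTL window whose share of the additive genetic variance is known.

All randomness descends from one top-level seed through
``numpy.random.SeedSequence`` spawning, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relmat import _parent_positions, build_A, _mendelian_variance, sort_pedigree
from .types import GenotypeMatrix, TrueGeneticState, TRAIT_NAMES

__all__ = [
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_breeding_values",
    "make_phenotypes",
    "simulate_traits",
    "plant_qtl",
    "flag_genotyped",
    "discretize_scores",
    "count_scheduled_animals",
]

#: genotyped fraction of the herd mirroring a ~44% genotyping rate
DEFAULT_GENOTYPED_FRACTION = 1038 / 2384

#: ordinal reporting scales: (low, high) after collapsing is NOT applied here
SCORE_SCALES = {
    "MARB": (100, 999),
    "COLOR": (1, 8),
    "TEXT": (1, 7),
    "FIRM": (1, 5),
}


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one top-level seed into ``n`` independent generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def count_scheduled_animals(
    n_founders: int, n_generations: int, offspring_per_mating: int
) -> int:
    """Total animals produced by the deterministic mating schedule.

    Each generation performs ``n_founders // 2`` matings with
    ``offspring_per_mating`` offspring each.
    """
    matings = n_founders // 2
    return n_founders + n_generations * matings * offspring_per_mating


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int = 2,
    year_span: tuple[int, int] = (1989, 2018),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a multibreed pedigree.

    Founders have unknown parents and breed fractions covering [0, 1]
    (both endpoints are always present).  Each subsequent generation mates
    ``n_founders // 2`` randomly drawn pairs from all existing animals,
    rejecting parent-offspring pairings, with ``offspring_per_mating``
    offspring per mating.  A non-founder's breed fraction is the parental
    mean.  Birth years advance one generation at a time across ``year_span``.

    Returns a pedigree DataFrame sorted parents-first (see
    :mod:`ssgblup.types` for the schema).
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    y0, y1 = int(year_span[0]), int(year_span[1])
    if y1 < y0:
        raise ValueError("year_span must be increasing")
    year_step = max(1, (y1 - y0) // max(1, n_generations))

    breed = rng.uniform(0.0, 1.0, size=n_founders)
    breed[0] = 0.0
    if n_founders > 1:
        breed[1] = 1.0

    animal = list(range(1, n_founders + 1))
    sire = [0] * n_founders
    dam = [0] * n_founders
    year = [y0] * n_founders
    frac = list(breed)
    parent_of = {a: (0, 0) for a in animal}

    next_id = n_founders + 1
    matings_per_gen = n_founders // 2
    for g in range(1, n_generations + 1):
        gen_year = min(y0 + g * year_step, y1)
        pool = np.array(animal)
        for _ in range(matings_per_gen):
            while True:
                p1, p2 = rng.choice(pool, size=2, replace=False)
                s1, d1 = parent_of[int(p1)]
                s2, d2 = parent_of[int(p2)]
                if int(p1) in (s2, d2) or int(p2) in (s1, d1):
                    continue  # avoid parent-offspring matings
                break
            f = 0.5 * (frac[animal.index(int(p1))] + frac[animal.index(int(p2))])
            for _ in range(offspring_per_mating):
                animal.append(next_id)
                sire.append(int(p1))
                dam.append(int(p2))
                year.append(gen_year)
                frac.append(f)
                parent_of[next_id] = (int(p1), int(p2))
                next_id += 1
    ped = pd.DataFrame(
        {
            "animal": animal,
            "sire": sire,
            "dam": dam,
            "birth_year": year,
            "breed_fraction": frac,
        }
    )
    return ped


def _marker_map(
    n_markers: int, n_chromosomes: int, chrom_length_bp: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Random sorted marker map: markers split evenly across chromosomes."""
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(1, n_chromosomes + 1):
        m = int(per[c - 1])
        bp = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=m, replace=False))
        for b in bp:
            k += 1
            rows.append((f"SNP{k}", str(c), int(b)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "bp"])


def _recomb_prob(marker_map: pd.DataFrame) -> np.ndarray:
    """Recombination probability between adjacent markers (Haldane, 1 cM/Mb).

    Across chromosome boundaries the probability is 0.5 (free recombination).
    """
    bp = marker_map["bp"].to_numpy()
    chrom = marker_map["chrom"].to_numpy()
    d_morgan = np.abs(np.diff(bp)) / 1e8  # 1 cM/Mb = 1e-8 Morgan/bp
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def simulate_genotypes(
    ped: pd.DataFrame,
    n_markers: int,
    n_chromosomes: int = 10,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    chrom_length_bp: int = 100_000_000,
    missing_rate: float = 0.0,
    founder_ld_pool: int | None = None,
    founder_ld_block_bp: int = 1_000_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes for every animal in the pedigree.

    Founder haplotype alleles are drawn per marker with frequencies uniform
    over ``founder_maf_range``; non-founders inherit one recombinant gamete
    from each parent (Haldane map function, 1 cM/Mb).  Codes are 0/1/2 allele
    counts, with optional uniformly random missing calls (NaN).

    With ``founder_ld_pool = k``, founder haplotypes are assembled from a
    pool of ``k`` distinct haplotypes per ``founder_ld_block_bp`` genomic
    segment (pool alleles still drawn per marker from the frequency range,
    segments independent).  This emulates the block linkage disequilibrium
    of a real genotyping array at a chosen physical scale — the structure a
    1-Mb window statistic relies on — while leaving markers in different
    blocks unassociated.  The default (``None``) keeps founder markers fully
    independent.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree")
    lo, hi = founder_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
    if founder_ld_pool is not None and founder_ld_pool < 2:
        raise ValueError("founder_ld_pool must be >= 2 haplotypes")
    ped = sort_pedigree(ped)
    rng_map, rng_founder, rng_drop, rng_miss = _rngs(seed, 4)
    marker_map = _marker_map(n_markers, n_chromosomes, chrom_length_bp, rng_map)
    r = _recomb_prob(marker_map)

    sire, dam = _parent_positions(ped)
    n = len(ped)
    hap = np.zeros((n, 2, n_markers), dtype=np.int8)
    p = rng_founder.uniform(lo, hi, size=n_markers)

    if founder_ld_pool is not None:
        # segment key: (chromosome, block index); pool per segment
        seg = pd.MultiIndex.from_arrays(
            [
                marker_map["chrom"],
                (marker_map["bp"].to_numpy() - 1) // founder_ld_block_bp,
            ]
        )
        seg_codes = pd.factorize(seg)[0]
        pools = []
        for sid in range(seg_codes.max() + 1):
            cols_s = np.flatnonzero(seg_codes == sid)
            pools.append(
                (rng_founder.random((founder_ld_pool, len(cols_s))) < p[cols_s]).astype(np.int8)
            )

        def founder_haplotype() -> np.ndarray:
            out = np.empty(n_markers, dtype=np.int8)
            for sid, pool in enumerate(pools):
                cols_s = np.flatnonzero(seg_codes == sid)
                out[cols_s] = pool[rng_founder.integers(0, founder_ld_pool)]
            return out

    else:

        def founder_haplotype() -> np.ndarray:
            return (rng_founder.random(n_markers) < p).astype(np.int8)

    cols = np.arange(n_markers)
    for i in range(n):
        for h, parent in enumerate((sire[i], dam[i])):
            if parent < 0:
                hap[i, h] = founder_haplotype()
            else:
                switch = rng_drop.random(n_markers - 1) < r
                which = (rng_drop.integers(0, 2) + np.concatenate(([0], np.cumsum(switch)))) % 2
                hap[i, h] = hap[parent, which, cols]
    codes = hap.sum(axis=1).astype(float)
    if missing_rate > 0:
        mask = rng_miss.random(codes.shape) < missing_rate
        codes[mask] = np.nan
    return GenotypeMatrix(
        animal_ids=ped["animal"].to_numpy(),
        marker_ids=marker_map["marker"].to_numpy(),
        marker_map=marker_map,
        codes=codes,
    )


def _check_covariance(M: np.ndarray, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError(f"{name} must be a symmetric square matrix")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8 * max(1.0, np.trace(M)):
        raise ValueError(f"{name} is not positive semi-definite")
    return M


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Matrix square root robust to semi-definite input."""
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_breeding_values(
    ped: pd.DataFrame,
    T_true: np.ndarray,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> TrueGeneticState:
    """Recursive breeding values under the pedigree.

    Founders are drawn from MVN(0, T); a non-founder is the parental mean
    plus a Mendelian-sampling deviation with covariance
    T * (0.5 - 0.25 (F_s + F_d)), parental inbreeding F from the numerator
    relationship matrix (0.75 - 0.25 F_p with one parent known, T itself for
    founders).
    """
    T = _check_covariance(T_true, "T_true")
    t = T.shape[0]
    ped = sort_pedigree(ped)
    sire, dam = _parent_positions(ped)
    _, F = build_A(ped)
    d = _mendelian_variance(F, sire, dam)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    L = _psd_factor(T)
    n = len(ped)
    u = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        ms = z[i] @ L.T * np.sqrt(d[i])
        parent_mean = np.zeros(t)
        if sire[i] >= 0:
            parent_mean += 0.5 * u[sire[i]]
        if dam[i] >= 0:
            parent_mean += 0.5 * u[dam[i]]
        u[i] = parent_mean + ms
    if trait_names is None:
        trait_names = list(TRAIT_NAMES[:t]) if t <= len(TRAIT_NAMES) else [f"T{j}" for j in range(t)]
    return TrueGeneticState(
        breeding_values=u,
        qtl_effects=np.zeros((0, t)),
        T_true=T,
        R_true=np.zeros((t, t)),
        trait_names=list(trait_names),
    )


def plant_qtl(
    geno: GenotypeMatrix,
    window: tuple[str, int, int],
    target_pct: float,
    traits: list[int] | list[str],
    state: TrueGeneticState,
    seed: int = 0,
) -> TrueGeneticState:
    """Plant a QTL explaining ``target_pct`` % of sigma_u2 for chosen traits.

    One marker in the window (the most variable one, deterministically) gets
    an allele-substitution effect scaled so that the population variance of
    its centered genotypic values equals ``target_pct`` percent of the
    trait's additive variance; the pre-existing polygenic values are rescaled
    by sqrt(1 - target_pct/100) so total additive variance is unchanged.
    """
    if not (0.0 <= target_pct < 100.0):
        raise ValueError("target_pct must lie in [0, 100)")
    chrom, start, end = window
    m = geno.marker_map
    inwin = (m["chrom"].astype(str) == str(chrom)) & (m["bp"] >= start) & (m["bp"] <= end)
    idx = np.flatnonzero(inwin.to_numpy())
    if len(idx) == 0:
        raise ValueError("window contains no markers")
    codes = np.nan_to_num(geno.codes[:, idx], nan=0.0)
    var = codes.var(axis=0)  # population variance across individuals
    j = idx[int(np.argmax(var))]
    col = np.nan_to_num(geno.codes[:, j], nan=0.0)
    var_j = col.var()
    if var_j <= 0:
        raise ValueError("no segregating marker in window")

    tnames = state.trait_names
    t_idx = [tnames.index(tr) if isinstance(tr, str) else int(tr) for tr in traits]

    u = state.breeding_values.copy()
    q = np.zeros((geno.n_markers, state.T_true.shape[0]))
    if state.qtl_effects.size:
        q[: state.qtl_effects.shape[0]] = state.qtl_effects
    if u.shape[0] != geno.n_animals:
        raise ValueError(
            "plant_qtl requires genotypes for every animal carrying a breeding value"
        )
    zc = col - col.mean()
    for ti in t_idx:
        sigma_u2 = state.T_true[ti, ti]
        a = np.sqrt((target_pct / 100.0) * sigma_u2 / var_j)
        q[j, ti] = a
        u[:, ti] *= np.sqrt(1.0 - target_pct / 100.0)
        u[:, ti] += a * zc
    return TrueGeneticState(
        breeding_values=u,
        qtl_effects=q,
        T_true=state.T_true,
        R_true=state.R_true,
        trait_names=tnames,
    )


def make_phenotypes(
    ped: pd.DataFrame,
    state: TrueGeneticState,
    R_true: np.ndarray,
    year_effects: dict[int, np.ndarray] | None = None,
    age_slope: np.ndarray | float = 0.0,
    trait_means: np.ndarray | float = 0.0,
    age_mean: float = 550.0,
    age_sd: float = 45.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueGeneticState]:
    """Phenotypes = trait mean + year effect + age slope * age + u + e.

    ``year_effects`` maps birth year to a per-trait offset vector; when None,
    offsets are drawn N(0, (0.3 * phenotypic SD)^2) per year and trait.  Age
    at slaughter is N(age_mean, age_sd) days, and enters centered.
    """
    R = _check_covariance(R_true, "R_true")
    t = R.shape[0]
    if state.T_true.shape[0] != t:
        raise ValueError("T_true and R_true dimension mismatch")
    ped = sort_pedigree(ped)
    n = len(ped)
    rng_e, rng_year, rng_age = _rngs(seed + 1, 3)

    pheno_sd = np.sqrt(np.diag(state.T_true) + np.diag(R))
    years = np.sort(ped["birth_year"].unique())
    if year_effects is None:
        year_effects = {int(y): rng_year.normal(0.0, 0.3 * pheno_sd) for y in years}
    age = rng_age.normal(age_mean, age_sd, size=n).clip(min=1.0)
    age_c = age - age.mean()
    slope = np.broadcast_to(np.asarray(age_slope, dtype=float), (t,))
    means = np.broadcast_to(np.asarray(trait_means, dtype=float), (t,))

    e = rng_e.standard_normal((n, t)) @ _psd_factor(R).T
    ye = np.stack([year_effects[int(y)] for y in ped["birth_year"]])
    Y = means + ye + np.outer(age_c, slope) + state.breeding_values + e

    table = pd.DataFrame(
        {
            "animal_id": ped["animal"].to_numpy(),
            "birth_year": ped["birth_year"].to_numpy(),
            "age_at_slaughter": age,
        }
    )
    for j, name in enumerate(state.trait_names):
        table[name] = Y[:, j]
    new_state = TrueGeneticState(
        breeding_values=state.breeding_values,
        qtl_effects=state.qtl_effects,
        T_true=state.T_true,
        R_true=R,
        trait_names=state.trait_names,
    )
    return table, new_state


def simulate_traits(
    ped: pd.DataFrame,
    T_true: np.ndarray,
    R_true: np.ndarray,
    year_effects: dict[int, np.ndarray] | None = None,
    age_slope: np.ndarray | float = 0.0,
    trait_means: np.ndarray | float = 0.0,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> tuple[pd.DataFrame, TrueGeneticState]:
    """Breeding values plus phenotypes in one call (no QTL).

    Equivalent to :func:`simulate_breeding_values` followed by
    :func:`make_phenotypes`; returns (TraitTable, TrueGeneticState).
    """
    T = _check_covariance(T_true, "T_true")
    R = _check_covariance(R_true, "R_true")
    if T.shape != R.shape:
        raise ValueError("T_true and R_true must have equal dimension")
    state = simulate_breeding_values(ped, T, seed=seed, trait_names=trait_names)
    return make_phenotypes(
        ped,
        state,
        R,
        year_effects=year_effects,
        age_slope=age_slope,
        trait_means=trait_means,
        seed=seed,
    )


def flag_genotyped(
    ped: pd.DataFrame,
    fraction: float = DEFAULT_GENOTYPED_FRACTION,
    seed: int = 0,
) -> np.ndarray:
    """Randomly flag a subset of animals as genotyped.

    Returns positions (into the parents-first pedigree order) of the
    genotyped animals, sorted ascending.  The default fraction mirrors a
    herd where roughly 44% of animals are on the genotyping panel.
    """
    ped = sort_pedigree(ped)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    n = len(ped)
    k = max(1, int(round(fraction * n)))
    return np.sort(rng.choice(n, size=k, replace=False))


def discretize_scores(
    table: pd.DataFrame, scales: dict[str, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Discretize continuous liabilities onto ordinal reporting scales.

    Each named trait column is affinely mapped from its observed mean +/- 3 SD
    onto the declared (low, high) range by fixed thresholds, then rounded and
    clipped.  Only for fixture realism; the analysis treats scores as
    continuous.
    """
    scales = SCORE_SCALES if scales is None else scales
    out = table.copy()
    for name, (lo, hi) in scales.items():
        if name not in out.columns:
            continue
        x = out[name].to_numpy(dtype=float)
        mu, sd = np.nanmean(x), np.nanstd(x)
        if sd == 0:
            sd = 1.0
        scaled = (x - mu) / (6 * sd) * (hi - lo) + (lo + hi) / 2.0
        out[name] = np.clip(np.round(scaled), lo, hi)
    return out
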