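"""Phenotype preparation and marker quality control.

Covers the pre-analysis steps of a carcass/meat-quality evaluation: collapsing
sparse top categories of ordinal scores, averaging sensory-panel scores per
steak, filtering markers on chromosome type / minor allele frequency / call
rate, computing reference-allele frequencies, and building the centered
genotype matrix Zc used by every genomic relationship computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

__all__ = [
    "collapse_scores",
    "average_panel_scores",
    "filter_markers",
    "allele_frequencies",
    "impute_missing",
]

#: (trait, original full scale, mapping applied to the top categories)
SCORE_COLLAPSE = {
    "COLOR": {"range": (1, 8), "map": {8: 7}},
    "TEXT": {"range": (1, 7), "map": {6: 5, 7: 5}},
    "FIRM": {"range": (1, 5), "map": {5: 4}},
}

#: chromosome labels treated as sex chromosomes by default
SEX_CHROMOSOMES = frozenset({"X", "Y", "MT", "30", "31"})


def collapse_scores(traits: pd.DataFrame) -> pd.DataFrame:
    """Collapse sparse top score categories of the visual quality traits.

    COLOR 8 -> 7, TEXT {6, 7} -> 5, FIRM 5 -> 4; every other value is left
    unchanged (missing values pass through).  Raises ``ValueError`` when a
    present score lies outside the trait's declared original scale.
    """
    out = traits.copy()
    for name, rule in SCORE_COLLAPSE.items():
        if name not in out.columns:
            continue
        x = out[name].to_numpy(dtype=float)
        lo, hi = rule["range"]
        bad = (~np.isnan(x)) & ((x < lo) | (x > hi))
        if bad.any():
            raise ValueError(
                f"{name} scores outside the original {lo}-{hi} scale: "
                f"{sorted(set(x[bad]))}"
            )
        y = x.copy()
        for src, dst in rule["map"].items():
            y[x == src] = dst
        out[name] = y
    return out


def average_panel_scores(
    panelist_records: pd.DataFrame,
    steak_col: str = "animal_id",
    panelist_col: str = "panelist",
) -> pd.DataFrame:
    """Arithmetic mean sensory score per steak across panel members.

    ``panelist_records`` holds one row per (steak, panelist) with one column
    per sensory trait; the result holds one row per steak.  Raises on an
    empty input (a steak group with no panelists cannot occur in a frame,
    but an empty frame would silently yield nothing).
    """
    if len(panelist_records) == 0:
        raise ValueError("no panelist records to average")
    value_cols = [
        c for c in panelist_records.columns if c not in (steak_col, panelist_col)
    ]
    means = panelist_records.groupby(steak_col, sort=True)[value_cols].mean()
    return means.reset_index()


def _marker_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(call rate, minor allele frequency) per marker; MAF is NaN when no calls."""
    n = codes.shape[0]
    called = np.sum(~np.isnan(codes), axis=0)
    call_rate = called / n
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return call_rate, maf


def filter_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    autosomes_only: bool = True,
    sex_chromosomes: frozenset[str] = SEX_CHROMOSOMES,
) -> GenotypeMatrix:
    """Marker QC: drop sex-chromosome, low-MAF and low-call-rate markers.

    Keeps a marker when (i) its chromosome is autosomal (unless
    ``autosomes_only`` is False), (ii) its minor allele frequency is at least
    ``maf_min``, and (iii) its call rate is at least ``callrate_min``.
    Survivor order is preserved.  The default thresholds drop markers with
    MAF < 1% or call rate < 90%.
    """
    for thr, name in ((maf_min, "maf_min"), (callrate_min, "callrate_min")):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    call_rate, maf = _marker_stats(geno.codes)
    keep = call_rate >= callrate_min
    keep &= ~np.isnan(maf) & (maf >= maf_min)
    if autosomes_only:
        chrom = geno.marker_map["chrom"].astype(str).to_numpy()
        keep &= ~np.isin(chrom, list(sex_chromosomes))
    return geno.subset_markers(np.flatnonzero(keep))


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Reference-allele frequency per marker from the current population.

    p_i = mean(code)/2 over non-missing calls.  Raises when any marker has
    no calls at all.
    """
    called = np.sum(~np.isnan(geno.codes), axis=0)
    if np.any(called == 0):
        bad = geno.marker_ids[called == 0]
        raise ValueError(f"markers with no non-missing calls: {bad[:5]}...")
    return np.nanmean(geno.codes, axis=0) / 2.0


def impute_missing(geno: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """Centered genotype matrix Zc = codes - 2p with missing imputed to 2p.

    A missing call therefore contributes exactly zero after centering.
    Returns a dense float array (animals x markers).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (geno.n_markers,):
        raise ValueError("freqs length does not match marker count")
    if np.any((freqs < 0.0) | (freqs > 1.0)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    Zc = geno.codes - 2.0 * freqs
    return np.nan_to_num(Zc, nan=0.0)
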