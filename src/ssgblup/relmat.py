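"""Relationship matrices for single-step evaluation.

Builds the pedigree numerator relationship matrix A (tabular method), its
inverse by Henderson's rules with Meuwissen-Luo inbreeding, the genotyped
sub-block A22 and inverse, the (optionally weighted) genomic relationship
matrix G, the blended G inverse, and the joint single-step inverse H^-1.

All builders preserve pedigree order: genotyped animals are addressed through
an index vector into the pedigree ordering rather than reordered.
"""

from __future__ import annotations

import graphlib

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "sort_pedigree",
    "build_A",
    "inbreeding",
    "build_Ainv",
    "build_A22",
    "build_G",
    "blend_and_invert_G",
    "build_Hinv",
]


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Return the pedigree sorted so parents precede offspring.

    Raises ``ValueError`` on cyclic pedigrees (an animal its own ancestor).
    """
    ids = set(ped["animal"])
    graph: dict[int, set[int]] = {}
    for row in ped.itertuples(index=False):
        parents = {p for p in (row.sire, row.dam) if p != 0 and p in ids}
        graph[row.animal] = parents
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise ValueError(f"cyclic pedigree: {exc}") from exc
    rank = {a: i for i, a in enumerate(order)}
    return ped.sort_values("animal", key=lambda s: s.map(rank), kind="stable").reset_index(
        drop=True
    )


def _parent_positions(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sire/dam row positions (-1 for unknown) for a parent-first pedigree."""
    pos = {a: i for i, a in enumerate(ped["animal"])}
    sire = np.array([pos.get(s, -1) for s in ped["sire"]], dtype=np.intp)
    dam = np.array([pos.get(d, -1) for d in ped["dam"]], dtype=np.intp)
    order_ok = True
    for i, (s, d) in enumerate(zip(sire, dam)):
        if (s >= i and s != -1) or (d >= i and d != -1):
            order_ok = False
            break
    if not order_ok:
        raise ValueError("pedigree is not sorted parents-first; use sort_pedigree()")
    return sire, dam


def build_A(ped: pd.DataFrame) -> tuple[RelationshipMatrix, np.ndarray]:
    """Numerator relationship matrix by the tabular method.

    Parameters
    ----------
    ped : DataFrame
        Pedigree with parents before offspring (``sort_pedigree`` otherwise).

    Returns
    -------
    (RelationshipMatrix, ndarray)
        A with pedigree labels, and the inbreeding coefficients
        F = diag(A) - 1.
    """
    ped = sort_pedigree(ped)
    sire, dam = _parent_positions(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d >= 0:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    rel = RelationshipMatrix(labels=ped["animal"].to_numpy(), values=A, kind="A")
    return rel, np.diag(A) - 1.0


def inbreeding(ped: pd.DataFrame) -> np.ndarray:
    """Inbreeding coefficients F in pedigree order (diag(A) - 1)."""
    _, F = build_A(ped)
    return F


def _mendelian_variance(F: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance share per animal.

    0.5 - 0.25(F_s + F_d) with both parents known, 0.75 - 0.25 F_p with one,
    and 1 for founders.
    """
    n = len(sire)
    d = np.ones(n)
    both = (sire >= 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    one_s = (sire >= 0) & (dam < 0)
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    one_d = (sire < 0) & (dam >= 0)
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def mendelian_sampling_variance(ped: pd.DataFrame) -> np.ndarray:
    """Public helper: Mendelian sampling variance share per animal."""
    ped = sort_pedigree(ped)
    sire, dam = _parent_positions(ped)
    _, F = build_A(ped)
    return _mendelian_variance(F, sire, dam)


def build_Ainv(ped: pd.DataFrame) -> RelationshipMatrix:
    """Inverse of A by Henderson's rules, accounting for inbreeding.

    Contributions alpha_i = 1/d_i with d_i the Mendelian sampling variance
    from Meuwissen-Luo inbreeding coefficients are added at (i,i): alpha,
    (i,parent): -alpha/2, (parent,parent'): alpha/4.
    """
    ped = sort_pedigree(ped)
    sire, dam = _parent_positions(ped)
    _, F = build_A(ped)
    d = _mendelian_variance(F, sire, dam)
    n = len(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        alpha = 1.0 / d[i]
        Ainv[i, i] += alpha
        for p in (sire[i], dam[i]):
            if p >= 0:
                Ainv[i, p] -= alpha / 2.0
                Ainv[p, i] -= alpha / 2.0
        for p in (sire[i], dam[i]):
            for q in (sire[i], dam[i]):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4.0
    return RelationshipMatrix(labels=ped["animal"].to_numpy(), values=Ainv, kind="Ainv")


def build_A22(
    A: RelationshipMatrix, genotyped_index: np.ndarray
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Genotyped sub-block of A and its dense inverse."""
    idx = np.asarray(genotyped_index, dtype=np.intp)
    sub = A.values[np.ix_(idx, idx)]
    labels = A.labels[idx]
    a22 = RelationshipMatrix(labels=labels, values=sub, kind="A22")
    a22inv = RelationshipMatrix(labels=labels, values=np.linalg.inv(sub), kind="A22inv")
    return a22, a22inv


def scaling_parameter(freqs: np.ndarray) -> float:
    """lambda = 1 / (2 * sum p_i (1 - p_i)), the G-matrix scaling constant."""
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all markers fixed: zero scaling denominator for G")
    return 1.0 / denom


def build_G(
    Zc: np.ndarray,
    freqs: np.ndarray,
    D: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix G = Zc D Zc' / (2 sum p_i (1 - p_i)).

    ``Zc`` is the column-centered genotype matrix (missing imputed to the
    column mean, i.e. zero after centering); ``D`` is a positive per-marker
    weight vector (identity when omitted, giving the unweighted G).
    """
    Zc = np.asarray(Zc, dtype=float)
    lam = scaling_parameter(freqs)
    if D is None:
        G = (Zc @ Zc.T) * lam
    else:
        D = np.asarray(D, dtype=float)
        if np.any(D <= 0):
            raise ValueError("marker weights must be positive")
        G = (Zc * D) @ Zc.T * lam
    if labels is None:
        labels = np.arange(Zc.shape[0])
    return RelationshipMatrix(labels=np.asarray(labels), values=G, kind="G")


def blend_and_invert_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, weight: float = 0.95
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Blend G with A22 to avoid singularity and invert.

    Returns (G*, G*^-1) with G* = weight*G + (1-weight)*A22.
    """
    if G.values.shape != A22.values.shape:
        raise ValueError("G and A22 dimension mismatch")
    if not np.array_equal(G.labels, A22.labels):
        raise ValueError("G and A22 must share the same animal ordering")
    Gb = weight * G.values + (1.0 - weight) * A22.values
    try:
        Ginv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"blended G numerically singular: {exc}") from exc
    blend = RelationshipMatrix(labels=G.labels, values=Gb, kind="Gblend")
    inv = RelationshipMatrix(labels=G.labels, values=Ginv, kind="Ginv")
    return blend, inv


def build_Hinv(
    Ainv: RelationshipMatrix,
    A22inv: RelationshipMatrix,
    Ginv: RelationshipMatrix,
    genotyped_index: np.ndarray,
) -> RelationshipMatrix:
    """Single-step joint inverse: H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1].

    ``genotyped_index`` maps the rows of G/A22 into the ordering of A; the
    correction touches only the genotyped block.
    """
    idx = np.asarray(genotyped_index, dtype=np.intp)
    n = Ainv.values.shape[0]
    if len(idx) and (idx.min() < 0 or idx.max() >= n):
        raise IndexError("genotyped_index out of range for A inverse")
    if Ginv.values.shape[0] != len(idx) or A22inv.values.shape[0] != len(idx):
        raise ValueError("Ginv/A22inv dimension does not match genotyped_index")
    H = Ainv.values.copy()
    if len(idx):
        H[np.ix_(idx, idx)] += Ginv.values - A22inv.values
    return RelationshipMatrix(labels=Ainv.labels, values=H, kind="Hinv")
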