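"""Pleiotropic-region detection and candidate-gene flagging.

Per trait, 1-Mb windows are classified as associated (explaining more than
1% of the direct additive genetic variance), suggestive (0.9-1%) or
background.  Overlapping associated windows from two or more traits merge
into a pleiotropic region; an associated window overlapping only a
suggestive-band window of a *different* trait yields a suggestive call.
Region bounds report the intersection of the member windows (the union is
retained alongside).

Within a region, markers are ranked by their largest standardized absolute
effect across the member traits; genes containing one of the top 20 markers
are flagged as candidate pleiotropic genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CandidateGeneHit, PleiotropyCall, SnpEffectSet

__all__ = [
    "classify_windows",
    "find_pleiotropic_regions",
    "flag_candidate_genes",
    "calls_table",
]

ASSOCIATED = "associated"
SUGGESTIVE_BAND = "suggestive_band"
BACKGROUND = "background"


def classify_windows(
    windows: pd.DataFrame,
    assoc_thr: float = 1.0,
    sugg_band: tuple[float, float] = (0.9, 1.0),
) -> pd.DataFrame:
    """Partition one trait's windows into associated / suggestive / background.

    Associated: pct_var > ``assoc_thr``; suggestive band:
    ``sugg_band[0]`` <= pct_var <= ``sugg_band[1]``; everything else is
    background.  Returns a copy with a ``status`` column.
    """
    if assoc_thr < 0 or sugg_band[0] < 0:
        raise ValueError("thresholds must be non-negative")
    out = windows.copy()
    pct = out["pct_var"].to_numpy()
    status = np.full(len(out), BACKGROUND, dtype=object)
    status[(pct >= sugg_band[0]) & (pct <= sugg_band[1])] = SUGGESTIVE_BAND
    status[pct > assoc_thr] = ASSOCIATED
    out["status"] = status
    return out


def _cluster_intervals(df: pd.DataFrame) -> list[np.ndarray]:
    """Group overlapping closed intervals (rows of df) transitively."""
    order = df.sort_values(["start_bp", "end_bp"]).index.to_numpy()
    clusters: list[list] = []
    cur: list = []
    cur_end = -1
    for i in order:
        s, e = df.at[i, "start_bp"], df.at[i, "end_bp"]
        if cur and s <= cur_end:
            cur.append(i)
            cur_end = max(cur_end, e)
        else:
            if cur:
                clusters.append(cur)
            cur = [i]
            cur_end = e
    if cur:
        clusters.append(cur)
    return [np.array(c) for c in clusters]


def find_pleiotropic_regions(
    classified: dict[str, pd.DataFrame],
    assoc_thr: float = 1.0,
) -> list[PleiotropyCall]:
    """Cross-trait overlap calls from per-trait classified window sets.

    ``classified`` maps trait name to a window frame carrying a ``status``
    column (see :func:`classify_windows`).  Windows classified as background
    never participate.  A cluster of mutually overlapping windows yields

    - ``pleiotropic`` when >= 2 distinct traits contribute associated
      windows;
    - ``suggestive`` when >= 1 trait contributes an associated window and a
      *different* trait contributes a suggestive-band window.

    Region bounds are the intersection of the contributing windows
    (associated only for pleiotropic calls; associated plus suggestive for
    suggestive calls); if a transitive chain leaves the intersection empty,
    the union bounds are reported with a warning.
    """
    if len(classified) < 2:
        raise ValueError("need window results for at least two traits")
    frames = []
    for trait, df in classified.items():
        sel = df[df["status"].isin([ASSOCIATED, SUGGESTIVE_BAND])].copy()
        sel["trait"] = trait
        frames.append(sel)
    pool = pd.concat(frames, ignore_index=True)
    calls: list[PleiotropyCall] = []
    for chrom, grp in pool.groupby("chrom", sort=False):
        for cluster in _cluster_intervals(grp):
            sub = grp.loc[cluster]
            assoc = sub[sub["status"] == ASSOCIATED]
            sugg = sub[sub["status"] == SUGGESTIVE_BAND]
            assoc_traits = set(assoc["trait"])
            sugg_traits = set(sugg["trait"]) - assoc_traits
            if len(assoc_traits) >= 2:
                status = "pleiotropic"
                members = assoc
            elif len(assoc_traits) >= 1 and len(sugg_traits) >= 1:
                status = "suggestive"
                members = sub[sub["trait"].isin(assoc_traits | sugg_traits)]
            else:
                continue
            rs = int(members["start_bp"].max())
            re_ = int(members["end_bp"].min())
            us = int(sub["start_bp"].min())
            ue = int(sub["end_bp"].max())
            if rs > re_:
                warnings.warn(
                    f"empty window intersection on {chrom}; reporting union bounds",
                    stacklevel=2,
                )
                rs, re_ = us, ue
            traits = {
                t: float(members.loc[members["trait"] == t, "pct_var"].max())
                for t in members["trait"].unique()
            }
            calls.append(
                PleiotropyCall(
                    chrom=str(chrom),
                    region_start=rs,
                    region_end=re_,
                    union_start=us,
                    union_end=ue,
                    traits=traits,
                    status=status,
                )
            )
    return calls


def flag_candidate_genes(
    region: PleiotropyCall,
    effects: dict[str, SnpEffectSet],
    map_df: pd.DataFrame,
    annotation: pd.DataFrame,
    top_n: int = 20,
) -> list[CandidateGeneHit]:
    """Flag genes containing the region's top-ranked markers.

    Markers inside the region are ranked by the largest |a|/sd(a) across the
    region's member traits (per-trait standardization puts the effects on a
    common scale); ties at the cutoff break by bp position.  Only the top
    ``top_n`` markers are considered, and a hit is emitted only when a
    marker's position falls inside a gene span.  ``annotation`` needs
    columns gene_id / chrom / start / end (1-based closed).
    """
    member_traits = [t for t in region.traits if t in effects]
    if not member_traits:
        raise ValueError("no effect sets supplied for the region's member traits")
    chrom_genes = annotation[annotation["chrom"].astype(str) == str(region.chrom)]
    if len(chrom_genes) == 0:
        warnings.warn(
            f"no annotation for chromosome {region.chrom}; region skipped",
            stacklevel=2,
        )
        return []

    m = map_df
    inreg = (
        (m["chrom"].astype(str) == str(region.chrom))
        & (m["bp"] >= region.region_start)
        & (m["bp"] <= region.region_end)
    )
    idx = np.flatnonzero(inreg.to_numpy())
    if len(idx) == 0:
        return []

    scores = np.zeros(len(idx))
    for t in member_traits:
        a = effects[t].effects
        sd = float(np.std(a))
        if sd == 0:
            continue
        scores = np.maximum(scores, np.abs(a[idx]) / sd)

    bp = m["bp"].to_numpy()[idx]
    order = np.lexsort((bp, -scores))  # score desc, bp asc on ties
    top = idx[order[:top_n]]
    ranks = {j: r + 1 for r, j in enumerate(top)}

    marker_ids = m["marker"].to_numpy()
    hits: list[CandidateGeneHit] = []
    for j in top:
        pos = int(m["bp"].iloc[j])
        inside = chrom_genes[(chrom_genes["start"] <= pos) & (chrom_genes["end"] >= pos)]
        for g in inside.itertuples(index=False):
            hits.append(
                CandidateGeneHit(
                    gene_id=str(g.gene_id),
                    marker_id=str(marker_ids[j]),
                    chrom=str(region.chrom),
                    bp=pos,
                    traits=list(member_traits),
                    rank=ranks[j],
                )
            )
    return hits


def calls_table(calls: list[PleiotropyCall]) -> pd.DataFrame:
    """Long-format table of region calls (one row per region x trait)."""
    rows = []
    for c in calls:
        for t, pct in sorted(c.traits.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "chrom": c.chrom,
                    "region_start": c.region_start,
                    "region_end": c.region_end,
                    "union_start": c.union_start,
                    "union_end": c.union_end,
                    "status": c.status,
                    "trait": t,
                    "pct_var": pct,
                }
            )
    return pd.DataFrame(rows)
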