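"""Shared containers for the single-step GBLUP / ssGWAS pipeline.

Tabular data (pedigrees, phenotypes, marker maps, window results) travel as
pandas DataFrames with documented schemas; composite numerical objects get
small dataclasses so that downstream code can rely on field names instead of
positional tuples.

Pedigree schema (one row per animal, parents listed before offspring):
    animal : int        unique positive id
    sire   : int        sire id, 0 = unknown
    dam    : int        dam id, 0 = unknown
    birth_year : int
    breed_fraction : float in [0, 1]   proportion of the second founder breed

Phenotype table schema (one row per animal):
    animal_id, birth_year, age_at_slaughter, plus one column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the eight analysis traits, in the conventional reporting order
TRAIT_NAMES = ["MARB", "REA", "TEND", "JUIC", "FLAV", "COLOR", "TEXT", "FIRM"]

#: traits whose model omits the age-at-slaughter covariate
NO_AGE_TRAITS = frozenset({"TEND", "FLAV"})


@dataclass
class GenotypeMatrix:
    """Animals x markers additive genotype codes with a physical marker map.

    ``codes`` is a float array with values in {0, 1, 2} and NaN for missing
    calls.  ``marker_map`` has columns ``marker``, ``chrom``, ``bp`` (1-based)
    and is sorted by (chrom, bp) in the same column order as ``codes``.
    """

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    marker_map: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.codes.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        if len(self.marker_map) != len(self.marker_ids):
            raise ValueError("marker_map length does not match marker count")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the marker positions in ``keep``."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            marker_ids=self.marker_ids[keep],
            marker_map=self.marker_map.iloc[keep].reset_index(drop=True),
            codes=self.codes[:, keep],
        )


@dataclass
class TrueGeneticState:
    """Simulation ground truth: breeding values, QTL effects and (co)variances."""

    breeding_values: np.ndarray  # animals x traits
    qtl_effects: np.ndarray  # markers x traits allele-substitution effects
    T_true: np.ndarray  # traits x traits additive covariance
    R_true: np.ndarray  # traits x traits residual covariance
    trait_names: list[str] = field(default_factory=list)


@dataclass
class RelationshipMatrix:
    """A symmetric relationship (or inverse-relationship) matrix with labels.

    ``kind`` is one of ``A, Ainv, A22, A22inv, G, Gblend, Ginv, H, Hinv``;
    kinds ending in ``inv`` hold the inverse of the named matrix.
    """

    labels: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square and match labels")

    @property
    def is_inverse(self) -> bool:
        return self.kind.endswith("inv")

    def dense(self) -> np.ndarray:
        """The (non-inverse) relationship matrix, inverting if needed."""
        if self.is_inverse:
            return np.linalg.inv(self.values)
        return self.values

    def inverse(self) -> np.ndarray:
        """The inverse relationship matrix, inverting if needed."""
        if self.is_inverse:
            return self.values
        return np.linalg.inv(self.values)


@dataclass
class ModelDesign:
    """One trait's mixed-model design: response, fixed effects and incidence.

    One record per animal; ``animal_ids`` links each record to the pedigree.
    ``X`` has one dummy column per birth-year class (no intercept) followed by
    centered covariates.
    """

    trait: str
    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    animal_ids: np.ndarray
    conditional: bool = False

    @property
    def n_records(self) -> int:
        return len(self.y)

    def animal_index(self, labels: np.ndarray) -> np.ndarray:
        """Positions of each record's animal within ``labels`` (pedigree order)."""
        pos = {a: i for i, a in enumerate(np.asarray(labels))}
        try:
            return np.array([pos[a] for a in self.animal_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"animal {exc} has a record but is not in the pedigree")


@dataclass
class VarComp:
    """Variance-component estimates from AI-REML.

    Single-trait fits fill ``sigma_u2``/``sigma_e2``/``h2``; bivariate fits
    fill the 2x2 ``T`` and ``R`` plus the derived correlations.  Standard
    errors come from the inverse average-information matrix (delta method for
    ratios) and are approximate.
    """

    sigma_u2: float | None = None
    sigma_e2: float | None = None
    T: np.ndarray | None = None
    R: np.ndarray | None = None
    h2: float | None = None
    r_g: float | None = None
    r_p: float | None = None
    se: dict = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = False
    n_rounds: int = 0
    traits: list[str] = field(default_factory=list)


@dataclass
class MMESolution:
    """Solutions of the mixed-model equations for one trait."""

    fixed_effects: np.ndarray
    fixed_names: list[str]
    u: np.ndarray  # breeding values for every animal in pedigree order
    labels: np.ndarray
    singular_fixed: bool = False


@dataclass
class SnpEffectSet:
    """Backsolved marker effects and their variance weights for one iteration."""

    trait: str
    effects: np.ndarray  # per-marker allele substitution effects (trait units)
    weights: np.ndarray  # per-marker variance weights used to produce them
    iteration: int
    sigma_u2_used: float

    @property
    def n_markers(self) -> int:
        return len(self.effects)


@dataclass
class PleiotropyCall:
    """A cross-trait genomic region call.

    ``traits`` maps each member trait to the largest window variance share
    (percent of additive genetic variance) it contributed to the region.
    ``region_start/region_end`` are the intersection of the member windows;
    ``union_start/union_end`` retain the full extent.
    """

    chrom: str
    region_start: int
    region_end: int
    union_start: int
    union_end: int
    traits: dict[str, float]
    status: str  # "pleiotropic" or "suggestive"


@dataclass
class CandidateGeneHit:
    """A gene flagged by a top-ranked marker inside a pleiotropic region."""

    gene_id: str
    marker_id: str
    chrom: str
    bp: int
    traits: list[str]
    rank: int
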