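"""Readers and writers for the pipeline's file formats.

Dialects
--------
- Pedigree TSV: columns ``animal, sire, dam, birth_year, breed_fraction``;
  0 denotes an unknown parent.
- Marker map TSV: ``marker, chrom, bp`` with 1-based positions; windows are
  closed intervals.
- Phenotype TSV: ``animal_id, birth_year, age_at_slaughter`` plus one column
  per trait; empty cells are missing.
- PLINK-RAW: header ``FID IID PAT MAT SEX PHENOTYPE`` then one ``<marker>_A``
  column per SNP with additive codes 0/1/2 or NA (the marker map travels in
  the separate map TSV).
- VCF: minimal VCF 4.2 with GT fields only; read through cyvcf2 with 0/1/2
  genotype coding (missing -> NaN).
- Gene annotation: BED (0-based half-open, converted to 1-based closed on
  read) or GFF3 ``gene`` features with an ID/gene_id attribute.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, TrueGeneticState

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_marker_map",
    "write_marker_map",
    "read_phenotypes",
    "write_phenotypes",
    "read_plink_raw",
    "write_plink_raw",
    "read_vcf",
    "write_vcf",
    "read_bed_genes",
    "read_gff3_genes",
    "read_annotation",
    "write_truth",
    "write_matrix",
]


# -- pedigree ---------------------------------------------------------------

def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t")
    required = {"animal", "sire", "dam", "birth_year", "breed_fraction"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return ped


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, sep="\t", index=False)


# -- marker map -------------------------------------------------------------

def read_marker_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"marker", "chrom", "bp"}
    if required - set(m.columns):
        raise ValueError(f"marker map missing columns: {sorted(required - set(m.columns))}")
    return m


def write_marker_map(map_df: pd.DataFrame, path) -> None:
    map_df.to_csv(path, sep="\t", index=False)


# -- phenotypes -------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index=False, na_rep="")


# -- PLINK-RAW --------------------------------------------------------------

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(geno: GenotypeMatrix, path, ped: pd.DataFrame | None = None) -> None:
    """Write additive-coded genotypes as a PLINK .raw table."""
    snp_cols = [f"{m}_A" for m in geno.marker_ids]
    out = pd.DataFrame(geno.codes, columns=snp_cols)
    parents = {}
    if ped is not None:
        parents = {
            r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)
        }
    out.insert(0, "FID", 1)
    out.insert(1, "IID", geno.animal_ids)
    out.insert(2, "PAT", [parents.get(a, (0, 0))[0] for a in geno.animal_ids])
    out.insert(3, "MAT", [parents.get(a, (0, 0))[1] for a in geno.animal_ids])
    out.insert(4, "SEX", 0)
    out.insert(5, "PHENOTYPE", -9)
    with open(path, "w") as fh:
        fh.write(" ".join(_RAW_META + snp_cols) + "\n")
        for _, row in out.iterrows():
            vals = []
            for c in _RAW_META:
                vals.append(str(row[c]))
            for c in snp_cols:
                v = row[c]
                vals.append("NA" if pd.isna(v) else str(int(v)))
            fh.write(" ".join(vals) + "\n")


def read_plink_raw(path, map_df: pd.DataFrame) -> GenotypeMatrix:
    """Read a PLINK .raw file; marker order must match ``map_df``."""
    raw = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    snp_cols = [c for c in raw.columns if c not in _RAW_META]
    markers = [c.rsplit("_", 1)[0] for c in snp_cols]
    expected = list(map_df["marker"].astype(str))
    if markers != expected:
        raise ValueError("PLINK-RAW marker columns do not match the marker map")
    return GenotypeMatrix(
        animal_ids=raw["IID"].to_numpy(),
        marker_ids=np.array(markers),
        marker_map=map_df.reset_index(drop=True),
        codes=raw[snp_cols].to_numpy(dtype=float),
    )


# -- VCF --------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields (REF=A, ALT=B placeholders)."""
    samples = [str(a) for a in geno.animal_ids]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.marker_map["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in enumerate(geno.marker_map.itertuples(index=False)):
            gts = [
                "./." if np.isnan(v) else gt_map[float(v)] for v in geno.codes[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.bp}\t{row.marker}\tA\tB\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT-coded genotypes from a VCF through cyvcf2 (ALT allele counted)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    rows = []
    codes_cols = []
    for var in vcf:
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS)))
        g = var.gt_types.astype(float)  # 0/1/2, 3 = unknown with gts012
        g[g == 3] = np.nan
        codes_cols.append(g)
    map_df = pd.DataFrame(rows, columns=["marker", "chrom", "bp"])
    codes = np.column_stack(codes_cols) if codes_cols else np.empty((len(samples), 0))
    # try to restore integer animal ids
    try:
        animal_ids = samples.astype(int)
    except ValueError:
        animal_ids = samples
    return GenotypeMatrix(
        animal_ids=animal_ids,
        marker_ids=map_df["marker"].to_numpy(),
        marker_map=map_df,
        codes=codes,
    )


# -- annotation -------------------------------------------------------------

def read_bed_genes(path) -> pd.DataFrame:
    """BED gene intervals -> DataFrame(gene_id, chrom, start, end), 1-based closed."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    out = pd.DataFrame(
        {
            "gene_id": bed["gene_id"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(int) + 1,  # 0-based half-open -> 1-based closed
            "end": bed["end"].astype(int),
        }
    )
    return out


def _gff_attr(attrs: str, keys=("gene_id", "ID", "Name")) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            return fields[k]
    return attrs.strip()


def read_gff3_genes(path) -> pd.DataFrame:
    """GFF3 gene features -> DataFrame(gene_id, chrom, start, end), 1-based closed."""
    gff = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        dtype={0: str},
    )
    genes = gff[gff["type"] == "gene"]
    return pd.DataFrame(
        {
            "gene_id": genes["attrs"].map(_gff_attr).to_numpy(),
            "chrom": genes["chrom"].astype(str).to_numpy(),
            "start": genes["start"].astype(int).to_numpy(),
            "end": genes["end"].astype(int).to_numpy(),
        }
    )


def read_annotation(path) -> pd.DataFrame:
    """Dispatch on extension: .bed -> BED, .gff/.gff3 -> GFF3 gene features."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed_genes(path)
    if suffix in (".gff", ".gff3"):
        return read_gff3_genes(path)
    raise ValueError(f"unrecognized annotation format: {suffix}")


# -- misc -------------------------------------------------------------------

def write_truth(state: TrueGeneticState, animal_ids: np.ndarray, path_prefix) -> None:
    """Write simulation truth: breeding values and QTL effects as TSVs."""
    bv = pd.DataFrame(state.breeding_values, columns=state.trait_names)
    bv.insert(0, "animal_id", animal_ids)
    bv.to_csv(f"{path_prefix}_breeding_values.tsv", sep="\t", index=False)
    if state.qtl_effects.size:
        q = pd.DataFrame(state.qtl_effects, columns=state.trait_names)
        q.insert(0, "marker_index", np.arange(len(q)))
        q = q.loc[(q[state.trait_names] != 0).any(axis=1)]
        q.to_csv(f"{path_prefix}_qtl_effects.tsv", sep="\t", index=False)


def write_matrix(rel, path) -> None:
    """Whitespace TSV with a header row of animal ids."""
    df = pd.DataFrame(rel.values, columns=[str(a) for a in rel.labels])
    df.to_csv(path, sep="\t", index=False)
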