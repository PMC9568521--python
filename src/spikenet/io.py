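"""Core data containers and TSV/GFF3 readers for the spike time-course pipeline.

The substrate of every analysis stage is a gene-by-sample expression matrix
(raw counts or TPM) together with a sample sheet mapping each sample to a
developmental stage (Waddington scale labels such as W1, W2, W3.0, W3.25,
W3.5 for the spike time course, or free-form tissue labels for reference
atlases) and a replicate index.  Gene annotations carry transcription-factor
family labels, confidence class and genomic coordinates used by the
enrichment and QTL-proximity stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "StageDesign",
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_gff3_genes",
    "counts_to_tpm",
    "stage_means",
    "well_expressed",
]

#: one million — the TPM column total
TPM_SCALE = 1e6


@dataclass
class StageDesign:
    """Ordered stage labels and the replicate count at each stage.

    Paired and variance-based tests require at least two replicates per
    stage; the time course itself needs at least two stages.
    """

    stages: list[str]
    replicates: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a stage design needs >= 2 stages")
        for s in self.stages:
            if self.replicates.get(s, 0) < 1:
                raise ValueError(f"stage {s!r} has no replicates")

    @classmethod
    def uniform(cls, stages: list[str], n_replicates: int) -> "StageDesign":
        return cls(list(stages), {s: n_replicates for s in stages})

    @property
    def n_samples(self) -> int:
        return sum(self.replicates[s] for s in self.stages)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample stage metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.  All
        entries must be finite and non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``stage`` and
        ``replicate``; must cover exactly the columns of ``values``.
    unit
        ``"counts"`` or ``"tpm"``.  TPM matrices are checked to sum to 1e6
        per sample within relative tolerance 1e-6.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "tpm"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicated sample id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"sample(s) missing from sample sheet: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.unit == "tpm":
            sums = arr.sum(axis=0)
            if (sums <= 0).any():
                bad = self.values.columns[int(np.argmax(sums <= 0))]
                raise ValueError(f"all-zero TPM column {bad!r}")
            if not np.allclose(sums, TPM_SCALE, rtol=1e-6):
                raise ValueError("TPM columns must each sum to 1e6 (rtol 1e-6)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance (sample-sheet) order."""
        return list(dict.fromkeys(self.sample_meta["stage"]))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta, self.unit)

    def design(self) -> StageDesign:
        counts = self.sample_meta.groupby("stage", sort=False).size().to_dict()
        return StageDesign(self.stages, counts)


@dataclass
class GeneAnnotation:
    """Per-gene annotation table: TF family, confidence class, coordinates.

    Coordinates are 1-based inclusive (GFF convention).  ``length_bp``
    defaults to the gene span ``end - start + 1`` when no explicit length
    column is supplied; an explicit column always takes precedence.
    """

    table: pd.DataFrame
    tf_families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "gene_id":
            if "gene_id" in t.columns:
                t = t.set_index("gene_id")
            else:
                raise ValueError("annotation table needs a gene_id column or index")
        if t.index.duplicated().any():
            raise ValueError("duplicated gene id in annotation")
        for col in ("chromosome", "start", "end"):
            if col not in t.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        if (t["start"] > t["end"]).any():
            raise ValueError("annotation has start > end")
        if "length_bp" not in t.columns:
            t = t.assign(length_bp=t["end"] - t["start"] + 1)
        if (t["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if "tf_family" not in t.columns:
            t = t.assign(tf_family=pd.Series(pd.NA, index=t.index))
        if "confidence" not in t.columns:
            t = t.assign(confidence="high")
        if self.tf_families:
            fams = set(self.tf_families)
            bad = set(t["tf_family"].dropna()) - fams
            if bad:
                raise ValueError(f"unknown TF families: {sorted(bad)}")
        self.table = t

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self, genes) -> pd.Series:
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise KeyError(f"gene(s) without annotation/length: {missing[:5]}")
        return self.table.loc[list(genes), "length_bp"]

    def tf_genes(self) -> set[str]:
        return set(self.table.index[self.table["tf_family"].notna()])

    def family_members(self, family: str) -> set[str]:
        return set(self.table.index[self.table["tf_family"] == family])


def read_expression(path, sample_sheet_path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus its sample sheet.

    The matrix TSV has a header row of sample ids and gene ids in the
    first column.  The sheet is a TSV with columns ``sample_id``,
    ``stage`` and ``replicate`` and must cover every sample in the
    matrix.  Samples are reordered by (stage, replicate) following the
    sheet's stage order.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    bad = values.columns[[not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]]
    if len(bad):
        col = bad[0]
        row = values.index[pd.to_numeric(values[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str, "stage": str})
    sheet = sheet.set_index("sample_id")
    missing = [s for s in values.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"sample(s) missing from sample sheet: {missing}")
    sheet = sheet.loc[list(values.columns)]
    stage_rank = {s: i for i, s in enumerate(dict.fromkeys(sheet["stage"]))}
    order = sorted(values.columns, key=lambda s: (stage_rank[sheet.loc[s, "stage"]], sheet.loc[s, "replicate"]))
    return ExpressionMatrix(values[order], sheet.loc[order])


def write_expression(em: ExpressionMatrix, path, sample_sheet_path=None) -> None:
    """Write matrix (and optionally its sheet) as TSV with full float precision."""
    em.values.to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")
    if sample_sheet_path is not None:
        em.sample_meta.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_annotation(path, tf_families=None) -> GeneAnnotation:
    """Read a gene annotation TSV (gene_id, chromosome, start, end, ...)."""
    t = pd.read_csv(path, sep="\t")
    return GeneAnnotation(t, list(tf_families or []))


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff3_genes(path) -> GeneAnnotation:
    """Extract gene records from a GFF3 file into a GeneAnnotation.

    Only rows whose feature type is ``gene`` are retained; the gene id is
    taken from the ``ID=`` attribute.  Coordinates stay 1-based inclusive.
    """
    t = pd.read_csv(path, sep="\t", comment="#", header=None, names=_GFF_COLS)
    genes = t[t["type"] == "gene"].copy()
    ids = genes["attributes"].str.extract(r"(?:^|;)ID=([^;]+)")[0]
    if ids.isna().any():
        raise ValueError("gene record without an ID attribute")
    out = pd.DataFrame(
        {
            "gene_id": ids.values,
            "chromosome": genes["seqid"].values,
            "start": genes["start"].astype(int).values,
            "end": genes["end"].astype(int).values,
        }
    )
    return GeneAnnotation(out)


def counts_to_tpm(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Convert raw counts to Transcripts Per Million.

    Per sample, ``TPM_g = 1e6 * (c_g / l_g) / sum_j (c_j / l_j)`` with
    ``l_g`` the gene length in bp.  Every gene must have a length; a
    sample with all-zero counts has no defined TPM and is a hard error.
    """
    if counts.unit != "counts":
        raise ValueError("input matrix is not tagged as counts")
    lengths = annotation.lengths(counts.gene_ids).to_numpy(dtype=float)
    c = counts.values.to_numpy(dtype=float)
    rate = c / lengths[:, None]
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        bad = counts.sample_ids[int(np.argmax(denom <= 0))]
        raise ValueError(f"sample {bad!r} has all-zero counts; TPM undefined")
    tpm = TPM_SCALE * rate / denom
    values = pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values, counts.sample_meta, unit="tpm")


def stage_means(em: ExpressionMatrix) -> pd.DataFrame:
    """Mean expression per stage (genes x stages, stage order preserved)."""
    groups = em.sample_meta["stage"]
    out = em.values.T.groupby(groups, sort=False).mean().T
    return out[em.stages]


def well_expressed(em: ExpressionMatrix, threshold: float = 1.0) -> pd.Index:
    """Genes with stage-mean expression above ``threshold`` in >= 1 stage.

    With TPM input and the default threshold this is the time course's
    'well-expressed' filter (stage mean > 1 TPM somewhere); 'expressed'
    (> 0 in any sample) is the threshold-0 special case on raw values.
    """
    sm = stage_means(em)
    return em.values.index[(sm > threshold).any(axis=1)]
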