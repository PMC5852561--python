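"""Readers and writers for the plain-text formats the pipeline touches.

All tabular formats are TSV (UTF-8, tab-separated, header row).  Expression
matrices default to genes-as-rows; annotation is GENCODE-style GTF parsed at
the gene-feature level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotationSet,
    SubtypeLabels,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: GENCODE biotypes treated as protein-coding for the ``is_coding`` flag.
CODING_BIOTYPES = frozenset({"protein_coding"})


def read_expression(path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read an expression TSV into an :class:`ExpressionMatrix`.

    The first column holds gene IDs (or sample IDs when
    ``orientation='samples_by_genes'``), the header row the other axis.
    Rows containing any missing value are dropped with a logged count, so
    genes with incomplete measurements never reach the models.

    Raises
    ------
    ValidationError
        On duplicate IDs or non-numeric cells (the offending location is
        named in the message).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation: {orientation!r}")

    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs in {path}: {dups}")

    # empty cells are missing data; anything else non-numeric is an error
    missing_mask = df.isna() | (df == "")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing_mask
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValidationError(
            f"non-numeric cell at gene {gene!r}, sample {sample!r} in {path}"
        )

    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d gene(s) with missing data: %s",
            int(incomplete.sum()),
            list(numeric.index[incomplete][:10]),
        )
    numeric = numeric[~incomplete].astype(float)
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_annotation(path) -> GeneAnnotationSet:
    """Parse gene features from a GENCODE-style GTF into annotation records.

    Only ``gene`` features are consumed; ``length_bp = end - start + 1``
    (1-based inclusive GTF coordinates).  A gene feature lacking a
    ``gene_type`` attribute is kept with ``biotype='unknown'``.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise ValidationError(f"malformed GTF line {lineno} in {path}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                raise ValidationError(f"GTF line {lineno}: gene feature without gene_id")
            biotypes = feat.attributes.get("gene_type") or feat.attributes.get("gene_biotype")
            biotype = biotypes[0] if biotypes else "unknown"
            records.append(
                {
                    "gene_id": gene_ids[0],
                    "biotype": biotype,
                    "chrom": feat.chrom,
                    "start": int(feat.start),
                    "end": int(feat.end),
                    "length_bp": int(feat.end) - int(feat.start) + 1,
                    "is_coding": biotype in CODING_BIOTYPES,
                }
            )
    if not records:
        logger.warning("no gene features found in %s", path)
        return GeneAnnotationSet()
    return GeneAnnotationSet(pd.DataFrame.from_records(records))


def read_labels(path, vocabulary=None) -> SubtypeLabels:
    """Read a two-column TSV (sample_id, subtype) into SubtypeLabels.

    Empty or missing labels become UNLABELED.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_col, label_col = df.columns[:2]
    labels = df.set_index(sample_col)[label_col].fillna("UNLABELED").replace("", "UNLABELED")
    kwargs = {"vocabulary": tuple(vocabulary)} if vocabulary is not None else {}
    return SubtypeLabels(labels, **kwargs)


def write_labels(labels: SubtypeLabels, path) -> None:
    labels.labels.rename("subtype").to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path) -> ClinicalTable:
    """Read the clinical covariate/endpoint TSV (first column sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in df.columns:
        if col.endswith("_time") or col.endswith("_event") or col == "age":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample_id")


def write_selection_report(result, path) -> None:
    """Serialize a SelectionResult's final gene table to TSV.

    Columns: gene_id, iteration, subtype_attribution (semicolon-joined in
    the fixed subtype order), weight_magnitude.
    """
    rows = []
    weights = result.weight_magnitudes or {}
    for gene in sorted(result.iteration1_genes):
        iteration = 2 if gene in result.iteration2_genes else 1
        attributed = result.subtype_attribution.get(gene, set())
        rows.append(
            {
                "gene_id": gene,
                "iteration": iteration,
                "subtype_attribution": ";".join(sorted(attributed)),
                "weight_magnitude": weights.get(gene, np.nan),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "iteration", "subtype_attribution", "weight_magnitude"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_selection_report(path) -> pd.DataFrame:
    """Read back a selection report written by :func:`write_selection_report`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "subtype_attribution": str})
    df["subtype_attribution"] = df["subtype_attribution"].fillna("")
    return df


def write_curve(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False, float_format="%.10g")
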