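"""In-memory containers for the pipeline.

Expression data follows the genes-as-rows convention common in bulk
transcriptomics (each row one gene, each column one sample); estimators
transpose to the samples-by-features orientation scikit-learn expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Breast-cancer intrinsic subtypes in the fixed class order used for
#: one-vs-rest tie-breaking throughout the package.
SUBTYPES = ("Basal", "Her2", "LumA", "LumB")

UNLABELED = "UNLABELED"


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with identifier bookkeeping.

    Values are arbitrary non-negative expression units; genes and samples
    carry unique string identifiers.
    """

    data: pd.DataFrame  # index = gene_ids, columns = sample_ids

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if values.size and (values < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def X(self) -> np.ndarray:
        """Samples x genes float array (scikit-learn orientation)."""
        return self.data.to_numpy(dtype=float).T

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass
class SubtypeLabels:
    """Mapping sample -> intrinsic subtype (or UNLABELED)."""

    labels: pd.Series  # index = sample_id, values = label strings
    vocabulary: tuple = SUBTYPES

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in labels")
        allowed = set(self.vocabulary) | {UNLABELED}
        bad = set(self.labels.unique()) - allowed
        if bad:
            raise ValidationError(f"labels outside vocabulary: {sorted(bad)}")

    @property
    def labeled_mask(self) -> pd.Series:
        return self.labels != UNLABELED

    def labeled_samples(self) -> list[str]:
        return list(self.labels.index[self.labeled_mask])

    def unlabeled_samples(self) -> list[str]:
        return list(self.labels.index[~self.labeled_mask])

    def y(self, sample_ids) -> np.ndarray:
        return self.labels.loc[list(sample_ids)].to_numpy()


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival endpoints.

    Expected columns (missing values as empty string / NaN): os_time,
    os_event, rfs_time, rfs_event, age, race, treatment, stage, histology,
    er, pr, her2.  Times are in days; event flags are 0/1.
    """

    data: pd.DataFrame  # index = sample_id

    SURVIVAL_COLS = ("os_time", "os_event", "rfs_time", "rfs_event")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in clinical table")
        for col in self.SURVIVAL_COLS:
            if col not in self.data.columns:
                continue
            vals = pd.to_numeric(self.data[col], errors="coerce").dropna()
            if col.endswith("_time") and (vals < 0).any():
                raise ValidationError(f"negative values in {col}")
            if col.endswith("_event") and not vals.isin([0, 1]).all():
                raise ValidationError(f"{col} must be 0/1")

    def endpoint(self, which: str) -> tuple[pd.Series, pd.Series]:
        """Return (time, event) for endpoint 'OS' or 'RFS', complete cases."""
        which = which.upper()
        if which not in ("OS", "RFS"):
            raise ValueError("endpoint must be 'OS' or 'RFS'")
        prefix = "os" if which == "OS" else "rfs"
        time = pd.to_numeric(self.data[f"{prefix}_time"], errors="coerce")
        event = pd.to_numeric(self.data[f"{prefix}_event"], errors="coerce")
        keep = time.notna() & event.notna()
        return time[keep], event[keep].astype(int)


@dataclass
class GeneAnnotationSet:
    """Gene-level annotation records (one per gene_id).

    Columns: gene_id, biotype, chrom, start, end, length_bp, is_coding.
    Coordinates are 1-based inclusive (GTF convention); length_bp is the
    annotated gene-feature span end - start + 1.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene_id", "biotype", "chrom", "start", "end", "length_bp", "is_coding")

    def __post_init__(self) -> None:
        if self.data.empty:
            self.data = pd.DataFrame(columns=list(self.REQUIRED))
            return
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene IDs in annotation")
        if (self.data["end"] < self.data["start"]).any():
            raise ValidationError("annotation has end < start")
        if (self.data["length_bp"] < 1).any():
            raise ValidationError("annotation has length_bp < 1")

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self) -> pd.DataFrame:
        return self.data.set_index("gene_id")
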