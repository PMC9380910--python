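"""Reading, validation and normalisation of OTU count tables.

The canonical in-memory orientation is features x samples (the classic OTU
table convention); every downstream stage that follows the scikit-learn
convention (samples x features) transposes explicitly at its boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint", "group")
OPTIONAL_METADATA_COLUMNS = ("subtype", "calprotectin")

DEFAULT_PSEUDO = 1e-6
DEFAULT_MIN_READS = 10_000


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class CountTable:
    """Integer OTU counts, features x samples."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTU ids x {len(self.sample_ids)} sample ids"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")

    @property
    def n_features(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class AbundanceTable:
    """Relative abundances plus an optional transformed view (features x samples)."""

    otu_ids: list[str]
    sample_ids: list[str]
    rel: np.ndarray
    transformed: np.ndarray | None = None
    transform_kind: Literal["log10_pseudo", "clr", None] = None

    def __post_init__(self) -> None:
        self.rel = np.asarray(self.rel, dtype=float)
        col_sums = self.rel.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValidationError("relative-abundance columns must sum to 1")
        if self.transformed is not None and not np.all(np.isfinite(self.transformed)):
            raise ValidationError("transformed abundances must be finite")


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        if not np.all(np.isfinite(self.table["timepoint"].to_numpy(dtype=float))):
            raise ValidationError("non-finite timepoint in metadata")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self, sample_ids: list[str] | None = None) -> pd.Series:
        s = self.table.set_index("sample_id")["group"]
        return s.loc[sample_ids] if sample_ids is not None else s

    def check_covers(self, count_table: CountTable) -> None:
        """Every counted sample must have a metadata row (silent drops hide bad joins)."""
        missing = set(count_table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} samples present in counts but absent from metadata: "
                f"{sorted(missing)[:5]}..."
            )


def read_count_table(
    path: str | Path,
    orientation: Literal["features_rows", "samples_rows"] = "features_rows",
) -> CountTable:
    """Read a TSV OTU table into canonical features x samples orientation.

    The first column holds row ids and the header holds column ids. With
    ``orientation="samples_rows"`` the file is transposed after reading.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at row '{df.index[bad[0]]}', column '{df.columns[bad[1]]}'"
        )
    if orientation == "samples_rows":
        body = body.T
    elif orientation != "features_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    counts = body.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("counts must be integers")
    return CountTable(
        otu_ids=[str(i) for i in body.index],
        sample_ids=[str(c) for c in body.columns],
        counts=np.round(counts).astype(np.int64),
    )


def write_count_table(t: CountTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleMetadata(df)


def write_metadata(m: SampleMetadata, path: str | Path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def filter_low_depth(t: CountTable, min_reads: int = DEFAULT_MIN_READS) -> CountTable:
    """Drop samples whose read depth is strictly below ``min_reads``.

    A sample with exactly ``min_reads`` reads is kept (strict "<" rule).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = t.depths() >= min_reads
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_depth: removed %d of %d samples", n_removed, t.n_samples)
    if not keep.any():
        raise ValidationError("depth filter removed every sample")
    return CountTable(
        otu_ids=list(t.otu_ids),
        sample_ids=[s for s, k in zip(t.sample_ids, keep) if k],
        counts=t.counts[:, keep],
    )


def to_relative(t: CountTable) -> AbundanceTable:
    """Divide each sample's counts by its total read count."""
    depths = t.depths()
    if np.any(depths == 0):
        bad = [s for s, d in zip(t.sample_ids, depths) if d == 0]
        raise ValidationError(f"zero-depth samples (filter first): {bad}")
    rel = t.counts / depths[np.newaxis, :]
    return AbundanceTable(list(t.otu_ids), list(t.sample_ids), rel)


def log10_pseudo_transform(a: AbundanceTable, pseudo: float = DEFAULT_PSEUDO) -> AbundanceTable:
    """log10(rel + pseudo), elementwise."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    return AbundanceTable(
        a.otu_ids, a.sample_ids, a.rel,
        transformed=np.log10(a.rel + pseudo),
        transform_kind="log10_pseudo",
    )


def clr_transform(a: AbundanceTable, pseudo: float = DEFAULT_PSEUDO) -> AbundanceTable:
    """Centered log-ratio: per sample, ln(rel+pseudo) minus its feature mean."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    logs = np.log(a.rel + pseudo)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return AbundanceTable(a.otu_ids, a.sample_ids, a.rel, transformed=clr, transform_kind="clr")


def write_abundance_table(a: AbundanceTable, path: str | Path, view: str = "transformed") -> None:
    m = a.transformed if view == "transformed" else a.rel
    if m is None:
        raise ValueError("no transformed view; apply a transform first")
    pd.DataFrame(m, index=a.otu_ids, columns=a.sample_ids).to_csv(
        path, sep="\t", index_label="otu_id", float_format="%.10g"
    )
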