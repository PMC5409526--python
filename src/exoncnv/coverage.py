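"""Per-target read counting and the coverage matrix.

The unit of analysis throughout the package is the targets x samples matrix
of read counts.  Counts are individual reads (not fragments): primary,
non-duplicate, non-supplementary alignments with mapping quality >= a
threshold (default 20) whose aligned span overlaps the target by at least
one base.  A read overlapping two targets increments both — overlapping
capture targets are counted independently.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .targets import TargetRegion, TargetSet

__all__ = [
    "CoverageMatrix",
    "count_reads",
    "count_pool",
    "read_coverage_tsv",
    "write_coverage_tsv",
]

KEY_COLUMNS = ["chrom", "start", "end", "gene"]


class CoverageMatrix:
    """Targets x samples matrix of non-negative integer read counts."""

    def __init__(
        self,
        targets: TargetSet,
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape != (len(targets), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(targets)} targets x {len(sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        ids = [str(s) for s in sample_ids]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        self.targets = targets
        self.sample_ids: list[str] = ids
        self.counts = counts.astype(np.int64, copy=False)
        self._index = {s: j for j, s in enumerate(ids)}

    @property
    def n_targets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def with_count(
        self, target_index: int, sample_id: str, value: int
    ) -> "CoverageMatrix":
        """Copy of the matrix with a single cell replaced."""
        if not 0 <= target_index < self.n_targets:
            raise IndexError(f"target index {target_index} out of range")
        if value < 0:
            raise ValueError("count must be non-negative")
        counts = self.counts.copy()
        counts[target_index, self.sample_index(sample_id)] = value
        return CoverageMatrix(self.targets, self.sample_ids, counts)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CoverageMatrix":
        cols = [self.sample_index(s) for s in sample_ids]
        return CoverageMatrix(self.targets, list(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        df = self.targets.to_frame().drop(columns=["custom_number"])
        for j, s in enumerate(self.sample_ids):
            df[s] = self.counts[:, j]
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageMatrix):
            return NotImplemented
        return (
            self.targets == other.targets
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def count_reads(
    alignments: str | Path | pysam.AlignmentFile,
    targets: TargetSet,
    min_mapq: int = 20,
) -> np.ndarray:
    """Count qualifying reads per target for one sample.

    The alignment file must be coordinate-sorted and indexed.  A target on a
    chromosome absent from the file gets count 0 with a warning.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if not af.has_index():
            raise ValueError(
                f"alignment file {af.filename!r} has no index; "
                "coordinate-sort and index it first"
            )
        refs = set(af.references)
        out = np.zeros(len(targets), dtype=np.int64)
        warned: set[str] = set()
        for i, t in enumerate(targets):
            if t.chrom not in refs:
                if t.chrom not in warned:
                    warnings.warn(
                        f"chromosome {t.chrom!r} not present in alignment file; "
                        "affected targets get count 0"
                    )
                    warned.add(t.chrom)
                continue
            n = 0
            for read in af.fetch(t.chrom, t.start, t.end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                n += 1
            out[i] = n
        return out
    finally:
        if own:
            af.close()


def count_pool(
    bam_paths: Iterable[str | Path],
    targets: TargetSet,
    min_mapq: int = 20,
    sample_ids: Sequence[str] | None = None,
) -> CoverageMatrix:
    """Count reads per target for a pool of BAM files.

    Sample ids default to the file basenames without extension.
    """
    paths = [Path(p) for p in bam_paths]
    if sample_ids is None:
        sample_ids = [p.stem for p in paths]
    cols = [count_reads(p, targets, min_mapq=min_mapq) for p in paths]
    return CoverageMatrix(targets, list(sample_ids), np.column_stack(cols))


def write_coverage_tsv(matrix: CoverageMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageMatrix:
    """Read a coverage matrix TSV (chrom, start, end, gene, then one column
    per sample).  Duplicate sample columns and non-integer or negative counts
    are rejected."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = [c for c in header if c not in KEY_COLUMNS]
    if len(set(sample_cols)) != len(sample_cols):
        dupes = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicated sample columns {dupes}")
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing key columns {missing}")
    regions = [
        TargetRegion(
            str(row.chrom),
            int(row.start),
            int(row.end),
            "" if pd.isna(row.gene) else str(row.gene),
        )
        for row in df.itertuples(index=False)
    ]
    targets = TargetSet(regions)
    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        values = df[col].to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError(f"{path}: non-integer counts in column {col!r}")
        counts[:, j] = values
    if (counts < 0).any():
        raise ValueError(f"{path}: negative counts")
    # Re-align rows to the sorted/de-duplicated target order (first
    # occurrence wins for duplicated intervals).
    key_to_row: dict[tuple[str, int, int], int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        key = (str(row.chrom), int(row.start), int(row.end))
        key_to_row.setdefault(key, i)
    counts = counts[[key_to_row[t.key] for t in targets]]
    return CoverageMatrix(targets, sample_cols, counts)
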