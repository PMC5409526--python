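"""Panel target definitions.

A targeted capture panel is described by a BED file of exon-level intervals,
optionally refined by a user annotation file that attaches gene symbols and
the exon numbering conventional for each transcript.  The ordered list of
targets defines the state sequence of the copy-number HMM, so ordering and
de-duplication are part of the contract, not cosmetics.

Coordinates follow the BED convention internally (0-based, half-open);
reported calls use 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TargetRegion",
    "TargetSet",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
    "annotate_targets",
]


@dataclass(frozen=True)
class TargetRegion:
    """One capture target (typically a single exon).

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.  ``gene`` may be
    empty; ``custom_number`` is the transcript-direction exon number from the
    annotation file, if supplied.
    """

    chrom: str
    start: int
    end: int
    gene: str = ""
    custom_number: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


class TargetSet:
    """Ordered, de-duplicated collection of targets.

    Targets are sorted by (chrom, start, end); this order is the exon order
    the HMM walks.  Overlapping targets are allowed (capture panels tile
    exons); exact duplicates are dropped.
    """

    def __init__(self, regions: Iterable[TargetRegion]):
        ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        seen: set[TargetRegion] = set()
        uniq: list[TargetRegion] = []
        for r in ordered:
            if r not in seen:
                seen.add(r)
                uniq.append(r)
        if not uniq:
            raise ValueError("TargetSet requires at least one region")
        self._regions: tuple[TargetRegion, ...] = tuple(uniq)

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self._regions)

    def __getitem__(self, i: int) -> TargetRegion:
        return self._regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetSet):
            return NotImplemented
        return self._regions == other._regions

    def __repr__(self) -> str:
        return f"TargetSet({len(self)} targets)"

    @property
    def regions(self) -> tuple[TargetRegion, ...]:
        return self._regions

    @property
    def chroms(self) -> np.ndarray:
        return np.array([r.chrom for r in self._regions])

    @property
    def starts(self) -> np.ndarray:
        return np.array([r.start for r in self._regions], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([r.end for r in self._regions], dtype=np.int64)

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self._regions]

    def gaps(self) -> np.ndarray:
        """Inter-target distances in bp, length ``len(self) - 1``.

        The gap between consecutive targets on the same chromosome is
        ``next.start - prev.end`` clamped at 0 (overlapping targets);
        chromosome changes are infinite, which makes adjacent targets
        independent in the HMM.
        """
        out = np.empty(max(len(self) - 1, 0), dtype=float)
        for i in range(len(self) - 1):
            a, b = self._regions[i], self._regions[i + 1]
            out[i] = max(b.start - a.end, 0) if a.chrom == b.chrom else np.inf
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self._regions],
                "start": self.starts,
                "end": self.ends,
                "gene": self.genes,
                "custom_number": [r.custom_number for r in self._regions],
            }
        )


def read_bed(path: str | Path) -> TargetSet:
    """Parse a BED file (>= 3 tab-separated columns) into a :class:`TargetSet`.

    The optional 4th column is stored as the gene symbol.  Lines starting
    with ``#``, ``track`` or ``browser`` and blank lines are skipped.
    Malformed lines raise :class:`ValueError` naming the line number.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            gene = parts[3].strip() if len(parts) > 3 else ""
            try:
                regions.append(TargetRegion(parts[0], start, end, gene))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not regions:
        raise ValueError(f"{path}: no target regions found")
    return TargetSet(regions)


def write_bed(targets: TargetSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in targets:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene", "custom_number"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a target annotation TSV (chrom, start, end, gene, custom_number)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation file lacks columns {missing}")
    return df[ANNOTATION_COLUMNS]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def annotate_targets(targets: TargetSet, annotation: pd.DataFrame) -> TargetSet:
    """Attach gene symbols and custom exon numbers to matching targets.

    Matching is exact on (chrom, start, end); unmatched targets are kept
    unchanged.
    """
    lookup: dict[tuple[str, int, int], tuple[str, int | None]] = {}
    for row in annotation.itertuples(index=False):
        num = None if pd.isna(row.custom_number) else int(row.custom_number)
        lookup[(str(row.chrom), int(row.start), int(row.end))] = (
            str(row.gene),
            num,
        )
    out = []
    for r in targets:
        if r.key in lookup:
            gene, num = lookup[r.key]
            out.append(replace(r, gene=gene, custom_number=num))
        else:
            out.append(r)
    return TargetSet(out)
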