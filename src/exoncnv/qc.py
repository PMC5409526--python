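"""Quality-control flags for samples and targets.

Negative CNV reports are only safe when the data could have shown a CNV.
Two checks guard that: a sample whose best inter-sample correlation is low
has no adequate reference and its calls (and non-calls) are suspect; a
target whose median coverage across the pool is low carries too little
signal.  Flags annotate results — they never suppress calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .reference import ReferenceSelection

__all__ = ["QCThresholds", "QCReport", "flag_samples", "flag_targets", "build_report"]


@dataclass(frozen=True)
class QCThresholds:
    """min_correlation: lowest acceptable best-candidate correlation per
    sample; min_coverage: lowest acceptable median per-target count."""

    min_correlation: float = 0.98
    min_coverage: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_correlation <= 1.0:
            raise ValueError(
                f"min_correlation must be in (0, 1], got {self.min_correlation}"
            )
        if self.min_coverage < 0:
            raise ValueError(f"min_coverage must be >= 0, got {self.min_coverage}")


@dataclass
class QCReport:
    """Per-sample and per-target QC tables for one run."""

    samples: pd.DataFrame  # sample, max_correlation, n_comp, status
    targets: pd.DataFrame  # chrom, start, end, gene, median_count, status


def flag_samples(
    selections: Iterable[ReferenceSelection] | Mapping[str, ReferenceSelection],
    thresholds: QCThresholds,
) -> pd.DataFrame:
    """One row per sample; fail iff max_correlation < min_correlation."""
    if isinstance(selections, Mapping):
        selections = selections.values()
    rows = []
    for sel in selections:
        ok = sel.max_correlation >= thresholds.min_correlation
        rows.append(
            {
                "sample": sel.test_id,
                "max_correlation": sel.max_correlation,
                "n_comp": sel.n_comp,
                "status": "pass" if ok else "fail",
            }
        )
    return pd.DataFrame(rows, columns=["sample", "max_correlation", "n_comp", "status"])


def flag_targets(matrix: CoverageMatrix, thresholds: QCThresholds) -> pd.DataFrame:
    """One row per target; fail iff median count across samples < min_coverage.

    The median of an even number of samples is the mean of the central pair,
    and a median exactly equal to the threshold passes.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    medians = np.median(matrix.counts, axis=1)
    rows = []
    for i, t in enumerate(matrix.targets):
        ok = medians[i] >= thresholds.min_coverage
        rows.append(
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "gene": t.gene,
                "median_count": medians[i],
                "status": "pass" if ok else "fail",
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "median_count", "status"]
    )


def build_report(
    selections: Iterable[ReferenceSelection] | Mapping[str, ReferenceSelection],
    matrix: CoverageMatrix,
    thresholds: QCThresholds,
) -> QCReport:
    return QCReport(
        samples=flag_samples(selections, thresholds),
        targets=flag_targets(matrix, thresholds),
    )
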