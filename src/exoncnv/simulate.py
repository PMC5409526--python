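"""In-silico evaluation studies: single-exon spike-ins and depth/pool grids.

Two complementary experiments measure calling performance without any new
sequencing:

* **Spike-in sensitivity.**  In a pool of CNV-negative samples, the coverage
  of one exon in one randomly chosen sample is increased or decreased by 50%
  (emulating a heterozygous duplication or deletion), the caller is re-run on
  the spiked sample, and the fraction of repeats in which a call of the right
  type overlaps the spiked exon is the per-exon sensitivity.

* **Depth x pool-size grid.**  Starting from a pool with known implanted
  CNVs, each replicate draws a sub-pool without replacement, rescales every
  sample to a target depth by binomial read resampling (each read contributes
  Binomial(n, p) times, with n*p the depth ratio and (n, p) chosen to stay
  close to Poisson), calls every pool member, and scores sensitivity and
  specificity against the truth.  Replicate pools containing no CNV samples
  are excluded from the sensitivity average; pools consisting entirely of CNV
  samples are excluded from the specificity average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CNVCall, call_sample
from .coverage import CoverageMatrix
from .hmm import HMMParams
from .qc import QCThresholds

__all__ = [
    "DELETION_FACTOR",
    "DUPLICATION_FACTOR",
    "TruthVariant",
    "SpikeSpec",
    "ResampleSpec",
    "SimulationResult",
    "spike_exon",
    "single_exon_sensitivity",
    "resample_count",
    "resample_matrix",
    "score_calls",
    "grid_experiment",
]

DELETION_FACTOR = 0.5
DUPLICATION_FACTOR = 1.5

_KIND_CODE = {"deletion": 0, "duplication": 1}


@dataclass(frozen=True)
class TruthVariant:
    """A known implanted CNV: sample, inclusive target-index span, kind."""

    sample: str
    first_target: int
    last_target: int
    kind: str  # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODE:
            raise ValueError(f"bad kind {self.kind!r}")
        if self.first_target > self.last_target:
            raise ValueError("first_target must be <= last_target")


@dataclass(frozen=True)
class SpikeSpec:
    """One single-exon spike: which cell to scale and in which direction."""

    sample: str
    target_index: int
    kind: str  # "deletion" (x0.5) | "duplication" (x1.5)
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODE:
            raise ValueError(f"bad kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def factor(self) -> float:
        return DELETION_FACTOR if self.kind == "deletion" else DUPLICATION_FACTOR


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def spike_exon(matrix: CoverageMatrix, spec: SpikeSpec) -> CoverageMatrix:
    """Scale one (target, sample) cell by the spike factor (rounded
    half-away-from-zero); every other cell is untouched."""
    old = int(matrix.counts[spec.target_index, matrix.sample_index(spec.sample)])
    return matrix.with_count(
        spec.target_index, spec.sample, _round_half_away(old * spec.factor)
    )


def single_exon_sensitivity(
    matrix: CoverageMatrix,
    target_indices: Sequence[int],
    kind: str,
    reps: int = 100,
    seed: int = 0,
    params: HMMParams | None = None,
    qc: QCThresholds | None = None,
    max_refs: int = 10,
    factor: float | None = None,
) -> pd.Series:
    """Per-target spike-in sensitivity (%) over ``reps`` random repeats.

    The input pool must be CNV-negative by construction.  Each repeat picks a
    random sample, spikes the target, re-calls that sample, and scores a
    success iff some call of the spiked kind overlaps the spiked target.
    Per-(target, kind) RNG substreams keep exons independent and the whole
    result reproducible for a fixed seed.  ``factor`` overrides the spike
    scale (1.0 gives a null spike whose "sensitivity" is the false-call rate).
    """
    if kind not in _KIND_CODE:
        raise ValueError(f"bad kind {kind!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out = {}
    for t in target_indices:
        if not 0 <= t < matrix.n_targets:
            raise IndexError(f"target index {t} out of range")
        rng = np.random.default_rng([seed, _KIND_CODE[kind], int(t)])
        hits = 0
        for _ in range(reps):
            sid = matrix.sample_ids[rng.integers(matrix.n_samples)]
            spec = SpikeSpec(sample=sid, target_index=int(t), kind=kind)
            spiked = matrix
            if factor is None:
                spiked = spike_exon(matrix, spec)
            elif factor != 1.0:
                old = int(matrix.counts[t, matrix.sample_index(sid)])
                spiked = matrix.with_count(t, sid, _round_half_away(old * factor))
            calls, _ = call_sample(
                spiked, sid, params=params, qc=qc, max_refs=max_refs
            )
            if any(c.cnv_type == kind and c.overlaps_target(t) for c in calls):
                hits += 1
        out[int(t)] = 100.0 * hits / reps
    return pd.Series(out, name=f"{kind}_sensitivity_pct")


@dataclass(frozen=True)
class ResampleSpec:
    """Binomial read-resampling parameters.

    Each original read contributes Binomial(n, p) reads to the resampled
    data, with ``n * p`` equal to the depth ratio ``factor``.  For
    downsampling (factor <= 1) the choice (n=1, p=factor) is exact Poisson
    thinning; for upsampling n = ceil(10 * factor) keeps the variance within
    10% of the mean, the closest binomial approximation to Poisson coverage.
    """

    factor: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        if abs(self.n * self.p - self.factor) > 1e-9:
            raise ValueError(
                f"n*p = {self.n * self.p} must equal factor = {self.factor}"
            )

    @classmethod
    def from_factor(cls, factor: float) -> "ResampleSpec":
        if factor <= 0:
            raise ValueError("factor must be positive")
        if factor <= 1.0:
            return cls(factor=factor, n=1, p=factor)
        n = math.ceil(10.0 * factor)
        return cls(factor=factor, n=n, p=factor / n)


def resample_count(count: int, spec: ResampleSpec, rng: np.random.Generator) -> int:
    """Sum of ``count`` iid Binomial(n, p) read-replication draws, realised
    as a single Binomial(n * count, p) draw.  Expectation = factor * count."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return 0
    return int(rng.binomial(spec.n * count, spec.p))


def resample_matrix(
    matrix: CoverageMatrix, spec: ResampleSpec, rng: np.random.Generator
) -> CoverageMatrix:
    """Apply read resampling to every cell of the matrix."""
    counts = rng.binomial(spec.n * matrix.counts, spec.p)
    return CoverageMatrix(matrix.targets, matrix.sample_ids, counts)


def score_calls(
    calls_by_sample: Mapping[str, Sequence[CNVCall]],
    truth: Iterable[TruthVariant],
) -> tuple[float | None, float | None]:
    """(sensitivity %, specificity %) of a set of calls against known truth.

    A truth variant is detected iff some call in that sample of the same kind
    overlaps its target span by >=1 target.  Specificity is the fraction of
    CNV-negative samples (samples in ``calls_by_sample`` with no truth
    variant) that received zero calls.  Either value is ``None`` when its
    denominator is empty.
    """
    truth = list(truth)
    truth_samples = {t.sample for t in truth}
    detected = 0
    for tv in truth:
        calls = calls_by_sample.get(tv.sample, ())
        if any(
            c.cnv_type == tv.kind
            and c.first_target <= tv.last_target
            and c.last_target >= tv.first_target
            for c in calls
        ):
            detected += 1
    sensitivity = 100.0 * detected / len(truth) if truth else None
    negatives = [s for s in calls_by_sample if s not in truth_samples]
    if negatives:
        clean = sum(1 for s in negatives if not calls_by_sample[s])
        specificity = 100.0 * clean / len(negatives)
    else:
        specificity = None
    return sensitivity, specificity


@dataclass
class SimulationResult:
    """Aggregated grid-study outcome; ``grid`` has one row per cell with mean
    and range of sensitivity/specificity plus exclusion counts."""

    grid: pd.DataFrame
    replicates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


GRID_COLUMNS = [
    "pool_size",
    "coverage_factor",
    "n_reps",
    "mean_sensitivity",
    "min_sensitivity",
    "max_sensitivity",
    "mean_specificity",
    "min_specificity",
    "max_specificity",
    "n_excluded_sensitivity",
    "n_excluded_specificity",
]


def grid_experiment(
    matrix: CoverageMatrix,
    truth: Sequence[TruthVariant],
    pool_sizes: Sequence[int],
    coverage_factors: Sequence[float],
    reps: int = 50,
    seed: int = 0,
    params: HMMParams | None = None,
    qc: QCThresholds | None = None,
    max_refs: int = 10,
) -> SimulationResult:
    """Sensitivity/specificity over a (pool size) x (depth factor) grid.

    ``coverage_factors`` are depth ratios relative to the native depth of
    ``matrix``.  Each replicate draws its pool without replacement, resamples
    every cell, calls every pool member, and scores against the truth
    restricted to pool members.  Bit-identical for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for size in pool_sizes:
        if size > matrix.n_samples:
            raise ValueError(
                f"pool size {size} exceeds available samples ({matrix.n_samples})"
            )
        if size < 2:
            raise ValueError("pool size must be >= 2")
    truth_by_sample: dict[str, list[TruthVariant]] = {}
    for tv in truth:
        truth_by_sample.setdefault(tv.sample, []).append(tv)

    grid_rows = []
    rep_rows = []
    for ci, (size, factor) in enumerate(
        (s, f) for s in pool_sizes for f in coverage_factors
    ):
        spec = ResampleSpec.from_factor(float(factor))
        sens_values: list[float] = []
        spec_values: list[float] = []
        n_excl_sens = 0
        n_excl_spec = 0
        for rep in range(reps):
            rng = np.random.default_rng([seed, ci, rep])
            pool_ids = list(
                rng.choice(matrix.sample_ids, size=size, replace=False)
            )
            pool = matrix.subset_samples(pool_ids)
            if spec.n != 1 or spec.p != 1.0:
                pool = resample_matrix(pool, spec, rng)
            calls_by_sample = {
                sid: call_sample(pool, sid, params=params, qc=qc, max_refs=max_refs)[0]
                for sid in pool_ids
            }
            pool_truth = [
                tv for sid in pool_ids for tv in truth_by_sample.get(sid, [])
            ]
            sens, spc = score_calls(calls_by_sample, pool_truth)
            if sens is None:
                n_excl_sens += 1
            else:
                sens_values.append(sens)
            if spc is None:
                n_excl_spec += 1
            else:
                spec_values.append(spc)
            rep_rows.append(
                {
                    "pool_size": size,
                    "coverage_factor": factor,
                    "replicate": rep,
                    "sensitivity": sens,
                    "specificity": spc,
                }
            )
        grid_rows.append(
            {
                "pool_size": size,
                "coverage_factor": factor,
                "n_reps": reps,
                "mean_sensitivity": float(np.mean(sens_values)) if sens_values else None,
                "min_sensitivity": float(np.min(sens_values)) if sens_values else None,
                "max_sensitivity": float(np.max(sens_values)) if sens_values else None,
                "mean_specificity": float(np.mean(spec_values)) if spec_values else None,
                "min_specificity": float(np.min(spec_values)) if spec_values else None,
                "max_specificity": float(np.max(spec_values)) if spec_values else None,
                "n_excluded_sensitivity": n_excl_sens,
                "n_excluded_specificity": n_excl_spec,
            }
        )
    return SimulationResult(
        grid=pd.DataFrame(grid_rows, columns=GRID_COLUMNS),
        replicates=pd.DataFrame(rep_rows),
    )
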