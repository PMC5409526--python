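"""Synthetic panels and coverage pools with the structure the caller assumes.

Real exon-capture coverage has three dominant layers of variation: per-target
probe efficiency (shared across samples in a pool — the reason inter-sample
correlation is high and reference normalisation works), per-sample library
size, and counting noise slightly wider than Poisson.  The generator draws

    count[i, j] ~ NegBin(mean = depth * e_i * s_j * c_ij / 2, size)

with probe efficiencies ``e_i`` log-normal (shared across samples), library
factors ``s_j`` log-normal, and implanted copy numbers ``c_ij`` in {1, 2, 3}.
Defaults emulate a two-gene BRCA-like panel (23 + 26 exons across ~80-85 kb
each) at ~1000 reads/target, the order of per-exon depth of a 48-plex
capture pool on a rapid-run flow cell.  Depths and spreads are documented
assumptions, not measurements of any particular kit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .simulate import TruthVariant
from .targets import TargetRegion, TargetSet

__all__ = [
    "GeneModel",
    "PanelModel",
    "Implant",
    "SimSpec",
    "make_panel",
    "simulate_pool",
    "evaluation_implants",
    "write_truth_tsv",
    "read_truth_tsv",
]


@dataclass(frozen=True)
class GeneModel:
    """One synthetic gene: exon count and total genomic span."""

    name: str
    chrom: str
    strand: str  # "+" or "-"
    n_exons: int
    span_bp: int

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


#: Two BRCA-like genes on separate synthetic chromosomes; the second is on
#: the reverse strand so custom exon numbers descend with coordinate.
DEFAULT_GENES = (
    GeneModel("GENEA", "chrS1", "+", 23, 80_000),
    GeneModel("GENEB", "chrS2", "-", 26, 85_000),
)


@dataclass(frozen=True)
class PanelModel:
    genes: tuple[GeneModel, ...] = DEFAULT_GENES


@dataclass(frozen=True)
class Implant:
    """A CNV to implant: gene + inclusive custom-exon range in one sample."""

    sample_index: int
    gene: str
    exon_first: int
    exon_last: int
    kind: str  # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.exon_first > self.exon_last:
            raise ValueError("exon_first must be <= exon_last")


@dataclass(frozen=True)
class SimSpec:
    """Pool-level generation parameters (see module docstring for the model)."""

    n_samples: int = 48
    mean_depth: float = 1000.0
    probe_log_sd: float = 0.6
    library_log_sd: float = 0.1
    dispersion: float | None = 500.0  # negative-binomial size; None = Poisson
    implants: tuple[Implant, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.probe_log_sd < 0 or self.library_log_sd < 0:
            raise ValueError("log-sd parameters must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")


def make_panel(
    model: PanelModel | None = None, seed: int = 0
) -> tuple[TargetSet, pd.DataFrame]:
    """Deterministic synthetic panel: TargetSet plus annotation table.

    Exon lengths are drawn in 120-400 bp and intron gaps fill the stated gene
    span.  Custom exon numbers follow the transcript direction, so they
    descend with genomic coordinate on reverse-strand genes.
    """
    model = model or PanelModel()
    rng = np.random.default_rng(seed)
    regions: list[TargetRegion] = []
    for gene in model.genes:
        lengths = rng.integers(120, 401, size=gene.n_exons)
        intron_total = gene.span_bp - int(lengths.sum())
        if gene.n_exons > 1:
            if intron_total < gene.n_exons - 1:
                raise ValueError(f"{gene.name}: span too small for exon count")
            w = rng.random(gene.n_exons - 1)
            gaps = np.maximum((w / w.sum() * intron_total).astype(int), 1)
        else:
            gaps = np.zeros(0, dtype=int)
        pos = 1_000_000
        numbers = (
            range(1, gene.n_exons + 1)
            if gene.strand == "+"
            else range(gene.n_exons, 0, -1)
        )
        for i, number in enumerate(numbers):
            start = pos
            end = start + int(lengths[i])
            regions.append(
                TargetRegion(gene.chrom, start, end, gene.name, int(number))
            )
            pos = end + (int(gaps[i]) if i < len(gaps) else 0)
    targets = TargetSet(regions)
    annotation = targets.to_frame()
    return targets, annotation


def _implant_span(
    targets: TargetSet, implant: Implant
) -> tuple[int, int, list[int]]:
    idx = [
        i
        for i, t in enumerate(targets)
        if t.gene == implant.gene
        and t.custom_number is not None
        and implant.exon_first <= t.custom_number <= implant.exon_last
    ]
    if not idx:
        raise ValueError(
            f"implant matches no targets: {implant.gene} "
            f"exons {implant.exon_first}-{implant.exon_last}"
        )
    return min(idx), max(idx), idx


def simulate_pool(
    spec: SimSpec, targets: TargetSet
) -> tuple[CoverageMatrix, list[TruthVariant]]:
    """Draw a coverage pool and return it with the implant truth list."""
    rng = np.random.default_rng(spec.seed)
    K, J = len(targets), spec.n_samples
    sample_ids = [f"S{j + 1:02d}" for j in range(J)]
    e = rng.lognormal(0.0, spec.probe_log_sd, size=K)
    s = rng.lognormal(0.0, spec.library_log_sd, size=J)
    copy = np.full((K, J), 2.0)
    truth: list[TruthVariant] = []
    for implant in spec.implants:
        if not 0 <= implant.sample_index < J:
            raise ValueError(
                f"implant sample index {implant.sample_index} out of range"
            )
        first, last, idx = _implant_span(targets, implant)
        copy[idx, implant.sample_index] = 1.0 if implant.kind == "deletion" else 3.0
        truth.append(
            TruthVariant(
                sample=sample_ids[implant.sample_index],
                first_target=first,
                last_target=last,
                kind=implant.kind,
            )
        )
    mean = spec.mean_depth * e[:, None] * s[None, :] * copy / 2.0
    if spec.dispersion is None:
        counts = rng.poisson(mean)
    else:
        size = spec.dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    return CoverageMatrix(targets, sample_ids, counts), truth


def evaluation_implants() -> tuple[Implant, ...]:
    """A 16-CNV evaluation mix for a 96-sample pool.

    One CNV per carrier sample, weighted toward deletions and including
    single-exon events of both kinds and multi-exon spans up to a large part
    of a gene — the composition typical of clinical BRCA exon-CNV panels.
    """
    return (
        Implant(0, "GENEA", 5, 8, "duplication"),
        Implant(6, "GENEA", 13, 13, "duplication"),
        Implant(12, "GENEA", 20, 20, "deletion"),
        Implant(18, "GENEA", 1, 12, "deletion"),
        Implant(24, "GENEA", 1, 2, "deletion"),
        Implant(30, "GENEA", 21, 23, "deletion"),
        Implant(36, "GENEA", 8, 13, "deletion"),
        Implant(42, "GENEA", 16, 16, "deletion"),
        Implant(48, "GENEA", 22, 22, "deletion"),
        Implant(54, "GENEA", 20, 22, "deletion"),
        Implant(60, "GENEB", 14, 16, "deletion"),
        Implant(66, "GENEB", 1, 11, "deletion"),
        Implant(72, "GENEB", 1, 2, "deletion"),
        Implant(78, "GENEB", 2, 2, "deletion"),
        Implant(84, "GENEB", 21, 21, "duplication"),
        Implant(90, "GENEB", 21, 24, "deletion"),
    )


def write_truth_tsv(truth: Sequence[TruthVariant], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": tv.sample,
                "first_target": tv.first_target,
                "last_target": tv.last_target,
                "kind": tv.kind,
            }
            for tv in truth
        ],
        columns=["sample", "first_target", "last_target", "kind"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthVariant(
            sample=str(row.sample),
            first_target=int(row.first_target),
            last_target=int(row.last_target),
            kind=str(row.kind),
        )
        for row in df.itertuples(index=False)
    ]
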