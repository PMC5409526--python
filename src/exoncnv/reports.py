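"""Call/QC file writers and static per-call visualisations.

The calls TSV schema (one row per call, header always written):

    sample, correlation, n_comp, cnv_type, n_exons, chrom, start, end,
    gene, custom_first, custom_last, bf, reads_expected, reads_observed,
    reads_ratio

Coordinates are 1-based inclusive.  The per-call figure mirrors the
two-panel layout clinical analysts expect: log-normalised coverage of the
test sample against its reference samples on top, and the observed/expected
ratio with a pointwise 95% interval (beta-binomial quantiles under normal
copy number) below, called targets highlighted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .betabin import BetaBinFit, _PHI_BINOMIAL
from .calling import CNVCall
from .coverage import CoverageMatrix
from .qc import QCReport
from .reference import ReferenceSelection

__all__ = [
    "CALLS_COLUMNS",
    "calls_to_frame",
    "write_calls",
    "write_qc",
    "ratio_interval",
    "plot_call",
]

CALLS_COLUMNS = [
    "sample",
    "correlation",
    "n_comp",
    "cnv_type",
    "n_exons",
    "chrom",
    "start",
    "end",
    "gene",
    "custom_first",
    "custom_last",
    "bf",
    "reads_expected",
    "reads_observed",
    "reads_ratio",
]


def calls_to_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample,
            "correlation": c.correlation,
            "n_comp": c.n_comp,
            "cnv_type": c.cnv_type,
            "n_exons": c.n_exons,
            "chrom": c.chrom,
            "start": c.genomic_start,
            "end": c.genomic_end,
            "gene": ";".join(c.genes),
            "custom_first": c.custom_first,
            "custom_last": c.custom_last,
            "bf": c.bf,
            "reads_expected": c.reads_expected,
            "reads_observed": c.reads_observed,
            "reads_ratio": c.reads_ratio,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)


def write_calls(calls: Sequence[CNVCall], path: str | Path) -> None:
    """Write the calls TSV; a run with no calls yields a header-only file."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_qc(
    report: QCReport, samples_path: str | Path, targets_path: str | Path
) -> None:
    report.samples.to_csv(samples_path, sep="\t", index=False)
    report.targets.to_csv(targets_path, sep="\t", index=False)


def ratio_interval(
    totals: np.ndarray, fit: BetaBinFit, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise interval for observed/expected under normal copy number.

    Quantiles of the fitted beta-binomial at each target's total count,
    divided by the expected count ``n * mu``.  Targets with zero total get a
    degenerate (nan, nan) interval.
    """
    n = np.asarray(totals, dtype=float)
    lo = np.full(n.shape, np.nan)
    hi = np.full(n.shape, np.nan)
    keep = n > 0
    if keep.any():
        alpha = (1.0 - level) / 2.0
        nn = n[keep]
        if fit.phi < _PHI_BINOMIAL:
            dist = stats.binom(nn.astype(int), fit.mu)
        else:
            s = (1.0 - fit.phi) / fit.phi
            dist = stats.betabinom(
                nn.astype(int), fit.mu * s, (1.0 - fit.mu) * s
            )
        expected = nn * fit.mu
        lo[keep] = dist.ppf(alpha) / expected
        hi[keep] = dist.ppf(1.0 - alpha) / expected
    return lo, hi


def plot_call(
    call: CNVCall,
    matrix: CoverageMatrix,
    selection: ReferenceSelection,
    fit: BetaBinFit,
    path: str | Path,
) -> None:
    """Render the two-panel figure for one call and save it to ``path``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if call.sample != selection.test_id:
        raise ValueError("call and selection belong to different samples")
    test = matrix.column(call.sample).astype(float)
    x = np.arange(matrix.n_targets)
    called = (x >= call.first_target) & (x <= call.last_target)

    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(10, 6), sharex=True,
        gridspec_kw={"height_ratios": [1.2, 1.0]},
    )

    # Top: log-normalised coverage (log of count / sample total).
    with np.errstate(divide="ignore"):
        for sid in selection.chosen:
            y = matrix.column(sid).astype(float)
            ax_top.plot(x, np.log(y / y.sum()), color="0.6", lw=0.8, zorder=1)
        ax_top.plot(
            x, np.log(test / test.sum()), color="tab:blue", lw=1.5, zorder=2,
            label=call.sample,
        )
    ax_top.set_ylabel("log normalised coverage")
    ax_top.legend(loc="upper right", fontsize=8)
    title = (
        f"{call.sample}: {call.cnv_type} {call.chrom}:"
        f"{call.genomic_start}-{call.genomic_end} "
        f"({', '.join(call.genes) or 'no gene'}; {call.n_exons} exon(s); "
        f"BF={call.bf:.1f})"
    )
    ax_top.set_title(title, fontsize=10)

    # Bottom: observed/expected ratio with 95% interval under CN2.
    totals = test + selection.ref_counts.astype(float)
    expected = totals * fit.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, test / expected, np.nan)
    lo, hi = ratio_interval(totals, fit)
    ax_bot.fill_between(x, lo, hi, color="0.85", label="95% interval (CN2)")
    ax_bot.axhline(1.0, color="0.4", lw=0.8, ls="--")
    ax_bot.plot(x[~called], ratio[~called], "o", ms=3, color="tab:blue")
    ax_bot.plot(x[called], ratio[called], "o", ms=5, color="tab:red",
                label="called targets")
    ax_bot.set_xlabel("target index (panel order)")
    ax_bot.set_ylabel("observed / expected")
    ax_bot.legend(loc="upper right", fontsize=8)

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
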