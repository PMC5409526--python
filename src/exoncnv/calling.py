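"""End-to-end CNV calling for one sample or a whole pool.

The pipeline per test sample is: select a reference set, fit the
beta-binomial proportion model, evaluate emission log-likelihoods for copy
numbers 1/2/3 at every target, decode the maximum-a-posteriori state path
with the distance-aware HMM, and segment the path into calls.  Each call
carries a log10 Bayes factor (called path vs all-normal over the called
span), observed/expected read counts, and the QC context of the test sample
(best correlation, number of comparison samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .betabin import BetaBinFit, betabin_logpmf
from .coverage import CoverageMatrix
from .hmm import (
    COPY_NUMBERS,
    DELETION,
    NORMAL,
    HMMParams,
    state_mean,
    viterbi,
)
from .qc import QCThresholds
from .reference import ReferenceSelection, select_reference
from .targets import TargetSet

__all__ = ["CNVCall", "emission_matrix", "segment_calls", "call_sample", "call_pool"]

_LN10 = np.log(10.0)


@dataclass
class CNVCall:
    """One called deletion or duplication segment.

    Genomic coordinates are 1-based inclusive.  ``bf`` is the log10
    likelihood ratio of the called copy number vs normal over the span.
    ``correlation`` and ``n_comp`` echo the test sample's reference-selection
    summary so every reported row carries its QC context.
    """

    sample: str
    cnv_type: str  # "deletion" | "duplication"
    first_target: int
    last_target: int
    chrom: str
    genomic_start: int
    genomic_end: int
    n_exons: int
    genes: tuple[str, ...]
    custom_first: int | None
    custom_last: int | None
    bf: float
    reads_observed: int
    reads_expected: int
    reads_ratio: float
    correlation: float
    n_comp: int

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"bad cnv_type {self.cnv_type!r}")
        if self.first_target > self.last_target:
            raise ValueError("first_target must be <= last_target")
        if self.n_exons != self.last_target - self.first_target + 1:
            raise ValueError("n_exons inconsistent with target span")

    def overlaps_target(self, target_index: int) -> bool:
        return self.first_target <= target_index <= self.last_target


def emission_matrix(
    test_counts: np.ndarray,
    ref_counts: np.ndarray,
    fit: BetaBinFit,
) -> np.ndarray:
    """(K, 3) log-likelihood of each test count under copy numbers 1, 2, 3.

    Targets with zero total count are uninformative: all three states get
    log-likelihood 0 there.
    """
    t = np.asarray(test_counts, dtype=float)
    n = t + np.asarray(ref_counts, dtype=float)
    out = np.zeros((t.size, 3))
    keep = n > 0
    if keep.any():
        for j, c in enumerate(COPY_NUMBERS):
            mu_c = state_mean(fit.mu, c)
            out[keep, j] = betabin_logpmf(t[keep], n[keep], mu_c, fit.phi)
    return out


def segment_calls(
    path: np.ndarray,
    targets: TargetSet,
    test_counts: np.ndarray,
    ref_counts: np.ndarray,
    fit: BetaBinFit,
    selection: ReferenceSelection,
    emissions: np.ndarray | None = None,
) -> list[CNVCall]:
    """Turn a decoded state path into maximal per-chromosome call segments."""
    path = np.asarray(path)
    if len(path) != len(targets):
        raise ValueError("path length does not match targets")
    if emissions is None:
        emissions = emission_matrix(test_counts, ref_counts, fit)
    test = np.asarray(test_counts)
    totals = test + np.asarray(ref_counts)
    chroms = targets.chroms

    calls: list[CNVCall] = []
    i = 0
    K = len(path)
    while i < K:
        state = path[i]
        if state == NORMAL:
            i += 1
            continue
        j = i
        while (
            j + 1 < K
            and path[j + 1] == state
            and chroms[j + 1] == chroms[i]
        ):
            j += 1
        span = slice(i, j + 1)
        bf = float((emissions[span, state] - emissions[span, NORMAL]).sum() / _LN10)
        observed = int(test[span].sum())
        expected = int(np.round(totals[span].astype(float) * fit.mu).sum())
        genes = tuple(dict.fromkeys(g for g in targets.genes[span] if g))
        calls.append(
            CNVCall(
                sample=selection.test_id,
                cnv_type="deletion" if state == DELETION else "duplication",
                first_target=i,
                last_target=j,
                chrom=str(chroms[i]),
                genomic_start=int(targets[i].start) + 1,
                genomic_end=int(targets[j].end),
                n_exons=j - i + 1,
                genes=genes,
                custom_first=targets[i].custom_number,
                custom_last=targets[j].custom_number,
                bf=bf,
                reads_observed=observed,
                reads_expected=expected,
                reads_ratio=observed / expected if expected > 0 else float("nan"),
                correlation=selection.max_correlation,
                n_comp=selection.n_comp,
            )
        )
        i = j + 1
    return calls


def call_sample(
    matrix: CoverageMatrix,
    test_id: str,
    params: HMMParams | None = None,
    qc: QCThresholds | None = None,
    max_refs: int = 10,
) -> tuple[list[CNVCall], dict]:
    """Run the full calling pipeline for one test sample.

    Returns the call list and a per-sample QC row (sample, max_correlation,
    n_comp, status).  Deterministic for fixed input.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >=2 samples in the pool to call CNVs")
    params = params or HMMParams()
    qc = qc or QCThresholds()
    try:
        selection, fit = select_reference(matrix, test_id, max_refs=max_refs)
        test = matrix.column(test_id)
        em = emission_matrix(test, selection.ref_counts, fit)
        path = viterbi(em, matrix.targets.gaps(), params)
        calls = segment_calls(
            path, matrix.targets, test, selection.ref_counts, fit, selection,
            emissions=em,
        )
    except ValueError as exc:
        raise ValueError(f"sample {test_id!r}: {exc}") from exc
    qc_row = {
        "sample": test_id,
        "max_correlation": selection.max_correlation,
        "n_comp": selection.n_comp,
        "status": "pass"
        if selection.max_correlation >= qc.min_correlation
        else "fail",
    }
    return calls, qc_row


def call_pool(
    matrix: CoverageMatrix,
    params: HMMParams | None = None,
    qc: QCThresholds | None = None,
    max_refs: int = 10,
) -> tuple[list[CNVCall], "pd.DataFrame"]:
    """Call every sample in the pool against the rest.

    Returns all calls plus the per-sample QC table.
    """
    import pandas as pd

    all_calls: list[CNVCall] = []
    rows = []
    for sid in matrix.sample_ids:
        calls, qc_row = call_sample(matrix, sid, params=params, qc=qc, max_refs=max_refs)
        all_calls.extend(calls)
        rows.append(qc_row)
    return all_calls, pd.DataFrame(
        rows, columns=["sample", "max_correlation", "n_comp", "status"]
    )
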