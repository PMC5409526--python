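import numpy as np
import pytest

from exoncnv import (
    BetaBinFit,
    CoverageMatrix,
    HMMParams,
    Implant,
    SimSpec,
    call_sample,
    segment_calls,
    simulate_pool,
)
from exoncnv.hmm import DELETION, NORMAL
from exoncnv.reference import ReferenceSelection
from exoncnv.targets import TargetRegion, TargetSet


def _selection(test_id, ref_counts):
    return ReferenceSelection(
        test_id=test_id,
        candidate_order=["r"],
        correlations={"r": 0.999},
        chosen=["r"],
        ref_counts=np.asarray(ref_counts),
        n_comp=1,
        max_correlation=0.999,
    )


@pytest.fixture()
def four_targets():
    return TargetSet(
        [TargetRegion("chr1", 100 * i, 100 * i + 50, "G", i + 1) for i in range(4)]
    )


class TestSegmentCalls:
    def test_all_normal_path_gives_no_calls(self, four_targets):
        test = np.full(4, 1000)
        ref = np.full(4, 10_000)
        fit = BetaBinFit(mu=1 / 11, phi=1e-4)
        calls = segment_calls(
            np.full(4, NORMAL), four_targets, test, ref, fit, _selection("t", ref)
        )
        assert calls == []

    def test_run_length_segmentation(self, four_targets):
        test = np.array([1000, 500, 500, 1000])
        ref = np.full(4, 10_000)
        fit = BetaBinFit(mu=1 / 11, phi=1e-4)
        path = np.array([NORMAL, DELETION, DELETION, NORMAL])
        calls = segment_calls(path, four_targets, test, ref, fit, _selection("t", ref))
        assert len(calls) == 1
        c = calls[0]
        assert (c.first_target, c.last_target, c.n_exons) == (1, 2, 2)
        assert c.cnv_type == "deletion"
        assert (c.genomic_start, c.genomic_end) == (101, 250)
        assert (c.custom_first, c.custom_last) == (2, 3)
        assert c.bf > 0

    def test_spiked_halved_exon_reads_ratio(self, four_targets):
        """Against a deep aggregate reference a 1000->500 spike shows the
        arithmetic ratio observed / round(total * mu)."""
        test = np.array([1000, 500, 1000, 1000])
        ref = np.full(4, 20_000)
        mu = 1000 / 21_000
        fit = BetaBinFit(mu=mu, phi=1e-4)
        path = np.array([NORMAL, DELETION, NORMAL, NORMAL])
        calls = segment_calls(path, four_targets, test, ref, fit, _selection("t", ref))
        c = calls[0]
        assert c.reads_observed == 500
        assert c.reads_expected == round((500 + 20_000) * mu)
        assert c.reads_ratio == pytest.approx(500 / round((500 + 20_000) * mu))
        assert c.reads_ratio == pytest.approx(0.5, abs=0.02)

    def test_runs_never_span_chromosomes(self):
        targets = TargetSet(
            [
                TargetRegion("chr1", 100, 150, "A"),
                TargetRegion("chr2", 100, 150, "B"),
            ]
        )
        test = np.array([400, 400])
        ref = np.array([8000, 8000])
        fit = BetaBinFit(mu=0.1, phi=1e-4)
        path = np.array([DELETION, DELETION])
        calls = segment_calls(path, targets, test, ref, fit, _selection("t", ref))
        assert len(calls) == 2
        assert {c.chrom for c in calls} == {"chr1", "chr2"}


class TestCallSample:
    def test_implanted_events_called_with_correct_type_and_span(self, implant_pool):
        matrix, truth = implant_pool
        for tv in truth:
            calls, qc_row = call_sample(matrix, tv.sample)
            match = [
                c
                for c in calls
                if c.cnv_type == tv.kind
                and c.first_target == tv.first_target
                and c.last_target == tv.last_target
            ]
            assert len(match) == 1, f"{tv} -> {calls}"
            c = match[0]
            assert c.bf > 0
            assert (c.reads_ratio < 1) == (tv.kind == "deletion")
            assert set(qc_row) == {"sample", "max_correlation", "n_comp", "status"}

    def test_no_calls_on_unimplanted_samples(self, implant_pool):
        matrix, truth = implant_pool
        carriers = {tv.sample for tv in truth}
        for sid in matrix.sample_ids:
            if sid in carriers:
                continue
            calls, _ = call_sample(matrix, sid)
            assert calls == []

    def test_identical_to_references_gives_no_calls(self):
        targets = TargetSet(
            [TargetRegion("chr1", 100 * i, 100 * i + 50, "G") for i in range(12)]
        )
        rng = np.random.default_rng(0)
        base = rng.integers(200, 2000, size=12)
        counts = np.column_stack([base] * 6)
        m = CoverageMatrix(targets, [f"s{i}" for i in range(6)], counts)
        calls, _ = call_sample(m, "s0")
        assert calls == []

    def test_calls_invariant_under_reference_column_order(self, implant_pool):
        matrix, truth = implant_pool
        tv = truth[0]
        rng = np.random.default_rng(5)
        perm = list(rng.permutation(matrix.sample_ids))
        shuffled = matrix.subset_samples(perm)
        a, _ = call_sample(matrix, tv.sample)
        b, _ = call_sample(shuffled, tv.sample)
        assert [
            (c.cnv_type, c.first_target, c.last_target, c.bf, c.reads_ratio)
            for c in a
        ] == [
            (c.cnv_type, c.first_target, c.last_target, c.bf, c.reads_ratio)
            for c in b
        ]

    def test_deterministic_for_fixed_input(self, implant_pool):
        matrix, truth = implant_pool
        tv = truth[1]
        a, _ = call_sample(matrix, tv.sample)
        b, _ = call_sample(matrix, tv.sample)
        assert [(c.first_target, c.bf) for c in a] == [(c.first_target, c.bf) for c in b]

    def test_needs_at_least_two_samples(self, tiny_targets):
        m = CoverageMatrix(
            tiny_targets, ["only"], np.ones((len(tiny_targets), 1), dtype=int)
        )
        with pytest.raises(ValueError):
            call_sample(m, "only")

    def test_raising_cnv_rate_never_reduces_call_count(self, panel):
        """More permissive transition prior => at least as many segments."""
        for seed in range(10):
            spec = SimSpec(
                n_samples=12,
                seed=100 + seed,
                implants=(
                    Implant(0, "GENEA", 3, 4, "deletion"),
                    Implant(1, "GENEB", 20, 20, "duplication"),
                ),
            )
            matrix, _ = simulate_pool(spec, panel)
            previous = -1
            for q in [0.001, 0.01, 0.05]:
                n = 0
                for sid in ["S01", "S02"]:
                    calls, _ = call_sample(
                        matrix, sid, params=HMMParams(cnv_rate=q)
                    )
                    n += len(calls)
                assert n >= previous
                previous = n
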