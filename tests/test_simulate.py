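import numpy as np
import pytest
from scipy import stats

from exoncnv import (
    Implant,
    ResampleSpec,
    SimSpec,
    SpikeSpec,
    TruthVariant,
    call_sample,
    grid_experiment,
    resample_count,
    resample_matrix,
    score_calls,
    simulate_pool,
    single_exon_sensitivity,
    spike_exon,
)
from exoncnv.calling import CNVCall


def _call(sample, first, last, kind):
    return CNVCall(
        sample=sample,
        cnv_type=kind,
        first_target=first,
        last_target=last,
        chrom="chr1",
        genomic_start=1,
        genomic_end=2,
        n_exons=last - first + 1,
        genes=("G",),
        custom_first=None,
        custom_last=None,
        bf=5.0,
        reads_observed=1,
        reads_expected=2,
        reads_ratio=0.5 if kind == "deletion" else 1.5,
        correlation=0.99,
        n_comp=5,
    )


class TestSpike:
    def test_duplication_adds_exactly_fifty_percent(self, random_matrix):
        m = random_matrix.with_count(1, "B", 1000)
        out = spike_exon(m, SpikeSpec(sample="B", target_index=1, kind="duplication"))
        assert out.counts[1, 1] == 1500

    def test_deletion_removes_exactly_fifty_percent(self, random_matrix):
        m = random_matrix.with_count(1, "B", 1000)
        out = spike_exon(m, SpikeSpec(sample="B", target_index=1, kind="deletion"))
        assert out.counts[1, 1] == 500

    def test_zero_count_is_a_fixed_point(self, random_matrix):
        m = random_matrix.with_count(0, "A", 0)
        for kind in ["deletion", "duplication"]:
            out = spike_exon(m, SpikeSpec(sample="A", target_index=0, kind=kind))
            assert out.counts[0, 0] == 0

    def test_rounding_is_half_away_from_zero(self, random_matrix):
        m = random_matrix.with_count(0, "A", 999)
        out = spike_exon(m, SpikeSpec(sample="A", target_index=0, kind="deletion"))
        assert out.counts[0, 0] == 500  # 499.5 rounds away from zero

    def test_other_cells_untouched(self, random_matrix):
        out = spike_exon(
            random_matrix, SpikeSpec(sample="C", target_index=3, kind="duplication")
        )
        mask = np.ones_like(random_matrix.counts, dtype=bool)
        mask[3, 2] = False
        assert np.array_equal(out.counts[mask], random_matrix.counts[mask])

    def test_bad_kind_rejected(self):
        with pytest.raises(ValueError):
            SpikeSpec(sample="A", target_index=0, kind="inversion")


class TestResample:
    def test_spec_from_factor(self):
        down = ResampleSpec.from_factor(0.5)
        assert (down.n, down.p) == (1, 0.5)
        up = ResampleSpec.from_factor(2.0)
        assert up.n == 20
        assert up.n * up.p == pytest.approx(2.0)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            ResampleSpec(factor=0.5, n=1, p=0.4)

    def test_identity_spec_is_identity(self):
        rng = np.random.default_rng(0)
        spec = ResampleSpec(factor=1.0, n=1, p=1.0)
        for count in [0, 1, 17, 100_000]:
            assert resample_count(count, spec, rng) == count

    def test_zero_count_maps_to_zero(self):
        rng = np.random.default_rng(0)
        assert resample_count(0, ResampleSpec.from_factor(0.3), rng) == 0

    def test_thinning_moments_of_fixed_count(self):
        """Thinning a fixed count n' with (1, p) is Binomial(n', p):
        mean f*count and variance n'*p*(1-p)."""
        rng = np.random.default_rng(1)
        spec = ResampleSpec.from_factor(0.5)
        count = 1_000_000
        draws = np.array([resample_count(count, spec, rng) for _ in range(200)])
        assert draws.mean() == pytest.approx(0.5 * count, rel=0.005)
        assert draws.var() == pytest.approx(count * 0.25, rel=0.2)

    def test_upsampling_moments(self):
        rng = np.random.default_rng(2)
        spec = ResampleSpec.from_factor(2.0)
        count = 100_000
        draws = np.array([resample_count(count, spec, rng) for _ in range(200)])
        assert draws.mean() == pytest.approx(2.0 * count, rel=0.01)
        # variance within 10% of the mean keeps the result Poisson-like
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.12)

    def test_thinning_preserves_poisson_dispersion(self):
        """Index-of-dispersion test not rejected at alpha=0.01 over 1e4 draws
        when the input counts are themselves Poisson."""
        rng = np.random.default_rng(3)
        n_draws = 10_000
        originals = rng.poisson(1000.0, size=n_draws)
        spec = ResampleSpec.from_factor(0.5)
        thinned = rng.binomial(originals, spec.p)
        statistic = (n_draws - 1) * thinned.var(ddof=1) / thinned.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n_draws - 1)
        assert lo < statistic < hi

    def test_resample_matrix_scales_every_cell(self, random_matrix):
        rng = np.random.default_rng(4)
        out = resample_matrix(random_matrix, ResampleSpec.from_factor(0.4), rng)
        assert out.counts.shape == random_matrix.counts.shape
        assert (out.counts <= random_matrix.counts).all()


class TestScoreCalls:
    def test_perfect_calls_score_hundred(self):
        truth = [TruthVariant("s1", 2, 4, "deletion")]
        calls = {"s1": [_call("s1", 2, 4, "deletion")], "s2": []}
        assert score_calls(calls, truth) == (100.0, 100.0)

    def test_wrong_type_is_not_detected(self):
        truth = [TruthVariant("s1", 2, 4, "deletion")]
        calls = {"s1": [_call("s1", 2, 4, "duplication")], "s2": []}
        sens, spec = score_calls(calls, truth)
        assert sens == 0.0

    def test_single_target_overlap_suffices(self):
        truth = [TruthVariant("s1", 2, 6, "deletion")]
        calls = {"s1": [_call("s1", 6, 8, "deletion")]}
        sens, _ = score_calls(calls, truth)
        assert sens == 100.0

    def test_one_spurious_among_three_negatives(self):
        truth = [TruthVariant("s0", 0, 0, "deletion")]
        calls = {
            "s0": [_call("s0", 0, 0, "deletion")],
            "n1": [],
            "n2": [_call("n2", 5, 5, "duplication")],
            "n3": [],
        }
        sens, spec = score_calls(calls, truth)
        assert sens == 100.0
        assert spec == pytest.approx(100 * 2 / 3)

    def test_empty_truth_reports_absent_sensitivity(self):
        sens, spec = score_calls({"a": []}, [])
        assert sens is None
        assert spec == 100.0


class TestSingleExonSensitivity:
    def test_same_seed_reproduces_results(self, clean_pool):
        a = single_exon_sensitivity(clean_pool, [3, 11], "deletion", reps=4, seed=9)
        b = single_exon_sensitivity(clean_pool, [3, 11], "deletion", reps=4, seed=9)
        assert a.equals(b)

    def test_high_coverage_deletion_fully_detected(self, clean_pool):
        sens = single_exon_sensitivity(clean_pool, [10], "deletion", reps=10, seed=1)
        assert sens.loc[10] == 100.0

    def test_null_spike_sensitivity_is_false_call_rate(self, clean_pool):
        sens = single_exon_sensitivity(
            clean_pool, [10], "deletion", reps=10, seed=1, factor=1.0
        )
        assert sens.loc[10] <= 10.0

    def test_sensitivity_nondecreasing_in_coverage(self, panel):
        depths = [120.0, 700.0, 3000.0]
        values = []
        for depth in depths:
            matrix, _ = simulate_pool(
                SimSpec(n_samples=20, mean_depth=depth, seed=6), panel
            )
            sens = single_exon_sensitivity(
                matrix, [20], "duplication", reps=20, seed=2
            )
            values.append(sens.loc[20])
        assert values[0] <= values[1] <= values[2]

    def test_rejects_bad_reps(self, clean_pool):
        with pytest.raises(ValueError):
            single_exon_sensitivity(clean_pool, [0], "deletion", reps=0, seed=0)


@pytest.fixture(scope="module")
def small_pool(panel):
    spec = SimSpec(
        n_samples=10,
        seed=21,
        implants=(
            Implant(0, "GENEA", 4, 6, "deletion"),
            Implant(1, "GENEB", 9, 9, "duplication"),
        ),
    )
    return simulate_pool(spec, panel)


class TestGridExperiment:
    def test_fixed_seed_gives_identical_results(self, small_pool):
        matrix, truth = small_pool
        kwargs = dict(pool_sizes=[6], coverage_factors=[0.8], reps=2, seed=13)
        a = grid_experiment(matrix, truth, **kwargs)
        b = grid_experiment(matrix, truth, **kwargs)
        assert a.grid.equals(b.grid)
        assert a.replicates.equals(b.replicates)

    def test_identity_cell_matches_direct_evaluation(self, small_pool):
        """factor 1 with the whole pool must reproduce un-resampled calling."""
        matrix, truth = small_pool
        res = grid_experiment(
            matrix, truth, pool_sizes=[10], coverage_factors=[1.0], reps=1, seed=0
        )
        direct = {
            sid: call_sample(matrix, sid)[0] for sid in matrix.sample_ids
        }
        want_sens, want_spec = score_calls(direct, truth)
        row = res.grid.iloc[0]
        assert row["mean_sensitivity"] == want_sens
        assert row["mean_specificity"] == want_spec

    def test_truth_free_pools_excluded_from_sensitivity(self, small_pool):
        matrix, truth = small_pool
        res = grid_experiment(
            matrix, truth, pool_sizes=[3], coverage_factors=[1.0], reps=12, seed=3
        )
        row = res.grid.iloc[0]
        # with 2 carriers among 10 samples, some 3-sample pools carry no CNV
        assert row["n_excluded_sensitivity"] > 0
        reps = res.replicates
        included = reps["sensitivity"].notna().sum()
        assert included + row["n_excluded_sensitivity"] == 12

    def test_oversized_pool_rejected(self, small_pool):
        matrix, truth = small_pool
        with pytest.raises(ValueError):
            grid_experiment(
                matrix, truth, pool_sizes=[11], coverage_factors=[1.0], reps=1, seed=0
            )
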