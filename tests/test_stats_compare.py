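import numpy as np
import pytest
from scipy import stats as spstats

from mcomeda import (
    ConditionMatrix,
    Signal,
    aggregate_by_condition,
    edasymp,
    friedman,
    lilliefors,
    wilcoxon_pairwise_bonferroni,
    wilcoxon_signed_rank,
)
from oracles import friedman_bruteforce, wilcoxon_enumeration


def _sine(freq_hz, duration_s=120.0, fs=5.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return Signal(values=amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)


class TestEdasymp:
    def test_in_band_tone_dominates_out_of_band_tone(self):
        in_band = edasymp(_sine(0.1))
        out_band = edasymp(_sine(0.5))
        assert in_band > 100 * out_band

    def test_zero_signal_zero_index(self):
        sig = Signal(values=np.zeros(600), fs=5.0)
        assert edasymp(sig) == 0.0

    def test_window_count_rule(self):
        # 60 s -> 2 windows; 59 s -> 1 window: the 2nd half differs between them
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        full = Signal(values=y, fs=5.0)
        short = Signal(values=y[:295], fs=5.0)
        first_window = Signal(values=y[:150], fs=5.0)
        assert edasymp(short) == pytest.approx(edasymp(first_window))
        assert edasymp(full) != pytest.approx(edasymp(first_window))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            edasymp(Signal(values=np.random.default_rng(0).normal(size=100), fs=5.0))

    def test_scales_with_power(self):
        assert edasymp(_sine(0.1, amp=2.0)) == pytest.approx(
            4 * edasymp(_sine(0.1, amp=1.0)), rel=1e-9
        )


class TestAggregate:
    def test_mean_within_cell(self):
        records = [("s1", "sca", 0.4), ("s1", "sca", 0.6), ("s1", "rel", 0.2),
                   ("s2", "sca", 0.5), ("s2", "rel", 0.1)]
        matrix = aggregate_by_condition(records)
        assert matrix.column("sca")[list(matrix.subject_ids).index("s1")] == 0.5

    def test_identity_with_one_value_per_cell(self):
        records = [("s1", "a", 1.0), ("s1", "b", 2.0),
                   ("s2", "a", 3.0), ("s2", "b", 4.0)]
        matrix = aggregate_by_condition(records)
        np.testing.assert_array_equal(
            matrix.to_frame().loc[["s1", "s2"], ["a", "b"]].to_numpy(),
            [[1.0, 2.0], [3.0, 4.0]],
        )

    def test_cohort_shape_30x4(self, rng):
        records = [
            (f"s{s}", cond, rng.uniform())
            for s in range(30)
            for cond in ("amu", "bor", "rel", "sca")
            for _ in range(2)  # two videos per emotion
        ]
        matrix = aggregate_by_condition(records)
        assert matrix.values.shape == (30, 4)

    def test_missing_cell_errors(self):
        records = [("s1", "a", 1.0), ("s1", "b", 2.0), ("s2", "a", 3.0)]
        with pytest.raises(ValueError, match="missing.*s2:b"):
            aggregate_by_condition(records)


class TestLilliefors:
    def test_uniform_sample_rejected(self):
        sample = np.random.default_rng(8).uniform(size=200)
        _, p, reject = lilliefors(sample)
        assert p < 0.05 and reject

    def test_normal_sample_not_rejected(self):
        sample = np.random.default_rng(8).normal(size=200)
        _, p, _ = lilliefors(sample)
        assert p > 0.01

    def test_affine_invariance_of_statistic(self):
        sample = np.random.default_rng(9).normal(size=60)
        s1, _, _ = lilliefors(sample)
        s2, _, _ = lilliefors(5.0 * sample - 3.0)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="constant"):
            lilliefors(np.full(20, 1.0))

    def test_tiny_sample_errors(self):
        with pytest.raises(ValueError):
            lilliefors(np.array([1.0, 2.0, 3.0]))


class TestFriedman:
    def test_consistent_ranking_worked_example(self):
        matrix = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [0.0, 1.0, 2.0]])
        chi2, p = friedman(matrix)
        assert chi2 == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(np.exp(-3.0), rel=1e-9)

    def test_all_equal_degenerate(self):
        chi2, p = friedman(np.ones((5, 4)))
        assert (chi2, p) == (0.0, 1.0)

    def test_column_permutation_invariant(self, rng):
        matrix = rng.normal(size=(12, 4))
        chi2, _ = friedman(matrix)
        chi2_perm, _ = friedman(matrix[:, [2, 0, 3, 1]])
        assert chi2 == pytest.approx(chi2_perm, abs=1e-9)

    def test_matches_bruteforce_and_scipy(self, rng):
        matrix = rng.normal(size=(10, 4))  # continuous -> no ties
        chi2, p = friedman(matrix)
        assert chi2 == pytest.approx(friedman_bruteforce(matrix), abs=1e-9)
        chi2_sp, p_sp = spstats.friedmanchisquare(*matrix.T)
        assert chi2 == pytest.approx(chi2_sp, abs=1e-9)
        assert p == pytest.approx(p_sp, abs=1e-12)

    def test_monotone_transform_invariant(self, rng):
        matrix = rng.normal(size=(8, 3))
        chi2, _ = friedman(matrix)
        chi2_t, _ = friedman(np.exp(matrix))
        assert chi2 == pytest.approx(chi2_t, abs=1e-9)


class TestWilcoxon:
    def test_six_uniform_signs_exact(self):
        x = np.arange(1.0, 7.0) + 1.0
        y = np.arange(1.0, 7.0)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(2 / 64, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_full_enumeration(self, n, rng):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-12)

    def test_matches_enumeration_with_ties(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x + np.array([1.0, -1.0, 2.0, -2.0, 1.0, 2.0, -1.0])
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-12)

    def test_matches_scipy_exact_when_no_ties(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p = wilcoxon_signed_rank(x, y)
        p_sp = spstats.wilcoxon(x, y, mode="exact").pvalue
        assert p == pytest.approx(p_sp, abs=1e-12)

    def test_large_n_normal_approximation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0.5, 1.0, size=60)
        _, p = wilcoxon_signed_rank(x, y)
        p_sp = spstats.wilcoxon(x, y, mode="approx", correction=False).pvalue
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_all_zero_differences(self):
        x = np.ones(8)
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_monotone_transform_invariant(self, rng):
        # signed ranks depend only on difference ordering; a common positive
        # rescaling of both samples keeps them
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        _, p1 = wilcoxon_signed_rank(x, y)
        _, p2 = wilcoxon_signed_rank(3.0 * x, 3.0 * y)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestPairwiseBonferroni:
    def _matrix(self, rng, shift=0.0):
        base = rng.normal(size=(12, 4))
        base[:, 3] += shift
        return ConditionMatrix(base, tuple(f"s{i}" for i in range(12)),
                               ("amu", "bor", "rel", "sca"))

    def test_six_comparisons_for_four_conditions(self, rng):
        report = wilcoxon_pairwise_bonferroni(self._matrix(rng, shift=3.0))
        assert report.n_comparisons == 6
        assert len(report.pairwise_adjusted) == 6

    def test_cap_at_one(self, rng):
        report = wilcoxon_pairwise_bonferroni(self._matrix(rng, shift=3.0))
        for (pair, adj), raw in zip(report.pairwise_adjusted.items(),
                                    report.pairwise_raw.values()):
            assert adj == pytest.approx(min(1.0, raw * 6), abs=1e-12)
            assert raw <= adj <= 1.0

    def test_table_symmetric_empty_diagonal(self, rng):
        report = wilcoxon_pairwise_bonferroni(self._matrix(rng, shift=3.0))
        table = report.pairwise_table()
        np.testing.assert_allclose(table.to_numpy(), table.to_numpy().T)
        assert np.all(np.isnan(np.diag(table.to_numpy())))

    def test_friedman_gate_blocks_posthoc(self, rng):
        matrix = ConditionMatrix(
            np.tile(rng.normal(size=(12, 1)), (1, 4)) ,
            tuple(f"s{i}" for i in range(12)), ("a", "b", "c", "d"),
        )
        report = wilcoxon_pairwise_bonferroni(matrix)
        assert report.friedman_p == 1.0
        assert not report.posthoc_run
        assert report.pairwise_adjusted == {}

    def test_gate_can_be_disabled(self, rng):
        matrix = self._matrix(rng)
        report = wilcoxon_pairwise_bonferroni(matrix, friedman_gate=False)
        assert len(report.pairwise_adjusted) == 6


def test_group_pipeline_power(rng):
    """Synthetic condition effect is detected with power > 0.8 at n=30."""
    rejections = 0
    n_runs = 10
    for run in range(n_runs):
        local = np.random.default_rng(1000 + run)
        base = local.normal(size=(30, 1))
        values = base + local.normal(0, 0.4, size=(30, 2))
        values[:, 1] += 0.4  # true paired effect
        matrix = ConditionMatrix(values, tuple(f"s{i}" for i in range(30)),
                                 ("ctrl", "effect"))
        report = wilcoxon_pairwise_bonferroni(matrix)
        if report.posthoc_run and min(report.pairwise_adjusted.values()) < 0.05:
            rejections += 1
    assert rejections / n_runs > 0.8
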