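import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from traitgrowth import (
    DEFAULT_THRESHOLDS,
    PerformanceCategory,
    ThresholdTable,
    categorize,
    consensus,
    md,
    msd_decomposition,
    pearson_r2,
    rmsd,
    scale_thresholds,
)

finite_vec = arrays(
    np.float64, st.integers(2, 40),
    elements=st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False),
)


class TestBasicStatistics:
    def test_pearson_r2_hand_values(self):
        assert pearson_r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        # r2 is blind to scale: amplified predictions still correlate perfectly
        assert pearson_r2([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        # cross-checked against scipy.stats.pearsonr: r = 0.6, r^2 = 0.36
        from scipy.stats import pearsonr

        r, _ = pearsonr([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert pearson_r2([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(r * r)

    def test_pearson_r2_undefined_on_zero_variance(self):
        assert math.isnan(pearson_r2([1, 2, 3], [5, 5, 5]))

    def test_rmsd_hand_values(self):
        assert rmsd([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmsd([0, 0], [3, 4]) == pytest.approx(math.sqrt(12.5))
        x = np.array([1.0, 5.0, 9.0])
        assert rmsd(x, x + 7.0) == pytest.approx(7.0)  # pure bias

    def test_md_sign_convention(self):
        x = np.array([1.0, 5.0, 9.0])
        assert md(x, x + 2) == pytest.approx(2.0)  # over-prediction positive
        assert md(x, x - 2) == pytest.approx(-2.0)
        # bias-free but inaccurate: md 0, rmsd 2
        assert md([1, 3], [3, 1]) == 0.0
        assert rmsd([1, 3], [3, 1]) == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd([1, 2], [1, 2, 3])


class TestDecomposition:
    def test_identical_vectors_have_zero_components(self):
        s = msd_decomposition([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert s.msd == s.sb == s.sdsd == s.lcs == 0.0

    def test_pure_bias_isolates_sb(self):
        x = np.array([2.0, 4.0, 9.0])
        s = msd_decomposition(x, x + 3.0)
        assert s.sb == pytest.approx(9.0)
        assert s.sdsd == pytest.approx(0.0, abs=1e-12)
        assert s.lcs == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(finite_vec, st.floats(-100, 100), st.floats(0.1, 3.0), st.data())
    def test_identity_msd_equals_mean_squared_difference(self, x, shift, gain, data):
        y = gain * x + shift + np.asarray(
            data.draw(arrays(np.float64, len(x), elements=st.floats(-10, 10)))
        )
        s = msd_decomposition(x, y)
        direct = float(np.mean((y - x) ** 2))  # brute-force oracle
        assert s.msd == pytest.approx(direct, abs=1e-10 * max(1.0, direct))
        assert s.msd == pytest.approx(s.sb + s.sdsd + s.lcs, abs=1e-10 * max(1.0, s.msd))
        assert s.msd == pytest.approx(s.rmsd**2, abs=1e-10 * max(1.0, s.msd))
        assert s.msv == pytest.approx(s.sdsd + s.lcs)
        assert s.rmsd >= abs(s.md) - 1e-9 * max(1.0, abs(s.md))

    def test_rmsd_equals_abs_md_iff_constant_residuals(self):
        x = np.array([1.0, 2.0, 3.0])
        s = msd_decomposition(x, x + 5.0)
        assert s.rmsd == pytest.approx(abs(s.md))
        s2 = msd_decomposition(x, x + np.array([4.0, 5.0, 6.0]))
        assert s2.rmsd > abs(s2.md)


class TestCategorization:
    # (metric, mode, cuts) -> probes: just below / at / just above each cut
    @pytest.mark.parametrize("metric,mode", [
        ("r2", "naive"), ("rmsd", "naive"), ("md", "naive"),
        ("r2", "cv"), ("rmsd", "cv"), ("md", "cv"),
    ])
    def test_boundary_grid(self, metric, mode):
        cuts = DEFAULT_THRESHOLDS.cuts[(metric, mode)]
        order = list(PerformanceCategory)
        eps = 1e-9
        for i, c in enumerate(cuts):
            better, worse = order[i], order[i + 1]
            if metric == "r2":  # value >= cut claims the better category
                assert categorize(metric, mode, c + eps) == better
                assert categorize(metric, mode, c) == better
                assert categorize(metric, mode, c - eps) == worse
            else:  # value < cut claims the better category
                assert categorize(metric, mode, c - eps) == better
                assert categorize(metric, mode, c) == worse
                assert categorize(metric, mode, c + eps) == worse

    def test_representative_values(self):
        assert categorize("r2", "naive", 0.80) == PerformanceCategory.good
        assert categorize("rmsd", "cv", 600) == PerformanceCategory.bad
        # bias categorized on magnitude, in either direction
        assert categorize("md", "naive", -20) == PerformanceCategory.adequate

    def test_undefined_or_infinite_maps_to_bad(self):
        assert categorize("r2", "naive", math.nan) == PerformanceCategory.bad
        assert categorize("rmsd", "cv", math.inf) == PerformanceCategory.bad

    def test_monotone_step_function(self):
        grid = np.linspace(0, 700, 400)
        cats = [categorize("rmsd", "naive", v) for v in grid]
        assert all(b >= a for a, b in zip(cats, cats[1:]))
        r2cats = [categorize("r2", "cv", v) for v in np.linspace(0, 1, 200)]
        assert all(b <= a for a, b in zip(r2cats, r2cats[1:]))

    def test_unknown_metric_mode_raises(self):
        with pytest.raises(KeyError):
            categorize("bias", "naive", 1.0)


class TestConsensus:
    C = PerformanceCategory

    def test_majority_and_middle_rules(self):
        assert consensus([self.C.poor, self.C.poor, self.C.bad]) == self.C.poor
        assert consensus([self.C.good, self.C.good, self.C.good]) == self.C.good
        assert consensus([self.C.good, self.C.adequate, self.C.bad]) == self.C.adequate

    def test_permutation_invariance_over_all_triples(self):
        for triple in itertools.product(PerformanceCategory, repeat=3):
            base = consensus(list(triple))
            for perm in itertools.permutations(triple):
                assert consensus(list(perm)) == base

    def test_requires_exactly_three(self):
        with pytest.raises(ValueError):
            consensus([self.C.good, self.C.bad])


class TestThresholdTable:
    def test_scaling_multiplies_cm_cuts_only(self):
        doubled = scale_thresholds(DEFAULT_THRESHOLDS, 2.0)
        assert doubled.cuts[("rmsd", "naive")][0] == 100.0
        assert doubled.cuts[("md", "cv")] == (100.0, 200.0, 1000.0)
        assert doubled.cuts[("r2", "naive")] == DEFAULT_THRESHOLDS.cuts[("r2", "naive")]

    def test_identity_scale_and_bad_factor(self):
        assert scale_thresholds(DEFAULT_THRESHOLDS, 1.0).cuts == DEFAULT_THRESHOLDS.cuts
        with pytest.raises(ValueError):
            scale_thresholds(DEFAULT_THRESHOLDS, 0.0)

    def test_round_trip_via_dict(self):
        d = DEFAULT_THRESHOLDS.to_dict()
        assert ThresholdTable.from_dict(d).cuts == DEFAULT_THRESHOLDS.cuts

    def test_unordered_cuts_rejected(self):
        with pytest.raises(ValueError):
            ThresholdTable({("rmsd", "naive"): (100.0, 50.0, 200.0)})
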