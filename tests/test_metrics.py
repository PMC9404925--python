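import itertools

import numpy as np
import pytest

from wavebp.metrics import (
    EvalReport,
    FeaturePoints,
    delineate,
    dtw_distance,
    evaluate,
    mae_features,
    match_features,
    normalized_dtw,
    rmse,
)
from wavebp.synth import DEFAULT_ABP_LOBES, SynthConfig, generate_beat_template, generate_record


def brute_force_dtw(x, y):
    """Independent oracle: exhaustive enumeration of all monotone warping
    paths from (0, 0) to (n-1, m-1) with steps right/down/diagonal."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestRmse:
    def test_identical(self, rng):
        x = rng.normal(size=30)
        assert rmse(x, x) == 0.0

    def test_hand_computed(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_symmetric(self, rng):
        x, y = rng.normal(size=(2, 25))
        assert rmse(x, y) == rmse(y, x)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestDelineate:
    def test_constant_signal_has_no_features(self):
        pts = delineate(np.full(500, 100.0), fs=125.0)
        assert pts.n_sbp == 0 and pts.n_dbp == 0

    def test_single_beat_template(self):
        tpl = generate_beat_template(DEFAULT_ABP_LOBES, 300)
        abp = 80.0 + 40.0 * tpl
        pts = delineate(abp, fs=125.0)
        assert pts.n_sbp == 1
        assert pts.sbp_values[0] == 120.0
        assert pts.n_dbp == 2  # flanking troughs
        # the beat starts at its diastolic minimum, so the leading trough is
        # exact and the trailing one ends a fraction above it
        assert pts.dbp_values[0] == 80.0
        assert pts.dbp_values[1] == pytest.approx(80.0, abs=1.0)

    def test_noise_free_record_recovers_ground_truth(self, clean_record):
        _, rec, gt = clean_record
        pts = delineate(rec.abp, rec.fs)
        for idx, val in zip(gt.sbp_indices, gt.sbp_values):
            d = np.abs(pts.sbp_indices - idx)
            j = int(np.argmin(d))
            assert d[j] <= 2 and pts.sbp_values[j] == val
        for idx, val in zip(gt.dbp_indices, gt.dbp_values):
            d = np.abs(pts.dbp_indices - idx)
            j = int(np.argmin(d))
            assert d[j] <= 2 and pts.dbp_values[j] == val

    def test_alternation(self, clean_record):
        _, rec, _ = clean_record
        pts = delineate(rec.abp, rec.fs)
        merged = sorted([(i, "p") for i in pts.sbp_indices]
                        + [(i, "t") for i in pts.dbp_indices])
        kinds = "".join(k for _, k in merged)
        assert "pp" not in kinds and "tt" not in kinds

    def test_too_short(self):
        with pytest.raises(ValueError):
            delineate(np.zeros(100), fs=125.0)


class TestMatchFeatures:
    def _pts(self, indices, values=None):
        indices = np.asarray(indices)
        values = np.asarray(values if values is not None else indices, dtype=float)
        return FeaturePoints(indices, values, np.array([], dtype=np.int64), np.array([]))

    def test_identical_all_matched(self):
        a = self._pts([100, 200, 300], [120.0, 118.0, 122.0])
        m = match_features(a, a)
        pairs, disc = m["sbp"]
        assert len(pairs) == 3 and disc == 0

    def test_displacement_of_exactly_tol_not_matched(self):
        a = self._pts([100], [120.0])
        b = self._pts([110], [119.0])
        pairs, disc = match_features(a, b, tol_samples=10)["sbp"]
        assert pairs == [] and disc == 1
        # one sample closer is matched
        pairs, disc = match_features(a, self._pts([109], [119.0]), 10)["sbp"]
        assert len(pairs) == 1 and disc == 0

    def test_one_candidate_two_references(self):
        a = self._pts([100, 200], [120.0, 121.0])
        b = self._pts([105], [119.0])
        pairs, disc = match_features(a, b, 10)["sbp"]
        assert pairs == [(120.0, 119.0)] and disc == 1

    def test_each_reconstructed_feature_used_once(self):
        a = self._pts([100, 103], [1.0, 2.0])
        b = self._pts([101], [5.0])
        pairs, disc = match_features(a, b, 10)["sbp"]
        assert len(pairs) == 1 and disc == 1


class TestMae:
    def test_single_exact_pair(self):
        assert mae_features([(120.0, 120.0)]) == 0.0

    def test_hand_computed(self):
        assert mae_features([(120.0, 118.0), (118.0, 121.0)]) == pytest.approx(2.5)

    def test_order_invariant(self):
        pairs = [(120.0, 118.0), (118.0, 121.0), (119.0, 119.5)]
        assert mae_features(pairs) == mae_features(pairs[::-1])

    def test_zero_pairs_is_error(self):
        with pytest.raises(ValueError):
            mae_features([])


class TestDtw:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=40)
        assert dtw_distance(x, x) == 0.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [1.0]) == 1.0

    def test_warping_absorbs_duplicated_sample(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == 0.0

    def test_symmetry(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=12)
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x))

    def test_bounded_by_diagonal_path(self, rng):
        x, y = rng.normal(size=(2, 30))
        assert dtw_distance(x, y) <= np.sum(np.abs(x - y)) + 1e-12

    def test_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(60):
            x = rng.integers(0, 3, rng.integers(1, 7)).astype(float)
            y = rng.integers(0, 3, rng.integers(1, 7)).astype(float)
            assert dtw_distance(x, y) == pytest.approx(brute_force_dtw(x, y))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestNormalizedDtw:
    def test_identical_zero(self, rng):
        x = rng.normal(size=20)
        assert normalized_dtw(x, x) == 0.0

    def test_hand_dp_two_by_two(self):
        # d([0,0],[1,1]) = 2 along the diagonal; normalized by 2N = 4
        assert normalized_dtw([0.0, 0.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_scale_property(self, rng):
        x, y = rng.normal(size=(2, 6))
        base = normalized_dtw(x, y)
        assert normalized_dtw(3.0 * x, 3.0 * y) == pytest.approx(3.0 * base)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            normalized_dtw([1.0, 2.0], [1.0])


class TestEvaluate:
    @pytest.fixture(scope="class")
    def abp(self):
        rec, _ = generate_record(SynthConfig(duration_s=20, noise_sd=0.0, seed=13))
        return rec.abp

    def test_self_evaluation_is_perfect(self, abp):
        rep = evaluate(abp, abp, fs=125.0)
        assert rep.rmse == 0.0 and rep.pearson_r == 1.0
        assert rep.mae_sbp == 0.0 and rep.mae_dbp == 0.0
        assert rep.dtw_norm == 0.0
        assert rep.n_discarded_sbp == 0 and rep.n_discarded_dbp == 0

    def test_constant_offset(self, abp):
        rep = evaluate(abp, abp + 1.0, fs=125.0)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae_sbp == pytest.approx(1.0)
        assert rep.mae_dbp == pytest.approx(1.0)
        assert rep.dtw_norm <= 1.0

    def test_report_invariants_on_noisy_pairs(self, abp, rng):
        rec = abp + rng.normal(0, 2.0, len(abp))
        rep = evaluate(abp, rec, fs=125.0)
        assert rep.rmse >= 0 and rep.dtw_norm >= 0
        assert -1.0 <= rep.pearson_r <= 1.0
        ref_pts = delineate(abp, 125.0)
        assert rep.n_matched_sbp + rep.n_discarded_sbp == ref_pts.n_sbp
        assert rep.n_matched_dbp + rep.n_discarded_dbp == ref_pts.n_dbp

    def test_length_mismatch(self, abp):
        with pytest.raises(ValueError):
            evaluate(abp, abp[:-1])
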