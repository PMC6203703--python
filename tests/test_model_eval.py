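import itertools

import numpy as np
import pytest

from climrefugia.model_eval import (
    ReplicateEnsemble,
    UndefinedResultError,
    binarize_refined,
    choose_replication_mode,
    continuous_boyce_index,
    jackknife_significance,
    mss_threshold,
    poisson_binomial_tail,
    refine_ensemble,
)
from climrefugia.raster_core import GridSpec, RasterLayer


def brute_force_tail(probs, s):
    """Independent oracle: enumerate all 2^n outcomes."""
    total = 0.0
    n = len(probs)
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) >= s:
            pr = 1.0
            for o, p in zip(outcome, probs):
                pr *= p if o else (1 - p)
            total += pr
    return total


def brute_force_mss(pres, bg):
    """Independent oracle: exhaustive scan over candidate thresholds."""
    best_t, best_val = None, -1.0
    for t in sorted(set(list(pres) + list(bg))):
        sens = np.mean(np.asarray(pres) >= t)
        spec = np.mean(np.asarray(bg) < t)
        if sens + spec > best_val + 1e-15:
            best_val, best_t = sens + spec, t
    return best_t


class TestReplicationMode:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (4, ("excluded", 0)),
            (5, ("jackknife", 5)),
            (29, ("jackknife", 29)),
            (30, ("crossvalidation", 10)),
            (31, ("crossvalidation", 10)),
            (400, ("crossvalidation", 10)),
        ],
    )
    def test_mode_boundaries(self, n, expected):
        assert choose_replication_mode(n) == expected


class TestMssThreshold:
    def test_worked_example(self):
        # sens 1.0 + spec 0.5 = 1.5 is maximal at t = 0.4
        assert mss_threshold([0.9, 0.7, 0.4], [0.2, 0.5, 0.8, 0.1]) == 0.4

    def test_separable_case(self):
        t = mss_threshold([0.8, 0.9], [0.1, 0.2])
        assert t == 0.8  # min presence, sens + spec = 2

    def test_tie_takes_smallest_candidate(self):
        vals = [0.1, 0.4, 0.7]
        assert mss_threshold(vals, vals) == 0.1

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            pres = rng.uniform(size=rng.integers(1, 20))
            bg = rng.uniform(size=rng.integers(1, 40))
            assert mss_threshold(pres, bg) == brute_force_mss(pres, bg)


class TestPoissonBinomial:
    def test_all_successes_product(self):
        assert poisson_binomial_tail([0.1, 0.1, 0.1], 3) == pytest.approx(1e-3)

    def test_two_coin_enumeration(self):
        assert poisson_binomial_tail([0.5, 0.5], 1) == pytest.approx(0.75)

    def test_s_zero_is_one(self, rng):
        assert poisson_binomial_tail(rng.uniform(size=7), 0) == 1.0

    def test_s_above_n_is_zero(self):
        assert poisson_binomial_tail([0.9, 0.9], 3) == 0.0

    def test_matches_enumeration_small_n(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 10))
            p = rng.uniform(size=n)
            s = int(rng.integers(0, n + 2))
            assert poisson_binomial_tail(p, s) == pytest.approx(
                brute_force_tail(p, s), abs=1e-12
            )


def _flat_ensemble(grid, maps_values, thresholds, heldout, mode="jackknife"):
    layers = [RasterLayer(grid, v) for v in maps_values]
    return ReplicateEnsemble(
        mode=mode,
        maps={"present": layers},
        thresholds=list(thresholds),
        heldout_rowcol=list(heldout),
    )


class TestJackknifeSignificance:
    def test_all_predicted_small_area(self):
        grid = GridSpec(10, 10, 0.0, 0.0, 1.0)
        maps = []
        for _ in range(5):
            v = np.zeros((10, 10))
            v[0, :10] = 1.0  # 10% of cells suitable
            maps.append(v)
        ens = _flat_ensemble(grid, maps, [0.5] * 5, [(0, i) for i in range(5)])
        q, p = jackknife_significance(ens)
        assert q == 1.0
        assert p == pytest.approx(1e-5)

    def test_no_successes(self):
        grid = GridSpec(4, 4, 0.0, 0.0, 1.0)
        maps = [np.zeros((4, 4)) for _ in range(5)]
        ens = _flat_ensemble(grid, maps, [0.5] * 5, [(0, 0)] * 5)
        q, p = jackknife_significance(ens)
        assert q == 0.0 and p == 1.0

    def test_mode_mismatch(self):
        grid = GridSpec(4, 4, 0.0, 0.0, 1.0)
        ens = _flat_ensemble(
            grid, [np.zeros((4, 4))] * 2, [0.5] * 2, [(0, 0)] * 2,
            mode="crossvalidation",
        )
        with pytest.raises(ValueError, match="jackknife"):
            jackknife_significance(ens)

    def test_null_calibration(self, rng):
        """Random presences on random maps: p should be near-uniform, so
        the rejection rate at 0.05 stays in a loose band around nominal."""
        from scipy import ndimage

        grid = GridSpec(20, 20, 0.0, 0.0, 1.0)
        n_pts = 8
        hits = 0
        repeats = 200
        for _ in range(repeats):
            field = ndimage.gaussian_filter(
                rng.standard_normal((20, 20)), sigma=2
            )
            pts = [(int(r), int(c)) for r, c in
                   zip(rng.integers(0, 20, n_pts), rng.integers(0, 20, n_pts))]
            vals = np.array([field[r, c] for r, c in pts])
            bg = field.ravel()
            maps, thrs = [], []
            for i in range(n_pts):
                others = np.delete(vals, i)
                thrs.append(mss_threshold(others, bg))
                maps.append(field)
            ens = _flat_ensemble(grid, maps, thrs, pts)
            _, p = jackknife_significance(ens)
            hits += p < 0.05
        assert 0.01 <= hits / repeats <= 0.12


class TestBoyceIndex:
    def test_presences_in_top_decile_score_high(self):
        # noiseless construction: presences fill the top decile of a
        # uniform background
        bg = np.linspace(0.0, 1.0, 5001)
        pres = np.linspace(0.9, 1.0, 301)
        assert continuous_boyce_index(pres, bg) >= 0.9

    def test_null_resampling_near_zero(self, rng):
        vals = []
        for _ in range(100):
            bg = rng.uniform(size=2000)
            pres = rng.choice(bg, size=100)
            vals.append(abs(continuous_boyce_index(pres, bg)))
        assert np.mean(vals) < 0.25

    def test_reversal_flips_sign(self, rng):
        bg = rng.uniform(size=3000)
        pres = rng.beta(5, 1, size=200)
        cbi = continuous_boyce_index(pres, bg)
        flipped = continuous_boyce_index(1 - pres, 1 - bg)
        assert flipped == pytest.approx(-cbi, abs=1e-9)

    def test_degenerate_range_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            continuous_boyce_index([0.5, 0.5], [0.5, 0.5])


class TestRefinement:
    def _ensemble_with_agreement(self, k_suitable, n_reps=10):
        grid = GridSpec(1, 2, 0.0, 0.0, 1.0)
        maps = []
        for i in range(n_reps):
            v = np.array([[0.9 if i < k_suitable else 0.1, 0.9]])
            maps.append(v)
        return _flat_ensemble(
            grid, maps, [0.5] * n_reps, [(0, 0)] * n_reps, mode="crossvalidation"
        )

    def test_nine_of_ten_removed(self):
        refined = refine_ensemble(self._ensemble_with_agreement(9), "present")
        assert refined.values[0, 0] == 0.0

    def test_ten_of_ten_retained_with_mean(self):
        refined = refine_ensemble(self._ensemble_with_agreement(10), "present")
        assert refined.values[0, 0] == pytest.approx(0.9)

    def test_identical_replicates_idempotent(self):
        grid = GridSpec(2, 2, 0.0, 0.0, 1.0)
        v = np.array([[0.8, 0.2], [0.6, 0.4]])
        ens = _flat_ensemble(grid, [v] * 4, [0.5] * 4, [(0, 0)] * 4)
        refined = refine_ensemble(ens, "present")
        np.testing.assert_allclose(refined.values, np.where(v >= 0.5, v, 0.0))

    def test_refined_never_exceeds_mean_map(self, rng):
        grid = GridSpec(6, 6, 0.0, 0.0, 1.0)
        maps = [rng.uniform(size=(6, 6)) for _ in range(8)]
        thrs = rng.uniform(0.3, 0.7, size=8)
        ens = _flat_ensemble(grid, maps, thrs, [(0, 0)] * 8)
        refined = refine_ensemble(ens, "present")
        assert np.all(refined.values <= np.mean(maps, axis=0) + 1e-12)


class TestBinarize:
    def _simple_ensemble(self, thrs):
        grid = GridSpec(1, 3, 0.0, 0.0, 1.0)
        return _flat_ensemble(
            grid, [np.zeros((1, 3))] * len(thrs), thrs, [(0, 0)] * len(thrs)
        )

    def test_value_at_threshold_is_suitable(self):
        ens = self._simple_ensemble([0.4, 0.6])  # mean 0.5
        grid = GridSpec(1, 3, 0.0, 0.0, 1.0)
        refined = RasterLayer(grid, np.array([[0.5, 0.49, 0.51]]))
        out = binarize_refined(refined, ens)
        np.testing.assert_array_equal(out.values, [[1.0, 0.0, 1.0]])

    def test_all_zero_stays_zero(self):
        ens = self._simple_ensemble([0.4, 0.6])
        grid = GridSpec(1, 3, 0.0, 0.0, 1.0)
        out = binarize_refined(RasterLayer(grid, np.zeros((1, 3))), ens)
        assert not out.values.any()

    def test_raising_threshold_monotone(self, rng):
        grid = GridSpec(1, 5, 0.0, 0.0, 1.0)
        refined = RasterLayer(grid, rng.uniform(size=(1, 5)))
        low = binarize_refined(refined, self._simple_ensemble([0.3, 0.3]))
        high = binarize_refined(refined, self._simple_ensemble([0.7, 0.7]))
        assert np.all(high.values <= low.values)
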