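import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from gazestate.pipeline import build_ranges, cohort_unit_table, merge_ranges
from gazestate.ranges import (Interval, RangeDiscriminator, StateRange,
                              ZScorePool, classify, intersect_ranges,
                              merge_across_paradigms, remove_overlap, round3,
                              state_range, zscore)
from gazestate.synth import GeneratorParams

intervals = st.tuples(st.floats(-5, 5), st.floats(0, 4)).map(
    lambda t: Interval(t[0], t[0] + t[1]))


class TestZScore:
    def test_pool_center(self):
        pool = ZScorePool.fit([1.0, 2.0, 3.0])
        assert zscore(2.0, pool) == pytest.approx(0.0)

    def test_pool_applied_to_itself(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(3.0, 2.0, 50)
        z = zscore(vals, ZScorePool.fit(vals))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, c, b):
        vals = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        z1 = zscore(vals, ZScorePool.fit(vals))
        z2 = zscore(c * vals + b, ZScorePool.fit(c * vals + b))
        assert np.allclose(z1, z2, atol=1e-9)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            ZScorePool("p", "i", 0.0, 0.0)


class TestStateRange:
    @pytest.mark.parametrize("mean,sd,lo,hi", [
        (0.317, 0.771, -0.454, 1.088),   # blink duration, fusion
        (0.816, 1.492, -0.676, 2.308),   # peak velocity, rivalry
        (0.0, 1.0, -1.0, 1.0),
    ])
    def test_endpoints(self, mean, sd, lo, hi):
        sr = StateRange("fusion", mean, sd)
        assert round3(sr.lower) == lo
        assert round3(sr.upper) == hi

    def test_from_values(self):
        sr = state_range([0.0, 1.0, 2.0], "rivalry")
        assert sr.mean == pytest.approx(1.0)
        assert sr.sd == pytest.approx(1.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            state_range([1.0], "fusion")

    @given(st.floats(-10, 10), st.floats(0, 5))
    def test_endpoint_identity(self, mean, sd):
        sr = StateRange("fusion", mean, sd)
        assert sr.lower == mean - sd
        assert sr.upper == mean + sd


class TestRemoveOverlap:
    def test_shared_boundary_point_passes_through(self):
        # adjacent published blink-duration ranges share only -0.454
        fus = Interval(-0.454, 1.088)
        riv = Interval(-0.854, -0.454)
        res = remove_overlap(fus, riv)
        assert res.fusion == fus
        assert res.rivalry == riv
        assert res.abstain.is_empty

    def test_partial_overlap_excised(self):
        res = remove_overlap(Interval(0, 2), Interval(1, 3))
        assert res.fusion == Interval(0, 1)
        assert res.rivalry == Interval(2, 3)
        assert res.abstain == Interval(1, 2)

    def test_identical_intervals_all_abstain(self):
        iv = Interval(-1, 1)
        res = remove_overlap(iv, iv)
        assert res.fusion.is_empty and res.rivalry.is_empty
        assert res.abstain == iv

    def test_containment_flags(self):
        res = remove_overlap(Interval(0, 4), Interval(1, 2))
        assert res.rivalry.is_empty
        assert res.fusion == Interval(2, 4)  # larger remaining piece
        assert any("rivalry" in f for f in res.flags)


class TestIntersect:
    def test_published_rivalry_amplitude_triple(self):
        out = intersect_ranges([Interval(-1.471, -0.693),
                                Interval(-0.905, 1.700),
                                Interval(-1.392, 0.608)])
        assert out == Interval(-0.905, -0.693)

    def test_idempotent_and_empty(self):
        assert intersect_ranges([Interval(0, 1), Interval(0, 1)]) == \
            Interval(0, 1)
        assert intersect_ranges([Interval(0, 1), Interval(2, 3)]).is_empty
        with pytest.raises(ValueError):
            intersect_ranges([])

    @given(intervals, intervals, intervals)
    def test_algebra(self, a, b, c):
        ab = intersect_ranges([a, b])
        ba = intersect_ranges([b, a])
        assert ab == ba
        left = intersect_ranges([intersect_ranges([a, b]), c])
        right = intersect_ranges([a, intersect_ranges([b, c])])
        assert left.is_empty == right.is_empty
        if not left.is_empty:
            assert left == right
            for iv in (a, b, c):
                assert left.lower >= iv.lower - 1e-12
                assert left.upper <= iv.upper + 1e-12


class TestMerge:
    directions = {"gaze_stability": 1.607, "straight_curve": -1.809,
                  "smooth_pursuit": 2.421}

    def test_inverted_paradigm_dropped_for_fusion(self):
        ivs = {"gaze_stability": Interval(-0.244, 1.294),
               "straight_curve": Interval(-1.919, -0.905),
               "smooth_pursuit": Interval(0.608, 2.234)}
        m = merge_across_paradigms(ivs, "fusion", self.directions)
        assert m.interval == Interval(0.608, 1.294)
        assert m.dropped_paradigms == ("straight_curve",)
        assert round3(m.midpoint) == 0.951
        assert round3(m.half_width) == 0.343

    def test_rivalry_keeps_all_paradigms(self):
        ivs = {"gaze_stability": Interval(-1.167, -0.403),
               "straight_curve": Interval(-0.827, 1.545),
               "smooth_pursuit": Interval(-1.196, -0.444)}
        m = merge_across_paradigms(ivs, "rivalry", self.directions)
        assert m.interval == Interval(-0.827, -0.444)
        assert m.dropped_paradigms == ()

    def test_identical_intervals_unchanged(self):
        ivs = {p: Interval(-1, 1) for p in self.directions}
        m = merge_across_paradigms(ivs, "fusion", self.directions)
        assert m.interval == Interval(-1, 1)
        assert m.dropped_paradigms == ()

    def test_no_feasible_subset_errors(self):
        ivs = {"a": Interval(0, 1), "b": Interval(2, 3),
               "c": Interval(4, 5)}
        with pytest.raises(ValueError):
            merge_across_paradigms(ivs, "fusion", {})


class TestClassify:
    fusion = Interval(0.608, 1.294)
    rivalry = Interval(-0.905, -0.693)

    @pytest.mark.parametrize("z,expected", [
        (-0.8, "rivalry"), (1.0, "fusion"), (0.0, "indeterminate"),
        (-0.905, "rivalry"), (5.0, "indeterminate"),
    ])
    def test_membership(self, z, expected):
        assert classify(z, self.fusion, self.rivalry) == expected

    def test_shared_endpoint_indeterminate(self):
        assert classify(-0.454, Interval(-0.454, 1.088),
                        Interval(-0.854, -0.454)) == "indeterminate"

    def test_overlapping_ranges_error(self):
        with pytest.raises(ValueError):
            classify(0.0, Interval(0, 2), Interval(1, 3))


class TestRangeDiscriminator:
    def test_fit_predict_separated(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(2.0, 0.3, 40),
                            rng.normal(-2.0, 0.3, 20)])
        y = np.array(["fusion"] * 40 + ["rivalry"] * 20)
        disc = RangeDiscriminator().fit(x, y)
        assert disc.fusion_interval_.lower > disc.rivalry_interval_.upper
        pred = disc.predict([2.0, -2.0])
        assert list(pred) == ["fusion", "rivalry"]
        acc, abstain = disc.determinate_accuracy(x, y)
        assert acc > 0.95

    def test_sklearn_clone_compatible(self):
        disc = RangeDiscriminator(trim_overlap=False)
        assert clone(disc).get_params() == disc.get_params()

    def test_numeric_labels(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(1, 0.2, 20), rng.normal(-1, 0.2, 10)])
        y = np.array([0] * 20 + [1] * 10)
        disc = RangeDiscriminator().fit(x, y)
        assert disc.predict([-1.0])[0] == "rivalry"


class TestCohortRangeProperties:
    def test_state_gap_monotone_in_effect_size(self):
        # z-gap between state means grows with the generator separation
        gaps = []
        for delta in (0.5, 1.0, 1.5, 2.0):
            params = GeneratorParams(
                trial_duration=6.0,
                amplitude_effect={"gaze_stability": -delta})
            _, units = cohort_unit_table(10, params, master_seed=11,
                                         paradigms=("gaze_stability",),
                                         use_ground_truth=True)
            pools, ranges, _ = build_ranges(
                units, indicators=("avg_saccade_amplitude",))
            rr = ranges[("gaze_stability", "avg_saccade_amplitude")]
            gaps.append(rr["fusion"].mean - rr["rivalry"].mean)
        assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_heldout_accuracy_with_merged_ranges(self):
        # merged ranges from a training cohort classify held-out units of
        # the included paradigms with >= 80% determinate accuracy
        params = GeneratorParams(trial_duration=8.0)
        _, train = cohort_unit_table(30, params, master_seed=7,
                                     use_ground_truth=True)
        _, test = cohort_unit_table(30, params, master_seed=1007,
                                    use_ground_truth=True)
        pools, ranges, trimmed = build_ranges(
            train, indicators=("avg_saccade_amplitude",))
        merged = merge_ranges(ranges, trimmed, ["avg_saccade_amplitude"])
        mf = merged[("avg_saccade_amplitude", "fusion")]
        mr = merged[("avg_saccade_amplitude", "rivalry")]
        applicable = set(mf.included_paradigms) & set(mr.included_paradigms)
        assert applicable
        disc = RangeDiscriminator.from_intervals(mf.interval, mr.interval)
        correct = total = 0
        for paradigm in applicable:
            pool = pools[(paradigm, "avg_saccade_amplitude")]
            block = test[test["paradigm"] == paradigm]
            z = zscore(block["avg_saccade_amplitude"].to_numpy(), pool)
            pred = disc.predict(z)
            det = pred != "indeterminate"
            correct += (pred[det] == block["state"].to_numpy()[det]).sum()
            total += det.sum()
        assert total > 30
        assert correct / total >= 0.80
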