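"""Engagement, trajectory fitness and the 20-statistic feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabdss.exceptions import (
    InvalidMeasurementError,
    MalformedSessionError,
    UndefinedFitnessError,
)
from rehabdss.metrics import (
    FEATURE_NAMES,
    SessionSignals,
    TrajectoryPair,
    WorkMeasurements,
    compute_engagement,
    compute_fitness,
    constant_session,
    extract_features,
)


class TestEngagement:
    @pytest.mark.parametrize(
        "w_total,w_motor,w_robot,expected",
        [
            (10, 10, 4, 0.0),  # robot did all the work: no patient contribution
            (10, 4, 4, 100.0),  # robot only did its unloaded work
            (10, 7, 4, 50.0),  # half the required arm work delivered
        ],
    )
    def test_hand_computed_values(self, w_total, w_motor, w_robot, expected):
        w = WorkMeasurements(w_total=w_total, w_motor=w_motor, w_robot=w_robot)
        assert compute_engagement(w) == pytest.approx(expected)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(InvalidMeasurementError):
            compute_engagement(WorkMeasurements(w_total=4, w_motor=2, w_robot=4))

    def test_negative_or_nonfinite_work_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            WorkMeasurements(w_total=-1, w_motor=0, w_robot=0)
        with pytest.raises(InvalidMeasurementError):
            WorkMeasurements(w_total=float("nan"), w_motor=0, w_robot=0)

    def test_clipped_to_0_100(self):
        # patient "fought" the robot: motor work exceeds total
        assert compute_engagement(WorkMeasurements(10, 12, 4)) == 0.0
        # arm out-worked the requirement
        assert compute_engagement(WorkMeasurements(10, 0, 4)) == 100.0

    def test_derived_work_identities(self):
        w = WorkMeasurements(w_total=10, w_motor=7, w_robot=4)
        assert w.w_user == 3
        assert w.w_arm == 6

    @given(
        w_robot=st.floats(0, 50),
        extra=st.floats(0.1, 50),
        m1=st.floats(0, 100),
        m2=st.floats(0, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_motor_work(self, w_robot, extra, m1, m2):
        w_total = w_robot + extra
        lo, hi = sorted([m1, m2])
        e_lo = compute_engagement(WorkMeasurements(w_total, lo, w_robot))
        e_hi = compute_engagement(WorkMeasurements(w_total, hi, w_robot))
        assert e_hi <= e_lo


class TestFitness:
    def test_perfect_tracking_is_100(self):
        t = TrajectoryPair(actual=[0.0, 1.0, 2.5, 3.0], preset=[0.0, 1.0, 2.5, 3.0])
        assert compute_fitness(t) == 100.0

    def test_negative_r2_clips_to_zero(self):
        # SS_res = 14, SS_tot = 5 -> R^2 = -1.8, clipped
        t = TrajectoryPair(actual=[0, 1, 2, 3], preset=[3, 3, 3, 3])
        assert compute_fitness(t) == 0.0

    def test_hand_computed_half(self):
        # residuals (0,0,1): SS_res=1; mean 2, SS_tot=2 -> R^2 = 0.5
        t = TrajectoryPair(actual=[1, 2, 3], preset=[1, 2, 4])
        assert compute_fitness(t) == pytest.approx(50.0)

    def test_constant_actual_raises(self):
        with pytest.raises(UndefinedFitnessError):
            compute_fitness(TrajectoryPair(actual=[2, 2, 2], preset=[1, 2, 3]))

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(UndefinedFitnessError):
            TrajectoryPair(actual=[1, 2], preset=[1, 2, 3])
        with pytest.raises(UndefinedFitnessError):
            TrajectoryPair(actual=[1], preset=[1])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shift_invariance_and_100_iff_zero_residuals(self, actual, shift):
        actual = np.asarray(actual)
        # skip sequences whose squared deviations underflow to zero (fitness
        # is then undefined), including collapse caused by the shift
        if (
            np.sum((actual - actual.mean()) ** 2) == 0
            or np.sum((actual + shift - (actual + shift).mean()) ** 2) == 0
        ):
            return
        base = compute_fitness(TrajectoryPair(actual=actual, preset=actual))
        assert base == 100.0
        shifted = compute_fitness(
            TrajectoryPair(actual=actual + shift, preset=actual + shift)
        )
        assert shifted == 100.0


class TestExtractFeatures:
    def test_constant_session_statistics(self):
        s = constant_session("passive", force=2.0, velocity=0.1,
                             fitness=80.0, engagement=50.0, n=50)
        f = extract_features(s)
        for stat in ("mean", "max", "min", "median"):
            assert f[f"{stat}_force"] == 2.0
            assert f[f"{stat}_engagement"] == 50.0
        assert f["sd_force"] == 0.0

    def test_exactly_20_features(self):
        f = extract_features(constant_session("assisted", n=10))
        assert len(f.values) == 20
        assert set(f.values) == set(FEATURE_NAMES)

    def test_hand_computed_statistics(self):
        s = SessionSignals(
            force=[1, 2, 3, 4],
            velocity=[0.1, 0.1, 0.1, 0.1],
            fitness_trace=[50, 60, 70, 80],
            engagement_trace=[10, 20, 30, 40],
            mode="passive",
        )
        f = extract_features(s)
        assert f["mean_force"] == pytest.approx(2.5)
        assert f["median_force"] == pytest.approx(2.5)
        assert f["max_force"] == 4.0
        assert f["min_force"] == 1.0
        # sample (n-1) standard deviation
        assert f["sd_force"] == pytest.approx(np.sqrt(5.0 / 3.0))

    def test_permutation_invariance(self, rng):
        base = rng.uniform(0, 100, size=200)
        perm = rng.permutation(base)
        make = lambda e: SessionSignals(
            force=np.ones(200), velocity=np.ones(200),
            fitness_trace=np.ones(200), engagement_trace=e, mode="passive",
        )
        f1, f2 = extract_features(make(base)), extract_features(make(perm))
        for stat in ("mean", "max", "min", "sd", "median"):
            assert f1[f"{stat}_engagement"] == pytest.approx(f2[f"{stat}_engagement"])

    def test_malformed_sessions_rejected(self):
        with pytest.raises(MalformedSessionError):
            SessionSignals(force=[], velocity=[], fitness_trace=[],
                           engagement_trace=[], mode="passive")
        with pytest.raises(MalformedSessionError):
            SessionSignals(force=[1, 2], velocity=[1], fitness_trace=[50, 50],
                           engagement_trace=[50, 50], mode="passive")
        with pytest.raises(MalformedSessionError):
            SessionSignals(force=[1, 2], velocity=[1, 2], fitness_trace=[50, 101],
                           engagement_trace=[50, 50], mode="passive")
        with pytest.raises(MalformedSessionError):
            extract_features(
                SessionSignals(force=[1], velocity=[1], fitness_trace=[50],
                               engagement_trace=[50], mode="passive")
            )
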