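import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovigait import (
    CohortConfig,
    TemplateParams,
    TrajectoryParams,
    calibrate_template,
    simulate_cohort,
    simulate_session,
    solve_dip_depth,
    stance_template,
    template_mean_to_peak,
    trajectory_value,
)
from ovigait.errors import CalibrationError, ResolutionError, ValidationError


class TestStanceTemplate:
    def test_half_sine_mean_to_peak_is_two_over_pi(self):
        # d = 0, q = 1: finely sampled ratio converges to the analytic 2/pi
        y = stance_template(TemplateParams(42.0, 0.58), sampling_rate=20000)
        assert y.mean() / y.max() == pytest.approx(2 / np.pi, rel=1e-6)

    def test_m_shape_has_two_humps_and_one_valley(self):
        y = stance_template(TemplateParams(42.0, 0.585, dip_depth=0.5), 200)
        maxima = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
        minima = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])) + 1
        assert len(maxima) == 2
        assert len(minima) == 1
        assert 0 < minima[0] < len(y) - 1

    @settings(derandomize=True, max_examples=50)
    @given(
        peak=st.floats(5.0, 90.0),
        t_c=st.floats(0.2, 1.0),
        d=st.floats(0.0, 0.95),
        q=st.floats(0.3, 3.0),
        a=st.floats(0.5, 1.5),
    )
    def test_max_equals_requested_peak_exactly(self, peak, t_c, d, q, a):
        y = stance_template(
            TemplateParams(peak, t_c, dip_depth=d, hump_power=q, hump_asymmetry=a), 50.0
        )
        assert y.max() == pytest.approx(peak, abs=1e-12)
        assert np.all(y > 0)

    def test_endpoints_vanish_within_one_sample(self):
        y = stance_template(TemplateParams(42.0, 0.58), 50.0)
        # midpoint sampling: boundary samples sit half a step from the zero crossings
        assert y[0] < 42.0 * np.sin(np.pi / len(y))
        assert y[-1] < 42.0 * np.sin(np.pi / len(y))

    def test_too_short_contact_raises(self):
        with pytest.raises(ResolutionError):
            stance_template(TemplateParams(42.0, 0.1), 50.0)

    def test_invalid_dip_depth_rejected(self):
        with pytest.raises(ValidationError):
            TemplateParams(42.0, 0.58, dip_depth=1.0)


class TestSolveDipDepth:
    def test_half_sine_target_returns_zero(self):
        assert solve_dip_depth(2 / np.pi) == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("branch", ["shallow", "deep"])
    def test_printed_control_ratio_verified_by_forward_simulation(self, branch):
        target = 28.0 / 42.0
        d = solve_dip_depth(target, branch=branch)
        assert template_mean_to_peak(d) == pytest.approx(target, abs=1e-4)
        if branch == "deep":  # the M-shaped solution
            assert d > 1 / 3

    def test_unachievable_ratio_reports_interval(self):
        with pytest.raises(CalibrationError, match=r"\[0\.5\d+, 0\.7\d+\]"):
            solve_dip_depth(0.99)

    def test_ratio_monotone_decreasing_on_deep_branch(self):
        # past its interior maximum (near d = 0.5) the ratio falls steadily:
        # the basis for the deep-branch root search
        ds = np.linspace(0.55, 0.99, 30)
        ratios = [template_mean_to_peak(d) for d in ds]
        assert np.all(np.diff(ratios) < 0)

    def test_ratio_increasing_on_shallow_branch(self):
        ds = np.linspace(0.0, 0.45, 20)
        ratios = [template_mean_to_peak(d) for d in ds]
        assert np.all(np.diff(ratios) > 0)


class TestCalibrateTemplate:
    @pytest.mark.parametrize("peak,mean,t_c,style", [
        (42.0, 28.0, 0.58, "m_shape"),    # healthy hind
        (62.0, 45.0, 0.52, "m_shape"),    # healthy fore
        (23.0, 11.5, 0.28, "single_hump"),  # acutely lame hind
    ])
    def test_sampled_template_hits_peak_and_mean(self, peak, mean, t_c, style):
        tp = calibrate_template(peak, mean, t_c, 50.0, style=style)
        y = stance_template(tp, 50.0)
        assert y.max() == pytest.approx(peak, abs=1e-9)
        assert y.mean() == pytest.approx(mean, rel=1e-4)

    def test_lame_template_is_single_humped_and_sharp(self):
        tp = calibrate_template(23.0, 11.5, 0.28, 50.0, style="single_hump")
        assert tp.dip_depth == 0.0
        assert tp.hump_power > 1.5  # mean/peak 0.5 needs a peaked curve
        y = stance_template(tp, 225.0)  # odd sample count: unique maximum sample
        maxima = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
        assert len(maxima) == 1


class TestTrajectory:
    def test_endpoints(self):
        tp = TrajectoryParams(23.0, 42.0, t_start=7, t_recovery=160)
        assert trajectory_value(tp, 7) == 23.0
        assert trajectory_value(tp, 160) == 42.0
        assert trajectory_value(tp, 500) == 42.0

    def test_linear_interpolation_hand_check(self):
        tp = TrajectoryParams(23.0, 42.0, t_start=0, t_recovery=160)
        assert trajectory_value(tp, 80) == pytest.approx(32.5)

    def test_query_before_walking_raises(self):
        tp = TrajectoryParams(23.0, 42.0, t_start=7, t_recovery=160)
        with pytest.raises(ValidationError):
            trajectory_value(tp, 3)

    def test_compensatory_elevation_decays_to_control(self):
        tp = TrajectoryParams(38.0, 28.0, t_start=7, t_recovery=160)
        assert trajectory_value(tp, 7) == 38.0
        assert trajectory_value(tp, 200) == 28.0


class TestSimulateSession:
    def _session(self, seed, noise_cv, n_phases=8):
        rng = np.random.default_rng(seed)
        tp = calibrate_template(42.0, 28.0, 0.58, 50.0, "m_shape")
        return simulate_session({"IH": tp}, n_phases, noise_cv, 57.9, rng)["IH"]

    def test_no_noise_phases_identical(self):
        sim = self._session(1, 0.0)
        lengths = {t.end_index - t.start_index for t in sim.phases}
        peaks = {t.peak_pct for t in sim.phases}
        assert lengths == {29} and peaks == {42.0}

    def test_same_seed_bit_identical(self):
        a, b = self._session(7, 0.05), self._session(7, 0.05)
        np.testing.assert_array_equal(a.recording.forces, b.recording.forces)

    def test_noise_cv_recovered_at_large_n(self):
        sim = self._session(3, 0.05, n_phases=1000)
        peaks = np.array([t.peak_pct for t in sim.phases])
        cv = peaks.std(ddof=1) / peaks.mean()
        assert cv == pytest.approx(0.05, abs=0.005)

    def test_gaps_are_exact_zeros(self):
        sim = self._session(2, 0.05)
        f = sim.recording.forces
        mask = np.ones(f.size, bool)
        for t in sim.phases:
            mask[t.start_index:t.end_index] = False
        assert np.all(f[mask] == 0.0)
        # inter-phase gaps at least 0.3 s
        for prev, nxt in zip(sim.phases, sim.phases[1:]):
            assert (nxt.start_index - prev.end_index) / 50.0 >= 0.3


class TestSimulateCohort:
    def test_counting_contract(self):
        cfg = CohortConfig(n_operated=1, n_control=1, session_days=(7, 14, 21),
                           phases_per_session=(3, 3), rng_seed=0)
        sims = simulate_cohort(cfg)
        assert len(sims) == 2 * 4 * 3  # animals x limbs x days

    def test_pure_function_of_config(self):
        cfg = CohortConfig(n_operated=1, n_control=1, session_days=(7, 14),
                           phases_per_session=(3, 3), rng_seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.recording.forces, rb.recording.forces)

    def test_different_seeds_same_structure_different_forces(self):
        mk = lambda s: simulate_cohort(CohortConfig(
            n_operated=1, n_control=0, session_days=(7, 14),
            phases_per_session=(3, 3), noise_cv=0.05, rng_seed=s))
        a, b = mk(1), mk(2)
        assert [(r.recording.session_id, r.recording.limb) for r in a] == \
               [(r.recording.session_id, r.recording.limb) for r in b]
        assert any(
            ra.recording.forces.shape != rb.recording.forces.shape
            or not np.array_equal(ra.recording.forces, rb.recording.forces)
            for ra, rb in zip(a, b)
        )

    def test_sessions_before_first_walking_day_skipped(self, caplog):
        cfg = CohortConfig(n_operated=1, n_control=0, session_days=(3, 7),
                           phases_per_session=(2, 2), rng_seed=0)
        with caplog.at_level("WARNING"):
            sims = simulate_cohort(cfg)
        assert {r.recording.day_postop for r in sims} == {7}
        assert any("skipping day 3" in m for m in caplog.messages)
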