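"""Epileptor vector field, integration, bifurcation and stimulation."""

import numpy as np
import pytest

from criticaldyn import epileptor as ep
from criticaldyn.pipeline import single_pulse_response_ll


class TestDerivative:
    def test_fixed_point_has_zero_derivative(self, params, fixed_point):
        d = ep.epileptor_derivative(fixed_point, params)
        assert np.abs(d).max() < 1e-7

    def test_f1_lower_branch_hand_value(self, params):
        # x1 = -1 on the x1 < 0 branch: f1 = (-1)^3 - 3(-1)^2 = -4
        s = ep.EpileptorState(x1=-1.0, y1=0.0, z=3.0, x2=0.0, y2=0.0, g=0.0)
        d = ep.epileptor_derivative(s, params)
        # dx1 = y1 - f1 - z + I1 = 0 + 4 - 3 + 3.1
        assert d[0] == pytest.approx(4.1)

    @pytest.mark.parametrize("x2, f2", [(-0.5, 0.0), (0.0, 1.5)])
    def test_f2_branches_hand_values(self, params, x2, f2):
        s = ep.EpileptorState(x1=-1.0, y1=0.0, z=3.0, x2=x2, y2=0.0, g=0.0)
        d = ep.epileptor_derivative(s, params)
        # dy2 = (-y2 + f2)/tau2 with y2 = 0
        assert d[4] == pytest.approx(f2 / params.tau2)

    def test_nonfinite_state_rejected(self, params):
        s = ep.EpileptorState(np.nan, 0, 3, 0, 0, 0)
        with pytest.raises(ep.BlowupError):
            ep.epileptor_derivative(s, params)


class TestFixedPoint:
    def test_residual_and_stability(self, params, fixed_point):
        d = ep.epileptor_derivative(fixed_point, params)
        assert np.linalg.norm(d) < 1e-8
        assert fixed_point.x1 < -4.0 / 3.0  # interictal branch

    def test_perturbation_relaxes_back(self, params, fixed_point):
        v = fixed_point.to_vector()
        v[0] += 1e-3
        sim = ep.integrate_deterministic(
            params, ep.EpileptorState.from_vector(v), None, n_steps=20_000)
        assert np.abs(sim.states[-1] - fixed_point.to_vector()).max() < 1e-3

    def test_epileptogenic_x0_has_no_stable_rest(self, params):
        with pytest.raises(ValueError, match="critical point"):
            ep.find_fixed_point(params.with_(x0=-2.0))


class TestIntegration:
    def test_deterministic_runs_are_bit_identical(self, params, fixed_point):
        stim = ep.StimulusTrain.empty()
        a = ep.integrate_deterministic(params, fixed_point, stim, 5000)
        b = ep.integrate_deterministic(params, fixed_point, stim, 5000)
        assert np.array_equal(a.states, b.states)

    def test_same_seed_reproduces_stochastic_run(self, params, fixed_point):
        a = ep.integrate_stochastic(params, fixed_point, None, 5000, seed=42)
        b = ep.integrate_stochastic(params, fixed_point, None, 5000, seed=42)
        assert np.array_equal(a.states, b.states)

    def test_zero_noise_matches_rk4_from_rest(self, params, fixed_point):
        p0 = params.with_(noise_var_x1=0, noise_var_x2=0, noise_var_y2=0)
        det = ep.integrate_deterministic(p0, fixed_point, None, 10_000)
        sto = ep.integrate_stochastic(p0, fixed_point, None, 10_000, seed=1)
        assert np.abs(det.states - sto.states).max() < 1e-6

    def test_zero_noise_tracks_rk4_on_transient(self, params, fixed_point):
        # Heun is O(dt^2): agreement on a decaying transient is scheme-
        # limited, not noise-limited
        p0 = params.with_(noise_var_x1=0, noise_var_x2=0, noise_var_y2=0)
        v = fixed_point.to_vector()
        v[0] += 1e-2
        init = ep.EpileptorState.from_vector(v)
        det = ep.integrate_deterministic(p0, init, None, 10_000)
        sto = ep.integrate_stochastic(p0, init, None, 10_000, seed=1)
        assert np.abs(det.states - sto.states).max() < 1e-3

    def test_rk4_convergence_order(self, params, fixed_point):
        # Richardson order estimate on a smooth sub-threshold relaxation
        # (no branch switches, no stimulation); RK4 should show order >= 3
        v = fixed_point.to_vector()
        v[0] += 0.5
        v[3] += 0.3
        init = ep.EpileptorState.from_vector(v)
        T = 1.0  # model time units
        ends = []
        for dt in (0.1, 0.05, 0.025):
            sim = ep.integrate_deterministic(params.with_(dt=dt), init, None,
                                             int(round(T / dt)))
            ends.append(sim.states[-1])
        e1 = np.linalg.norm(ends[0] - ends[1])
        e2 = np.linalg.norm(ends[1] - ends[2])
        order = np.log2(e1 / e2)
        assert order >= 3.0

    def test_epoch_variance_stable_across_seeds(self, params, fixed_point):
        # stationary fluctuation strength is a property of the SDE, not of
        # the noise realization
        variances = []
        for seed in range(5):
            sim = ep.integrate_stochastic(params, fixed_point, None,
                                          40_000, seed=seed)
            x = sim.ieeg_proxy[100:]
            variances.append(x.var())
        v = np.array(variances)
        assert v.min() > 0
        assert v.std() / v.mean() < 0.5


class TestSeizureDetection:
    def test_constant_subthreshold_gives_none(self, params, fixed_point):
        sim = ep.integrate_deterministic(params, fixed_point, None, 20_000)
        assert ep.detect_seizure(sim) is None

    def test_short_crossing_does_not_count(self, params):
        # synthetic trajectory crossing for fewer steps than the dwell
        n = 3000
        states = np.full((n, 6), -1.5)
        states[1000:1050, 0] = 0.5  # 0.5 s above threshold
        sim = ep.SimulationResult(
            time_ms=np.arange(n) * 10.0, states=states,
            ieeg_proxy=states[:, 0], stim_trace=np.zeros(n), params=params)
        assert ep.detect_seizure(sim) is None

    def test_onset_matches_bruteforce_scan(self, params):
        p = params.with_(x0=-2.0)
        init = ep.EpileptorState(-1.3, -7.45, 2.8, -1.0, 0.0, -130.0)
        sim = ep.integrate_deterministic(p, init, None, 1_000_000)
        crit = ep.SeizureCriterion()
        onset = ep.detect_seizure(sim, crit)
        assert onset is not None
        # oracle: exhaustive scan over every candidate crossing
        x1 = sim.states[:, 0]
        dwell = int(crit.dwell_s * 100)
        expected = None
        for i in np.flatnonzero(x1 > crit.onset_threshold):
            seg = x1[i:i + dwell] > crit.sustain_threshold
            if seg.size >= dwell and seg.all():
                expected = sim.time_ms[i]
                break
        assert onset == expected

    def test_spontaneous_seizure_counts_by_condition(self, params):
        # probe conditions: silent; epileptogenic: recurrent
        for x0 in (-2.30, -2.25, -2.20):
            p = params.with_(x0=x0)
            fp = ep.find_fixed_point(p)
            sim = ep.integrate_deterministic(p, fp, None, 500_000)
            assert ep.detect_all_seizures(sim) == []
        p = params.with_(x0=-2.0)
        init = ep.EpileptorState(-1.3, -7.45, 2.8, -1.0, 0.0, -130.0)
        sim = ep.integrate_deterministic(p, init, None, 3_000_000)
        assert len(ep.detect_all_seizures(sim)) >= 2


class TestBifurcation:
    def test_bistable_interval_exists(self, params):
        diag = ep.bifurcation_diagram(params, np.linspace(2.0, 4.5, 26))
        n_stable = [diag.n_stable(i) for i in range(len(diag.z_grid))]
        assert max(n_stable) >= 2

    def test_fold_location_two_sided(self, params):
        # analytic fold of the x1 < 0 cubic: x1 = -4/3,
        # z = -x1^3 - 2 x1^2 + y0 + I1
        expect = (4.0 / 3.0) ** 3 - 2.0 * (4.0 / 3.0) ** 2 + 1.0 + 3.1
        a = ep.bifurcation_diagram(params, [2.0, 4.0])
        b = ep.bifurcation_diagram(params, [2.8, 3.0])
        assert a.fold_z == pytest.approx(expect, abs=1e-6)
        assert b.fold_z == pytest.approx(a.fold_z, abs=1e-9)

    def test_monostable_far_from_fold(self, params):
        diag = ep.bifurcation_diagram(params, [2.0, 4.4, 4.45])
        assert diag.n_stable(2) == 1

    def test_grid_must_bracket_fold(self, params):
        with pytest.raises(ValueError, match="bracket"):
            ep.bifurcation_diagram(params, [3.5, 4.0])

    def test_critical_x0_between_probe_and_epileptogenic(self, params):
        xc = ep.critical_x0(params)
        assert -2.20 > xc > -2.25 or -2.20 < xc < -2.0
        assert xc == pytest.approx(-2.062, abs=0.01)


class TestStimulus:
    def test_rhythmic_train_spacing(self):
        st = ep.build_stimulus("train", frequency_hz=20.0, duration_s=1.0)
        assert st.pulse_onsets_ms.size == 20
        assert np.allclose(np.diff(st.pulse_onsets_ms), 50.0)

    def test_paired_pulse_interval(self):
        st = ep.build_stimulus("paired-pulse", inter_pulse_interval_ms=6.0)
        assert st.pulse_onsets_ms[1] - st.pulse_onsets_ms[0] == 6.0

    def test_arrhythmic_rate_across_seeds(self):
        rates = []
        for seed in range(100):
            st = ep.build_stimulus("arrhythmic", frequency_hz=20.0,
                                   duration_s=1.0, seed=seed)
            rates.append(st.pulse_onsets_ms.size
                         / (st.pulse_onsets_ms[-1] / 1000.0))
        assert np.mean(rates) == pytest.approx(20.0, rel=0.15)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            ep.build_stimulus("burst")


class TestTimeToSeizure:
    def test_monotone_in_x0_and_frequency(self, params):
        grid = {}
        for x0 in (-2.30, -2.25, -2.20):
            for f in (20.0, 30.0, 40.0):
                grid[(x0, f)] = ep.time_to_seizure(
                    params.with_(x0=x0), frequency_hz=f, max_duration_s=120.0)
        for f in (20.0, 30.0, 40.0):
            assert grid[(-2.20, f)] < grid[(-2.25, f)] < grid[(-2.30, f)]
        for x0 in (-2.30, -2.25, -2.20):
            assert grid[(x0, 40.0)] < grid[(x0, 30.0)] < grid[(x0, 20.0)]

    def test_zero_intensity_never_provokes(self, params):
        tts = ep.time_to_seizure(params, frequency_hz=20.0,
                                 intensity_scale=0.0, max_duration_s=5.0)
        assert tts is None


def test_single_pulse_ll_grows_toward_critical_point():
    # evoked excursion length increases as x0 approaches the fold
    lls = [single_pulse_response_ll(ep.EpileptorParams(x0=x0), 1.0)
           for x0 in (-2.40, -2.32, -2.25, -2.18, -2.12)]
    assert np.all(np.diff(lls) > 0)
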