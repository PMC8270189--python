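"""Integrate-and-fire dynamics: conductances, integration, refractoriness.

The production integrator (exponential Euler with event-driven two-state
synapse updates, numba-compiled) is checked against an independent
brute-force scalar-loop reference that evaluates the summed alpha
conductances by direct kernel summation at every step.
"""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import lsosim as L
from lsosim.neuron import bin_impulses


def _fixture_trains(duration=40.0, seed=9, rate_ex=250.0, rate_inh=150.0):
    rng = np.random.default_rng(seed)
    ex = [L.homogeneous_poisson(rate_ex, duration, rng) for _ in range(20)]
    inh = [L.homogeneous_poisson(rate_inh, duration, rng) for _ in range(8)]
    return L.SpikeTrainSet(excitatory=ex, inhibitory=inh, duration=duration)


def reference_integrate(model, params, syn, trains, dt):
    """Brute-force scalar-loop integrator with direct kernel summation.

    Spike times are aligned to the step grid (floor), as in the production
    path; conductances are then evaluated by explicit summation of alpha
    kernels over all past presynaptic spikes at every step.
    """
    n_steps = int(round(trains.duration / dt))
    tgrid = np.arange(n_steps) * dt

    def summed(trains_, A, tau):
        g = np.zeros(n_steps)
        for train in trains_:
            for t0 in np.asarray(train):
                onset = math.floor(t0 / dt) * dt
                g += L.alpha_kernel(tgrid - onset, A, tau)
        return g

    g_ex = summed(trains.excitatory, syn.A_ex, syn.tau_ex)
    g_inh = summed(trains.inhibitory, syn.A_inh, syn.tau_inh)
    spikes = []
    ref_until = -1.0
    if model == "active":
        V, d = L.resting_state(params)
        s1 = s2 = 0.0
        dec1 = math.exp(-dt / params.spike_tau1)
        dec2 = math.exp(-dt / params.spike_tau2)
        for n in range(n_steps):
            t = n * dt
            a_d = params.klva_rate * math.exp((V - params.klva_vhalf) / params.klva_slope)
            b_d = params.klva_rate * math.exp(-(V - params.klva_vhalf) / params.klva_slope)
            d_inf = a_d / (a_d + b_d)
            d = d_inf + (d - d_inf) * math.exp(-dt * (a_d + b_d))
            I_spk = 1000.0 * (s1 - s2)
            G = params.g_L + params.g_KL * d + g_ex[n] + g_inh[n]
            V_inf = (
                params.g_L * params.E_L
                + params.g_KL * d * params.E_K
                + g_ex[n] * syn.E_ex
                + g_inh[n] * syn.E_inh
                + I_spk
            ) / G
            V = V_inf + (V - V_inf) * math.exp(-dt * G / params.C)
            s1 *= dec1
            s2 *= dec2
            if t >= ref_until and V >= params.V_theta:
                spikes.append(t)
                ref_until = t + params.T_ref
                s1 += params.spike_amp1
                s2 += params.spike_amp2
    else:
        V = params.E_L
        for n in range(n_steps):
            t = n * dt
            if t < ref_until:
                V = params.V_reset
            else:
                G = params.g_L + g_ex[n] + g_inh[n]
                V_inf = (
                    params.g_L * params.E_L + g_ex[n] * syn.E_ex + g_inh[n] * syn.E_inh
                ) / G
                V = V_inf + (V - V_inf) * math.exp(-dt * G / params.C)
            if t >= ref_until and V >= params.V_theta:
                spikes.append(t)
                ref_until = t + params.T_ref
                V = params.V_reset
    return np.array(spikes)


class TestAlphaConductance:
    def test_kernel_peak_and_support(self):
        assert L.alpha_kernel(0.16, 3.5, 0.16) == pytest.approx(3.5, rel=1e-14)
        assert L.alpha_kernel(0.0, 3.5, 0.16) == 0.0
        assert L.alpha_kernel(-1.0, 3.5, 0.16) == 0.0

    def test_single_spike_peak(self):
        g = L.total_conductance([[10.0]], 3.5, 0.16, 10.16)
        assert g == pytest.approx(3.5, rel=1e-14)

    def test_empty_trains_are_silent(self):
        assert L.total_conductance([], 3.5, 0.16, 5.0) == 0.0
        assert L.total_conductance([[], []], 12.0, 0.32, 5.0) == 0.0

    def test_coincident_spikes_superpose(self):
        g = L.total_conductance([[2.0], [2.0]], 12.0, 0.32, 2.32)
        assert g == pytest.approx(24.0, rel=1e-14)

    def test_superposition_linearity_exact(self):
        rng = np.random.default_rng(3)
        a = [np.sort(rng.uniform(0, 50, 12)), np.sort(rng.uniform(0, 50, 7))]
        b = [np.sort(rng.uniform(0, 50, 9))]
        t = np.linspace(0, 60, 301)
        g_all = L.total_conductance(a + b, 3.5, 0.16, t)
        g_sum = L.total_conductance(a, 3.5, 0.16, t) + L.total_conductance(b, 3.5, 0.16, t)
        np.testing.assert_allclose(g_all, g_sum, rtol=0, atol=1e-12)

    def test_two_state_filter_matches_kernel_summation(self):
        # 10 on-grid spikes; recorded conductance trace vs direct summation
        dt = 0.004
        spikes = np.array([1, 2, 3, 5, 8, 13, 21, 24, 30, 33]) * 0.25
        spikes = np.round(spikes / dt) * dt
        trains = L.SpikeTrainSet(excitatory=[spikes], inhibitory=[], duration=12.0)
        syn = L.SynapseParams(M_ex=1, M_inh=0)
        out = L.simulate_active(L.ActiveIFParams(), syn, trains, dt=dt, record=True)
        ref = L.total_conductance([spikes], syn.A_ex, syn.tau_ex, out.time)
        scale = max(1.0, ref.max())
        np.testing.assert_allclose(out.g_ex / scale, ref / scale, rtol=0, atol=1e-9)

    def test_impulse_binning_conserves_spike_count(self):
        trains = [np.array([0.0, 0.0011, 9.9999]), np.array([5.0])]
        imp = bin_impulses(trains, 0.002, 5000, 2.0)
        assert imp.sum() == pytest.approx(4 * 2.0, rel=1e-14)


class TestActiveModel:
    def test_resting_potential_is_conductance_balance(self):
        p = L.ActiveIFParams()
        v_rest, d_rest = L.resting_state(p)

        def balance(v):
            return p.g_L * (p.E_L - v) + p.g_KL * p.d_inf(v) * (p.E_K - v)

        assert brentq(balance, -75.0 + 1e-9, -45.8) == pytest.approx(v_rest, abs=1e-9)
        assert d_rest == pytest.approx(p.d_inf(v_rest), abs=1e-12)
        # between the leak and potassium reversal potentials, below threshold
        assert p.E_K < v_rest < p.E_L

    def test_zero_input_settles_at_rest_without_spiking(self):
        trains = L.SpikeTrainSet(excitatory=[], inhibitory=[], duration=50.0)
        out = L.simulate_active(L.ActiveIFParams(), L.SynapseParams(), trains, record=True)
        v_rest, _ = L.resting_state(L.ActiveIFParams())
        assert out.n_spikes == 0
        np.testing.assert_allclose(out.voltage, v_rest, atol=1e-6)

    def test_matches_brute_force_reference(self):
        trains = _fixture_trains()
        params, syn = L.ActiveIFParams(), L.SynapseParams()
        out = L.simulate_active(params, syn, trains, dt=0.004)
        ref = reference_integrate("active", params, syn, trains, 0.004)
        assert out.n_spikes == len(ref)
        np.testing.assert_allclose(out.spike_times, ref, atol=1e-9)

    def test_refractory_floor_on_interspike_intervals(self):
        # strong drive at the most excitable ILD
        rng = np.random.default_rng(21)
        for _ in range(10):
            ts = L.make_spike_trains(L.ToneStimulus(ild=-45.0), 20, 8, rng.spawn(1)[0])
            out = L.simulate_active(L.ActiveIFParams(), L.SynapseParams(), ts)
            if out.n_spikes >= 2:
                assert np.diff(out.spike_times).min() >= L.ActiveIFParams().T_ref - 1e-9


class TestPassiveModel:
    def test_zero_input_holds_leak_equilibrium(self):
        trains = L.SpikeTrainSet(excitatory=[], inhibitory=[], duration=30.0)
        out = L.simulate_passive(L.PassiveIFParams(), L.SynapseParams(), trains, record=True)
        assert out.n_spikes == 0
        np.testing.assert_allclose(out.voltage, -60.0, atol=1e-12)

    def test_matches_brute_force_reference(self):
        trains = _fixture_trains(seed=10)
        params, syn = L.PassiveIFParams(), L.SynapseParams()
        out = L.simulate_passive(params, syn, trains, dt=0.004)
        ref = reference_integrate("passive", params, syn, trains, 0.004)
        assert out.n_spikes == len(ref)
        np.testing.assert_allclose(out.spike_times, ref, atol=1e-9)

    def test_constant_drive_period_matches_closed_form(self):
        # dense regular excitatory spikes give a near-constant conductance
        # g = r * A_ex * e * tau_ex; the leaky IF then fires periodically with
        # period T_ref + tau_m * ln((V_inf - V0)/(V_inf - V_theta)).
        p = L.PassiveIFParams()
        dt = 0.002
        spacing = 0.02  # ms, << tau_ex so the conductance ripple is tiny
        duration = 400.0
        spikes = np.arange(spacing, duration, spacing)
        syn = L.SynapseParams(M_ex=1, M_inh=0)
        trains = L.SpikeTrainSet(excitatory=[spikes], inhibitory=[], duration=duration)
        out = L.simulate_passive(p, syn, trains, dt=dt)
        g = (1.0 / spacing) * syn.A_ex * math.e * syn.tau_ex  # nS
        G = p.g_L + g
        v_inf = (p.g_L * p.E_L + g * syn.E_ex) / G
        tau_m = p.C / G
        period = p.T_ref + tau_m * math.log(
            (v_inf - p.V_reset) / (v_inf - p.V_theta)
        )
        isis = np.diff(out.spike_times)[5:]
        assert isis.std() < 0.05
        assert isis.mean() == pytest.approx(period, rel=0.02)

    def test_passive_params_validation(self):
        with pytest.raises(ValueError):
            L.PassiveIFParams(g_KL=1.0)


class TestConvergence:
    @pytest.mark.parametrize("ild", [-45.0, -20.0, 0.0])
    def test_dt_halving_changes_rates_by_less_than_one_percent(self, ild):
        sc = L.ScenarioSpec(m_inh=8)
        grid = [L.ToneStimulus(ild=ild)]
        c1 = L.run_tuning(grid, sc, n_trials=120, dt=0.004, seed=77)
        c2 = L.run_tuning(grid, sc, n_trials=120, dt=0.002, seed=77)
        # identical presynaptic trains (stream keyed by stimulus and trial),
        # so the difference is purely the integration error
        assert c1.mean_rate[0] == pytest.approx(c2.mean_rate[0], rel=0.01)
        assert np.abs(c1.counts - c2.counts).max() <= 1
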