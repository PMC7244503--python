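"""Mass-action simulation, circuit builders, normalization and fitting."""

import numpy as np
import pytest

from tmsd.kinetics import (
    CATALYTIC_CONCENTRATIONS,
    PULSE_CONCENTRATIONS,
    RATE_ASSAY_CONCENTRATIONS,
    DegenerateTraceError,
    KineticsError,
    Reaction,
    ReactionNetwork,
    Trace,
    build_catalytic_model,
    build_pulse_model,
    build_rate_assay_model,
    dilution,
    fit_rate_constant,
    normalize_trace,
    simulate_network,
    strand_conservation,
)
from tmsd.synthetic import NoiseModel, generate_trace, simple_protocol

MINUTE = 60.0


class TestSimulateNetwork:
    def test_irreversible_bimolecular_matches_closed_form(self):
        # A + B -> C with a0 != b0:
        # x(t) = a0 b0 (exp((b0-a0)kt) - 1) / (b0 exp((b0-a0)kt) - a0)
        a0, b0, k = 10e-9, 25e-9, 1e5
        net = ReactionNetwork(species={"A": a0, "B": b0, "C": 0.0},
                              reactions=[Reaction(("A", "B"), ("C",), k)])
        t = np.linspace(0, 2e4, 50)
        sim = simulate_network(net, t)
        e = np.exp((b0 - a0) * k * t)
        x = a0 * b0 * (e - 1) / (b0 * e - a0)
        assert np.allclose(sim["C"], x, rtol=1e-8, atol=1e-16)

    def test_zero_rates_leave_trajectories_constant(self):
        net = ReactionNetwork(species={"A": 1e-8, "B": 2e-8, "C": 0.0},
                              reactions=[Reaction(("A", "B"), ("C",), 0.0)])
        sim = simulate_network(net, np.linspace(0, 1e5, 20))
        assert np.all(sim["A"] == 1e-8)
        assert np.all(sim["C"] == 0.0)

    def test_reversible_equilibrium_satisfies_detailed_balance(self):
        kf, kr = 1e6, 1e-3
        net = ReactionNetwork(
            species={"A": 20e-9, "B": 30e-9, "C": 0.0},
            reactions=[Reaction(("A", "B"), ("C",), kf),
                       Reaction(("C",), ("A", "B"), kr)])
        sim = simulate_network(net, np.linspace(0, 1e7, 50))
        a, b, c = sim["A"][-1], sim["B"][-1], sim["C"][-1]
        assert c / (a * b) == pytest.approx(kf / kr, rel=1e-3)

    @pytest.mark.parametrize("builder,kwargs", [
        (build_rate_assay_model, {"k_disp": 2.6e3}),
        (build_rate_assay_model, {"k_disp": 1.8e5, "reporter": "explicit",
                                  "k_rep": 1e6}),
        (build_catalytic_model, {"k_leak": 100.0}),
        (build_pulse_model, {}),
    ])
    def test_strand_conservation(self, builder, kwargs):
        net = builder(**kwargs)
        sim = simulate_network(net, np.linspace(0, 3e4, 40))
        totals = strand_conservation(net, sim)
        for strand in totals:
            col = totals[strand].to_numpy()
            assert np.abs(col - col[0]).max() <= 1e-9 * max(col[0], 1e-30)

    def test_solver_failure_reports_context(self):
        net = ReactionNetwork(species={"A": 1e-8}, reactions=[])
        with pytest.raises(KineticsError):
            simulate_network(net, np.array([0.0]))


class TestRateAssayModel:
    def test_preset_concentrations_follow_dilution_arithmetic(self):
        assert RATE_ASSAY_CONCENTRATIONS["I"] == pytest.approx(
            dilution(2.4e-6, 10e-6, 1.92e-3))
        assert RATE_ASSAY_CONCENTRATIONS["I"] == pytest.approx(12.5e-9)
        assert RATE_ASSAY_CONCENTRATIONS["Rep"] == pytest.approx(25e-9)
        assert PULSE_CONCENTRATIONS["I5"] / PULSE_CONCENTRATIONS["OT"] == 4
        assert PULSE_CONCENTRATIONS["I3"] / PULSE_CONCENTRATIONS["OT"] == 2

    def test_instantaneous_and_fast_explicit_reporter_agree(self):
        t = np.arange(0.0, 500 * MINUTE, MINUTE)
        k = 1.8e5
        inst = build_rate_assay_model(k_disp=k)
        expl = build_rate_assay_model(k_disp=k, reporter="explicit",
                                      k_rep=100 * k)
        si = simulate_network(inst, t)
        se = simulate_network(expl, t)
        a = si.observable(inst.signal_species) / inst.signal_scale
        b = se.observable(expl.signal_species) / expl.signal_scale
        assert np.abs(a - b).max() < 0.02

    def test_no_substrate_gives_flat_zero_signal(self):
        net = build_rate_assay_model(k_disp=1e5,
                                     concentrations={"OT": 0.0})
        sim = simulate_network(net, np.linspace(0, 1e4, 20))
        assert np.all(sim.observable(net.signal_species) == 0.0)


class TestCatalyticModel:
    def test_no_catalyst_no_leak_is_flat(self):
        net = build_catalytic_model(concentrations={"A": 0.0})
        sim = simulate_network(net, np.linspace(0, 3e4, 30))
        assert sim.observable(net.signal_species).max() < 1e-15

    def test_leak_channel_converts_without_catalyst(self):
        # the C2 variant: a strong direct C + B.D channel produces output
        # at every t > 0, exceeding the leak-free system
        t = np.linspace(0, 500 * MINUTE, 60)
        strong = build_catalytic_model(k_leak=1e4,
                                       concentrations={"A": 0.0})
        none = build_catalytic_model(concentrations={"A": 0.0})
        s = simulate_network(strong, t).observable(strong.signal_species)
        z = simulate_network(none, t).observable(none.signal_species)
        assert np.all(s[1:] > z[1:])
        assert s[-1] > 0.5 * strong.signal_scale

    def test_catalyst_accelerates_conversion(self):
        t = np.linspace(0, 500 * MINUTE, 60)
        on = build_catalytic_model(k_leak=10.0)
        off = build_catalytic_model(k_leak=10.0, concentrations={"A": 0.0})
        son = simulate_network(on, t).observable(on.signal_species)
        soff = simulate_network(off, t).observable(off.signal_species)
        assert son[-1] > 5 * soff[-1]

    def test_symmetric_exchange_with_sink_runs_to_completion(self):
        # the reporter sink keeps removing B, so even a neutral exchange
        # eventually converts all substrate
        net = build_catalytic_model()
        sim = simulate_network(net, np.linspace(0, 2e6, 80))
        released = sim["BF"][-1] + sim["B"][-1]
        assert released == pytest.approx(CATALYTIC_CONCENTRATIONS["BD"],
                                         rel=1e-3)

    def test_equilibrium_yield_unaffected_by_catalysis(self):
        # reporter disabled; both systems share the weak leak channel so
        # the uncatalysed one can equilibrate at all
        t = np.linspace(0, 6e6, 120)
        yields = {}
        for a0 in (CATALYTIC_CONCENTRATIONS["A"], 0.0):
            net = build_catalytic_model(k_leak=100.0, reporter=False,
                                        concentrations={"A": a0})
            sim = simulate_network(net, t)
            bd, cd = sim["BD"][-1], sim["CD"][-1]
            yields[a0] = cd / (bd + cd)
        a, b = yields.values()
        assert abs(a - b) / b < 1e-3

    def test_hidden_driving_orderings(self):
        # stronger reverse-rate bias on the second exchange (mismatch
        # eliminated in C.D) raises catalysed conversion at fixed leak;
        # a direct leak channel raises uncatalysed conversion
        t = np.linspace(0, 500 * MINUTE, 60)
        base = build_catalytic_model(k_leak=10.0)
        driven = build_catalytic_model(k2r=5e3, k_leak=10.0)
        s0 = simulate_network(base, t).observable(base.signal_species)
        s1 = simulate_network(driven, t).observable(driven.signal_species)
        assert np.all(s1[1:] >= s0[1:] * (1 - 1e-6))
        assert s1[5] > s0[5]
        quiet = build_catalytic_model(k_leak=10.0,
                                      concentrations={"A": 0.0})
        noisy = build_catalytic_model(k_leak=1e4,
                                      concentrations={"A": 0.0})
        q = simulate_network(quiet, t).observable(quiet.signal_species)
        n = simulate_network(noisy, t).observable(noisy.signal_species)
        assert np.all(n[1:] > q[1:])

    def test_inconsistent_leak_reverse_rate_warns(self):
        with pytest.warns(UserWarning, match="cycle"):
            build_catalytic_model(k_leak=100.0, k_leakr=123.0)


class TestPulseModel:
    def test_fast_i3_gives_interior_maximum_then_decay(self):
        net = build_pulse_model()
        t = np.arange(0.0, 500 * MINUTE, MINUTE)
        sim = simulate_network(net, t)
        i3t = sim["I3T"]
        peak = i3t.argmax()
        assert 0 < peak < len(t) - 1
        assert i3t[-1] < 0.6 * i3t[peak]
        assert sim["I5T"][-1] > i3t[-1]

    def test_symmetric_rates_and_equal_invaders_coincide(self):
        net = build_pulse_model(k3=1e4, k3r=5.0, k5=1e4, k5r=5.0,
                                k_ex=1e4, k_exr=1e4,
                                concentrations={"I3": 50e-9, "I5": 50e-9})
        sim = simulate_network(net, np.linspace(0, 3e4, 40))
        assert np.allclose(sim["I3T"], sim["I5T"], rtol=1e-6, atol=1e-15)

    def test_equilibrium_invariant_under_uniform_rescaling(self):
        slow = build_pulse_model()
        fast = build_pulse_model(k3=1e6, k3r=500.0, k5=5e4, k5r=25.0,
                                 k_ex=5e4, k_exr=5e4)
        eq_slow = simulate_network(slow, np.linspace(0, 4e7, 50))
        eq_fast = simulate_network(fast, np.linspace(0, 4e6, 50))
        for sp in ("I3T", "I5T", "OT"):
            assert eq_slow[sp][-1] == pytest.approx(eq_fast[sp][-1],
                                                    rel=1e-4)

    def test_cycle_violation_warns(self):
        with pytest.warns(UserWarning, match="cycle"):
            build_pulse_model(k_exr=1.0)


class TestNormalizeTrace:
    def test_max_window_maps_to_one(self):
        t = np.arange(0.0, 100 * MINUTE, MINUTE)
        sig = np.where(t < 30 * MINUTE, 2.0, 10.0)
        tr = normalize_trace(Trace(t, sig), (0, 20 * MINUTE),
                             (60 * MINUTE, 90 * MINUTE))
        assert np.all(tr.signal[t >= 60 * MINUTE] == 1.0)
        assert np.all(tr.signal[t < 20 * MINUTE] == 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 200 * MINUTE, MINUTE)
        sig = np.cumsum(rng.random(len(t)))
        raw = Trace(t, sig)
        scaled = Trace(t, 3.7 * sig - 11.0)
        w1, w2 = (0, 30 * MINUTE), (150 * MINUTE, 199 * MINUTE)
        assert np.allclose(normalize_trace(raw, w1, w2).signal,
                           normalize_trace(scaled, w1, w2).signal,
                           rtol=1e-12)

    def test_degenerate_trace_rejected(self):
        t = np.arange(0.0, 10 * MINUTE, MINUTE)
        with pytest.raises(DegenerateTraceError):
            normalize_trace(Trace(t, np.ones_like(t)), (0, 120), (300, 500))

    def test_catalytic_normalization_matches_fractional_conversion(self):
        # normalizing a synthetic catalytic run against its own endpoint
        # reproduces the raw fractional conversion of B
        net = build_catalytic_model(k1=2e6, k2=2e6, k1r=2e4, k2r=2e4,
                                    k_leak=100.0)
        t = np.arange(0.0, 2000 * MINUTE, MINUTE)
        sim = simulate_network(net, t)
        frac = sim["BF"] / net.signal_scale
        arb = Trace(t, 40.0 + 900.0 * frac)  # arbitrary affine readout
        norm = normalize_trace(arb, (0.0, 0.0),
                               (t[-1] - 10 * MINUTE, t[-1]))
        tail = frac[-11:].mean()
        assert np.allclose(norm.signal, frac / tail, atol=2e-3)


class TestFitRateConstant:
    def test_noiseless_self_consistency_within_one_percent(self):
        k = 2.6e3
        tr = generate_trace(build_rate_assay_model(k_disp=k),
                            simple_protocol(500 * MINUTE),
                            NoiseModel(sigma_abs=0.0))
        fit = fit_rate_constant(tr, build_rate_assay_model, ["k_disp"],
                                {"k_disp": 1e4})
        assert fit.converged
        assert abs(fit["k_disp"] - k) / k < 0.01

    def test_fit_is_deterministic(self):
        tr = generate_trace(build_rate_assay_model(k_disp=5e4),
                            simple_protocol(200 * MINUTE),
                            NoiseModel(sigma_abs=0.01, seed=3))
        a = fit_rate_constant(tr, build_rate_assay_model, ["k_disp"],
                              {"k_disp": 1e4})
        b = fit_rate_constant(tr, build_rate_assay_model, ["k_disp"],
                              {"k_disp": 1e4})
        assert a.params == b.params
        assert a.rss == b.rss

    def test_noisy_replicates_unbiased(self):
        # 2% full-scale Gaussian noise, 50 seeded replicates: the mean
        # fitted constant must sit within 2 SE of the generating value
        k = 2.6e3
        net = build_rate_assay_model(k_disp=k)
        protocol = simple_protocol(500 * MINUTE, sample_interval=120.0)
        fits = []
        for seed in range(50):
            tr = generate_trace(net, protocol,
                                NoiseModel(sigma_abs=0.02, seed=seed))
            res = fit_rate_constant(tr, build_rate_assay_model, ["k_disp"],
                                    {"k_disp": 1e3}, n_starts=1)
            fits.append(res["k_disp"])
        fits = np.array(fits)
        se = fits.std(ddof=1) / np.sqrt(len(fits))
        assert abs(fits.mean() - k) < 2 * se

    def test_too_few_points_rejected(self):
        tr = Trace(np.array([0.0, 60.0]), np.array([0.0, 0.1]))
        with pytest.raises(KineticsError):
            fit_rate_constant(tr, build_rate_assay_model, ["k_disp"],
                              {"k_disp": 1e4})
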