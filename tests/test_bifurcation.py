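import numpy as np
import pytest

import fearsis as fs
from fearsis.bifurcation import (
    detect_limit_cycle,
    find_hopf_threshold,
    forward_threshold_beta,
    matignon_margin,
    perturbed_equilibrium,
    predator_invasion_threshold_beta,
    sweep,
)
from fearsis.model import jacobian


class TestForwardThresholds:
    def test_disease_invasion_threshold(self, table_params):
        assert forward_threshold_beta(table_params) == pytest.approx(0.05, rel=1e-12)

    def test_threshold_inverse_in_recruitment(self, table_params):
        doubled = table_params.replace(Lambda=2 * table_params.Lambda)
        assert forward_threshold_beta(doubled) == pytest.approx(
            forward_threshold_beta(table_params) / 2
        )

    def test_r0_is_one_at_threshold(self, table_params):
        p = table_params.replace(beta=forward_threshold_beta(table_params))
        assert fs.basic_reproduction_number(p) == pytest.approx(1.0, rel=1e-12)

    def test_predator_invasion_threshold(self, table_params):
        thr = predator_invasion_threshold_beta(table_params)
        assert thr == pytest.approx(1 / 19, rel=1e-12)
        # R0 at the invasion threshold
        R0 = fs.basic_reproduction_number(table_params.replace(beta=thr))
        assert R0 == pytest.approx(20 / 19, rel=1e-12)

    def test_predator_invasion_threshold_small_saturation(self, table_params):
        # a -> 0: sigma -> d/n = 0.5, threshold -> (delta+omega)*mu/(Lambda-0.25)
        p = table_params.replace(a=1e-9)
        assert predator_invasion_threshold_beta(p) == pytest.approx(0.5 / 9.75, rel=1e-6)

    def test_invasion_eigenvalue_crosses_zero_at_threshold(self, table_params):
        thr = predator_invasion_threshold_beta(table_params)
        lo = fs.invasion_eigenvalue(table_params.replace(beta=thr * 0.999))
        hi = fs.invasion_eigenvalue(table_params.replace(beta=thr * 1.001))
        assert lo < 0 < hi

    def test_absent_when_predator_cannot_invade(self, table_params):
        assert predator_invasion_threshold_beta(table_params.replace(n=0.4)) is None


class TestMatignonMargin:
    def test_all_real_negative_spectrum(self, table_params):
        # at beta=0.04 the disease-free spectrum is real negative:
        # margin = alpha*pi/2 - pi < 0 for any alpha <= 1
        p = table_params.replace(beta=0.04)
        assert matignon_margin(p, "pdpf") == pytest.approx(0.95 * np.pi / 2 - np.pi)

    def test_positive_past_hopf(self, table_params):
        assert matignon_margin(table_params.replace(beta=0.6), "cep") > 0

    def test_missing_equilibrium_raises(self, table_params):
        with pytest.raises(ValueError):
            matignon_margin(table_params.replace(beta=0.04), "cep")


class TestHopfThreshold:
    def test_beta_threshold_location(self, table_params):
        res = find_hopf_threshold(table_params, "beta", (0.055, 0.08))
        assert res.value == pytest.approx(0.0651, rel=5e-3)
        assert abs(res.margin_residual) < 1e-6
        assert res.method == "margin-bisection"

    def test_alpha_threshold_matches_closed_form(self, table_params):
        # margin root in alpha must equal (2/pi) atan(Im/Re) of the unstable
        # eigenpair, since the spectrum does not depend on alpha
        res = find_hopf_threshold(table_params, "alpha", (0.5, 0.9999))
        eigs = np.linalg.eigvals(jacobian(fs.cep(table_params), table_params))
        pair = eigs[np.abs(eigs.imag) > 1e-10][0]
        closed = 2 / np.pi * np.arctan(abs(pair.imag) / pair.real)
        assert res.value == pytest.approx(closed, abs=1e-5)

    def test_margin_monotone_in_alpha(self, table_params):
        # at a fixed spectrum the margin is strictly increasing in alpha
        margins = [
            matignon_margin(table_params.replace(alpha=a), "cep")
            for a in np.linspace(0.62, 1.0, 10)
        ]
        assert all(m1 < m2 for m1, m2 in zip(margins, margins[1:]))

    def test_no_sign_change_raises(self, table_params):
        with pytest.raises(ValueError, match="sign"):
            find_hopf_threshold(table_params, "beta", (0.7, 0.9))

    def test_losing_equilibrium_raises(self, table_params):
        with pytest.raises(ValueError):
            find_hopf_threshold(table_params, "beta", (0.04, 0.08))


class TestCycleDetection:
    def test_constant_trajectory_is_equilibrium(self):
        times = np.linspace(0, 10, 500)
        states = np.tile([3.0, 1.0, 0.5], (500, 1))
        cls, amp = detect_limit_cycle(fs.Trajectory(times, states))
        assert cls == "equilibrium"
        np.testing.assert_allclose(amp, 0.0)

    def test_sinusoid_amplitude_recovered(self):
        times = np.linspace(0, 100, 4000)
        A, mean = 0.7, 5.0
        states = np.column_stack(
            [mean + A * np.sin(times), np.ones_like(times), np.ones_like(times)]
        )
        cls, amp = detect_limit_cycle(fs.Trajectory(times, states))
        assert cls == "cycle"
        assert amp[0] == pytest.approx(2 * A / mean, rel=0.05)

    def test_short_tail_rejected(self):
        times = np.linspace(0, 1, 50)
        states = np.zeros((50, 3))
        with pytest.raises(ValueError):
            detect_limit_cycle(fs.Trajectory(times, states))


class TestSweep:
    def test_grid_must_be_monotone(self, table_params):
        with pytest.raises(ValueError):
            sweep(table_params, "beta", [0.1, 0.05, 0.2])

    def test_sweep_from_exact_stable_equilibrium_has_zero_amplitude(self, table_params):
        p = table_params.replace(beta=1.8367)  # re-stabilised interior point
        res = sweep(
            p, "beta", [1.8367], fs.SolverConfig(h=0.05, t_end=50.0), y0=fs.cep(p)
        )
        assert res.classes == ["equilibrium"]
        assert np.max(res.amplitudes) < 1e-6

    def test_cycle_amplitude_shrinks_toward_hopf_point(self, table_params):
        # approaching the Hopf threshold (~0.0653) from the unstable side the
        # limit-cycle amplitude must decrease
        cfg = fs.SolverConfig(h=0.05, t_end=1000.0)
        res = sweep(table_params, "beta", [0.10, 0.085, 0.075, 0.068], cfg)
        amps = res.amplitudes.max(axis=1)
        assert res.classes[0] == "cycle"
        assert all(a1 > a2 for a1, a2 in zip(amps, amps[1:]))

    def test_sweep_frame_columns(self, table_params):
        p = table_params.replace(beta=1.8367)
        res = sweep(p, "beta", [1.8367], fs.SolverConfig(h=0.05, t_end=50.0), y0=fs.cep(p))
        df = res.to_frame()
        assert list(df.columns) == [
            "beta", "class", "S_min", "S_max", "I_min", "I_max", "P_min", "P_max",
        ]


def test_default_initial_condition_rule(table_params):
    # interior point exists for the default set: +5% on every component
    y0 = perturbed_equilibrium(table_params)
    np.testing.assert_allclose(y0, fs.cep(table_params) * 1.05)
    # disease-free only: zero components replaced by a small inoculum
    p = table_params.replace(beta=0.04)
    y0 = perturbed_equilibrium(p)
    np.testing.assert_allclose(y0, [21.0, 0.1, 0.1])
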