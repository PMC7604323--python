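"""Floquet machinery, phase diffusion, synchronization and chain theory."""

import numpy as np
import pytest

from eiwaves.params import (CASE_B, CASE_C, ModuleParams, coupling_profile,
                            reference_case)
from eiwaves.rate import simulate_deterministic, simulate_stochastic
from eiwaves import theory as th


class TestFixedPoint:
    def test_alpha_linearity_in_weights(self, case_a, table):
        from dataclasses import replace

        a1, b1 = th.effective_constants(case_a, table)
        a2, b2 = th.effective_constants(replace(case_a, w_EE=2 * case_a.w_EE),
                                        table)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)
        a3, b3 = th.effective_constants(replace(case_a, w_EI=2 * case_a.w_EI),
                                        table)
        assert b3 == pytest.approx(2 * b1, rel=1e-12)
        a0, _ = th.effective_constants(replace(case_a, w_EE=0.0), table)
        assert a0 == 0.0

    def test_case_a_is_oscillatory_unstable(self, case_a, table):
        rep = th.fixed_point_stability(case_a, table)
        assert rep.classification == "unstable-complex"

    def test_weak_coupling_is_stable(self, table):
        p = ModuleParams(w_EE=0.3, w_IE=1.0, w_EI=0.5)
        rep = th.fixed_point_stability(p, table)
        assert rep.stable and rep.alpha < 1.0

    def test_closed_form_matches_eigendecomposition(self, table):
        """Characteristic-polynomial classification equals the direct
        eigenvalue classification for random synaptic weights."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            p = ModuleParams(w_EE=rng.uniform(0.0, 2.5),
                             w_IE=rng.uniform(0.1, 3.0),
                             w_EI=rng.uniform(0.02, 1.2))
            rep = th.fixed_point_stability(p, table)
            eig = rep.eigenvalues
            stable = bool(np.all(eig.real < 0))
            complex_ = bool(np.any(np.abs(eig.imag) > 1e-12))
            assert rep.stable == stable
            assert rep.oscillatory == complex_


class TestLimitCycle:
    def test_no_limit_cycle_in_stable_region(self, table):
        p = ModuleParams(w_EE=0.8, w_IE=2.0, w_EI=0.32)
        with pytest.raises(th.NoLimitCycleError):
            th.find_limit_cycle(p, table, transient=800.0, window=600.0)

    def test_cycle_closes(self, cycle_a):
        assert cycle_a.closure < 1e-6
        assert cycle_a.T > 0
        assert np.all(cycle_a.r0_E >= 0)

    def test_phase_origin_at_mean_upcrossing(self, cycle_a):
        mean = cycle_a.r0_E.mean()
        assert cycle_a.r0_E[0] == pytest.approx(mean, abs=0.05)
        assert cycle_a.dI0_E[0] > 0


class TestFloquet:
    def test_neutral_multiplier_and_tangent(self, cycle_a, floquet_a):
        assert abs(complex(floquet_a.mu1) - 1.0) < 1e-3
        tangent = np.array([cycle_a.dI0_E[0], cycle_a.dI0_I[0]])
        e1 = floquet_a.e1[0]
        cosang = np.dot(tangent, e1.real) / (
            np.linalg.norm(tangent) * np.linalg.norm(e1.real))
        assert cosang == pytest.approx(1.0, abs=1e-9)

    def test_biorthogonality_everywhere(self, floquet_a):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, floquet_a.e1.shape[0], size=50)
        for g, e, expect in ((floquet_a.g1, floquet_a.e1, 1.0),
                             (floquet_a.g2, floquet_a.e2, 1.0),
                             (floquet_a.g1, floquet_a.e2, 0.0),
                             (floquet_a.g2, floquet_a.e1, 0.0)):
            dots = np.einsum("ij,ij->i", g[idx], e[idx])
            assert np.allclose(dots, expect, atol=1e-6)

    @pytest.mark.parametrize("case", ["A", "B", "C"])
    def test_observed_cycles_are_stable(self, case, table):
        p = reference_case(case).calibrated(table)
        cyc = th.find_limit_cycle(p, table)
        fd = th.floquet_analysis(cyc, p, table)
        assert abs(fd.mu2) < 1.0


class TestPhaseDiffusion:
    def test_origin_invariance(self, cycle_a, floquet_a, case_a, table):
        """Diffusion constants do not depend on the Poincare-section anchor."""
        D = th.phase_diffusion(cycle_a, floquet_a, case_a, table, 8000, 2000)
        shifted = cycle_a.shifted(cycle_a.n_t // 3)
        fd2 = th.floquet_analysis(shifted, case_a, table)
        D2 = th.phase_diffusion(shifted, fd2, case_a, table, 8000, 2000)
        assert np.allclose(D, D2, rtol=0.02)

    def test_decorrelation_time_linear_in_N(self):
        assert th.decorrelation_time(64.0, 0.25) == pytest.approx(
            10 * th.decorrelation_time(64.0, 2.5))
        with pytest.raises(ValueError):
            th.decorrelation_time(-1.0, 2.5)

    def test_phase_variance_growth_recovers_D_N(self, case_a, table,
                                                cycle_a, floquet_a):
        """Crossing-time phase dispersion of stochastic runs grows at rate
        D_N.  Phases are read from Poincare crossings of the low-passed
        rate (the band-passed Hilbert phase drift is biased by in-band
        noise); mean-square displacements pool all origins of 20 runs."""
        from scipy.signal import butter, sosfiltfilt

        p = case_a.with_N(100_000)
        _, _, D_N = th.phase_diffusion(cycle_a, floquet_a, case_a, table,
                                       p.N_E, p.N_I)
        sos = butter(3, 50, btype="lowpass", fs=10_000.0, output="sos")
        runs = []
        for s in range(20):
            tr = simulate_stochastic(p, table, T_sim=15_000.0, seed=1000 + s)
            tr = tr.discard_transient(2500.0)
            x = sosfiltfilt(sos, tr.r_E[:, 0] - tr.r_E[:, 0].mean())
            up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
            runs.append(tr.t[up] + tr.dt * (-x[up]) / (x[up + 1] - x[up]))
        K = min(len(c) for c in runs)
        tmat = np.array([c[:K] for c in runs])

        def msd(m):
            d = tmat[:, m:] - tmat[:, :-m]
            return d.var(ddof=1)

        slope = (msd(18) - msd(6)) / (12 * cycle_a.T)
        assert slope == pytest.approx(D_N, rel=0.20)


class TestSynchronizationFunction:
    def test_zeros_and_antisymmetry(self, cycle_a, floquet_a, case_a, table):
        T = cycle_a.T
        grid = np.array([0.0, 0.2 * T, 0.5 * T, -0.2 * T])
        for mode in ("EE", "EEI"):
            S = th.sync_function(cycle_a, floquet_a, case_a, table, mode, grid)
            scale = np.max(np.abs(S))
            assert abs(S[0]) < 1e-10 * max(scale, 1.0)
            assert abs(S[2]) < 1e-6 * max(scale, 1.0)   # S(T/2) = 0
            assert S[3] == pytest.approx(-S[1], rel=1e-6)

    def test_slope_at_origin_equals_dphi_constant(self, cycle_a, floquet_a,
                                                  case_a, table):
        for mode in ("EE", "EEI"):
            Dphi = th.dphi_constant(cycle_a, floquet_a, case_a, table, mode)
            eps = 0.05
            S = th.sync_function(cycle_a, floquet_a, case_a, table, mode,
                                 np.array([eps, -eps]))
            slope = (S[0] - S[1]) / (2 * eps)
            assert slope == pytest.approx(-2.0 * Dphi, rel=0.01)

    @pytest.mark.parametrize("case", ["A", "B", "C"])
    def test_dphi_signs(self, case, table):
        p = reference_case(case).calibrated(table)
        cyc = th.find_limit_cycle(p, table)
        fd = th.floquet_analysis(cyc, p, table)
        assert th.dphi_constant(cyc, fd, p, table, "EE") < 0
        assert th.dphi_constant(cyc, fd, p, table, "EEI") > 0


class TestTwoModuleFloquet:
    def test_decoupled_limit(self, cycle_a, case_a, table):
        fd = th.two_module_floquet(cycle_a, case_a, table, "EE", 0.0)
        assert abs(complex(fd.mu1) - 1.0) < 1e-3

    def test_multiplier_slope_matches_dphi(self, cycle_a, floquet_a, case_a,
                                           table):
        """Richardson-extrapolated d mu1/d f_lr equals -2 D_phi T within 2%."""
        mu0 = complex(th.two_module_floquet(cycle_a, case_a, table, "EE",
                                            0.0).mu1).real
        for mode in ("EE", "EEI"):
            Dphi = th.dphi_constant(cycle_a, floquet_a, case_a, table, mode)

            def slope(f):
                mu = complex(th.two_module_floquet(
                    cycle_a, case_a, table, mode, f).mu1).real
                return (mu - mu0) / f

            extrap = 2 * slope(1e-4) - slope(2e-4)
            assert extrap == pytest.approx(-2.0 * Dphi * cycle_a.T, rel=0.02)

    def test_critical_coupling_spans_printed_band(self, table):
        """f_lr* sweeps the 2-7% band as w_IE varies at fixed inhibitory
        feedback: ~2% at the weak end, ~7% at the strong end, monotone."""
        feedback = 2.0 * 0.32  # case-A inhibitory loop w_IE * w_EI
        stars = []
        for w_IE in (1.8, 2.4, 3.2):
            p = ModuleParams(w_EE=1.6, w_IE=w_IE,
                             w_EI=feedback / w_IE).calibrated(table)
            cyc = th.find_limit_cycle(p, table)
            stars.append(th.critical_f_lr(cyc, p, table, "EE"))
        assert stars[0] == pytest.approx(0.02, rel=0.15)
        assert stars[-1] == pytest.approx(0.07, rel=0.10)
        assert stars == sorted(stars)
        assert 0.02 <= stars[1] <= 0.07

    def test_bracket_failure_raises(self, cycle_a, case_a, table):
        with pytest.raises(RuntimeError, match="bracket"):
            th.critical_f_lr(cycle_a, case_a, table, "EE", bracket=(0.1, 0.3))


class TestTwoModeVariance:
    def test_vanishes_at_infinite_N(self, cycle_a, case_a, table, floquet_a):
        pred = th.two_mode_variance(cycle_a, case_a, table, 0.05,
                                    int(8e12), int(2e12), floquet=floquet_a)
        assert pred["two_mode"] < 1e-7
        assert pred["phase_periodic"] < 1e-7

    def test_weak_coupling_reduces_to_phase_approximation(
            self, cycle_a, case_a, table, floquet_a):
        pred = th.two_mode_variance(cycle_a, case_a, table, 1e-4,
                                    80_000_000, 20_000_000, floquet=floquet_a)
        assert pred["two_mode"] == pytest.approx(pred["phase_linear"], rel=0.05)

    def test_scales_inversely_with_N(self, cycle_a, case_a, table, floquet_a):
        a = th.two_mode_variance(cycle_a, case_a, table, 0.05, 80_000, 20_000,
                                 floquet=floquet_a)["two_mode"]
        b = th.two_mode_variance(cycle_a, case_a, table, 0.05, 800_000,
                                 200_000, floquet=floquet_a)["two_mode"]
        assert a == pytest.approx(10 * b, rel=1e-9)

    def test_against_stochastic_simulation(self, cycle_a, case_a, table,
                                           floquet_a):
        """Linear phase+amplitude prediction vs 60 s two-module runs at
        N = 1e5.  At f_lr = 0.1 the linearization is accurate (25%); at
        f_lr = 0.02 phase excursions are a sizable fraction of the period
        and the linear result overestimates, so the band is wider (35%)."""
        p = case_a.with_N(100_000)
        for f_lr, tol in ((0.1, 0.25), (0.02, 0.35)):
            pred = th.two_mode_variance(cycle_a, case_a, table, f_lr,
                                        p.N_E, p.N_I, floquet=floquet_a)
            cp = coupling_profile(2, mode="two_module_EEI", f_lr=f_lr)
            tr = simulate_stochastic(p, table, cp, T_sim=60_500.0, seed=29)
            tr = tr.discard_transient(500.0)
            d = tr.r_E[:, 0] - tr.r_E[:, 1]
            meas = 0.5 * np.mean(d ** 2) - pred["poisson_floor_per_bin"] / tr.dt
            assert pred["two_mode"] == pytest.approx(meas, rel=tol)

    def test_complex_multipliers_give_real_variance(self, cycle_a, case_a,
                                                    table, floquet_a):
        fd = th.two_module_floquet(cycle_a, case_a, table, "EEI", 0.3)
        assert abs(complex(fd.mu1).imag) > 0  # genuinely complex pair
        pred = th.two_mode_variance(cycle_a, case_a, table, 0.3,
                                    80_000, 20_000, floquet=floquet_a)
        assert pred["two_mode"] > 0


class TestChain:
    def test_two_module_equivalence_at_q_pi(self, cycle_a, case_a, table):
        cp = coupling_profile(64, lam=1.0 / 3.0, mode="chain_EEI")
        disp = th.chain_dispersion(cycle_a, case_a, table, cp)
        i_pi = np.argmin(np.abs(disp["q"] - np.pi))
        f_eq = (1.0 - cp.fourier(disp["q"][i_pi])) / 2.0
        fd = th.two_module_floquet(cycle_a, case_a, table, "EEI", f_eq)
        assert np.allclose(np.sort(np.abs(disp["multipliers"][i_pi])),
                           np.sort(np.abs(fd.multipliers)), atol=1e-6)

    def test_neutral_mode_at_q_zero(self, cycle_a, case_a, table):
        cp = coupling_profile(16, lam=1.0 / 3.0, mode="chain_EEI")
        disp = th.chain_dispersion(cycle_a, case_a, table, cp)
        assert abs(np.max(np.abs(disp["multipliers"][0])) - 1.0) < 1e-3

    def test_longest_wavelength_relaxation_rate(self, cycle_a, case_a, table,
                                                floquet_a):
        """The longest-wavelength modulation of a deterministic E->E,I chain
        decays at the exact per-q Floquet rate -ln(mu1)/T; the closed-form
        sigma_q = D_phi^EI [1 - C~(q)] is its weak-coupling expansion and
        approaches the exact rate at long chains."""
        Dphi = th.dphi_constant(cycle_a, floquet_a, case_a, table, "EEI")
        for L in (64, 128):
            cp = coupling_profile(L, lam=1.0 / 3.0, mode="chain_EEI")
            q = 2.0 * np.pi / L
            f_eff = float(cp.effective_f_lr(q))
            mu1 = complex(th.two_module_floquet(cycle_a, case_a, table,
                                                "EEI", f_eff).mu1).real
            exact_rate = -np.log(mu1) / cycle_a.T
            shift = 1.0 * np.cos(q * np.arange(L))
            idx0 = np.round(shift / cycle_a.h).astype(int) % cycle_a.n_t
            init = (cycle_a.I0_E[idx0], cycle_a.I0_I[idx0])
            tr = simulate_deterministic(case_a, table, cp, T_sim=5000.0,
                                        init_state=init, record_dt=1.0)
            mod = np.abs(np.fft.fft(tr.r_E, axis=1)[:, 1]) / L
            n_per = int(round(cycle_a.T))
            n_cyc = mod.size // n_per
            env = mod[: n_cyc * n_per].reshape(n_cyc, n_per).max(axis=1)
            t_env = cycle_a.T * (np.arange(n_cyc) + 0.5)
            keep = (t_env > 800.0) & (env > 1e-9)
            slope = -np.polyfit(t_env[keep], np.log(env[keep]), 1)[0]
            assert slope == pytest.approx(exact_rate, rel=0.05)
        # closed form vs exact rate at long wavelength (L = 256)
        cp = coupling_profile(256, lam=1.0 / 3.0, mode="chain_EEI")
        q = 2.0 * np.pi / 256
        mu1 = complex(th.two_module_floquet(
            cycle_a, case_a, table, "EEI",
            float(cp.effective_f_lr(q))).mu1).real
        exact_rate = -np.log(mu1) / cycle_a.T
        assert Dphi * (1.0 - cp.fourier(q)) == pytest.approx(exact_rate,
                                                             rel=0.10)

    def test_phase_spectrum_inverse_square_law(self, cycle_a, case_a, table,
                                               floquet_a):
        cp = coupling_profile(1024, lam=1.0 / 3.0, mode="chain_EEI")
        D_E, D_I, _ = th.phase_diffusion(cycle_a, floquet_a, case_a, table,
                                         8000, 2000)
        Dphi = th.dphi_constant(cycle_a, floquet_a, case_a, table, "EEI")
        q = cp.q_grid[1:]
        ct = cp.fourier(q)
        phi_sq = (D_I / 2000 + D_E / 8000 * ct ** 2) / (2 * Dphi * (1 - ct))
        assert phi_sq[1] / phi_sq[3] == pytest.approx(4.0, rel=0.05)

    def test_spectrum_matches_stochastic_chain(self, cycle_a, case_a, table,
                                               floquet_a):
        """Two-mode spatial power spectrum vs a 20 s stochastic chain run:
        agreement within a factor 1.5 at every wavenumber above 4 cycles."""
        from eiwaves.signal import spatial_power_spectrum

        p = case_a.with_N(10_000)
        cp = coupling_profile(64, lam=1.0 / 3.0, mode="chain_EEI")
        pred = th.chain_spectrum(cycle_a, case_a, table, cp, p.N_E, p.N_I,
                                 bin_ms=0.1, floquet=floquet_a)
        tr = simulate_stochastic(p, table, cp, T_sim=21_000.0, seed=5)
        q, P = spatial_power_spectrum(tr.discard_transient(1000.0))
        sel = pred["q"] >= 2.0 * np.pi * 4 / 64
        ratio = P[1:][sel] / pred["rate_two_mode"][sel]
        assert np.all(ratio < 1.5) and np.all(ratio > 1 / 1.5)

    def test_spectrum_scales_inversely_with_N(self, cycle_a, case_a, table,
                                              floquet_a):
        cp = coupling_profile(16, lam=1.0 / 3.0, mode="chain_EEI")
        s1 = th.chain_spectrum(cycle_a, case_a, table, cp, 8000, 2000,
                               floquet=floquet_a)
        s10 = th.chain_spectrum(cycle_a, case_a, table, cp, 80_000, 20_000,
                                floquet=floquet_a)
        assert np.allclose(s1["phi_sq"], 10 * s10["phi_sq"], rtol=1e-9)
        net1 = s1["rate_two_mode"] - s1["poisson_floor"]
        net10 = s10["rate_two_mode"] - s10["poisson_floor"]
        assert np.allclose(net1, 10 * net10, rtol=1e-6)
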