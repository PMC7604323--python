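"""Deterministic and weak-noise theory of the oscillatory E-I module.

Fixed-point stability, the deterministic limit cycle and its Floquet
(monodromy) analysis, finite-size phase-diffusion constants, synchronization
functions for weakly coupled modules, full two-module and chain stability,
and the two-mode (phase + amplitude) fluctuation predictions.

Phase convention: the oscillation phase carries units of time (ms) with
period T, so phase gradients are reported in ms and phase-coupling
constants in 1/ms.

Internal unit system: ms, mV; synaptic weights are converted from the
public mV*s to mV*ms and rates from Hz to 1/ms inside the quadratures, so
that all reported constants come out in the printed units (D in ms,
D_phi in 1/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .eif import TransferTable
from .params import CouplingProfile, ModuleParams, fourier_closed_form
from .rate import simulate_deterministic

__all__ = [
    "LimitCycle", "FloquetData", "StabilityReport", "NoLimitCycleError",
    "effective_constants", "fixed_point_stability", "find_limit_cycle",
    "floquet_analysis", "phase_diffusion", "decorrelation_time",
    "sync_function", "dphi_constant", "two_module_floquet", "critical_f_lr",
    "two_mode_variance", "chain_dispersion", "chain_spectrum",
]


class NoLimitCycleError(RuntimeError):
    """Raised when the deterministic dynamics settles to a fixed point."""


# --------------------------------------------------------------------------
# fixed point
# --------------------------------------------------------------------------

@dataclass
class StabilityReport:
    alpha: float
    beta: float
    tau_E: float           # tau^(FAT) at the excitatory fixed point (ms)
    tau_I: float
    eigenvalues: np.ndarray  # of the linear stability matrix (1/ms)
    classification: str      # {stable,unstable}-{real,complex}

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")

    @property
    def oscillatory(self) -> bool:
        return self.classification.endswith("complex")


def _fixed_point(params: ModuleParams, table: TransferTable):
    I_E_s = table.rate_inverse(params.r_E_s)
    I_I_s = table.rate_inverse(params.r_I_s)
    return I_E_s, I_I_s


def effective_constants(params: ModuleParams, table: TransferTable) -> tuple[float, float]:
    """Dimensionless gain constants of the fixed point.

    ``alpha = Phi'_E(I_E^s) w_EE`` measures recurrent excitation,
    ``beta = Phi'_I(I_I^s) Phi'_E(I_E^s) w_EI w_IE`` the inhibitory feedback
    loop (Hz/mV times mV*s is dimensionless).
    """
    I_E_s, I_I_s = _fixed_point(params, table)
    dE = table.drate(I_E_s)
    dI = table.drate(I_I_s)
    return dE * params.w_EE, dI * dE * params.w_EI * params.w_IE


def stability_matrix(params: ModuleParams, table: TransferTable) -> np.ndarray:
    """Linearization of the module dynamics about the fixed point (1/ms)."""
    I_E_s, I_I_s = _fixed_point(params, table)
    dE = table.drate(I_E_s)    # Hz/mV
    dI = table.drate(I_I_s)
    tE = table.tau(I_E_s)      # ms
    tI = table.tau(I_I_s)
    return np.array([
        [(-1.0 + params.w_EE * dE) / tE, -params.w_EI * dI / tE],
        [params.w_IE * dE / tI, -1.0 / tI],
    ])


def fixed_point_stability(params: ModuleParams, table: TransferTable) -> StabilityReport:
    """Classify the steady state from the characteristic polynomial.

    The growth rates solve ``tau_E tau_I k^2 + [tau_E + tau_I(1-alpha)] k +
    (1 - alpha + beta) = 0``; the classification is cross-checked against the
    eigenvalues of the assembled stability matrix.
    """
    alpha, beta = effective_constants(params, table)
    I_E_s, I_I_s = _fixed_point(params, table)
    tE = float(table.tau(I_E_s))
    tI = float(table.tau(I_I_s))
    roots = np.roots([tE * tI, tE + tI * (1.0 - alpha), 1.0 - alpha + beta])
    stable = np.all(roots.real < 0)
    complex_ = np.any(np.abs(roots.imag) > 1e-12)
    classification = f"{'stable' if stable else 'unstable'}-{'complex' if complex_ else 'real'}"
    eig = np.linalg.eigvals(stability_matrix(params, table))
    return StabilityReport(alpha=alpha, beta=beta, tau_E=tE, tau_I=tI,
                           eigenvalues=eig, classification=classification)


# --------------------------------------------------------------------------
# limit cycle
# --------------------------------------------------------------------------

@dataclass
class LimitCycle:
    """One period of the deterministic orbit, sampled uniformly.

    ``t_grid`` holds ``n_t`` samples with spacing ``T/n_t`` (close to the
    integration step); phase origin t = 0 is the upward crossing of r_E
    through its time mean.  ``dI0`` is the on-model time derivative of the
    currents (mV/ms).
    """

    T: float
    t_grid: np.ndarray
    I0_E: np.ndarray
    I0_I: np.ndarray
    r0_E: np.ndarray
    r0_I: np.ndarray
    dI0_E: np.ndarray
    dI0_I: np.ndarray
    closure: float  # |I(T) - I(0)| of the converged orbit (mV)

    @property
    def n_t(self) -> int:
        return self.t_grid.size

    @property
    def h(self) -> float:
        return self.T / self.n_t

    def shifted(self, k: int) -> "LimitCycle":
        """Cycle with the phase origin moved by k samples (analysis results
        must be invariant under this)."""
        def roll(x):
            return np.roll(x, -k)
        return LimitCycle(self.T, self.t_grid, roll(self.I0_E), roll(self.I0_I),
                          roll(self.r0_E), roll(self.r0_I),
                          roll(self.dI0_E), roll(self.dI0_I), self.closure)

    def fourier_coefficients(self, n_max: int = 12) -> np.ndarray:
        """|r~_n| harmonics of the excitatory rate (Hz), n = 0..n_max."""
        c = np.fft.rfft(self.r0_E) / self.n_t
        return np.abs(c[: n_max + 1])


def find_limit_cycle(
    params: ModuleParams,
    table: TransferTable,
    dt: float = 0.01,
    transient: float = 2000.0,
    window: float = 1500.0,
    min_cycles: int = 10,
    rel_tol: float = 1e-4,
) -> LimitCycle:
    """Locate the stable periodic orbit of the deterministic module.

    Integrates past the transient, detects upward crossings of r_E through
    its time mean (the Poincare section), requires at least ``min_cycles``
    successive crossing intervals agreeing to ``rel_tol`` relative, and
    resamples one period onto a uniform grid by cubic interpolation.
    """
    from scipy.interpolate import CubicSpline

    if params.I_ext_E is None:
        params = params.calibrated(table)
    tr = simulate_deterministic(params, table, T_sim=transient + window,
                                dt=dt, record_dt=dt)
    keep = tr.t >= transient
    t = tr.t[keep]
    rE = tr.r_E[keep, 0]
    if rE.max() - rE.min() < 1e-3:
        raise NoLimitCycleError(
            "no limit cycle: the deterministic trajectory converged to a "
            "fixed point (oscillation amplitude below 1e-3 Hz)")
    x = rE - rE.mean()
    up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
    if up.size < min_cycles + 1:
        raise NoLimitCycleError(
            f"no limit cycle: only {up.size} Poincare crossings in the "
            "detection window")
    tc = t[up] + dt * x[up] / (x[up] - x[up + 1])
    intervals = np.diff(tc)[-min_cycles:]
    T = float(np.mean(intervals))
    if np.max(np.abs(intervals - T)) / T > rel_tol:
        raise NoLimitCycleError(
            "crossing intervals did not converge; increase the transient")
    # average over all complete cycles in the window for a tighter period
    n_full = tc.size - 1
    T = float((tc[-1] - tc[0]) / n_full)

    n_t = int(round(T / dt))
    h = T / n_t
    t0 = tc[-1] - T
    sE = CubicSpline(t, tr.I_E[keep, 0])
    sI = CubicSpline(t, tr.I_I[keep, 0])
    ts = t0 + h * np.arange(n_t)
    I0_E = sE(ts)
    I0_I = sI(ts)
    closure = float(np.hypot(sE(t0 + T) - I0_E[0], sI(t0 + T) - I0_I[0]))
    r0_E = table.rate(I0_E)
    r0_I = table.rate(I0_I)
    dI0_E = (-I0_E + params.I_ext_E + params.w_EE * r0_E - params.w_EI * r0_I) / table.tau(I0_E)
    dI0_I = (-I0_I + params.I_ext_I + params.w_IE * r0_E) / table.tau(I0_I)
    return LimitCycle(T=T, t_grid=h * np.arange(n_t), I0_E=I0_E, I0_I=I0_I,
                      r0_E=r0_E, r0_I=r0_I, dI0_E=dI0_E, dI0_I=dI0_I,
                      closure=closure)


# --------------------------------------------------------------------------
# Floquet machinery
# --------------------------------------------------------------------------

@njit(cache=True)
def _monodromy_kernel(L11, L12, L21, L22, h):
    n = L11.size
    M = np.empty((n + 1, 2, 2))
    a, b, c, d = 1.0, 0.0, 0.0, 1.0
    M[0, 0, 0] = a; M[0, 0, 1] = b; M[0, 1, 0] = c; M[0, 1, 1] = d
    for k in range(n):
        na = a + h * (L11[k] * a + L12[k] * c)
        nb = b + h * (L11[k] * b + L12[k] * d)
        nc = c + h * (L21[k] * a + L22[k] * c)
        nd = d + h * (L21[k] * b + L22[k] * d)
        a, b, c, d = na, nb, nc, nd
        M[k + 1, 0, 0] = a; M[k + 1, 0, 1] = b; M[k + 1, 1, 0] = c; M[k + 1, 1, 1] = d
    return M


def _linearization(cycle: LimitCycle, params: ModuleParams, table: TransferTable,
                   cE: float = 1.0, cI: float = 1.0):
    """Entries of the periodic linearization matrix L(t) along the cycle (1/ms).

    ``cE``/``cI`` rescale the recurrent excitatory gain terms; they encode
    the antisymmetric two-module problem (c = 1 - 2 f_lr) and the per-
    wavenumber chain problem (c = C~(q)).
    """
    dphiE = table.drate(cycle.I0_E)      # Hz/mV
    dphiI = table.drate(cycle.I0_I)
    tauE = table.tau(cycle.I0_E)         # ms
    tauI = table.tau(cycle.I0_I)
    dtauE = table.dtau_dI(cycle.I0_E)    # ms/mV
    dtauI = table.dtau_dI(cycle.I0_I)
    L11 = (-1.0 + cE * params.w_EE * dphiE - dtauE * cycle.dI0_E) / tauE
    L12 = -params.w_EI * dphiI / tauE
    L21 = cI * params.w_IE * dphiE / tauI
    L22 = -(1.0 + dtauI * cycle.dI0_I) / tauI
    return L11, L12, L21, L22


def _monodromy(cycle, params, table, cE=1.0, cI=1.0) -> np.ndarray:
    L11, L12, L21, L22 = _linearization(cycle, params, table, cE, cI)
    return _monodromy_kernel(L11, L12, L21, L22, cycle.h)


@dataclass
class FloquetData:
    """Monodromy matrix, multipliers and biorthogonal periodic bases.

    ``e1`` is the tangent mode (neutral, multiplier 1); ``g1`` its adjoint,
    the phase-response vector of the module.  ``g_i(t) . e_j(t) = delta_ij``
    at every sample by construction.
    """

    M_T: np.ndarray
    mu1: complex
    mu2: complex
    e1: np.ndarray   # (n_t, 2)
    e2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    M_t: np.ndarray  # (n_t + 1, 2, 2)

    @property
    def multipliers(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2])


def _floquet_from_monodromy(M: np.ndarray, e1_0: np.ndarray | None = None) -> FloquetData:
    """Multipliers and periodic biorthogonal bases from a monodromy history.

    ``e1_0`` overrides the first eigenvector; the single-module analysis
    passes the cycle tangent there (the exact neutral mode, which the
    numerical eigenvector only approximates).  Coupled-mode problems must
    use the true eigenvectors, so they leave it unset.
    """
    n_t = M.shape[0] - 1
    M_T = M[n_t]
    w, V = np.linalg.eig(M_T)
    # order: mu1 = multiplier closest to the neutral value 1; complex pairs
    # are kept as conjugates
    order = np.argsort(np.abs(w - 1.0))
    w = w[order]
    V = V[:, order]
    mu1, mu2 = w
    if abs(mu1.imag) < 1e-12 and abs(mu2.imag) < 1e-12:
        w = w.real
        V = V.real
        mu1, mu2 = float(w[0]), float(w[1])
        dtype = float
    else:
        dtype = complex
    e1_vec = (np.asarray(e1_0, dtype=dtype) if e1_0 is not None
              else V[:, 0].astype(dtype))
    e2_vec = V[:, 1].astype(dtype)
    Mt = M[:n_t].astype(dtype)
    e1 = Mt @ e1_vec
    e2 = Mt @ e2_vec
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    if np.any(np.abs(det) < 1e-14):
        raise RuntimeError("ill-conditioned Floquet basis (tangent and "
                           "second mode nearly parallel)")
    g1 = np.stack([e2[:, 1] / det, -e2[:, 0] / det], axis=1)
    g2 = np.stack([-e1[:, 1] / det, e1[:, 0] / det], axis=1)
    return FloquetData(M_T=M_T, mu1=mu1, mu2=mu2, e1=e1, e2=e2, g1=g1, g2=g2, M_t=M)


def floquet_analysis(cycle: LimitCycle, params: ModuleParams,
                     table: TransferTable) -> FloquetData:
    """Monodromy analysis of the single-module limit cycle.

    Integrates ``dM/dt = L(t) M`` over one period with the same explicit
    Euler scheme used for the trajectory.  The tangent ``(I0_E'(0),
    I0_I'(0))`` is the neutral eigenmode (multiplier 1 up to integration
    error); the second multiplier must lie inside the unit circle for a
    stable orbit.
    """
    if params.I_ext_E is None:
        params = params.calibrated(table)
    M = _monodromy(cycle, params, table)
    e1_0 = np.array([cycle.dI0_E[0], cycle.dI0_I[0]])
    fd = _floquet_from_monodromy(M, e1_0)
    # normalize the adjoint so that g1 . e1 = 1 with e1 the true tangent
    return fd


# --------------------------------------------------------------------------
# phase diffusion and synchronization functions
# --------------------------------------------------------------------------

def _cycle_average(cycle: LimitCycle, integrand: np.ndarray):
    """(1/T) * integral over one period, trapezoid on the periodic grid."""
    return np.sum(integrand) * cycle.h / cycle.T


def phase_diffusion(cycle: LimitCycle, floquet: FloquetData,
                    params: ModuleParams, table: TransferTable,
                    N_E: int | None = None, N_I: int | None = None):
    """Finite-size phase-diffusion constants (D_E, D_I, D_N), all in ms.

    Quadratures of the squared phase-response projections of the Poisson
    noise along the limit cycle; ``D_N = D_E/N_E + D_I/N_I`` is the phase
    diffusion coefficient of a module with the given population sizes.
    """
    N_E = N_E if N_E is not None else params.N_E
    N_I = N_I if N_I is not None else params.N_I
    WEE, WIE, WEI = 1e3 * params.w_EE, 1e3 * params.w_IE, 1e3 * params.w_EI  # mV*ms
    tauE = table.tau(cycle.I0_E)
    tauI = table.tau(cycle.I0_I)
    phiE = 1e-3 * cycle.r0_E  # 1/ms
    phiI = 1e-3 * cycle.r0_I
    g1E = floquet.g1[:, 0].real
    g1I = floquet.g1[:, 1].real
    D_E = _cycle_average(cycle, (g1E * WEE / tauE + g1I * WIE / tauI) ** 2 * phiE)
    D_I = _cycle_average(cycle, (g1E * WEI / tauE) ** 2 * phiI)
    D_N = D_E / N_E + D_I / N_I
    return float(D_E), float(D_I), float(D_N)


def decorrelation_time(T: float, D_N: float) -> float:
    """Autocorrelation decay time tau_D = T^2 / (2 pi^2 D_N) (ms)."""
    if T <= 0 or D_N <= 0:
        raise ValueError("T and D_N must be positive")
    return T ** 2 / (2.0 * np.pi ** 2 * D_N)


def _periodic_shift(cycle: LimitCycle, y: np.ndarray, dphi: float) -> np.ndarray:
    """y(t + dphi) for a T-periodic sampled signal (linear interpolation)."""
    t = cycle.t_grid
    ts = np.mod(t + dphi, cycle.T)
    tp = np.concatenate([t, [cycle.T]])
    yp = np.concatenate([y, [y[0]]])
    return np.interp(ts, tp, yp)


def _phase_response_weight(cycle, floquet, params, table, mode: str):
    """w_EE g1E/tau_E (EE) or w_EE g1E/tau_E + w_IE g1I/tau_I (EEI), mV*ms/ms."""
    WEE, WIE = 1e3 * params.w_EE, 1e3 * params.w_IE
    tauE = table.tau(cycle.I0_E)
    tauI = table.tau(cycle.I0_I)
    g1E = floquet.g1[:, 0].real
    g1I = floquet.g1[:, 1].real
    if mode == "EE":
        return g1E * WEE / tauE
    if mode == "EEI":
        return g1E * WEE / tauE + g1I * WIE / tauI
    raise ValueError("mode must be 'EE' or 'EEI'")


def sync_function(cycle: LimitCycle, floquet: FloquetData, params: ModuleParams,
                  table: TransferTable, mode: str,
                  dphi_grid: np.ndarray) -> np.ndarray:
    """Synchronization function S(dphi) (dimensionless; drift per unit f_lr).

    ``d(Delta phi)/dt = f_lr S(Delta phi)``; S(0) = S(T/2) = 0 by symmetry
    and a negative slope at a zero marks a stable phase difference.
    """
    weight = _phase_response_weight(cycle, floquet, params, table, mode)
    phiE = 1e-3 * cycle.r0_E
    out = np.empty(np.asarray(dphi_grid, dtype=float).size)
    for i, dphi in enumerate(np.atleast_1d(dphi_grid)):
        diff = (_periodic_shift(cycle, phiE, -dphi)
                - _periodic_shift(cycle, phiE, +dphi))
        out[i] = _cycle_average(cycle, weight * diff)
    return out


def dphi_constant(cycle: LimitCycle, floquet: FloquetData, params: ModuleParams,
                  table: TransferTable, mode: str) -> float:
    """Phase-coupling constant D_phi (1/ms): S(dphi) ~ -2 dphi D_phi.

    Negative for E->E connectivity (in-phase locking unstable at weak
    coupling), positive for E->E,I (synchronizing).
    """
    weight = _phase_response_weight(cycle, floquet, params, table, mode)
    dphiE = 1e-3 * table.drate(cycle.I0_E)  # 1/(ms mV)
    return float(_cycle_average(cycle, weight * dphiE * cycle.dI0_E))


# --------------------------------------------------------------------------
# two-module Floquet problem and noise-synchronization competition
# --------------------------------------------------------------------------

def _mode_couplings(mode: str, c: float) -> tuple[float, float]:
    if mode == "EE":
        return c, 1.0
    if mode == "EEI":
        return c, c
    raise ValueError("mode must be 'EE' or 'EEI'")


def two_module_floquet(cycle: LimitCycle, params: ModuleParams,
                       table: TransferTable, mode: str,
                       f_lr: float) -> FloquetData:
    """Floquet problem of the antisymmetric (phase-difference) perturbation.

    The antisymmetric linearization equals the single-module L(t) with the
    recurrent excitatory gain rescaled by ``1 - 2 f_lr`` (E->E: the E->E
    term only; E->E,I: both excitatory terms).  Its largest multiplier
    crossing 1 marks loss of full synchrony.
    """
    if params.I_ext_E is None:
        params = params.calibrated(table)
    if not 0.0 <= f_lr <= 0.5:
        raise ValueError("f_lr must lie in [0, 0.5]")
    cE, cI = _mode_couplings(mode, 1.0 - 2.0 * f_lr)
    M = _monodromy(cycle, params, table, cE, cI)
    return _floquet_from_monodromy(M)


def _max_multiplier(cycle, params, table, mode, f_lr) -> float:
    fd = two_module_floquet(cycle, params, table, mode, f_lr)
    return float(np.max(np.abs(fd.multipliers)))


def critical_f_lr(cycle: LimitCycle, params: ModuleParams, table: TransferTable,
                  mode: str = "EE", bracket: tuple[float, float] = (1e-4, 0.3),
                  tol: float = 1e-4) -> float:
    """Long-range fraction f_lr* where the largest antisymmetric multiplier
    crosses 1 (bisection; full synchrony is unstable below f_lr*)."""
    if params.I_ext_E is None:
        params = params.calibrated(table)
    lo, hi = bracket
    f_lo = _max_multiplier(cycle, params, table, mode, lo) - 1.0
    f_hi = _max_multiplier(cycle, params, table, mode, hi) - 1.0
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"bisection bracket failure: multiplier - 1 is {f_lo:.3g} at "
            f"f_lr={lo} and {f_hi:.3g} at f_lr={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (_max_multiplier(cycle, params, table, mode, mid) - 1.0) * f_lo > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def two_mode_variance(cycle: LimitCycle, params: ModuleParams,
                      table: TransferTable, f_lr: float,
                      N_E: int, N_I: int,
                      floquet: FloquetData | None = None) -> dict:
    """Predicted mean-square excitatory rate difference of two coupled modules.

    Returns a dict with three theoretical levels for
    ``<(r_E,1 - r_E,2)^2>/2`` (Hz^2):

    - ``two_mode``: the full linear phase+amplitude calculation around the
      synchronized orbit (valid at any coupling, small noise),
    - ``phase_linear``: the linearized phase approximation (diverges as
      f_lr -> 0),
    - ``phase_periodic``: the phase approximation respecting the
      periodicity of the rate in the phase,

    together with ``phase_msd`` = <(phi_1 - phi_2)^2> (ms^2) and the
    separate Poisson sampling floor per unit bin (Hz^2*ms; divide by the
    sampling bin in ms).
    """
    if params.I_ext_E is None:
        params = params.calibrated(table)
    if floquet is None:
        floquet = floquet_analysis(cycle, params, table)
    mode_fd = two_module_floquet(cycle, params, table, "EEI", f_lr)
    mu = mode_fd.multipliers
    if np.max(np.abs(mu[0] * mu[1])) >= 1.0 or np.max(np.abs(mu) ** 2) >= 1.0:
        raise RuntimeError("non-contracting antisymmetric mode: |mu_j mu_k| >= 1")

    WEE, WIE, WEI = 1e3 * params.w_EE, 1e3 * params.w_IE, 1e3 * params.w_EI
    tauE = table.tau(cycle.I0_E)
    tauI = table.tau(cycle.I0_I)
    phiE = 1e-3 * cycle.r0_E
    phiI = 1e-3 * cycle.r0_I
    dphiE = table.drate(cycle.I0_E)  # Hz/mV (rate output in Hz^2)

    eA = np.stack([mode_fd.e1[:, 0], mode_fd.e2[:, 0]], axis=0)  # (2, n_t), E comp
    g = np.stack([mode_fd.g1, mode_fd.g2], axis=0)               # (2, n_t, 2)
    c = 1.0 - 2.0 * f_lr
    wE = g[:, :, 0] * WEE / tauE + g[:, :, 1] * WIE / tauI       # (2, n_t)
    wI = g[:, :, 0] * WEI / tauE
    # b_jk(u): projected noise covariance along the cycle (non-conjugated
    # products; complex multipliers handled in complex arithmetic)
    b = (c ** 2 * wE[:, None, :] * wE[None, :, :] * phiE / N_E
         + wI[:, None, :] * wI[None, :, :] * phiI / N_I)          # (2, 2, n_t)
    h = cycle.h
    cum = np.concatenate([np.zeros_like(b[..., :1]), np.cumsum(b, axis=-1)], axis=-1)[..., :-1] * h
    total = b.sum(axis=-1) * h                                    # (2, 2)
    mumu = mu[:, None] * mu[None, :]
    kernel = cum + (mumu / (1.0 - mumu))[:, :, None] * total[:, :, None]
    var_I = np.einsum("jt,kt,jkt->t", eA, eA, kernel)             # <delta I_A,E^2>(t)
    two_mode = _cycle_average(cycle, dphiE ** 2 * var_I)
    if np.max(np.abs(np.imag(np.atleast_1d(two_mode)))) > 1e-8 * max(abs(np.real(two_mode)), 1e-300):
        raise RuntimeError("two-mode variance has a non-negligible imaginary part")
    two_mode = float(np.real(two_mode))

    D_E, D_I, _ = phase_diffusion(cycle, floquet, params, table, N_E, N_I)
    D_N = D_E / N_E + D_I / N_I
    Dphi = dphi_constant(cycle, floquet, params, table, "EEI")
    phase_msd = D_N / (2.0 * f_lr * Dphi)
    mean_sq_slope = _cycle_average(cycle, (dphiE * cycle.dI0_E) ** 2)  # Hz^2/ms^2
    phase_linear = 0.5 * phase_msd * mean_sq_slope
    rn = cycle.fourier_coefficients(24)
    n = np.arange(1, rn.size)
    phase_periodic = 2.0 * np.sum(
        rn[1:] ** 2 * (1.0 - np.exp(-2.0 * np.pi ** 2 * n ** 2 * phase_msd / cycle.T ** 2)))
    poisson_floor = float(np.mean(cycle.r0_E)) / N_E * 1e3  # Hz^2 * ms
    return {
        "two_mode": two_mode,
        "phase_linear": float(phase_linear),
        "phase_periodic": float(phase_periodic),
        "phase_msd": float(phase_msd),
        "poisson_floor_per_bin": poisson_floor,
        "multipliers": mu,
    }


# --------------------------------------------------------------------------
# chain: dispersion and spectra
# --------------------------------------------------------------------------

def q_star_from_f(f_lr_star: float, lam: float) -> tuple[float, float]:
    """Critical chain wavenumber from the two-module threshold coupling.

    Exact inversion of C~(q) = 1 - 2 f_lr* for the exponential profile, and
    its small-lambda approximation q = lam sqrt(2 f/(1-2f)); both in units
    of lam.
    """
    c = 1.0 - 2.0 * f_lr_star
    cosq = (1.0 - 2.0 * f_lr_star * np.cosh(lam)) / c
    exact = float(np.arccos(cosq) / lam)
    approx = float(np.sqrt(2.0 * f_lr_star / c))
    return exact, approx


def chain_dispersion(cycle: LimitCycle, params: ModuleParams,
                     table: TransferTable, coupling: CouplingProfile) -> dict:
    """Stability of the fully synchronized chain, wavenumber by wavenumber.

    Each spatial mode q maps onto the two-module antisymmetric problem with
    effective gain ``C~(q)``.  For E->E connectivity the report includes the
    critical wavenumber q* (largest multiplier crossing 1) and the
    fastest-growing wavenumber q_m, both in units of lambda; for E->E,I all
    modes are stable and the long-wavelength relaxation rate
    ``sigma_q = D_phi^EI [1 - C~(q)]`` is reported instead.
    """
    if params.I_ext_E is None:
        params = params.calibrated(table)
    mode = "EE" if coupling.mode.endswith("_EE") else "EEI"
    qs = coupling.q_grid
    mults = np.empty((qs.size, 2), dtype=complex)
    for i, q in enumerate(qs):
        cE, cI = _mode_couplings(mode, float(coupling.fourier(q)))
        fd = _floquet_from_monodromy(_monodromy(cycle, params, table, cE, cI))
        mults[i] = fd.multipliers
    out = {"q": qs, "multipliers": mults, "mode": mode}
    lam = coupling.lam
    if mode == "EE":
        f_star = critical_f_lr(cycle, params, table, "EE")
        exact, approx = q_star_from_f(f_star, lam)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda f: -_max_multiplier(cycle, params, table, "EE", f),
            bounds=(1e-4, f_star), method="bounded", options={"xatol": 1e-5})
        f_m = float(res.x)
        qm_exact, qm_approx = q_star_from_f(f_m, lam)
        out.update(f_lr_star=f_star, q_star=exact * lam, q_star_over_lam=exact,
                   q_star_over_lam_approx=approx, f_lr_max_growth=f_m,
                   q_m=qm_exact * lam, q_m_over_lam=qm_exact,
                   q_m_over_lam_approx=qm_approx)
    else:
        floquet = floquet_analysis(cycle, params, table)
        Dphi = dphi_constant(cycle, floquet, params, table, "EEI")
        sigma_exact = Dphi * (1.0 - coupling.fourier(qs))
        sigma_small_q = Dphi * qs ** 2 / (2.0 * (np.cosh(lam) - 1.0))
        out.update(sigma_q=sigma_exact, sigma_q_small=sigma_small_q, D_phi_EI=Dphi)
    return out


def _two_mode_spectrum_at_q(cycle, params, table, ctilde, N_E, N_I) -> float:
    """Time-averaged <|r~_E,q|^2> (Hz^2) of one chain Fourier mode, from the
    linear phase+amplitude calculation (Hermitian products, valid for
    complex multipliers)."""
    cE, cI = ctilde, ctilde
    fd = _floquet_from_monodromy(_monodromy(cycle, params, table, cE, cI))
    mu = fd.multipliers
    if np.max(np.abs(mu)) >= 1.0:
        raise RuntimeError("non-contracting chain mode")
    WEE, WIE, WEI = 1e3 * params.w_EE, 1e3 * params.w_IE, 1e3 * params.w_EI
    tauE = table.tau(cycle.I0_E)
    tauI = table.tau(cycle.I0_I)
    phiE = 1e-3 * cycle.r0_E
    phiI = 1e-3 * cycle.r0_I
    dphiE = table.drate(cycle.I0_E)
    eA = np.stack([fd.e1[:, 0], fd.e2[:, 0]], axis=0)
    g = np.stack([fd.g1, fd.g2], axis=0)
    wE = g[:, :, 0] * WEE / tauE + g[:, :, 1] * WIE / tauI
    wI = g[:, :, 0] * WEI / tauE
    b = (ctilde ** 2 * wE[:, None, :] * np.conj(wE)[None, :, :] * phiE / N_E
         + wI[:, None, :] * np.conj(wI)[None, :, :] * phiI / N_I)
    h = cycle.h
    cum = np.concatenate([np.zeros_like(b[..., :1]), np.cumsum(b, axis=-1)], axis=-1)[..., :-1] * h
    total = b.sum(axis=-1) * h
    mumu = mu[:, None] * np.conj(mu)[None, :]
    kernel = cum + (mumu / (1.0 - mumu))[:, :, None] * total[:, :, None]
    var_I = np.einsum("jt,kt,jkt->t", eA, np.conj(eA), kernel)
    return float(np.real(_cycle_average(cycle, dphiE ** 2 * var_I)))


def chain_spectrum(cycle: LimitCycle, params: ModuleParams, table: TransferTable,
                   coupling: CouplingProfile, N_E: int, N_I: int,
                   bin_ms: float = 0.1,
                   floquet: FloquetData | None = None) -> dict:
    """Predicted spatial power spectra of a stochastic E->E,I chain.

    Per wavenumber q = 2 pi k/L (q = 0 is the neutral global phase and is
    skipped): the phase mean-square amplitude ``<|phi~_q|^2>`` (ms^2), the
    rate spectrum in the phase approximation (periodicity-aware), and the
    two-mode (phase+amplitude) rate spectrum including the Poisson sampling
    floor ``<r0_E>/(N_E bin)``.  Spatial Fourier convention:
    ``r~_q = L^{-1/2} sum_n delta r_n exp(-i q n)``, matching
    ``signal_analysis.spatial_power_spectrum``.
    """
    if params.I_ext_E is None:
        params = params.calibrated(table)
    if not coupling.targets_inhibitory:
        raise ValueError("chain_spectrum applies to the synchronizing E->E,I mode")
    if floquet is None:
        floquet = floquet_analysis(cycle, params, table)
    D_E, D_I, _ = phase_diffusion(cycle, floquet, params, table, N_E, N_I)
    Dphi = dphi_constant(cycle, floquet, params, table, "EEI")
    qs = coupling.q_grid[1:]  # skip the neutral q = 0 mode
    ct = coupling.fourier(qs)
    phi_sq = (D_I / N_I + D_E / N_E * ct ** 2) / (2.0 * Dphi * (1.0 - ct))

    # phase-approximation rate spectrum, periodicity respected
    L = coupling.L
    full_phi_sq = np.concatenate([[0.0], phi_sq])
    dq = coupling.q_grid
    deltas = np.arange(L)
    # <(phi_n - phi_{n+d})^2> = (2/L) sum_q <|phi_q|^2>(1 - cos q d)
    msd = (2.0 / L) * ((full_phi_sq[None, :] *
                        (1.0 - np.cos(dq[None, :] * deltas[:, None]))).sum(axis=1))
    rn = cycle.fourier_coefficients(24)
    n = np.arange(1, rn.size)
    C_delta = 2.0 * (rn[None, 1:] ** 2 *
                     np.exp(-2.0 * np.pi ** 2 * n[None, :] ** 2 * msd[:, None]
                            / cycle.T ** 2)).sum(axis=1)
    rate_phase = np.array([(C_delta * np.cos(q * deltas)).sum() for q in qs])
    poisson = float(np.mean(cycle.r0_E)) / (N_E * 1e-3 * bin_ms)

    rate_two_mode = np.array([
        _two_mode_spectrum_at_q(cycle, params, table, float(c), N_E, N_I)
        for c in ct])
    return {
        "q": qs, "ctilde": ct, "phi_sq": phi_sq,
        "rate_phase": rate_phase + poisson,
        "rate_two_mode": rate_two_mode + poisson,
        "poisson_floor": poisson, "D_E": D_E, "D_I": D_I, "D_phi_EI": Dphi,
    }
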