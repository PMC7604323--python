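"""Single-neuron EIF numerics.

Steady-state firing rate, linear rate response and the fitted adaptive
timescale of the exponential integrate-and-fire (EIF) neuron driven by white
noise, computed with the threshold-integration method for the associated
Fokker-Planck equation.  The results are packaged into an interpolable
:class:`TransferTable` (f-I curve, its derivatives and the adaptive timescale
on a uniform current grid) that all population-level modules build on.

Units: voltages in mV, times in ms, rates in Hz, currents in mV (input
current divided by the leak conductance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EIFParams",
    "TransferTable",
    "steady_rate",
    "linear_response",
    "fit_adaptive_timescale",
    "build_transfer_table",
]


@dataclass(frozen=True)
class EIFParams:
    """Parameters of a noise-driven EIF neuron.

    The membrane potential obeys
    ``tau_m dV/dt = E_L - V + Delta_T exp((V - V_T)/Delta_T) + I + sigma sqrt(tau_m) xi``
    with a spike registered at ``V >= V_thresh`` followed by a reset to
    ``V_reset`` held for ``tau_ref``.
    """

    tau_m: float = 10.0      # membrane time constant (ms)
    E_L: float = -65.0       # leak/resting potential (mV)
    V_T: float = -59.9       # spike threshold potential (mV)
    Delta_T: float = 3.5     # spike sharpness (mV)
    V_reset: float = -68.0   # reset potential (mV)
    V_thresh: float = -30.0  # numerical spike cutoff (mV)
    tau_ref: float = 1.7     # refractory period (ms)
    sigma: float = 10.0      # total noise strength (mV)

    def __post_init__(self) -> None:
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must lie below V_thresh")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.sigma <= 0:
            raise ValueError(
                "sigma must be positive: the noise-free regime is not "
                "supported by the diffusion (Fokker-Planck) formulation"
            )

    def psi(self, V: np.ndarray) -> np.ndarray:
        """Deterministic membrane drift E_L - V + Delta_T exp((V-V_T)/Delta_T) (mV)."""
        arg = np.minimum((np.asarray(V) - self.V_T) / self.Delta_T, 30.0)
        return self.E_L - V + self.Delta_T * np.exp(arg)


def _voltage_grid(params: EIFParams, dV: float) -> np.ndarray:
    """Uniform grid from the lower integration bound up to V_thresh."""
    V_lb = params.E_L - 10.0 * params.sigma
    n = int(np.ceil((params.V_thresh - V_lb) / dV))
    return params.V_thresh - dV * np.arange(n + 1)  # descending


def _steady_solution(
    params: EIFParams, I: np.ndarray, dV: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold integration of the stationary Fokker-Planck equation.

    Returns ``(V, p0, rate)`` where ``V`` is the descending voltage grid,
    ``p0`` the normalized stationary density (per mV, including the
    refractory correction) of shape ``(len(I), len(V))`` and ``rate`` the
    stationary firing rate in Hz for each input current.
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    V = _voltage_grid(params, dV)
    sig2 = params.sigma ** 2
    # p' = a(V) p - b, with a = 2(psi+I)/sigma^2 and b = 2 tau_m j / sigma^2;
    # integrated downward with the per-step exponential (integrating-factor)
    # update, which is stable for strongly drift-dominated regions.
    a = 2.0 * (params.psi(V)[None, :] + I[:, None]) / sig2  # (nI, nV)
    j = np.where(V >= params.V_reset - 1e-12, 1.0, 0.0)     # unit emitted flux
    b = 2.0 * params.tau_m * j / sig2                        # (nV,)

    p = np.zeros((I.size, V.size))
    for k in range(V.size - 1):
        ak = a[:, k]
        x = ak * dV
        # (1 - exp(-x))/x, accurate for small x
        fac = np.where(np.abs(x) > 1e-8, -np.expm1(-np.where(np.abs(x) > 1e-8, x, 1.0)) / np.where(np.abs(x) > 1e-8, x, 1.0), 1.0 - 0.5 * x)
        p[:, k + 1] = p[:, k] * np.exp(-x) + b[k] * dV * fac

    mass = np.trapezoid(p[:, ::-1], dx=dV, axis=1)  # = 1 / r_free (ms)
    if not np.all(np.isfinite(mass)) or np.any(mass <= 0):
        raise RuntimeError(
            "steady-state threshold integration failed to converge; "
            "refine the voltage grid or check the input current"
        )
    rate_ms = 1.0 / (params.tau_ref + mass)          # 1/ms, refractory folded in
    p0 = p * rate_ms[:, None]                         # normalized density
    return V, p0, 1000.0 * rate_ms


def steady_rate(params: EIFParams, I: float | np.ndarray, dV: float = 0.01) -> float | np.ndarray:
    """Stationary mean firing rate (Hz) of an EIF neuron at mean input ``I`` (mV).

    Computed by steady-state Fokker-Planck threshold integration from
    ``V_thresh`` down to ``E_L - 10 sigma``; the refractory period enters as
    ``rate = 1/(tau_ref + 1/r_free)``.
    """
    _, _, r = _steady_solution(params, I, dV)
    return float(r[0]) if np.isscalar(I) else r


def linear_response(
    params: EIFParams,
    I: float | np.ndarray,
    f: float | np.ndarray,
    dV: float = 0.01,
) -> np.ndarray:
    """Complex linear firing-rate response (Hz/mV) at modulation frequency ``f`` (Hz).

    First-order rate response to a small sinusoidal modulation of the mean
    input current about ``I``, obtained by threshold integration of the
    time-periodic Fokker-Planck problem: two backward sweeps (one carrying
    unit emitted flux with delayed re-injection at the reset, one driven by
    the stationary density) are combined so that the probability flux
    vanishes at the lower voltage bound.

    Broadcasts over both ``I`` and ``f``; the result has shape
    ``(len(I), len(f))`` (squeezed for scalar input).
    """
    scalar = np.isscalar(I) and np.isscalar(f)
    I_arr = np.atleast_1d(np.asarray(I, dtype=float))
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValueError("modulation frequencies must be positive")

    V, p0, _ = _steady_solution(params, I_arr, dV)
    sig2 = params.sigma ** 2
    omega = 2e-3 * np.pi * f_arr  # rad/ms
    a = 2.0 * (params.psi(V)[None, :] + I_arr[:, None]) / sig2  # (nI, nV)

    nI, nf, nV = I_arr.size, f_arr.size, V.size
    # Solution r: unit emitted flux, no drive.  Solution e: unit current
    # modulation, no emitted flux.
    j_r = np.ones((nI, nf), dtype=complex)
    p_r = np.zeros((nI, nf), dtype=complex)
    j_e = np.zeros((nI, nf), dtype=complex)
    p_e = np.zeros((nI, nf), dtype=complex)
    iw = 1j * omega[None, :]                    # (1, nf)
    reinject = np.exp(-iw * params.tau_ref)[0]  # delayed reset re-injection
    # index of the first grid point at or below V_reset (descending grid)
    k_reset = int(np.searchsorted(-V, -params.V_reset))

    two_over_sig2 = 2.0 / sig2
    taum = params.tau_m
    for k in range(nV - 1):
        ak = a[:, k][:, None]                  # (nI, 1)
        x = ak * dV
        ex = np.exp(-x)
        fac = np.where(np.abs(x) > 1e-8, (1.0 - ex) / np.where(np.abs(x) > 1e-8, x, 1.0), 1.0 - 0.5 * x)
        # dj/dV = -i w p  (integrate downward: j(V-dV) = j(V) + dV * i w p)
        j_r_new = j_r + dV * iw * p_r
        j_e_new = j_e + dV * iw * p_e
        if k + 1 == k_reset:
            j_r_new = j_r_new - reinject[None, :]
        # p' = a p - b with b = (2/sigma^2)(tau_m j - Ihat p0)
        b_r = two_over_sig2 * taum * j_r
        b_e = two_over_sig2 * (taum * j_e - p0[:, k][:, None])
        p_r = p_r * ex + b_r * dV * fac
        p_e = p_e * ex + b_e * dV * fac
        j_r, j_e = j_r_new, j_e_new

    with np.errstate(invalid="raise"):
        try:
            gain = -j_e / j_r  # per-ms rate per mV
        except FloatingPointError as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError("linear-response threshold integration did not converge") from exc
    gain_Hz = 1000.0 * gain
    return complex(gain_Hz[0, 0]) if scalar else gain_Hz


def _lorentzian_fit(f: np.ndarray, modulus: np.ndarray) -> tuple[float, float, float]:
    """Fit ``A / sqrt(1 + (2 pi f tau)^2)`` to ``modulus``; returns (tau_ms, A, sse).

    Unweighted least squares; the amplitude is concentrated out, leaving a
    one-dimensional profile objective in ``tau`` minimized by golden-section
    refinement of a log-spaced bracket scan.
    """
    from scipy.optimize import minimize_scalar

    f_kHz = 1e-3 * np.asarray(f, dtype=float)
    y = np.asarray(modulus, dtype=float)

    def sse_of(log_tau: float) -> float:
        tau = np.exp(log_tau)
        m = 1.0 / np.sqrt(1.0 + (2.0 * np.pi * f_kHz * tau) ** 2)
        A = float(m @ y) / float(m @ m)
        resid = y - A * m
        return float(resid @ resid)

    # coarse scan to bracket the minimum, then local refinement
    grid = np.log(np.geomspace(1e-2, 1e3, 121))
    vals = np.array([sse_of(g) for g in grid])
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    res = minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    tau = float(np.exp(res.x))
    m = 1.0 / np.sqrt(1.0 + (2.0 * np.pi * f_kHz * tau) ** 2)
    A = float(m @ y) / float(m @ m)
    return tau, A, float(res.fun)


def fit_adaptive_timescale(
    params: EIFParams,
    I: float,
    f_grid: np.ndarray | None = None,
    dV: float = 0.01,
    modulus: np.ndarray | None = None,
) -> float:
    """Fitted adaptive timescale tau^(FAT) (ms) at mean current ``I``.

    The modulus of the linear rate response over ``f_grid`` (default
    1 Hz - 1 kHz in 1 Hz steps) is fitted by the two-parameter family
    ``A / sqrt(1 + (2 pi f tau)^2)`` -- the Fourier modulus of an exponential
    relaxation kernel -- and the fitted ``tau`` is returned.

    ``modulus`` may be supplied to fit precomputed response data (used when
    tabulating many currents at once).
    """
    if f_grid is None:
        f_grid = np.arange(1.0, 1001.0)
    if modulus is None:
        modulus = np.abs(linear_response(params, I, f_grid, dV=dV)).ravel()
    tau, _, sse = _lorentzian_fit(np.asarray(f_grid), np.asarray(modulus))
    if not np.isfinite(tau) or tau <= 0:
        raise RuntimeError(f"adaptive-timescale fit failed (tau={tau}, sse={sse})")
    return tau


@dataclass
class TransferTable:
    """Tabulated EIF transfer properties on a uniform current grid.

    Attributes
    ----------
    I_grid : current grid (mV), uniform step ``dI``
    phi : stationary rate Phi_sigma(I) (Hz)
    dphi, ddphi : first/second central-difference derivatives (Hz/mV, Hz/mV^2)
    tau_fat : fitted adaptive timescale (ms)
    dtau : central-difference derivative of tau_fat (ms/mV)
    """

    I_grid: np.ndarray
    phi: np.ndarray
    dphi: np.ndarray
    ddphi: np.ndarray
    tau_fat: np.ndarray
    dtau: np.ndarray = field(default=None)  # type: ignore[assignment]
    params: EIFParams = field(default_factory=EIFParams)
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.dtau is None:
            self.dtau = np.gradient(self.tau_fat, self.I_grid)
        self.validate()

    @property
    def dI(self) -> float:
        return float(self.I_grid[1] - self.I_grid[0])

    def validate(self) -> None:
        if np.any(self.phi < 0):
            raise ValueError("transfer table contains negative rates")
        if np.any(np.diff(self.phi) < -1e-9):
            raise ValueError("f-I curve must be non-decreasing")
        if np.any(~np.isfinite(self.tau_fat)) or np.any(self.tau_fat <= 0):
            raise ValueError("tau_fat must be positive and finite")
        if self.params.tau_ref > 0 and np.any(self.phi >= 1000.0 / self.params.tau_ref):
            raise ValueError("rates exceed the refractory bound 1000/tau_ref")

    def _check_range(self, I: np.ndarray) -> None:
        I = np.asarray(I)
        if np.any(I < self.I_grid[0]) or np.any(I > self.I_grid[-1]):
            bad = I[(I < self.I_grid[0]) | (I > self.I_grid[-1])]
            raise ValueError(
                f"current {np.atleast_1d(bad).ravel()[0]:.3f} mV outside the table "
                f"range [{self.I_grid[0]:.1f}, {self.I_grid[-1]:.1f}] mV; rebuild "
                "the table with a wider current range"
            )

    def _interp(self, I, y):
        self._check_range(I)
        if self.interpolation == "cubic":
            from scipy.interpolate import CubicSpline

            return CubicSpline(self.I_grid, y)(I)
        return np.interp(I, self.I_grid, y)

    def rate(self, I):
        """Phi(I) in Hz."""
        return self._interp(I, self.phi)

    def drate(self, I):
        """Phi'(I) in Hz/mV."""
        return self._interp(I, self.dphi)

    def ddrate(self, I):
        """Phi''(I) in Hz/mV^2."""
        return self._interp(I, self.ddphi)

    def tau(self, I):
        """tau^(FAT)(I) in ms."""
        return self._interp(I, self.tau_fat)

    def dtau_dI(self, I):
        """d tau^(FAT)/dI in ms/mV."""
        return self._interp(I, self.dtau)

    def rate_inverse(self, r: float) -> float:
        """Phi^{-1}(r) for r in Hz, by inversion of the monotone table."""
        if r < self.phi[0] or r > self.phi[-1]:
            raise ValueError(f"rate {r} Hz outside tabulated range "
                             f"[{self.phi[0]:.3g}, {self.phi[-1]:.3g}] Hz")
        # phi may have flat stretches at the resolution floor; keep strictly
        # increasing support for interpolation
        keep = np.concatenate(([True], np.diff(self.phi) > 0))
        return float(np.interp(r, self.phi[keep], self.I_grid[keep]))

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            g = h.create_group("transfer_table")
            for name in ("I_grid", "phi", "dphi", "ddphi", "tau_fat", "dtau"):
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["interpolation"] = self.interpolation
            for k, v in vars(self.params).items():
                g.attrs[f"eif_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "TransferTable":
        import h5py

        with h5py.File(path, "r") as h:
            g = h["transfer_table"]
            data = {name: g[name][...] for name in
                    ("I_grid", "phi", "dphi", "ddphi", "tau_fat", "dtau")}
            eif = EIFParams(**{k[4:]: float(v) for k, v in g.attrs.items()
                               if k.startswith("eif_")})
            return cls(params=eif, interpolation=str(g.attrs["interpolation"]), **data)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "I_mV": self.I_grid, "phi_Hz": self.phi, "dphi_Hz_per_mV": self.dphi,
            "ddphi_Hz_per_mV2": self.ddphi, "tau_fat_ms": self.tau_fat,
            "dtau_ms_per_mV": self.dtau,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: EIFParams | None = None) -> "TransferTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            I_grid=df["I_mV"].to_numpy(), phi=df["phi_Hz"].to_numpy(),
            dphi=df["dphi_Hz_per_mV"].to_numpy(), ddphi=df["ddphi_Hz_per_mV2"].to_numpy(),
            tau_fat=df["tau_fat_ms"].to_numpy(), dtau=df["dtau_ms_per_mV"].to_numpy(),
            params=params or EIFParams(),
        )


def ob_timescale(table: "TransferTable") -> np.ndarray:
    """Alternative analytically-motivated timescale tau_m Delta_T Phi'/Phi (ms).

    Config variant for comparison with the fitted timescale; steeper at low
    rates and not used by the simulators.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = table.params.tau_m * table.params.Delta_T * table.dphi / table.phi
    return np.where(table.phi > 0, tau, np.inf)


def build_transfer_table(
    params: EIFParams | None = None,
    I_range: tuple[float, float] = (-28.0, 20.0),
    dI: float = 0.1,
    f_grid: np.ndarray | None = None,
    dV: float = 0.01,
    interpolation: str = "linear",
    progress: bool = False,
) -> TransferTable:
    """Tabulate Phi, Phi', Phi'', and tau^(FAT) on a uniform current grid.

    The rate response is evaluated at every grid current over ``f_grid``
    (default 1 Hz-1 kHz in 1 Hz steps) and fitted per current by the
    Lorentzian-modulus family.  Derivatives are central finite differences on
    the grid (one-sided at the ends).  Expect minutes of runtime at the
    default resolution; coarser ``f_grid``/``dV`` give quick approximate
    tables for exploratory work.
    """
    params = params or EIFParams()
    if f_grid is None:
        f_grid = np.arange(1.0, 1001.0)
    f_grid = np.asarray(f_grid, dtype=float)
    I_grid = np.arange(I_range[0], I_range[1] + 0.5 * dI, dI)

    _, _, phi = _steady_solution(params, I_grid, dV)

    # responses for all currents at once (vectorized over I x f); chunk over
    # currents to bound memory
    tau_fat = np.empty_like(I_grid)
    chunk = max(1, int(2e7 // (f_grid.size * 16)))
    for s in range(0, I_grid.size, chunk):
        sl = slice(s, min(s + chunk, I_grid.size))
        gain = np.abs(linear_response(params, I_grid[sl], f_grid, dV=dV))
        for i in range(gain.shape[0]):
            tau_fat[s + i] = fit_adaptive_timescale(
                params, I_grid[sl][i], f_grid, modulus=gain[i])
        if progress:  # pragma: no cover
            print(f"  transfer table: {sl.stop}/{I_grid.size} currents done", flush=True)

    dphi = np.gradient(phi, I_grid)    # central differences, one-sided at ends
    ddphi = np.gradient(dphi, I_grid)
    return TransferTable(I_grid=I_grid, phi=phi, dphi=dphi, ddphi=ddphi,
                         tau_fat=tau_fat, params=params, interpolation=interpolation)
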