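"""Trace post-processing: correlations, Hilbert phases, and phase waves.

Correlation functions with the Poisson-sampling correction, fitting of the
harmonic-sum autocorrelation decay (shared decay time tau_D with the n^2
harmonic scaling), band-pass Hilbert phase extraction, detection of
propagating phase-gradient events, and spatial power spectra of chain
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate import RateTrace

__all__ = [
    "PhaseField", "PropagationEvent", "correlation", "averaged_gradients",
    "fit_autocorrelation_decay", "hilbert_phase", "detect_propagation",
    "spatial_power_spectrum",
]


def correlation(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    dt: float,
    max_lag: float,
    poisson_correct: bool = False,
    N: int | None = None,
    bin_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram C(tau) = (1/M) sum_i dr_a(t_i) dr_b(t_i + tau).

    ``trace_a``/``trace_b`` are equal-length rate series (Hz) sampled at
    ``dt`` (ms); means are removed.  With ``poisson_correct`` (auto-
    correlations only) the expected zero-lag Poisson contribution
    ``mean(r)/(N bin)`` is subtracted at tau = 0.  Returns ``(lags, C)``
    with lags from -max_lag to +max_lag.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be equal-length 1-D arrays")
    n_lag = int(round(max_lag / dt))
    if n_lag >= a.size:
        raise ValueError("max_lag exceeds the trace duration")
    from scipy.signal import correlate as _xcorr

    da = a - a.mean()
    db = b - b.mean()
    M = a.size
    full = _xcorr(da, db, mode="full", method="fft") / M
    mid = a.size - 1
    C = full[mid - n_lag: mid + n_lag + 1]
    lags = dt * np.arange(-n_lag, n_lag + 1)
    if poisson_correct:
        if a is not b and not np.array_equal(a, b):
            raise ValueError("the Poisson correction applies to autocorrelations")
        if N is None or bin_ms is None:
            raise ValueError("poisson_correct requires N and bin_ms")
        C[n_lag] -= a.mean() / (N * 1e-3 * bin_ms)
    return lags, C


def _eq_harmonic_model(lags, T, tau_D, amps):
    n = np.arange(1, amps.size + 1)
    return 2.0 * (amps[None, :] *
                  np.cos(2.0 * np.pi * n[None, :] * lags[:, None] / T) *
                  np.exp(-n[None, :] ** 2 * lags[:, None] / tau_D)).sum(axis=1)


def fit_autocorrelation_decay(
    lags: np.ndarray,
    C: np.ndarray,
    T_hint: float,
    n_harmonics: int = 3,
    fit_T: bool = True,
) -> dict:
    """Decay time tau_D from a dephasing-oscillator autocorrelation.

    Fits ``C(tau) = 2 sum_n |r_n|^2 cos(2 pi n tau/T) exp(-n^2 tau/tau_D)``
    to the positive lags: a single decay time shared across harmonics, each
    harmonic decaying n^2 times faster.  Returns a dict with ``tau_D`` (ms),
    the fitted period ``T``, harmonic powers and the residual.
    """
    from scipy.optimize import least_squares

    lags = np.asarray(lags, dtype=float)
    C = np.asarray(C, dtype=float)
    pos = lags > 0
    x = lags[pos]
    y = C[pos]
    if x.max() < 3.0 * T_hint:
        raise ValueError("correlogram must cover at least 3 periods of lag")

    def unpack(p):
        T = p[0] if fit_T else T_hint
        tau_D = p[1]
        amps = p[2:] ** 2  # powers, kept non-negative via squaring
        return T, tau_D, amps

    def resid(p):
        T, tau_D, amps = unpack(p)
        return _eq_harmonic_model(x, T, tau_D, amps) - y

    a0 = np.sqrt(max(C.max(), 1e-12) / 2.0)
    p0 = np.array([T_hint, 5.0 * T_hint] + [a0] + [0.3 * a0] * (n_harmonics - 1))
    res = least_squares(resid, p0, method="lm", max_nfev=20000)
    T, tau_D, amps = unpack(res.x)
    if not (np.isfinite(tau_D) and tau_D > 0):
        raise RuntimeError(f"autocorrelation fit diverged (tau_D={tau_D}, "
                           f"cost={res.cost:.3g})")
    return {"tau_D": float(abs(tau_D)), "T": float(T), "powers": amps,
            "residual": float(res.cost), "success": bool(res.success)}


@dataclass
class PhaseField:
    """Instantaneous oscillation phases of a (chain of) module(s).

    ``theta`` holds the unwrapped Hilbert phase (radians) per module on a
    1 ms grid; ``T_bar`` is the mean oscillation period from the spectral
    peak, used to convert phase differences to time units via T_bar/(2 pi).
    """

    t: np.ndarray
    theta: np.ndarray       # (n_samples, L), radians, unwrapped in time
    T_bar: float            # ms
    dt: float = 1.0

    @property
    def L(self) -> int:
        return self.theta.shape[1]

    def gradients(self) -> np.ndarray:
        """Nearest-neighbour phase differences in time units (ms), mapped
        periodically into (-T_bar/2, T_bar/2].

        Sign convention: the phase is the peak-time delay, so a wave
        travelling towards increasing module index has a positive gradient
        and velocity 1/gradient (modules per ms).
        """
        dtheta = -np.diff(self.theta, axis=1)  # angle leads = earlier peak
        grad = dtheta * self.T_bar / (2.0 * np.pi)
        return -np.mod(-grad + 0.5 * self.T_bar, self.T_bar) + 0.5 * self.T_bar


def averaged_gradients(field: PhaseField, window: int = 5):
    """Spatially extended phase gradients and their retention mask.

    Local nearest-neighbour gradients are averaged over ``window``
    neighbouring pairs; a window is retained when its absolute average
    exceeds the standard deviation of the contributing local differences.
    Returns ``(gbar, retained)`` of shape ``(n_t, n_windows)``; the mean of
    ``|gbar[retained]|`` is the summary gradient statistic of a chain run.
    """
    grads = field.gradients()
    n_t, n_pairs = grads.shape
    if n_pairs < window:
        raise ValueError(f"need at least {window + 1} modules")
    sl = np.lib.stride_tricks.sliding_window_view(grads, window, axis=1)
    gbar = sl.mean(axis=2)
    # the 1e-6 ms floor suppresses spurious retention of numerically zero
    # gradients (e.g. perfectly synchronized noiseless chains)
    retained = np.abs(gbar) > np.maximum(sl.std(axis=2), 1e-6)
    return gbar, retained


@dataclass
class PropagationEvent:
    position: int          # module index at the window start
    time: float            # ms
    mean_gradient: float   # ms per module (five-module average)
    velocity: float        # modules per ms, from optimal frame shifts
    shifts: np.ndarray = field(default_factory=lambda: np.empty(0))


def _bin_average(x: np.ndarray, k: int) -> np.ndarray:
    n = (x.shape[0] // k) * k
    return x[:n].reshape(n // k, k, *x.shape[1:]).mean(axis=1)


def hilbert_phase(
    trace: RateTrace,
    band: tuple[float, float] = (15.0, 40.0),
    resample_ms: float = 1.0,
    filter_order: int = 5,
) -> PhaseField:
    """Band-passed Hilbert phase of the excitatory activity, per module.

    The rate is averaged into ``resample_ms`` bins, band-pass filtered
    (Butterworth, zero-phase forward-backward application so the filter does
    not bias phases), and the analytic-signal phase is unwrapped in time.
    ``T_bar`` is taken from the power-spectral peak of the module-averaged
    rate.
    """
    from scipy.signal import butter, hilbert, periodogram, sosfiltfilt

    if trace.t[-1] - trace.t[0] < 1000.0:
        raise ValueError("need at least 1 s of trace for phase extraction")
    fs = 1000.0 / resample_ms  # Hz
    if band[1] >= fs / 2.0:
        raise ValueError("band upper edge must lie below Nyquist")
    k = max(1, int(round(resample_ms / trace.dt)))
    r = _bin_average(trace.r_E, k)
    t = _bin_average(trace.t, k)
    dr = r - r.mean(axis=0, keepdims=True)
    sos = butter(filter_order, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, dr, axis=0)
    theta = np.unwrap(np.angle(hilbert(filt, axis=0)), axis=0)

    f, P = periodogram(dr, fs=fs, axis=0)
    P = P.mean(axis=1)  # per-module periodograms averaged over the chain
    sel = (f >= band[0]) & (f <= band[1])
    f_peak = f[sel][np.argmax(P[sel])]
    return PhaseField(t=t, theta=theta, T_bar=1000.0 / f_peak, dt=resample_ms)


def detect_propagation(
    field: PhaseField,
    window: int = 5,
    lags: range = range(1, 6),
    max_shift: int = 15,
) -> list[PropagationEvent]:
    """Detect spatially extended phase gradients and their propagation speed.

    Phase differences are averaged over ``window`` neighbouring module pairs;
    a window is retained when the absolute average gradient exceeds the
    standard deviation of its contributing local differences.  For retained
    windows the propagation velocity is inferred from the lateral shift that
    best matches the local phase profile at later frames (smallest |shift|
    wins ties), averaged over the frame lags.
    """
    grads = field.gradients()            # (n_t, L-1), ms/module
    gbar_all, retained = averaged_gradients(field, window)
    n_t, n_pairs = grads.shape
    theta_ms = field.theta * field.T_bar / (2.0 * np.pi)
    events: list[PropagationEvent] = []
    Tb = field.T_bar
    shifts_range = np.arange(-max_shift, max_shift + 1)
    order = np.argsort(np.abs(shifts_range), kind="stable")  # prefer small |shift|
    max_lag = max(lags)
    for i in range(n_t - max_lag):
        for x in range(n_pairs - window + 1):
            if not retained[i, x]:
                continue
            gbar = gbar_all[i, x]
            prof = theta_ms[i, x: x + window]
            opt = np.empty(len(lags))
            for j_idx, j in enumerate(lags):
                dist = np.full(shifts_range.size, np.inf)
                for si, s in enumerate(shifts_range):
                    lo = x + s
                    if lo < 0 or lo + window > field.L:
                        continue
                    diff = prof - theta_ms[i + j, lo: lo + window]
                    # phase differences taken modulo one period, centred
                    diff = np.mod(diff + 0.5 * Tb, Tb) - 0.5 * Tb
                    dist[si] = np.sum(diff ** 2)
                best_si = min(order, key=lambda si: (dist[si], abs(shifts_range[si])))
                best = float(shifts_range[best_si])
                # sub-module refinement: parabola through the neighbours
                if 0 < best_si < shifts_range.size - 1:
                    dm, d0, dp = dist[best_si - 1], dist[best_si], dist[best_si + 1]
                    if np.isfinite(dm) and np.isfinite(dp):
                        denom = dm - 2.0 * d0 + dp
                        if denom > 1e-15:
                            best += 0.5 * (dm - dp) / denom
                opt[j_idx] = best / (j * field.dt)
            # least-squares slope of shift vs lag (through the origin):
            # long lags carry more displacement signal than the 1-frame shift
            jarr = np.asarray(lags, dtype=float) * field.dt
            disp = opt * jarr
            v_ls = float(np.dot(jarr, disp) / np.dot(jarr, jarr))
            events.append(PropagationEvent(
                position=x, time=float(field.t[i]), mean_gradient=float(gbar),
                velocity=v_ls, shifts=opt))
    return events


def events_to_csv(events: list[PropagationEvent], path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "time_ms": e.time, "position": e.position,
        "gradient_ms_per_module": e.mean_gradient,
        "velocity_modules_per_ms": e.velocity,
    } for e in events]).to_csv(path, index=False)


def spatial_power_spectrum(
    trace: RateTrace,
    avg_window_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial power of the excitatory activity profile per wavenumber.

    Per frame, ``P(q) = |L^{-1/2} sum_n dr_n exp(-i q n)|^2`` with the
    module-mean-removed-in-time rates, averaged over frames in the window
    (whole trace by default).  Satisfies Parseval per frame:
    ``sum_q P(q) = sum_n dr_n^2``.
    """
    if trace.L < 8:
        raise ValueError("need a chain of at least 8 modules")
    r = trace.r_E
    if avg_window_s is not None:
        n = int(round(1000.0 * avg_window_s / trace.dt))
        r = r[-n:]
    dr = r - r.mean(axis=0, keepdims=True)
    F = np.fft.fft(dr, axis=1) / np.sqrt(trace.L)
    P = (np.abs(F) ** 2).mean(axis=0)
    q = 2.0 * np.pi * np.arange(trace.L) / trace.L
    return q, P
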