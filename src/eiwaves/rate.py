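"""Deterministic and stochastic simulation of the FAT rate model.

The fitted-adaptive-timescale (FAT) rate model describes each population by a
current ``I`` relaxing with the state-dependent timescale tau(I) towards its
synaptic drive, with the firing rate given by the EIF f-I curve,
``tau(I) dI/dt = -I + I_ext + (synaptic drive)``, ``r = Phi(I)``.

Finite population size is modelled by Poissonian sampling of the spike
counts: at each step the number of emitted spikes per population is drawn
from a Poisson law with mean ``N Phi(I) dt`` and the instantaneous rate is
the count divided by ``N dt`` (never negative by construction).

Integration is forward Euler with dt = 0.01 ms by default; inner loops are
JIT-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .eif import TransferTable
from .params import CouplingProfile, ModuleParams

__all__ = ["RateTrace", "simulate_deterministic", "simulate_stochastic"]


@dataclass
class RateTrace:
    """Time-binned population currents and rates, one column per module.

    Rates are bin averages over the recording step; currents are sampled at
    bin ends.  Shapes are ``(n_samples, L)``.
    """

    t: np.ndarray
    I_E: np.ndarray
    I_I: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.r_E.shape[1]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def discard_transient(self, t_min: float = 250.0) -> "RateTrace":
        keep = self.t >= t_min
        return RateTrace(self.t[keep], self.I_E[keep], self.I_I[keep],
                         self.r_E[keep], self.r_I[keep], dict(self.metadata))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            for name in ("t", "I_E", "I_I", "r_E", "r_I"):
                h.create_dataset(name, data=getattr(self, name))
            for k, v in self.metadata.items():
                h.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "RateTrace":
        import h5py

        with h5py.File(path, "r") as h:
            data = {name: h[name][...] for name in ("t", "I_E", "I_I", "r_E", "r_I")}
            meta = dict(h.attrs)
        return cls(metadata=meta, **data)

    def to_csv(self, path) -> None:
        """Long-format export: time, module, population, rate."""
        import pandas as pd

        frames = []
        for pop, r in (("E", self.r_E), ("I", self.r_I)):
            for m in range(self.L):
                frames.append(pd.DataFrame({
                    "time_ms": self.t, "module": m, "population": pop,
                    "rate_Hz": r[:, m]}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@njit(cache=True)
def _rate_kernel(IE, II, n_steps, dt, Ig, phi, tau, wEE, wEI, wIE,
                 IextE, IextI, CE, CI, stochastic, NE, NI, seed, stride,
                 rec_IE, rec_II, rec_rE, rec_rI):
    if stochastic:
        np.random.seed(seed)
    L = IE.size
    accE = np.zeros(L)
    accI = np.zeros(L)
    rE = np.empty(L)
    rI = np.empty(L)
    Imin = Ig[0]
    Imax = Ig[-1]
    rec = 0
    for step in range(n_steps):
        for n in range(L):
            if IE[n] < Imin or IE[n] > Imax:
                return 1, step, n
            if II[n] < Imin or II[n] > Imax:
                return 2, step, n
        phiE = np.interp(IE, Ig, phi)
        phiI = np.interp(II, Ig, phi)
        if stochastic:
            for n in range(L):  # fixed draw order: E modules 0..L-1, then I
                lam = NE * phiE[n] * dt * 1e-3
                rE[n] = np.random.poisson(lam) / (NE * dt * 1e-3)
            for n in range(L):
                lam = NI * phiI[n] * dt * 1e-3
                rI[n] = np.random.poisson(lam) / (NI * dt * 1e-3)
        else:
            rE[:] = phiE
            rI[:] = phiI
        accE += rE
        accI += rI
        driveE = wEE * np.dot(CE, rE) - wEI * rI  # mV*s times Hz gives mV
        driveI = wIE * np.dot(CI, rE)
        tauE = np.interp(IE, Ig, tau)
        tauI = np.interp(II, Ig, tau)
        for n in range(L):
            IE[n] += dt / tauE[n] * (-IE[n] + IextE + driveE[n])
            II[n] += dt / tauI[n] * (-II[n] + IextI + driveI[n])
        if (step + 1) % stride == 0:
            rec_IE[rec] = IE
            rec_II[rec] = II
            rec_rE[rec] = accE / stride
            rec_rI[rec] = accI / stride
            accE[:] = 0.0
            accI[:] = 0.0
            rec += 1
    return 0, n_steps, -1


def _coupling_matrices(coupling: CouplingProfile | None):
    if coupling is None:
        one = np.ones((1, 1))
        return one, one.copy(), 1
    L = coupling.L
    idx = (np.arange(L)[:, None] - np.arange(L)[None, :]) % L
    CE = coupling.weights[idx]
    CI = CE if coupling.targets_inhibitory else np.eye(L)
    return np.ascontiguousarray(CE), np.ascontiguousarray(CI), L


def _default_init(params: ModuleParams, table: TransferTable, L: int,
                  init_noise: float, rng: np.random.Generator | None):
    I_E_s = table.rate_inverse(params.r_E_s)
    I_I_s = table.rate_inverse(params.r_I_s)
    IE = np.full(L, I_E_s)
    II = np.full(L, I_I_s)
    if rng is not None and init_noise > 0:
        IE += init_noise * rng.standard_normal(L)
    else:
        IE += init_noise  # uniform kick off the fixed point
    return IE, II


def _simulate(params, table, coupling, T_sim, dt, init_state, record_dt,
              stochastic, seed, init_noise, init_noise_seed):
    if params.I_ext_E is None or params.I_ext_I is None:
        params = params.calibrated(table)
    CE, CI, L = _coupling_matrices(coupling)
    if init_state is not None:
        IE = np.array(init_state[0], dtype=float).copy()
        II = np.array(init_state[1], dtype=float).copy()
        if IE.size != L or II.size != L:
            raise ValueError(f"init_state must provide {L} modules")
    else:
        rng = (np.random.default_rng(init_noise_seed)
               if init_noise_seed is not None else None)
        IE, II = _default_init(params, table, L, init_noise, rng)

    stride = max(1, int(round(record_dt / dt)))
    n_steps = int(round(T_sim / dt)) // stride * stride
    n_rec = n_steps // stride
    rec = [np.empty((n_rec, L)) for _ in range(4)]
    status, step, mod = _rate_kernel(
        IE, II, n_steps, dt, table.I_grid, table.phi, table.tau_fat,
        params.w_EE, params.w_EI, params.w_IE,
        params.I_ext_E, params.I_ext_I, CE, CI,
        stochastic, params.N_E, params.N_I,
        int(seed) if seed is not None else 0, stride, *rec)
    if status != 0:
        pop = "E" if status == 1 else "I"
        raise RuntimeError(
            f"current of population {pop}, module {mod} left the transfer-table "
            f"range at t = {step * dt:.2f} ms; rebuild the table with a wider "
            "current range")
    t = dt * stride * np.arange(1, n_rec + 1)
    meta = {
        "mode": coupling.mode if coupling is not None else "single",
        "stochastic": stochastic, "dt": dt, "record_dt": dt * stride,
        "seed": -1 if seed is None else int(seed),
        "w_EE": params.w_EE, "w_IE": params.w_IE, "w_EI": params.w_EI,
        "N_E": params.N_E, "N_I": params.N_I,
    }
    return RateTrace(t, rec[0], rec[1], rec[2], rec[3], meta)


def simulate_deterministic(
    params: ModuleParams,
    table: TransferTable,
    coupling: CouplingProfile | None = None,
    T_sim: float = 1000.0,
    dt: float = 0.01,
    init_state: tuple[np.ndarray, np.ndarray] | None = None,
    record_dt: float = 0.1,
    init_noise: float = 0.1,
    init_noise_seed: int | None = None,
) -> RateTrace:
    """Integrate the deterministic FAT equations (forward Euler).

    By default the system starts at the calibrated fixed point with a 0.1 mV
    kick on the excitatory currents (uniform across modules, or Gaussian per
    module when ``init_noise_seed`` is given).  ``init_state = (I_E, I_I)``
    overrides the initial currents entirely.
    """
    return _simulate(params, table, coupling, T_sim, dt, init_state, record_dt,
                     False, None, init_noise, init_noise_seed)


def simulate_stochastic(
    params: ModuleParams,
    table: TransferTable,
    coupling: CouplingProfile | None = None,
    T_sim: float = 1000.0,
    dt: float = 0.01,
    seed: int = 0,
    init_state: tuple[np.ndarray, np.ndarray] | None = None,
    record_dt: float = 0.1,
    init_noise: float = 0.1,
    init_noise_seed: int | None = None,
) -> RateTrace:
    """Integrate the FAT equations with Poisson finite-size sampling.

    Identical seeds give bit-identical traces; Poisson draws are consumed in
    a fixed order (excitatory populations module 0..L-1, then inhibitory).
    """
    return _simulate(params, table, coupling, T_sim, dt, init_state, record_dt,
                     True, seed, init_noise, init_noise_seed)
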