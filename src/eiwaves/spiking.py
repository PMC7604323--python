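"""Scaled-down EIF spiking-network simulator.

Validates the rate-model description: single E-I modules, two coupled
modules and short chains of exponential integrate-and-fire neurons with
all-to-all local connectivity, delta synapses (instantaneous voltage jumps)
and long-range excitation.  External currents impose the target fixed-point
rates and external noise is calibrated so the total (external plus
synaptic) noise equals sigma_tot.

Two cross-module connectivity schemes are available:

- ``sampled`` (two modules): each targeted neuron receives a finite number
  C_lr = round(f_lr N_E) of excitatory synapses from randomly drawn neurons
  of the other module at full weight, while within-module all-to-all
  weights are rescaled by (1 - f_lr); this keeps cross-module shot noise.
- ``mixed`` (chains, or two modules at large N): all-to-all across modules
  with weights scaled by the coupling profile, i.e. the population spike
  counts are mixed mean-field style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .eif import EIFParams
from .params import CouplingProfile, ModuleParams
from .rate import RateTrace

__all__ = [
    "SpikingNetParams", "SpikeRecord", "calibrate_noise", "simulate_spiking",
    "build_long_range_connections", "bin_population_rate",
]


@dataclass
class SpikingNetParams:
    """Everything needed to run a spiking module (or several)."""

    eif: EIFParams
    module: ModuleParams     # must carry calibrated I_ext_E / I_ext_I
    coupling: CouplingProfile | None = None
    scheme: str = "sampled"  # "sampled" (two modules) or "mixed"
    dt: float = 0.01         # ms
    V_init_spread: float = 5.0  # Gaussian spread of initial potentials (mV)

    @property
    def J_EE(self) -> float:
        """Per-synapse weight w_EE/(N_E tau_m) in mV (tau_m in seconds)."""
        return self.module.w_EE / (self.module.N_E * self.eif.tau_m * 1e-3)

    @property
    def J_IE(self) -> float:
        return self.module.w_IE / (self.module.N_E * self.eif.tau_m * 1e-3)

    @property
    def J_EI(self) -> float:
        return self.module.w_EI / (self.module.N_I * self.eif.tau_m * 1e-3)


def calibrate_noise(params: SpikingNetParams) -> tuple[float, float]:
    """External noise strengths (sigma_E, sigma_I) in mV.

    The recurrent delta synapses contribute shot noise of variance
    ``J^2 N tau_m r`` per presynaptic population; the external noise makes
    the total up to sigma_tot^2:
    ``sigma_X^2 = sigma_tot^2 - sum_Y J_XY^2 N_Y tau_m r_Y^(s)``.
    """
    m = params.module
    tau_s = params.eif.tau_m * 1e-3  # s, so that J^2 N tau r is mV^2
    var_syn_E = (params.J_EE ** 2 * m.N_E * tau_s * m.r_E_s
                 + params.J_EI ** 2 * m.N_I * tau_s * m.r_I_s)
    var_syn_I = params.J_IE ** 2 * m.N_E * tau_s * m.r_E_s
    s2 = params.eif.sigma ** 2
    if var_syn_E >= s2 or var_syn_I >= s2:
        raise ValueError(
            "recurrent synaptic variance exceeds the total noise budget "
            f"sigma_tot^2 = {s2} mV^2 (E: {var_syn_E:.2f}, I: {var_syn_I:.2f}); "
            "reduce weights or increase N")
    return float(np.sqrt(s2 - var_syn_E)), float(np.sqrt(s2 - var_syn_I))


@dataclass
class SpikeRecord:
    """Spike times and neuron ids per population per module (times in ms)."""

    times_E: list
    ids_E: list
    times_I: list
    ids_I: list
    N_E: int
    N_I: int
    T_sim: float
    metadata: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.times_E)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.times_E) + sum(t.size for t in self.times_I))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.attrs.update({"N_E": self.N_E, "N_I": self.N_I,
                            "T_sim": self.T_sim, "L": self.L})
            for k, v in self.metadata.items():
                h.attrs[k] = v
            for m in range(self.L):
                g = h.create_group(f"module_{m}")
                g.create_dataset("times_E", data=self.times_E[m])
                g.create_dataset("ids_E", data=self.ids_E[m])
                g.create_dataset("times_I", data=self.times_I[m])
                g.create_dataset("ids_I", data=self.ids_I[m])

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRecord":
        import h5py

        with h5py.File(path, "r") as h:
            L = int(h.attrs["L"])
            return cls(
                times_E=[h[f"module_{m}/times_E"][...] for m in range(L)],
                ids_E=[h[f"module_{m}/ids_E"][...] for m in range(L)],
                times_I=[h[f"module_{m}/times_I"][...] for m in range(L)],
                ids_I=[h[f"module_{m}/ids_I"][...] for m in range(L)],
                N_E=int(h.attrs["N_E"]), N_I=int(h.attrs["N_I"]),
                T_sim=float(h.attrs["T_sim"]))


def build_long_range_connections(
    N_E: int,
    coupling: CouplingProfile,
    n_post: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Presynaptic excitatory source assignment for ``n_post`` target neurons.

    Every target neuron keeps a total excitatory in-degree of exactly
    ``N_E`` inputs.  The number received from the module at periodic offset
    ``l`` follows the relative contribution of the coupling profile
    (deterministic floor allocation, random largest-remainder top-up);
    individual source ids within each module are drawn uniformly.

    Returns ``(counts, sources)`` where ``counts`` has shape
    ``(n_post, L)`` (inputs per source-module offset, rows summing to N_E)
    and ``sources`` has shape ``(n_post, N_E)`` holding source neuron ids
    encoded as ``offset * N_E + id``.
    """
    L = coupling.L
    rng = np.random.default_rng(seed)
    quota = coupling.weights * N_E
    base = np.floor(quota).astype(np.int64)
    rem = quota - base
    counts = np.empty((n_post, L), dtype=np.int64)
    sources = np.empty((n_post, N_E), dtype=np.int64)
    p = rem / rem.sum() if rem.sum() > 0 else None
    for i in range(n_post):
        c = base.copy()
        missing = N_E - int(c.sum())
        if missing > 0:
            extra = rng.choice(L, size=missing, replace=True, p=p)
            np.add.at(c, extra, 1)
        counts[i] = c
        pos = 0
        for off in range(L):
            k = c[off]
            if k == 0:
                continue
            ids = rng.choice(N_E, size=k, replace=False)
            sources[i, pos: pos + k] = off * N_E + ids
            pos += k
    return counts, sources


def _cross_adjacency(N_E: int, n_post_E: int, n_post_I: int, C_lr: int,
                     rng: np.random.Generator):
    """Forward adjacency source (other module's E) -> cross-module targets.

    Targets encoded as target-neuron index within the receiving population;
    returns CSR-style (indptr, targets) pairs for E and I target pools.
    """
    def build(n_post):
        if n_post == 0 or C_lr == 0:
            return np.zeros(N_E + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
        srcs = np.empty((n_post, C_lr), dtype=np.int64)
        for i in range(n_post):
            srcs[i] = rng.choice(N_E, size=C_lr, replace=False)
        flat_src = srcs.ravel()
        flat_tgt = np.repeat(np.arange(n_post, dtype=np.int64), C_lr)
        order = np.argsort(flat_src, kind="stable")
        targets = flat_tgt[order]
        counts = np.bincount(flat_src, minlength=N_E)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return indptr, targets

    return build(n_post_E), build(n_post_I)


@njit(cache=True)
def _spiking_kernel(n_steps, dt, L, NE, NI, V_spread,
                    tau_m, E_L, V_T, Delta_T, V_reset, V_thresh, ref_steps,
                    IextE, IextI, sigE, sigI,
                    JEE, JIE, JEI, wEE_within, wIE_within,
                    CE, CI, use_adj, J_crossE, J_crossI,
                    adjE_indptr, adjE_tgt, adjI_indptr, adjI_tgt,
                    seed, bin_stride, rateE, rateI,
                    rec_times, rec_ids, rec_mod, rec_pop, max_spikes):
    np.random.seed(seed)
    VE = np.empty((L, NE))
    VI = np.empty((L, NI))
    for m in range(L):
        for i in range(NE):
            VE[m, i] = E_L + V_spread * np.random.standard_normal()
        for i in range(NI):
            VI[m, i] = E_L + V_spread * np.random.standard_normal()
    refE = np.zeros((L, NE), dtype=np.int64)
    refI = np.zeros((L, NI), dtype=np.int64)
    nE = np.zeros(L)
    nI = np.zeros(L)
    pendE = np.zeros((L, NE))
    pendI = np.zeros((L, NI))
    spk_buf = np.empty(NE, dtype=np.int64)
    n_rec = 0
    sq = np.sqrt(dt / tau_m)
    for step in range(n_steps):
        if use_adj:
            dVE_pop = wEE_within * JEE * nE - JEI * nI
            dVI_pop = wIE_within * JIE * nE
        else:
            dVE_pop = JEE * np.dot(CE, nE) - JEI * nI
            dVI_pop = JIE * np.dot(CI, nE)
        nE[:] = 0.0
        nI[:] = 0.0
        t_now = step * dt
        for m in range(L):
            n_spk = 0
            for i in range(NE):
                if refE[m, i] > 0:
                    refE[m, i] -= 1
                    pendE[m, i] = 0.0
                    continue  # clamped at reset; synaptic input discarded
                v = VE[m, i]
                arg = (v - V_T) / Delta_T
                if arg > 30.0:
                    arg = 30.0
                v += dt / tau_m * (E_L - v + Delta_T * np.exp(arg) + IextE) \
                    + sigE * sq * np.random.standard_normal() \
                    + dVE_pop[m] + pendE[m, i]
                pendE[m, i] = 0.0
                if v >= V_thresh:
                    nE[m] += 1.0
                    spk_buf[n_spk] = i
                    n_spk += 1
                    if n_rec < max_spikes:
                        rec_times[n_rec] = t_now
                        rec_ids[n_rec] = i
                        rec_mod[n_rec] = m
                        rec_pop[n_rec] = 0
                        n_rec += 1
                    v = V_reset
                    refE[m, i] = ref_steps
                VE[m, i] = v
            if use_adj and n_spk > 0:
                other = 1 - m
                for s_idx in range(n_spk):
                    s = spk_buf[s_idx]
                    for ptr in range(adjE_indptr[s], adjE_indptr[s + 1]):
                        pendE[other, adjE_tgt[ptr]] += J_crossE
                    for ptr in range(adjI_indptr[s], adjI_indptr[s + 1]):
                        pendI[other, adjI_tgt[ptr]] += J_crossI
            for i in range(NI):
                if refI[m, i] > 0:
                    refI[m, i] -= 1
                    pendI[m, i] = 0.0
                    continue
                v = VI[m, i]
                arg = (v - V_T) / Delta_T
                if arg > 30.0:
                    arg = 30.0
                v += dt / tau_m * (E_L - v + Delta_T * np.exp(arg) + IextI) \
                    + sigI * sq * np.random.standard_normal() \
                    + dVI_pop[m] + pendI[m, i]
                pendI[m, i] = 0.0
                if v >= V_thresh:
                    nI[m] += 1.0
                    if n_rec < max_spikes:
                        rec_times[n_rec] = t_now
                        rec_ids[n_rec] = i
                        rec_mod[n_rec] = m
                        rec_pop[n_rec] = 1
                        n_rec += 1
                    v = V_reset
                    refI[m, i] = ref_steps
                VI[m, i] = v
            b = step // bin_stride
            rateE[b, m] += nE[m]
            rateI[b, m] += nI[m]
    return n_rec


def simulate_spiking(
    params: SpikingNetParams,
    T_sim: float,
    seed: int = 0,
    record_dt: float = 0.1,
    max_spikes: int = 20_000_000,
) -> tuple[SpikeRecord, RateTrace]:
    """Euler-Maruyama integration of the EIF network.

    A spike is registered at ``V >= V_thresh``; the neuron is reset to
    ``V_reset`` and held (synaptic input discarded) for ``tau_ref``.  Delta
    synapses are applied as voltage increments at the end of the step in
    which the presynaptic spike is registered (one-step effective delay).
    Returns the spike record and the binned population-rate trace.
    """
    m = params.module
    if m.I_ext_E is None or m.I_ext_I is None:
        raise ValueError("module external currents must be calibrated first "
                         "(ModuleParams.calibrated or calibrate_external_inputs)")
    sigE, sigI = calibrate_noise(params)
    c = params.coupling
    L = 1 if c is None else c.L
    use_adj = False
    wEE_within = wIE_within = 1.0
    CE = CI = np.ones((1, 1))
    empty_ptr = np.zeros(m.N_E + 1, dtype=np.int64)
    empty_tgt = np.empty(0, dtype=np.int64)
    adjE = (empty_ptr, empty_tgt)
    adjI = (empty_ptr, empty_tgt)
    if c is not None:
        if params.scheme == "sampled":
            if L != 2:
                raise ValueError("the sampled connectivity scheme supports "
                                 "two modules; use scheme='mixed' for chains")
            f_lr = c.f_lr
            C_lr = int(round(f_lr * m.N_E))
            rng = np.random.default_rng(seed + 987654321)
            n_post_I = m.N_I if c.targets_inhibitory else 0
            adjE, adjI = _cross_adjacency(m.N_E, m.N_E, n_post_I, C_lr, rng)
            use_adj = True
            wEE_within = 1.0 - f_lr
            wIE_within = 1.0 - f_lr if c.targets_inhibitory else 1.0
        elif params.scheme == "mixed":
            idx = (np.arange(L)[:, None] - np.arange(L)[None, :]) % L
            CE = np.ascontiguousarray(c.weights[idx])
            CI = CE if c.targets_inhibitory else np.eye(L)
        else:
            raise ValueError("scheme must be 'sampled' or 'mixed'")
    dt = params.dt
    stride = max(1, int(round(record_dt / dt)))
    n_steps = int(round(T_sim / dt)) // stride * stride
    n_bins = n_steps // stride
    rateE = np.zeros((n_bins, L))
    rateI = np.zeros((n_bins, L))
    rec_times = np.empty(max_spikes)
    rec_ids = np.empty(max_spikes, dtype=np.int64)
    rec_mod = np.empty(max_spikes, dtype=np.int64)
    rec_pop = np.empty(max_spikes, dtype=np.int64)
    e = params.eif
    n_rec = _spiking_kernel(
        n_steps, dt, L, m.N_E, m.N_I, params.V_init_spread,
        e.tau_m, e.E_L, e.V_T, e.Delta_T, e.V_reset, e.V_thresh,
        int(round(e.tau_ref / dt)),
        m.I_ext_E, m.I_ext_I, sigE, sigI,
        params.J_EE, params.J_IE, params.J_EI, wEE_within, wIE_within,
        CE, CI, use_adj, params.J_EE, params.J_IE,
        adjE[0], adjE[1], adjI[0], adjI[1],
        int(seed), stride, rateE, rateI,
        rec_times, rec_ids, rec_mod, rec_pop, max_spikes)
    if n_rec >= max_spikes:
        raise RuntimeError("spike record overflow; raise max_spikes")
    bin_s = dt * stride * 1e-3
    rateE /= m.N_E * bin_s
    rateI /= m.N_I * bin_s
    t = dt * stride * np.arange(1, n_bins + 1)
    sel_t, sel_i, sel_m, sel_p = (rec_times[:n_rec], rec_ids[:n_rec],
                                  rec_mod[:n_rec], rec_pop[:n_rec])
    rec = SpikeRecord(
        times_E=[sel_t[(sel_m == mm) & (sel_p == 0)] for mm in range(L)],
        ids_E=[sel_i[(sel_m == mm) & (sel_p == 0)] for mm in range(L)],
        times_I=[sel_t[(sel_m == mm) & (sel_p == 1)] for mm in range(L)],
        ids_I=[sel_i[(sel_m == mm) & (sel_p == 1)] for mm in range(L)],
        N_E=m.N_E, N_I=m.N_I, T_sim=n_steps * dt,
        metadata={"seed": seed, "sigma_E": sigE, "sigma_I": sigI,
                  "scheme": params.scheme if c is not None else "single"})
    nan = np.full((n_bins, L), np.nan)
    trace = RateTrace(t, nan, nan.copy(), rateE, rateI,
                      {"mode": "spiking", "seed": seed, "dt": dt,
                       "record_dt": dt * stride, "N_E": m.N_E, "N_I": m.N_I})
    return rec, trace


def bin_population_rate(record: SpikeRecord, bin_ms: float = 0.1) -> RateTrace:
    """Population rate per bin: spike count / (N * bin), per module."""
    if record.total_spikes() == 0:
        raise ValueError("empty spike record")
    n_bins = int(np.ceil(record.T_sim / bin_ms))
    edges = bin_ms * np.arange(n_bins + 1)
    rE = np.zeros((n_bins, record.L))
    rI = np.zeros((n_bins, record.L))
    for mmod in range(record.L):
        rE[:, mmod], _ = np.histogram(record.times_E[mmod], bins=edges)
        rI[:, mmod], _ = np.histogram(record.times_I[mmod], bins=edges)
    rE /= record.N_E * bin_ms * 1e-3
    rI /= record.N_I * bin_ms * 1e-3
    t = edges[1:]
    nan = np.full_like(rE, np.nan)
    return RateTrace(t, nan, nan.copy(), rE, rI,
                     {"mode": "spiking-binned", "record_dt": bin_ms})
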