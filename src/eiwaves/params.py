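"""Module-level network parameters and distance-dependent coupling profiles.

An "E-I module" is a recurrently coupled pair of excitatory and inhibitory
populations; modules interact through long-range excitation whose strength
decays with distance.  Synaptic weights are total population strengths in
mV*s (the per-synapse weight times the presynaptic population size times the
membrane time constant), rates are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .eif import TransferTable

__all__ = [
    "ModuleParams",
    "CouplingProfile",
    "coupling_profile",
    "load_params",
    "calibrate_external_inputs",
    "CASE_A",
    "CASE_B",
    "CASE_C",
    "reference_case",
]

MODES = ("two_module_EE", "two_module_EEI", "chain_EE", "chain_EEI")


@dataclass(frozen=True)
class ModuleParams:
    """Synaptic strengths and operating point of a single E-I module."""

    w_EE: float = 1.6    # E-to-E total synaptic strength (mV*s)
    w_IE: float = 2.0    # E-to-I total synaptic strength (mV*s)
    w_EI: float = 0.32   # I-to-E total synaptic strength (mV*s)
    r_E_s: float = 5.0   # target fixed-point excitatory rate (Hz)
    r_I_s: float = 10.0  # target fixed-point inhibitory rate (Hz)
    N_E: int = 8000      # excitatory population size (stochastic mode)
    N_I: int = 2000      # inhibitory population size (stochastic mode)
    I_ext_E: float | None = None  # derived external current (mV)
    I_ext_I: float | None = None

    def __post_init__(self) -> None:
        if min(self.w_EE, self.w_IE, self.w_EI) < 0:
            raise ValueError("synaptic strengths must be non-negative")
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")

    def with_N(self, N: int) -> "ModuleParams":
        """Same module with total size N split 4:1 between E and I."""
        return replace(self, N_E=int(0.8 * N), N_I=int(0.2 * N))

    def calibrated(self, table: TransferTable) -> "ModuleParams":
        I_E, I_I = calibrate_external_inputs(self, table)
        return replace(self, I_ext_E=I_E, I_ext_I=I_I)


# Reference synaptic-strength cases (fixed-point rates 5/10 Hz throughout).
CASE_A = ModuleParams(w_EE=1.6, w_IE=2.0, w_EI=0.32)
CASE_B = ModuleParams(w_EE=1.6, w_IE=1.6, w_EI=0.8)
CASE_C = ModuleParams(w_EE=1.76, w_IE=3.2, w_EI=0.4)


def load_params(path) -> tuple[ModuleParams, "EIFParams"]:
    """Read a YAML parameter file using the standard symbol names.

    Recognized keys: w_EE, w_IE, w_EI, r_E_s, r_I_s, N_E, N_I (module) and
    sigma_tot, tau_m, E_L, V_T, Delta_T, V_reset, V_thresh, tau_ref
    (neuron).  Missing keys fall back to the reference defaults.
    """
    import yaml

    from .eif import EIFParams

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    mod_keys = {"w_EE", "w_IE", "w_EI", "r_E_s", "r_I_s", "N_E", "N_I"}
    eif_map = {"sigma_tot": "sigma", "tau_m": "tau_m", "E_L": "E_L",
               "V_T": "V_T", "Delta_T": "Delta_T", "V_reset": "V_reset",
               "V_thresh": "V_thresh", "tau_ref": "tau_ref"}
    unknown = set(data) - mod_keys - set(eif_map)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    module = ModuleParams(**{k: data[k] for k in mod_keys & set(data)})
    eif = EIFParams(**{eif_map[k]: v for k, v in data.items() if k in eif_map})
    return module, eif


def reference_case(name: str) -> ModuleParams:
    try:
        return {"A": CASE_A, "B": CASE_B, "C": CASE_C}[name.upper()]
    except KeyError:
        raise ValueError(f"unknown reference case {name!r}; expected A, B or C")


def calibrate_external_inputs(
    params: ModuleParams, table: TransferTable
) -> tuple[float, float]:
    """External currents imposing the target fixed-point rates.

    ``I_ext_E = Phi^-1(r_E_s) - w_EE r_E_s + w_EI r_I_s`` and
    ``I_ext_I = Phi^-1(r_I_s) - w_IE r_E_s`` (weights mV*s, rates Hz).
    """
    I_E_s = table.rate_inverse(params.r_E_s)
    I_I_s = table.rate_inverse(params.r_I_s)
    I_ext_E = I_E_s - params.w_EE * params.r_E_s + params.w_EI * params.r_I_s
    I_ext_I = I_I_s - params.w_IE * params.r_E_s
    return I_ext_E, I_ext_I


@dataclass(frozen=True)
class CouplingProfile:
    """Normalized distance-dependent long-range excitation weights.

    ``weights[l]`` is the fraction of a neuron's excitatory input coming from
    modules at (periodic) distance ``l``; the profile sums to one.  For the
    two-module modes the single parameter is the long-range fraction
    ``f_lr``; chains use an exponential decay ``C(l) ~ exp(-lambda |l|)``
    with periodic boundary conditions, optionally mixed with a purely local
    component: ``C(l) ~ (1 - alpha) delta_l0 + alpha exp(-lambda |l|)``.
    """

    L: int
    mode: str
    weights: np.ndarray
    lam: float | None = None     # exponential decay constant (per module)
    f_lr: float | None = None    # long-range fraction (two-module modes)
    alpha_mix: float = 1.0       # fraction of non-local excitation

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("coupling weights must sum to 1 within 1e-12")
        if np.any(w < -1e-15):
            raise ValueError("coupling weights must be non-negative")
        if self.L >= 2 and not np.allclose(w, w[np.r_[0, self.L - 1:0:-1]], atol=1e-12):
            raise ValueError("coupling weights must satisfy C(l) = C(L-l)")

    @property
    def targets_inhibitory(self) -> bool:
        """True when long-range excitation also targets inhibitory neurons."""
        return self.mode.endswith("EEI")

    def fourier(self, q: float | np.ndarray) -> float | np.ndarray:
        """Discrete Fourier transform C~(q) = sum_l C(l) exp(i q l) (real)."""
        l = np.arange(self.L)
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        out = (self.weights[None, :] * np.cos(q_arr[:, None] * l[None, :])).sum(axis=1)
        return float(out[0]) if np.isscalar(q) else out

    @property
    def q_grid(self) -> np.ndarray:
        """Chain wavenumbers q_k = 2 pi k / L, k = 0..L-1."""
        return 2.0 * np.pi * np.arange(self.L) / self.L

    def effective_f_lr(self, q: float | np.ndarray):
        """Two-module coupling equivalent to a chain perturbation at wavenumber q:
        f_lr(q) = [1 - C~(q)]/2."""
        return (1.0 - self.fourier(q)) / 2.0


def coupling_profile(
    L: int,
    lam: float | None = None,
    mode: str = "chain_EEI",
    alpha_mix: float = 1.0,
    f_lr: float | None = None,
) -> CouplingProfile:
    """Build a normalized coupling profile.

    Two-module modes require ``f_lr`` (0 <= f_lr <= 0.5); chain modes require
    the decay constant ``lam > 0``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must lie in [0, 1]")
    if mode.startswith("two_module"):
        if L != 2:
            raise ValueError("two-module modes require L = 2")
        if f_lr is None or not 0.0 <= f_lr <= 0.5:
            raise ValueError("two-module modes require 0 <= f_lr <= 0.5")
        w = np.array([1.0 - f_lr, f_lr])
        return CouplingProfile(L=2, mode=mode, weights=w, f_lr=f_lr)
    if L < 2:
        raise ValueError("chain modes require L >= 2")
    if lam is None or lam <= 0:
        raise ValueError("chain modes require lambda > 0")
    l = np.arange(L)
    expo = np.exp(-lam * l) + np.exp(-lam * (L - l))
    expo[0] = np.exp(-lam * L) + 1.0  # |l| = 0 term plus its periodic image
    expo /= expo.sum()
    w = alpha_mix * expo
    w[0] += 1.0 - alpha_mix
    w /= w.sum()
    return CouplingProfile(L=L, mode=mode, weights=w, lam=lam, alpha_mix=alpha_mix)


def fourier_closed_form(q: float | np.ndarray, lam: float):
    """Long-chain closed form C~_lambda(q) = (cosh(lam) - 1)/(cosh(lam) - cos(q))."""
    return (np.cosh(lam) - 1.0) / (np.cosh(lam) - np.cos(q))
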