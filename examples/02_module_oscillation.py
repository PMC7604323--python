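"""A single E-I module: limit cycle, phase diffusion, decorrelation time.

Builds the desk-scale transfer table, finds the deterministic limit cycle
of the reference module, and evaluates the finite-size phase-diffusion
quadratures.  tau_D is the time over which the oscillation phase of a
module of N neurons decorrelates; it grows linearly with N.
"""
import numpy as np
from eiwaves import CASE_A, build_transfer_table
from eiwaves import theory as th

table = build_transfer_table(dI=0.2, f_grid=np.arange(1., 1001., 2.), dV=0.02)
params = CASE_A.calibrated(table)
cycle = th.find_limit_cycle(params, table)
fl = th.floquet_analysis(cycle, params, table)
print(f"limit cycle: T = {cycle.T:.2f} ms ({1000/cycle.T:.1f} Hz), "
      f"contraction per cycle mu2 = {complex(fl.mu2).real:.3f}")
D_E, D_I, _ = th.phase_diffusion(cycle, fl, params, table)
print(f"noise amplitudes: D_E = {D_E:.3g} ms, D_I = {D_I:.3g} ms")
for N in (10_000, 100_000):
    D_N = D_E / (0.8 * N) + D_I / (0.2 * N)
    print(f"  N = {N:>6}: D_N = {D_N:.3f} ms, "
          f"tau_D = {th.decorrelation_time(cycle.T, D_N):6.0f} ms")
# A 10x bigger module keeps its oscillation phase coherent 10x longer.
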