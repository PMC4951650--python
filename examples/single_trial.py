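"""One flash trial inside the Griffiths phase.

A 30x30 photoreceptor square lights a 3x3 LGN patch; the activity then
propagates through the columns in waves separated by quiet stretches
(the EPSPs crawl along dendrites between soma spikes).  Each wave is one
avalanche.
"""

import numpy as np

from corticrit import NetworkConfig, build_network, extract_avalanches
from corticrit.dynamics import DynParams
from corticrit.engine import run_trial

cfg = NetworkConfig(L=20)
net = build_network(cfg, seed=7)
res = run_trial(net, DynParams(E=1.15, max_steps=30_000))

series = extract_avalanches(res.A)
print(f"E = 1.15 mV, L = {cfg.L}: propagation time T = {res.T} steps, "
      f"terminated by {res.terminated}")
print(f"N_R = {res.N_R} of {cfg.n_bulk} neurons fired "
      f"(rho for this trial = {res.N_R / cfg.n_bulk:.3f})")
print(f"{len(series)} avalanches; sizes: {series.sizes.tolist()[:15]}"
      + (" ..." if len(series) > 15 else ""))
print(f"total activity {res.A.sum()} = sum of avalanche sizes "
      f"{series.sizes.sum()} (partition is exact)")
print()
print("activity profile (spikes per 25-step bin):")
bins = np.add.reduceat(res.A, np.arange(0, len(res.A), 25))
print(" ".join(f"{b:d}" for b in bins))
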