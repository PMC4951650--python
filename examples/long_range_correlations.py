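"""Long-range temporal correlations of the activity.

Inside the critical region the raw activity series A(t) is long-range
correlated: its DFA exponent g lies between 0.7 and 1 (0.5 would be
uncorrelated noise).  The avalanche-sequence power spectrum S(f) ~ f^-b
with b ~ 1 is a full-scale phenomenon - at desk scale a trial emits only
tens of avalanches in quasi-periodic waves, far too few for a stable
spectral slope - so the estimator is demonstrated here on a synthetic
long-memory series with known truth instead.
"""

import numpy as np

from corticrit import NetworkConfig, dfa, power_spectrum
from corticrit.correlations import avalanche_autocorrelation
from corticrit.dynamics import DynParams
from corticrit.engine import run_ensemble
from corticrit.synthetic import fractional_gaussian_noise

for E in (1.15, 2.5):
    ens = run_ensemble(NetworkConfig(L=20), DynParams(E=E, max_steps=30_000),
                       30, seed=9, key=(int(E * 100), 20), store_activity=True)
    gs = [dfa(np.asarray(A, float)).g for A in ens.activities
          if len(A) >= 64 and np.ptp(A) > 0]
    line = f"E = {E:4.2f} mV: DFA exponent g = {np.mean(gs):.2f}"
    try:
        ac = avalanche_autocorrelation(ens.avalanches)
        if np.isfinite(ac.tau):
            line += f", autocorrelation cutoff tau = {ac.tau:.1f} avalanche lags"
    except ValueError:
        pass
    print(line)

print()
rng = np.random.default_rng(1)
H = 0.9
series = [fractional_gaussian_noise(2 ** 14, H, rng) for _ in range(6)]
spec = power_spectrum(series_list=series, mode="index", band=(1e-3, 0.1))
print(f"spectral estimator check on synthetic long-memory data (Hurst H = {H}):")
print(f"  fitted b = {spec.b:.2f}, expected 2H - 1 = {2 * H - 1:.2f}")
print()
print("g in [0.7, 1] marks the long-range correlated critical activity; the")
print("supercritical point shows the smoother, trend-dominated profile.")
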