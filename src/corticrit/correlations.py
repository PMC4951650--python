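"""Long-range temporal correlation estimators.

Three views of the same trial data:

* the autocorrelation C(t') of the ordered avalanche-size sequence s(n),
  with t' the lag in avalanche index, fitted by a power law with an
  exponential cutoff, C ~ t'^(-theta) exp(-t'/tau);
* the power spectrum S(f) of the avalanche time series, fitted by 1/f^b
  below 100 Hz (1 time step = 1 ms, so f is in Hz); as the Fourier pair
  of C, theta + b = 1 holds for lags well below the cutoff;
* detrended fluctuation analysis (DFA) of the raw activity series A(t),
  whose exponent g is 0.5 for uncorrelated noise and in (0.5, 1] for
  long-range correlated series.

Avalanche lags and time steps are different clocks: tau is fitted in
avalanche lags and converted to time steps with the mean inter-avalanche
interval of the same data.  The spectrum embeds each avalanche size at
its onset time on the time-step grid by default so that frequencies are
physical; a pure index-domain periodogram is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy import stats as sstats

from .avalanches import extract_avalanches

__all__ = [
    "CorrelationResult",
    "SpectrumResult",
    "DFAResult",
    "avalanche_autocorrelation",
    "power_spectrum",
    "dfa",
    "exponent_vs_E",
]

TS_PER_SECOND = 1000.0  # 1 time step = 1 ms


@dataclass
class CorrelationResult:
    lags: np.ndarray
    C: np.ndarray  #: ensemble-averaged normalised autocorrelation, C(0) = 1
    theta: float  #: power-law decay exponent
    tau: float  #: exponential-cutoff characteristic time, in avalanche lags
    tau_ts: float  #: tau converted to time steps via the mean inter-avalanche interval
    amplitude: float
    fit_lags: tuple
    n_series: int


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var == 0:
        raise ValueError("degenerate constant series")
    full = np.correlate(x, x, mode="full")[x.size - 1 :]
    lags = np.arange(max_lag + 1)
    return full[: max_lag + 1] / (x.size - lags) / var


def avalanche_autocorrelation(
    series_list,
    max_lag: int | None = None,
    fit_lags: tuple | None = None,
    mean_interval_ts: float | None = None,
) -> CorrelationResult:
    """Ensemble-averaged autocorrelation of avalanche-size sequences with a
    t'^(-theta) exp(-t'/tau) fit.

    ``series_list`` is one sequence or a list of per-trial sequences (each
    with >= 4 avalanches; >= 50 pooled are required).  ``mean_interval_ts``
    converts tau to time steps; if omitted, tau_ts is NaN.
    """
    if isinstance(series_list, np.ndarray) and series_list.ndim == 1:
        series_list = [series_list]
    series = [np.asarray(s, dtype=float) for s in series_list if len(s) >= 4]
    total = sum(len(s) for s in series)
    if total < 50:
        raise ValueError(f"need >= 50 pooled avalanches, got {total}")
    if max_lag is None:
        max_lag = min(200, max(len(s) for s in series) // 2)

    acc = np.zeros(max_lag + 1)
    wgt = np.zeros(max_lag + 1)
    for s in series:
        ml = min(max_lag, len(s) // 2)
        if ml < 1 or np.ptp(s) == 0:
            continue
        a = _acf(s, ml)
        w = len(s) - np.arange(ml + 1)
        acc[: ml + 1] += a * w
        wgt[: ml + 1] += w
    keep = wgt > 0
    lags = np.arange(max_lag + 1)[keep]
    C = acc[keep] / wgt[keep]

    # fit on strictly positive C from lag 1 up to the first sign change
    pos = np.flatnonzero(C[1:] <= 0)
    hi = int(pos[0]) if pos.size else len(C) - 1
    if fit_lags is None:
        fit_lags = (1, max(hi, 2))
    lo_f, hi_f = fit_lags
    m = (lags >= lo_f) & (lags <= hi_f) & (C > 0)
    if m.sum() >= 3:
        def model(t, A, theta, tau):
            return A * t ** (-theta) * np.exp(-t / tau)

        p0 = (max(C[m][0], 1e-3), 0.1, max(hi_f / 2.0, 1.0))
        popt, _ = optimize.curve_fit(
            model, lags[m].astype(float), C[m], p0=p0,
            bounds=([1e-8, 0.0, 1e-3], [10.0, 5.0, 1e7]), maxfev=20000,
        )
        A, theta, tau = map(float, popt)
    else:  # essentially uncorrelated sizes: no decay law to fit
        A = theta = tau = float("nan")
    tau_ts = tau * mean_interval_ts if mean_interval_ts else float("nan")
    return CorrelationResult(lags=lags, C=C, theta=theta, tau=tau, tau_ts=tau_ts,
                             amplitude=A, fit_lags=(lo_f, hi_f), n_series=len(series))


@dataclass
class SpectrumResult:
    f: np.ndarray  #: Hz under the 1 ts = 1 ms convention (cycles/step in index mode)
    S: np.ndarray
    b: float
    b_err: float
    band: tuple
    mode: str
    n_series: int


def power_spectrum(
    activities=None,
    series_list=None,
    mode: str = "onset",
    band: tuple = (1.0, 100.0),
    n_grid: int = 80,
) -> SpectrumResult:
    """Trial-averaged periodogram of the avalanche time series with a
    log-log 1/f^b fit in ``band``.

    In the default "onset" mode each trial's avalanche sizes are placed at
    their onset times on the time-step grid (zeros elsewhere), computed
    from the raw activity series in ``activities``; frequencies are then
    in Hz.  In "index" mode the periodogram of the bare size sequences in
    ``series_list`` is used and frequencies are cycles per avalanche.
    """
    if mode == "onset":
        if activities is None:
            raise ValueError("onset mode needs raw activity series")
        fs = TS_PER_SECOND
        emb = []
        for A in activities:
            av = extract_avalanches(np.asarray(A))
            if len(av) < 2:
                continue
            y = np.zeros(len(A))
            y[av.onsets] = av.sizes
            emb.append(y)
    elif mode == "index":
        if series_list is None:
            raise ValueError("index mode needs avalanche size sequences")
        fs = 1.0
        emb = [np.asarray(s, dtype=float) for s in series_list if len(s) >= 8]
    else:
        raise ValueError(f"unknown spectrum mode {mode!r}")
    emb = [y for y in emb if len(y) >= 16 and np.ptp(y) > 0]
    if not emb:
        raise ValueError("no usable series for the spectrum")
    n_av = sum(len(extract_avalanches(y).sizes) if mode == "onset" else len(y) for y in emb)
    if n_av < 128:
        raise ValueError(f"need >= 128 avalanches pooled, got {n_av}")

    f_lo = max(fs / min(len(y) for y in emb), 1e-12)
    f_hi = fs / 2.0
    grid = np.logspace(np.log10(f_lo), np.log10(f_hi), n_grid)
    acc = np.zeros(n_grid)
    cnt = np.zeros(n_grid)
    for y in emb:
        f, p = signal.periodogram(y, fs=fs, detrend="constant")
        good = (f > 0) & (p > 0)
        if good.sum() < 4:
            continue
        m = grid >= f[good].min()
        acc[m] += np.interp(np.log10(grid[m]), np.log10(f[good]), np.log10(p[good]))
        cnt[m] += 1
    keep = cnt > 0
    f_out = grid[keep]
    S = 10 ** (acc[keep] / cnt[keep])

    lo_b, hi_b = band
    m = (f_out >= lo_b) & (f_out <= min(hi_b, f_hi))
    if m.sum() < 4:
        raise ValueError("fit band too narrow for the available frequencies")
    res = sstats.linregress(np.log(f_out[m]), np.log(S[m]))
    return SpectrumResult(f=f_out, S=S, b=float(-res.slope), b_err=float(res.stderr),
                          band=(lo_b, hi_b), mode=mode, n_series=len(emb))


@dataclass
class DFAResult:
    windows: np.ndarray
    F: np.ndarray  #: root-mean-square fluctuation per window size
    g: float
    g_err: float
    order: int


def dfa(x: np.ndarray, order: int = 1, windows: np.ndarray | None = None) -> DFAResult:
    """Detrended fluctuation analysis of a time series.

    The mean-removed series is integrated, split into non-overlapping
    windows of each size, detrended with a polynomial of the given order,
    and the RMS residual F is regressed against window size on log-log
    axes; the slope is the DFA exponent g.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("series too short for DFA")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant series")
    y = np.cumsum(x - x.mean())
    if windows is None:
        windows = np.unique(np.round(np.logspace(np.log10(8), np.log10(x.size // 4), 20)).astype(int))
    windows = windows[(windows >= order + 2) & (windows <= x.size // 2)]
    if windows.size < 4:
        raise ValueError("need at least 4 usable window sizes")
    F = np.empty(windows.size)
    for i, w in enumerate(windows):
        nseg = y.size // w
        seg = y[: nseg * w].reshape(nseg, w)
        t = np.arange(w, dtype=float)
        # least-squares polynomial detrend of every segment at once
        V = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(V, seg.T, rcond=None)
        resid = seg.T - V @ coef
        F[i] = np.sqrt(np.mean(resid ** 2))
    res = sstats.linregress(np.log(windows.astype(float)), np.log(F))
    return DFAResult(windows=windows, F=F, g=float(res.slope), g_err=float(res.stderr),
                     order=order)


def exponent_vs_E(ensembles: dict, band: tuple = (1.0, 100.0),
                  min_len: int = 64) -> "object":
    """Tabulate the spectral exponent b and DFA exponent g across an E grid.

    ``ensembles`` maps E -> Ensemble (with stored activities).  g is the
    trial-average DFA exponent with its standard error; b comes from the
    trial-averaged onset-embedded spectrum.
    """
    import pandas as pd

    if len(ensembles) < 3:
        raise ValueError("need at least 3 values of E")
    rows = []
    for E in sorted(ensembles):
        ens = ensembles[E]
        if ens.activities is None:
            raise ValueError("exponent_vs_E needs ensembles run with store_activity=True")
        row = {"E": E, "b": np.nan, "b_err": np.nan, "g": np.nan, "g_err": np.nan}
        try:
            spec = power_spectrum(activities=ens.activities, band=band)
            row["b"], row["b_err"] = spec.b, spec.b_err
        except ValueError:
            pass
        gs = []
        for A in ens.activities:
            if len(A) >= min_len and np.ptp(A) > 0:
                try:
                    gs.append(dfa(np.asarray(A, dtype=float)).g)
                except ValueError:
                    continue
        if gs:
            row["g"] = float(np.mean(gs))
            row["g_err"] = float(np.std(gs, ddof=1) / np.sqrt(len(gs))) if len(gs) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
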