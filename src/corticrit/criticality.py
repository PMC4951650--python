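"""Order parameter, susceptibility and finite-size scaling.

The quantity of interest is the density of neurons activated by one
flash, rho = <N_R / N>, averaged over independent rewirings of the
quenched disorder at fixed EPSP E and size L.  Its N-scaled trial
variance chi = N (<rho^2> - <rho>^2) and the complex-network form
chi_rho = chi / <rho> probe criticality: at a critical point

    rho(E_c; L) ~ L^(-beta/nu_perp),      chi_rho(E_c; L) ~ L^(gamma/nu_perp),

and the mean propagation time obeys <T> ~ L^mu.  A Griffiths phase is an
extended E interval over which both power laws hold simultaneously -
rho shrinking and chi_rho growing with L - rather than a single point;
its upper edge is the transition point E_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "Ensemble",
    "FSSFit",
    "order_parameter",
    "susceptibility",
    "fss_fit",
    "locate_critical_region",
    "propagation_time_analysis",
    "CriticalRegion",
    "PropagationTimeAnalysis",
]


@dataclass
class Ensemble:
    """Per-(E, L) collection of independent quenched-disorder trials."""

    E: float
    L: int
    nr_frac: np.ndarray  #: per-trial N_R / N in [0, 1]
    T: np.ndarray  #: per-trial propagation times (steps)
    avalanches: list  #: per-trial ordered avalanche-size arrays
    n_trials: int
    seed: int
    activities: list | None = None  #: optional per-trial A(t) series
    n_capped: int = 0  #: trials that hit max_steps (flagged, not dropped)

    @property
    def N(self) -> int:
        return 4 * self.L * self.L

    def pooled_sizes(self) -> np.ndarray:
        arrs = [a for a in self.avalanches if len(a)]
        return np.concatenate(arrs) if arrs else np.empty(0, dtype=np.int64)


def order_parameter(ens: Ensemble) -> tuple[float, float]:
    """rho = <N_R/N> with its standard error over trials."""
    x = np.asarray(ens.nr_frac, dtype=float)
    se = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
    return float(x.mean()), float(se)


def susceptibility(ens: Ensemble) -> tuple[float, float]:
    """(chi, chi_rho): N-scaled unbiased trial variance of N_R/N, and the
    mean-normalised form chi/<rho>.  chi_rho is NaN when rho = 0."""
    x = np.asarray(ens.nr_frac, dtype=float)
    if x.size < 2:
        raise ValueError("susceptibility needs at least 2 trials")
    chi = ens.N * x.var(ddof=1)
    rho = x.mean()
    chi_rho = chi / rho if rho > 0 else float("nan")
    return float(chi), float(chi_rho)


@dataclass
class FSSFit:
    """One finite-size-scaling power law fitted across system sizes."""

    kind: str  #: "rho", "chi_rho" or "T"
    exponent: float  #: beta/nu_perp (rho), gamma/nu_perp (chi_rho) or mu (T)
    exponent_err: float
    amplitude: float
    E: float | None
    values_by_L: dict
    r_squared: float
    p_value: float


_FSS_SIGN = {"rho": -1.0, "chi_rho": +1.0, "T": +1.0}


def fss_fit(values_by_L: dict, kind: str, E: float | None = None) -> FSSFit:
    """Log-log regression of an observable against L.

    The reported exponent is positive by convention: -slope for the
    decaying order parameter, +slope for the diverging susceptibility and
    for the propagation time (mu).
    """
    if kind not in _FSS_SIGN:
        raise ValueError(f"unknown FSS quantity kind {kind!r}")
    items = sorted((int(L), float(v)) for L, v in values_by_L.items())
    if len(items) < 3:
        raise ValueError("need values for at least 3 distinct L")
    L = np.array([it[0] for it in items], dtype=float)
    v = np.array([it[1] for it in items], dtype=float)
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("FSS fit requires positive finite values")
    res = sstats.linregress(np.log(L), np.log(v))
    return FSSFit(
        kind=kind,
        exponent=float(_FSS_SIGN[kind] * res.slope),
        exponent_err=float(res.stderr),
        amplitude=float(np.exp(res.intercept)),
        E=E,
        values_by_L=dict(items),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
    )


def gamma_prime_ratio(rho_fit: FSSFit, chi_fit: FSSFit) -> tuple[float, float]:
    """gamma'/nu_perp = (gamma - beta)/nu_perp from the two fitted ratios,
    with errors combined in quadrature.  The modified susceptibility
    defines gamma = gamma' + beta, so the plain-variance exponent follows
    by subtraction."""
    if rho_fit.kind != "rho" or chi_fit.kind != "chi_rho":
        raise ValueError("need one rho fit and one chi_rho fit")
    val = chi_fit.exponent - rho_fit.exponent
    err = float(np.hypot(chi_fit.exponent_err, rho_fit.exponent_err))
    return val, err


@dataclass
class CriticalRegion:
    """Result of the Griffiths-phase scan over an E grid."""

    gp_values: np.ndarray  #: E values satisfying both scaling conditions
    E_min: float
    E_max: float  #: the transition point E_c (upper edge of the region)
    diagnostics: list  #: per-E dict with both regressions

    @property
    def E_c(self) -> float:
        return self.E_max


def locate_critical_region(
    ensembles: dict,
    r2_min: float = 0.9,
    p_max: float = 0.05,
) -> CriticalRegion:
    """Find the E interval where rho decays and chi_rho grows with L as
    power laws (the Griffiths-phase signature).

    ``ensembles`` maps E -> {L -> Ensemble} with at least 3 sizes per E.
    The thresholds (minimum R^2 and the one-sided slope sign test level of
    each log-log regression) are configurable; E_c is the upper edge of
    the interval.
    """
    gp, diags = [], []
    for E in sorted(ensembles):
        by_L = ensembles[E]
        if len(by_L) < 3:
            raise ValueError(f"need >= 3 sizes L at E = {E}")
        rho = {L: order_parameter(e)[0] for L, e in by_L.items()}
        chr_ = {L: susceptibility(e)[1] for L, e in by_L.items()}
        diag = {"E": E, "rho_by_L": rho, "chi_rho_by_L": chr_}
        ok = False
        try:
            f_rho = fss_fit(rho, "rho", E=E)
            f_chi = fss_fit(chr_, "chi_rho", E=E)
            diag["rho_fit"], diag["chi_fit"] = f_rho, f_chi
            # one-sided sign test: halve the two-sided regression p-value
            ok = (
                f_rho.exponent > 0 and f_rho.p_value / 2 < p_max
                and f_rho.r_squared >= r2_min
                and f_chi.exponent > 0 and f_chi.p_value / 2 < p_max
                and f_chi.r_squared >= r2_min
            )
        except ValueError as exc:  # rho = 0 or chi_rho undefined at this E
            diag["error"] = str(exc)
        diag["in_gp"] = ok
        diags.append(diag)
        if ok:
            gp.append(E)
    gp_arr = np.asarray(gp, dtype=float)
    if gp_arr.size == 0:
        return CriticalRegion(gp_arr, float("nan"), float("nan"), diags)
    return CriticalRegion(gp_arr, float(gp_arr.min()), float(gp_arr.max()), diags)


@dataclass
class PropagationTimeAnalysis:
    table: "object"  #: DataFrame (E, L, T_mean, T_var, n_trials)
    minima: dict  #: L -> E of the deepest interior local minimum of <T>(E)
    mu_fit: FSSFit | None
    collapse: dict | None  #: L -> (E, T/L^mu) rescaled curves


def propagation_time_analysis(ensembles: dict, E_c: float | None = None) -> PropagationTimeAnalysis:
    """Mean and variance of the propagation time across the E grid, local
    minimum detection, and the T ~ L^mu finite-size fit at E_c."""
    import pandas as pd

    rows = []
    for E in sorted(ensembles):
        for L, ens in sorted(ensembles[E].items()):
            T = np.asarray(ens.T, dtype=float)
            rows.append({
                "E": E, "L": int(L), "T_mean": T.mean(),
                "T_var": T.var(ddof=1) if T.size > 1 else 0.0,
                "n_trials": T.size,
            })
    table = pd.DataFrame(rows)

    minima = {}
    for L, sub in table.groupby("L"):
        sub = sub.sort_values("E").reset_index(drop=True)
        t = sub["T_mean"].to_numpy()
        if len(t) >= 3:
            interior = np.flatnonzero((t[1:-1] < t[:-2]) & (t[1:-1] < t[2:])) + 1
            if interior.size:
                minima[int(L)] = float(sub["E"].iloc[interior[np.argmin(t[interior])]])

    mu_fit, coll = None, None
    if E_c is not None and E_c in ensembles and len(ensembles[E_c]) >= 3:
        tmean = {L: float(np.mean(e.T)) for L, e in ensembles[E_c].items()}
        mu_fit = fss_fit(tmean, "T", E=E_c)
        coll = {}
        for L in sorted({int(x) for x in table["L"]}):
            sub = table[table["L"] == L].sort_values("E")
            coll[L] = (sub["E"].to_numpy(), sub["T_mean"].to_numpy() / L ** mu_fit.exponent)
    return PropagationTimeAnalysis(table=table, minima=minima, mu_fit=mu_fit, collapse=coll)
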