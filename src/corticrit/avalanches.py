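"""Avalanche extraction and size-distribution analysis.

An avalanche is all network activity between two consecutive time steps
with zero soma spikes; its size s is the summed spike count of the run.
The toolkit works on the complementary cumulative distribution
F(s) = P(size >= s), which near criticality follows a truncated power law

    F(s) = c1 * s^(1 - alpha) + c2        for s <= Z,

whose root F(Z) = 0 defines the cutoff Z = (-c2/c1)^(1/(1-alpha)).  At a
critical point the cutoff grows with the lateral system size as
Z ~ L^D; D is the characteristic dimensionality of the avalanches and
its absence (D = 0) rules criticality out regardless of any power-law
shape.  Distributions for several L collapse onto a single curve when
plotted as s^(alpha-1) F(s) against s / L^D with the right exponents.

Power-law decay over a fixed range is additionally testable by discrete
maximum likelihood with a Kolmogorov-Smirnov goodness-of-fit obtained
from a parametric bootstrap (Clauset-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "AvalancheSeries",
    "SizeDistribution",
    "CutoffFit",
    "DimensionFit",
    "CollapseResult",
    "MLTestResult",
    "extract_avalanches",
    "cumulative_distribution",
    "log_binned_pdf",
    "fit_cutoff",
    "fit_two_range",
    "fit_dimension",
    "collapse",
    "ml_powerlaw_test",
    "sample_discrete_powerlaw",
]


@dataclass
class AvalancheSeries:
    """Ordered avalanche sizes of one trial with their time-step bounds."""

    sizes: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray  #: inclusive index of the last active step of each run

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def total_activity(self) -> int:
        return int(self.sizes.sum())


def extract_avalanches(A: np.ndarray) -> AvalancheSeries:
    """Partition an activity series into maximal zero-separated runs.

    Sizes are the run sums, so the partition conserves total activity
    exactly: sum(sizes) == sum(A).  An all-zero series yields an empty
    (valid) partition.
    """
    a = np.asarray(A)
    if a.ndim != 1 or (a.size and a.min() < 0):
        raise ValueError("activity must be a 1-D non-negative series")
    nz = np.concatenate(([0], (a > 0).astype(np.int8), [0]))
    d = np.diff(nz)
    onsets = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    cs = np.concatenate(([0], np.cumsum(a)))
    sizes = cs[ends] - cs[onsets]
    return AvalancheSeries(sizes=sizes.astype(np.int64), onsets=onsets, offsets=ends - 1)


@dataclass
class SizeDistribution:
    """Empirical avalanche-size distribution on the raw support."""

    s: np.ndarray  #: unique observed sizes, ascending
    ccdf: np.ndarray  #: F(s) = P(size >= s); F(s_min) = 1, non-increasing
    counts: np.ndarray
    n: int

    def pdf(self) -> np.ndarray:
        return self.counts / self.n


def cumulative_distribution(sizes: np.ndarray) -> SizeDistribution:
    """Exact complementary cumulative distribution of avalanche sizes."""
    sz = np.asarray(sizes)
    if sz.size == 0:
        raise ValueError("need at least one avalanche")
    s, counts = np.unique(sz, return_counts=True)
    tail = np.cumsum(counts[::-1])[::-1]
    return SizeDistribution(s=s, ccdf=tail / sz.size, counts=counts, n=sz.size)


def log_binned_pdf(sizes: np.ndarray, base: float = 2.0):
    """Logarithmically binned probability density (display only; all
    fitting in this module uses the raw cumulative distribution)."""
    sz = np.asarray(sizes, dtype=float)
    top = np.ceil(np.log(sz.max()) / np.log(base)) + 1
    edges = base ** np.arange(0, top + 1)
    hist, _ = np.histogram(sz, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = hist / (widths * sz.size)
    keep = hist > 0
    return centers[keep], dens[keep]


# ---------------------------------------------------------------------------
# cutoff fitting
# ---------------------------------------------------------------------------

@dataclass
class CutoffFit:
    """Truncated power-law fit of the cumulative distribution."""

    alpha: float
    c1: float
    c2: float
    Z: float
    fit_range: tuple
    converged: bool
    message: str = ""
    n_iter: int = 0
    resid: float = float("nan")
    alpha_err: float = float("nan")


def _cutoff_from_coeffs(c1: float, alpha: float, c2: float) -> tuple[float, str]:
    if c2 == 0:
        return np.inf, "c2 = 0: cutoff undefined (pure power law)"
    if c1 * c2 > 0:
        return np.inf, "c1 and c2 share a sign: no root, no cutoff detected"
    return float((-c2 / c1) ** (1.0 / (1.0 - alpha))), ""


def _model(s, c1, alpha, c2):
    return c1 * s ** (1.0 - alpha) + c2


def fit_cutoff(
    data,
    s_min: float = 3.0,
    s_max: float | None = None,
    iterate: bool = True,
    max_iter: int = 30,
    log_spacing: bool = False,
) -> CutoffFit:
    """Fit F(s) = c1 s^(1-alpha) + c2 and locate the cutoff Z.

    ``data`` is a :class:`SizeDistribution` or a raw size array.  The
    lower bound skips discreteness (default s >= 3); when ``iterate`` is
    true the upper fit bound is moved to the running Z estimate until
    self-consistent, since the form is only assumed valid for s <= Z.
    Relative (sigma = F) weighting makes the fit effectively log-scale
    while keeping the approach to zero at the cutoff meaningful.  With
    ``log_spacing`` the support is subsampled log-uniformly first, so
    every decade carries equal weight regardless of point density.
    """
    dist = data if isinstance(data, SizeDistribution) else cumulative_distribution(data)
    s_all = dist.s.astype(float)
    F_all = dist.ccdf
    if log_spacing and s_all.size > 30:
        grid = np.logspace(np.log10(s_all.min()), np.log10(s_all.max()), 120)
        idx = np.unique(np.searchsorted(s_all, grid, side="left").clip(0, s_all.size - 1))
        s_all, F_all = s_all[idx], F_all[idx]
    hi = float(s_max) if s_max is not None else float(s_all.max())
    lo = float(s_min)
    span = lambda m: (np.log10(s_all[m].max() / s_all[m].min()) if m.sum() >= 4 else 0.0)

    mask = (s_all >= lo) & (s_all <= hi)
    if mask.sum() < 4 or span(mask) < 0.5:
        return CutoffFit(np.nan, np.nan, np.nan, np.nan, (lo, hi), False,
                         "fit range too narrow (need several points over >= half a decade)")

    # initial guesses from the log-log mid-range slope
    sl, ic = np.polyfit(np.log(s_all[mask]), np.log(F_all[mask]), 1)
    alpha0 = max(1.05, 1.0 - sl)
    c10 = float(np.exp(ic))
    c20 = -0.5 * c10 * hi ** (1.0 - alpha0)

    p = (c10, alpha0, c20)
    Z_prev = hi
    msg, n_it = "", 0
    for n_it in range(1, max_iter + 1):
        try:
            p, cov = optimize.curve_fit(
                _model, s_all[mask], F_all[mask], p0=p,
                sigma=np.maximum(F_all[mask], 1e-12), maxfev=20000,
            )
        except RuntimeError as exc:
            return CutoffFit(np.nan, np.nan, np.nan, np.nan, (lo, float(s_all[mask].max())),
                             False, f"non-convergence: {exc}", n_it)
        c1, alpha, c2 = map(float, p)
        Z, msg = _cutoff_from_coeffs(c1, alpha, c2)
        if not iterate or not np.isfinite(Z):
            break
        new_hi = min(hi, Z)
        new_mask = (s_all >= lo) & (s_all <= new_hi)
        if new_mask.sum() < 4 or span(new_mask) < 0.5:
            msg = "cutoff estimate collapsed onto the lower bound; kept last stable fit"
            break
        mask = new_mask
        if abs(np.log(max(Z, 1e-12)) - np.log(Z_prev)) < 1e-3:
            break
        Z_prev = Z

    resid = float(np.sqrt(np.mean(
        ((_model(s_all[mask], *p) - F_all[mask]) / np.maximum(F_all[mask], 1e-12)) ** 2)))
    aerr = float(np.sqrt(cov[1, 1])) if np.all(np.isfinite(cov)) else np.nan
    ok = np.isfinite(alpha) and alpha > 1.0
    return CutoffFit(alpha, c1, c2, Z, (lo, float(s_all[mask].max())),
                     ok, msg, n_it, resid, aerr)


def fit_two_range(data, breakpoint: float, s_min: float = 3.0) -> tuple[CutoffFit, CutoffFit]:
    """Two power-law ranges split at the columnar bump s = N_c.

    In the weakly percolating phase the distribution shows a bump at the
    column size separating two power-law ranges.  The lower range
    (s < N_c) is fitted at fixed range; the upper range (s > N_c) is
    fitted with log-uniform support weighting up to the dominating-
    avalanche gap: system-spanning avalanches pile up at a scale set by
    rho N and are separated from the power-law range by a wide empty
    stretch of support, which is excluded as a distinct mode.
    """
    dist = data if isinstance(data, SizeDistribution) else cumulative_distribution(data)
    below = fit_cutoff(dist, s_min=s_min, s_max=breakpoint, iterate=False)
    sup = dist.s[dist.s > breakpoint].astype(float)
    hi = None
    if sup.size >= 3:
        ratios = sup[1:] / sup[:-1]
        ok = sup[:-1] >= 2 * breakpoint  # ignore sparseness right above the bump
        if np.any(ok) and ratios[ok].max() >= 2.0:
            cand = np.flatnonzero(ok)
            gi = int(cand[np.argmax(ratios[cand])])
            hi = float(sup[gi])
    above = fit_cutoff(dist, s_min=breakpoint, s_max=hi, iterate=hi is None,
                       log_spacing=True)
    return below, above


def exclude_dominating(avalanche_lists, nr_frac, rho_threshold: float = 0.5) -> np.ndarray:
    """Pool avalanche sizes, dropping each percolated trial's largest one.

    In the percolating phase most of a trial's activity rides in a single
    system-spanning ("dominating") avalanche whose size is set by rho N,
    not by the power-law background; it piles up near the distribution's
    end and is excluded here as a separate mode.  Trials with activated
    fraction below ``rho_threshold`` are kept whole.
    """
    out = []
    for frac, s in zip(nr_frac, avalanche_lists):
        s = np.asarray(s)
        if frac > rho_threshold and len(s) > 1:
            s = np.delete(s, int(np.argmax(s)))
        out.append(s)
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


@dataclass
class DimensionFit:
    """Cutoff scaling Z ~ L^D across system sizes."""

    D: float
    D_err: float
    amplitude: float
    Z_by_L: dict
    r_squared: float


def fit_dimension(Z_by_L: dict) -> DimensionFit:
    """Log-log regression of the cutoff against the lateral size."""
    items = sorted((int(L), float(Z)) for L, Z in Z_by_L.items())
    if len(items) < 3:
        raise ValueError("need cutoffs for at least 3 distinct L")
    L = np.array([it[0] for it in items], dtype=float)
    Z = np.array([it[1] for it in items], dtype=float)
    if np.any(~np.isfinite(Z)) or np.any(Z <= 0):
        raise ValueError("cutoffs must be finite and positive")
    from scipy import stats

    res = stats.linregress(np.log(L), np.log(Z))
    return DimensionFit(
        D=float(res.slope), D_err=float(res.stderr),
        amplitude=float(np.exp(res.intercept)),
        Z_by_L=dict(items), r_squared=float(res.rvalue ** 2),
    )


# ---------------------------------------------------------------------------
# distribution collapse
# ---------------------------------------------------------------------------

@dataclass
class CollapseResult:
    alpha: float
    D: float
    curves: dict  #: L -> (x, y) rescaled curves, x = s/L^D, y = s^(alpha-1) F(s)
    quality: float  #: mean pairwise L2 distance of log-curves on common support


def collapse(dists: dict, alpha: float, D: float, n_grid: int = 60) -> CollapseResult:
    """Rescale cumulative distributions for several L onto one master curve.

    Quality is the mean pairwise root-mean-square distance between the
    log10 rescaled curves interpolated on a common log-spaced support; a
    perfect collapse scores 0.
    """
    if len(dists) < 2:
        raise ValueError("need distributions for at least 2 system sizes")
    curves = {}
    for L, dist in sorted(dists.items()):
        d = dist if isinstance(dist, SizeDistribution) else cumulative_distribution(dist)
        x = d.s / float(L) ** D
        y = d.s.astype(float) ** (alpha - 1.0) * d.ccdf
        curves[int(L)] = (x, y)
    lo = max(c[0].min() for c in curves.values())
    hi = min(c[0].max() for c in curves.values())
    if not (hi > lo > 0):
        return CollapseResult(alpha, D, curves, float("inf"))
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    interp = []
    for x, y in curves.values():
        interp.append(np.interp(np.log10(grid), np.log10(x), np.log10(np.maximum(y, 1e-300))))
    interp = np.asarray(interp)
    k = len(interp)
    dsum, npair = 0.0, 0
    for i in range(k):
        for j in range(i + 1, k):
            dsum += float(np.sqrt(np.mean((interp[i] - interp[j]) ** 2)))
            npair += 1
    return CollapseResult(alpha, D, curves, dsum / npair)


# ---------------------------------------------------------------------------
# maximum-likelihood power-law test
# ---------------------------------------------------------------------------

@dataclass
class MLTestResult:
    alpha: float
    ks: float
    p_value: float
    n: int
    fit_range: tuple
    n_boot: int


def _pl_norm(alpha: float, s_min: int, s_max: int) -> float:
    return float(special.zeta(alpha, s_min) - special.zeta(alpha, s_max + 1))


def _pl_mle(data: np.ndarray, s_min: int, s_max: int) -> float:
    slog = float(np.log(data).sum())
    n = data.size

    def nll(a):
        return a * slog + n * np.log(_pl_norm(a, s_min, s_max))

    res = optimize.minimize_scalar(nll, bounds=(1.001, 6.0), method="bounded")
    return float(res.x)


def _pl_ccdf(s: np.ndarray, alpha: float, s_min: int, s_max: int) -> np.ndarray:
    z = _pl_norm(alpha, s_min, s_max)
    return (special.zeta(alpha, s) - special.zeta(alpha, s_max + 1)) / z


def sample_discrete_powerlaw(alpha: float, s_min: int, s_max: int, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF sampler for p(s) ~ s^-alpha on integers
    [s_min, s_max] (the synthetic-truth generator for estimator checks)."""
    support = np.arange(s_min, s_max + 1)
    p = support.astype(float) ** -alpha
    cdf = np.cumsum(p / p.sum())
    return support[np.searchsorted(cdf, rng.random(n), side="left")]


def _ks_stat(data: np.ndarray, alpha: float, s_min: int, s_max: int) -> float:
    s = np.sort(data)
    n = s.size
    model_cdf = 1.0 - _pl_ccdf(s + 1, alpha, s_min, s_max)  # P(S <= s)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.abs(emp_hi - model_cdf).max(), np.abs(emp_lo - model_cdf).max()))


def ml_powerlaw_test(
    sizes: np.ndarray,
    s_min: int,
    s_max: int,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> MLTestResult:
    """Discrete power-law MLE on [s_min, s_max] with a parametric-bootstrap
    Kolmogorov-Smirnov goodness-of-fit p-value.

    p is the fraction of synthetic samples (drawn from the fitted law,
    refitted each time) whose KS distance is at least the observed one;
    small p rejects the power law.
    """
    if rng is None:
        rng = np.random.default_rng()
    sz = np.asarray(sizes, dtype=np.int64)
    data = sz[(sz >= s_min) & (sz <= s_max)]
    if data.size < 100:
        raise ValueError(f"need >= 100 samples in [{s_min}, {s_max}], got {data.size}")
    alpha = _pl_mle(data, s_min, s_max)
    ks_obs = _ks_stat(data, alpha, s_min, s_max)
    worse = 0
    for _ in range(n_boot):
        boot = sample_discrete_powerlaw(alpha, s_min, s_max, data.size, rng)
        a_b = _pl_mle(boot, s_min, s_max)
        if _ks_stat(boot, a_b, s_min, s_max) >= ks_obs:
            worse += 1
    return MLTestResult(alpha=alpha, ks=ks_obs, p_value=worse / n_boot,
                        n=int(data.size), fit_range=(s_min, s_max), n_boot=n_boot)
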