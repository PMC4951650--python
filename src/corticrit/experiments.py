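"""Experiment orchestration: E x L sweeps, persistence, reproduction recipes.

A sweep runs independent quenched-disorder ensembles on a grid of EPSP
values and system sizes, writes one directory per grid point (trial
summary, avalanche sizes, provenance record) and assembles a phase-diagram
table.  Completed points are skipped on re-run, so sweeps are resumable;
everything is reproducible from the master seed, with one independent
random substream per (grid point, trial) regardless of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .criticality import Ensemble, order_parameter, susceptibility
from .dynamics import DynParams
from .engine import run_ensemble
from .network import NetworkConfig

__all__ = ["ExperimentPlan", "run_experiment", "load_point", "reproduce_figure"]


@dataclass
class ExperimentPlan:
    """One E x L sweep.

    ``E_grid`` and ``L_list`` span the grid; ``trials`` is either an int
    (same everywhere) or a dict L -> int so large systems can run fewer
    trials.  All dynamics options other than E are shared.
    """

    E_grid: list
    L_list: list
    trials: object = 50
    seed: int = 0
    out_dir: str = "sweep"
    lam: float = 0.996
    v_T: float = 10.0
    R: int = 1_000_000_000
    max_steps: int = 30_000
    stimulus_side: int = 30
    store_activity: bool = False
    config_overrides: dict = field(default_factory=dict)

    def n_trials(self, L: int) -> int:
        return int(self.trials[L]) if isinstance(self.trials, dict) else int(self.trials)

    def network_config(self, L: int) -> NetworkConfig:
        return NetworkConfig(L=int(L), **self.config_overrides)

    def dyn_params(self, E: float) -> DynParams:
        return DynParams(E=float(E), lam=self.lam, v_T=self.v_T, R=self.R,
                         max_steps=self.max_steps)

    def point_key(self, E: float, L: int) -> tuple:
        return (int(round(E * 1000)), int(L))

    def point_dir(self, E: float, L: int) -> str:
        return f"E{E:.3f}_L{int(L):03d}"

    def provenance(self, E: float, L: int) -> dict:
        cfg = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps({"plan": cfg, "E": E, "L": int(L)}, sort_keys=True, default=str)
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
            "E": E,
            "L": int(L),
            "n_trials": self.n_trials(L),
            "version": __version__,
        }


def _write_point(path: Path, ens: Ensemble, prov: dict) -> None:
    tmp = path.with_name(path.name + ".partial")
    if tmp.exists():
        import shutil

        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    pd.DataFrame(
        {
            "trial": np.arange(ens.n_trials),
            "nr_frac": ens.nr_frac,
            "T": ens.T,
            "n_avalanches": [len(a) for a in ens.avalanches],
        }
    ).to_csv(tmp / "summary.tsv", sep="\t", index=False)
    rows = [(i, s) for i, av in enumerate(ens.avalanches) for s in av]
    pd.DataFrame(rows, columns=["trial", "size"]).to_csv(
        tmp / "avalanches.tsv", sep="\t", index=False
    )
    if ens.activities is not None:
        arows = [(i, t, a) for i, A in enumerate(ens.activities) for t, a in enumerate(A)]
        pd.DataFrame(arows, columns=["trial", "t", "A"]).to_csv(
            tmp / "activity.tsv", sep="\t", index=False
        )
    with open(tmp / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    tmp.rename(path)  # only complete points ever carry the final name


def load_point(path, E: float | None = None, L: int | None = None) -> Ensemble:
    """Reload one grid point written by :func:`run_experiment`."""
    path = Path(path)
    prov = json.loads((path / "provenance.json").read_text())
    summary = pd.read_csv(path / "summary.tsv", sep="\t")
    av = pd.read_csv(path / "avalanches.tsv", sep="\t")
    avalanches = [
        av.loc[av["trial"] == i, "size"].to_numpy(dtype=np.int64)
        for i in summary["trial"]
    ]
    acts = None
    if (path / "activity.tsv").exists():
        act = pd.read_csv(path / "activity.tsv", sep="\t")
        acts = [
            act.loc[act["trial"] == i].sort_values("t")["A"].to_numpy(dtype=np.int64)
            for i in summary["trial"]
        ]
    return Ensemble(
        E=float(prov.get("E", E)), L=int(prov.get("L", L)),
        nr_frac=summary["nr_frac"].to_numpy(), T=summary["T"].to_numpy(dtype=np.int64),
        avalanches=avalanches, n_trials=len(summary), seed=int(prov["seed"]),
        activities=acts,
    )


def run_experiment(plan: ExperimentPlan, force: bool = False, progress=None):
    """Run (or resume) a sweep; returns (phase-diagram DataFrame, ensembles).

    ``ensembles`` maps E -> {L -> Ensemble}.  Existing completed points
    are loaded instead of recomputed unless ``force``; partial points are
    never mistaken for complete ones (they are written to a side name and
    atomically renamed).
    """
    out = Path(plan.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensembles: dict = {}
    rows = []
    for E in plan.E_grid:
        ensembles[E] = {}
        for L in plan.L_list:
            pdir = out / plan.point_dir(E, L)
            if pdir.exists() and not force:
                ens = load_point(pdir, E=E, L=L)
                status = "loaded"
            else:
                ens = run_ensemble(
                    plan.network_config(L), plan.dyn_params(E), plan.n_trials(L),
                    seed=plan.seed, side=plan.stimulus_side,
                    store_activity=plan.store_activity, key=plan.point_key(E, L),
                )
                _write_point(pdir, ens, plan.provenance(E, L))
                status = "computed"
            if progress:
                progress(f"{plan.point_dir(E, L)}: {status}")
            ensembles[E][int(L)] = ens
            rho, rho_se = order_parameter(ens)
            if ens.n_trials >= 2:
                chi, chi_rho = susceptibility(ens)
            else:
                chi = chi_rho = float("nan")
            T = np.asarray(ens.T, dtype=float)
            rows.append({
                "E": E, "L": int(L), "n_trials": ens.n_trials,
                "rho": rho, "rho_se": rho_se, "chi": chi, "chi_rho": chi_rho,
                "T_mean": T.mean(), "T_var": T.var(ddof=1) if T.size > 1 else 0.0,
                "n_capped": ens.n_capped, "status": status,
            })
    table = pd.DataFrame(rows)
    table.to_csv(out / "phase_diagram.tsv", sep="\t", index=False)
    return table, ensembles


# ---------------------------------------------------------------------------
# reproduction recipes
# ---------------------------------------------------------------------------

_DESK = {
    "fig2": dict(E_grid=[0.9, 1.0, 1.05, 1.1, 1.15, 1.2, 1.25, 1.3, 1.4, 1.88, 13.0],
                 L_list=[10, 20, 40], trials={10: 40, 20: 40, 40: 20}),
    "fig3": dict(E_grid=[1.15], L_list=[10, 20, 40], trials={10: 100, 20: 100, 40: 40}),
    "fig4": dict(E_grid=[1.1, 1.15, 1.88, 13.0], L_list=[20, 32], trials={20: 40, 32: 25}),
    "fig5": dict(E_grid=[1.12, 1.15, 1.18, 1.25, 1.6], L_list=[20], trials=40),
}

_FULL = {
    "fig2": dict(E_grid=list(np.round(np.arange(0.9, 2.01, 0.02), 3)) + [13.0],
                 L_list=[20, 40, 80, 99], trials=100),
    "fig3": dict(E_grid=[1.15], L_list=[20, 40, 80, 99], trials=100),
    "fig4": dict(E_grid=[1.1, 1.15, 1.88, 13.0], L_list=[20, 40, 80, 99], trials=100),
    "fig5": dict(E_grid=list(np.round(np.arange(1.05, 1.61, 0.05), 3)), L_list=[99],
                 trials=100),
}


def reproduce_figure(name: str, out_dir: str, scale: str = "desk", seed: int = 0,
                     overrides: dict | None = None, progress=None) -> dict:
    """Run the reduced-scale recipe behind one published-figure protocol.

    Returns a dict of result tables (also written as TSV under
    ``out_dir``).  ``scale`` is "desk" (minutes) or "full" (the original
    protocol; hours to days).  ``overrides`` may replace any
    :class:`ExperimentPlan` field, e.g. tiny grids for smoke tests.
    """
    recipes = _DESK if scale == "desk" else _FULL if scale == "full" else None
    if recipes is None:
        raise ValueError(f"unknown scale {scale!r}")
    if name not in recipes:
        raise ValueError(f"unknown figure recipe {name!r}; choose from {sorted(recipes)}")
    kw = dict(recipes[name])
    kw.update(overrides or {})
    if name == "fig5":
        kw.setdefault("store_activity", True)
    plan = ExperimentPlan(seed=seed, out_dir=str(Path(out_dir) / f"{name}_{scale}"), **kw)
    table, ens = run_experiment(plan, progress=progress)
    out = Path(plan.out_dir)
    results: dict = {"phase_diagram": table, "provenance": plan.provenance(0.0, 0)}

    if name == "fig2":
        from .criticality import locate_critical_region

        if min(len(v) for v in ens.values()) >= 3:
            region = locate_critical_region(ens)
            results["gp_interval"] = (region.E_min, region.E_max)
    elif name == "fig3":
        from .avalanches import cumulative_distribution, fit_cutoff, fit_dimension

        E = plan.E_grid[0]
        rows, Zs = [], {}
        for L, e in ens[E].items():
            f = fit_cutoff(e.pooled_sizes())
            Zs[L] = f.Z
            rows.append({"L": L, "alpha": f.alpha, "Z": f.Z, "converged": f.converged})
        fits = pd.DataFrame(rows)
        if len(Zs) >= 3 and all(np.isfinite(z) for z in Zs.values()):
            D = fit_dimension(Zs)
            fits.attrs["D"] = D.D
            results["dimension"] = {"D": D.D, "D_err": D.D_err}
        results["cutoff_fits"] = fits
        fits.to_csv(out / "cutoff_fits.tsv", sep="\t", index=False)
    elif name == "fig4":
        from .avalanches import collapse, cumulative_distribution, fit_two_range

        rows = []
        for E in plan.E_grid:
            sizes = np.concatenate([e.pooled_sizes() for e in ens[E].values()])
            lo, hi = fit_two_range(sizes, breakpoint=196)
            dists = {L: cumulative_distribution(e.pooled_sizes()) for L, e in ens[E].items()
                     if len(e.pooled_sizes())}
            qual = collapse(dists, lo.alpha, 1.0).quality if len(dists) >= 2 else np.nan
            rows.append({"E": E, "alpha1": lo.alpha, "alpha2": hi.alpha,
                         "collapse_quality_D1": qual})
        results["two_range"] = pd.DataFrame(rows)
        results["two_range"].to_csv(out / "two_range.tsv", sep="\t", index=False)
    elif name == "fig5":
        from .correlations import exponent_vs_E

        L = plan.L_list[0]
        results["exponents"] = exponent_vs_E({E: ens[E][L] for E in plan.E_grid})
        results["exponents"].to_csv(out / "correlation_exponents.tsv", sep="\t", index=False)
    return results
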