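"""Compartmental signal-propagation dynamics.

Discrete-time rules, one compartment per time step:

* a delivery of amplitude E lands on dendritic compartment m (counted as
  distance from the soma) and crawls inward, attenuated by lambda per hop,
  reaching the soma after m steps scaled by lambda^m;
* a non-refractory soma whose incoming potential reaches v_T emits a spike
  and is reset to the refractory value R (time steps); nothing integrates
  across steps at the soma itself;
* the spike enters axonal compartment k = 1 on the next step and shifts
  toward the axon tip, triggering every synapse attached to the
  compartment it currently occupies.

A trial is ignited by a single flash on the photoreceptor sheet (mapped
deterministically onto LGN neurons) and runs until the network is
quiescent.  Because dendritic traversal takes tens of steps, the soma
spike count A(t) naturally splits into separated waves - the model's
avalanches.

This module holds the explicit (readable, array-per-compartment)
simulator used for unit-level validation; :mod:`corticrit.engine` runs
the same dynamics event-driven and compiled for production ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, NetworkConfig

__all__ = [
    "DynParams",
    "NeuronState",
    "TrialResult",
    "stimulus_targets",
    "apply_stimulus",
    "init_state",
    "step",
    "run_trial_reference",
]


@dataclass
class DynParams:
    """Dynamical parameters.

    E : EPSP amplitude in mV (the control parameter).
    lam : dendritic attenuation per compartment per step.
    v_T : soma firing threshold in mV.
    R : refractory period in time steps.  The default is adjusted beyond
        any achievable re-excitation interval (effectively one spike per
        neuron per trial): shorter values let slow activity fronts
        re-excite recovered neurons through the interlayer loops and the
        dynamics loses its absorbing character.
    max_steps : hard cap; hitting it is flagged, never silent.
    """

    E: float
    lam: float = 0.996
    v_T: float = 10.0
    R: int = 1_000_000_000
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if not (self.E >= 0 and 0 < self.lam <= 1 and self.v_T > 0 and self.R >= 1):
            raise ValueError("invalid dynamical parameters")


@dataclass
class NeuronState:
    """Explicit compartment state of all bulk neurons at one time step."""

    dend: np.ndarray  #: (N, n_dend) summed EPSP; column j is compartment m = j+1
    axon: np.ndarray  #: (N, n_axon) binary spike indicators
    soma_in: np.ndarray  #: (N,) potential arriving at the soma this step
    next_ok: np.ndarray  #: (N,) earliest step at which the soma may fire again
    fired: np.ndarray  #: (N,) bool, ever fired in this trial

    def refractory_counter(self, t: int) -> np.ndarray:
        """Remaining refractory steps at time t (0 = excitable)."""
        return np.maximum(self.next_ok - t, 0)


@dataclass
class TrialResult:
    """Outcome of one stimulus propagation.

    A : spikes per time step, trimmed at the last spike.
    N_R : number of distinct neurons that fired (stimulated LGN included).
    T : propagation time, steps from the flash (t = 0) to the last spike.
    terminated : "quiescence" or "max_steps".
    """

    A: np.ndarray
    N_R: int
    T: int
    terminated: str
    seed: int | None = None

    @property
    def total_spikes(self) -> int:
        return int(self.A.sum())


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

def stimulus_targets(config: NetworkConfig, side: int = 30,
                     center: tuple[int, int] | None = None) -> np.ndarray:
    """LGN neuron ids activated by flashing a ``side`` x ``side`` square of
    photoreceptors.

    The square is snapped to the 10x10 photoreceptor->LGN block grid, so a
    centred 30x30 flash lights exactly a 3x3 LGN region and a 10x10 flash
    exactly one LGN neuron.  ``center`` is in photoreceptor coordinates;
    default is the middle of the Input sheet.
    """
    n_in = 10 * config.L
    if not (1 <= side <= n_in):
        raise ValueError(f"flash side {side} outside the {n_in}x{n_in} Input sheet")
    cx, cy = (n_in / 2, n_in / 2) if center is None else center
    if not (0 <= cx <= n_in and 0 <= cy <= n_in):
        raise ValueError(f"flash centre {center} outside the Input sheet")

    def _snap(c: float) -> int:
        x0 = int(round((c - side / 2) / 10.0)) * 10
        return min(max(x0, 0), n_in - side)

    x0, y0 = _snap(cx), _snap(cy)
    bx = np.arange(x0 // 10, (x0 + side - 1) // 10 + 1)
    by = np.arange(y0 // 10, (y0 + side - 1) // 10 + 1)
    ids = (bx[:, None] * config.L + by[None, :]).ravel()
    return ids.astype(np.int64)  # LGN layer occupies global ids [0, L^2)


def apply_stimulus(state: "NeuronState", stim_ids: np.ndarray, params: DynParams) -> int:
    """Fire the flash-mapped LGN neurons at t = 0.  Returns the spike count."""
    state.fired[stim_ids] = True
    state.next_ok[stim_ids] = params.R + 1
    state.axon[stim_ids, :] = 0  # spikes enter axon compartment 1 at t = 1
    state.axon[stim_ids, -1] = 0
    state._pending_spikes = stim_ids  # type: ignore[attr-defined]
    return len(stim_ids)


# ---------------------------------------------------------------------------
# explicit reference simulator
# ---------------------------------------------------------------------------

def init_state(net: Network) -> NeuronState:
    """All-zero initial condition (every potential at rest)."""
    cfg = net.config
    n = cfg.n_bulk
    return NeuronState(
        dend=np.zeros((n, cfg.n_dend)),
        axon=np.zeros((n, cfg.n_axon), dtype=np.uint8),
        soma_in=np.zeros(n),
        next_ok=np.zeros(n, dtype=np.int64),
        fired=np.zeros(n, dtype=bool),
    )


def step(net: Network, state: NeuronState, params: DynParams, t: int) -> int:
    """Advance the explicit state from t-1 to t; returns the spike count A(t).

    Update order: dendritic shift (one hop soma-ward, one factor of
    lambda), axonal shift, synaptic deliveries from the compartments the
    spikes now occupy, then the soma threshold test.
    """
    cfg = net.config
    lam, E = params.lam, params.E

    # dendrite: compartment m feeds m-1; compartment 1 feeds the soma
    state.soma_in = lam * state.dend[:, 0]
    state.dend[:, :-1] = lam * state.dend[:, 1:]
    state.dend[:, -1] = 0.0

    # axon: indicators shift toward the tip; spikes emitted at t-1 enter k=1
    state.axon[:, 1:] = state.axon[:, :-1]
    state.axon[:, 0] = 0
    pending = getattr(state, "_pending_spikes", None)
    if pending is not None and len(pending):
        state.axon[pending, 0] = 1
    state._pending_spikes = None  # type: ignore[attr-defined]

    # deliveries: every synapse whose axonal compartment holds a spike now
    bulk = net.dend_comp > 0  # Output-sheet terminals receive, but are passive
    live = state.axon[net.pre[bulk], net.axon_comp[bulk] - 1] == 1
    if np.any(live):
        posts = net.post[bulk][live]
        comps = net.dend_comp[bulk][live] - 1
        np.add.at(state.dend, (posts, comps), E)

    # soma: fire iff excitable and the arriving potential reaches threshold
    can = (t >= state.next_ok) & (state.soma_in >= params.v_T)
    spikers = np.nonzero(can)[0]
    if len(spikers):
        state.fired[spikers] = True
        state.next_ok[spikers] = t + params.R + 1
        state._pending_spikes = spikers  # type: ignore[attr-defined]
    return len(spikers)


def run_trial_reference(net: Network, params: DynParams,
                        stim_ids: np.ndarray | None = None) -> TrialResult:
    """Run one trial with the explicit simulator (small networks only).

    Terminates once every in-flight potential has provably decayed: no
    spike can occur later than n_axon + n_dend steps after the last one.
    """
    cfg = net.config
    if stim_ids is None:
        stim_ids = stimulus_targets(cfg)
    state = init_state(net)
    horizon = cfg.n_axon + cfg.n_dend + 1
    A = [apply_stimulus(state, np.asarray(stim_ids), params)]
    last = 0
    t = 1
    terminated = "quiescence"
    while t - last <= horizon:
        if t > params.max_steps:
            terminated = "max_steps"
            break
        a = step(net, state, params, t)
        A.append(a)
        if a:
            last = t
        t += 1
    return TrialResult(
        A=np.asarray(A[: last + 1], dtype=np.int64),
        N_R=int(state.fired.sum()),
        T=last,
        terminated=terminated,
    )
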