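"""Quenched-disorder network of the layered, columnar visual-cortex model.

The model propagates activity through six square layers: a photoreceptor
Input sheet, the parvocellular LGN, the V1 layers IVCbeta, II/III and VI,
and an Output sheet of axon terminals projecting to V2.  The four internal
("bulk") layers are L x L grids of compartmental neurons (100 dendritic
compartments, soma, 10 axonal compartments).  The Input and Output sheets
have (10 L)^2 elements each; photoreceptors map onto LGN neurons by a
deterministic 10x10 block rule and carry no synapses.

Synaptic wiring is random and re-drawn per trial (quenched disorder).  A
synapse is built in four steps:

  (a) pick a postsynaptic neuron in the adjacent layer with a 2-D Gaussian
      inside an l x l excitatory field centred in front of the presynaptic
      neuron (default l = 7, one cortical column of N_c = 4 l^2 neurons);
  (b) pick the presynaptic axonal compartment with a truncated exponential
      concentrated at the axon tip;
  (c) pick the postsynaptic dendritic compartment with a Gaussian of mean
      50 and standard deviation 10, truncated to 1..100;
  (d) connect the chosen compartments.

Out-degrees are fixed per presynaptic layer (see the shipped default
config), so the synapse *count* is deterministic; only the endpoints are
random.  Multiple synapses between the same neuron pair are allowed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable

import numpy as np
import yaml
from numba import njit
from scipy import stats as sstats

__all__ = [
    "LAYER_NAMES",
    "OUTPUT_LAYER",
    "NetworkConfig",
    "Network",
    "SynapseStats",
    "build_network",
    "network_stats",
    "sample_postsynaptic",
    "sample_axonal_compartment",
    "sample_dendritic_compartment",
    "axon_compartment_pmf",
    "dend_compartment_pmf",
]

#: Bulk layers, in storage order.  Global neuron id = layer_index * L^2 + x * L + y.
LAYER_NAMES = ("LGN", "IVCb", "II_III", "VI")
#: Pseudo-layer index of the Output sheet of axon terminals.
OUTPUT_LAYER = 4

_LAYER_INDEX = {name: i for i, name in enumerate(LAYER_NAMES)}
_LAYER_INDEX["Output"] = OUTPUT_LAYER


class ConfigError(ValueError):
    """Raised for structurally invalid network configurations."""


def _default_out_degree() -> dict:
    with resources.files("corticrit.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)["out_degree"]


@dataclass
class NetworkConfig:
    """Structural parameters of the layered network.

    Parameters
    ----------
    L : int
        Lateral size of the four internal layers; the bulk has N = 4 L^2
        neurons and the Input/Output sheets (10 L)^2 elements each.
    l : int
        Half-width parameter of the excitatory field (odd).  One column
        holds N_c = 4 l^2 neurons.
    out_degree : dict
        Synapses per presynaptic neuron for each directed layer pair,
        keyed "PRE->POST" with layer names LGN, IVCb, II_III, VI, Output.
    n_dend, n_axon : int
        Compartments per dendrite / axon.
    axon_rate : float
        Rate of the truncated exponential in the distance from the axon
        tip used for step (b); larger values concentrate synapses at the
        tip.
    dend_mean, dend_sd : float
        Gaussian parameters for step (c).
    field_sd : float or None
        Per-axis standard deviation (in grid units) of the 2-D Gaussian of
        step (a); ``None`` means l / 2.
    """

    L: int = 20
    l: int = 7
    out_degree: dict = field(default_factory=_default_out_degree)
    n_dend: int = 100
    n_axon: int = 10
    axon_rate: float = 0.5
    dend_mean: float = 50.0
    dend_sd: float = 10.0
    field_sd: float | None = None

    def __post_init__(self) -> None:
        if self.l < 1 or self.L < self.l:
            raise ConfigError(f"need L >= l >= 1, got L={self.L}, l={self.l}")
        if self.l % 2 == 0:
            raise ConfigError("excitatory-field width l must be odd (centred field)")
        for key, d in self.out_degree.items():
            try:
                pre, post = key.split("->")
                pre_i, post_i = _LAYER_INDEX[pre], _LAYER_INDEX[post]
            except (ValueError, KeyError) as exc:
                raise ConfigError(f"bad out_degree key {key!r}") from exc
            if pre_i == OUTPUT_LAYER:
                raise ConfigError("Output sheet cannot be presynaptic")
            if not (isinstance(d, (int, np.integer)) and d >= 0):
                raise ConfigError(f"out_degree[{key!r}] must be a non-negative int")

    # -- derived quantities -------------------------------------------------
    @property
    def n_bulk(self) -> int:
        """Bulk neuron count N = 4 L^2."""
        return 4 * self.L * self.L

    @property
    def n_io(self) -> int:
        """Elements per Input/Output sheet, (10 L)^2."""
        return (10 * self.L) ** 2

    @property
    def column_size(self) -> int:
        """Neurons per cortical column, N_c = 4 l^2."""
        return 4 * self.l * self.l

    @property
    def field_halfwidth(self) -> int:
        return (self.l - 1) // 2

    @property
    def effective_field_sd(self) -> float:
        return self.l / 2.0 if self.field_sd is None else float(self.field_sd)

    def pair_table(self) -> list[tuple[int, int, int]]:
        """Directed layer pairs as (pre_index, post_index, out_degree)."""
        return [
            (_LAYER_INDEX[k.split("->")[0]], _LAYER_INDEX[k.split("->")[1]], int(d))
            for k, d in sorted(self.out_degree.items())
        ]

    def total_synapses(self) -> int:
        """Deterministic total synapse count, sum of neurons x out-degree."""
        return self.L * self.L * sum(int(d) for d in self.out_degree.values())

    # -- (de)serialisation ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path_or_stream) -> "NetworkConfig":
        if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(path_or_stream)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, stream=None) -> str | None:
        return yaml.safe_dump(asdict(self), stream, sort_keys=True)


# ---------------------------------------------------------------------------
# sampling distributions (Python-level reference API; the numba builder below
# implements the same draws inline)
# ---------------------------------------------------------------------------

def axon_compartment_pmf(config: NetworkConfig) -> np.ndarray:
    """p(k) for the axonal compartment k = 1..n_axon, exponential in the
    distance from the axon tip so that most synapses start at its end."""
    k = np.arange(1, config.n_axon + 1)
    w = np.exp(-config.axon_rate * (config.n_axon - k))
    return w / w.sum()


def dend_compartment_pmf(config: NetworkConfig) -> np.ndarray:
    """p(m) for the dendritic compartment m = 1..n_dend: a rounded Gaussian
    (mean 50, sd 10 by default) truncated to the dendrite."""
    m = np.arange(1, config.n_dend + 1)
    lo = (m - 0.5 - config.dend_mean) / config.dend_sd
    hi = (m + 0.5 - config.dend_mean) / config.dend_sd
    p = sstats.norm.cdf(hi) - sstats.norm.cdf(lo)
    return p / p.sum()


def sample_axonal_compartment(config: NetworkConfig, rng: np.random.Generator, size=None):
    """Draw presynaptic axonal compartment indices (1-based)."""
    pmf = axon_compartment_pmf(config)
    return rng.choice(np.arange(1, config.n_axon + 1), p=pmf, size=size)


def sample_dendritic_compartment(config: NetworkConfig, rng: np.random.Generator, size=None):
    """Draw postsynaptic dendritic compartment indices (1-based) by
    round-and-reject sampling of the truncated Gaussian."""
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        draw = np.rint(rng.normal(config.dend_mean, config.dend_sd, size=2 * (n - got)))
        ok = draw[(draw >= 1) & (draw <= config.n_dend)]
        take = min(ok.size, n - got)
        out[got : got + take] = ok[:take]
        got += take
    if size is None:
        return int(out[0])
    return out.reshape(size)


def sample_postsynaptic(
    pre_position: tuple[int, int], config: NetworkConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick a postsynaptic grid position in the adjacent layer.

    The offset from the presynaptic position is a rounded isotropic 2-D
    Gaussian truncated to the l x l excitatory field; draws landing outside
    the field or outside the layer are redrawn, so the out-degree is
    preserved exactly (edge neurons simply aim inward more often).
    """
    x, y = pre_position
    if not (0 <= x < config.L and 0 <= y < config.L):
        raise ValueError(f"pre position {pre_position} outside an {config.L}x{config.L} layer")
    h = config.field_halfwidth
    sd = config.effective_field_sd
    while True:
        dx = int(np.rint(rng.normal(0.0, sd)))
        dy = int(np.rint(rng.normal(0.0, sd)))
        if abs(dx) > h or abs(dy) > h:
            continue
        tx, ty = x + dx, y + dy
        if 0 <= tx < config.L and 0 <= ty < config.L:
            return tx, ty


# ---------------------------------------------------------------------------
# numba bulk builder
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_synapses(
    L, half, field_sd, n_dend, dend_mean, dend_sd, axon_cdf,
    pre_layers, post_layers, degrees, seed,
):  # pragma: no cover - exercised through build_network
    np.random.seed(seed)
    n_axon = axon_cdf.shape[0]
    n_pairs = degrees.shape[0]
    n_cells = L * L
    n_bulk = 4 * n_cells
    total = 0
    for p in range(n_pairs):
        total += degrees[p] * n_cells
    pre = np.empty(total, dtype=np.int32)
    post = np.empty(total, dtype=np.int32)
    kcomp = np.empty(total, dtype=np.uint8)
    mcomp = np.empty(total, dtype=np.uint8)

    idx = 0
    # outer loop over presynaptic layers then neurons keeps `pre` sorted,
    # which lets the dynamics engine index synapses with analytic offsets
    for layer in range(4):
        for x in range(L):
            for y in range(L):
                pid = layer * n_cells + x * L + y
                for p in range(n_pairs):
                    if pre_layers[p] != layer:
                        continue
                    qlayer = post_layers[p]
                    for _ in range(degrees[p]):
                        # (a) postsynaptic target inside the excitatory field
                        while True:
                            dx = int(np.rint(field_sd * np.random.randn()))
                            dy = int(np.rint(field_sd * np.random.randn()))
                            if dx < -half or dx > half or dy < -half or dy > half:
                                continue
                            tx = x + dx
                            ty = y + dy
                            if 0 <= tx < L and 0 <= ty < L:
                                break
                        # (b) axonal compartment, exponential toward the tip
                        u = np.random.random()
                        k = 1
                        while axon_cdf[k - 1] < u and k < n_axon:
                            k += 1
                        # (c) dendritic compartment, truncated Gaussian
                        if qlayer == 4:
                            # Output sheet: terminal, no dendrite
                            m = 0
                            post_id = n_bulk + (10 * tx + np.random.randint(0, 10)) * (10 * L) \
                                + (10 * ty + np.random.randint(0, 10))
                        else:
                            while True:
                                g = dend_mean + dend_sd * np.random.randn()
                                m = int(np.rint(g))
                                if 1 <= m <= n_dend:
                                    break
                            post_id = qlayer * n_cells + tx * L + ty
                        pre[idx] = pid
                        post[idx] = post_id
                        kcomp[idx] = k
                        mcomp[idx] = m
                        idx += 1
    return pre, post, kcomp, mcomp


@dataclass
class Network:
    """One quenched-disorder realisation of the wiring.

    Synapses are stored structure-of-arrays; row ``i`` is the synapse
    (pre[i], axon_comp[i]) -> (post[i], dend_comp[i]).  ``dend_comp == 0``
    marks terminals on the Output sheet (no dendrite).  The structure is
    fixed once built; rewiring means building a new ``Network``.
    """

    config: NetworkConfig
    pre: np.ndarray
    post: np.ndarray
    axon_comp: np.ndarray
    dend_comp: np.ndarray
    seed: int

    @property
    def n_synapses(self) -> int:
        return self.pre.shape[0]

    def layer_of(self, neuron_id) -> np.ndarray:
        """Layer index (0..3 bulk, 4 = Output) of global neuron ids."""
        nid = np.asarray(neuron_id)
        return np.where(nid < self.config.n_bulk, nid // (self.config.L ** 2), OUTPUT_LAYER)

    def adjacency(self) -> dict:
        """Inward index: (post, dend_comp) -> list of (pre, axon_comp).

        Intended for inspection and small networks; the simulation engine
        uses the flat arrays directly.
        """
        adj: dict = {}
        for p, q, k, m in zip(self.pre, self.post, self.axon_comp, self.dend_comp):
            adj.setdefault((int(q), int(m)), []).append((int(p), int(k)))
        return adj

    def to_tsv(self, path_or_stream) -> None:
        """Dump one synapse per row: pre_layer, pre_id, axon_comp,
        post_layer, post_id, dend_comp (tab-separated, with header)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "pre_layer": [LAYER_NAMES[i] for i in self.layer_of(self.pre)],
                "pre_id": self.pre,
                "axon_comp": self.axon_comp,
                "post_layer": [
                    "Output" if i == OUTPUT_LAYER else LAYER_NAMES[i]
                    for i in self.layer_of(self.post)
                ],
                "post_id": self.post,
                "dend_comp": self.dend_comp,
            }
        )
        df.to_csv(path_or_stream, sep="\t", index=False)


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Build one wiring realisation (steps a-d) with fixed out-degrees.

    The same (config, seed) always yields the identical synapse list.
    """
    pairs = config.pair_table()
    pre_layers = np.array([p[0] for p in pairs], dtype=np.int64)
    post_layers = np.array([p[1] for p in pairs], dtype=np.int64)
    degrees = np.array([p[2] for p in pairs], dtype=np.int64)
    axon_cdf = np.cumsum(axon_compartment_pmf(config))
    pre, post, k, m = _build_synapses(
        config.L,
        config.field_halfwidth,
        config.effective_field_sd,
        config.n_dend,
        config.dend_mean,
        config.dend_sd,
        axon_cdf,
        pre_layers,
        post_layers,
        degrees,
        int(seed) & 0x7FFFFFFF,
    )
    return Network(config=config, pre=pre, post=post, axon_comp=k, dend_comp=m, seed=int(seed))


@dataclass
class SynapseStats:
    """Structural summary of one built network."""

    total_synapses: int
    #: average inward synapses per dendritic compartment of bulk neurons
    mean_syn_per_dend_comp: float
    out_per_layer: dict
    in_per_layer: dict

    def as_frame(self):
        import pandas as pd

        rows = [
            {"layer": name, "out_synapses": self.out_per_layer.get(name, 0),
             "in_synapses": self.in_per_layer.get(name, 0)}
            for name in (*LAYER_NAMES, "Output")
        ]
        return pd.DataFrame(rows)


def network_stats(net: Network) -> SynapseStats:
    """Exact synapse tallies and the mean inward synapses per dendritic
    compartment, <n_syn> = (inward synapses of bulk neurons) / (N * 100)."""
    if net.n_synapses == 0:
        raise ValueError("empty network")
    cfg = net.config
    pre_layer = net.layer_of(net.pre)
    post_layer = net.layer_of(net.post)
    out_counts = {LAYER_NAMES[i]: int(np.sum(pre_layer == i)) for i in range(4)}
    in_counts = {LAYER_NAMES[i]: int(np.sum(post_layer == i)) for i in range(4)}
    in_counts["Output"] = int(np.sum(post_layer == OUTPUT_LAYER))
    inward_bulk = sum(in_counts[name] for name in LAYER_NAMES)
    return SynapseStats(
        total_synapses=net.n_synapses,
        mean_syn_per_dend_comp=inward_bulk / (cfg.n_bulk * cfg.n_dend),
        out_per_layer=out_counts,
        in_per_layer=in_counts,
    )


def column_neuron_count(net_or_config, center: tuple[int, int] | None = None) -> int:
    """Count the neurons of one cortical column (the l x l footprint around
    ``center``, stacked over the four bulk layers) in a built network or
    directly from a config.  Equals N_c = 4 l^2 away from the layer edge."""
    cfg = net_or_config if isinstance(net_or_config, NetworkConfig) else net_or_config.config
    L, h = cfg.L, cfg.field_halfwidth
    cx, cy = (L // 2, L // 2) if center is None else center
    xs = [x for x in range(cx - h, cx + h + 1) if 0 <= x < L]
    ys = [y for y in range(cy - h, cy + h + 1) if 0 <= y < L]
    return 4 * len(xs) * len(ys)
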