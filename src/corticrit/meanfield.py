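"""Mean-field activation threshold of the compartmental network.

A neuron fires when the attenuated synaptic drive arriving at its soma
reaches the firing threshold v_T.  In the naive mean-field picture the
drive delivered to one dendritic compartment by its <n_syn> inward
synapses (all presynaptic partners firing together) reaches the soma
scaled by the average dissipation factor

    <f(lambda)> = sum_m p(m) * lambda^m,

where p(m) is the dendritic-compartment choice distribution (truncated
Gaussian, mean 50, sd 10) and lambda the per-compartment attenuation.
Balancing excitation against dissipation gives the activation threshold

    E_th = v_T / (<n_syn> * <f(lambda)>),

the EPSP above which the whole network is expected to activate.  The
estimate deliberately ignores spatial structure and arrival-time jitter
and therefore overestimates the empirical transition point E_c; the
toolkit asserts that ordering rather than equality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network, NetworkConfig, dend_compartment_pmf, network_stats

__all__ = ["MeanFieldInputs", "dissipation_factor", "activation_threshold", "mean_field_report"]


@dataclass
class MeanFieldInputs:
    """Ingredients of the mean-field threshold.

    n_syn : average inward synapses per dendritic compartment (bulk neurons).
    f_lambda : average fraction of a unit EPSP that reaches the soma.
    v_T : firing threshold in mV.
    """

    n_syn: float
    f_lambda: float
    v_T: float = 10.0

    def __post_init__(self) -> None:
        if not (self.n_syn > 0 and 0 < self.f_lambda <= 1 and self.v_T > 0):
            raise ValueError("mean-field inputs must be positive with f_lambda <= 1")


def dissipation_factor(lam: float, config: NetworkConfig | None = None,
                       pmf: np.ndarray | None = None) -> float:
    """<f(lambda)>: the compartment-distribution average of lambda^m.

    ``pmf`` may override the compartment distribution (index 0 <-> m = 1);
    otherwise it is taken from ``config`` (default config if omitted).
    """
    if not (0 < lam <= 1):
        raise ValueError("attenuation must satisfy 0 < lambda <= 1")
    if pmf is None:
        pmf = dend_compartment_pmf(config or NetworkConfig())
    m = np.arange(1, len(pmf) + 1)
    return float(np.sum(pmf * lam ** m))


def activation_threshold(inputs: MeanFieldInputs) -> float:
    """E_th in mV: the EPSP at which mean synaptic drive balances v_T."""
    drive = inputs.n_syn * inputs.f_lambda
    if drive <= 0:
        raise ValueError("zero mean synaptic drive")
    return inputs.v_T / drive


def mean_field_report(net: Network, lam: float = 0.996, v_T: float = 10.0) -> dict:
    """Measure <n_syn> on a built network and return the full estimate."""
    stats = network_stats(net)
    f = dissipation_factor(lam, net.config)
    inputs = MeanFieldInputs(n_syn=stats.mean_syn_per_dend_comp, f_lambda=f, v_T=v_T)
    return {
        "n_syn": inputs.n_syn,
        "f_lambda": f,
        "v_T": v_T,
        "E_th": activation_threshold(inputs),
    }
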