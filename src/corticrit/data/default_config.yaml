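# Default structural parameters of the layered columnar network.
#
# Out-degrees are synapses per presynaptic neuron for each directed layer
# pair (layer names: LGN, IVCb, II_III, VI, Output).  The table is the
# package's reconstruction of the model's wiring statistics: it is
# calibrated so that the largest simulated size, L = 99, carries about
# 32.5e6 synapses in total, and so that the desk-scale phase diagram
# reproduces the published landmarks (Griffiths phase containing
# E = 1.15 mV, percolation onset near E ~ 1.2 mV, full activation at
# large E via the VI->LGN corticothalamic feedback).  See docs/methods.md
# for the calibration rationale.
L: 20
l: 7
out_degree:
  LGN->IVCb: 890
  IVCb->VI: 761
  VI->IVCb: 870
  VI->LGN: 229
  IVCb->II_III: 184
  II_III->Output: 382
n_dend: 100
n_axon: 10
axon_rate: 0.5
dend_mean: 50.0
dend_sd: 10.0
field_sd: 3.3
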