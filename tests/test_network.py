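"""Structural tests: construction steps, sampling distributions, tallies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from corticrit import NetworkConfig, build_network, network_stats, column_neuron_count
from corticrit.network import (
    ConfigError,
    axon_compartment_pmf,
    dend_compartment_pmf,
    sample_axonal_compartment,
    sample_dendritic_compartment,
    sample_postsynaptic,
)


class TestConfig:
    def test_derived_counts(self):
        cfg = NetworkConfig(L=20)
        assert cfg.n_bulk == 4 * 20 * 20
        assert cfg.n_io == 200 * 200
        assert cfg.column_size == 196  # N_c = 4 l^2 with l = 7

    def test_column_count_matches_formula_and_direct_count(self, tiny_config):
        assert column_neuron_count(tiny_config) == 4 * tiny_config.l ** 2 == 196

    @pytest.mark.parametrize(
        "kwargs",
        [dict(L=5, l=7), dict(L=10, l=4), dict(L=10, out_degree={"LGN->IVCb": -1}),
         dict(L=10, out_degree={"Nowhere->IVCb": 5}), dict(L=10, out_degree={"Output->LGN": 5})],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            NetworkConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = NetworkConfig(L=12, field_sd=2.5)
        p = tmp_path / "cfg.yaml"
        with open(p, "w") as fh:
            cfg.to_yaml(fh)
        assert NetworkConfig.from_yaml(p) == cfg


class TestBuild:
    def test_synapse_count_deterministic(self, tiny_network, tiny_config):
        # out-degrees are fixed per neuron: the count never fluctuates
        assert tiny_network.n_synapses == tiny_config.total_synapses()

    def test_same_seed_identical_wiring(self, tiny_config):
        a = build_network(tiny_config, seed=20)
        b = build_network(tiny_config, seed=20)
        assert np.array_equal(a.pre, b.pre) and np.array_equal(a.post, b.post)
        assert np.array_equal(a.axon_comp, b.axon_comp)
        assert np.array_equal(a.dend_comp, b.dend_comp)

    def test_rewiring_changes_endpoints_not_totals(self, tiny_config):
        a = build_network(tiny_config, seed=1)
        b = build_network(tiny_config, seed=2)
        assert not np.array_equal(a.post, b.post)
        sa, sb = network_stats(a), network_stats(b)
        assert sa.out_per_layer == sb.out_per_layer
        assert sa.total_synapses == sb.total_synapses

    def test_layer_adjacency_respected(self, small_network):
        cfg = small_network.config
        allowed = {tuple(p[:2]) for p in cfg.pair_table()}
        pre_l = small_network.layer_of(small_network.pre)
        post_l = small_network.layer_of(small_network.post)
        assert set(zip(pre_l.tolist(), post_l.tolist())) <= allowed

    def test_compartment_ranges(self, small_network):
        assert small_network.axon_comp.min() >= 1
        assert small_network.axon_comp.max() <= 10
        bulk = small_network.dend_comp > 0
        assert small_network.dend_comp[bulk].min() >= 1
        assert small_network.dend_comp[bulk].max() <= 100
        # Output terminals carry no dendritic compartment
        out_mask = small_network.post >= small_network.config.n_bulk
        assert np.all(small_network.dend_comp[out_mask] == 0)

    def test_targets_inside_field_and_layer(self, small_network):
        cfg = small_network.config
        h = cfg.field_halfwidth
        bulk = small_network.post < cfg.n_bulk
        n2 = cfg.L ** 2
        px, py = (small_network.pre % n2) // cfg.L, (small_network.pre % n2) % cfg.L
        qx, qy = (small_network.post % n2) // cfg.L, (small_network.post % n2) % cfg.L
        assert np.all(np.abs(px[bulk] - qx[bulk]) <= h)
        assert np.all(np.abs(py[bulk] - qy[bulk]) <= h)

    def test_adjacency_roundtrip(self, tiny_network):
        adj = tiny_network.adjacency()
        assert sum(len(v) for v in adj.values()) == tiny_network.n_synapses

    def test_tsv_dump(self, tiny_network, tmp_path):
        p = tmp_path / "net.tsv"
        tiny_network.to_tsv(p)
        df = pd.read_csv(p, sep="\t")
        assert len(df) == tiny_network.n_synapses
        assert list(df.columns) == ["pre_layer", "pre_id", "axon_comp",
                                    "post_layer", "post_id", "dend_comp"]


class TestStats:
    def test_mean_syn_matches_bruteforce_recount(self, tiny_network):
        st = network_stats(tiny_network)
        cfg = tiny_network.config
        # independent tally through pandas instead of the vectorised path
        df = pd.DataFrame({"post": tiny_network.post, "m": tiny_network.dend_comp})
        inward = int((df["post"] < cfg.n_bulk).sum())
        assert st.mean_syn_per_dend_comp == pytest.approx(inward / (cfg.n_bulk * cfg.n_dend))

    def test_doubling_degrees_doubles_total(self):
        cfg = NetworkConfig(L=7)
        doubled = NetworkConfig(L=7, out_degree={k: 2 * v for k, v in cfg.out_degree.items()})
        assert doubled.total_synapses() == 2 * cfg.total_synapses()

    def test_empty_network_rejected(self, tiny_network):
        from dataclasses import replace

        empty = replace(tiny_network, pre=tiny_network.pre[:0])
        with pytest.raises(ValueError):
            network_stats(empty)


class TestSamplers:
    def test_axonal_mode_at_tip_and_pmf_chi2(self, rng):
        cfg = NetworkConfig(L=7)
        draws = sample_axonal_compartment(cfg, rng, size=100_000)
        assert draws.min() >= 1 and draws.max() <= 10
        counts = np.bincount(draws, minlength=11)[1:]
        assert np.argmax(counts) == 9  # compartment 10: most synapses at the tip
        pmf = axon_compartment_pmf(cfg)
        assert np.all(np.diff(pmf) > 0)  # monotone toward the tip
        chi2 = sstats.chisquare(counts, pmf * draws.size)
        assert chi2.pvalue > 1e-4

    def test_dendritic_moments_and_range(self, rng):
        cfg = NetworkConfig(L=7)
        draws = sample_dendritic_compartment(cfg, rng, size=100_000)
        assert draws.min() >= 1 and draws.max() <= 100
        assert 49.7 < draws.mean() < 50.3
        assert 9.8 < draws.std() < 10.2
        assert np.mean((draws < 20) | (draws > 80)) < 0.003  # 3-sigma tail

    def test_dend_pmf_is_proper(self):
        pmf = dend_compartment_pmf(NetworkConfig(L=7))
        assert pmf.sum() == pytest.approx(1.0)
        assert np.argmax(pmf) == 49  # compartment 50

    def test_field_centered_and_truncated(self, rng):
        cfg = NetworkConfig(L=31)
        center = (15, 15)
        pts = np.array([sample_postsynaptic(center, cfg, rng) for _ in range(20_000)])
        off = pts - np.array(center)
        assert np.all(np.abs(off) <= cfg.field_halfwidth)
        se = off.std(axis=0) / np.sqrt(len(off))
        assert np.all(np.abs(off.mean(axis=0)) < 3 * se + 1e-9)

    def test_corner_targets_stay_inside_layer(self, rng):
        cfg = NetworkConfig(L=9)
        pts = np.array([sample_postsynaptic((0, 0), cfg, rng) for _ in range(2000)])
        assert pts.min() >= 0 and pts.max() < cfg.L

    def test_builder_compartments_match_python_pmfs(self, small_network):
        """The compiled builder and the Python samplers draw from the same laws."""
        cfg = small_network.config
        bulk = small_network.dend_comp > 0
        k = np.bincount(small_network.axon_comp[bulk], minlength=11)[1:]
        p = axon_compartment_pmf(cfg)
        assert sstats.chisquare(k, p * k.sum()).pvalue > 1e-6
        m = small_network.dend_comp[bulk].astype(float)
        assert abs(m.mean() - 50.0) < 0.2
        assert abs(m.std() - 10.0) < 0.2
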