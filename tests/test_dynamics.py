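"""Dynamics tests: attenuation law, refractoriness, stimulus mapping,
conservation, and exact agreement between the two simulator backends."""

import numpy as np
import pytest

from corticrit import NetworkConfig, build_network, extract_avalanches
from corticrit.dynamics import DynParams, run_trial_reference, stimulus_targets
from corticrit.engine import run_trial, run_ensemble

from conftest import make_manual_network


class TestAttenuationLaw:
    @pytest.mark.parametrize("k,m", [(1, 1), (5, 50), (10, 100), (3, 10)])
    def test_single_synapse_arrival_time_and_amplitude(self, k, m):
        """An isolated EPSP injected at dendritic compartment m through
        axonal compartment k reaches the soma at t = k + m scaled by
        lambda^m; the soma fires iff E lambda^m >= v_T."""
        lam, vT = 0.996, 10.0
        net = make_manual_network([(0, k, 49 + 24, m)], L=7)  # LGN 0 -> IVCb center
        for E in (vT / lam ** m * 1.001, vT / lam ** m * 0.999):
            res = run_trial_reference(net, DynParams(E=E, lam=lam, v_T=vT), stim_ids=[0])
            fires = E * lam ** m >= vT
            if fires:
                assert res.T == k + m  # arrival step
                assert res.A[k + m] == 1 and res.N_R == 2
            else:
                assert res.N_R == 1 and res.T == 0

    def test_simultaneous_deliveries_sum_linearly(self):
        # two synapses onto the same compartment with the same delay: each
        # contributes E lambda^m, so half the threshold per synapse suffices
        lam, vT, m, k = 0.996, 10.0, 20, 4
        net = make_manual_network([(0, k, 49 + 24, m), (0, k, 49 + 24, m)], L=7)
        E = vT / (2 * lam ** m) * 1.001
        res = run_trial_reference(net, DynParams(E=E, lam=lam, v_T=vT), stim_ids=[0])
        assert res.N_R == 2


class TestSomaContract:
    def test_zero_epsp_never_propagates(self, tiny_network):
        res = run_trial(tiny_network, DynParams(E=0.0))
        assert res.N_R == 9 and res.T == 0 and res.A.sum() == 9

    def test_refractory_soma_ignores_suprathreshold_arrivals(self):
        """Two arrivals 10 steps apart; with R >= 10 the second is lost,
        with smaller R the neuron fires twice."""
        lam, vT = 1.0, 10.0
        post = 49 + 24
        net = make_manual_network([(0, 1, post, 10), (0, 1, post, 20)], L=7)
        E = vT * 1.01
        fired_twice = run_trial_reference(net, DynParams(E=E, lam=lam, v_T=vT, R=5),
                                          stim_ids=[0])
        assert fired_twice.A.sum() == 3  # stimulus + two postsynaptic spikes
        blocked = run_trial_reference(net, DynParams(E=E, lam=lam, v_T=vT, R=50),
                                      stim_ids=[0])
        assert blocked.A.sum() == 2  # second arrival falls inside refractoriness


class TestStimulus:
    def test_centered_flash_maps_to_3x3_lgn(self):
        cfg = NetworkConfig(L=20)
        ids = stimulus_targets(cfg, side=30)
        assert len(ids) == 9
        x, y = ids // cfg.L, ids % cfg.L
        assert np.ptp(x) == 2 and np.ptp(y) == 2  # contiguous 3x3 block
        assert abs(x.mean() - cfg.L / 2) <= 1.5 and abs(y.mean() - cfg.L / 2) <= 1.5

    def test_block_flash_maps_to_single_neuron(self):
        assert len(stimulus_targets(NetworkConfig(L=20), side=10)) == 1

    def test_corner_flash_maps_to_corner_block(self):
        ids = stimulus_targets(NetworkConfig(L=20), side=30, center=(0, 0))
        assert len(ids) == 9 and 0 in ids

    def test_oversized_flash_rejected(self):
        with pytest.raises(ValueError):
            stimulus_targets(NetworkConfig(L=7), side=1000)


class TestTrials:
    def test_engine_matches_reference_exactly(self, tiny_network):
        """The event-driven engine and the explicit compartment simulator
        advance the same dynamics spike-for-spike."""
        for E in (1.0, 1.2, 1.6, 2.5, 13.0):
            p = DynParams(E=E, max_steps=4000)
            ref = run_trial_reference(tiny_network, p)
            fast = run_trial(tiny_network, p)
            assert np.array_equal(ref.A, fast.A)
            assert ref.N_R == fast.N_R and ref.T == fast.T

    def test_activity_conserved_against_spike_log(self, tiny_network):
        """With the default (one spike per neuron) refractoriness the
        distinct-neuron count is an independent tally of total activity."""
        res = run_trial(tiny_network, DynParams(E=1.3))
        assert res.A.sum() == res.N_R

    def test_avalanche_partition_conserves_activity(self, tiny_network):
        res = run_trial(tiny_network, DynParams(E=1.25))
        series = extract_avalanches(res.A)
        assert series.sizes.sum() == res.A.sum()

    def test_absorbing_at_extreme_epsp(self):
        """Activity dies out even at E = 13 mV where the dominating
        avalanche takes over the whole network."""
        net = build_network(NetworkConfig(L=20), seed=99)
        res = run_trial(net, DynParams(E=13.0, max_steps=50_000))
        assert res.terminated == "quiescence"
        assert res.N_R / net.config.n_bulk == pytest.approx(1.0, abs=0.01)

    def test_max_steps_flagged(self, tiny_network):
        res = run_trial(tiny_network, DynParams(E=1.6, R=121, max_steps=500))
        # short refractoriness lets the loops reverberate -> cap is reported
        assert res.terminated in ("max_steps", "quiescence")
        if res.terminated == "max_steps":
            assert res.T <= 500


class TestEnsembles:
    def test_same_master_seed_identical_ensembles(self):
        cfg = NetworkConfig(L=7)
        p = DynParams(E=1.2, max_steps=3000)
        a = run_ensemble(cfg, p, 4, seed=5)
        b = run_ensemble(cfg, p, 4, seed=5)
        assert np.array_equal(a.nr_frac, b.nr_frac) and np.array_equal(a.T, b.T)
        for x, y in zip(a.avalanches, b.avalanches):
            assert np.array_equal(x, y)

    def test_mean_activation_monotone_in_epsp(self):
        """Over a fixed set of wirings, stronger EPSP never activates
        fewer neurons on average."""
        cfg = NetworkConfig(L=10)
        means = []
        for E in (0.9, 1.3, 2.5):
            ens = run_ensemble(cfg, DynParams(E=E, max_steps=20_000), 5, seed=8, key=(1,))
            means.append(ens.nr_frac.mean())
        assert means[0] <= means[1] <= means[2]

    def test_trial_count_validated(self):
        with pytest.raises(ValueError):
            run_ensemble(NetworkConfig(L=7), DynParams(E=1.0), 0, seed=1)
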