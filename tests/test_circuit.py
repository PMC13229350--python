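"""Microcircuit construction: placement, typing, connectivity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pfceeg import build_circuit, default_config, place_neurons, sample_connectivity
from pfceeg.circuit import CircuitGraph, type_counts
from pfceeg.config import CircuitVolume, ConnectionRule, PopulationSpec


class TestPlacement:
    def test_default_type_counts(self, default_cfg):
        counts = type_counts(1000, default_cfg.populations)
        assert counts == {"Pyr": 720, "PV": 90, "SST": 50, "VIP": 140}

    @pytest.mark.parametrize("n", [1, 7, 137, 999])
    def test_counts_sum_to_n_any_size(self, n, default_cfg):
        counts = type_counts(n, default_cfg.populations)
        assert sum(counts.values()) == n
        assert all(v >= 0 for v in counts.values())

    def test_positions_inside_volume_and_depth_range(self, default_cfg):
        neurons = place_neurons(1000, default_cfg.populations, default_cfg.volume, 7)
        assert len(neurons) == 1000
        assert neurons["x_um"].between(0, 500).all()
        assert neurons["y_um"].between(0, 500).all()
        # depth below pia spans L2/3
        assert neurons["z_um"].between(250, 1200).all()

    def test_placement_deterministic_in_seed(self, default_cfg):
        a = place_neurons(200, default_cfg.populations, default_cfg.volume, 9)
        b = place_neurons(200, default_cfg.populations, default_cfg.volume, 9)
        pd.testing.assert_frame_equal(a, b)

    def test_positional_uniformity_pooled_ks(self, default_cfg):
        # pooled over 10 seeds, each axis must be consistent with uniform
        frames = [
            place_neurons(500, default_cfg.populations, default_cfg.volume, s)
            for s in range(10)
        ]
        pooled = pd.concat(frames)
        for col, lo, hi in [("x_um", 0, 500), ("y_um", 0, 500), ("z_um", 250, 1200)]:
            u = (pooled[col] - lo) / (hi - lo)
            assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_invalid_arguments(self, default_cfg):
        with pytest.raises(ValueError):
            place_neurons(0, default_cfg.populations, default_cfg.volume, 1)
        bad = [PopulationSpec("Pyr", 0.5), PopulationSpec("PV", 0.1)]
        with pytest.raises(ValueError):
            place_neurons(10, bad, default_cfg.volume, 1)


class TestConnectivity:
    def test_pyr_pyr_edge_count_matches_bernoulli(self, default_cfg):
        # oracle: expected count p * n_pyr * (n_pyr - 1); empirical within 3 SD
        neurons = place_neurons(1000, default_cfg.populations, default_cfg.volume, 3)
        counts = []
        for s in range(20):
            edges = sample_connectivity(neurons, default_cfg.rules, s)
            types = neurons.set_index("id")["type"]
            pre_t = edges["pre"].map(types)
            post_t = edges["post"].map(types)
            counts.append(int(((pre_t == "Pyr") & (post_t == "Pyr")).sum()))
        n_pairs = 720 * 719
        p = 0.15
        expected = p * n_pairs
        sd = np.sqrt(n_pairs * p * (1 - p))
        mean_count = np.mean(counts)
        assert abs(mean_count - expected) < 3 * sd / np.sqrt(len(counts))

    def test_no_self_connections(self, circuit):
        assert (circuit.edges["pre"] != circuit.edges["post"]).all()

    def test_zero_probability_yields_no_edges(self, default_cfg):
        neurons = place_neurons(300, default_cfg.populations, default_cfg.volume, 3)
        edges = sample_connectivity(neurons, default_cfg.rules, 5)
        types = neurons.set_index("id")["type"]
        pre_t = edges["pre"].map(types)
        post_t = edges["post"].map(types)
        # SST->SST has probability 0 in the default table
        assert not ((pre_t == "SST") & (post_t == "SST")).any()

    def test_sst_to_pyr_targets_apical(self, circuit):
        types = circuit.neurons.set_index("id")["type"]
        edges = circuit.edges
        sst_pyr = edges[
            (edges["pre"].map(types) == "SST") & (edges["post"].map(types) == "Pyr")
        ]
        assert len(sst_pyr) > 0
        assert (sst_pyr["compartment"] == "apical").all()

    def test_pv_to_pyr_targets_basal(self, circuit):
        types = circuit.neurons.set_index("id")["type"]
        edges = circuit.edges
        pv_pyr = edges[
            (edges["pre"].map(types) == "PV") & (edges["post"].map(types) == "Pyr")
        ]
        assert len(pv_pyr) > 0
        assert (pv_pyr["compartment"] == "basal_somatic").all()

    def test_receptor_content_consistent(self, circuit):
        types = circuit.neurons.set_index("id")["type"]
        e = circuit.edges
        inhibitory = e["pre"].map(types).isin(["PV", "SST", "VIP"])
        assert (e.loc[inhibitory, "g_gaba_nS"] > 0).all()
        assert (e.loc[inhibitory, ["g_ampa_nS", "g_nmda_nS"]] == 0).all().all()
        assert (e.loc[~inhibitory, "g_gaba_nS"] == 0).all()
        assert (e.loc[~inhibitory, "g_ampa_nS"] > 0).all()

    def test_nmda_ratio_convention(self, circuit):
        # Pyr->PV uses 1:0.2, other excitatory rules 1:1
        types = circuit.neurons.set_index("id")["type"]
        e = circuit.edges
        pyr_pv = e[(e["pre"].map(types) == "Pyr") & (e["post"].map(types) == "PV")]
        np.testing.assert_allclose(
            pyr_pv["g_nmda_nS"], 0.2 * pyr_pv["g_ampa_nS"], rtol=1e-12
        )
        pyr_pyr = e[(e["pre"].map(types) == "Pyr") & (e["post"].map(types) == "Pyr")]
        np.testing.assert_allclose(pyr_pyr["g_nmda_nS"], pyr_pyr["g_ampa_nS"], rtol=1e-12)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            ConnectionRule("Pyr", "Pyr", 1.5)


class TestBuildCircuit:
    def test_default_build(self, circuit):
        assert circuit.n_neurons == 1000
        assert circuit.counts()["Pyr"] == 720

    def test_n_zero_rejected(self, default_cfg):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(default_cfg, n_neurons=0)

    def test_seeds_give_different_edges_same_statistics(self, default_cfg):
        c1 = build_circuit(default_cfg, 1)
        c2 = build_circuit(default_cfg, 2)
        assert not c1.edges.equals(c2.edges)
        # marginal connection probability agrees across seeds within 2%
        p1 = len(c1.edges) / (1000 * 999)
        p2 = len(c2.edges) / (1000 * 999)
        assert abs(p1 - p2) / p1 < 0.02

    def test_same_seed_identical(self, default_cfg):
        c1 = build_circuit(default_cfg, 77)
        c2 = build_circuit(default_cfg, 77)
        pd.testing.assert_frame_equal(c1.neurons, c2.neurons)
        pd.testing.assert_frame_equal(c1.edges, c2.edges)

    def test_csv_round_trip(self, small_circuit, tmp_path):
        np_, ep = tmp_path / "n.csv", tmp_path / "e.csv"
        small_circuit.to_csv(np_, ep)
        back = CircuitGraph.from_csv(np_, ep, small_circuit.config)
        pd.testing.assert_frame_equal(
            back.neurons, small_circuit.neurons, check_dtype=False
        )
        pd.testing.assert_frame_equal(back.edges, small_circuit.edges, check_dtype=False)
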