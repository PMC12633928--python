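"""Directed modularity, module detection, betweenness, hub ranking."""

import numpy as np
import pandas as pd
import pytest
from conftest import betweenness_oracle, modularity_oracle
from sklearn.metrics import adjusted_rand_score

from abn import network_metrics as nm
from abn.errors import DegenerateNetworkError, ValidationError
from abn.synthetic import GeneratorConfig, make_density


class TestModularity:
    def test_one_community_is_zero_at_gamma_one(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(6, 6))
        np.fill_diagonal(W, 0.0)
        q = nm.modularity(W, [0] * 6, gamma=1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_reciprocal_pairs_give_half(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        assert nm.modularity(W, [0, 0, 1, 1], gamma=1.0) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for n in (3, 5, 8):
            for _ in range(10):
                W = rng.uniform(size=(n, n)) * (rng.uniform(size=(n, n)) < 0.6)
                np.fill_diagonal(W, 0.0)
                if W.sum() == 0:
                    continue
                labels = rng.integers(0, 3, size=n)
                gamma = float(rng.uniform(0.5, 2.0))
                assert nm.modularity(W, labels, gamma=gamma) == pytest.approx(
                    modularity_oracle(W, labels, gamma), abs=1e-12)

    def test_monotone_nonincreasing_in_gamma(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(size=(7, 7))
        np.fill_diagonal(W, 0.0)
        labels = [0, 0, 1, 1, 2, 2, 2]
        qs = [nm.modularity(W, labels, gamma=g)
              for g in np.linspace(0.5, 2.0, 21)]
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_empty_network_rejected(self):
        with pytest.raises(DegenerateNetworkError):
            nm.modularity(np.zeros((3, 3)), [0, 1, 2])

    def test_scale_invariant_at_fixed_partition(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(size=(6, 6))
        np.fill_diagonal(W, 0.0)
        labels = [0, 1, 0, 1, 2, 2]
        q1 = nm.modularity(W, labels, gamma=1.3)
        q2 = nm.modularity(37.0 * W, labels, gamma=1.3)
        assert q1 == pytest.approx(q2)


class TestDetectModules:
    def test_two_disconnected_blocks_recovered(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        truth = [0] * 4 + [1] * 4
        for seed in range(5):
            p = nm.detect_modules(W, gamma=1.0, seed=seed)
            labels = [p.assignment[str(i)] for i in range(8)]
            assert adjusted_rand_score(truth, labels) == 1.0

    def test_complete_uniform_digraph_single_community(self):
        W = np.ones((6, 6))
        np.fill_diagonal(W, 0.0)
        p = nm.detect_modules(W, gamma=1.0, seed=0)
        assert len(set(p.assignment.values())) == 1
        assert p.q == pytest.approx(0.0, abs=1e-12)

    def test_beats_trivial_partitions(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(size=(10, 10))
        np.fill_diagonal(W, 0.0)
        p = nm.detect_modules(W, gamma=1.0, seed=1)
        q_single = nm.modularity(W, [0] * 10, gamma=1.0)
        q_singleton = nm.modularity(W, list(range(10)), gamma=1.0)
        assert p.q >= q_single - 1e-12
        assert p.q >= q_singleton - 1e-12

    def test_planted_blocks_recovered_over_seeds(self):
        cfg = GeneratorConfig(seed=5, within_density=0.5,
                              between_density=0.05, n_blocks=4)
        dm, truth = make_density(cfg)
        labels_true = [truth["blocks"][r] for r in dm.regions]
        for seed in range(10):
            p = nm.detect_modules(dm.rho, gamma=1.0, seed=seed,
                                  regions=dm.regions)
            labels = [p.assignment[r] for r in dm.regions]
            assert adjusted_rand_score(labels_true, labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        W = rng.uniform(size=(12, 12))
        p1 = nm.detect_modules(W, gamma=1.4, seed=42)
        p2 = nm.detect_modules(W, gamma=1.4, seed=42)
        assert p1.assignment == p2.assignment and p1.q == p2.q


class TestBetweenness:
    def test_directed_path_intermediate(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 1.0
        bt = nm.betweenness(W, regions=["A", "B", "C"])
        vals = bt.set_index("region")["betweenness"]
        assert vals["B"] == pytest.approx(1.0)
        assert vals["A"] == vals["C"] == 0.0

    def test_complete_uniform_digraph_all_zero(self):
        W = np.ones((5, 5))
        np.fill_diagonal(W, 0.0)
        bt = nm.betweenness(W)
        assert (bt["betweenness"] == 0).all()

    def test_fewer_than_three_nodes_all_zero(self):
        bt = nm.betweenness(np.array([[0.0, 1.0], [2.0, 0.0]]))
        assert (bt["betweenness"] == 0).all()

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            W = rng.uniform(0.1, 1.0, size=(7, 7)) \
                * (rng.uniform(size=(7, 7)) < 0.5)
            np.fill_diagonal(W, 0.0)
            bt = nm.betweenness(W)
            np.testing.assert_allclose(bt["betweenness"].to_numpy(),
                                       betweenness_oracle(W), atol=1e-9)

    def test_scale_invariant(self):
        rng = np.random.default_rng(8)
        W = rng.uniform(size=(8, 8)) * (rng.uniform(size=(8, 8)) < 0.6)
        np.fill_diagonal(W, 0.0)
        b1 = nm.betweenness(W)["betweenness"]
        b2 = nm.betweenness(123.0 * W)["betweenness"]
        np.testing.assert_allclose(b1, b2)

    def test_normalization_factor(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 2] = W[2, 3] = 1.0
        bt = nm.betweenness(W)
        np.testing.assert_allclose(bt["betweenness_norm"],
                                   bt["betweenness"] / 6.0)


class TestHubsAndSets:
    def _ct(self):
        return pd.DataFrame({
            "brain_id": ["b1"] * 4 + ["b2"] * 4,
            "condition": "ZT0-4",
            "region": ["A", "B", "C", "D"] * 2,
            "betweenness": [5.0, 3.0, 3.0, 1.0, 5.0, 3.0, 3.0, 0.0]})

    def test_full_ranking_is_permutation(self):
        out = nm.rank_hubs(self._ct(), k=4)
        assert sorted(out["rank"]) == [1, 2, 3, 4]

    def test_ties_alphabetical(self):
        out = nm.rank_hubs(self._ct(), k=3)
        assert list(out["region"]) == ["A", "B", "C"]  # B == C tie -> B first

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            nm.rank_hubs(self._ct(), k=9)

    def test_singleton_set_equals_region_centrality(self):
        out = nm.set_centrality(self._ct(), {"A"})
        assert out["mean"].iloc[0] == pytest.approx(5.0)

    def test_whole_network_set_is_global_mean(self):
        out = nm.set_centrality(self._ct(), {"A", "B", "C", "D"})
        assert out["mean"].iloc[0] == pytest.approx((3.0 + 2.75) / 2)

    def test_missing_members_reported(self):
        out = nm.set_centrality(self._ct(), {"A", "ZZZ"})
        assert out.attrs["missing"] == ["ZZZ"]
        with pytest.raises(ValidationError):
            nm.set_centrality(self._ct(), {"ZZZ"})

    def test_planted_bridge_tops_ranking(self):
        cfg = GeneratorConfig(seed=9, bridge_region="PH",
                              between_density=0.01)
        dm, _ = make_density(cfg)
        bt = nm.betweenness(dm.rho, regions=dm.regions)
        assert bt.sort_values("betweenness").iloc[-1]["region"] == "PH"

    def test_hub_tier_beats_periphery(self):
        """With a planted bridge, the bridge-containing set out-centralizes
        an equal-size peripheral set."""
        cfg = GeneratorConfig(seed=10, bridge_region="SCm",
                              between_density=0.01)
        dm, truth = make_density(cfg)
        ct = nm.betweenness(dm.rho, regions=dm.regions).assign(
            brain_id="b1", condition="ZT0-4")
        periphery = [r for r in dm.regions if r != "SCm"][:3]
        hub_mean = nm.set_centrality(ct, {"SCm"})["mean"].iloc[0]
        per_mean = nm.set_centrality(ct, set(periphery))["mean"].iloc[0]
        assert hub_mean > per_mean


class TestSweepAndInvariance:
    def test_sweep_shape_and_gamma_trend(self):
        cfg = GeneratorConfig(seed=11)
        dm, _ = make_density(cfg)
        sw = nm.sweep_modularity(dm.rho, gammas=[0.5, 1.0, 2.0], seed=0,
                                 regions=dm.regions, restarts=3)
        assert list(sw.columns) == ["gamma", "q", "n_modules"]
        assert len(sw) == 3
        # finer resolution can only split modules further
        assert sw["n_modules"].iloc[-1] >= sw["n_modules"].iloc[0]

    def test_global_rescaling_changes_nothing(self):
        """Overall connection strength does not dictate network structure:
        partitions, Q, centralities and rankings are identical under W -> cW."""
        cfg = GeneratorConfig(seed=12, bridge_region="PH")
        dm, _ = make_density(cfg)
        W = dm.rho
        for c in (0.01, 1.0, 250.0):
            p = nm.detect_modules(c * W, gamma=1.0, seed=3, regions=dm.regions)
            p0 = nm.detect_modules(W, gamma=1.0, seed=3, regions=dm.regions)
            assert p.assignment == p0.assignment
            assert p.q == pytest.approx(p0.q)
            b = nm.betweenness(c * W, regions=dm.regions)
            b0 = nm.betweenness(W, regions=dm.regions)
            np.testing.assert_allclose(b["betweenness"], b0["betweenness"])
            assert list(b["rank"]) == list(b0["rank"])
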