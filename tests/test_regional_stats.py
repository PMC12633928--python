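"""Regional counts, composition ratios, z-scores, layer ratios, group tests."""

import numpy as np
import pandas as pd
import pytest
from conftest import counts_oracle

from abn import regional_stats as rs
from abn.atlas import MAJOR_REGIONS, ExclusionSet
from abn.errors import (
    EmptyBrainError,
    InsufficientDataError,
    NoLayerError,
    ScopePartitionError,
)


def _neurons(region_ids, brain="b1", condition="ZT0-4"):
    return pd.DataFrame({
        "neuron_id": [f"n{i}" for i in range(len(region_ids))],
        "brain_id": brain, "condition": condition,
        "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
        "region_id": region_ids})


class TestCountRegions:
    def test_rollup_to_majors(self, tiny_tree):
        neurons = _neurons([778, 778, 778, 262, 170])  # 3x VISp5, RT, LGd
        c = rs.count_regions(neurons, tiny_tree, {"Isocortex", "TH"})
        assert c.counts == {"Isocortex": 3, "TH": 2}
        assert c.total == 5

    def test_exclusion_drops_subtree(self, tiny_tree):
        neurons = _neurons([778, 778, 778, 262, 170])
        c = rs.count_regions(neurons, tiny_tree, {"Isocortex", "TH"},
                             ExclusionSet(frozenset({"Isocortex"})))
        assert c.counts == {"TH": 2}
        assert c.total == 2
        assert c.n_excluded == 3

    def test_unassigned_kept_out_of_denominator(self, tiny_tree):
        c = rs.count_regions(_neurons([778, 0, 0]), tiny_tree, {"Isocortex"})
        assert c.total == 1
        assert c.n_unassigned == 2

    def test_nested_scope_rejected(self, tiny_tree):
        with pytest.raises(ScopePartitionError):
            rs.count_regions(_neurons([778]), tiny_tree, {"Isocortex", "VISp"})

    def test_against_linear_scan_oracle(self, tiny_tree):
        rng = np.random.default_rng(11)
        ids = [n.region_id for n in tiny_tree.nodes()]
        neurons = _neurons(rng.choice(ids, size=500))
        scope = set(MAJOR_REGIONS) & {n.acronym for n in tiny_tree.nodes()}
        excl = ExclusionSet(frozenset({"OLF", "CB"}))
        c = rs.count_regions(neurons, tiny_tree, scope, excl)
        assert c.counts == counts_oracle(neurons, tiny_tree, scope,
                                         {"OLF", "CB", "MOB"})

    def test_permutation_invariant_and_additive(self, tiny_tree):
        rng = np.random.default_rng(3)
        ids = [n.region_id for n in tiny_tree.nodes()]
        n1 = _neurons(rng.choice(ids, size=80), brain="b1")
        n2 = _neurons(rng.choice(ids, size=120), brain="b1")
        scope = {"Isocortex", "TH", "HY"}
        both = rs.count_regions(pd.concat([n1, n2], ignore_index=True),
                                tiny_tree, scope)
        shuffled = rs.count_regions(
            pd.concat([n2, n1], ignore_index=True).sample(frac=1, random_state=9),
            tiny_tree, scope)
        assert both.counts == shuffled.counts
        c1 = rs.count_regions(n1, tiny_tree, scope)
        c2 = rs.count_regions(n2, tiny_tree, scope)
        for a in scope:
            assert both.counts.get(a, 0) == c1.counts.get(a, 0) + c2.counts.get(a, 0)


class TestRatios:
    def test_definition(self):
        c = rs.RegionCounts("b", "ZT0-4", {"A": 30, "B": 70}, 100)
        r = rs.ratios(c).set_index("acronym")["ratio"]
        assert r["A"] == pytest.approx(0.3)
        assert r["B"] == pytest.approx(0.7)

    def test_single_region_is_one(self):
        c = rs.RegionCounts("b", "ZT0-4", {"A": 12}, 12)
        assert rs.ratios(c)["ratio"].iloc[0] == 1.0

    def test_sums_to_one(self, small_assigned, small_atlas):
        counts = rs.count_table(small_assigned, small_atlas.hierarchy,
                                MAJOR_REGIONS, ExclusionSet())
        table = rs.ratio_table(counts)
        sums = table.groupby("brain_id")["ratio"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_brain_rejected(self):
        with pytest.raises(EmptyBrainError):
            rs.ratios(rs.RegionCounts("b", "c", {}, 0))


class TestZScore:
    def _table(self, values, acronym="A"):
        return pd.DataFrame({
            "brain_id": [f"b{i}" for i in range(len(values))],
            "condition": "ZT0-4", "acronym": acronym, "ratio": values})

    def test_two_values_hand_computed(self):
        # sd(ddof=1) of {0.1, 0.3} is 0.1414...; z = +/- 1/sqrt(2)
        z = rs.zscore_across_conditions(self._table([0.1, 0.3]))["z"]
        assert np.allclose(sorted(z), [-0.7071067811865475, 0.7071067811865475])

    def test_zero_variance_flagged(self):
        out = rs.zscore_across_conditions(self._table([0.2, 0.2, 0.2]))
        assert (out["z"] == 0).all()
        assert out["zero_variance"].all()

    def test_per_region_centering_and_scaling(self, small_assigned, small_atlas):
        counts = rs.count_table(small_assigned, small_atlas.hierarchy,
                                MAJOR_REGIONS, ExclusionSet())
        out = rs.zscore_across_conditions(rs.ratio_table(counts))
        for _, g in out.groupby("acronym"):
            if not g["zero_variance"].any():
                assert abs(g["z"].mean()) < 1e-9
                assert g["z"].std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        vals = np.array([0.11, 0.25, 0.17, 0.31])
        z1 = rs.zscore_across_conditions(self._table(vals))["z"]
        z2 = rs.zscore_across_conditions(self._table(3.5 * vals + 0.2))["z"]
        assert np.allclose(z1, z2)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            rs.zscore_across_conditions(self._table([0.5]))


class TestLayerRatios:
    def test_two_layer_split(self, tiny_tree):
        neurons = _neurons([778] * 10 + [821] * 10)  # VISp5, VISp2/3
        out = rs.layer_ratios(neurons, "VISp", tiny_tree)
        r = out.set_index("layer")["ratio"]
        assert r["L5"] == pytest.approx(0.5)
        assert r["L2/3"] == pytest.approx(0.5)

    def test_single_layer(self, tiny_tree):
        out = rs.layer_ratios(_neurons([593, 593]), "VISp", tiny_tree)
        assert out.set_index("layer")["ratio"]["L1"] == 1.0

    def test_non_laminar_parent_rejected(self, tiny_tree):
        with pytest.raises(NoLayerError):
            rs.layer_ratios(_neurons([262]), "TH", tiny_tree)

    def test_recovers_planted_enrichment(self, small_cfg, small_assigned,
                                         small_atlas):
        out = rs.layer_ratios(small_assigned, "Isocortex",
                              small_atlas.hierarchy)
        for cond in small_cfg.conditions:
            planted = small_cfg.layer_probs[cond]["L5"]
            g = out[(out["condition"] == cond) & (out["layer"] == "L5")]
            # each brain's laminar population is ~ iso_share * n_neurons
            n = small_cfg.n_neurons_per_brain * 0.25
            tol = 3 * np.sqrt(planted * (1 - planted) / n)
            assert np.all(np.abs(g["ratio"] - planted) < tol)


class TestCompareGroups:
    def test_identical_groups_null(self):
        out = rs.compare_groups([1, 2, 3], [1, 2, 3])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        out = rs.compare_groups([0, 0, 0], [1, 1, 1])
        assert out["degenerate"]
        assert out["p_value"] == 0.0
        assert out["statistic"] == -np.inf

    def test_matches_welch(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(0.5, 2.0, size=5)
        out = rs.compare_groups(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert out["statistic"] == pytest.approx(ref.statistic)
        assert out["p_value"] == pytest.approx(ref.pvalue)

    def test_too_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            rs.compare_groups([1.0], [1.0, 2.0])

    def test_bh_adjustment_present_when_requested(self):
        table = pd.DataFrame({
            "brain_id": list("abcdefgh"),
            "condition": ["x"] * 4 + ["y"] * 4,
            "acronym": ["R1", "R2"] * 4,
            "ratio": np.arange(8) / 10.0})
        out = rs.compare_regions(table, "x", "y", adjust=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


def test_ratio_stable_under_subsampling(small_assigned, small_atlas):
    """Composition ratios are invariant to uniform subsampling in expectation."""
    h = small_atlas.hierarchy
    one = small_assigned[small_assigned["brain_id"] == "ZT0-4a"]
    full = rs.ratios(rs.count_regions(one, h, MAJOR_REGIONS, ExclusionSet()))
    full = full.set_index("acronym")["ratio"]
    rng = np.random.default_rng(4)
    halves = []
    for _ in range(200):
        sub = one.sample(frac=0.5, random_state=rng.integers(2**31))
        r = rs.ratios(rs.count_regions(sub, h, MAJOR_REGIONS, ExclusionSet()))
        halves.append(r.set_index("acronym")["ratio"].reindex(full.index))
    halves = pd.concat(halves, axis=1)
    mean, sd = halves.mean(axis=1), halves.std(axis=1, ddof=1)
    # the mean over 200 half-subsamples stays within 2 sd of the full ratio
    assert np.all(np.abs(mean - full) <= 2 * sd)
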