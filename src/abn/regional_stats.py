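"""Per-brain regional composition: counts, ratios, z-scores, layer ratios,
and two-group comparisons.

Composition is always expressed relative to a *scope partition*: a set of
acronyms that are pairwise non-nested along any root path (e.g. the major
brain divisions, or the cortical areas).  Each assigned neuron is rolled up
to the unique scope member on its ancestor path; neurons matching no scope
member, landing in excluded regions, or left unassigned (region_id 0) are
dropped from all denominators.  Working with ratios rather than raw counts
absorbs the large brain-to-brain variability in the total number of
tagged neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ExclusionSet, RegionHierarchy, parse_layer
from .errors import (
    EmptyBrainError,
    InsufficientDataError,
    NoLayerError,
    ScopePartitionError,
)


@dataclass
class RegionCounts:
    """Active-neuron counts n[A] for one brain over a scope partition."""

    brain_id: str
    condition: str
    counts: dict[str, int]
    total: int
    n_unassigned: int = 0      # region_id 0 (out of volume / white matter)
    n_excluded: int = 0        # in an excluded subtree
    n_out_of_scope: int = 0    # assigned but under no scope member

    def as_vector(self, regions: Sequence[str]) -> np.ndarray:
        return np.array([self.counts.get(r, 0) for r in regions], dtype=float)


def _check_scope(scope_set: Iterable[str], h: RegionHierarchy) -> list[str]:
    scope = sorted(set(scope_set))
    for a, b in combinations(scope, 2):
        pa = h.by_acronym(a).id_path
        pb = h.by_acronym(b).id_path
        if pa[: len(pb)] == pb or pb[: len(pa)] == pa:
            raise ScopePartitionError(f"scope members {a!r} and {b!r} are nested")
    return scope


def scope_lookup(h: RegionHierarchy, scope_set: Iterable[str],
                 exclusions: ExclusionSet | None = None) -> dict[int, str | None]:
    """Map every region ID to its scope member (None = out of scope or excluded)."""
    scope = _check_scope(scope_set, h)
    excluded = exclusions.excluded_ids(h) if exclusions else set()
    table: dict[int, str | None] = {}
    for node in h.nodes():
        if node.region_id in excluded:
            table[node.region_id] = None
            continue
        hits = [a for a in h.acronym_path(node.region_id) if a in set(scope)]
        table[node.region_id] = hits[0] if hits else None
    return table


def count_regions(neurons: pd.DataFrame, h: RegionHierarchy,
                  scope_set: Iterable[str],
                  exclusions: ExclusionSet | None = None) -> RegionCounts:
    """Roll one brain's assigned neurons up to a scope partition.

    ``neurons`` must carry a ``region_id`` column and belong to a single
    brain (brain_id/condition are read off the table).
    """
    if neurons["brain_id"].nunique() > 1:
        raise ValueError("count_regions expects a single brain; use count_table")
    scope = _check_scope(scope_set, h)
    excluded = exclusions.excluded_ids(h) if exclusions else set()

    counts = {a: 0 for a in scope}
    n_unassigned = n_excluded = n_out = 0
    lut: dict[int, str | None] = {}
    for rid in neurons["region_id"].astype(int):
        if rid == 0:
            n_unassigned += 1
            continue
        if rid in excluded:
            n_excluded += 1
            continue
        if rid not in lut:
            hits = [a for a in h.acronym_path(rid) if a in set(scope)]
            lut[rid] = hits[0] if hits else None
        member = lut[rid]
        if member is None:
            n_out += 1
        else:
            counts[member] += 1
    counts = {a: c for a, c in counts.items() if c > 0}
    return RegionCounts(
        brain_id=str(neurons["brain_id"].iloc[0]) if len(neurons) else "",
        condition=str(neurons["condition"].iloc[0]) if len(neurons) else "",
        counts=counts, total=sum(counts.values()),
        n_unassigned=n_unassigned, n_excluded=n_excluded, n_out_of_scope=n_out)


def count_table(neurons: pd.DataFrame, h: RegionHierarchy,
                scope_set: Iterable[str],
                exclusions: ExclusionSet | None = None) -> list[RegionCounts]:
    """count_regions per brain, in sorted brain_id order."""
    return [count_regions(g, h, scope_set, exclusions)
            for _, g in neurons.groupby("brain_id", sort=True)]


def ratios(counts: RegionCounts) -> pd.DataFrame:
    """Composition ratios n[A]/total for one brain; rows sum to 1."""
    if counts.total == 0:
        raise EmptyBrainError(
            f"brain {counts.brain_id!r} has no neurons in scope")
    rows = [(counts.brain_id, counts.condition, a, c / counts.total)
            for a, c in sorted(counts.counts.items())]
    return pd.DataFrame(rows, columns=["brain_id", "condition", "acronym", "ratio"])


def ratio_table(all_counts: Iterable[RegionCounts]) -> pd.DataFrame:
    """Tidy ratio table over many brains (one row per brain x region)."""
    return pd.concat([ratios(c) for c in all_counts], ignore_index=True)


def zscore_across_conditions(table: pd.DataFrame,
                             per_condition_mean: bool = False) -> pd.DataFrame:
    """Z-score each region's ratios across brains.

    Default pools the per-brain ratios of all conditions: for region A,
    z = (ratio - mean_A) / sd_A with ddof=1, so each region's z values have
    mean 0 and unit sd.  ``per_condition_mean`` instead z-scores the
    condition means of each region.  Zero-variance regions get z = 0 and
    ``zero_variance`` = True.
    """
    df = table.copy()
    if per_condition_mean:
        df = (df.groupby(["condition", "acronym"], as_index=False)["ratio"]
                .mean())
    out = []
    for acr, g in df.groupby("acronym", sort=True):
        vals = g["ratio"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise InsufficientDataError(
                f"region {acr!r} has {len(vals)} ratio value(s); need >= 2")
        sd = vals.std(ddof=1)
        gg = g.copy()
        # identical ratios can leave a ~1e-17 sd from rounding; treat as zero
        if sd <= 1e-12 * max(1.0, np.abs(vals).max()):
            gg["z"] = 0.0
            gg["zero_variance"] = True
        else:
            gg["z"] = (vals - vals.mean()) / sd
            gg["zero_variance"] = False
        out.append(gg)
    return pd.concat(out, ignore_index=True)


def layer_ratios(neurons: pd.DataFrame, parent_acronym: str,
                 h: RegionHierarchy) -> pd.DataFrame:
    """Per-brain cortical layer composition under ``parent_acronym``.

    Uses the trailing layer token of each neuron's assigned acronym
    (L1, L2/3, L4, L5, L6a, L6b).  Passing the cortical root pools every
    laminar area, giving each layer's share of the total cortical
    population.
    """
    under = h.descendants(parent_acronym)
    laminar = {rid: parse_layer(h.node(rid).acronym) for rid in under}
    if not any(v for v in laminar.values()):
        raise NoLayerError(f"{parent_acronym!r} has no laminar children")
    sub = neurons[neurons["region_id"].isin(
        [rid for rid, lab in laminar.items() if lab is not None])]
    rows = []
    for brain, g in sub.groupby("brain_id", sort=True):
        labels = g["region_id"].map(laminar)
        total = len(labels)
        cond = str(g["condition"].iloc[0])
        for layer, n in labels.value_counts().sort_index().items():
            rows.append((str(brain), cond, layer, n / total))
    return pd.DataFrame(rows, columns=["brain_id", "condition", "layer", "ratio"])


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> dict:
    """Two-sided Welch's t-test between two groups of per-brain values.

    Returns ``{"statistic", "p_value", "degenerate"}``; groups whose
    pooled variance is zero are flagged (p reported as the 0 or 1 limit).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group, got {len(a)} and {len(b)}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"statistic": 0.0, "p_value": 1.0, "degenerate": True}
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return {"statistic": sign * np.inf, "p_value": 0.0, "degenerate": True}
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "degenerate": False}


def compare_regions(table: pd.DataFrame, condition_a: str, condition_b: str,
                    adjust: bool = False) -> pd.DataFrame:
    """Welch test per region between two conditions of a ratio table.

    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values for
    multi-region screens (raw p-values are always reported).
    """
    rows = []
    for acr, g in table.groupby("acronym", sort=True):
        va = g.loc[g["condition"] == condition_a, "ratio"].to_numpy()
        vb = g.loc[g["condition"] == condition_b, "ratio"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue
        r = compare_groups(va, vb)
        rows.append((acr, r["statistic"], r["p_value"], r["degenerate"]))
    out = pd.DataFrame(rows, columns=["acronym", "statistic", "p_value",
                                      "degenerate"])
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
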