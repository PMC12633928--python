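"""Network analysis of active-connectivity matrices.

Modularity uses the directed Newman-Leicht generalization with a
resolution parameter gamma:

    Q = (1/m) * sum_ij [ W_ij - gamma * s_i^out * s_j^in / m ] * [c_i == c_j]

with out/in strengths s and total weight m.  gamma tunes the preferred
module size (gamma > 1 favors smaller modules).  Module detection is a
seeded multi-restart Louvain optimization of this objective.

Betweenness centrality treats W as a directed graph with edge length
1/W (strong connections are short), counts the fraction of all-pairs
shortest paths passing through each node, and is reported both raw and
normalized by (R-1)(R-2).  All quantities here are invariant to a global
rescaling of W: an overall increase in connection strength does not, by
construction, change partitions, centralities, or rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .active_connectivity import ActiveConnectivity
from .errors import DegenerateNetworkError, ValidationError

#: Entries below this fraction of max(W) are treated as absent edges,
#: avoiding pathological near-infinite path lengths.
EDGE_FLOOR = 1e-12


@dataclass
class Partition:
    """A community assignment of network regions at a given resolution."""

    assignment: dict[str, int]
    gamma: float
    q: float = float("nan")

    def labels(self, regions: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[r] for r in regions])


def _as_matrix(W) -> np.ndarray:
    M = np.asarray(W.W if isinstance(W, ActiveConnectivity) else W, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"W must be square, got shape {M.shape}")
    if not np.isfinite(M).all() or (M < 0).any():
        raise ValidationError("W must be finite and non-negative")
    return M


def _regions_of(W, regions: Sequence[str] | None) -> list[str]:
    if isinstance(W, ActiveConnectivity):
        return list(W.regions)
    if regions is None:
        return [str(i) for i in range(np.asarray(W).shape[0])]
    return [str(r) for r in regions]


def modularity(W, partition: Partition | Mapping[str, int] | Sequence[int],
               gamma: float = 1.0,
               regions: Sequence[str] | None = None) -> float:
    """Directed modularity Q of a partition at resolution gamma."""
    M = _as_matrix(W)
    regs = _regions_of(W, regions)
    if isinstance(partition, Partition):
        labels = partition.labels(regs)
    elif isinstance(partition, Mapping):
        labels = np.array([partition[r] for r in regs])
    else:
        labels = np.asarray(list(partition))
    m = M.sum()
    if m <= 0:
        raise DegenerateNetworkError("total network weight is zero")
    s_out = M.sum(axis=1)
    s_in = M.sum(axis=0)
    same = labels[:, None] == labels[None, :]
    q = (M[same].sum() - gamma * (np.outer(s_out, s_in)[same].sum()) / m) / m
    return float(q)


def _thresholded(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    mx = out.max()
    if mx > 0:
        out[out < EDGE_FLOOR * mx] = 0.0
    return out


def _digraph(M: np.ndarray, regs: Sequence[str],
             length_transform: str = "inverse") -> nx.DiGraph:
    M = _thresholded(M)
    G = nx.DiGraph()
    G.add_nodes_from(regs)
    mx = M.max()
    for i, a in enumerate(regs):
        for j, b in enumerate(regs):
            if i != j and M[i, j] > 0:
                w = M[i, j]
                if length_transform == "inverse":
                    length = 1.0 / w
                elif length_transform == "neglog":
                    # log(max/w) >= 0; scale-invariant like 1/w up to monotonicity
                    length = float(np.log(mx / w)) + 1e-12
                else:
                    raise ValidationError(
                        f"unknown length transform {length_transform!r}")
                G.add_edge(a, b, weight=w, length=length)
    return G


def _canonical(assignment: dict[str, int], regs: Sequence[str]) -> tuple:
    relabel: dict[int, int] = {}
    out = []
    for r in regs:
        c = assignment[r]
        if c not in relabel:
            relabel[c] = len(relabel)
        out.append(relabel[c])
    return tuple(out)


def detect_modules(W, gamma: float = 1.0, seed: int = 0,
                   regions: Sequence[str] | None = None,
                   restarts: int = 10, symmetrize: bool = False) -> Partition:
    """Seeded multi-restart Louvain optimization of directed modularity.

    The best partition over ``restarts`` seeded runs is kept (by Q, ties
    by the lexicographically smallest canonical labeling), and is
    guaranteed to score at least as high as both the singleton and the
    one-community partition.
    """
    M = _thresholded(_as_matrix(W))
    if symmetrize:
        M = (M + M.T) / 2.0
    regs = _regions_of(W, regions)
    if M.sum() <= 0:
        raise DegenerateNetworkError("total network weight is zero")
    G = nx.DiGraph()
    G.add_nodes_from(regs)
    for i, a in enumerate(regs):
        for j, b in enumerate(regs):
            if i != j and M[i, j] > 0:
                G.add_edge(a, b, weight=float(M[i, j]))

    candidates: list[dict[str, int]] = [
        {r: 0 for r in regs},                 # one community
        {r: i for i, r in enumerate(regs)},   # singletons
    ]
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma,
            seed=int(rng.integers(0, 2**31 - 1)))
        candidates.append({r: ci for ci, comm in enumerate(comms) for r in comm})
    scored = [(modularity(M, a, gamma=gamma, regions=regs), a)
              for a in candidates]
    best_q = max(q for q, _ in scored)
    best = min((a for q, a in scored if q >= best_q - 1e-12),
               key=lambda a: _canonical(a, regs))
    return Partition(assignment={r: best[r] for r in regs}, gamma=float(gamma),
                     q=best_q)


def sweep_modularity(W, gammas: Iterable[float] = None, seed: int = 0,
                     regions: Sequence[str] | None = None,
                     restarts: int = 10) -> pd.DataFrame:
    """Optimized modularity across a gamma grid (default 21 points on [0.5, 2])."""
    if gammas is None:
        gammas = np.linspace(0.5, 2.0, 21)
    rows = []
    for g in gammas:
        p = detect_modules(W, gamma=float(g), seed=seed, regions=regions,
                           restarts=restarts)
        rows.append((float(g), p.q, len(set(p.assignment.values()))))
    return pd.DataFrame(rows, columns=["gamma", "q", "n_modules"])


def betweenness(W, regions: Sequence[str] | None = None,
                length_transform: str = "inverse",
                brain_id: str = "", condition: str = "") -> pd.DataFrame:
    """Weighted-directed node betweenness with fractional credit for ties.

    Edge length is 1/W (or log(max/W) with ``length_transform='neglog'``).
    Returns one row per region: raw pair counts, the (R-1)(R-2)-normalized
    value, and dense descending ranks (ties broken alphabetically).
    Networks with fewer than 3 nodes have no intermediaries: all zeros.
    """
    M = _as_matrix(W)
    regs = _regions_of(W, regions)
    R = len(regs)
    if R < 3:
        raw = {r: 0.0 for r in regs}
    else:
        G = _digraph(M, regs, length_transform)
        raw = nx.betweenness_centrality(G, weight="length", normalized=False)
    norm = 1.0 / ((R - 1) * (R - 2)) if R >= 3 else 0.0
    df = pd.DataFrame({
        "region": regs,
        "betweenness": [raw[r] for r in regs],
        "betweenness_norm": [raw[r] * norm for r in regs],
    })
    df["brain_id"] = brain_id
    df["condition"] = condition
    order = df.sort_values(["betweenness", "region"],
                           ascending=[False, True], kind="mergesort")
    df.loc[order.index, "rank"] = np.arange(1, R + 1)
    df["rank"] = df["rank"].astype(int)
    return df


def centrality_table(acs: Sequence[ActiveConnectivity],
                     length_transform: str = "inverse") -> pd.DataFrame:
    """Betweenness per brain, stacked into one tidy table."""
    return pd.concat(
        [betweenness(a, length_transform=length_transform,
                     brain_id=a.brain_id, condition=a.condition) for a in acs],
        ignore_index=True)


def rank_hubs(ct: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k regions by mean betweenness across brains (per condition pool).

    Ties in mean centrality are broken alphabetically by acronym.
    """
    means = (ct.groupby("region")["betweenness"].mean()
               .rename("mean_betweenness").reset_index())
    if k > len(means):
        raise ValidationError(f"k={k} exceeds {len(means)} regions")
    means = means.sort_values(["mean_betweenness", "region"],
                              ascending=[False, True], kind="mergesort")
    means["rank"] = np.arange(1, len(means) + 1)
    return means.head(k).reset_index(drop=True)


def set_centrality(ct: pd.DataFrame, region_set: Iterable[str]) -> pd.DataFrame:
    """Mean betweenness of a region set (e.g. the DMN), per brain then
    summarized per condition (mean +/- sd over brains).

    Members absent from the network are reported in the ``missing``
    attribute of the returned frame.
    """
    wanted = sorted(set(region_set))
    present = sorted(set(wanted) & set(ct["region"]))
    missing = sorted(set(wanted) - set(present))
    if not present:
        raise ValidationError(f"no member of {wanted} is in the network")
    sub = ct[ct["region"].isin(present)]
    per_brain = (sub.groupby(["condition", "brain_id"])["betweenness"]
                    .mean().rename("set_mean").reset_index())
    out = (per_brain.groupby("condition")["set_mean"]
                    .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_brains="count")
                    .reset_index())
    out.attrs["missing"] = missing
    out.attrs["members"] = present
    return out
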