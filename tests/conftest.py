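"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: region
roll-up by linear path scan, 1-NN by exhaustive distance scan, modularity
by a naive double loop, betweenness by Floyd-Warshall plus shortest-path
counting, and active connectivity by a triple loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abn.atlas import RegionHierarchy, RegionNode
from abn.synthetic import GeneratorConfig, make_atlas, make_brains, make_reference


# ---------------------------------------------------------------------------
# A small hand-built structure tree (20 nodes)

def tree_records() -> list[dict]:
    """Structure-graph records: root -> majors -> areas -> layer leaves."""
    rows = [
        (997, "root", None),
        (315, "Isocortex", 997),
        (385, "VISp", 315),
        (593, "VISp1", 385),
        (821, "VISp2/3", 385),
        (721, "VISp4", 385),
        (778, "VISp5", 385),
        (33, "VISp6a", 385),
        (305, "VISp6b", 385),
        (894, "RSPagl", 315),
        (671, "RSPagl2/3", 894),
        (28, "RSPagl5", 894),
        (549, "TH", 997),
        (262, "RT", 549),
        (170, "LGd", 549),
        (1097, "HY", 997),
        (946, "PH", 1097),
        (698, "OLF", 997),
        (507, "MOB", 698),
        (512, "CB", 997),
    ]
    parents = {rid: pid for rid, _, pid in rows}

    def path(rid):
        chain = []
        while rid is not None:
            chain.append(rid)
            rid = parents[rid]
        return "/" + "/".join(str(i) for i in reversed(chain)) + "/"

    return [{"id": rid, "acronym": acr, "name": acr,
             "parent_structure_id": pid, "structure_id_path": path(rid)}
            for rid, acr, pid in rows]


def build_hierarchy(records: list[dict]) -> RegionHierarchy:
    parents = {r["id"]: r["parent_structure_id"] for r in records}

    def path(rid):
        chain = []
        while rid is not None:
            chain.append(rid)
            rid = parents[rid]
        return tuple(reversed(chain))

    return RegionHierarchy(
        RegionNode(r["id"], r["acronym"], r["name"],
                   r["parent_structure_id"], path(r["id"]))
        for r in records)


@pytest.fixture(scope="session")
def tiny_tree() -> RegionHierarchy:
    return build_hierarchy(tree_records())


@pytest.fixture(scope="session")
def tiny_tree_file(tmp_path_factory):
    import json
    p = tmp_path_factory.mktemp("tree") / "tree.json"
    p.write_text(json.dumps(tree_records()))
    return p


# ---------------------------------------------------------------------------
# Scaled-down synthetic study shared across test modules

@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=7, brains_per_condition=2,
                           n_neurons_per_brain=600, n_reference_cells=10000)


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    return make_atlas(small_cfg)


@pytest.fixture(scope="session")
def small_brains(small_cfg, small_atlas) -> pd.DataFrame:
    return make_brains(small_cfg, small_atlas)


@pytest.fixture(scope="session")
def small_reference(small_cfg, small_atlas) -> pd.DataFrame:
    return make_reference(small_cfg, small_atlas)


@pytest.fixture(scope="session")
def small_assigned(small_brains, small_atlas) -> pd.DataFrame:
    from abn.atlas import assign_regions
    return assign_regions(small_brains, small_atlas.volume)


# ---------------------------------------------------------------------------
# Oracles

def scope_member_oracle(h: RegionHierarchy, region_id: int,
                        scope: set[str]) -> str | None:
    """Linear scan of the ancestor path for the unique scope member."""
    hits = [a for a in h.acronym_path(region_id) if a in scope]
    assert len(hits) <= 1
    return hits[0] if hits else None


def counts_oracle(neurons: pd.DataFrame, h: RegionHierarchy, scope: set[str],
                  excluded: set[str]) -> dict[str, int]:
    """Per-neuron linear scan roll-up (no vectorization, no caching)."""
    out: dict[str, int] = {}
    for rid in neurons["region_id"].astype(int):
        if rid == 0:
            continue
        path = h.acronym_path(rid)
        if any(a in excluded for a in path):
            continue
        hits = [a for a in path if a in scope]
        if hits:
            out[hits[0]] = out.get(hits[0], 0) + 1
    return out


def nn_oracle(neurons_xyz: np.ndarray, neuron_regions: np.ndarray,
              ref: pd.DataFrame) -> list[tuple[str | None, float]]:
    """Exhaustive same-region 1-NN scan; ties -> smallest cell_id."""
    out = []
    ref_xyz = ref[["x_um", "y_um", "z_um"]].to_numpy(float)
    for x, rid in zip(neurons_xyz, neuron_regions):
        mask = (ref["region_id"].to_numpy() == rid) & ref["is_neuron"].to_numpy()
        if not mask.any():
            out.append((None, np.nan))
            continue
        d = np.linalg.norm(ref_xyz[mask] - x, axis=1)
        ids = ref.loc[mask, "cell_id"].to_numpy()
        dmin = d.min()
        tied = sorted(ids[d <= dmin + 1e-9 * max(1.0, dmin)])
        out.append((tied[0], dmin))
    return out


def modularity_oracle(W: np.ndarray, labels, gamma: float) -> float:
    """Naive double-loop evaluation of the directed modularity sum."""
    W = np.asarray(W, float)
    labels = list(labels)
    m = W.sum()
    s_out = W.sum(axis=1)
    s_in = W.sum(axis=0)
    q = 0.0
    for i in range(len(W)):
        for j in range(len(W)):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * s_out[i] * s_in[j] / m
    return q / m


def betweenness_oracle(W: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Raw betweenness by Floyd-Warshall + shortest-path counting.

    Edge length 1/W; equal-length paths share credit fractionally.
    """
    W = np.asarray(W, float)
    n = len(W)
    L = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j]
    D = L.copy()
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]

    def close(a, b):
        return abs(a - b) <= eps * max(1.0, abs(a), abs(b))

    # sigma[s, t]: number of shortest s->t paths, by increasing distance
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(D[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(D[s, t]):
                continue
            total = 0.0
            for u in range(n):
                if u != t and np.isfinite(D[s, u]) and np.isfinite(L[u, t]) \
                        and close(D[s, u] + L[u, t], D[s, t]):
                    total += sigma[s, u]
            sigma[s, t] = total
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if np.isfinite(D[s, v]) and np.isfinite(D[v, t]) \
                        and close(D[s, v] + D[v, t], D[s, t]):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def active_connectivity_oracle(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Triple-loop W[A,B] = rho[A,B] * n[A] * n[B], zero diagonal."""
    R = len(n)
    W = np.zeros((R, R))
    for a in range(R):
        for b in range(R):
            if a != b:
                W[a, b] = rho[a, b] * n[a] * n[b]
    return W
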