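"""Molecular identity by region-constrained nearest-neighbor matching.

Each activity-tagged neuron is matched to its "twin": the closest neuronal
cell of a spatial transcriptomic reference *within the same atlas region*.
Restricting candidates to the neuron's own region removes spurious
matches across region boundaries, where spatially adjacent cells can be
molecularly unrelated.  The twin's labels (neurotransmitter class, E/I
identity) are inherited by the neuron.  Because the reference covers a
single hemisphere, neurons from the other hemisphere are first reflected
across the midline, assuming left/right symmetry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import RegionHierarchy
from .errors import ValidationError
from .regional_stats import scope_lookup

REFERENCE_COLUMNS = ["cell_id", "x_um", "y_um", "z_um", "region_id",
                     "is_neuron", "neurotransmitter"]

_COORDS = ["x_um", "y_um", "z_um"]


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a spatial transcriptomic reference table CSV."""
    df = pd.read_csv(path, dtype={"cell_id": str, "neurotransmitter": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: reference table lacks columns {missing}")
    df["is_neuron"] = df["is_neuron"].astype(bool)
    return df


def mirror_to_reference_hemisphere(neurons: pd.DataFrame, midline_um: float,
                                   axis: int = 0,
                                   reference_side: str = "low") -> pd.DataFrame:
    """Reflect neurons on the non-reference side across the midline plane.

    ``reference_side='low'`` means the reference occupies coordinates below
    ``midline_um`` along ``axis``.  Adds a boolean ``mirrored`` column;
    points exactly on the midline are untouched.  Applying the operation
    twice restores the original coordinates (reflection is an involution
    on the mirrored subset).
    """
    col = _COORDS[axis]
    out = neurons.copy()
    x = out[col].to_numpy(dtype=float)
    flip = x > midline_um if reference_side == "low" else x < midline_um
    out[col] = np.where(flip, 2.0 * midline_um - x, x)
    out["mirrored"] = flip
    return out


def _match_one_region(nx: np.ndarray, ref_xyz: np.ndarray,
                      ref_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-NN with ties broken by smallest cell_id.

    Reference rows are pre-sorted by cell_id; ties (distance equal within
    1e-9 relative) are resolved by a ball query over the tied radius.
    """
    tree = cKDTree(ref_xyz)
    k = min(2, len(ref_xyz))
    dist, idx = tree.query(nx, k=k)
    if k == 1:
        return dist.ravel(), ref_ids[idx.ravel()]
    d1, d2 = dist[:, 0], dist[:, 1]
    best = idx[:, 0].copy()
    tied = d2 - d1 <= 1e-9 * np.maximum(1.0, d1)
    for i in np.flatnonzero(tied):
        r = d1[i] * (1 + 1e-9) + 1e-12
        cand = tree.query_ball_point(nx[i], r)
        cand = [j for j in cand if
                np.linalg.norm(ref_xyz[j] - nx[i]) <= d1[i] + 1e-9 * max(1.0, d1[i])]
        best[i] = min(cand)  # rows sorted by cell_id -> smallest id wins
    return d1, ref_ids[best]


def match(neurons: pd.DataFrame, reference: pd.DataFrame,
          h: RegionHierarchy | None = None) -> pd.DataFrame:
    """Region-constrained exact 1-NN matching of neurons to reference cells.

    Non-neuronal reference cells are excluded up front.  Neurons in regions
    absent from the (neuronal) reference are returned unmatched with a
    reason code rather than dropped.  Deterministic: distance ties go to
    the lexicographically smallest cell_id.
    """
    if len(reference) == 0:
        raise ValidationError("empty reference")
    ref = reference[reference["is_neuron"]].copy()
    if len(ref) == 0:
        raise ValidationError("reference contains no neuronal cells")
    ref = ref.sort_values("cell_id", kind="mergesort").reset_index(drop=True)

    out = pd.DataFrame({
        "neuron_id": neurons["neuron_id"].to_numpy(),
        "region_id": neurons["region_id"].astype(int).to_numpy(),
        "twin_cell_id": pd.array([None] * len(neurons), dtype="object"),
        "distance_um": np.full(len(neurons), np.nan),
        "neurotransmitter": pd.array([None] * len(neurons), dtype="object"),
        "matched": np.zeros(len(neurons), dtype=bool),
        "reason": pd.array([""] * len(neurons), dtype="object"),
    }, index=neurons.index)

    nt_by_id = dict(zip(ref["cell_id"], ref["neurotransmitter"]))
    ref_groups = {rid: g for rid, g in ref.groupby(ref["region_id"].astype(int))}
    coords = neurons[_COORDS].to_numpy(dtype=float)
    for rid, rows in neurons.groupby(neurons["region_id"].astype(int)).groups.items():
        if rid == 0:
            out.loc[rows, "reason"] = "unassigned"
            continue
        g = ref_groups.get(rid)
        if g is None or len(g) == 0:
            out.loc[rows, "reason"] = "region-not-in-reference"
            continue
        nx = coords[neurons.index.get_indexer(rows)]
        dist, ids = _match_one_region(nx, g[_COORDS].to_numpy(dtype=float),
                                      g["cell_id"].to_numpy())
        out.loc[rows, "twin_cell_id"] = ids
        out.loc[rows, "distance_um"] = dist
        out.loc[rows, "neurotransmitter"] = [nt_by_id[i] for i in ids]
        out.loc[rows, "matched"] = True
        out.loc[rows, "reason"] = "matched"
    return out


def distance_qc(matches: pd.DataFrame,
                thresholds_um: Iterable[float] = (40.0, 100.0)) -> dict:
    """Match-distance quality summary: quantiles and tail fractions.

    A well-immersed dataset against a dense reference should see nearly
    all matches within 100 um and the majority within 40 um.
    """
    d = matches.loc[matches["matched"], "distance_um"].to_numpy(dtype=float)
    if len(d) == 0:
        raise ValidationError("no matched neurons to QC")
    qc = {
        "n_matched": int(len(d)),
        "q50_um": float(np.quantile(d, 0.50)),
        "q90_um": float(np.quantile(d, 0.90)),
        "q99_um": float(np.quantile(d, 0.99)),
    }
    for t in thresholds_um:
        qc[f"n_above_{t:g}um"] = int((d > t).sum())
        qc[f"frac_above_{t:g}um"] = float((d > t).mean())
    return qc


def composition(matches: pd.DataFrame, neurons: pd.DataFrame,
                scope_set: Iterable[str],
                h: RegionHierarchy) -> pd.DataFrame:
    """Per-brain, per-scope-region neurotransmitter composition.

    Fractions are over *matched* neurons of the region; the unmatched
    count is reported per row group.  One row per
    (brain, region, neurotransmitter).
    """
    lut = scope_lookup(h, scope_set)
    df = matches
    if "brain_id" not in df.columns:
        df = df.merge(neurons[["neuron_id", "brain_id"]], on="neuron_id",
                      how="left")
    df["scope_region"] = [lut.get(r) if r != 0 else None
                          for r in df["region_id"].astype(int)]
    df = df[df["scope_region"].notna()]
    rows = []
    for (brain, region), g in df.groupby(["brain_id", "scope_region"], sort=True):
        m = g[g["matched"]]
        n_un = int((~g["matched"]).sum())
        total = len(m)
        if total == 0:
            continue
        for nt, n in m["neurotransmitter"].value_counts().sort_index().items():
            rows.append((brain, region, nt, int(n), n / total, n_un))
    return pd.DataFrame(rows, columns=["brain_id", "acronym", "neurotransmitter",
                                       "n", "fraction", "n_unmatched"])


def ei_ratio(comp: pd.DataFrame) -> pd.DataFrame:
    """Excitatory/inhibitory ratio per (brain, region).

    E/I = glutamatergic fraction / GABAergic fraction; rows with no
    GABAergic matches are flagged ``undefined`` instead of dividing by 0.
    """
    rows = []
    for (brain, region), g in comp.groupby(["brain_id", "acronym"], sort=True):
        fr = dict(zip(g["neurotransmitter"], g["fraction"]))
        e = fr.get("glutamatergic", 0.0)
        i = fr.get("GABAergic", 0.0)
        if i == 0.0:
            rows.append((brain, region, np.nan, True))
        else:
            rows.append((brain, region, e / i, False))
    return pd.DataFrame(rows, columns=["brain_id", "acronym", "ei_ratio",
                                       "undefined"])
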