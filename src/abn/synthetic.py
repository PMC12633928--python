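"""Synthetic inputs with controllable ground truth.

Generates the four inputs every other module consumes — a fixture atlas
(structure tree + annotation volume of rectangular parcels), per-brain
neuron tables with planted condition/layer effects, a spatial
transcriptomic reference with planted per-region cell-type proportions,
and a block-structured connection-density matrix with planted modules
and an optional bridge hub — so each analysis stage can be tested
against the parameters that produced its input.

Geometry: the atlas occupies a box whose left half (low x) mirrors onto
the right half, emulating a bilaterally symmetric brain whose reference
dataset covers a single hemisphere.  Each leaf region is a rectangular
parcel on a lattice in the left hemisphere, mirrored to the right.

Determinism: one integer seed drives everything through fixed-purpose
substreams (``[seed, k]`` seed sequences per artifact), so identical
configs give byte-identical outputs and adding a generator does not
shift existing ones.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .active_connectivity import DensityMatrix
from .atlas import LAYERS, AnnotationVolume, RegionHierarchy, RegionNode
from .errors import ValidationError

CONDITIONS = ("ZT0-4", "ZT8-12", "ZT12-16", "ZT20-24")

_LAYER_TOKENS = {"L1": "1", "L2/3": "2/3", "L4": "4", "L5": "5",
                 "L6a": "6a", "L6b": "6b"}

#: Cortical areas and their share of the cortical population.
DEFAULT_CORTICAL_AREAS: dict[str, float] = {
    "VISp": 0.22, "VISa": 0.10, "RSPagl": 0.14, "ACA": 0.12,
    "PL": 0.10, "TEa": 0.10, "PTLp": 0.12, "FRP": 0.10,
}

#: Subcortical leaves per major division, with population weights.
DEFAULT_SUBCORTICAL: dict[str, dict[str, float]] = {
    "HPF": {"CA": 0.10, "DG": 0.06},
    "CTXsp": {"CLA": 0.04, "EP": 0.03},
    "STR": {"CP": 0.12, "ACB": 0.08},
    "PAL": {"GPe": 0.04, "GPi": 0.03},
    "TH": {"RT": 0.08, "LGd": 0.07},
    "HY": {"PH": 0.09, "LHA": 0.07},
    "MB": {"SCm": 0.09, "VTA": 0.04},
    "P": {"PRNc": 0.03, "PB": 0.03},
}

#: Leaves under the routinely damaged (excluded) divisions.
DEFAULT_EXCLUDED_LEAVES: dict[str, list[str]] = {
    "OLF": ["MOB"], "CB": ["CBX"], "MY": ["MV"],
}

#: Fraction of each brain's neurons landing in excluded divisions.
EXCLUDED_MASS = 0.03

#: Cortical share of the in-scope population per condition.  The planted
#: contrast (rest onset high vs. active onset low) is the effect the
#: composition statistics must recover.
DEFAULT_ISOCORTEX_SHARE = {"ZT0-4": 0.50, "ZT8-12": 0.40,
                           "ZT12-16": 0.30, "ZT20-24": 0.45}

_BASE_LAYER_PROBS = {"L1": 0.08, "L2/3": 0.27, "L4": 0.14,
                     "L5": 0.25, "L6a": 0.18, "L6b": 0.08}
_L5_ENRICHED = {"L1": 0.06, "L2/3": 0.21, "L4": 0.11,
                "L5": 0.40, "L6a": 0.15, "L6b": 0.07}

#: Laminar depth profile per condition; the dark-period end is L5-enriched.
DEFAULT_LAYER_PROBS = {
    "ZT0-4": dict(_BASE_LAYER_PROBS), "ZT8-12": dict(_BASE_LAYER_PROBS),
    "ZT12-16": dict(_BASE_LAYER_PROBS), "ZT20-24": dict(_L5_ENRICHED),
}

_CORTICAL_TYPES = {"glutamatergic": 0.85, "GABAergic": 0.15}

#: Planted neurotransmitter mix per leaf region.  RT is almost purely
#: GABAergic and VTA dopaminergic-rich, mirroring the two anatomically
#: distinct validation regions.
DEFAULT_TYPE_PROBS: dict[str, dict[str, float]] = {
    "CA": {"glutamatergic": 0.90, "GABAergic": 0.10},
    "DG": {"glutamatergic": 0.88, "GABAergic": 0.12},
    "CLA": {"glutamatergic": 0.90, "GABAergic": 0.10},
    "EP": {"glutamatergic": 0.85, "GABAergic": 0.15},
    "CP": {"GABAergic": 0.95, "other": 0.05},
    "ACB": {"GABAergic": 0.93, "dopaminergic": 0.02, "other": 0.05},
    "GPe": {"GABAergic": 0.95, "glutamatergic": 0.05},
    "GPi": {"GABAergic": 0.95, "glutamatergic": 0.05},
    "RT": {"GABAergic": 0.98, "glutamatergic": 0.02},
    "LGd": {"glutamatergic": 0.90, "GABAergic": 0.10},
    "PH": {"glutamatergic": 0.80, "GABAergic": 0.20},
    "LHA": {"glutamatergic": 0.60, "GABAergic": 0.40},
    "SCm": {"glutamatergic": 0.70, "GABAergic": 0.30},
    "VTA": {"dopaminergic": 0.65, "GABAergic": 0.30, "glutamatergic": 0.05},
    "PRNc": {"glutamatergic": 0.70, "GABAergic": 0.30},
    "PB": {"glutamatergic": 0.85, "GABAergic": 0.15},
    "MOB": {"glutamatergic": 0.70, "GABAergic": 0.30},
    "CBX": {"glutamatergic": 0.60, "GABAergic": 0.40},
    "MV": {"glutamatergic": 0.70, "GABAergic": 0.30},
}


def _layer_type_probs(layer: str) -> dict[str, float]:
    if layer == "L1":  # layer 1 is dominated by inhibitory interneurons
        return {"GABAergic": 0.90, "glutamatergic": 0.10}
    return dict(_CORTICAL_TYPES)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study's default values."""

    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    brains_per_condition: int = 3
    n_neurons_per_brain: int = 5000
    cortical_areas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORTICAL_AREAS))
    subcortical: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBCORTICAL.items()})
    excluded_leaves: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EXCLUDED_LEAVES.items()})
    isocortex_share: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOCORTEX_SHARE))
    region_probs: dict[str, dict[str, float]] | None = None  # overrides shares
    layer_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAYER_PROBS.items()})
    type_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    mirrored_fraction: float = 0.5
    # reference
    n_reference_cells: int = 60000
    non_neuronal_fraction: float = 0.15
    segregation: float | dict[str, float] | None = None  # None = per-region default
    # geometry
    voxel_size_um: float = 50.0
    parcel_voxels: tuple[int, int, int] = (4, 4, 4)
    # density matrix
    n_blocks: int = 4
    within_density: float = 0.5
    between_density: float = 0.05
    density_noise: float = 0.2
    bridge_region: str | None = None
    bridge_density: float = 0.8

    # -- derived ----------------------------------------------------------
    @property
    def network_regions(self) -> list[str]:
        """Scope regions entering networks: cortical areas + subcortical leaves."""
        out = list(self.cortical_areas)
        for leaves in self.subcortical.values():
            out.extend(leaves)
        return out

    @property
    def n_regions(self) -> int:
        return len(self.network_regions)

    def leaf_regions(self) -> list[str]:
        """All annotated leaves, including excluded divisions."""
        out = []
        for area in self.cortical_areas:
            out.extend(area + _LAYER_TOKENS[lay] for lay in LAYERS)
        for leaves in self.subcortical.values():
            out.extend(leaves)
        for leaves in self.excluded_leaves.values():
            out.extend(leaves)
        return out

    def leaf_type_probs(self, leaf: str, layer: str | None = None) -> dict[str, float]:
        if leaf in self.type_probs:
            probs = self.type_probs[leaf]
        elif layer is not None:
            probs = _layer_type_probs(layer)
        else:
            probs = DEFAULT_TYPE_PROBS.get(leaf, dict(_CORTICAL_TYPES))
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"type probabilities of {leaf!r} sum to {total}")
        return dict(probs)

    def leaf_segregation(self, leaf: str, is_cortical: bool) -> float:
        if isinstance(self.segregation, dict):
            return float(self.segregation.get(leaf, 1.0))
        if self.segregation is not None:
            return float(self.segregation)
        # realistic default: subcortical nuclei spatially segregated,
        # cortical sheets substantially intermixed
        return 0.3 if is_cortical else 1.0

    def condition_region_probs(self, condition: str) -> dict[str, float]:
        """Probability of each scope region (incl. excluded divisions)."""
        if self.region_probs is not None:
            probs = dict(self.region_probs[condition])
        else:
            iso = self.isocortex_share[condition]
            aw = _normalized(self.cortical_areas)
            sub: dict[str, float] = {}
            for leaves in self.subcortical.values():
                sub.update(leaves)
            sw = _normalized(sub)
            n_excl = sum(len(v) for v in self.excluded_leaves.values())
            excl_mass = EXCLUDED_MASS if n_excl else 0.0
            probs = {a: iso * w for a, w in aw.items()}
            probs.update({s: (1 - iso - excl_mass) * w for s, w in sw.items()})
            for leaves in self.excluded_leaves.values():
                for leaf in leaves:
                    probs[leaf] = excl_mass / n_excl
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"region probabilities of {condition!r} sum to {total}")
        return probs


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    if total <= 0:
        return {}
    return {k: v / total for k, v in weights.items()}


# ---------------------------------------------------------------------------
# Atlas


@dataclass
class SyntheticAtlas:
    hierarchy: RegionHierarchy
    volume: AnnotationVolume
    parcels: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]
    midline_um: float
    voxel_size_um: float

    def parcel_bounds_um(self, leaf: str) -> tuple[np.ndarray, np.ndarray]:
        off, size = self.parcels[leaf]
        lo = np.asarray(off, dtype=float) * self.voxel_size_um
        hi = lo + np.asarray(size, dtype=float) * self.voxel_size_um
        return lo, hi


def make_atlas(cfg: GeneratorConfig) -> SyntheticAtlas:
    """Build the fixture hierarchy and a mirrored parcel annotation volume."""
    leaves = cfg.leaf_regions()
    if len(leaves) < 2:
        raise ValidationError("need at least 2 leaf regions")

    # hierarchy -----------------------------------------------------------
    nodes: list[RegionNode] = []
    next_id = [1]

    def add(acronym: str, name: str, parent: RegionNode | None) -> RegionNode:
        rid = next_id[0]
        next_id[0] += 1
        path = (parent.id_path if parent else ()) + (rid,)
        node = RegionNode(rid, acronym, name, parent.region_id if parent else None,
                          path)
        nodes.append(node)
        return node

    root = add("root", "root", None)
    if cfg.cortical_areas:
        iso = add("Isocortex", "Isocortex", root)
        for area in cfg.cortical_areas:
            anode = add(area, f"{area} area", iso)
            for lay in LAYERS:
                add(area + _LAYER_TOKENS[lay], f"{area} layer {lay[1:]}", anode)
    for major, leaves_of in list(cfg.subcortical.items()) + \
            [(m, {k: 0.0 for k in v}) for m, v in cfg.excluded_leaves.items()]:
        if not leaves_of:
            continue
        mnode = add(major, f"{major} division", root)
        for leaf in leaves_of:
            add(leaf, f"{leaf} nucleus", mnode)
    hierarchy = RegionHierarchy(nodes)
    by_acr = {n.acronym: n for n in nodes}

    # volume --------------------------------------------------------------
    px, py, pz = cfg.parcel_voxels
    pitch = (px + 1, py + 1, pz + 1)
    n_leaves = len(leaves)
    gy = gz = int(np.ceil(np.sqrt(n_leaves / 3)))
    gx = int(np.ceil(n_leaves / (gy * gz)))
    half_x = gx * pitch[0] + 1
    ny = gy * pitch[1] + 1
    nz = gz * pitch[2] + 1
    values = np.zeros((2 * half_x, ny, nz), dtype=np.int32)

    parcels: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {}
    for k, leaf in enumerate(leaves):
        cx, rem = divmod(k, gy * gz)
        cy, cz = divmod(rem, gz)
        off = (1 + cx * pitch[0], 1 + cy * pitch[1], 1 + cz * pitch[2])
        sl = (slice(off[0], off[0] + px), slice(off[1], off[1] + py),
              slice(off[2], off[2] + pz))
        if (values[sl] != 0).any():
            raise ValidationError(f"parcel for {leaf!r} overlaps a previous one")
        values[sl] = by_acr[leaf].region_id
        parcels[leaf] = (off, (px, py, pz))
    # mirror the left hemisphere onto the right
    values[half_x:, :, :] = values[half_x - 1:: -1, :, :]

    vol = AnnotationVolume(values=values,
                           voxel_size_um=(cfg.voxel_size_um,) * 3)
    vol.validate_against(hierarchy)
    return SyntheticAtlas(hierarchy=hierarchy, volume=vol, parcels=parcels,
                          midline_um=half_x * cfg.voxel_size_um,
                          voxel_size_um=cfg.voxel_size_um)


# ---------------------------------------------------------------------------
# Cell placement shared by brains and reference


def _sample_positions(rng: np.random.Generator, atlas: SyntheticAtlas,
                      leaf: str, types: np.ndarray,
                      type_probs: dict[str, float],
                      segregation: float) -> np.ndarray:
    """Place cells in the leaf's (left-hemisphere) parcel.

    With probability ``segregation`` a cell sits in a tight Gaussian
    cluster specific to its type (clusters spaced along y, spread well
    under their separation); otherwise uniformly in the parcel, fully
    interleaved with other types.
    """
    lo, hi = atlas.parcel_bounds_um(leaf)
    n = len(types)
    pos = rng.uniform(lo, hi, size=(n, 3))
    if segregation > 0:
        names = sorted(type_probs)
        centers_y = {t: lo[1] + (i + 0.5) / len(names) * (hi[1] - lo[1])
                     for i, t in enumerate(names)}
        sep = (hi[1] - lo[1]) / len(names)
        sd = sep / 6.0  # clusters ~6 sd apart: effectively disjoint
        clustered = rng.uniform(size=n) < segregation
        mid = (lo + hi) / 2.0
        for i in np.flatnonzero(clustered):
            c = np.array([mid[0], centers_y[types[i]], mid[2]])
            pos[i] = np.clip(rng.normal(c, sd), lo + 1e-6, hi - 1e-6)
    return pos


def _leaf_of(cfg: GeneratorConfig, scope_region: str, layer: str | None) -> str:
    if layer is not None:
        return scope_region + _LAYER_TOKENS[layer]
    return scope_region


# ---------------------------------------------------------------------------
# Brains


def make_brains(cfg: GeneratorConfig, atlas: SyntheticAtlas) -> pd.DataFrame:
    """Neuron tables for all brains, with planted ground truth alongside.

    Per neuron: scope region ~ condition's regional composition, layer ~
    condition's laminar profile (cortical regions only), neurotransmitter
    type and position via the shared placement model, and a coin flip to
    the non-reference hemisphere.  Truth columns (``true_*``,
    ``hemisphere``, ``x_um_mirrored``) are carried for parameter-recovery
    tests and are not consumed by any analysis stage.
    """
    cortical = set(cfg.cortical_areas)
    frames = []
    brain_index = 0
    for condition in cfg.conditions:
        rp = cfg.condition_region_probs(condition)
        region_names = sorted(rp)
        region_p = np.array([rp[r] for r in region_names])
        lp = cfg.layer_probs[condition]
        layer_names = sorted(lp)
        layer_p = np.array([lp[x] for x in layer_names])
        for b in range(cfg.brains_per_condition):
            rng = np.random.default_rng([cfg.seed, 1, brain_index])
            brain_id = f"{condition}{string.ascii_lowercase[b]}"
            n = cfg.n_neurons_per_brain
            regions = rng.choice(region_names, size=n, p=region_p)
            layers = np.full(n, None, dtype=object)
            is_ctx = np.isin(regions, sorted(cortical))
            layers[is_ctx] = rng.choice(layer_names, size=int(is_ctx.sum()),
                                        p=layer_p)
            leaves = np.array([_leaf_of(cfg, r, la)
                               for r, la in zip(regions, layers)])
            types = np.empty(n, dtype=object)
            pos = np.empty((n, 3))
            for leaf in sorted(set(leaves)):
                idx = np.flatnonzero(leaves == leaf)
                layer = layers[idx[0]]
                tp = cfg.leaf_type_probs(leaf, layer)
                names = sorted(tp)
                types[idx] = rng.choice(names, size=len(idx),
                                        p=np.array([tp[x] for x in names]))
                seg = cfg.leaf_segregation(leaf, regions[idx[0]] in cortical)
                pos[idx] = _sample_positions(rng, atlas, leaf, types[idx],
                                             tp, seg)
            right = rng.uniform(size=n) < cfg.mirrored_fraction
            x_left = pos[:, 0].copy()
            x = np.where(right, 2.0 * atlas.midline_um - x_left, x_left)
            frames.append(pd.DataFrame({
                "neuron_id": [f"{brain_id}-{i:05d}" for i in range(n)],
                "brain_id": brain_id, "condition": condition,
                "x_um": x, "y_um": pos[:, 1], "z_um": pos[:, 2],
                "true_scope": regions, "true_layer": layers,
                "true_leaf": leaves, "true_neurotransmitter": types,
                "hemisphere": np.where(right, "right", "left"),
                "x_um_mirrored": x_left}))
            brain_index += 1
    return pd.concat(frames, ignore_index=True)[[
        "neuron_id", "brain_id", "condition", "x_um", "y_um", "z_um",
        "true_scope", "true_layer", "true_leaf", "true_neurotransmitter",
        "hemisphere", "x_um_mirrored"]]


# ---------------------------------------------------------------------------
# Reference


def make_reference(cfg: GeneratorConfig, atlas: SyntheticAtlas) -> pd.DataFrame:
    """Spatial transcriptomic reference covering the left hemisphere.

    Cells are spread evenly over the annotated leaves; a configurable
    fraction is non-neuronal (excluded by the matcher).  Neuronal cells
    draw a neurotransmitter type from the leaf's planted proportions and
    are placed with the same segregation model as the brains, so a
    planted type is spatially recoverable exactly when the model says it
    should be.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    leaves = cfg.leaf_regions()
    per_leaf = np.full(len(leaves), cfg.n_reference_cells // len(leaves))
    per_leaf[: cfg.n_reference_cells % len(leaves)] += 1
    cortical = set(cfg.cortical_areas)
    frames = []
    counter = 0
    for leaf, n in zip(leaves, per_leaf):
        area = max((a for a in cortical if leaf.startswith(a)),
                   key=len, default=None)
        layer = ("L" + leaf[len(area):]) if area else None
        tp = cfg.leaf_type_probs(leaf, layer)
        names = sorted(tp)
        is_neuron = rng.uniform(size=n) >= cfg.non_neuronal_fraction
        types = rng.choice(names, size=n, p=np.array([tp[x] for x in names]))
        seg = cfg.leaf_segregation(leaf, area is not None)
        pos = _sample_positions(rng, atlas, leaf, types, tp, seg)
        lo, hi = atlas.parcel_bounds_um(leaf)
        pos[~is_neuron] = rng.uniform(lo, hi, size=((~is_neuron).sum(), 3))
        rid = atlas.hierarchy.by_acronym(leaf).region_id
        frames.append(pd.DataFrame({
            "cell_id": [f"ref{counter + i:07d}" for i in range(n)],
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "region_id": rid,
            "is_neuron": is_neuron,
            "neurotransmitter": np.where(is_neuron, types, "non-neuronal"),
        }))
        counter += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Density matrix


def make_density(cfg: GeneratorConfig) -> tuple[DensityMatrix, dict]:
    """Block-model connection density over the network regions.

    Within-block densities exceed between-block densities by
    ``within_density / between_density``; an optional bridge region gets
    strong links to and from every other region, planting a
    high-betweenness hub.  Returns the matrix and the planted truth
    (block assignment, bridge region).
    """
    rng = np.random.default_rng([cfg.seed, 3])
    regions = cfg.network_regions
    r = len(regions)
    blocks = {}
    for bi, chunk in enumerate(np.array_split(np.array(regions), cfg.n_blocks)):
        for a in chunk:
            blocks[str(a)] = bi
    labels = np.array([blocks[a] for a in regions])
    base = np.where(labels[:, None] == labels[None, :],
                    cfg.within_density, cfg.between_density)
    noise = rng.uniform(1.0 - cfg.density_noise, 1.0 + cfg.density_noise,
                        size=(r, r))
    rho = base * noise
    if cfg.bridge_region is not None:
        if cfg.bridge_region not in regions:
            raise ValidationError(
                f"bridge region {cfg.bridge_region!r} not a network region")
        bi = regions.index(cfg.bridge_region)
        scale = rng.uniform(1.0 - cfg.density_noise, 1.0 + cfg.density_noise,
                            size=(2, r))
        rho[bi, :] = cfg.bridge_density * scale[0]
        rho[:, bi] = cfg.bridge_density * scale[1]
    np.fill_diagonal(rho, 0.0)
    truth = {"blocks": blocks, "bridge_region": cfg.bridge_region}
    return DensityMatrix(regions=list(regions), rho=rho), truth


# ---------------------------------------------------------------------------
# Full emission


def write_all(cfg: GeneratorConfig, out_dir: str | Path) -> dict:
    """Emit every synthetic input in the file formats the pipeline consumes,
    plus a ``truth/`` directory of planted parameters.  Returns file paths."""
    out = Path(out_dir)
    (out / "neurons").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    atlas = make_atlas(cfg)
    atlas.hierarchy.save(out / "tree.json")
    atlas.volume.save(out / "annotation.nrrd")

    brains = make_brains(cfg, atlas)
    neuron_files = []
    for brain_id, g in brains.groupby("brain_id", sort=True):
        p = out / "neurons" / f"{brain_id}.csv"
        g[["neuron_id", "brain_id", "condition", "x_um", "y_um", "z_um"]].to_csv(
            p, index=False)
        neuron_files.append(str(p))
    brains.to_csv(out / "truth" / "neurons_truth.csv", index=False)

    reference = make_reference(cfg, atlas)
    reference.to_csv(out / "reference.csv", index=False)

    density, density_truth = make_density(cfg)
    density.save(out / "density.csv")

    truth = {
        "seed": cfg.seed,
        "midline_um": atlas.midline_um,
        "region_probs": {c: cfg.condition_region_probs(c)
                         for c in cfg.conditions},
        "layer_probs": cfg.layer_probs,
        "density": density_truth,
        "n_regions": cfg.n_regions,
    }
    (out / "truth" / "planted.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return {
        "tree": str(out / "tree.json"),
        "annotation": str(out / "annotation.nrrd"),
        "neurons": neuron_files,
        "reference": str(out / "reference.csv"),
        "density": str(out / "density.csv"),
        "midline_um": atlas.midline_um,
    }
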