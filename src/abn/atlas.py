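"""Atlas handling: structure tree, annotation volume, region assignment.

The structure tree follows the Allen structure-graph dialect: a JSON
array of node objects with ``id``, ``acronym``, ``name``,
``parent_structure_id`` and ``structure_id_path`` keys.  The annotation
volume is an NRRD image whose voxels carry integer region IDs (0 =
unannotated background).  Neuron coordinates live in the volume's
physical frame: micrometers, origin at the corner of voxel [0, 0, 0],
half-open voxels ``[i*s, (i+1)*s)`` so a point exactly on a boundary
belongs to the higher-index voxel.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import nrrdio
from .errors import (
    HierarchyIntegrityError,
    MissingParentError,
    RegionLookupError,
    ScopePartitionError,
    ValidationError,
)

#: Major brain divisions used for whole-brain composition summaries.
MAJOR_REGIONS = ("Isocortex", "HPF", "CTXsp", "STR", "PAL", "TH", "HY", "MB", "P")

#: Regions excluded from analysis by default (tissue routinely damaged
#: during extraction/clearing: olfactory areas, cerebellum, medulla).
DEFAULT_EXCLUSIONS = frozenset({"OLF", "CB", "MY"})

NEURON_COLUMNS = ["neuron_id", "brain_id", "condition", "x_um", "y_um", "z_um"]

_LAYER_RE = re.compile(r"(2/3|6a|6b|1|4|5)$")

#: Canonical cortical layer labels, superficial to deep.
LAYERS = ("L1", "L2/3", "L4", "L5", "L6a", "L6b")


@dataclass(frozen=True)
class RegionNode:
    region_id: int
    acronym: str
    name: str
    parent_id: int | None
    id_path: tuple[int, ...]


class RegionHierarchy:
    """The atlas structure tree: unique region IDs and acronyms, one root,
    and per-node ancestor paths (root -> self)."""

    def __init__(self, nodes: Iterable[RegionNode]):
        self._by_id: dict[int, RegionNode] = {}
        self._by_acronym: dict[str, RegionNode] = {}
        for node in nodes:
            if node.region_id in self._by_id:
                raise HierarchyIntegrityError(
                    f"duplicate region_id {node.region_id}")
            if node.acronym in self._by_acronym:
                raise HierarchyIntegrityError(
                    f"duplicate acronym {node.acronym!r}")
            self._by_id[node.region_id] = node
            self._by_acronym[node.acronym] = node
        self._validate()
        self._children: dict[int, list[int]] = {i: [] for i in self._by_id}
        for node in self._by_id.values():
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.region_id)

    def _validate(self) -> None:
        roots = [n for n in self._by_id.values() if n.parent_id is None]
        if len(roots) != 1:
            raise HierarchyIntegrityError(
                f"expected exactly one root, found {len(roots)}")
        for node in self._by_id.values():
            if node.parent_id is not None and node.parent_id not in self._by_id:
                raise MissingParentError(
                    f"node {node.acronym!r} references missing parent "
                    f"{node.parent_id}")
            if not node.id_path or node.id_path[-1] != node.region_id:
                raise HierarchyIntegrityError(
                    f"id_path of {node.acronym!r} does not end with its own id")
            if node.parent_id is not None:
                parent = self._by_id[node.parent_id]
                if node.id_path[:-1] != parent.id_path:
                    raise HierarchyIntegrityError(
                        f"id_path of {node.acronym!r} is not an extension of "
                        f"its parent's path")

    # -- lookups -----------------------------------------------------------
    def __contains__(self, region_id: int) -> bool:
        return region_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def node(self, region_id: int) -> RegionNode:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise RegionLookupError(f"unknown region_id {region_id}") from None

    def by_acronym(self, acronym: str) -> RegionNode:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise RegionLookupError(f"unknown acronym {acronym!r}") from None

    @property
    def root(self) -> RegionNode:
        return next(n for n in self._by_id.values() if n.parent_id is None)

    def id_path(self, region_id: int) -> tuple[int, ...]:
        return self.node(region_id).id_path

    def acronym_path(self, region_id: int) -> tuple[str, ...]:
        return tuple(self._by_id[i].acronym for i in self.id_path(region_id))

    def children(self, region_id: int) -> tuple[int, ...]:
        self.node(region_id)
        return tuple(self._children[region_id])

    def descendants(self, acronym: str) -> set[int]:
        """All region IDs at or below ``acronym`` (inclusive)."""
        start = self.by_acronym(acronym).region_id
        out, stack = set(), [start]
        while stack:
            rid = stack.pop()
            out.add(rid)
            stack.extend(self._children[rid])
        return out

    def leaves(self) -> list[RegionNode]:
        return [n for n in self._by_id.values() if not self._children[n.region_id]]

    def nodes(self) -> list[RegionNode]:
        return list(self._by_id.values())

    def is_ancestor(self, ancestor_acronym: str, region_id: int) -> bool:
        anc = self.by_acronym(ancestor_acronym).region_id
        return anc in self.id_path(region_id)

    def to_records(self) -> list[dict]:
        """Serialize to the structure-graph JSON dialect."""
        recs = []
        for n in self._by_id.values():
            recs.append({
                "id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
                "structure_id_path": "/" + "/".join(str(i) for i in n.id_path) + "/",
            })
        return recs

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1,
                                         sort_keys=True) + "\n")


def _coerce_path(value, region_id: int, parents: Mapping[int, int | None]) -> tuple[int, ...]:
    """Recompute the root->self path from parent links, then check it against
    the file's declared structure_id_path (list or Allen slash-string)."""
    chain: list[int] = []
    cur: int | None = region_id
    seen: set[int] = set()
    while cur is not None:
        if cur in seen:
            raise HierarchyIntegrityError(f"cycle through region {cur}")
        seen.add(cur)
        chain.append(cur)
        if cur not in parents:
            raise MissingParentError(f"region {chain[-2]} references missing "
                                     f"parent {cur}")
        cur = parents[cur]
    path = tuple(reversed(chain))
    if value is not None:
        if isinstance(value, str):
            declared = tuple(int(t) for t in value.strip("/").split("/") if t)
        else:
            declared = tuple(int(t) for t in value)
        if declared != path:
            raise HierarchyIntegrityError(
                f"declared structure_id_path {declared} of region {region_id} "
                f"disagrees with parent links {path}")
    return path


def load_structure_tree(path: str | Path) -> RegionHierarchy:
    """Load a structure tree from a structure-graph JSON file.

    The per-node ``structure_id_path`` is recomputed from parent links and
    validated against the file's declared value when present.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):  # AllenSDK wraps the array in {"msg": [...]}
        raw = raw.get("msg", raw)
    ids = [int(r["id"]) for r in raw]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise HierarchyIntegrityError(f"duplicate region ids {dupes}")
    parents = {int(r["id"]):
               (None if r.get("parent_structure_id") in (None, "null", "")
                else int(r["parent_structure_id"])) for r in raw}
    nodes = []
    for r in raw:
        rid = int(r["id"])
        nodes.append(RegionNode(
            region_id=rid,
            acronym=str(r["acronym"]),
            name=str(r.get("name", r["acronym"])),
            parent_id=parents[rid],
            id_path=_coerce_path(r.get("structure_id_path"), rid, parents),
        ))
    return RegionHierarchy(nodes)


@dataclass
class AnnotationVolume:
    """Voxelized region labels: integer region ID per voxel, 0 = background."""

    values: np.ndarray                 # 3-D integer array
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError("annotation volume must be 3-D")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValidationError(
                f"voxel sizes must be strictly positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size_um)

    def lookup(self, coords_um: np.ndarray) -> np.ndarray:
        """Vectorized voxel lookup: region ID per coordinate, 0 out of bounds."""
        coords = np.atleast_2d(np.asarray(coords_um, dtype=float))
        idx = np.floor(coords / np.asarray(self.voxel_size_um)).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        out = np.zeros(len(coords), dtype=self.values.dtype)
        ii = idx[inside]
        out[inside] = self.values[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def validate_against(self, h: RegionHierarchy) -> None:
        labels = np.unique(self.values)
        unknown = [int(v) for v in labels if v != 0 and int(v) not in h]
        if unknown:
            raise ValidationError(f"annotation labels not in hierarchy: {unknown}")

    def save(self, path: str | Path, encoding: str = "raw") -> None:
        nrrdio.write(path, self.values, spacings=self.voxel_size_um,
                     encoding=encoding)


def load_annotation(path: str | Path) -> AnnotationVolume:
    """Load an annotation volume from NRRD; voxel size from the header."""
    values, header = nrrdio.read(path)
    spacings = header.get("spacings")
    if spacings is None:
        raise ValidationError(f"{path}: NRRD header lacks voxel spacings")
    return AnnotationVolume(values=values, voxel_size_um=tuple(spacings))


@dataclass(frozen=True)
class ExclusionSet:
    """Acronyms whose whole subtrees are dropped from analysis."""

    excluded_acronyms: frozenset[str] = field(default_factory=lambda: DEFAULT_EXCLUSIONS)

    def __post_init__(self):
        object.__setattr__(self, "excluded_acronyms",
                           frozenset(self.excluded_acronyms))

    def validate(self, h: RegionHierarchy) -> None:
        for a in self.excluded_acronyms:
            h.by_acronym(a)

    def excluded_ids(self, h: RegionHierarchy) -> set[int]:
        out: set[int] = set()
        for a in self.excluded_acronyms:
            out |= h.descendants(a)
        return out


# ---------------------------------------------------------------------------
# Neuron tables

def read_neurons(path: str | Path) -> pd.DataFrame:
    """Read a neuron table CSV (one row per segmented active neuron)."""
    df = pd.read_csv(path, dtype={"neuron_id": str, "brain_id": str,
                                  "condition": str})
    missing = [c for c in NEURON_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: neuron table lacks columns {missing}")
    return df


def write_neurons(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _check_coords(neurons: pd.DataFrame) -> np.ndarray:
    coords = neurons[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        names = neurons.loc[bad, "neuron_id"].tolist()[:5]
        raise ValidationError(f"non-finite coordinates for neurons {names}")
    return coords


def assign_regions(neurons: pd.DataFrame, vol: AnnotationVolume) -> pd.DataFrame:
    """Assign each neuron the region ID of the voxel containing it.

    Points outside the volume get region_id 0.  Returns a copy with a
    ``region_id`` column; input row order is preserved.
    """
    coords = _check_coords(neurons)
    out = neurons.copy()
    out["region_id"] = vol.lookup(coords).astype(int)
    return out


def ancestor_at_level(region_id: int, target_set: Iterable[str],
                      h: RegionHierarchy) -> str | None:
    """The unique member of ``target_set`` on the node's root->self path,
    or None.  Used to roll leaf labels up to major regions or cortical areas."""
    targets = set(target_set)
    hits = [a for a in h.acronym_path(region_id) if a in targets]
    if not hits:
        return None
    if len(hits) > 1:
        raise ScopePartitionError(
            f"target set members {hits} are nested along one root path")
    return hits[0]


def parse_layer(acronym: str) -> str | None:
    """Cortical layer label from the trailing layer token of an acronym.

    ``VISp5 -> 'L5'``, ``RSPagl2/3 -> 'L2/3'``; returns None when the
    acronym carries no layer token (non-laminar regions).
    """
    m = _LAYER_RE.search(acronym)
    if m is None:
        return None
    return "L" + m.group(1)
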