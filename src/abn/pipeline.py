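"""End-to-end orchestration: assign -> stats -> match -> connect -> network.

Stages communicate only through their documented file formats (CSV/JSON
under the output directory), so each stage can also be run in isolation
from the command line.  A deterministic run manifest records input
checksums, the seed, per-stage row counts and statuses; re-running with
identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import active_connectivity as ac
from . import network_metrics as nm
from . import regional_stats as rs
from . import transcriptomic_match as tm
from .atlas import (
    DEFAULT_EXCLUSIONS,
    MAJOR_REGIONS,
    ExclusionSet,
    assign_regions,
    load_annotation,
    load_structure_tree,
    read_neurons,
    write_neurons,
)
from .errors import AbnError

log = logging.getLogger("abn")

STAGES = ("assign", "stats", "match", "connect", "network")
_DEPENDS = {"assign": (), "stats": ("assign",), "match": ("assign",),
            "connect": ("stats",), "network": ("connect",)}


def default_region_set() -> list[str]:
    """Core default-mode-network acronyms packaged with the library."""
    text = resources.files("abn.data").joinpath("dmn.txt").read_text()
    return [t.strip() for t in text.splitlines()
            if t.strip() and not t.startswith("#")]


@dataclass
class RunConfig:
    neurons: list[str]
    tree: str
    annotation: str
    reference: str
    density: str
    out_dir: str
    region_set: str | None = None        # file of acronyms; None = packaged DMN
    exclusions: list[str] = field(default_factory=lambda: sorted(DEFAULT_EXCLUSIONS))
    midline_um: float | None = None      # None = half the volume's x extent
    mirror_axis: int = 0
    gamma_min: float = 0.5
    gamma_max: float = 2.0
    gamma_steps: int = 21
    top_k: int = 10
    seed: int = 0
    restarts: int = 10
    length_transform: str = "inverse"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self, strict: bool = True) -> list[str]:
        missing = [str(p) for p in self.input_files() if not Path(p).exists()]
        if missing and strict:
            raise FileNotFoundError(f"missing input files: {missing}")
        return missing

    def input_files(self) -> list[str]:
        out = [*self.neurons, self.tree, self.annotation, self.reference,
               self.density]
        if self.region_set:
            out.append(self.region_set)
        return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _meta_header(cfg: RunConfig) -> str:
    return f"# abn {__version__} seed={cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(cfg))
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Stages


def stage_assign(cfg: RunConfig, out: Path) -> dict:
    vol = load_annotation(cfg.annotation)
    tree = load_structure_tree(cfg.tree)
    vol.validate_against(tree)
    (out / "assigned").mkdir(exist_ok=True)
    n_rows = 0
    for p in cfg.neurons:
        neurons = read_neurons(p)
        assigned = assign_regions(neurons, vol)
        write_neurons(assigned, out / "assigned" / Path(p).name)
        n_rows += len(assigned)
    return {"rows": n_rows, "brains": len(cfg.neurons)}


def _load_assigned(cfg: RunConfig, out: Path) -> pd.DataFrame:
    frames = [read_neurons(out / "assigned" / Path(p).name)
              for p in cfg.neurons]
    return pd.concat(frames, ignore_index=True)


def stage_stats(cfg: RunConfig, out: Path) -> dict:
    tree = load_structure_tree(cfg.tree)
    excl = ExclusionSet(frozenset(cfg.exclusions))
    excl.validate(tree)
    neurons = _load_assigned(cfg, out)

    majors = [a for a in MAJOR_REGIONS
              if a in {n.acronym for n in tree.nodes()}]
    counts_major = rs.count_table(neurons, tree, majors, excl)
    tidy = pd.DataFrame([(c.brain_id, c.condition, a, n)
                         for c in counts_major
                         for a, n in sorted(c.counts.items())],
                        columns=["brain_id", "condition", "acronym", "n"])
    _write_csv(tidy, out / "counts_major.csv", cfg)
    rt = rs.ratio_table(counts_major)
    _write_csv(rs.zscore_across_conditions(rt), out / "ratios_major.csv", cfg)

    iso_children = [tree.node(i).acronym
                    for i in tree.children(tree.by_acronym("Isocortex").region_id)] \
        if "Isocortex" in {n.acronym for n in tree.nodes()} else []
    if iso_children:
        ctx_counts = rs.count_table(
            neurons[neurons["region_id"].isin(
                list(tree.descendants("Isocortex")))],
            tree, iso_children, excl)
        ctx_rt = rs.ratio_table(ctx_counts)
        _write_csv(rs.zscore_across_conditions(ctx_rt),
                   out / "ratios_cortex.csv", cfg)
        _write_csv(rs.layer_ratios(neurons, "Isocortex", tree),
                   out / "layer_ratios_cortex.csv", cfg)

    # per-assigned-region counts (finest level): the connect stage rolls
    # these up to whatever region set the density matrix uses
    excluded_ids = excl.excluded_ids(tree)
    fine = neurons[(neurons["region_id"] != 0)
                   & ~neurons["region_id"].isin(list(excluded_ids))].copy()
    fine["acronym"] = [tree.node(int(r)).acronym for r in fine["region_id"]]
    tidy_fine = (fine.groupby(["brain_id", "condition", "acronym"])
                 .size().rename("n").reset_index()
                 .sort_values(["brain_id", "acronym"], kind="mergesort"))
    _write_csv(tidy_fine, out / "counts_leaves.csv", cfg)
    return {"rows": len(tidy) + len(tidy_fine), "brains": len(counts_major)}


def stage_match(cfg: RunConfig, out: Path) -> dict:
    tree = load_structure_tree(cfg.tree)
    neurons = _load_assigned(cfg, out)
    reference = tm.read_reference(cfg.reference)
    if cfg.midline_um is None:
        vol = load_annotation(cfg.annotation)
        midline = float(vol.extent_um[cfg.mirror_axis] / 2.0)
    else:
        midline = float(cfg.midline_um)
    mirrored = tm.mirror_to_reference_hemisphere(neurons, midline,
                                                 axis=cfg.mirror_axis)
    matches = tm.match(mirrored, reference, tree)
    matches = matches.merge(neurons[["neuron_id", "brain_id", "condition"]],
                            on="neuron_id")
    _write_csv(matches, out / "matches.csv", cfg)
    qc = tm.distance_qc(matches)
    (out / "match_qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True)
                                       + "\n")
    majors = [a for a in MAJOR_REGIONS if a in {n.acronym for n in tree.nodes()}]
    comp = tm.composition(matches, neurons, majors, tree)
    _write_csv(comp, out / "composition_major.csv", cfg)
    _write_csv(tm.ei_ratio(comp), out / "ei_major.csv", cfg)
    return {"rows": len(matches), "matched": int(matches["matched"].sum())}


def aggregate_counts(counts: pd.DataFrame, tree, regions: list[str]
                     ) -> list[rs.RegionCounts]:
    """Roll fine-grained per-acronym counts up to a target region set."""
    lut = {n.acronym: None for n in tree.nodes()}
    targets = set(regions)
    for n in tree.nodes():
        hits = [a for a in tree.acronym_path(n.region_id) if a in targets]
        lut[n.acronym] = hits[0] if hits else None
    out = []
    for (brain, cond), g in counts.groupby(["brain_id", "condition"], sort=True):
        cmap: dict[str, int] = {}
        for acr, n in zip(g["acronym"], g["n"].astype(int)):
            member = lut.get(acr)
            if member is not None:
                cmap[member] = cmap.get(member, 0) + n
        out.append(rs.RegionCounts(brain_id=str(brain), condition=str(cond),
                                   counts=cmap, total=sum(cmap.values())))
    return out


def stage_connect(cfg: RunConfig, out: Path) -> dict:
    density = ac.read_density(cfg.density)
    tree = load_structure_tree(cfg.tree)
    counts = _read_csv(out / "counts_leaves.csv")
    (out / "matrices").mkdir(exist_ok=True)
    per_brain: list[ac.ActiveConnectivity] = []
    for rc in aggregate_counts(counts, tree, density.regions):
        brain = rc.brain_id
        W = ac.build(density, rc)
        W.save(out / "matrices" / f"{brain}.csv")
        per_brain.append(W)
    strengths = []
    for cond in sorted({w.condition for w in per_brain}):
        group = [w for w in per_brain if w.condition == cond]
        mean = ac.average_condition(group)
        mean.save(out / "matrices" / f"mean_{cond}.csv")
        for w in group:
            strengths.append((w.brain_id, cond, ac.total_strength(w)))
    _write_csv(pd.DataFrame(strengths,
                            columns=["brain_id", "condition", "total_strength"]),
               out / "total_strength.csv", cfg)
    return {"rows": len(per_brain), "brains": len(per_brain)}


def stage_network(cfg: RunConfig, out: Path) -> dict:
    counts = _read_csv(out / "counts_leaves.csv")
    pairs = (counts[["brain_id", "condition"]].drop_duplicates()
             .sort_values(["brain_id"]))
    acs = [ac.load_matrix(out / "matrices" / f"{b}.csv", brain_id=str(b),
                          condition=str(c))
           for b, c in pairs.itertuples(index=False)]
    gammas = np.linspace(cfg.gamma_min, cfg.gamma_max, cfg.gamma_steps)

    sweeps, partitions = [], []
    for cond in sorted({a.condition for a in acs}):
        mean = ac.average_condition([a for a in acs if a.condition == cond])
        sw = nm.sweep_modularity(mean, gammas, seed=cfg.seed,
                                 restarts=cfg.restarts)
        sw.insert(0, "condition", cond)
        sweeps.append(sw)
        part = nm.detect_modules(mean, gamma=1.0, seed=cfg.seed,
                                 restarts=cfg.restarts)
        partitions.append(pd.DataFrame({
            "condition": cond,
            "region": list(part.assignment),
            "module": [part.assignment[r] for r in part.assignment],
            "q": part.q}))
    _write_csv(pd.concat(sweeps, ignore_index=True),
               out / "modularity_gamma.csv", cfg)
    _write_csv(pd.concat(partitions, ignore_index=True),
               out / "partition.csv", cfg)

    ct = nm.centrality_table(acs, length_transform=cfg.length_transform)
    _write_csv(ct, out / "centrality.csv", cfg)
    hubs = []
    for cond, g in ct.groupby("condition", sort=True):
        h = nm.rank_hubs(g, k=min(cfg.top_k, g["region"].nunique()))
        h.insert(0, "condition", cond)
        hubs.append(h)
    _write_csv(pd.concat(hubs, ignore_index=True), out / "hubs.csv", cfg)

    region_set = ([t.strip() for t in Path(cfg.region_set).read_text().splitlines()
                   if t.strip() and not t.startswith("#")]
                  if cfg.region_set else default_region_set())
    present = set(ct["region"]) & set(region_set)
    if present:
        dmn = nm.set_centrality(ct, region_set)
        _write_csv(dmn, out / "dmn_centrality.csv", cfg)
    return {"rows": len(ct), "n_regions": ct["region"].nunique()}


_STAGE_FN = {"assign": stage_assign, "stats": stage_stats, "match": stage_match,
             "connect": stage_connect, "network": stage_network}


# ---------------------------------------------------------------------------


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in dependency order and write the run manifest.

    A stage failure is recorded in the manifest; stages depending on it
    are skipped, independent stages still run.
    """
    missing = cfg.validate(strict=False)
    if missing:
        log.warning("missing input files: %s", missing)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {str(p): _sha256(p) for p in sorted(cfg.input_files())
                   if Path(p).exists()},
        "missing_inputs": missing,
        "stages": {},
    }
    status: dict[str, str] = {}
    for stage in STAGES:
        bad = [d for d in _DEPENDS[stage] if status.get(d) != "ok"]
        if bad:
            manifest["stages"][stage] = {"status": "skipped",
                                         "unmet_dependencies": bad}
            status[stage] = "skipped"
            log.info("stage %s skipped (needs %s)", stage, bad)
            continue
        log.info("stage %s starting", stage)
        try:
            info = _STAGE_FN[stage](cfg, out)
        except (AbnError, OSError, KeyError, ValueError) as exc:
            manifest["stages"][stage] = {"status": "failed",
                                         "error": f"{type(exc).__name__}: {exc}"}
            status[stage] = "failed"
            log.error("stage %s failed: %s", stage, exc)
            continue
        manifest["stages"][stage] = {"status": "ok", **info}
        status[stage] = "ok"
        log.info("stage %s done: %s", stage, info)
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
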