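"""The active-connectivity matrix.

Communication from region A to region B requires (i) a structural
projection from A to B and (ii) active neurons at both ends to emit and
relay the signal.  The active connection strength is therefore the
product of three factors: the normalized structural connection density
rho[A,B] and the active-neuron counts n[A] and n[B], i.e.

    W = diag(n) . rho . diag(n),   W[A,A] = 0,

a directed, weighted region-by-region matrix computed per brain and
averaged within a condition.  rho is taken as published (no
re-normalization); counts are raw per-brain counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .regional_stats import RegionCounts


@dataclass
class DensityMatrix:
    """Normalized structural connection density between regions (directed)."""

    regions: list[str]
    rho: np.ndarray

    def __post_init__(self):
        self.regions = [str(r) for r in self.regions]
        self.rho = np.asarray(self.rho, dtype=float)
        r = len(self.regions)
        if self.rho.shape != (r, r):
            raise ValidationError(
                f"rho shape {self.rho.shape} does not match {r} regions")
        if len(set(self.regions)) != r:
            raise ValidationError("duplicate region acronyms in density matrix")
        if not np.isfinite(self.rho).all() or (self.rho < 0).any():
            raise ValidationError("rho must be finite and non-negative")

    def save(self, path: str | Path) -> None:
        pd.DataFrame(self.rho, index=self.regions,
                     columns=self.regions).to_csv(path)


def read_density(path: str | Path) -> DensityMatrix:
    """Read a density matrix CSV (first row and column are acronyms)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column acronyms differ")
    return DensityMatrix(regions=list(df.index), rho=df.to_numpy(dtype=float))


@dataclass
class ActiveConnectivity:
    """Directed weighted active-connectivity matrix for one brain (or mean)."""

    regions: list[str]
    W: np.ndarray
    brain_id: str = ""
    condition: str = ""

    def save(self, path: str | Path) -> None:
        pd.DataFrame(self.W, index=self.regions,
                     columns=self.regions).to_csv(path)


def load_matrix(path: str | Path, brain_id: str = "",
                condition: str = "") -> ActiveConnectivity:
    df = pd.read_csv(path, index_col=0)
    return ActiveConnectivity(regions=list(df.index),
                              W=df.to_numpy(dtype=float),
                              brain_id=brain_id, condition=condition)


def build(rho: DensityMatrix, counts: RegionCounts | Mapping[str, int],
          keep_diagonal: bool = False) -> ActiveConnectivity:
    """W[A,B] = rho[A,B] * n[A] * n[B], diagonal zeroed.

    Count regions missing from rho are dropped (they do not enter the
    network); rho regions with no counts get n = 0, zeroing their row and
    column.  Both situations are reported via warnings.
    """
    if isinstance(counts, RegionCounts):
        cmap = dict(counts.counts)
        brain_id, condition = counts.brain_id, counts.condition
    else:
        cmap = dict(counts)
        brain_id = condition = ""
    missing = sorted(set(rho.regions) - set(cmap))
    extra = sorted(set(cmap) - set(rho.regions))
    if missing:
        warnings.warn(f"regions without counts (n=0): {missing}", stacklevel=2)
    if extra:
        warnings.warn(f"counted regions absent from density matrix, dropped: "
                      f"{extra}", stacklevel=2)
    n = np.array([cmap.get(r, 0) for r in rho.regions], dtype=float)
    if (n < 0).any():
        raise AlignmentError("negative counts")
    W = n[:, None] * rho.rho * n[None, :]
    if not keep_diagonal:
        np.fill_diagonal(W, 0.0)
    return ActiveConnectivity(regions=list(rho.regions), W=W,
                              brain_id=brain_id, condition=condition)


def total_strength(ac: ActiveConnectivity) -> float:
    """Sum of all off-diagonal entries (overall active connection strength)."""
    off = ac.W.copy()
    np.fill_diagonal(off, 0.0)
    return float(off.sum())


def average_condition(acs: Sequence[ActiveConnectivity]) -> ActiveConnectivity:
    """Entry-wise mean of one condition's per-brain matrices."""
    if not acs:
        raise ValidationError("no matrices to average")
    conditions = {a.condition for a in acs}
    if len(conditions) != 1:
        raise AlignmentError(f"mixed conditions: {sorted(conditions)}")
    regions = acs[0].regions
    for a in acs[1:]:
        if a.regions != regions:
            raise AlignmentError("matrices do not share a region order")
    W = np.mean([a.W for a in acs], axis=0)
    return ActiveConnectivity(regions=list(regions), W=W,
                              brain_id="mean", condition=acs[0].condition)
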