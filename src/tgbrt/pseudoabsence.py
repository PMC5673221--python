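"""The three pseudo-absence generation schemes.

Presence-only models need artificial absences. Three schemes are compared:

* **UTGB** (unweighted target-group background): for a focal species k the
  pseudo-absences are the presence points of the *other* species in the
  pooled target group, excluding any point sharing a raster cell with a
  focal presence. With no cell coincidences the count is a_k = D - p_k,
  where D is the total group size and p_k the focal presence count. All
  weights are 1, so the background carries far more weight than the
  presences.
* **WTGB** (weighted target-group background): the same points, but each
  pseudo-absence gets weight W_ik = p_k / a_k, so the summed pseudo-absence
  weight equals the summed presence weight: sum_i W_ik = p_k.
* **RDM** (random): p_k cells drawn uniformly at random from the study
  area excluding the focal presence cells, replicated several times (the
  replicate projections are averaged downstream). Weights are 1.

Because target-group points inherit the survey's sampling effort, TGB
backgrounds share the presence data's sampling bias, which random points
do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from tgbrt.spatial_data import OccurrenceSet


@dataclass
class TargetGroup:
    """Pooled multi-species occurrence set of D records."""

    species_sets: list[OccurrenceSet]

    def __post_init__(self) -> None:
        names = [s.species for s in self.species_sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names in target group")

    @property
    def D(self) -> int:
        return sum(s.n for s in self.species_sets)

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.species_sets]

    def get(self, name: str) -> OccurrenceSet:
        for s in self.species_sets:
            if s.species == name:
                return s
        raise KeyError(f"species {name!r} not in target group {self.species}")


@dataclass
class PseudoAbsenceSet:
    """Artificial absences for one focal species under one scheme."""

    focal_species: str
    scheme: str  # UTGB | WTGB | RDM
    points: np.ndarray  # (a_k, 2)
    weights: np.ndarray  # (a_k,)
    replicate_id: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("UTGB", "WTGB", "RDM"):
            raise ValueError(f"unknown pseudo-absence scheme {self.scheme!r}")
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        self.weights = np.asarray(self.weights, float).reshape(-1)
        if len(self.weights) != len(self.points):
            raise ValueError("weights and points length mismatch")
        if len(self.weights) and (self.weights <= 0).any():
            raise ValueError("all pseudo-absence weights must be positive")

    @property
    def a_k(self) -> int:
        return len(self.points)


def _cell_keys(points: np.ndarray, cell_size: float, origin: tuple[float, float]):
    pts = np.asarray(points, float).reshape(-1, 2)
    cols = np.floor((pts[:, 0] - origin[0]) / cell_size).astype(np.int64)
    rows = np.floor((pts[:, 1] - origin[1]) / cell_size).astype(np.int64)
    return rows * 10_000_019 + cols


def generate_utgb(group: TargetGroup, focal: str, cell_size: float = 1.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> PseudoAbsenceSet:
    """Unweighted target-group background for one focal species.

    Pseudo-absences are all other-species presence points whose raster cell
    does not coincide with any focal presence cell; with no coincidences
    a_k = D - p_k exactly. Unit weights.
    """
    if len(group.species_sets) < 2:
        raise ValueError("target group requires >= 2 species")
    focal_set = group.get(focal)
    focal_cells = set(_cell_keys(focal_set.points, cell_size, origin).tolist())
    pts = []
    for s in group.species_sets:
        if s.species == focal:
            continue
        keys = _cell_keys(s.points, cell_size, origin)
        keep = np.array([k not in focal_cells for k in keys.tolist()], dtype=bool)
        if keep.any():
            pts.append(s.points[keep])
    points = np.vstack(pts) if pts else np.empty((0, 2))
    if len(points) == 0:
        warnings.warn(f"UTGB background for {focal!r} is empty: every other-species "
                      "point shares a cell with a focal presence")
    return PseudoAbsenceSet(focal, "UTGB", points, np.ones(len(points)))


def generate_wtgb(group: TargetGroup, focal: str, cell_size: float = 1.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> PseudoAbsenceSet:
    """Weighted target-group background: same points as UTGB, each with
    weight W_ik = p_k / a_k so that the weights sum to p_k."""
    base = generate_utgb(group, focal, cell_size, origin)
    if base.a_k == 0:
        raise ValueError("cannot weight an empty background")
    p_k = group.get(focal).n
    w = np.full(base.a_k, p_k / base.a_k)
    return PseudoAbsenceSet(focal, "WTGB", base.points, w)


def generate_rdm(stack, focal_presences: OccurrenceSet, n_replicates: int = 4,
                 seed: int = 0) -> list[PseudoAbsenceSet]:
    """Random pseudo-absences: per replicate, p_k distinct cells drawn
    uniformly from the grid excluding the focal presence cells.

    Replicate r uses the deterministic sub-seed ``seed + r`` so replicates
    differ but the whole draw is reproducible from the master seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    p_k = focal_presences.n
    rows, cols = stack.cell_of(focal_presences.points)
    presence_flat = set((rows * stack.n_cols + cols).tolist())
    all_flat = np.arange(stack.n_rows * stack.n_cols)
    candidates = np.array([i for i in all_flat if i not in presence_flat])
    if len(candidates) < p_k:
        raise ValueError(f"RDM needs {p_k} non-presence cells but only "
                         f"{len(candidates)} are available")
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        pick = rng.choice(candidates, size=p_k, replace=False)
        rr, cc = np.divmod(pick, stack.n_cols)
        x = stack.origin[0] + (cc + 0.5) * stack.cell_size
        y = stack.origin[1] + (rr + 0.5) * stack.cell_size
        out.append(PseudoAbsenceSet(focal_presences.species, "RDM",
                                    np.column_stack([x, y]), np.ones(p_k),
                                    replicate_id=r, seed=seed + r))
    return out


def write_pseudoabsences(sets: list[PseudoAbsenceSet], path: str | Path) -> None:
    """CSV export (species, x, y, weight, scheme, replicate), readable by
    the occurrence reader."""
    frames = []
    for s in sets:
        frames.append(pd.DataFrame({
            "species": s.focal_species, "x": s.points[:, 0], "y": s.points[:, 1],
            "weight": s.weights, "scheme": s.scheme,
            "replicate": -1 if s.replicate_id is None else s.replicate_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
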