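"""Occurrence tables, point-to-grid aggregation and Moran's I screening.

Occurrence records are point coordinates (planar or geographic, one CRS per
study). Before model fitting, presence sets are screened for spatial
autocorrelation by aggregating points onto a regular grid (in the spirit of
a 1 x 1 km lattice over the study area) and computing global Moran's I on
the per-cell counts, with significance under the randomization null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OccurrenceSet:
    """Presence records for one species."""

    species: str
    points: np.ndarray  # (n, 2) array of (x, y)
    crs_note: str = "planar"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if np.isnan(self.points).any():
            raise ValueError(f"NaN coordinates in occurrence set {self.species!r}")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class MoranResult:
    """Global Moran's I with analytic randomization-null inference."""

    I: float
    z_score: float
    p_value: float
    n_cells: int
    weight_scheme: str
    expected_i: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "I": self.I, "z_score": self.z_score, "p_value": self.p_value,
            "n_cells": self.n_cells, "weight_scheme": self.weight_scheme,
            "expected_I": self.expected_i,
        }


@dataclass
class CountGrid:
    """Per-cell point counts on a regular grid anchored at ``origin``."""

    counts: np.ndarray  # (n_rows, n_cols), row 0 = lowest y
    origin: tuple[float, float]
    cell_size: float


def read_occurrences(path: str | Path) -> list[OccurrenceSet]:
    """Read a species/x/y CSV into one :class:`OccurrenceSet` per species.

    Row order within each species is preserved. Rows with non-numeric
    coordinates raise a :class:`ValueError` naming the offending row.
    """
    df = pd.read_csv(path)
    for col in ("species", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"occurrence file {path} is missing column {col!r}")
    xs = pd.to_numeric(df["x"], errors="coerce")
    ys = pd.to_numeric(df["y"], errors="coerce")
    bad = np.flatnonzero(xs.isna() | ys.isna())
    if len(bad):
        # +2: 1-based and one header line
        raise ValueError(f"non-numeric coordinate at data row {bad[0] + 1} (file line {bad[0] + 2})")
    sets = []
    for sp in df["species"].drop_duplicates():
        sub = df[df["species"] == sp]
        sets.append(OccurrenceSet(str(sp), np.column_stack([xs[sub.index], ys[sub.index]])))
    return sets


def write_occurrences(sets: list[OccurrenceSet], path: str | Path) -> None:
    """Write occurrence sets as a species/x/y CSV (decimal coordinates)."""
    frames = [
        pd.DataFrame({"species": s.species, "x": s.points[:, 0], "y": s.points[:, 1]})
        for s in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def grid_aggregate(points: OccurrenceSet | np.ndarray, cell_size: float,
                   origin: tuple[float, float] = (0.0, 0.0)) -> CountGrid:
    """Count points per grid cell.

    Cells are half-open ``[lower, upper)`` in both axes, so a point lying
    exactly on a boundary belongs to the higher-index cell. The grid extent
    expands to cover all points; total count is conserved.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    pts = points.points if isinstance(points, OccurrenceSet) else np.asarray(points, float)
    cols = np.floor((pts[:, 0] - origin[0]) / cell_size).astype(int)
    rows = np.floor((pts[:, 1] - origin[1]) / cell_size).astype(int)
    r0, c0 = rows.min(), cols.min()
    counts = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=int)
    np.add.at(counts, (rows - r0, cols - c0), 1)
    return CountGrid(counts, (origin[0] + c0 * cell_size, origin[1] + r0 * cell_size), cell_size)


def _neighbor_pairs(shape: tuple[int, int], valid: np.ndarray, scheme: str):
    """Ordered (i, j, w) arrays over flat indices of valid cells."""
    nr, nc = shape
    idx = np.full(shape, -1, dtype=int)
    idx[valid] = np.arange(valid.sum())
    if scheme in ("rook", "queen"):
        offs = [(0, 1), (1, 0)]
        if scheme == "queen":
            offs += [(1, 1), (1, -1)]
        ii, jj = [], []
        for di, dj in offs:
            r = np.arange(max(0, -di), min(nr, nr - di))
            c = np.arange(max(0, -dj), min(nc, nc - dj))
            rr, cc = np.meshgrid(r, c, indexing="ij")
            a, b = idx[rr, cc], idx[rr + di, cc + dj]
            ok = (a >= 0) & (b >= 0)
            ii.append(a[ok]); jj.append(b[ok])
        i = np.concatenate(ii); j = np.concatenate(jj)
        # symmetrize: keep both directions
        return np.concatenate([i, j]), np.concatenate([j, i]), np.ones(2 * len(i))
    if scheme == "inverse_distance":
        rr, cc = np.nonzero(valid)
        n = len(rr)
        if n > 2500:
            raise ValueError("inverse_distance weights limited to <= 2500 cells")
        dr = rr[:, None] - rr[None, :]
        dc = cc[:, None] - cc[None, :]
        d = np.hypot(dr, dc)
        i, j = np.nonzero(d > 0)
        return idx[rr[i], cc[i]], idx[rr[j], cc[j]], 1.0 / d[i, j]
    raise ValueError(f"unknown weight scheme {scheme!r}")


def morans_i(grid: CountGrid | np.ndarray, weight_scheme: str = "queen",
             permutations: int = 0, seed: int = 0) -> MoranResult:
    """Global Moran's I on a lattice of cell values.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    The z-score and two-sided p-value use the randomization null:
    E[I] = -1/(n-1) with the standard randomization variance. With
    ``permutations`` > 0 the p-value is instead the two-sided permutation
    probability over random relabelings of the cell values.
    """
    values = grid.counts if isinstance(grid, CountGrid) else np.asarray(grid, float)
    values = np.asarray(values, float)
    valid = np.isfinite(values)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("Moran's I requires at least 2 cells with data")
    x = values[valid].astype(float)
    z = x - x.mean()
    s2 = (z ** 2).sum()
    if s2 == 0:
        raise ValueError("Moran's I undefined for constant field")
    ii, jj, ww = _neighbor_pairs(values.shape, valid, weight_scheme)
    W = ww.sum()
    num = (ww * z[ii] * z[jj]).sum()
    I = (n / W) * num / s2

    e_i = -1.0 / (n - 1)
    # randomization variance (Cliff & Ord): symmetric weights
    s1 = 0.5 * ((2 * ww) ** 2).sum()  # w_ij + w_ji = 2w_ij for symmetric weights
    row = np.bincount(ii, weights=ww, minlength=n)
    col = np.bincount(jj, weights=ww, minlength=n)
    s2w = ((row + col) ** 2).sum()
    b2 = n * (z ** 4).sum() / s2 ** 2
    a = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2w + 3 * W ** 2)
    b = b2 * ((n ** 2 - n) * s1 - 2 * n * s2w + 6 * W ** 2)
    denom = (n - 1) * (n - 2) * (n - 3) * W ** 2
    var = (a - b) / denom - e_i ** 2 if denom != 0 else np.nan
    zsc = (I - e_i) / np.sqrt(var) if var and var > 0 else np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for k in range(permutations):
            zp = rng.permutation(z)
            sims[k] = (n / W) * (ww * zp[ii] * zp[jj]).sum() / s2
        p = (1 + (np.abs(sims - e_i) >= abs(I - e_i)).sum()) / (permutations + 1)
    else:
        p = 2 * stats.norm.sf(abs(zsc)) if np.isfinite(zsc) else np.nan
    return MoranResult(float(I), float(zsc), float(p), n, weight_scheme, e_i)


def write_moran_report(results: dict[str, MoranResult], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: v.to_dict() for k, v in results.items()}, indent=2))
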