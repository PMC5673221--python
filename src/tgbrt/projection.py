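"""Project fitted models over the environmental grid and discretize.

Projection evaluates the model at every raster cell, giving the relative
likelihood of occurrence on a continuous 0-1 scale. For the random
pseudo-absence scheme the replicate projections are averaged cell-wise.
Continuous maps are made discrete into five equal-width classes of
increasing likelihood (0-0.2, 0.2-0.4, 0.4-0.6, 0.6-0.8, 0.8-1.0; classes
half-open below, the top class closed at 1.0) and per-class areas are
reported in hectares and as percentages of the mapped area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from tgbrt.brt_engine import BRTModel
from tgbrt.synthetic_data import EnvStack, write_ascii_grid

CLASS_EDGES = (0.2, 0.4, 0.6, 0.8)
CLASS_LABELS = ("0-0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1.0")


@dataclass
class SuitabilityRaster:
    """Per-cell relative likelihood of occurrence with optional classes."""

    values: np.ndarray  # (n_rows, n_cols), NaN = no data
    species: str = ""
    scheme: str = ""
    replicate_id: Optional[int] = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    class_grid: Optional[np.ndarray] = None
    class_areas: Optional[pd.DataFrame] = None

    def write_ascii(self, path: str | Path) -> None:
        write_ascii_grid(self.values, path, self.cell_size, self.origin)


def project(model: BRTModel, stack: EnvStack, species: str = "",
            scheme: str = "", replicate_id: Optional[int] = None) -> SuitabilityRaster:
    """Predict the model at every cell of the stack.

    Cells with a missing value in any training predictor become no-data
    and are excluded from class areas.
    """
    missing = [f for f in model.feature_names if f not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing predictor layer(s): {missing}")
    cols = np.column_stack([stack.layers[f].ravel() for f in model.feature_names])
    ok = np.isfinite(cols).all(axis=1)
    out = np.full(len(cols), np.nan)
    if ok.any():
        out[ok] = model.predict(cols[ok])
    return SuitabilityRaster(out.reshape(stack.n_rows, stack.n_cols), species,
                             scheme, replicate_id, stack.cell_size, stack.origin)


def average_replicates(rasters: list[SuitabilityRaster]) -> SuitabilityRaster:
    """Cell-wise arithmetic mean of replicate projections.

    No-data at a cell in any replicate propagates to the mean.
    """
    if len(rasters) < 2:
        raise ValueError("averaging needs >= 2 rasters")
    shapes = {r.values.shape for r in rasters}
    grids = {(r.cell_size, r.origin) for r in rasters}
    if len(shapes) != 1 or len(grids) != 1:
        raise ValueError("replicate rasters must share grid and georeferencing")
    mean = np.mean([r.values for r in rasters], axis=0)
    r0 = rasters[0]
    return SuitabilityRaster(mean, r0.species, r0.scheme, None,
                             r0.cell_size, r0.origin)


def discretize_and_areas(raster: SuitabilityRaster,
                         cell_area_ha: Optional[float] = None) -> SuitabilityRaster:
    """Assign each mapped cell to one of the five likelihood classes and
    tabulate per-class areas.

    Default cell area is cell_size squared, read as hectares via the map
    units; pass ``cell_area_ha`` explicitly for geographic grids (e.g. 86
    ha for 30 arc-second cells).
    """
    if cell_area_ha is None:
        cell_area_ha = raster.cell_size ** 2
    if cell_area_ha <= 0:
        raise ValueError("cell_area_ha must be positive")
    v = raster.values
    mapped = np.isfinite(v)
    cls = np.zeros(v.shape, dtype=int)
    cls[mapped] = np.digitize(v[mapped], CLASS_EDGES, right=False) + 1
    n_mapped = int(mapped.sum())
    counts = np.bincount(cls[mapped], minlength=6)[1:]
    areas = counts * cell_area_ha
    pct = 100.0 * counts / n_mapped if n_mapped else np.zeros(5)
    table = pd.DataFrame({"class": CLASS_LABELS, "n_cells": counts,
                          "area_ha": areas, "percent": pct})
    raster.class_grid = np.where(mapped, cls, 0)
    raster.class_areas = table
    return raster
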