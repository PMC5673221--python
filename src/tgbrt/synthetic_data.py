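"""Virtual landscapes and virtual species with known suitability functions.

Every downstream stage (pseudo-absence generation, boosting, evaluation,
projection) is exercised on synthetic data: a stack of spatially
autocorrelated environmental layers — bioclimatic-style fields plus SLOPE
and ASPECT topographic layers — and virtual species whose true occurrence
probability is a logistic function of those layers. Because the generating
process is known, tests can check that the pipeline recovers it.

Layers are built as low-pass-filtered Gaussian noise plus a broad planar
gradient. Inter-layer collinearity (ubiquitous among bioclimatic surfaces)
is induced by mixing each layer with a shared latent field: with mixing
level ``correlation`` = c, two non-topographic layers have expected Pearson
correlation c. Non-topographic layers are standardized (mean 0, sd 1 over
cells); SLOPE is a non-negative half-normal-style field in degrees and
ASPECT wraps a smooth field onto the compass circle [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from tgbrt.spatial_data import OccurrenceSet
from tgbrt.pseudoabsence import TargetGroup


@dataclass
class EnvStack:
    """A stack of co-registered environmental raster layers.

    ``layers[name]`` is an (n_rows, n_cols) array with row 0 at the lowest
    y (south), matching cell-center coordinates produced by
    :meth:`cell_centers`. All layers share the grid and georeferencing.
    """

    layer_names: list[str]
    layers: dict[str, np.ndarray]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    units: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.layers[n].shape for n in self.layer_names}
        if len(shapes) != 1:
            raise ValueError("all layers must share grid dimensions")
        for name in self.layer_names:
            v = self.layers[name]
            if np.nanstd(v) == 0:
                raise ValueError(f"layer {name!r} is constant over the grid")
        if "ASPECT" in self.layers:
            a = self.layers["ASPECT"]
            if np.nanmin(a) < 0 or np.nanmax(a) >= 360:
                raise ValueError("ASPECT values must lie in [0, 360)")
        if "SLOPE" in self.layers and np.nanmin(self.layers["SLOPE"]) < 0:
            raise ValueError("SLOPE values must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.layers[self.layer_names[0]].shape[0]

    @property
    def n_cols(self) -> int:
        return self.layers[self.layer_names[0]].shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate grids, each (n_rows, n_cols)."""
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given (x, y) points."""
        pts = np.asarray(points, float).reshape(-1, 2)
        cols = np.floor((pts[:, 0] - self.origin[0]) / self.cell_size).astype(int)
        rows = np.floor((pts[:, 1] - self.origin[1]) / self.cell_size).astype(int)
        if (rows < 0).any() or (rows >= self.n_rows).any() \
                or (cols < 0).any() or (cols >= self.n_cols).any():
            raise ValueError("point outside the raster extent")
        return rows, cols

    def extract(self, points: np.ndarray, layer_names: list[str] | None = None) -> np.ndarray:
        """Layer values at point locations, as an (n_points, n_layers) array."""
        rows, cols = self.cell_of(points)
        names = layer_names if layer_names is not None else self.layer_names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def write_ascii(self, directory: str | Path) -> list[Path]:
        """Write each layer as an ESRI ASCII grid (<name>.asc)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self.layer_names:
            p = directory / f"{name}.asc"
            write_ascii_grid(self.layers[name], p, self.cell_size, self.origin)
            paths.append(p)
        return paths


def write_ascii_grid(values: np.ndarray, path: str | Path, cell_size: float,
                     origin: tuple[float, float], nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 of ``values`` = south)."""
    nr, nc = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    header = (f"ncols {nc}\nnrows {nr}\nxllcorner {origin[0]}\n"
              f"yllcorner {origin[1]}\ncellsize {cell_size}\nNODATA_value {nodata}\n")
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; returns (values, cell_size, origin)."""
    lines = Path(path).read_text().splitlines()
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split() and lines[i].split()[0].lower() in keys:
        key, val = lines[i].split()[:2]
        hdr[key.lower()] = float(val)
        i += 1
    vals = np.loadtxt(lines[i:])
    vals = vals.reshape(int(hdr["nrows"]), int(hdr["ncols"]))[::-1]
    if "nodata_value" in hdr:
        vals = np.where(vals == hdr["nodata_value"], np.nan, vals)
    return vals, hdr.get("cellsize", 1.0), (hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0))


@dataclass
class VirtualSpeciesSpec:
    """A species whose true suitability is logistic in the env layers.

    suitability = logistic(intercept + sum_j coeff_j * x_j
                           + sum interactions c * x_i * x_j)
    """

    name: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    interaction_terms: list[tuple[str, str, float]] = dc_field(default_factory=list)
    n_presences: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presences < 1:
            raise ValueError(f"species {self.name!r}: n_presences must be >= 1")
        nonzero = any(c != 0 for c in self.coefficients.values()) or \
            any(c != 0 for _, _, c in self.interaction_terms)
        if not nonzero:
            raise ValueError(f"species {self.name!r}: needs at least one nonzero coefficient")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, gradient: bool = True) -> np.ndarray:
    """Standardized low-pass-filtered noise, optionally plus a planar trend."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    if gradient:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.meshgrid(np.linspace(-1, 1, shape[0]), np.linspace(-1, 1, shape[1]),
                             indexing="ij")
        # Keep the trend a minor variance share: two random planes correlate
        # as |cos(angle)|, so a large trend amplitude would leak spurious
        # inter-layer correlation even when none is requested.
        f = f / (f.std() + 1e-12) + 0.35 * (np.cos(theta) * xx + np.sin(theta) * yy)
    return (f - f.mean()) / f.std()


def make_env_stack(n_rows: int, n_cols: int, n_layers: int, correlation: float = 0.0,
                   seed: int = 0, cell_size: float = 1.0,
                   origin: tuple[float, float] = (0.0, 0.0),
                   layer_names: list[str] | None = None) -> EnvStack:
    """Generate a synthetic environmental stack.

    The last two layers are designated SLOPE and ASPECT; the remainder are
    bioclimatic-style standardized fields named BIO1, BIO2, ... (or
    ``layer_names`` if given). ``correlation`` sets the expected pairwise
    Pearson correlation among the non-topographic layers.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10 x 10")
    if n_layers < 3:
        raise ValueError("need at least 3 layers (>= 1 bioclimatic + SLOPE + ASPECT)")
    if not 0 <= correlation < 1:
        raise ValueError("correlation must lie in [0, 1)")
    if layer_names is None:
        layer_names = [f"BIO{i + 1}" for i in range(n_layers - 2)] + ["SLOPE", "ASPECT"]
    elif len(layer_names) != n_layers:
        raise ValueError("layer_names length must equal n_layers")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    sigma = max(2.0, min(n_rows, n_cols) / 6)
    # Draw one latent smooth field per layer plus a shared one, then
    # orthogonalize them (QR on the centered cell x field matrix). Heavily
    # smoothed fields have few effective spatial degrees of freedom, so raw
    # draws correlate by chance; orthogonal latents make the requested
    # inter-layer correlation exact while keeping every field a smooth
    # combination of low-pass noise and broad trends.
    raw = np.column_stack([_smooth_field(rng, shape, sigma).ravel()
                           for _ in range(n_layers + 1)])
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    latents = q / q.std(axis=0)
    shared = latents[:, 0].reshape(shape)
    a, b = np.sqrt(correlation), np.sqrt(1 - correlation)
    layers: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for i, name in enumerate(layer_names):
        own = latents[:, i + 1].reshape(shape)
        if name == "SLOPE":
            layers[name] = np.abs(own) * 12.0  # degrees, half-normal-like
            units[name] = "degrees"
        elif name == "ASPECT":
            layers[name] = np.mod(own * 120.0 + 180.0, 360.0)
            units[name] = "degrees"
        else:
            layers[name] = a * shared + b * own
            units[name] = "z-score"
    return EnvStack(layer_names, layers, cell_size, origin, units)


def suitability_surface(stack: EnvStack, spec: VirtualSpeciesSpec) -> np.ndarray:
    """True per-cell occurrence probability of a virtual species."""
    missing = [p for p in spec.coefficients if p not in stack.layers]
    missing += [p for t in spec.interaction_terms for p in t[:2] if p not in stack.layers]
    if missing:
        raise KeyError(f"predictors not in stack: {sorted(set(missing))}")
    eta = np.full((stack.n_rows, stack.n_cols), float(spec.intercept))
    for name, c in spec.coefficients.items():
        eta = eta + c * stack.layers[name]
    for pi, pj, c in spec.interaction_terms:
        eta = eta + c * stack.layers[pi] * stack.layers[pj]
    return 1.0 / (1.0 + np.exp(-eta))


def sample_presences(suitability: np.ndarray, n: int, seed: int = 0,
                     stack: EnvStack | None = None,
                     cell_size: float = 1.0,
                     origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sample n distinct cells with probability proportional to suitability.

    Returns (n, 2) cell-center coordinates. Cells with zero suitability are
    never selected; if fewer than n cells have positive suitability an
    error is raised.
    """
    s = np.asarray(suitability, float)
    flat = s.ravel()
    avail = int((flat > 0).sum())
    if n > avail:
        raise ValueError(f"cannot sample {n} presences: only {avail} cells with positive suitability")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, s.shape)
    if stack is not None:
        cell_size, origin = stack.cell_size, stack.origin
    x = origin[0] + (cols + 0.5) * cell_size
    y = origin[1] + (rows + 0.5) * cell_size
    return np.column_stack([x, y])


def make_target_group(stack: EnvStack, specs: list[VirtualSpeciesSpec],
                      distinct_cells: bool = True) -> TargetGroup:
    """Sample presences for each virtual species and pool them.

    With ``distinct_cells`` (the default) species are sampled sequentially
    and cells already occupied by an earlier species are masked out, so no
    two species share a cell — the condition under which the target-group
    background count identity a_k = D - p_k holds exactly.
    """
    if len(specs) < 2:
        raise ValueError("a target group requires at least 2 species")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in target group")
    taken = np.zeros((stack.n_rows, stack.n_cols), dtype=bool)
    sets = []
    for spec in specs:
        suit = suitability_surface(stack, spec)
        if distinct_cells:
            suit = np.where(taken, 0.0, suit)
        pts = sample_presences(suit, spec.n_presences, seed=spec.seed, stack=stack)
        rows, cols = stack.cell_of(pts)
        taken[rows, cols] = True
        sets.append(OccurrenceSet(spec.name, pts))
    return TargetGroup(sets)
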