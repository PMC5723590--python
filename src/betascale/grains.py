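"""Grain designs, community aggregation, environment upscaling, topography.

A grain design tiles the plot with square quadrats of one size, anchored at
the lower-left corner; remainder strips that do not fit a whole grain are
discarded from the high-coordinate edges. On the 260 x 200 m plot this gives
130 / 48 / 30 / 20 grains (5.2 / 4.32 / 4.8 / 5.0 ha) for 20 / 30 / 40 / 50 m
grains.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist, pdist, squareform

from .io import SOIL_VARS, EnvSampleTable, StemMap, ValidationError

TOPO_VARS = ("mean_elev", "aspect", "slope", "convexity")


@dataclass(frozen=True)
class GrainDesign:
    """A tiling of the plot into n_x * n_y square grains of one size.

    Grains are indexed row-major: ``gid = iy * n_x + ix`` with ix along x.
    """

    plot_width: float
    plot_height: float
    grain_size: float
    n_x: int
    n_y: int

    @property
    def n_grains(self) -> int:
        return self.n_x * self.n_y

    @property
    def covered_area_ha(self) -> float:
        return self.n_grains * self.grain_size**2 / 1e4

    @property
    def origins(self) -> np.ndarray:
        g = self.grain_size
        ix, iy = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y))
        return np.column_stack([ix.ravel() * g, iy.ravel() * g])

    @property
    def centroids(self) -> np.ndarray:
        return self.origins + self.grain_size / 2.0

    def grain_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map points to grain ids; -1 for points in discarded remainder strips."""
        g = self.grain_size
        ix = np.floor(np.asarray(x, float) / g).astype(int)
        iy = np.floor(np.asarray(y, float) / g).astype(int)
        inside = (ix >= 0) & (ix < self.n_x) & (iy >= 0) & (iy < self.n_y)
        gid = np.where(inside, iy * self.n_x + ix, -1)
        return gid

    def vertices(self) -> np.ndarray:
        """Corner lattice of the covered region, shape ((n_x+1)*(n_y+1), 2)."""
        g = self.grain_size
        vx = np.arange(self.n_x + 1) * g
        vy = np.arange(self.n_y + 1) * g
        X, Y = np.meshgrid(vx, vy, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass
class CommunityMatrix:
    """Grains-by-species abundance table aligned to a GrainDesign."""

    design: GrainDesign
    counts: pd.DataFrame  # index: grain id 0..n-1, columns: species labels

    @property
    def n_grains(self) -> int:
        return len(self.counts)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


def make_grain_design(plot_dims: tuple[float, float], grain_size: float) -> GrainDesign:
    """Tile a (width, height) plot with square grains of the given size."""
    w, h = float(plot_dims[0]), float(plot_dims[1])
    g = float(grain_size)
    if g <= 0:
        raise ValueError("grain size must be positive")
    if g > min(w, h):
        raise ValueError(f"grain size {g} exceeds a plot dimension ({w} x {h})")
    # floor with a tolerance so 260/20 never lands on 12 from float noise
    n_x = int(math.floor(w / g + 1e-9))
    n_y = int(math.floor(h / g + 1e-9))
    return GrainDesign(w, h, g, n_x, n_y)


def aggregate_community(stem_map: StemMap, design: GrainDesign) -> CommunityMatrix:
    """Count living stems of each species per grain.

    Stems falling in remainder strips outside the covered region are
    excluded. Species with zero total abundance are dropped.
    """
    if (stem_map.plot_width, stem_map.plot_height) != (
        design.plot_width,
        design.plot_height,
    ):
        raise ValidationError(
            "stem map and grain design disagree on plot dimensions: "
            f"({stem_map.plot_width}, {stem_map.plot_height}) vs "
            f"({design.plot_width}, {design.plot_height})"
        )
    stems = stem_map.stems
    species = sorted(stems["species"].astype(str).unique()) if len(stems) else []
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(design.n_grains, name="grain"), columns=species, dtype=int
    )
    if len(stems):
        gid = design.grain_index(stems["x"].to_numpy(), stems["y"].to_numpy())
        keep = gid >= 0
        if keep.any():
            sp_codes = pd.Categorical(stems["species"].astype(str)[keep], categories=species)
            flat = gid[keep] * len(species) + sp_codes.codes
            tallies = np.bincount(flat, minlength=design.n_grains * len(species))
            counts.iloc[:, :] = tallies.reshape(design.n_grains, len(species))
    nonzero = counts.sum(axis=0) > 0
    counts = counts.loc[:, nonzero]
    return CommunityMatrix(design, counts)


# ---------------------------------------------------------------------------
# environment upscaling
# ---------------------------------------------------------------------------

def _fit_exponential_variogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> tuple[float, float, float]:
    """WLS fit of nugget + partial-sill exponential model to the empirical
    semivariogram (weights = pair counts / model^2, Cressie-style)."""
    d = pdist(points)
    gamma = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    hmax = d.max() / 2.0
    edges = np.linspace(0, hmax, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    centers, emp, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() >= 3:
            centers.append(d[m].mean())
            emp.append(gamma[m].mean())
            counts.append(m.sum())
    centers = np.asarray(centers)
    emp = np.asarray(emp)
    counts = np.asarray(counts, float)
    var = values.var()
    scale = max(np.abs(values).max(), 1.0)
    if var <= 1e-20 * scale**2 or len(centers) < 3:
        # (near-)constant residual field: pure nugget of negligible size
        return 0.0, max(var, 1e-12), max(hmax, 1.0)

    def resid(theta):
        nug, psill, rng = theta
        model = nug + psill * (1.0 - np.exp(-centers / rng))
        w = np.sqrt(counts) / np.maximum(model, 1e-12)
        return w * (emp - model)

    lb = np.array([0.0, 1e-12, 1e-6])
    ub = np.array([5 * var + 1e-9, 10 * var + 1e-9, 10 * hmax])
    x0 = np.clip(np.array([0.1 * var, var, hmax / 2.0]), lb + 1e-13, ub - 1e-13)
    sol = least_squares(resid, x0, bounds=(lb, ub))
    nug, psill, rng = sol.x
    return float(nug), float(psill), float(rng)


def _ordinary_krige(
    points: np.ndarray, values: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """First-order trend surface + ordinary kriging of the residuals with an
    exponential variogram; exact pass-through at coincident sample points."""
    n = len(points)
    A = np.column_stack([np.ones(n), points])
    beta, *_ = np.linalg.lstsq(A, values, rcond=None)
    resid = values - A @ beta
    nug, psill, rng = _fit_exponential_variogram(points, resid)
    # covariance form of the kriging system
    D = squareform(pdist(points))
    C = psill * np.exp(-D / rng)
    np.fill_diagonal(C, psill + nug)
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = C
    K[n, :n] = K[:n, n] = 1.0
    Dt = cdist(points, targets)
    k = np.vstack([psill * np.exp(-Dt / rng), np.ones(len(targets))])
    try:
        w = np.linalg.solve(K, k)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(K, k, rcond=None)[0]
    pred = w[:n].T @ resid + np.column_stack([np.ones(len(targets)), targets]) @ beta
    # coincident target/sample points reproduce the sample exactly
    exact = Dt < 1e-9
    for j, i in zip(*np.nonzero(exact.T)):
        pred[j] = values[i]
    return pred


def upscale_environment(
    samples: EnvSampleTable, design: GrainDesign, method: str = "block_mean"
) -> pd.DataFrame:
    """Carry base-grain soil values to the grains of ``design``.

    ``block_mean`` averages the base samples whose centers fall inside each
    target grain; ``kriging`` detrends (first-order polynomial), kriges the
    residuals with a WLS-fitted exponential variogram, and adds the trend
    back at the target grain centers. Either method is the identity when the
    target design is the base design itself.
    """
    if method not in ("block_mean", "kriging"):
        raise ValueError(f"unknown upscaling method {method!r}")
    pts = samples.samples[["cx", "cy"]].to_numpy(float)
    targets = design.centroids
    out = pd.DataFrame(index=pd.RangeIndex(design.n_grains, name="grain"))

    if (
        abs(design.grain_size - samples.base_grain) < 1e-9
        and len(pts) == design.n_grains
    ):
        gid = design.grain_index(pts[:, 0], pts[:, 1])
        if np.array_equal(np.sort(gid), np.arange(design.n_grains)):
            # native scale: either method is the identity
            for v in SOIL_VARS:
                col = np.empty(design.n_grains)
                col[gid] = samples.samples[v].to_numpy(float)
                out[v] = col
            return out

    if method == "block_mean":
        gid = design.grain_index(pts[:, 0], pts[:, 1])
        for v in SOIL_VARS:
            vals = samples.samples[v].to_numpy(float)
            sums = np.bincount(gid[gid >= 0], vals[gid >= 0], minlength=design.n_grains)
            nums = np.bincount(gid[gid >= 0], minlength=design.n_grains)
            if (nums == 0).any():
                raise ValidationError(
                    f"target grain(s) {np.flatnonzero(nums == 0).tolist()[:5]} "
                    "contain no base sample center"
                )
            out[v] = sums / nums
        return out

    if len(pts) < 10:
        raise ValidationError("kriging requires at least 10 samples for the variogram")
    for v in SOIL_VARS:
        out[v] = _ordinary_krige(pts, samples.samples[v].to_numpy(float), targets)
    return out


# ---------------------------------------------------------------------------
# topography
# ---------------------------------------------------------------------------

def _vertex_interpolator(vertex_table: pd.DataFrame) -> RegularGridInterpolator:
    vx = np.sort(vertex_table["vx"].unique())
    vy = np.sort(vertex_table["vy"].unique())
    grid = (
        vertex_table.pivot(index="vx", columns="vy", values="elev")
        .reindex(index=vx, columns=vy)
        .to_numpy()
    )
    if np.isnan(grid).any():
        raise ValidationError("vertex elevations do not form a complete regular lattice")
    return RegularGridInterpolator((vx, vy), grid, method="linear", bounds_error=True)


def _plane_gradient(xy: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([xy, np.ones(len(xy))])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return float(coef[0]), float(coef[1])


def topo_metrics(vertex_table: pd.DataFrame, design: GrainDesign) -> pd.DataFrame:
    """Mean elevation, slope, aspect and convexity per grain.

    Conventions (standard in large-plot forest ecology):

    * mean_elev — mean of the four grain-vertex elevations (m);
    * slope — mean, over the four triangles obtained by dropping each vertex
      in turn, of the angle of the triangle's plane (degrees);
    * aspect — downslope bearing of the least-squares plane through the four
      vertices, degrees clockwise from north (+y); flat grains get 0 and a
      ``flat`` flag;
    * convexity — grain mean elevation minus the mean of its (up to 8)
      neighboring grains' mean elevations (m).

    Vertices not in the supplied lattice (30/50 m designs on a 20 m base)
    are obtained by bilinear interpolation.
    """
    interp = _vertex_interpolator(vertex_table)
    g = design.grain_size
    vx = np.arange(design.n_x + 1) * g
    vy = np.arange(design.n_y + 1) * g
    X, Y = np.meshgrid(vx, vy, indexing="ij")
    Zv = interp(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)

    nx, ny = design.n_x, design.n_y
    mean_elev = np.empty((nx, ny))
    slope = np.empty((nx, ny))
    aspect = np.zeros((nx, ny))
    flat = np.zeros((nx, ny), dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            corners = np.array(
                [
                    [vx[ix], vy[iy], Zv[ix, iy]],
                    [vx[ix + 1], vy[iy], Zv[ix + 1, iy]],
                    [vx[ix], vy[iy + 1], Zv[ix, iy + 1]],
                    [vx[ix + 1], vy[iy + 1], Zv[ix + 1, iy + 1]],
                ]
            )
            mean_elev[ix, iy] = corners[:, 2].mean()
            angles = []
            for drop in range(4):
                tri = np.delete(corners, drop, axis=0)
                a, b = _plane_gradient(tri[:, :2], tri[:, 2])
                angles.append(math.degrees(math.atan(math.hypot(a, b))))
            slope[ix, iy] = float(np.mean(angles))
            a, b = _plane_gradient(corners[:, :2], corners[:, 2])
            if math.hypot(a, b) < 1e-10:
                flat[ix, iy] = True
                aspect[ix, iy] = 0.0
            else:
                aspect[ix, iy] = math.degrees(math.atan2(-a, -b)) % 360.0

    convexity = np.empty((nx, ny))
    for ix in range(nx):
        for iy in range(ny):
            nbrs = [
                mean_elev[jx, jy]
                for jx in range(max(0, ix - 1), min(nx, ix + 2))
                for jy in range(max(0, iy - 1), min(ny, iy + 2))
                if (jx, jy) != (ix, iy)
            ]
            convexity[ix, iy] = mean_elev[ix, iy] - float(np.mean(nbrs))

    # flatten in grain-id order (gid = iy * n_x + ix)
    out = pd.DataFrame(index=pd.RangeIndex(design.n_grains, name="grain"))
    out["mean_elev"] = mean_elev.T.ravel()
    out["aspect"] = aspect.T.ravel()
    out["slope"] = slope.T.ravel()
    out["convexity"] = convexity.T.ravel()
    out["flat"] = flat.T.ravel()
    return out


def environment_matrix(
    samples: EnvSampleTable, design: GrainDesign, method: str = "block_mean"
) -> pd.DataFrame:
    """Six upscaled soil variables plus the four topographic variables per grain."""
    soil = upscale_environment(samples, design, method=method)
    if samples.vertex_elevations is None:
        raise ValidationError("vertex elevations required for topographic variables")
    topo = topo_metrics(samples.vertex_elevations, design)
    return pd.concat([soil, topo[list(TOPO_VARS)]], axis=1)
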