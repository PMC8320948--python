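"""Spheroid shape model of the nuclear envelope.

The segmented nucleus is compared against a spheroid of equal volume centred
at the nucleus centroid — a sphere in physical coordinates, which is
anisotropic in voxel units when the section thickness differs from the
in-plane pixel size.  Rays are cast from the spheroid centre over a
longitude–latitude grid; for each ray the signed difference between the
distance to the (outermost) nuclear-envelope crossing and the distance to
the spheroid surface is recorded, positive where the envelope lies outside
the spheroid.  The resulting 2D surface map flattens the 3D envelope shape:
invaginations appear as valleys, protuberances as peaks.  Summary statistics
of the map (mean, standard deviation, range, pixel ratios within one
standard deviation of the mean) together with the nucleus volume and the
nucleus-vs-spheroid Jaccard index characterise how spherical and how rugged
the envelope is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .metrics import UndefinedMetricError, jaccard
from .stackio import DEFAULT_VOXEL_SIZE
from .volume import NucleusVolume


@dataclass
class Spheroid:
    """Equal-volume model surface.

    ``centre`` is in voxel coordinates (row, col, slice); ``semi_axes`` are
    the ellipsoid semi-axes in voxel units along (row, col, slice); for the
    default physical sphere they all correspond to the same physical radius.
    """

    centre: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    volume_um3: float = 0.0

    @property
    def semi_axes_nm(self) -> tuple[float, float, float]:
        return tuple(a * v for a, v in zip(self.semi_axes, self.voxel_size))

    def radius_along(self, direction: np.ndarray) -> np.ndarray:
        """Distance (nm) from the centre to the surface along unit physical
        direction(s); supports an (..., 3) array of directions."""
        d = np.asarray(direction, dtype=np.float64)
        axes = np.asarray(self.semi_axes_nm)
        return 1.0 / np.sqrt(np.sum((d / axes) ** 2, axis=-1))


@dataclass
class SurfaceMap:
    """Signed NE-to-spheroid distances on a longitude-latitude grid.

    ``grid`` has shape (n_lat, n_lon) with NaN marking rays that found no
    envelope crossing; values are in in-plane pixel units.  Rendering the
    grid as an image is an equirectangular (Mercator-style) projection of
    the envelope surface.
    """

    grid: np.ndarray

    @property
    def n_lat(self) -> int:
        return self.grid.shape[0]

    @property
    def n_lon(self) -> int:
        return self.grid.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.grid)

    @property
    def values(self) -> np.ndarray:
        """Non-missing grid values, flattened."""
        return self.grid[~self.missing]


@dataclass
class SurfaceMetrics:
    """Per-nucleus shape summary (Table-style row)."""

    volume_um3: float
    ji_spheroid: float
    mean_mu: float
    std_sigma: float
    range_: float
    pixel_ratio_above: float
    pixel_ratio_below: float


def _as_mask(nucleus: NucleusVolume | np.ndarray) -> np.ndarray:
    if isinstance(nucleus, NucleusVolume):
        return nucleus.mask
    return np.asarray(nucleus, dtype=bool)


def fit_spheroid(
    nucleus: NucleusVolume | np.ndarray,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> Spheroid:
    """Fit the equal-volume spheroid: centred at the nucleus centroid, with
    the radius that matches the nucleus physical volume (a sphere in nm).

    The physical radius r solves (4/3) pi r^3 = V; the voxel-space semi-axes
    are r divided by each voxel dimension, so with anisotropic voxels the
    rasterised model is a flattened ellipsoid in index space but a sphere in
    the specimen.
    """
    mask = _as_mask(nucleus)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("cannot fit a spheroid to an empty nucleus mask")
    centre = tuple(float(c) for c in ndi.center_of_mass(mask))
    voxel_volume = float(np.prod(voxel_size))  # nm^3
    volume_nm3 = count * voxel_volume
    radius_nm = (3.0 * volume_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi_axes = tuple(radius_nm / v for v in voxel_size)
    return Spheroid(
        centre=centre,
        semi_axes=semi_axes,
        voxel_size=tuple(voxel_size),
        volume_um3=volume_nm3 / 1e9,
    )


def rasterize_spheroid(spheroid: Spheroid, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean voxelisation of the spheroid on a grid of the given shape."""
    r = np.arange(shape[0], dtype=np.float64)[:, None, None]
    c = np.arange(shape[1], dtype=np.float64)[None, :, None]
    s = np.arange(shape[2], dtype=np.float64)[None, None, :]
    c0, c1, c2 = spheroid.centre
    a0, a1, a2 = spheroid.semi_axes
    q = ((r - c0) / a0) ** 2 + ((c - c1) / a1) ** 2 + ((s - c2) / a2) ** 2
    return q <= 1.0


def spheroid_jaccard(
    nucleus: NucleusVolume | np.ndarray, spheroid: Spheroid
) -> float:
    """Jaccard index between the nucleus and the rasterised spheroid: a
    measure of how spherical (not how accurate) the envelope is."""
    mask = _as_mask(nucleus)
    return jaccard(mask, rasterize_spheroid(spheroid, mask.shape))


def ray_distances(
    nucleus: NucleusVolume | np.ndarray,
    spheroid: Spheroid,
    n_lon: int = 360,
    n_lat: int = 180,
    voxel_size: tuple[float, float, float] | None = None,
) -> SurfaceMap:
    """Ray-trace the signed envelope-to-spheroid distance surface.

    For each direction of an ``n_lon`` x ``n_lat`` longitude/latitude grid a
    ray is cast from the spheroid centre; the envelope crossing is the
    OUTERMOST point of the nucleus mask along the ray, so invaginations read
    as negative values rather than being skipped.  The map value is
    (distance to envelope) − (distance to spheroid surface), converted from
    nm to in-plane pixel units; rays that never meet the mask are NaN.

    Latitude runs from −90° (low slice indices) to +90° in ``n_lat`` rows of
    cell-centred samples; longitude covers [0°, 360°).
    """
    mask = _as_mask(nucleus)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    if voxel_size is None:
        voxel_size = spheroid.voxel_size
    vr, vc, vs = voxel_size
    c0, c1, c2 = spheroid.centre

    lon = (np.arange(n_lon) + 0.5) * (2.0 * np.pi / n_lon)
    lat = -np.pi / 2.0 + (np.arange(n_lat) + 0.5) * (np.pi / n_lat)

    # Physical extent of the volume from the centre: sample rays out to the
    # farthest corner so no crossing is missed.
    corners_nm = [
        abs((e - c) * v)
        for c, v, n in zip(spheroid.centre, voxel_size, mask.shape)
        for e in (0, n - 1)
    ]
    t_max = float(np.sqrt(np.sum(np.square(np.reshape(corners_nm, (3, 2)).max(axis=1)))))
    dt = min(vr, vc) / 2.0
    t = np.arange(dt, t_max + dt, dt)  # (n_t,)

    grid = np.full((n_lat, n_lon), np.nan, dtype=np.float64)
    cos_lat, sin_lat = np.cos(lat), np.sin(lat)
    cos_lon, sin_lon = np.cos(lon), np.sin(lon)
    for j in range(n_lat):
        # unit physical directions for all longitudes at this latitude:
        # (row, col, slice) axes; poles point along the slice axis
        u = np.stack(
            [cos_lat[j] * cos_lon, cos_lat[j] * sin_lon,
             np.full(n_lon, sin_lat[j])],
            axis=-1,
        )  # (n_lon, 3)
        pts_r = c0 + (u[:, 0:1] * t) / vr  # (n_lon, n_t) voxel coords
        pts_c = c1 + (u[:, 1:2] * t) / vc
        pts_s = c2 + (u[:, 2:3] * t) / vs
        ir = np.rint(pts_r).astype(np.int64)
        ic = np.rint(pts_c).astype(np.int64)
        isl = np.rint(pts_s).astype(np.int64)
        inside = (
            (ir >= 0) & (ir < mask.shape[0])
            & (ic >= 0) & (ic < mask.shape[1])
            & (isl >= 0) & (isl < mask.shape[2])
        )
        hit = np.zeros_like(inside)
        hit[inside] = mask[ir[inside], ic[inside], isl[inside]]
        any_hit = hit.any(axis=1)
        # outermost crossing: the last sample on the ray inside the mask;
        # the true surface lies between that sample and the next, so take
        # the midpoint to avoid a systematic half-step bias
        last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
        d_ne = t[last] + dt / 2.0
        d_sph = spheroid.radius_along(u)
        vals = (d_ne - d_sph) / vr
        grid[j, any_hit] = vals[any_hit]
    return SurfaceMap(grid=grid)


def surface_metrics(
    surface: SurfaceMap,
    nucleus: NucleusVolume | np.ndarray,
    spheroid: Spheroid,
    voxel_size: tuple[float, float, float] | None = None,
) -> SurfaceMetrics:
    """Summarise a surface map together with its nucleus and model.

    mu and sigma (population) and the range are over the non-missing grid
    values; the pixel ratios are the fractions of grid values within one
    standard deviation above (mu, mu+sigma] and below [mu−sigma, mu) of the
    mean.  The volume comes from the nucleus voxel count and physical voxel
    volume; the Jaccard index from the rasterised spheroid.
    """
    vals = surface.values
    if vals.size == 0:
        raise UndefinedMetricError("surface map has no non-missing values")
    if voxel_size is None:
        voxel_size = spheroid.voxel_size
    mask = _as_mask(nucleus)
    mu = float(vals.mean())
    sigma = float(vals.std())
    rng = float(vals.max() - vals.min())
    above = float(np.count_nonzero((vals > mu) & (vals <= mu + sigma)) / vals.size)
    below = float(np.count_nonzero((vals >= mu - sigma) & (vals < mu)) / vals.size)
    volume_um3 = float(mask.sum()) * float(np.prod(voxel_size)) / 1e9
    return SurfaceMetrics(
        volume_um3=volume_um3,
        ji_spheroid=spheroid_jaccard(mask, spheroid),
        mean_mu=mu,
        std_sigma=sigma,
        range_=rng,
        pixel_ratio_above=above,
        pixel_ratio_below=below,
    )


def model_nucleus(
    nucleus: NucleusVolume | np.ndarray,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    n_lon: int = 360,
    n_lat: int = 180,
) -> tuple[Spheroid, SurfaceMap, SurfaceMetrics]:
    """Convenience wrapper: fit, ray-trace and summarise in one call."""
    sph = fit_spheroid(nucleus, voxel_size)
    smap = ray_distances(nucleus, sph, n_lon=n_lon, n_lat=n_lat)
    return sph, smap, surface_metrics(smap, nucleus, sph)


def metrics_table(rows: list[SurfaceMetrics]) -> pd.DataFrame:
    """Stack per-nucleus metric rows into a DataFrame."""
    return pd.DataFrame([vars(r) for r in rows])


def correlate_metrics(table: list[SurfaceMetrics] | pd.DataFrame) -> dict[str, float]:
    """Pearson correlations of the spheroid Jaccard index with the surface
    statistics mu, sigma and range across a cohort of nuclei.

    Raises ``UndefinedMetricError`` when a column has zero variance (the
    correlation is then undefined).
    """
    if not isinstance(table, pd.DataFrame):
        table = metrics_table(list(table))
    if len(table) < 3:
        raise ValueError("need at least 3 nuclei to correlate metrics")
    ji = table["ji_spheroid"].to_numpy(dtype=np.float64)
    out = {}
    for name, col in (
        ("ji_vs_mu", "mean_mu"),
        ("ji_vs_sigma", "std_sigma"),
        ("ji_vs_range", "range_"),
    ):
        x = table[col].to_numpy(dtype=np.float64)
        if ji.std() == 0 or x.std() == 0:
            raise UndefinedMetricError(f"zero variance: correlation {name} undefined")
        out[name] = float(np.corrcoef(ji, x)[0, 1])
    return out
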