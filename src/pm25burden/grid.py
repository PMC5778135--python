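"""Regular lat/lon raster primitives shared by every pipeline stage.

All gridded quantities (PM2.5, AOD, the PM2.5/AOD conversion factor,
population) live on one 0.5° x 0.5° cell-centred grid with a common land
mask.  Fields are plain 2-D float64 arrays wrapped with just enough
metadata (units, mask, grid spec) to make unit and grid mismatches loud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator


class ConfigurationError(ValueError):
    """Invalid grid or generator configuration."""


class GridMismatchError(ValueError):
    """Arithmetic attempted between fields on different grids/masks."""


class DomainError(ValueError):
    """Requested coordinates fall outside the available coverage."""


@dataclass(frozen=True)
class GridSpec:
    """Bounding box and resolution of a regular cell-centred raster.

    The default box (6.5-37.5 N, 67.5-97.5 E at 0.5 degrees) is a
    synthetic stand-in for the Indian landmass study domain.
    """

    lat_min: float = 6.5
    lat_max: float = 37.5
    lon_min: float = 67.5
    lon_max: float = 97.5
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError(f"resolution must be positive, got {self.resolution}")
        for lo, hi, name in (
            (self.lat_min, self.lat_max, "latitude"),
            (self.lon_min, self.lon_max, "longitude"),
        ):
            span = hi - lo
            if span <= 0:
                raise ConfigurationError(f"empty {name} span [{lo}, {hi}]")
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"resolution {self.resolution} does not divide the {name} span {span} exactly"
                )

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, ascending (north-up storage, row 0 = south)."""
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)


@dataclass
class GriddedField:
    """One physical quantity on a :class:`GridSpec` with a land mask."""

    values: np.ndarray
    units: str
    mask: np.ndarray
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "GriddedField":
        return GriddedField(np.array(values, dtype=np.float64), units or self.units, self.mask, self.grid)

    def require_compatible(self, other: "GriddedField") -> None:
        if self.grid != other.grid:
            raise GridMismatchError(f"grid mismatch: {self.grid} vs {other.grid}")
        if not np.array_equal(self.mask, other.mask):
            raise GridMismatchError("land masks differ between fields")

    def area_weights(self) -> np.ndarray:
        """cos(latitude) weights, zeroed off-land."""
        w = np.cos(np.deg2rad(self.grid.lats))[:, None] * np.ones(self.grid.nlon)[None, :]
        return np.where(self.mask, w, 0.0)

    def land_mean(self) -> float:
        """Area-weighted (cos-latitude) mean over land cells."""
        w = self.area_weights()
        tot = w.sum()
        if tot <= 0:
            raise ConfigurationError("empty land mask")
        return float((self.values * w).sum() / tot)

    def land_sum(self) -> float:
        """Plain sum over land cells (for extensive quantities like persons)."""
        return float(self.values[self.mask].sum())


def elliptical_land_mask(grid: GridSpec, fill: float = 0.92) -> np.ndarray:
    """Procedural land mask: an ellipse inscribed in the bounding box.

    `fill` scales the semi-axes; corners of the box become ocean.  The mask
    depends only on the grid, never on the random seed, so every raster in
    a bundle shares it.
    """
    la, lo = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    cy = 0.5 * (grid.lat_min + grid.lat_max)
    cx = 0.5 * (grid.lon_min + grid.lon_max)
    ry = fill * 0.5 * (grid.lat_max - grid.lat_min)
    rx = fill * 0.5 * (grid.lon_max - grid.lon_min)
    mask = ((la - cy) / ry) ** 2 + ((lo - cx) / rx) ** 2 <= 1.0
    if not mask.any():
        raise ConfigurationError("land mask is empty for this grid")
    return mask


def zone_ids(grid: GridSpec, mask: np.ndarray, k: int) -> np.ndarray:
    """k x k rectangular partition of the bounding box into synthetic 'states'.

    Returns an int array; ocean cells get -1.  Zone z = row*k + col counted
    from the south-west corner.
    """
    if k <= 0:
        raise ConfigurationError("zone partition k must be positive")
    la, lo = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    row = np.clip(((la - grid.lat_min) / (grid.lat_max - grid.lat_min) * k).astype(int), 0, k - 1)
    col = np.clip(((lo - grid.lon_min) / (grid.lon_max - grid.lon_min) * k).astype(int), 0, k - 1)
    z = row * k + col
    return np.where(mask, z, -1)


def downscale(
    coarse: GriddedField,
    target: GridSpec,
    target_mask: np.ndarray | None = None,
    method: str = "linear",
) -> GriddedField:
    """Statistically downscale a coarse field to `target` cell centres.

    Bilinear interpolation of cell-centre values (the default); nearest
    neighbour available via ``method="nearest"``.  Intensive quantities
    only — no area re-weighting of totals is performed.
    """
    lats, lons = coarse.grid.lats, coarse.grid.lons
    tlat, tlon = target.lats, target.lons
    if tlat.min() < lats.min() or tlat.max() > lats.max() or tlon.min() < lons.min() or tlon.max() > lons.max():
        raise DomainError(
            "target grid extends beyond the coarse field's cell-centre coverage"
        )
    interp = RegularGridInterpolator((lats, lons), coarse.values, method=method)
    pts_la, pts_lo = np.meshgrid(tlat, tlon, indexing="ij")
    vals = interp(np.stack([pts_la.ravel(), pts_lo.ravel()], axis=-1)).reshape(target.shape)
    if target_mask is None:
        target_mask = np.ones(target.shape, dtype=bool)
    return GriddedField(vals, coarse.units, target_mask, target)
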