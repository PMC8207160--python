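"""Scale of effect and buffer-based habitat amount on binary rasters.

The scale of effect — the landscape radius at which habitat amount best
predicts a biological response — is derived from home-range area HR:
linear distance LD = sqrt(HR), maximum dispersal distance MDD = 40 * LD, and
the candidate radius band is 30-50% of MDD.  Habitat amount is the
percentage of habitat cells among raster cells whose center falls within a
circular buffer around a site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScaleEffect",
    "scale_effect",
    "HabitatRaster",
    "habitat_amount",
    "site_landscape_table",
]


@dataclass(frozen=True)
class ScaleEffect:
    """Scale-of-effect distances derived from a home range (all meters;
    home_range in square meters).  Values are unrounded; use
    :meth:`rounded` for reporting to one decimal."""

    home_range: float
    linear_distance: float
    mdd: float
    scale_min: float
    scale_max: float

    def rounded(self) -> "ScaleEffect":
        return ScaleEffect(*(round(v, 1) for v in (
            self.home_range, self.linear_distance, self.mdd,
            self.scale_min, self.scale_max,
        )))


def scale_effect(home_range_m2: float) -> ScaleEffect:
    """Scale-of-effect band from a home-range area.

    LD = sqrt(HR); MDD = 40 * LD (computed from the unrounded LD);
    scale_min = 0.30 * MDD; scale_max = 0.50 * MDD.
    """
    if not np.isfinite(home_range_m2) or home_range_m2 <= 0:
        raise ValueError("home range must be a positive area in m^2")
    ld = float(np.sqrt(home_range_m2))
    mdd = 40.0 * ld
    return ScaleEffect(
        home_range=float(home_range_m2),
        linear_distance=ld,
        mdd=mdd,
        scale_min=0.30 * mdd,
        scale_max=0.50 * mdd,
    )


@dataclass
class HabitatRaster:
    """Binary habitat grid on a planar (meters) coordinate system.

    ``grid[0, 0]`` is the south-west (bottom-left) cell; row index increases
    northwards.  ``origin`` is the (x, y) of the lower-left corner of the
    lower-left cell.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("grid cells must be 0 or 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.grid = grid.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def habitat_fraction(self) -> float:
        return float(self.grid.mean())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centers, aligned with grid."""
        rows, cols = self.grid.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def center(self) -> tuple[float, float]:
        rows, cols = self.grid.shape
        return (
            self.origin[0] + cols * self.cell_size / 2.0,
            self.origin[1] + rows * self.cell_size / 2.0,
        )

    def complement(self) -> "HabitatRaster":
        return HabitatRaster(1 - self.grid, self.cell_size, self.origin)

    # -- plain-text persistence (grid file + JSON metadata sidecar) -------
    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.grid[::-1], fmt="%d")  # write top row first
        meta = {
            "cell_size_m": self.cell_size,
            "origin_x": self.origin[0],
            "origin_y": self.origin[1],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "HabitatRaster":
        path = Path(path)
        grid = np.loadtxt(path, dtype=int)[::-1]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(grid, meta["cell_size_m"], (meta["origin_x"], meta["origin_y"]))


def habitat_amount(
    raster: HabitatRaster,
    site_xy: tuple[float, float],
    radius_m: float,
    coverage_warn: float = 0.99,
) -> float:
    """Percentage of habitat within a circular buffer around a site.

    A cell belongs to the buffer when its *center* lies within ``radius_m``
    of the site.  Cells outside the raster extent are excluded from both
    counts; if the raster covers less than ``coverage_warn`` of the circle's
    area a warning is emitted.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    X, Y = raster.cell_centers()
    inside = (X - site_xy[0]) ** 2 + (Y - site_xy[1]) ** 2 <= radius_m**2
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("buffer contains no raster cells (circle off the raster?)")
    covered_area = n_in * raster.cell_size**2
    circle_area = np.pi * radius_m**2
    if covered_area / circle_area < coverage_warn:
        warnings.warn(
            f"buffer at {site_xy} r={radius_m}m: only "
            f"{100 * covered_area / circle_area:.1f}% of the circle is covered "
            "by the raster",
            stacklevel=2,
        )
    habitat = int(raster.grid[inside].sum())
    return 100.0 * habitat / n_in


def site_landscape_table(
    rasters: dict[str, HabitatRaster],
    sites: pd.DataFrame,
    radii: list[float],
) -> pd.DataFrame:
    """Habitat percentages per site and buffer radius.

    ``sites`` needs columns ``site_id``, ``x_m``, ``y_m``; each site's raster
    is looked up by ``site_id`` in ``rasters``.
    """
    rows = []
    for _, site in sites.iterrows():
        raster = rasters[site["site_id"]]
        row = {"site_id": site["site_id"]}
        for r in radii:
            row[f"habitat_pct_{int(round(r))}m"] = habitat_amount(
                raster, (site["x_m"], site["y_m"]), r
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")
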