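"""Core raster containers.

A :class:`Grid` is a single rectangular raster layer on a planar,
axis-aligned lattice.  The coordinate convention throughout the package is
x increasing to the right and y increasing *downward* from the top-left
corner of the top-left cell, with cell-centre registration for point
sampling: a point (x, y) falls in column ``floor((x - x0) / cell_size)``
and row ``floor((y - y0) / cell_size)`` (half-open cell intervals).

Sea / missing data is held internally as NaN; the ``nodata`` attribute is
the sentinel used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Grid", "EnvStack", "ProtectedAreas"]

#: bioclim layers dropped from variable selection because the source
#: surfaces carry interpolation artefacts (banding / saturation).
EXCLUDED_BIOCLIM = frozenset({"BIO2", "BIO3", "BIO8", "BIO9", "BIO15"})

#: temperature *level* layers: shifted under warming scenarios.
TEMPERATURE_LEVEL_LAYERS = frozenset(
    {"BIO1", "BIO5", "BIO6", "BIO8", "BIO9", "BIO10", "BIO11"}
)


@dataclass
class Grid:
    """A single-band raster: values + cell geometry + nodata sentinel.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values as floats; NaN marks nodata (sea).
    cell_size : float
        Cell edge length in map units; strictly positive.
    origin : tuple of float
        (x0, y0) of the top-left corner of the top-left cell.
    nodata : float
        Sentinel written to disk in place of NaN.
    crs_label : str
        Free-text tag describing the (planar) coordinate system.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    crs_label: str = "local-planar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Points outside the grid get out-of-range indices; callers decide
        whether that is an error or a drop.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    # -- masks --------------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data (land)."""
        return np.isfinite(self.values)

    @property
    def n_land(self) -> int:
        return int(self.mask.sum())

    def land_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, values: np.ndarray) -> "Grid":
        """A new grid sharing this grid's geometry with different values."""
        return replace(self, values=np.asarray(values, dtype=float))


def _check_registered(layers: Mapping[str, Grid]) -> None:
    grids = list(layers.values())
    for g in grids[1:]:
        if not grids[0].same_geometry(g):
            raise ValueError("all layers of an EnvStack must share shape/cell_size/origin")


@dataclass
class EnvStack:
    """Named set of co-registered raster layers for one period / climate model.

    ``excluded`` lists layer names generated for completeness but barred
    from variable selection (artefact-flagged bioclim surfaces).
    """

    layers: dict[str, Grid]
    period: str = "present"
    rcm: str = "observed"
    excluded: frozenset[str] = field(default_factory=lambda: frozenset(EXCLUDED_BIOCLIM))

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        _check_registered(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    @property
    def template(self) -> Grid:
        """Any layer, as a geometry template."""
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def selectable_names(self) -> list[str]:
        """Layer names eligible for variable selection."""
        return [n for n in self.layers if n not in self.excluded]

    def subset(self, names) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers missing from stack: {missing}")
        return EnvStack(
            layers={n: self.layers[n] for n in names},
            period=self.period,
            rcm=self.rcm,
            excluded=self.excluded,
        )


@dataclass
class ProtectedAreas:
    """Boolean protection masks per network (e.g. nature reserves vs plant areas)."""

    masks: dict[str, Grid]

    def __post_init__(self) -> None:
        if self.masks:
            _check_registered(self.masks)

    def __getitem__(self, network: str) -> Grid:
        if network not in self.masks:
            raise KeyError(
                f"unknown protected-area network {network!r}; have {sorted(self.masks)}"
            )
        return self.masks[network]

    @property
    def networks(self) -> list[str]:
        return list(self.masks)
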