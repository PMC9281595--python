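"""Multi-period suitability stacking into climate-stability (refugia) layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridTransform, SuitabilityMap, write_ascii_grid

__all__ = ["StabilityMap", "binarize", "stability_stack", "refugia_report"]


@dataclass
class StabilityMap:
    """Per-cell count of periods in which the cell was suitable."""

    grid: np.ndarray  # integer counts, -1 = nodata
    transform: GridTransform
    period_count: int
    crs: str = "EPSG:4326"
    nodata: int = -1

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def write(self, path) -> None:
        write_ascii_grid(path, self.grid.astype(float), self.transform,
                         nodata=float(self.nodata))


def binarize(smap: SuitabilityMap, midpoint: float = 0.5) -> SuitabilityMap:
    """Hard-threshold a suitability map; cells >= midpoint become 1.

    The tie at exactly ``midpoint`` is inclusive (counts as suitable).
    """
    if not 0 < midpoint < 1:
        raise ValueError("midpoint must lie in (0, 1)")
    valid = smap.valid_mask
    out = np.where(valid, (smap.grid >= midpoint).astype(float), smap.nodata)
    return SuitabilityMap(grid=out, transform=smap.transform, crs=smap.crs,
                          nodata=smap.nodata, period=smap.period)


def stability_stack(binary_maps: list[SuitabilityMap]) -> StabilityMap:
    """Per-cell sum of aligned binary maps; nodata wherever any period is."""
    if len(binary_maps) < 2:
        raise ValueError("need at least two aligned maps")
    first = binary_maps[0]
    for m in binary_maps[1:]:
        if m.grid.shape != first.grid.shape or m.transform != first.transform:
            raise ValueError("maps are not aligned on one grid")
    valid = np.logical_and.reduce([m.valid_mask for m in binary_maps])
    total = np.zeros(first.grid.shape, dtype=int)
    for m in binary_maps:
        total += np.where(valid, m.grid.astype(int), 0)
    grid = np.where(valid, total, -1)
    return StabilityMap(grid=grid, transform=first.transform,
                        period_count=len(binary_maps), crs=first.crs)


def refugia_report(stab: StabilityMap, threshold: int | None = None) -> dict:
    """Histogram of stability classes plus refugium count/fraction at
    ``threshold`` (default: suitable in every period)."""
    if threshold is None:
        threshold = stab.period_count
    if not 0 < threshold <= stab.period_count:
        raise ValueError("threshold must be in (0, period_count]")
    vals = stab.grid[stab.valid_mask]
    hist = {int(c): int((vals == c).sum()) for c in range(stab.period_count + 1)}
    n_valid = int(vals.size)
    n_refugia = int((vals >= threshold).sum())
    return {
        "period_count": stab.period_count,
        "threshold": threshold,
        "n_valid_cells": n_valid,
        "n_refugium_cells": n_refugia,
        "refugium_fraction": (n_refugia / n_valid) if n_valid else 0.0,
        "histogram": hist,
    }
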