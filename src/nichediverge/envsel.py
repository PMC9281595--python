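"""Environmental extraction, background regions, VIF selection, PCA."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet, haversine_km
from .raster import ClimateStack

__all__ = [
    "BackgroundRegion",
    "extract_env",
    "background_points",
    "vif",
    "stepwise_select",
    "pca_env",
    "PCAResult",
]

logger = logging.getLogger(__name__)

# Variable set retained by the default selection workflow; used as the
# downstream default when no stepwise pass is run.
DEFAULT_SELECTED = ["BIO8", "BIO9", "BIO10", "BIO11", "BIO12", "BIO15", "BIO18"]


@dataclass
class BackgroundRegion:
    """Union of great-circle buffers of ``radius_km`` around anchor points."""

    taxon: str
    radius_km: float
    anchors: np.ndarray  # (n, 2) lon/lat

    def __post_init__(self) -> None:
        self.anchors = np.atleast_2d(np.asarray(self.anchors, dtype=float))
        if self.anchors.shape[0] == 0:
            raise ValueError("background region needs at least one anchor point")
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")

    @classmethod
    def from_occurrences(cls, occ: OccurrenceSet, radius_km: float,
                         taxon: str | None = None) -> "BackgroundRegion":
        if taxon is not None:
            occ = occ.subset(taxon)
        name = taxon if taxon is not None else "+".join(occ.taxa)
        return cls(taxon=name, radius_km=radius_km, anchors=occ.coords())

    def contains(self, lon, lat) -> np.ndarray:
        """Membership = within radius_km of any anchor (great circle).

        Chunked over anchors to bound memory on large grids.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        pts = np.stack([lon, lat], axis=-1)
        inside = np.zeros(len(pts), dtype=bool)
        todo = np.arange(len(pts))
        for start in range(0, len(self.anchors), 256):
            chunk = self.anchors[start:start + 256]
            if todo.size == 0:
                break
            d = haversine_km(pts[todo, None, :], chunk[None, :, :])
            hit = (d <= self.radius_km).any(axis=1)
            inside[todo[hit]] = True
            todo = todo[~hit]
        return inside

    def union(self, other: "BackgroundRegion") -> "BackgroundRegion":
        if self.radius_km != other.radius_km:
            raise ValueError("cannot union regions with different radii")
        return BackgroundRegion(
            taxon=f"{self.taxon}+{other.taxon}",
            radius_km=self.radius_km,
            anchors=np.vstack([self.anchors, other.anchors]),
        )

    def to_geojson(self, path, n_vertices: int = 64) -> None:
        """Approximate polygon export (per-anchor circles unioned)."""
        from shapely.geometry import Polygon, mapping
        from shapely.ops import unary_union

        circles = []
        for lon, lat in self.anchors:
            # local degree radii for a metrically honest circle
            dlat = self.radius_km / 111.19492664455873
            dlon = dlat / max(np.cos(np.radians(lat)), 1e-6)
            theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
            ring = [(lon + dlon * np.cos(t), lat + dlat * np.sin(t)) for t in theta]
            circles.append(Polygon(ring))
        geom = unary_union(circles)
        feature = {
            "type": "Feature",
            "properties": {"taxon": self.taxon, "radius_km": self.radius_km},
            "geometry": mapping(geom),
        }
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def extract_env(occ: OccurrenceSet, stack: ClimateStack,
                variables: list[str] | None = None) -> pd.DataFrame:
    """One row per occurrence with per-layer values at the containing cell.

    Points outside the extent or on nodata cells are dropped with a warning.
    Returns a DataFrame with ``taxon``, ``lon``, ``lat``, ``label`` and one
    column per layer.
    """
    vals = stack.extract(occ.data["lon"].to_numpy(), occ.data["lat"].to_numpy())
    table = occ.data[["taxon", "lon", "lat"]].reset_index(drop=True).copy()
    for j, name in enumerate(stack.layer_names):
        table[name] = vals[:, j]
    bad = table[stack.layer_names].isna().any(axis=1)
    if bad.all():
        raise ValueError("all points fall outside the raster or on nodata")
    if bad.any():
        logger.warning("dropping %d points on nodata/outside extent", int(bad.sum()))
        table = table[~bad].reset_index(drop=True)
    table.insert(3, "label", "presence")
    if variables is not None:
        table = table[["taxon", "lon", "lat", "label"] + list(variables)]
    return table


def background_points(region: BackgroundRegion, stack: ClimateStack, n: int,
                      seed: int | None = None) -> OccurrenceSet:
    """``n`` points uniform over non-nodata cells inside the region."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = stack.valid_cell_table()
    inside = region.contains(cells["lon"].to_numpy(), cells["lat"].to_numpy())
    cells = cells[inside]
    if len(cells) == 0:
        raise ValueError("background region covers no valid raster cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cells), size=n)
    chosen = cells.iloc[idx]
    return _as_background_set(region.taxon, chosen)


def _as_background_set(taxon: str, cells: pd.DataFrame) -> OccurrenceSet:
    df = pd.DataFrame({
        "taxon": taxon,
        "lon": cells["lon"].to_numpy(),
        "lat": cells["lat"].to_numpy(),
    })
    occ = OccurrenceSet.__new__(OccurrenceSet)
    occ.data = df.reset_index(drop=True)  # skip dedup: repeated draws are valid
    return occ


def vif(table: pd.DataFrame, variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j).

    R²_j comes from an OLS regression of variable j on the remaining
    variables (with intercept). Perfect collinearity yields +inf.
    """
    variables = _numeric_variables(table, variables)
    if len(variables) < 2:
        raise ValueError("VIF needs at least two variables")
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than variables")
    out = {}
    for j, name in enumerate(variables):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def stepwise_select(candidates: list[str], seed_set: list[str],
                    table: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Greedy forward VIF screen.

    Starting from ``seed_set``, each candidate (in order) is tentatively
    added; if any VIF in the augmented set exceeds ``threshold`` the
    newcomer is rejected. Seed variables flagged above threshold are kept
    but logged.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    missing = [v for v in seed_set if v not in table.columns]
    if missing:
        raise ValueError(f"seed variables absent from table: {missing}")
    selected = list(seed_set)
    if len(selected) >= 2:
        flagged = vif(table, selected)
        high = flagged[flagged > threshold]
        if len(high):
            logger.warning("seed variables above VIF threshold: %s",
                           ", ".join(high.index))
    for cand in candidates:
        if cand in selected:
            continue
        if cand not in table.columns:
            raise ValueError(f"candidate variable {cand!r} absent from table")
        trial = selected + [cand]
        trial_vif = vif(table, trial)
        if (trial_vif > threshold).any():
            logger.info("rejecting %s (max VIF %.2f)", cand, trial_vif.max())
            continue
        selected = trial
    return selected


@dataclass
class PCAResult:
    scores: pd.DataFrame       # columns PC1.., plus taxon/label carried over
    loadings: pd.DataFrame     # variables x components
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    variables: list[str]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.variables].to_numpy(dtype=float)
        Z = (X - self.center) / self.scale
        return Z @ self.loadings.to_numpy()


def pca_env(table: pd.DataFrame, variables: list[str] | None = None) -> PCAResult:
    """PCA of the normalised (unit-variance) variables via SVD."""
    variables = _numeric_variables(table, variables)
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] < len(variables):
        raise ValueError("need at least as many rows as variables")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s): {[variables[i] for i in zero]}")
    Z = (X - center) / scale
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s ** 2
    evr = eig / eig.sum()
    comps = vt.T
    scores = Z @ comps
    cols = [f"PC{i + 1}" for i in range(comps.shape[1])]
    score_df = pd.DataFrame(scores, columns=cols)
    for meta in ("taxon", "label"):
        if meta in table.columns:
            score_df[meta] = table[meta].to_numpy()
    loadings = pd.DataFrame(comps, index=variables, columns=cols)
    return PCAResult(
        scores=score_df,
        loadings=loadings,
        explained_variance_ratio=evr,
        center=center,
        scale=scale,
        variables=variables,
    )


def _numeric_variables(table: pd.DataFrame, variables: list[str] | None) -> list[str]:
    if variables is not None:
        return list(variables)
    skip = {"taxon", "lon", "lat", "label", "row", "col"}
    return [c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
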