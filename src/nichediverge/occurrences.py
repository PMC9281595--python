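"""Occurrence records: reading, validation, spatial thinning, filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceSet",
    "read_occurrences",
    "haversine_km",
    "thin",
    "filter_taxa_min_n",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class OccurrenceSet:
    """Taxon-labelled georeferenced presence points.

    ``data`` holds columns ``taxon``, ``lon``, ``lat`` and optionally
    ``source``. Construction validates coordinate ranges and drops exact
    (taxon, lon, lat) duplicates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("taxon", "lon", "lat"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        df = df.copy()
        df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
        df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
        bad = (
            df["lon"].isna()
            | df["lat"].isna()
            | (df["lon"] < -180)
            | (df["lon"] > 180)
            | (df["lat"] < -90)
            | (df["lat"] > 90)
            | df["taxon"].astype(str).str.strip().eq("")
        )
        if bad.any():
            logger.warning("dropping %d invalid occurrence rows", int(bad.sum()))
            df = df[~bad]
        before = len(df)
        df = df.drop_duplicates(subset=["taxon", "lon", "lat"])
        if len(df) < before:
            logger.info("deduplicated %d exact duplicate rows", before - len(df))
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.data["taxon"].unique())

    def counts(self) -> pd.Series:
        return self.data["taxon"].value_counts()

    def subset(self, taxon: str) -> "OccurrenceSet":
        return OccurrenceSet(self.data[self.data["taxon"] == taxon].copy())

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return self.data[["lon", "lat"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_occurrences(path, taxon_col: str = "taxon", lon_col: str = "lon",
                     lat_col: str = "lat") -> OccurrenceSet:
    """Read a CSV of presence records; invalid rows are logged and dropped."""
    df = pd.read_csv(path)
    for col in (taxon_col, lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(f"input CSV lacks required column {col!r}")
    renames = {taxon_col: "taxon", lon_col: "lon", lat_col: "lat"}
    df = df.rename(columns=renames)
    keep = ["taxon", "lon", "lat"] + (["source"] if "source" in df.columns else [])
    return OccurrenceSet(df[keep])


def haversine_km(a, b) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points.

    ``a`` and ``b`` may be single points or broadcastable arrays of shape
    (..., 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(coords: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix for an (n, 2) array of (lon, lat)."""
    coords = np.asarray(coords, dtype=float)
    return haversine_km(coords[:, None, :], coords[None, :, :])


def _thin_once(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One greedy pass: repeatedly drop a max-conflict point (random ties)."""
    adj = adj.copy()
    alive = np.ones(adj.shape[0], dtype=bool)
    degrees = adj.sum(axis=1)
    while True:
        max_deg = degrees[alive].max() if alive.any() else 0
        if max_deg == 0:
            break
        cand = np.flatnonzero(alive & (degrees == max_deg))
        victim = cand[rng.integers(len(cand))]
        alive[victim] = False
        degrees -= adj[victim]
        adj[victim, :] = 0
        adj[:, victim] = 0
        degrees[victim] = 0
    return np.flatnonzero(alive)


def thin(occ: OccurrenceSet, min_km: float, reps: int = 100, seed: int | None = None,
         group_col: str = "taxon") -> OccurrenceSet:
    """Spatially thin records so no retained pair within a group is closer
    than ``min_km`` (great circle).

    Per group: ``reps`` randomized runs of the max-degree-removal heuristic;
    the run retaining the most points wins.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(occ) == 0:
        return occ
    rng = np.random.default_rng(seed)
    kept_frames = []
    for _, group in occ.data.groupby(group_col, sort=True):
        coords = group[["lon", "lat"]].to_numpy(dtype=float)
        n = len(coords)
        if n == 1:
            kept_frames.append(group)
            continue
        dist = pairwise_haversine_km(coords)
        adj = (dist < min_km).astype(np.int64)
        np.fill_diagonal(adj, 0)
        if adj.sum() == 0:
            kept_frames.append(group)
            continue
        best: np.ndarray | None = None
        for _ in range(reps):
            kept = _thin_once(adj, rng)
            if best is None or len(kept) > len(best):
                best = kept
        kept_frames.append(group.iloc[np.sort(best)])
    out = pd.concat(kept_frames, axis=0).reset_index(drop=True)
    logger.info("thinning retained %d of %d records", len(out), len(occ))
    return OccurrenceSet(out)


def filter_taxa_min_n(occ: OccurrenceSet, min_n: int) -> OccurrenceSet:
    """Drop every taxon with fewer than ``min_n`` records."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = occ.counts()
    keep_taxa = counts[counts >= min_n].index
    dropped = sorted(set(counts.index) - set(keep_taxa))
    if dropped:
        logger.info("excluding taxa below n=%d: %s", min_n, ", ".join(dropped))
    return OccurrenceSet(occ.data[occ.data["taxon"].isin(keep_taxa)].copy())
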