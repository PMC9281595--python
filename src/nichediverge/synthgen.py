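"""Synthetic landscapes, virtual species, occurrence samples and traits.

Everything downstream (thinning, variable selection, niche models, overlap
tests, refugia stacking, phylogenetic signal) can be exercised on data
generated here, with known ground truth and full seed control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .occurrences import OccurrenceSet
from .raster import ClimateStack, GridTransform

import pandas as pd

__all__ = [
    "DEFAULT_LAYERS",
    "VirtualSpecies",
    "make_climate_stack",
    "make_virtual_species",
    "sample_occurrences",
    "simulate_bm_traits",
    "make_paleo_series",
]

# Default layer set mirrors the seven low-collinearity bioclim variables used
# downstream: temperatures of the wettest/driest/warmest/coldest quarters,
# annual precipitation, precipitation seasonality, precipitation of the
# warmest quarter.
DEFAULT_LAYERS = ["BIO8", "BIO9", "BIO10", "BIO11", "BIO12", "BIO15", "BIO18"]


@dataclass
class VirtualSpecies:
    """A species whose true suitability is a known function of the layers."""

    name: str
    stack: ClimateStack
    true_coefficients: dict[str, float]
    intercept: float
    true_suitability: np.ndarray  # (rows, cols), NaN on nodata
    occurrences: OccurrenceSet | None = None


def make_climate_stack(n_rows: int, n_cols: int,
                       layer_names: list[str] | None = None,
                       spatial_range: float = 5.0,
                       cross_corr: np.ndarray | None = None,
                       seed: int | None = None,
                       transform: GridTransform | None = None) -> ClimateStack:
    """Gaussian-random-field climate layers with controlled cross-correlation.

    Independent white-noise fields are smoothed with a Gaussian kernel of sd
    ``spatial_range`` cells, standardized, then linearly mixed through the
    Cholesky factor of ``cross_corr`` so the inter-layer correlation matrix
    approximates the request. Deterministic given ``seed``.
    """
    if layer_names is None:
        layer_names = list(DEFAULT_LAYERS)
    k = len(layer_names)
    if cross_corr is None:
        cross_corr = np.eye(k)
    cross_corr = np.asarray(cross_corr, dtype=float)
    if cross_corr.shape != (k, k):
        raise ValueError("cross_corr dimension must match len(layer_names)")
    if not np.allclose(cross_corr, cross_corr.T, atol=1e-10):
        raise ValueError("cross_corr must be symmetric")
    eigvals = np.linalg.eigvalsh(cross_corr)
    if eigvals.min() < -1e-10:
        raise ValueError("cross_corr must be positive semi-definite")
    if spatial_range <= 0:
        raise ValueError("spatial_range must be positive")

    rng = np.random.default_rng(seed)
    fields = np.empty((k, n_rows * n_cols))
    for j in range(k):
        noise = rng.standard_normal((n_rows, n_cols))
        f = gaussian_filter(noise, sigma=spatial_range, mode="wrap")
        fields[j] = (f - f.mean()).ravel()
    # Smoothing leaves few effective degrees of freedom, so empirically
    # whiten the fields before mixing; the realized inter-layer correlation
    # then matches the request up to numerical error.
    cov = fields @ fields.T / fields.shape[1]
    white = np.linalg.solve(np.linalg.cholesky(cov), fields)
    # PSD-safe mixing root (handles semi-definite cross_corr)
    w, v = np.linalg.eigh(cross_corr)
    mix = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    mixed = (mix @ white).reshape(k, n_rows, n_cols)
    grid = np.moveaxis(mixed, 0, -1)
    if transform is None:
        # ~0.05 degree cells centred on the origin
        transform = GridTransform(
            x_origin=-n_cols * 0.05 / 2.0,
            y_origin=n_rows * 0.05 / 2.0,
            dx=0.05,
            dy=0.05,
        )
    return ClimateStack(layer_names=list(layer_names), grid=grid, transform=transform)


def make_virtual_species(stack: ClimateStack, coefficients: dict[str, float],
                         intercept: float = 0.0,
                         name: str = "virtual") -> VirtualSpecies:
    """Suitability = logistic(intercept + sum_j coef_j * z_j) with z the
    per-layer standardized values over valid cells."""
    unknown = set(coefficients) - set(stack.layer_names)
    if unknown:
        raise ValueError(f"unknown layer names: {sorted(unknown)}")
    valid = stack.valid_mask
    logit = np.full(stack.shape, float(intercept))
    for name_j, coef in coefficients.items():
        layer = stack.layer(name_j)
        vals = layer[valid]
        z = np.zeros_like(layer)
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"layer {name_j!r} is constant; cannot standardize")
        z[valid] = (layer[valid] - vals.mean()) / sd
        logit = logit + coef * z
    suit = expit(logit)
    suit = np.where(valid, suit, np.nan)
    return VirtualSpecies(
        name=name,
        stack=stack,
        true_coefficients=dict(coefficients),
        intercept=float(intercept),
        true_suitability=suit,
    )


def sample_occurrences(vs: VirtualSpecies, n: int, seed: int | None = None) -> OccurrenceSet:
    """Draw ``n`` presence points, cells weighted by true suitability.

    Distinct cells are drawn without replacement (probability proportional to
    suitability among the remaining cells) and points are placed at cell
    centers, so exactly ``n`` unique records come back. Errors when ``n``
    exceeds the number of positive-suitability cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stack = vs.stack
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    weights = vs.true_suitability[rows, cols]
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    n_positive = int((weights > 0).sum())
    if n > n_positive:
        raise ValueError(
            f"n={n} exceeds the {n_positive} non-nodata cells with positive suitability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False, p=weights / total)
    lon, lat = stack.transform.cell_center(rows[idx], cols[idx])
    occ = OccurrenceSet(pd.DataFrame({"taxon": vs.name, "lon": lon, "lat": lat}))
    vs.occurrences = occ
    return occ


def simulate_bm_traits(tree, sigma2: float, root_state: float = 0.0,
                       seed: int | None = None,
                       n_reps: int = 1) -> pd.DataFrame:
    """Brownian-motion tip values on a dendropy tree.

    Tip values are multivariate normal with mean ``root_state`` and
    covariance ``sigma2 * C`` where C is the shared-path-length matrix.
    Returns a DataFrame with one row per replicate, columns = taxon labels.
    """
    from .physig import phylo_vcv

    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C, labels = phylo_vcv(tree)
    if np.all(C == 0):
        raise ValueError("tree has zero depth; traits undefined")
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        vals = np.full((n_reps, len(labels)), root_state)
    else:
        # eigh root: robust to the singular C of trees with zero-length splits
        w, v = np.linalg.eigh(C)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((n_reps, len(labels)))
        vals = root_state + np.sqrt(sigma2) * z @ root.T
    return pd.DataFrame(vals, columns=labels)


def make_paleo_series(stack: ClimateStack,
                      per_period_offsets: list[dict[str, float]],
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      labels: list[str] | None = None) -> list[ClimateStack]:
    """Paleo stand-ins: base layers plus per-period additive shifts."""
    rng = np.random.default_rng(seed)
    out = []
    valid = stack.valid_mask
    for i, offsets in enumerate(per_period_offsets):
        unknown = set(offsets) - set(stack.layer_names)
        if unknown:
            raise ValueError(f"offset names not in stack: {sorted(unknown)}")
        grid = stack.grid.copy()
        for j, name in enumerate(stack.layer_names):
            shift = offsets.get(name, 0.0)
            layer = grid[:, :, j]
            add = np.full(stack.shape, shift)
            if noise_sd > 0:
                add = add + rng.normal(0.0, noise_sd, size=stack.shape)
            layer[valid] += add[valid]
        out.append(stack.with_grid(grid))
    return out
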