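"""Niche comparison machinery: overlap indices and permutation tests.

All tests operate on presence-background maxent models (or kernel occupancy
surfaces in the ordination flavour) fit to two taxa over a shared background,
and derive significance from permutation nulls under the (r+1)/(n+1) rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, spearmanr

from . import envsel
from .maxent import FeatureBuilder, FeatureSpec, MaxentModel, fit_maxent
from .occurrences import OccurrenceSet, haversine_km

__all__ = [
    "FitConfig",
    "NicheComparison",
    "OccupancySurface",
    "schoener_d",
    "lhs_overlap",
    "identity_test",
    "background_test",
    "rangebreak_linear",
    "rangebreak_blob",
    "build_occupancy",
    "ordination_equivalency",
    "ordination_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class NicheComparison:
    """Observed overlap, permutation null and p-value for one test."""

    test_name: str
    d_observed: float
    null_d: np.ndarray
    p_value: float
    n_reps: int
    direction: str  # lower | upper | two-sided
    rho: float | None = None
    p_lower: float | None = None
    p_upper: float | None = None

    def summary(self) -> dict:
        out = {
            "test": self.test_name,
            "D": self.d_observed,
            "rho": self.rho,
            "p": self.p_value,
            "n_reps": self.n_reps,
            "direction": self.direction,
        }
        if self.p_lower is not None:
            out["p_lower"] = self.p_lower
            out["p_upper"] = self.p_upper
        return out


@dataclass
class FitConfig:
    """How models inside the permutation tests are fit.

    ``background`` is the shared background environment table (rows =
    background cells/points, columns = variables); observed and null D are
    evaluated over these rows.
    """

    background: pd.DataFrame
    variables: list[str] | None = None
    spec: FeatureSpec = field(default_factory=lambda: FeatureSpec("LQ"))
    rm: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6

    def resolved_variables(self) -> list[str]:
        if self.variables is not None:
            return list(self.variables)
        skip = {"taxon", "lon", "lat", "label", "row", "col"}
        return [c for c in self.background.columns
                if c not in skip
                and pd.api.types.is_numeric_dtype(self.background[c])]


def _p_values(observed: float, null: np.ndarray) -> tuple[float, float]:
    n = len(null)
    p_lower = (np.sum(null <= observed) + 1.0) / (n + 1.0)
    p_upper = (np.sum(null >= observed) + 1.0) / (n + 1.0)
    return float(p_lower), float(p_upper)


def schoener_d(pA, pB) -> float:
    """D = 1 - 0.5 * sum|pA - pB| after normalizing each to sum 1."""
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    if pA.shape != pB.shape:
        raise ValueError("distributions must have the same shape")
    if (pA < 0).any() or (pB < 0).any():
        raise ValueError("densities must be non-negative")
    sA, sB = pA.sum(), pB.sum()
    if sA <= 0 or sB <= 0:
        raise ValueError("each distribution needs at least one positive value")
    return float(1.0 - 0.5 * np.abs(pA / sA - pB / sB).sum())


def _latin_hypercube(ranges: dict[str, tuple[float, float]], n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for var, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {var}")
        if hi == lo:
            logger.warning("degenerate range for %s; held constant", var)
            cols[var] = np.full(n, lo)
            continue
        edges = np.linspace(lo, hi, n + 1)
        draws = edges[:-1] + rng.random(n) * (edges[1:] - edges[:-1])
        cols[var] = rng.permutation(draws)
    return pd.DataFrame(cols)


def lhs_overlap(modelA: MaxentModel, modelB: MaxentModel,
                variable_ranges: dict[str, tuple[float, float]],
                n_samples: int = 10_000, seed: int | None = None) -> tuple[float, float]:
    """Schoener's D and Spearman rho over a Latin hypercube of environment
    space, both models evaluated clamped."""
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    needed = set(modelA.variables) | set(modelB.variables)
    missing = needed - set(variable_ranges)
    if missing:
        raise ValueError(f"ranges missing for: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    sample = _latin_hypercube(variable_ranges, n_samples, rng)
    sA = modelA.predict(sample, output="logistic", clamp=True)
    sB = modelB.predict(sample, output="logistic", clamp=True)
    d = schoener_d(sA, sB)
    rho = float(spearmanr(sA, sB).statistic)
    return d, rho


# ---------------------------------------------------------------------------
# Model-based permutation tests
# ---------------------------------------------------------------------------


class _TestWorkspace:
    """Shared feature matrices for repeated refits over one background.

    The background features (the expensive part) are built once; each
    replicate only re-indexes pooled presence features and re-runs the
    optimizer.
    """

    def __init__(self, fit_config: FitConfig, pooled_env: pd.DataFrame):
        self.cfg = fit_config
        variables = fit_config.resolved_variables()
        self.builder = FeatureBuilder(variables, fit_config.spec).fit(
            fit_config.background, pooled_env)
        self.Fb = self.builder.transform(fit_config.background, clamp=False)
        self.F_pooled = self.builder.transform(pooled_env, clamp=True)

    def fit_rows(self, rows: np.ndarray) -> np.ndarray:
        """Fit on a subset of pooled rows; returns raw suitability over the
        shared background (sums to 1)."""
        res = fit_maxent(self.F_pooled[rows], self.Fb, rm=self.cfg.rm,
                         feature_classes=self.builder.feature_classes,
                         max_iter=self.cfg.max_iter, tol=self.cfg.tol)
        score = self.Fb @ res.lambdas if self.Fb.shape[1] else np.zeros(len(self.Fb))
        return np.exp(score - res.log_partition)

    def fit_features(self, F: np.ndarray) -> np.ndarray:
        res = fit_maxent(F, self.Fb, rm=self.cfg.rm,
                         feature_classes=self.builder.feature_classes,
                         max_iter=self.cfg.max_iter, tol=self.cfg.tol)
        score = self.Fb @ res.lambdas if self.Fb.shape[1] else np.zeros(len(self.Fb))
        return np.exp(score - res.log_partition)


def _env_of(occ_or_env, stack, variables=None) -> pd.DataFrame:
    """Accept either an OccurrenceSet (extracted against stack) or a ready
    environment table."""
    if isinstance(occ_or_env, OccurrenceSet):
        if stack is None:
            raise ValueError("a ClimateStack is required to extract occurrences")
        return envsel.extract_env(occ_or_env, stack, variables=variables)
    return occ_or_env


def identity_test(occA, occB, stack, fit_config: FitConfig, n_reps: int = 99,
                  seed: int | None = None) -> NicheComparison:
    """Niche identity (equivalency) test.

    Null: pooled occurrences randomly repartitioned into the original sample
    sizes, both models refit, D recomputed over the shared background.
    Lower-tail: identity is rejected when the observed overlap is smaller
    than the null overlaps.
    """
    envA = _env_of(occA, stack)
    envB = _env_of(occB, stack)
    nA, nB = len(envA), len(envB)
    if min(nA, nB) < 2:
        raise ValueError("each taxon needs at least 2 usable occurrences")
    pooled = pd.concat([envA, envB], axis=0).reset_index(drop=True)
    ws = _TestWorkspace(fit_config, pooled)
    idx = np.arange(nA + nB)
    qA = ws.fit_rows(idx[:nA])
    qB = ws.fit_rows(idx[nA:])
    d_obs = schoener_d(qA, qB)
    rho = float(spearmanr(qA, qB).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(nA + nB)
        null[r] = schoener_d(ws.fit_rows(perm[:nA]), ws.fit_rows(perm[nA:]))
    p_lower, p_upper = _p_values(d_obs, null)
    return NicheComparison(
        test_name="id", d_observed=d_obs, null_d=null, p_value=p_lower,
        n_reps=n_reps, direction="lower", rho=rho,
        p_lower=p_lower, p_upper=p_upper,
    )


def background_test(occA, regionB: envsel.BackgroundRegion, occB, stack,
                    fit_config: FitConfig, n_reps: int = 99,
                    seed: int | None = None,
                    direction: str = "two-sided") -> NicheComparison:
    """Niche background (similarity) test of A against B's background.

    Null: B's occurrences replaced by random points from B's background
    region, B refit, D against the fixed A model. Both one-sided p's are
    reported; ``direction`` picks the headline p-value.
    """
    if direction not in ("lower", "upper", "two-sided"):
        raise ValueError("direction must be lower, upper or two-sided")
    envA = _env_of(occA, stack)
    envB = _env_of(occB, stack)
    pooled = pd.concat([envA, envB], axis=0).reset_index(drop=True)
    ws = _TestWorkspace(fit_config, pooled)
    nA, nB = len(envA), len(envB)
    idx = np.arange(nA + nB)
    qA = ws.fit_rows(idx[:nA])
    qB = ws.fit_rows(idx[nA:])
    d_obs = schoener_d(qA, qB)
    rho = float(spearmanr(qA, qB).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        draw = envsel.background_points(
            regionB, stack, nB, seed=int(rng.integers(2 ** 31)))
        env_draw = envsel.extract_env(draw, stack)
        F = ws.builder.transform(env_draw, clamp=True)
        null[r] = schoener_d(qA, ws.fit_features(F))
    p_lower, p_upper = _p_values(d_obs, null)
    if direction == "lower":
        p = p_lower
    elif direction == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    return NicheComparison(
        test_name="bg", d_observed=d_obs, null_d=null, p_value=p,
        n_reps=n_reps, direction=direction, rho=rho,
        p_lower=p_lower, p_upper=p_upper,
    )


def _rangebreak(occA, occB, stack, fit_config: FitConfig, n_reps: int,
                seed: int | None, mode: str) -> NicheComparison:
    envA = _env_of(occA, stack)
    envB = _env_of(occB, stack)
    nA, nB = len(envA), len(envB)
    if min(nA, nB) < 2:
        raise ValueError("each group needs at least 2 usable occurrences")
    pooled = pd.concat([envA, envB], axis=0).reset_index(drop=True)
    coords = pooled[["lon", "lat"]].to_numpy(dtype=float)
    ws = _TestWorkspace(fit_config, pooled)
    idx = np.arange(nA + nB)
    qA = ws.fit_rows(idx[:nA])
    qB = ws.fit_rows(idx[nA:])
    d_obs = schoener_d(qA, qB)
    rho = float(spearmanr(qA, qB).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        if mode == "linear":
            pivot = coords[rng.integers(len(coords))]
            theta = rng.uniform(0.0, np.pi)
            proj = (np.cos(theta) * (coords[:, 0] - pivot[0])
                    + np.sin(theta) * (coords[:, 1] - pivot[1]))
            order = np.argsort(proj, kind="stable")
        else:  # blob
            seed_pt = coords[rng.integers(len(coords))]
            dist = haversine_km(coords, seed_pt)
            order = np.argsort(dist, kind="stable")
        groupA = order[:nA]
        groupB = order[nA:]
        null[r] = schoener_d(ws.fit_rows(groupA), ws.fit_rows(groupB))
    p_lower, p_upper = _p_values(d_obs, null)
    return NicheComparison(
        test_name="lin" if mode == "linear" else "blob",
        d_observed=d_obs, null_d=null, p_value=p_lower, n_reps=n_reps,
        direction="lower", rho=rho, p_lower=p_lower, p_upper=p_upper,
    )


def rangebreak_linear(occA, occB, stack, fit_config: FitConfig,
                      n_reps: int = 99, seed: int | None = None) -> NicheComparison:
    """Linear range-breaking test: null partitions are splits of the pooled
    points by a random line (random bearing through a random pooled point)."""
    return _rangebreak(occA, occB, stack, fit_config, n_reps, seed, "linear")


def rangebreak_blob(occA, occB, stack, fit_config: FitConfig,
                    n_reps: int = 99, seed: int | None = None) -> NicheComparison:
    """Blob range-breaking test: null group A is the nA nearest pooled points
    (great circle) around a random seed point."""
    return _rangebreak(occA, occB, stack, fit_config, n_reps, seed, "blob")


# ---------------------------------------------------------------------------
# Ordination ("occupancy surface") flavour
# ---------------------------------------------------------------------------


@dataclass
class OccupancySurface:
    """Availability-corrected occupancy density over two ordination axes."""

    z: np.ndarray       # R x R, sums to 1
    x_grid: np.ndarray
    y_grid: np.ndarray
    taxon: str = ""


def build_occupancy(occ_scores: np.ndarray, background_scores: np.ndarray,
                    R: int = 100, bandwidth=None, taxon: str = "",
                    extent=None) -> OccupancySurface:
    """Kernel occupancy surface on the first two ordination axes.

    z = occurrence density / availability density (0 where availability is
    0), normalized to sum 1 over the R x R grid spanning the background
    (or the supplied ``extent``).
    """
    occ_scores = np.asarray(occ_scores, dtype=float)[:, :2]
    background_scores = np.asarray(background_scores, dtype=float)[:, :2]
    if len(occ_scores) < 5:
        raise ValueError("need at least 5 occurrences for a kernel surface")
    if extent is None:
        x_lo, x_hi = background_scores[:, 0].min(), background_scores[:, 0].max()
        y_lo, y_hi = background_scores[:, 1].min(), background_scores[:, 1].max()
    else:
        x_lo, x_hi, y_lo, y_hi = extent
    x_grid = np.linspace(x_lo, x_hi, R)
    y_grid = np.linspace(y_lo, y_hi, R)
    xx, yy = np.meshgrid(x_grid, y_grid, indexing="ij")
    mesh = np.vstack([xx.ravel(), yy.ravel()])
    kde_occ = gaussian_kde(occ_scores.T, bw_method=bandwidth)
    kde_bg = gaussian_kde(background_scores.T, bw_method=bandwidth)
    occ_d = kde_occ(mesh).reshape(R, R)
    bg_d = kde_bg(mesh).reshape(R, R)
    avail = bg_d > bg_d.max() * 1e-6
    z = np.where(avail, occ_d / np.where(avail, bg_d, 1.0), 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy surface is identically zero")
    return OccupancySurface(z=z / total, x_grid=x_grid, y_grid=y_grid, taxon=taxon)


def _pooled_ordination(envA, envB, bgA, bgB, variables=None):
    bg = pd.concat([bgA, bgB], axis=0).reset_index(drop=True)
    pca = envsel.pca_env(bg, variables=variables)
    return (
        pca.transform(envA), pca.transform(envB),
        pca.transform(bgA), pca.transform(bgB),
    )


def ordination_equivalency(envA: pd.DataFrame, envB: pd.DataFrame,
                           bgA: pd.DataFrame, bgB: pd.DataFrame,
                           R: int = 100, n_reps: int = 99,
                           seed: int | None = None,
                           variables: list[str] | None = None,
                           bandwidth=None) -> NicheComparison:
    """Identity test on ordination occupancy surfaces (kernel densities on
    the first two PCs of the pooled backgrounds)."""
    sA, sB, sbgA, sbgB = _pooled_ordination(envA, envB, bgA, bgB, variables)
    pooled_bg = np.vstack([sbgA, sbgB])
    extent = (pooled_bg[:, 0].min(), pooled_bg[:, 0].max(),
              pooled_bg[:, 1].min(), pooled_bg[:, 1].max())
    zA = build_occupancy(sA, pooled_bg, R=R, bandwidth=bandwidth, extent=extent)
    zB = build_occupancy(sB, pooled_bg, R=R, bandwidth=bandwidth, extent=extent)
    d_obs = schoener_d(zA.z.ravel(), zB.z.ravel())
    pooled = np.vstack([sA, sB])
    nA = len(sA)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(pooled))
        za = build_occupancy(pooled[perm[:nA]], pooled_bg, R=R,
                             bandwidth=bandwidth, extent=extent)
        zb = build_occupancy(pooled[perm[nA:]], pooled_bg, R=R,
                             bandwidth=bandwidth, extent=extent)
        null[r] = schoener_d(za.z.ravel(), zb.z.ravel())
    p_lower, p_upper = _p_values(d_obs, null)
    return NicheComparison(
        test_name="id_ord", d_observed=d_obs, null_d=null, p_value=p_lower,
        n_reps=n_reps, direction="lower", p_lower=p_lower, p_upper=p_upper,
    )


def ordination_similarity(envA: pd.DataFrame, envB: pd.DataFrame,
                          bgA: pd.DataFrame, bgB: pd.DataFrame,
                          R: int = 100, n_reps: int = 99,
                          seed: int | None = None,
                          variables: list[str] | None = None,
                          bandwidth=None,
                          direction: str = "two-sided") -> NicheComparison:
    """Background test on ordination surfaces: null shifts B's occurrence
    cloud to random positions within B's background extent."""
    sA, sB, sbgA, sbgB = _pooled_ordination(envA, envB, bgA, bgB, variables)
    pooled_bg = np.vstack([sbgA, sbgB])
    extent = (pooled_bg[:, 0].min(), pooled_bg[:, 0].max(),
              pooled_bg[:, 1].min(), pooled_bg[:, 1].max())
    zA = build_occupancy(sA, pooled_bg, R=R, bandwidth=bandwidth, extent=extent)
    zB = build_occupancy(sB, pooled_bg, R=R, bandwidth=bandwidth, extent=extent)
    d_obs = schoener_d(zA.z.ravel(), zB.z.ravel())
    rng = np.random.default_rng(seed)
    b_lo = sbgB[:, :2].min(axis=0)
    b_hi = sbgB[:, :2].max(axis=0)
    centroid = sB[:, :2].mean(axis=0)
    null = np.empty(n_reps)
    for r in range(n_reps):
        target = b_lo + rng.random(2) * (b_hi - b_lo)
        shifted = sB[:, :2] + (target - centroid)
        zb = build_occupancy(shifted, pooled_bg, R=R, bandwidth=bandwidth,
                             extent=extent)
        null[r] = schoener_d(zA.z.ravel(), zb.z.ravel())
    p_lower, p_upper = _p_values(d_obs, null)
    if direction == "lower":
        p = p_lower
    elif direction == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    return NicheComparison(
        test_name="bg_ord", d_observed=d_obs, null_d=null, p_value=p,
        n_reps=n_reps, direction=direction, p_lower=p_lower, p_upper=p_upper,
    )
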