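"""From-scratch maximum-entropy presence-background niche model.

The estimator finds the Gibbs distribution q(x) = exp(lambda . f(x)) / Z over
background cells maximizing the L1-penalized presence log-likelihood

    sum_presence log q(x_i)  -  sum_j beta_j |lambda_j|

by FISTA (accelerated proximal gradient) on the equivalent convex objective.
Feature construction (linear/quadratic/product/hinge/threshold classes),
per-class penalty scaling, AICc selection, AUC replicate evaluation,
permutation importances and clamped raster projection follow the published
presence-background modelling conventions; the reference Java implementation
is not replicated bit-for-bit (same optimum by convexity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .raster import ClimateStack, SuitabilityMap

__all__ = [
    "FeatureSpec",
    "FeatureBuilder",
    "MaxentModel",
    "ModelSelectionResult",
    "ReplicateEvaluation",
    "build_features",
    "fit_maxent",
    "fit_model",
    "predict",
    "aicc",
    "select_model",
    "evaluate_replicates",
    "permutation_importance",
    "project_raster",
    "auc_score",
]

logger = logging.getLogger(__name__)

VALID_CLASSES = "LQHPT"

# Per-class base L1 penalties, interpolated on presence sample size
# (published presence-background defaults; config constants by design).
_BETA_TABLES: dict[str, list[tuple[float, float]]] = {
    "L": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "Q": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "P": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "H": [(0, 0.5)],
    "T": [(0, 2.0), (100, 1.0)],
}

NONZERO_TOL = 1e-8  # |lambda| above this counts toward k in AICc


def _base_penalty(cls: str, n_presence: int) -> float:
    table = _BETA_TABLES[cls]
    ns = np.array([t[0] for t in table], dtype=float)
    bs = np.array([t[1] for t in table], dtype=float)
    return float(np.interp(n_presence, ns, bs))


@dataclass(frozen=True)
class FeatureSpec:
    """Feature classes and knot counts. ``classes`` is a subset of LQHPT."""

    classes: str = "LQ"
    hinge_knots: int = 5
    threshold_knots: int = 5

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        if ("H" in self.classes and self.hinge_knots < 2) or (
                "T" in self.classes and self.threshold_knots < 2):
            raise ValueError("hinge/threshold classes need >= 2 knots")

    @property
    def label(self) -> str:
        return self.classes or "none"


class FeatureBuilder:
    """Derives the feature matrix from raw variables.

    Fitted on training data: stores per-variable clamp bounds, knot
    positions and per-feature [0,1] rescaling computed over the training
    background.
    """

    def __init__(self, variables: list[str], spec: FeatureSpec):
        self.variables = list(variables)
        self.spec = spec
        self.feature_names: list[str] = []
        self.feature_classes: list[str] = []
        self.clamp_bounds: dict[str, tuple[float, float]] = {}
        self._scale_min: np.ndarray | None = None
        self._scale_max: np.ndarray | None = None
        self._keep: np.ndarray | None = None

    def fit(self, background: pd.DataFrame,
            presence: pd.DataFrame | None = None) -> "FeatureBuilder":
        frames = [background] if presence is None else [background, presence]
        combined = pd.concat([f[self.variables] for f in frames], axis=0)
        for v in self.variables:
            col = combined[v].to_numpy(dtype=float)
            self.clamp_bounds[v] = (float(col.min()), float(col.max()))
        raw, names, classes = self._raw_features(
            background[self.variables].to_numpy(dtype=float))
        mn = raw.min(axis=0)
        mx = raw.max(axis=0)
        keep = mx > mn
        dropped = [n for n, k in zip(names, keep) if not k]
        if dropped:
            logger.warning("dropping %d constant feature(s): %s",
                           len(dropped), ", ".join(dropped[:5]))
        self._scale_min = mn[keep]
        self._scale_max = mx[keep]
        self._keep = keep
        self.feature_names = [n for n, k in zip(names, keep) if k]
        self.feature_classes = [c for c, k in zip(classes, keep) if k]
        return self

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _knot_positions(self, v: str, count: int) -> np.ndarray:
        lo, hi = self.clamp_bounds[v]
        return np.linspace(lo, hi, count + 2)[1:-1]

    def _raw_features(self, X: np.ndarray):
        cols: list[np.ndarray] = []
        names: list[str] = []
        classes: list[str] = []
        spec = self.spec
        nv = len(self.variables)
        if "L" in spec.classes:
            for j, v in enumerate(self.variables):
                cols.append(X[:, j])
                names.append(f"L:{v}")
                classes.append("L")
        if "Q" in spec.classes:
            for j, v in enumerate(self.variables):
                cols.append(X[:, j] ** 2)
                names.append(f"Q:{v}")
                classes.append("Q")
        if "P" in spec.classes:
            for i in range(nv):
                for j in range(i + 1, nv):
                    cols.append(X[:, i] * X[:, j])
                    names.append(f"P:{self.variables[i]}*{self.variables[j]}")
                    classes.append("P")
        if "H" in spec.classes:
            for j, v in enumerate(self.variables):
                lo, hi = self.clamp_bounds[v]
                if hi <= lo:
                    continue
                for k in self._knot_positions(v, spec.hinge_knots):
                    cols.append(np.maximum(0.0, X[:, j] - k))
                    names.append(f"H+:{v}@{k:.6g}")
                    classes.append("H")
                    cols.append(np.maximum(0.0, k - X[:, j]))
                    names.append(f"H-:{v}@{k:.6g}")
                    classes.append("H")
        if "T" in spec.classes:
            for j, v in enumerate(self.variables):
                lo, hi = self.clamp_bounds[v]
                if hi <= lo:
                    continue
                for k in self._knot_positions(v, spec.threshold_knots):
                    cols.append((X[:, j] >= k).astype(float))
                    names.append(f"T:{v}@{k:.6g}")
                    classes.append("T")
        if not cols:
            return np.empty((X.shape[0], 0)), [], []
        return np.column_stack(cols), names, classes

    def transform(self, env: pd.DataFrame | np.ndarray, clamp: bool = True) -> np.ndarray:
        if isinstance(env, pd.DataFrame):
            missing = [v for v in self.variables if v not in env.columns]
            if missing:
                raise ValueError(f"missing variables: {missing}")
            X = env[self.variables].to_numpy(dtype=float)
        else:
            X = np.asarray(env, dtype=float)
        if clamp:
            X = X.copy()
            for j, v in enumerate(self.variables):
                lo, hi = self.clamp_bounds[v]
                np.clip(X[:, j], lo, hi, out=X[:, j])
        raw, _, _ = self._raw_features(X)
        raw = raw[:, self._keep]
        span = self._scale_max - self._scale_min
        return (raw - self._scale_min) / span


def build_features(env: pd.DataFrame, spec: FeatureSpec,
                   variables: list[str] | None = None,
                   builder: FeatureBuilder | None = None) -> tuple[np.ndarray, FeatureBuilder]:
    """Build the feature matrix for ``env``; fits a builder if none given."""
    if builder is None:
        if variables is None:
            skip = {"taxon", "lon", "lat", "label", "row", "col"}
            variables = [c for c in env.columns
                         if c not in skip and pd.api.types.is_numeric_dtype(env[c])]
        builder = FeatureBuilder(variables, spec).fit(env)
    return builder.transform(env, clamp=False), builder


@dataclass
class FitResult:
    lambdas: np.ndarray
    log_partition: float
    objective: float
    loglik: float
    converged: bool
    n_iter: int


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit_maxent(presence: np.ndarray, background: np.ndarray, rm: float = 1.0,
               feature_classes: list[str] | None = None,
               max_iter: int = 2000, tol: float = 1e-7) -> FitResult:
    """Fit penalized maxent weights from feature matrices.

    ``presence``/``background`` are feature rows (already built and scaled).
    beta_j = rm * base(class, n_presence) * sd_j(presence) / sqrt(n_presence).
    Returns the weight vector, log partition over the background, the
    penalized objective and the (unpenalized) presence log-likelihood.
    """
    Fp = np.asarray(presence, dtype=float)
    Fb = np.asarray(background, dtype=float)
    n_p, m = Fp.shape
    if n_p < 2:
        raise ValueError("need at least 2 presence rows")
    if Fb.shape[0] < n_p:
        raise ValueError("background must be at least as large as presence")
    if m == 0:
        logZ = float(np.log(Fb.shape[0]))
        return FitResult(np.zeros(0), logZ, logZ, -n_p * logZ, True, 0)
    if feature_classes is None:
        feature_classes = ["L"] * m
    if rm < 0:
        raise ValueError("rm must be >= 0")

    pbar = Fp.mean(axis=0)
    sd = Fp.std(axis=0)
    sd_b = Fb.std(axis=0)
    sd = np.where(sd > 0, sd, sd_b)
    sd = np.where(sd > 0, sd, 1.0)
    base = np.array([_base_penalty(c, n_p) for c in feature_classes])
    beta = rm * base * sd / np.sqrt(n_p)
    b = beta / n_p  # objective is scaled per presence point

    def smooth_val(lam: np.ndarray) -> tuple[float, np.ndarray]:
        u = Fb @ lam
        lse = float(logsumexp(u))
        return lse - float(pbar @ lam), u - lse

    lam = np.zeros(m)
    y = lam.copy()
    t_acc = 1.0
    L = 1.0
    s_lam, _ = smooth_val(lam)
    obj = s_lam + float(b @ np.abs(lam))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s_y, logw = smooth_val(y)
        g = Fb.T @ np.exp(logw) - pbar
        while True:
            lam_new = _soft_threshold(y - g / L, b / L)
            diff = lam_new - y
            s_new, _ = smooth_val(lam_new)
            quad = s_y + float(g @ diff) + 0.5 * L * float(diff @ diff)
            if s_new <= quad + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        obj_new = s_new + float(b @ np.abs(lam_new))
        if obj_new > obj:  # monotone restart
            y = lam.copy()
            t_acc = 1.0
            if abs(obj_new - obj) <= tol * max(1.0, abs(obj)):
                converged = True
                break
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc ** 2))
        y = lam_new + ((t_acc - 1.0) / t_next) * (lam_new - lam)
        lam = lam_new
        t_acc = t_next
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj_new)):
            obj = obj_new
            converged = True
            break
        obj = obj_new
        L *= 0.9  # allow the step size to grow back
    if not converged:
        logger.warning("maxent fit did not converge in %d iterations", max_iter)
    u = Fb @ lam
    logZ = float(logsumexp(u))
    loglik = float(n_p * (pbar @ lam - logZ))
    return FitResult(lam, logZ, obj, loglik, converged, n_iter)


@dataclass
class MaxentModel:
    """Fitted maxent model: builder (normalizers + clamp bounds), weights,
    partition constant and training-background entropy."""

    builder: FeatureBuilder
    rm: float
    lambdas: np.ndarray
    log_partition: float
    entropy: float
    n_presence: int
    n_background: int
    loglik: float
    converged: bool = True

    @property
    def feature_spec(self) -> FeatureSpec:
        return self.builder.spec

    @property
    def variables(self) -> list[str]:
        return self.builder.variables

    @property
    def k_nonzero(self) -> int:
        return int((np.abs(self.lambdas) > NONZERO_TOL).sum())

    def predict(self, env: pd.DataFrame | np.ndarray, output: str = "logistic",
                clamp: bool = True) -> np.ndarray:
        F = self.builder.transform(env, clamp=clamp)
        return self.predict_features(F, output=output)

    def predict_features(self, F: np.ndarray, output: str = "logistic") -> np.ndarray:
        score = F @ self.lambdas if F.shape[1] else np.zeros(F.shape[0])
        raw = np.exp(score - self.log_partition)
        if output == "raw":
            return raw
        if output == "logistic":
            # relative suitability r scaled by the exp-entropy of the training
            # distribution; tau = 0.5 gives r / (1 + r)
            r = raw * np.exp(self.entropy)
            return r / (1.0 + r)
        raise ValueError("output must be 'raw' or 'logistic'")

    def to_json(self, path) -> None:
        payload = {
            "variables": self.variables,
            "feature_spec": {
                "classes": self.feature_spec.classes,
                "hinge_knots": self.feature_spec.hinge_knots,
                "threshold_knots": self.feature_spec.threshold_knots,
            },
            "rm": self.rm,
            "feature_names": self.builder.feature_names,
            "lambdas": self.lambdas.tolist(),
            "clamp_bounds": {k: list(v) for k, v in self.builder.clamp_bounds.items()},
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_model(presence_env: pd.DataFrame, background_env: pd.DataFrame,
              spec: FeatureSpec, rm: float = 1.0,
              variables: list[str] | None = None,
              max_iter: int = 2000, tol: float = 1e-7,
              builder: FeatureBuilder | None = None) -> MaxentModel:
    """Convenience wrapper: build features, fit, package a MaxentModel."""
    if variables is None and builder is None:
        skip = {"taxon", "lon", "lat", "label", "row", "col"}
        variables = [c for c in background_env.columns
                     if c not in skip
                     and pd.api.types.is_numeric_dtype(background_env[c])]
    if builder is None:
        builder = FeatureBuilder(variables, spec).fit(background_env, presence_env)
    Fb = builder.transform(background_env, clamp=False)
    Fp = builder.transform(presence_env, clamp=True)
    res = fit_maxent(Fp, Fb, rm=rm, feature_classes=builder.feature_classes,
                     max_iter=max_iter, tol=tol)
    logq = (Fb @ res.lambdas if Fb.shape[1] else np.zeros(len(Fb))) - res.log_partition
    q = np.exp(logq)
    entropy = float(-(q * logq).sum())
    return MaxentModel(
        builder=builder,
        rm=rm,
        lambdas=res.lambdas,
        log_partition=res.log_partition,
        entropy=entropy,
        n_presence=len(presence_env),
        n_background=len(background_env),
        loglik=res.loglik,
        converged=res.converged,
    )


def predict(model: MaxentModel, env: pd.DataFrame, output: str = "logistic",
            clamp: bool = True) -> np.ndarray:
    return model.predict(env, output=output, clamp=clamp)


def aicc(loglik: float, k: int, n: int) -> float:
    """Sample-size-corrected Akaike criterion; +inf when n <= k + 1."""
    if n <= k + 1:
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class ModelSelectionResult:
    table: pd.DataFrame  # columns: classes, rm, loglik, k, aicc, delta_aicc
    models: list[MaxentModel]
    best_index: int

    @property
    def best(self) -> MaxentModel:
        return self.models[self.best_index]


def select_model(presence_env: pd.DataFrame, background_env: pd.DataFrame,
                 candidate_specs: list[FeatureSpec] | None = None,
                 candidate_rms: list[float] | None = None,
                 variables: list[str] | None = None,
                 max_iter: int = 2000, tol: float = 1e-7) -> ModelSelectionResult:
    """Fit every (feature spec, RM) candidate and rank by AICc.

    Ties break toward fewer nonzero weights, then smaller RM.
    """
    if candidate_specs is None:
        candidate_specs = [FeatureSpec(c) for c in ("L", "LQ", "LQH", "LQHP", "LQHPT")]
    if candidate_rms is None:
        candidate_rms = [0.5, 1.0, 2.0, 3.0, 4.0]
    if not candidate_specs or not candidate_rms:
        raise ValueError("need at least one candidate spec and one RM")
    rows = []
    models = []
    n = len(presence_env)
    for spec in candidate_specs:
        for rm in candidate_rms:
            model = fit_model(presence_env, background_env, spec, rm=rm,
                              variables=variables, max_iter=max_iter, tol=tol)
            k = model.k_nonzero
            rows.append({
                "classes": spec.label,
                "rm": rm,
                "loglik": model.loglik,
                "k": k,
                "aicc": aicc(model.loglik, k, n),
                "converged": model.converged,
            })
            models.append(model)
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise RuntimeError("no candidate model converged")
    finite = table["aicc"].replace([np.inf], np.nan)
    if finite.isna().all():
        raise RuntimeError("all candidates have undefined AICc (n <= k + 1)")
    order = sorted(
        range(len(table)),
        key=lambda i: (table.loc[i, "aicc"], table.loc[i, "k"], table.loc[i, "rm"]),
    )
    best = order[0]
    table["delta_aicc"] = table["aicc"] - table.loc[best, "aicc"]
    return ModelSelectionResult(table=table, models=models, best_index=best)


def auc_score(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    from scipy.stats import rankdata

    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need scores on both sides")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


@dataclass
class ReplicateEvaluation:
    aucs: np.ndarray
    models: list[MaxentModel]

    def mean_prediction(self, env: pd.DataFrame, output: str = "logistic",
                        clamp: bool = True) -> np.ndarray:
        preds = [m.predict(env, output=output, clamp=clamp) for m in self.models]
        return np.mean(preds, axis=0)


def evaluate_replicates(presence_env: pd.DataFrame, background_env: pd.DataFrame,
                        spec: FeatureSpec, rm: float, n_reps: int = 30,
                        train_frac: float = 0.75, seed: int | None = None,
                        variables: list[str] | None = None,
                        max_iter: int = 2000, tol: float = 1e-7) -> ReplicateEvaluation:
    """Random-split replicates: fit on ``train_frac`` of presences, AUC of
    held-out presences against the full background."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(presence_env)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("split leaves too few presences for training or testing")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_reps)
    models = []
    for i in range(n_reps):
        perm = rng.permutation(n)
        train = presence_env.iloc[perm[:n_train]]
        test = presence_env.iloc[perm[n_train:]]
        model = fit_model(train, background_env, spec, rm=rm,
                          variables=variables, max_iter=max_iter, tol=tol)
        pos = model.predict(test, output="raw", clamp=True)
        neg = model.predict(background_env, output="raw", clamp=True)
        aucs[i] = auc_score(pos, neg)
        models.append(model)
    return ReplicateEvaluation(aucs=aucs, models=models)


def permutation_importance(model: MaxentModel, presence_env: pd.DataFrame,
                           background_env: pd.DataFrame, n_perm: int = 10,
                           seed: int | None = None) -> pd.Series:
    """Percent contribution per variable from permutation AUC drops.

    Each variable is shuffled across the pooled presence+background rows;
    the drop in AUC (vs the unpermuted model) is averaged over ``n_perm``
    shuffles, floored at 0, and normalized to sum to 100.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    variables = model.variables
    pooled = pd.concat(
        [presence_env[variables], background_env[variables]], axis=0
    ).reset_index(drop=True)
    n_p = len(presence_env)
    base_auc = auc_score(
        model.predict(presence_env, output="raw"),
        model.predict(background_env, output="raw"),
    )
    drops = {}
    for v in variables:
        deltas = np.empty(n_perm)
        for i in range(n_perm):
            shuffled = pooled.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            pos = model.predict(shuffled.iloc[:n_p], output="raw")
            neg = model.predict(shuffled.iloc[n_p:], output="raw")
            deltas[i] = base_auc - auc_score(pos, neg)
        drops[v] = max(float(deltas.mean()), 0.0)
    ser = pd.Series(drops, name="importance_pct")
    total = ser.sum()
    if total <= 0:
        ser[:] = 100.0 / len(ser)
    else:
        ser = 100.0 * ser / total
    return ser


def project_raster(model: MaxentModel, stack: ClimateStack,
                   output: str = "logistic", clamp: bool = True,
                   period: str = "present") -> SuitabilityMap:
    """Predict suitability for every valid cell of ``stack``."""
    missing = [v for v in model.variables if v not in stack.layer_names]
    if missing:
        raise ValueError(f"stack lacks model variables: {missing}")
    cells = stack.valid_cell_table()
    preds = model.predict(cells, output=output, clamp=clamp)
    grid = np.full(stack.shape, stack.nodata)
    grid[cells["row"].to_numpy(), cells["col"].to_numpy()] = preds
    return SuitabilityMap(grid=grid, transform=stack.transform, crs=stack.crs,
                          nodata=stack.nodata, period=period)
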