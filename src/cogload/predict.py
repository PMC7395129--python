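"""Predictability of workload targets from physiological features.

Four estimators of association, in increasing generality:

* per-feature Pearson correlation ``r`` with its two-sided p-value;
* multivariate linear regression summarised as ``R_adj = sqrt(|adj R^2|)``,
  which puts the goodness of fit on a scale comparable to ``r``;
* quadratic regression (y on [1, x, x^2]) for inverted-U / U-shaped
  (Yerkes-Dodson) relations;
* a cascade-forward neural network (hidden sizes 10 and 8, direct input
  connections into every layer) trained by Levenberg-Marquardt on the
  squared error, scored by the repeated fivefold cross-validated correlation

      R_CV = mean over repeats of corr(out-of-fold predictions, y).

Scaling parameters and network weights are always fit on training folds
only; a null target therefore yields R_CV ~ 0 (leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .features import FEATURE_COLUMNS

__all__ = [
    "CFNetSpec",
    "CFNetModel",
    "PredictionResult",
    "pearson_feature_target",
    "fit_linear_multi",
    "fit_quadratic",
    "train_cf_net",
    "cross_validated_correlation",
    "build_prediction_table",
]


# ---------------------------------------------------------------------------
# simple associations


def pearson_feature_target(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution), pairwise-complete.

    Returns (nan, nan) for n < 3 or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LinearFit:
    r_adj: float
    r2: float
    r2_adj: float
    coef: np.ndarray
    n: int
    p: int


def fit_linear_multi(X: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS of y on all features with intercept; returns sqrt(|adj R^2|).

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1); the absolute value is taken
    before the square root because the adjustment can push R^2 below zero.
    Collinear columns are handled by the pseudo-inverse solver (no dropping).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    r2 = float(model.rsquared)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return LinearFit(
        r_adj=float(np.sqrt(abs(r2_adj))), r2=r2, r2_adj=float(r2_adj),
        coef=np.asarray(model.params), n=n, p=p,
    )


@dataclass
class QuadraticFit:
    coef: np.ndarray               # (c0, c1, c2) for y = c0 + c1 x + c2 x^2
    p2: float                      # F-test p of the quadratic model
    vertex: float
    u_shape: bool                  # positive curvature with vertex in-range
    significant: bool              # p2 < 0.05


def fit_quadratic(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> QuadraticFit:
    """OLS of y on [1, x, x^2] with the model F-test as significance.

    The U-shape flag requires positive curvature and the parabola's vertex
    inside the observed x-range; following the convention of reporting the
    quadratic fit only when significant, ``significant`` combines the flagged
    shape with ``p2 < alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero range")
    design = np.column_stack([np.ones_like(x), x, x * x])
    model = sm.OLS(y, design).fit()
    c0, c1, c2 = model.params
    p2 = float(model.f_pvalue)
    vertex = float(-c1 / (2 * c2)) if c2 != 0 else float("nan")
    u_shape = bool(c2 > 0 and np.isfinite(vertex) and x.min() <= vertex <= x.max())
    return QuadraticFit(
        coef=np.asarray([c0, c1, c2]), p2=p2, vertex=vertex,
        u_shape=u_shape, significant=bool(p2 < alpha),
    )


# ---------------------------------------------------------------------------
# cascade-forward network trained by Levenberg-Marquardt


@dataclass(frozen=True)
class CFNetSpec:
    """Cascade-forward net: input feeds every layer; tanh hidden, linear out."""

    hidden_sizes: tuple[int, int] = (10, 8)
    #: LM epoch budget; a modest budget stops short of interpolating the
    #: training fold, the usual implicit regulariser for small LM nets
    max_iter: int = 30
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    seed: int = 0


class _MinMaxScaler:
    """Map each column to [-1, 1] from training-data extremes."""

    def fit(self, X: np.ndarray) -> "_MinMaxScaler":
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        span = self.hi - self.lo
        self.span = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.lo) / self.span - 1.0

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return (Z + 1.0) / 2.0 * self.span + self.lo


def _init_weights(p: int, h1: int, h2: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def u(shape, fan_in):
        return rng.uniform(-1.0, 1.0, shape) / np.sqrt(fan_in)

    return {
        "W1": u((h1, p), p), "b1": u((h1,), p),
        "W2x": u((h2, p), p + h1), "W21": u((h2, h1), p + h1), "b2": u((h2,), p + h1),
        "W3x": u((p,), p + h1 + h2), "W31": u((h1,), p + h1 + h2),
        "W32": u((h2,), p + h1 + h2), "b3": u((1,), p + h1 + h2),
    }


def _pack(w: dict[str, np.ndarray]) -> np.ndarray:
    return np.concatenate([w[k].ravel() for k in sorted(w)])


def _unpack(vec: np.ndarray, shapes: dict[str, tuple]) -> dict[str, np.ndarray]:
    out, i = {}, 0
    for k in sorted(shapes):
        size = int(np.prod(shapes[k]))
        out[k] = vec[i : i + size].reshape(shapes[k])
        i += size
    return out


def _forward(w: dict[str, np.ndarray], X: np.ndarray):
    """Forward pass; returns prediction and layer activations."""
    h1 = np.tanh(X @ w["W1"].T + w["b1"])
    h2 = np.tanh(X @ w["W2x"].T + h1 @ w["W21"].T + w["b2"])
    yhat = X @ w["W3x"] + h1 @ w["W31"] + h2 @ w["W32"] + w["b3"][0]
    return yhat, h1, h2


def _jacobian(w: dict[str, np.ndarray], X: np.ndarray, h1: np.ndarray, h2: np.ndarray) -> dict[str, np.ndarray]:
    """d yhat / d w per sample (residual Jacobian up to sign)."""
    n = X.shape[0]
    d2 = 1.0 - h2 * h2                       # (n, h2)
    g2 = d2 * w["W32"]                       # d y / d pre2
    dy_dh1 = w["W31"] + g2 @ w["W21"]        # (n, h1)
    g1 = dy_dh1 * (1.0 - h1 * h1)            # d y / d pre1
    return {
        "W1": np.einsum("nm,nk->nmk", g1, X),
        "b1": g1,
        "W2x": np.einsum("nj,nk->njk", g2, X),
        "W21": np.einsum("nj,nm->njm", g2, h1),
        "b2": g2,
        "W3x": X,
        "W31": h1,
        "W32": h2,
        "b3": np.ones((n, 1)),
    }


@dataclass
class CFNetModel:
    spec: CFNetSpec
    weights: dict[str, np.ndarray]
    x_scaler: _MinMaxScaler
    y_scaler: _MinMaxScaler
    n_iter: int = 0
    sse: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = self.x_scaler.transform(X)
        yhat, _, _ = _forward(self.weights, Z)
        return self.y_scaler.inverse(yhat)


def train_cf_net(spec: CFNetSpec, X: np.ndarray, y: np.ndarray) -> CFNetModel:
    """Levenberg-Marquardt training of the cascade-forward net.

    Minimises the sum of squared errors with the standard damped Gauss-Newton
    update: solve (J'J + mu I) d = -J'r, accept the step when the SSE drops
    (then shrink mu), otherwise raise mu and retry.  Inputs and target are
    mapped to [-1, 1] with training-data extremes.  Deterministic for a fixed
    spec.seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training inputs")
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    h1_n, h2_n = spec.hidden_sizes
    rng = np.random.default_rng(spec.seed)
    xs = _MinMaxScaler().fit(X)
    ys = _MinMaxScaler().fit(y.reshape(-1, 1))
    Z = xs.transform(X)
    t = ys.transform(y.reshape(-1, 1)).ravel()

    w = _init_weights(X.shape[1], h1_n, h2_n, rng)
    shapes = {k: v.shape for k, v in w.items()}
    vec = _pack(w)
    mu = spec.mu0
    yhat, h1, h2 = _forward(w, Z)
    r = yhat - t
    sse = float(r @ r)
    it = 0
    for it in range(1, spec.max_iter + 1):
        parts = _jacobian(w, Z, h1, h2)
        J = np.concatenate([parts[k].reshape(Z.shape[0], -1) for k in sorted(shapes)], axis=1)
        g = J.T @ r
        if np.max(np.abs(g)) < spec.grad_tol:
            break
        JtJ = J.T @ J
        improved = False
        while mu <= spec.mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                mu *= spec.mu_inc
                continue
            trial_vec = vec + step
            trial_w = _unpack(trial_vec, shapes)
            trial_yhat, trial_h1, trial_h2 = _forward(trial_w, Z)
            trial_r = trial_yhat - t
            trial_sse = float(trial_r @ trial_r)
            if trial_sse < sse:
                vec, w = trial_vec, trial_w
                yhat, h1, h2, r, sse = trial_yhat, trial_h1, trial_h2, trial_r, trial_sse
                mu = max(mu * spec.mu_dec, 1e-15)
                improved = True
                break
            mu *= spec.mu_inc
        if not improved:
            break
    ys_scaler = ys

    class _YScaler:
        def __init__(self, inner):
            self.inner = inner

        def inverse(self, z):
            return self.inner.inverse(np.asarray(z).reshape(-1, 1)).ravel()

    return CFNetModel(spec=spec, weights=w, x_scaler=xs, y_scaler=_YScaler(ys_scaler), n_iter=it, sse=sse)


# ---------------------------------------------------------------------------
# repeated cross-validation


def fold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal test folds."""
    perm = rng.permutation(n)
    return np.array_split(perm, k)


@dataclass
class CVResult:
    r_cv: float                    # mean over repeats
    sd: float
    per_repeat: np.ndarray
    n_excluded: int                # repeats with undefined correlation


def cross_validated_correlation(
    spec: CFNetSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    repeats: int = 100,
    seed: int | None = None,
    model: str = "cfnet",
) -> CVResult:
    """Repeated k-fold cross-validated correlation R_CV.

    Each repeat draws a fresh random partition into k folds; the model is
    trained on k-1 folds and predicts the held-out fold, until every row has
    an out-of-fold prediction; one Pearson r of (prediction, actual) is
    computed over all rows.  R_CV is the mean of the per-repeat correlations
    (sd reported).  Repeats whose predictions are constant are excluded with
    a count.  ``model="linear"`` swaps the net for OLS (cross-checks).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2 * k:
        raise ValueError("need n >= 2k rows")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rs = np.full(repeats, np.nan)
    for rep in range(repeats):
        folds = fold_partition(n, k, rng)
        oof = np.empty(n)
        all_idx = np.arange(n)
        for fold in folds:
            train = np.setdiff1d(all_idx, fold, assume_unique=True)
            if model == "linear":
                Xtr = sm.add_constant(X[train], has_constant="add")
                beta = np.linalg.pinv(Xtr) @ y[train]
                oof[fold] = sm.add_constant(X[fold], has_constant="add") @ beta
            else:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                net = train_cf_net(
                    CFNetSpec(**{**spec.__dict__, "seed": sub_seed}), X[train], y[train]
                )
                oof[fold] = net.predict(X[fold])
        if np.ptp(oof) == 0 or np.ptp(y) == 0:
            continue
        rs[rep] = stats.pearsonr(oof, y)[0]
    valid = rs[np.isfinite(rs)]
    return CVResult(
        r_cv=float(valid.mean()) if valid.size else float("nan"),
        sd=float(valid.std()) if valid.size else float("nan"),
        per_repeat=rs,
        n_excluded=int(repeats - valid.size),
    )


# ---------------------------------------------------------------------------
# prediction table


@dataclass
class PredictionResult:
    table: pd.DataFrame            # one row per target, Table-1-like layout
    per_repeat: dict[str, np.ndarray] = field(default_factory=dict)


DEFAULT_TARGETS = ("nasa_tlx_avg", "reaction_time", "non_response_rate", "completion_time", "error_rate_10")


def build_prediction_table(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    spec: CFNetSpec | None = None,
    target_columns: tuple[str, ...] = DEFAULT_TARGETS,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
    repeats: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> PredictionResult:
    """Per-target association summary mirroring the pooled-task table.

    For every target: Pearson r (with a significance star at p < alpha) for
    each physiological feature, then R_adj of the all-feature linear
    regression and R_CV of the all-feature cascade-forward net.  Pairwise
    deletion for r; listwise complete rows for R_adj and R_CV.  NaN cells
    propagate as blanks.
    """
    spec = spec or CFNetSpec()
    rows, per_repeat = [], {}
    Xall = features[list(feature_columns)].to_numpy(dtype=float)
    for ti, tcol in enumerate(target_columns):
        if tcol not in targets.columns:
            continue
        yall = targets[tcol].to_numpy(dtype=float)
        row: dict[str, object] = {"target": tcol}
        for fcol in feature_columns:
            r, p = pearson_feature_target(features[fcol].to_numpy(dtype=float), yall)
            row[f"{fcol}_r"] = r
            row[f"{fcol}_p"] = p
            row[f"{fcol}_sig"] = bool(np.isfinite(p) and p < alpha)
        ok = np.isfinite(yall) & np.all(np.isfinite(Xall), axis=1)
        if ok.sum() > len(feature_columns) + 1:
            row["R_adj"] = fit_linear_multi(Xall[ok], yall[ok]).r_adj
            cv = cross_validated_correlation(
                spec, Xall[ok], yall[ok], repeats=repeats, seed=seed + ti
            )
            row["R_CV"] = cv.r_cv
            row["R_CV_sd"] = cv.sd
            per_repeat[tcol] = cv.per_repeat
        else:
            row["R_adj"] = float("nan")
            row["R_CV"] = float("nan")
            row["R_CV_sd"] = float("nan")
        rows.append(row)
    return PredictionResult(table=pd.DataFrame(rows), per_repeat=per_repeat)
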