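"""PLS1 calibration and model-quality metrics.

The calibration model is the single-response partial least squares
regression ``y = X b + e`` fitted with Helland's PLS1 algorithm: at each
step the weight vector is the covariance direction ``X' y`` (normalized),
the score is its projection, and X and y are deflated by the score before
the next component.  Predictors are column-centered and the response
centered before fitting; prediction is the affine map
``y_hat = (x - x_mean) . b + y_mean``.

Model quality is summarized by RMSEC / RMSEV (root-mean-square error on the
calibration and validation sets), the coefficient of determination R2, and
its adjusted form ``1 - (N-1)/(N-p-1) (1-R2)`` which penalizes the latent
variable count p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SplitSpec:
    """Random calibration/validation split (default 75 % calibration)."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split_train_val(n_obs: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-reproducible index split.

    Calibration size is ``round(train_fraction * n_obs)``.
    Returns ``(calibration_idx, validation_idx)``.
    """
    if n_obs < 4:
        raise ValueError(f"need at least 4 observations to split, got {n_obs}")
    n_cal = int(round(spec.train_fraction * n_obs))
    n_cal = min(max(n_cal, 1), n_obs - 1)
    perm = np.random.default_rng(spec.seed).permutation(n_obs)
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


@dataclass
class PLSModel:
    """Fitted PLS1 calibration at ``n_lv`` latent variables."""

    n_lv: int
    weights: np.ndarray  # (n_features, n_lv) normalized weight vectors
    scores: np.ndarray  # (n_obs, n_lv) training scores
    loadings: np.ndarray  # (n_features, n_lv) X loadings
    q: np.ndarray  # (n_lv,) y loadings
    b: np.ndarray  # (n_features,) regression vector
    x_mean: np.ndarray
    y_mean: float


def _helland_components(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    n_obs, n_feat = Xc.shape
    W = np.empty((n_feat, n_lv))
    T = np.empty((n_obs, n_lv))
    P = np.empty((n_feat, n_lv))
    q = np.empty(n_lv)
    E, f = Xc.copy(), yc.copy()
    scale = max(np.abs(Xc).max(), 1e-300)
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale * max(np.abs(yc).max(), 1e-300) * n_obs:
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank of the centered data "
                f"(degenerate component at a={a + 1})"
            )
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-24 * scale**2 * n_obs:
            raise ValueError(f"n_lv={n_lv} exceeds the rank of the centered predictors")
        p = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, p)
        f = f - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p, qa
    return W, T, P, q


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def pls1_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by Helland's algorithm at ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, T, P, q = _helland_components(X - x_mean, y - y_mean, n_lv)
    b = _regression_vector(W, P, q)
    return PLSModel(n_lv, W, T, P, q, b, x_mean, y_mean)


def pls1_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Affine prediction ``(X - x_mean) b + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.shape[0]:
        raise ValueError(
            f"X has {X_new.shape[1]} columns, model was trained on {model.b.shape[0]}"
        )
    return (X_new - model.x_mean) @ model.b + model.y_mean


def rmse(y_pred: np.ndarray, y_meas: np.ndarray) -> float:
    """Root-mean-square error between paired predictions and measurements."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_meas = np.asarray(y_meas, dtype=float).ravel()
    if y_pred.shape != y_meas.shape or y_pred.size == 0:
        raise ValueError("prediction and measurement vectors must have equal length >= 1")
    return float(np.sqrt(np.mean((y_pred - y_meas) ** 2)))


def r_squared(y_pred: np.ndarray, y_meas: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (about the mean of
    the measurements); negative for worse-than-mean predictions."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_meas = np.asarray(y_meas, dtype=float).ravel()
    if y_pred.shape != y_meas.shape:
        raise ValueError("prediction and measurement vectors must have equal length")
    ss_tot = float(np.sum((y_meas - y_meas.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant measurement vector")
    return 1.0 - float(np.sum((y_meas - y_pred) ** 2)) / ss_tot


def r_squared_adjusted(r2: float, n_obs: int, n_params: int) -> float:
    """Adjusted R2 = 1 - (N-1)/(N-p-1) (1-R2); equals R2 at p = 0."""
    if n_obs <= n_params + 1:
        raise ValueError(f"need n_obs > n_params + 1, got N={n_obs}, p={n_params}")
    return 1.0 - (n_obs - 1) / (n_obs - n_params - 1) * (1.0 - r2)


@dataclass
class FitMetrics:
    """Quality metrics of one fitted model on one food type."""

    rmsec: float
    rmsev: float
    r2_cal: float
    r2_val: float
    r2_adj: float  # adjusted validation R2
    n_obs: int
    n_params: int

    @property
    def r2(self) -> float:
        return self.r2_val


def evaluate_fit(y_cal, yhat_cal, y_val, yhat_val, n_params: int) -> FitMetrics:
    """Assemble :class:`FitMetrics` from calibration and validation vectors."""
    r2_val = r_squared(yhat_val, y_val)
    n_val = len(np.asarray(y_val).ravel())
    r2_adj = r_squared_adjusted(r2_val, n_val, n_params) if n_val > n_params + 1 else float("nan")
    return FitMetrics(
        rmsec=rmse(yhat_cal, y_cal),
        rmsev=rmse(yhat_val, y_val),
        r2_cal=r_squared(yhat_cal, y_cal),
        r2_val=r2_val,
        r2_adj=r2_adj,
        n_obs=n_val,
        n_params=n_params,
    )


@dataclass
class SweepResult:
    """Latent-variable sweep: metrics per LV count plus the optima."""

    table: pd.DataFrame
    best_lv_rmsev: int
    best_lv_rmsec: int


def lv_sweep(
    X: np.ndarray,
    y: np.ndarray,
    split: SplitSpec | None = None,
    lv_range=None,
) -> SweepResult:
    """Fit PLS1 at every latent-variable count and report metrics per count.

    One Helland pass at the maximum count supplies every smaller model (the
    components are nested), so the sweep costs a single decomposition.  The
    default range is 1..min(100, rank bound, n_cal - 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    split = SplitSpec() if split is None else split
    cal, val = split_train_val(len(y), split)
    X_cal, y_cal, X_val, y_val = X[cal], y[cal], X[val], y[val]
    rank_bound = min(X_cal.shape[0] - 1, X_cal.shape[1])
    if lv_range is None:
        lv_range = range(1, min(100, rank_bound) + 1)
    lv_list = sorted(set(int(a) for a in lv_range))
    if lv_list[0] < 1 or lv_list[-1] > rank_bound:
        raise ValueError(f"lv_range must lie within 1..{rank_bound}")

    x_mean = X_cal.mean(axis=0)
    y_mean = float(y_cal.mean())
    max_lv = lv_list[-1]
    try:
        W, T, P, q = _helland_components(X_cal - x_mean, y_cal - y_mean, max_lv)
    except ValueError:
        # rank exhausted before max_lv: shrink to the largest feasible count
        while max_lv > 1:
            max_lv -= 1
            try:
                W, T, P, q = _helland_components(X_cal - x_mean, y_cal - y_mean, max_lv)
                break
            except ValueError:
                continue
        lv_list = [a for a in lv_list if a <= max_lv]

    rows = []
    for a in lv_list:
        b = _regression_vector(W[:, :a], P[:, :a], q[:a])
        yhat_cal = (X_cal - x_mean) @ b + y_mean
        yhat_val = (X_val - x_mean) @ b + y_mean
        m = evaluate_fit(y_cal, yhat_cal, y_val, yhat_val, n_params=a)
        rows.append(
            {
                "n_lv": a,
                "rmsec": m.rmsec,
                "rmsev": m.rmsev,
                "r2_cal": m.r2_cal,
                "r2_val": m.r2_val,
                "r2_adj": m.r2_adj,
            }
        )
    table = pd.DataFrame(rows)
    return SweepResult(
        table=table,
        best_lv_rmsev=int(table.loc[table["rmsev"].idxmin(), "n_lv"]),
        best_lv_rmsec=int(table.loc[table["rmsec"].idxmin(), "n_lv"]),
    )
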