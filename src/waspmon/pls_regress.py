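"""PLS1 regression of storage day on spectra with grouped validation.

Storage time (integer day 1-6) is regressed on the spectral matrix with
NIPALS PLS1: successive latent variables capture the directions of maximal
covariance between spectra and day.  Model quality is assessed with
leave-one-lettuce-out cross-validation (all spectra of one head held out
per fold), pooling held-out predictions for R² = 1 - SS_res/SS_tot and
RMSE.  The latent-variable count is the one minimising the pooled
cross-validated RMSE.  Peaks of the regression vector folded back to
channel space mark the wavelengths that drive the storage-time prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffspec import pick_peaks
from .spectra_io import SpectraSet

__all__ = [
    "PlsModel",
    "RegressionReport",
    "fit_pls",
    "select_nr_lv",
    "lolo_regress",
    "exclude_outliers_pls",
    "regression_vector_peaks",
]


@dataclass
class PlsModel:
    nr_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    regression_vector: np.ndarray  # p

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.x_mean) @ self.regression_vector + self.y_mean


@dataclass
class RegressionReport:
    r2_cal: float
    rmse_cal: float
    r2_cv: float
    rmse_cv: float
    nr_lv: int
    n_used: int
    excluded_rows: list = field(default_factory=list)


def _as_xy(data, y):
    x = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != x.shape[0]:
        raise ValueError("y length must match number of spectra")
    return x, y


def fit_pls(data: SpectraSet | np.ndarray, y, nr_lv: int) -> PlsModel:
    """NIPALS PLS1 on centred X and y.

    For a single response the NIPALS weight vector per component is the
    (normalised) covariance X'y of the deflated data; the regression
    vector in channel space is W (P'W)^-1 q, so prediction is exactly
    ``(x - x_mean) @ b + y_mean``.
    """
    x, y = _as_xy(data, y)
    n, p = x.shape
    if not 1 <= nr_lv <= min(n - 1, p):
        raise ValueError(f"nr_lv must be in [1, {min(n - 1, p)}], got {nr_lv}")
    if np.std(y) == 0:
        raise ValueError("response y has zero variance")
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    e = x - x_mean
    f = y - y_mean
    ws, ps, qs = [], [], []
    for _ in range(nr_lv):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            break  # residual covariance exhausted
        w = w / norm
        t = e @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p_load = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p_load)
        f = f - q * t
        ws.append(w)
        ps.append(p_load)
        qs.append(q)
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_vec = np.array(qs)
    b = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PlsModel(
        nr_lv=len(qs),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        regression_vector=b,
    )


def _lolo_predictions(x: np.ndarray, y: np.ndarray, g: np.ndarray, nr_lv: int) -> np.ndarray:
    """Pooled held-out predictions, one grouped fold per specimen."""
    pred = np.empty_like(y)
    for s in np.unique(g):
        held = g == s
        model = fit_pls(x[~held], y[~held], nr_lv)
        pred[held] = model.predict(x[held])
    return pred


def select_nr_lv(data: SpectraSet | np.ndarray, y, group=None, max_lv: int = 20) -> int:
    """Latent-variable count minimising LOLO cross-validated RMSE (ties: fewer)."""
    x, y = _as_xy(data, y)
    g = np.asarray(
        group if group is not None else data.meta["specimen_id"].to_numpy()
    )
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    best_a, best_rmse = None, np.inf
    for a in range(1, max_lv + 1):
        pred = _lolo_predictions(x, y, g, a)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_a, best_rmse = a, rmse
    return best_a


def lolo_regress(data: SpectraSet | np.ndarray, y, group=None, nr_lv: int = 9) -> RegressionReport:
    """Calibration metrics from the full-data fit + pooled LOLO CV metrics."""
    x, y = _as_xy(data, y)
    g = np.asarray(
        group if group is not None else data.meta["specimen_id"].to_numpy()
    )
    if len(np.unique(g)) < 2:
        raise ValueError("grouped CV needs at least 2 specimens")
    full = fit_pls(x, y, nr_lv)
    cal_pred = full.predict(x)
    cv_pred = _lolo_predictions(x, y, g, nr_lv)
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def r2(pred):
        return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot

    return RegressionReport(
        r2_cal=r2(cal_pred),
        rmse_cal=float(np.sqrt(np.mean((cal_pred - y) ** 2))),
        r2_cv=r2(cv_pred),
        rmse_cv=float(np.sqrt(np.mean((cv_pred - y) ** 2))),
        nr_lv=nr_lv,
        n_used=len(y),
    )


def exclude_outliers_pls(
    data: SpectraSet,
    y=None,
    group=None,
    nr_lv: int = 9,
    threshold: float = 2.5,
    max_iter: int = 3,
) -> tuple[SpectraSet, list[int]]:
    """Iteratively drop rows with large grouped-CV residuals.

    A row is removed when its absolute cross-validated residual exceeds
    ``threshold`` times the current RMSE_CV; the model is refit and the
    rule reapplied up to ``max_iter`` times or until nothing is removed.
    Returned indices refer to rows of the input set.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y_all = np.asarray(
        y if y is not None else data.meta["day"].to_numpy(), dtype=float
    )
    g_all = np.asarray(
        group if group is not None else data.meta["specimen_id"].to_numpy()
    )
    keep = np.arange(data.n)
    excluded: list[int] = []
    for _ in range(max_iter):
        x = data.absorbance[keep]
        pred = _lolo_predictions(x, y_all[keep], g_all[keep], nr_lv)
        resid = np.abs(pred - y_all[keep])
        rmse = float(np.sqrt(np.mean(resid**2)))
        if rmse < 1e-8 * max(1.0, float(np.abs(y_all).max())):
            break  # model fits to numerical precision; nothing is an outlier
        bad = resid > threshold * rmse
        if not bad.any():
            break
        excluded.extend(keep[bad].tolist())
        keep = keep[~bad]
        if len(excluded) > 0.5 * data.n:
            raise RuntimeError(
                f"outlier exclusion removed {len(excluded)} of {data.n} rows; "
                "threshold too aggressive or data degenerate"
            )
    return data.select(keep), sorted(excluded)


def regression_vector_peaks(
    model: PlsModel, data: SpectraSet, min_rel_magnitude: float = 0.10
) -> pd.DataFrame:
    """Signed peaks of the channel-space regression vector (source ``pls_vector``)."""
    return pick_peaks(
        model.regression_vector,
        data.grid,
        min_rel_magnitude=min_rel_magnitude,
        source="pls_vector",
        context=f"NrLV {model.nr_lv}",
    )
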