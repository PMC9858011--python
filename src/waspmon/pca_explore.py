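"""Principal component analysis: decomposition, outlier screening, loading peaks.

PCA serves three roles in the workflow: compressing the collinear
wavelength channels ahead of LDA, screening spectral outliers, and — via
the loadings of the component along which day ordering emerges — locating
the wavelengths that drive storage-time variation.

The storage-trend component is not selected automatically (the study picks
PC 6 for inner and PC 7 for outer leaves by inspecting score ordering);
callers name the component to inspect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffspec import pick_peaks
from .spectra_io import SpectraSet

__all__ = ["PcaModel", "fit_pca", "flag_outliers", "loading_peaks"]


@dataclass
class PcaModel:
    """Top-k PCA of a spectra matrix.

    ``loadings`` has orthonormal columns (p x k); ``scores = (X - center) @
    loadings``.  ``eigenvalues`` are the full covariance spectrum (all
    min(n-1, p) of them), kept for the Q-residual control limit.
    """

    center: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def transform(self, x: np.ndarray, k: int | None = None) -> np.ndarray:
        k = self.k if k is None else k
        return (np.asarray(x, dtype=float) - self.center) @ self.loadings[:, :k]


def fit_pca(data: SpectraSet | np.ndarray, k: int) -> PcaModel:
    """Mean-centred PCA via SVD, keeping the top ``k`` components by variance.

    Deterministic sign convention: each loading's largest-|value| element is
    made positive, so peak signs in loading plots are reproducible.
    """
    x = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    n, p = x.shape
    max_k = min(n - 1, p)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}] for an {n}x{p} matrix, got {k}")
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = (s**2) / (n - 1)
    loadings = vt[:k].T.copy()
    # sign convention
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    total_var = xc.var(axis=0, ddof=1).sum()
    evr = eigenvalues[:k] / total_var if total_var > 0 else np.zeros(k)
    return PcaModel(
        center=center,
        loadings=loadings,
        explained_variance_ratio=evr,
        scores=xc @ loadings,
        eigenvalues=eigenvalues,
        n_samples=n,
    )


def hotelling_t2(model: PcaModel, k: int | None = None) -> np.ndarray:
    """Hotelling T² of each training row over the first ``k`` components."""
    k = model.k if k is None else k
    lam = model.eigenvalues[:k]
    return np.sum(model.scores[:, :k] ** 2 / lam, axis=1)


def q_residuals(model: PcaModel, data: SpectraSet | np.ndarray, k: int | None = None) -> np.ndarray:
    x = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    k = model.k if k is None else k
    t = (x - model.center) @ model.loadings[:, :k]
    resid = (x - model.center) - t @ model.loadings[:, :k].T
    return np.sum(resid**2, axis=1)


def t2_limit(model: PcaModel, k: int, alpha: float) -> float:
    """F-distribution control limit for training-set T² at level ``alpha``."""
    n = model.n_samples
    if k >= n:
        raise ValueError("k must be < number of samples")
    f = stats.f.ppf(1 - alpha, k, n - k)
    return k * (n - 1) / (n - k) * f


def q_limit(model: PcaModel, k: int, alpha: float) -> float:
    """Jackson-Mudholkar control limit for the Q residual at level ``alpha``.

    Uses the residual eigenvalue moments theta_i = sum lambda_j^i (j > k).
    If the residual spectrum is empty or degenerate the limit is 0.
    """
    lam = model.eigenvalues[k:]
    lam = lam[lam > 0]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = stats.norm.ppf(1 - alpha)
    inner = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    return float(th1 * max(inner, 0.0) ** (1.0 / h0))


def flag_outliers(
    model: PcaModel,
    data: SpectraSet | np.ndarray,
    k: int | None = None,
    alpha: float = 0.01,
    statistic: str = "either",
) -> np.ndarray:
    """Boolean mask of spectra exceeding T² and/or Q control limits.

    The study removes spectral outliers via PCA without naming a criterion;
    the rule here — Hotelling T² over the retained components against its
    F limit, and the Q residual against the Jackson-Mudholkar limit, either
    one flagging at ``alpha = 0.01`` — is this package's choice.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if statistic not in ("t2", "q", "either"):
        raise ValueError("statistic must be 't2', 'q' or 'either'")
    k = model.k if k is None else k
    masks = []
    if statistic in ("t2", "either"):
        masks.append(hotelling_t2(model, k) > t2_limit(model, k, alpha))
    if statistic in ("q", "either"):
        masks.append(q_residuals(model, data, k) > q_limit(model, k, alpha))
    out = masks[0]
    for m in masks[1:]:
        out = out | m
    return out


def loading_peaks(
    model: PcaModel,
    data: SpectraSet,
    component: int,
    min_rel_magnitude: float = 0.10,
) -> pd.DataFrame:
    """Signed peaks of one PCA loading, tagged ``pca_loading``.

    ``component`` is 1-based (PC 1 = largest variance), matching how
    components are referred to in loading plots.
    """
    if not 1 <= component <= model.k:
        raise ValueError(f"component must be in [1, {model.k}], got {component}")
    vec = model.loadings[:, component - 1]
    return pick_peaks(
        vec,
        data.grid,
        min_rel_magnitude=min_rel_magnitude,
        source="pca_loading",
        context=f"PC {component}",
    )
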