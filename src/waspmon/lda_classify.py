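"""PCA-LDA classification of storage day with grouped validation.

Spectra are compressed to ``nr_pcs`` principal components and classified
with Fisher linear discriminant analysis: discriminant directions maximise
the between-class to within-class variance ratio in PC space, and a sample
is assigned to the nearest class mean in discriminant space.

Validation is leave-one-lettuce-out (LOLO): all spectra of one head are
held out per fold, the PCA and LDA are refit on the remaining heads (no
specimen-level leakage), and pooled predictions over the folds form
percentage confusion matrices whose columns (one per true class) each sum
to 100; the average accuracy is the unweighted mean of the diagonal.
The number of retained components is chosen by threefold stratified
cross-validation over 1..30 components: highest validation accuracy, ties
broken by the smallest calibration-validation gap, then by fewer
components.

The per-wavelength contribution of a fitted model is obtained by folding
the discriminant directions back to channel space through the PCA loadings
and combining them with discriminant-eigenvalue weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .pca_explore import PcaModel, fit_pca
from .spectra_io import SpectraSet

__all__ = [
    "LdaModel",
    "ConfusionSummary",
    "confusion_from_predictions",
    "select_nr_pcs",
    "fit_lda",
    "lolo_validate",
    "wavelength_contributions",
]


@dataclass
class ConfusionSummary:
    """K x K percentage confusion matrix; columns = true class, rows = predicted."""

    labels: list
    matrix: np.ndarray
    average_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[f"pred {l}" for l in self.labels],
            columns=[f"true {l}" for l in self.labels],
        )


def confusion_from_predictions(y_true, y_pred, labels=None) -> ConfusionSummary:
    """Percentage confusion matrix per true class + unweighted diagonal mean.

    Entry (i, j) is the percentage of true-class-j samples predicted as
    class i, so every column with observations sums to 100.  The average
    accuracy is the plain mean of the diagonal percentages — the arithmetic
    used by the published classification tables.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = sorted(np.unique(y_true).tolist())
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        counts[idx[p], idx[t]] += 1
    col_tot = counts.sum(axis=0)
    pct = np.zeros_like(counts)
    nz = col_tot > 0
    pct[:, nz] = 100.0 * counts[:, nz] / col_tot[nz]
    diag = np.diag(pct)[nz]
    return ConfusionSummary(list(labels), pct, float(diag.mean()) if diag.size else float("nan"))


@dataclass
class LdaModel:
    nr_pcs: int
    pca: PcaModel
    class_labels: list
    discriminants: np.ndarray  # nr_pcs x n_discriminants, in PC space
    eigenvalue_share: np.ndarray  # weight of each discriminant
    class_means: np.ndarray  # n_classes x n_discriminants

    def _discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        return self.pca.transform(x, self.nr_pcs) @ self.discriminants

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Nearest class mean in discriminant space; ties go to the lowest label."""
        z = self._discriminant_scores(np.atleast_2d(np.asarray(x, dtype=float)))
        d2 = ((z[:, None, :] - self.class_means[None, :, :]) ** 2).sum(axis=2)
        # argmin returns the first (= lowest label, labels sorted) on ties
        return np.asarray(self.class_labels)[np.argmin(d2, axis=1)]


def fit_lda(data: SpectraSet | np.ndarray, labels, nr_pcs: int) -> LdaModel:
    """PCA compression to ``nr_pcs`` scores, then Fisher LDA.

    Solves the generalized eigenproblem S_b v = lambda S_w v in PC space and
    keeps the top ``n_classes - 1`` directions.  Raises if the within-class
    scatter is singular (too many PCs for the class sample sizes).
    """
    x = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    y = np.asarray(labels)
    if len(y) != x.shape[0]:
        raise ValueError("labels length must match number of spectra")
    class_labels = sorted(np.unique(y).tolist())
    if len(class_labels) < 2:
        raise ValueError("need at least two classes")
    pca = fit_pca(x, nr_pcs)
    t = pca.scores  # n x nr_pcs
    overall = t.mean(axis=0)
    sw = np.zeros((nr_pcs, nr_pcs))
    sb = np.zeros((nr_pcs, nr_pcs))
    means = []
    for lab in class_labels:
        tc = t[y == lab]
        mc = tc.mean(axis=0)
        means.append(mc)
        dev = tc - mc
        sw += dev.T @ dev
        db = (mc - overall)[:, None]
        sb += len(tc) * (db @ db.T)
    sw_eigs = np.linalg.eigvalsh(sw)
    if sw_eigs[0] <= 1e-10 * max(sw_eigs[-1], 1e-300):
        raise ValueError(
            "within-class scatter is singular; reduce nr_pcs or add samples"
        )
    try:
        evals, evecs = linalg.eigh(sb, sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular; reduce nr_pcs or add samples"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_disc = min(len(class_labels) - 1, nr_pcs)
    w = evecs[:, order[:n_disc]]
    ev = np.clip(evals[order[:n_disc]], 0, None)
    share = ev / ev.sum() if ev.sum() > 0 else np.full(n_disc, 1.0 / n_disc)
    class_means = np.vstack(means) @ w
    return LdaModel(
        nr_pcs=nr_pcs,
        pca=pca,
        class_labels=class_labels,
        discriminants=w,
        eigenvalue_share=share,
        class_means=class_means,
    )


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (fold index per sample)."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for lab in np.unique(y):
        idx = np.flatnonzero(y == lab)
        if len(idx) < folds:
            raise ValueError(f"class {lab!r} has fewer samples ({len(idx)}) than folds")
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


def select_nr_pcs(
    data: SpectraSet | np.ndarray,
    labels,
    max_pcs: int = 30,
    folds: int = 3,
    seed: int = 0,
) -> int:
    """Choose the PC count by stratified cross-validated LDA accuracy.

    Scans 1..max_pcs; returns the count with the highest validation
    accuracy, ties broken by the smallest |calibration - validation| gap,
    then by the smaller count.
    """
    x = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    fold_idx = _stratified_folds(y, folds, seed)
    best = None
    for k in range(1, max_pcs + 1):
        cal_acc, val_acc = [], []
        ok = True
        for f in fold_idx:
            train = np.setdiff1d(np.arange(len(y)), f)
            if len(np.unique(y[train])) < len(np.unique(y)):
                ok = False
                break
            try:
                model = fit_lda(x[train], y[train], k)
            except ValueError:
                ok = False
                break
            cal_acc.append(np.mean(model.predict(x[train]) == y[train]))
            val_acc.append(np.mean(model.predict(x[f]) == y[f]))
        if not ok:
            continue
        key = (-np.mean(val_acc), abs(np.mean(cal_acc) - np.mean(val_acc)), k)
        if best is None or key < best[0]:
            best = (key, k)
    if best is None:
        raise ValueError("no PC count admitted a valid stratified CV fit")
    return best[1]


def lolo_validate(
    data: SpectraSet,
    labels=None,
    group=None,
    nr_pcs: int = 24,
) -> tuple[ConfusionSummary, ConfusionSummary]:
    """Leave-one-specimen-out validation of PCA-LDA day classification.

    For each held-out specimen the PCA and LDA are refit on the remaining
    specimens; in-fold (calibration) and held-out (validation) predictions
    are pooled over all folds into percentage confusion matrices.
    """
    y = np.asarray(labels if labels is not None else data.meta["day"].to_numpy())
    g = np.asarray(group if group is not None else data.meta["specimen_id"].to_numpy())
    specimens = sorted(np.unique(g).tolist())
    if len(specimens) < 2:
        raise ValueError("LOLO validation needs at least 2 specimens")
    class_labels = sorted(np.unique(y).tolist())
    cal_true, cal_pred, val_true, val_pred = [], [], [], []
    for s in specimens:
        held = g == s
        train = ~held
        if set(np.unique(y[train])) != set(class_labels):
            warnings.warn(
                f"fold holding out {s!r}: training set misses a class; fold skipped"
            )
            continue
        model = fit_lda(data.absorbance[train], y[train], nr_pcs)
        cal_true.append(y[train])
        cal_pred.append(model.predict(data.absorbance[train]))
        val_true.append(y[held])
        val_pred.append(model.predict(data.absorbance[held]))
    cal = confusion_from_predictions(
        np.concatenate(cal_true), np.concatenate(cal_pred), class_labels
    )
    val = confusion_from_predictions(
        np.concatenate(val_true), np.concatenate(val_pred), class_labels
    )
    return cal, val


def wavelength_contributions(model: LdaModel, mode: str = "eigenweighted") -> np.ndarray:
    """Overall per-channel contribution of a PCA-LDA model, max-normalised.

    Each discriminant direction is back-projected to channel space through
    the PCA loadings; channel contributions are the discriminant-eigenvalue
    weighted sum of their absolute values (``eigenweighted``, default) or
    the root of the weighted sum of squares (``sumsq``).  The result is
    invariant to orthogonal re-rotations of the retained PC basis because
    the back-projected vectors themselves are.
    """
    if mode not in ("eigenweighted", "sumsq"):
        raise ValueError("mode must be 'eigenweighted' or 'sumsq'")
    b = model.pca.loadings[:, : model.nr_pcs] @ model.discriminants  # p x D
    w = model.eigenvalue_share
    if mode == "eigenweighted":
        contrib = (np.abs(b) * w[None, :]).sum(axis=1)
    else:
        contrib = np.sqrt(((b**2) * w[None, :]).sum(axis=1))
    m = contrib.max()
    return contrib / m if m > 0 else contrib
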