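"""Classical reference pipeline: CSP + shrinkage LDA for EEG, mean/slope
features + shrinkage LDA for fNIRS, and sliding-window cross-validated
evaluation.

Common spatial patterns solve the generalized eigenproblem of the two
trial-averaged class covariances (trace-normalized); kept filters come in
pairs from the two spectral extremes, and features are the log of the
normalized variance of each projected component.  The classifier is LDA
with a Ledoit-Wolf-shrunken covariance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import RepeatedStratifiedKFold

from .containers import Epoch, LABELS


# ---------------------------------------------------------------------------
# CSP


@dataclass
class CspModel:
    filters: np.ndarray          # (components, channels)
    eigenvalue_ratios: np.ndarray  # variance share of class 0 per component
    n_components: int


def _class_covariance(epochs: list[np.ndarray]) -> np.ndarray:
    covs = []
    for x in epochs:
        c = x @ x.T
        covs.append(c / np.trace(c))
    return np.mean(covs, axis=0)


def csp_fit(
    epochs_class0: list[np.ndarray | Epoch],
    epochs_class1: list[np.ndarray | Epoch],
    n_components: int = 4,
    reg: float = 1e-10,
) -> CspModel:
    """Fit CSP filters by simultaneous diagonalization of the two class
    covariances; keep ``n_components/2`` filters from each extreme."""
    if len(epochs_class0) < 2 or len(epochs_class1) < 2:
        raise ValueError("CSP needs at least 2 epochs per class")
    get = lambda e: e.data if isinstance(e, Epoch) else np.asarray(e)
    c0 = _class_covariance([get(e) for e in epochs_class0])
    c1 = _class_covariance([get(e) for e in epochs_class1])
    n_chan = c0.shape[0]
    composite = c0 + c1 + reg * np.eye(n_chan)
    try:
        evals, evecs = linalg.eigh(c0, composite)
    except linalg.LinAlgError as err:
        raise ValueError(f"rank-deficient covariances: {err}") from err
    order = np.argsort(evals)[::-1]  # large ratio = class-0 dominant
    evals, evecs = evals[order], evecs[:, order]
    half = n_components // 2
    keep = list(range(half)) + list(range(n_chan - half, n_chan))
    return CspModel(
        filters=evecs[:, keep].T,
        eigenvalue_ratios=evals[keep],
        n_components=n_components,
    )


def csp_features(model: CspModel, epoch: np.ndarray | Epoch) -> np.ndarray:
    """Log of normalized variance of each projected component."""
    x = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch)
    proj = model.filters @ x
    var = proj.var(axis=1)
    if np.any(var == 0):
        raise ValueError("zero-variance CSP component")
    return np.log(var / var.sum())


# ---------------------------------------------------------------------------
# fNIRS features


def mean_slope_features(epoch: np.ndarray | Epoch) -> np.ndarray:
    """Per-channel (mean, least-squares slope), concatenated.

    The slope is per second when the input is an :class:`Epoch` (per sample
    for a bare array).
    """
    if isinstance(epoch, Epoch):
        x = epoch.data
        t = np.arange(x.shape[1]) / epoch.sample_rate_hz
    else:
        x = np.asarray(epoch)
        t = np.arange(x.shape[1], dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples for a slope")
    tc = t - t.mean()
    slope = (x * tc).sum(axis=1) / (tc ** 2).sum()
    return np.concatenate([x.mean(axis=1), slope])


# ---------------------------------------------------------------------------
# shrinkage LDA


def slda_fit(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """LDA with Ledoit-Wolf analytic shrinkage of the pooled covariance."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("sLDA needs samples from both classes")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    return clf.fit(np.asarray(features), labels)


def slda_predict(model: LinearDiscriminantAnalysis, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features))


# ---------------------------------------------------------------------------
# sliding-window evaluation


def _window_starts(range_s: tuple[float, float], window_s: float, step_s: float) -> list[float]:
    lo, hi = range_s
    n = int(np.floor((hi - lo - window_s) / step_s)) + 1
    return [lo + i * step_s for i in range(n)]


def sliding_window_eval(
    trials: list[tuple[Epoch, str]],
    featurizer,
    window_s: float = 3.0,
    step_s: float = 1.0,
    range_s: tuple[float, float] = (-5.0, 20.0),
    n_splits: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[list[float], np.ndarray, float]:
    """Cross-validated accuracy per sliding window; the final score is the
    maximum over windows.

    ``trials`` holds (epoch, label) pairs whose epochs cover ``range_s``
    around the cue.  ``featurizer(window_epochs_by_class_or_list)`` is a
    callable mapping the per-window training epochs and test epochs to
    feature matrices; see :func:`csp_slda_featurizer` and
    :func:`mean_slope_featurizer`.  Folds are stratified, repeated and
    seeded.
    """
    starts = _window_starts(range_s, window_s, step_s)
    epochs = [e for e, _ in trials]
    for e in epochs:
        if e.t_start_s > range_s[0] or e.t_start_s + e.duration_s < range_s[1]:
            raise ValueError(
                f"trial context [{e.t_start_s}, {e.t_start_s + e.duration_s}) s "
                f"does not cover the sliding range {range_s}"
            )
    y = np.array([LABELS.index(lab) for _, lab in trials])
    accs = []
    for start in starts:
        cut = []
        for e in epochs:
            i0 = int(round((start - e.t_start_s) * e.sample_rate_hz))
            n = int(round(window_s * e.sample_rate_hz))
            cut.append(e.data[:, i0 : i0 + n])
        cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                     random_state=seed)
        fold_accs = []
        for tr_idx, te_idx in cv.split(np.zeros(len(cut)), y):
            Xtr, Xte = featurizer([cut[i] for i in tr_idx], y[tr_idx],
                                  [cut[i] for i in te_idx])
            clf = slda_fit(Xtr, y[tr_idx])
            fold_accs.append(float((slda_predict(clf, Xte) == y[te_idx]).mean()))
        accs.append(float(np.mean(fold_accs)))
    accs_arr = np.asarray(accs)
    return starts, accs_arr, float(accs_arr.max())


def csp_slda_featurizer(n_components: int = 4):
    """Featurizer closure: fit CSP on the training windows, project both."""

    def featurize(train_windows, train_y, test_windows):
        c0 = [w for w, lab in zip(train_windows, train_y) if lab == 0]
        c1 = [w for w, lab in zip(train_windows, train_y) if lab == 1]
        model = csp_fit(c0, c1, n_components=n_components)
        Xtr = np.stack([csp_features(model, w) for w in train_windows])
        Xte = np.stack([csp_features(model, w) for w in test_windows])
        return Xtr, Xte

    return featurize


def mean_slope_featurizer():
    """Featurizer closure for the fNIRS mean/slope features."""

    def featurize(train_windows, train_y, test_windows):
        Xtr = np.stack([mean_slope_features(w) for w in train_windows])
        Xte = np.stack([mean_slope_features(w) for w in test_windows])
        return Xtr, Xte

    return featurize
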