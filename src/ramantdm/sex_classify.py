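"""Donor-sex and pool discrimination from preprocessed spectra.

Dimension reduction by PCA (5 components or a 95% cumulative-variance
criterion), classification by LDA or SVM (linear kernel, cost 1000; radial
kernel, cost 10000, gamma 1), evaluated by repeated donor-grouped stratified
80/20 splits and threshold-averaged ROC curves.  Discriminant directions can
be mapped back through the PCA loadings to wavenumber space ("weighting
vectors") to attribute the discrimination to chemical bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .errors import RamanTDMError


@dataclass
class ReducedData:
    """PCA scores/loadings with a deterministic sign convention."""

    scores: np.ndarray                # samples x PCs
    loadings: np.ndarray              # PCs x channels, rows orthonormal
    explained_variance_ratio: np.ndarray
    n_pcs: int
    mean: np.ndarray                  # channel means removed before projection


def pca_reduce(
    X: np.ndarray,
    n_pcs: int | None = None,
    variance: float | None = None,
) -> ReducedData:
    """Centered PCA with either a fixed component count or a variance target.

    The variance selector returns the smallest k whose cumulative explained
    ratio reaches the threshold.  Signs are fixed so each loading's
    largest-magnitude element is positive.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if (n_pcs is None) == (variance is None):
        raise ValueError("specify exactly one of n_pcs or variance")
    if variance is not None and variance > 1:
        raise ValueError("variance threshold must be <= 1")
    max_k = min(X.shape[0] - 1, X.shape[1])
    # full SVD: deterministic (the auto-selected randomized solver is not)
    pca = PCA(n_components=max_k if n_pcs is None else min(n_pcs, max_k),
              svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if variance is not None:
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, variance - 1e-12) + 1)
        k = min(k, max_k)
    else:
        k = pca.n_components_
    loadings = pca.components_[:k]
    scores = scores[:, :k]
    signs = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    return ReducedData(
        scores=scores * signs,
        loadings=loadings * signs[:, None],
        explained_variance_ratio=ratios[:k],
        n_pcs=k,
        mean=pca.mean_,
    )


@dataclass
class ClassifierModel:
    """A trained classifier plus the feature standardization it expects."""

    kind: str
    estimator: object
    feat_mean: np.ndarray
    feat_std: np.ndarray
    classes: np.ndarray
    positive: object


DEFAULT_PARAMS = {
    "lda": {},
    "svm_linear": {"cost": 1000.0},
    "svm_radial": {"cost": 10000.0, "gamma": 1.0},
}


def train_classifier(
    scores: np.ndarray,
    labels: np.ndarray,
    kind: str = "lda",
    params: dict | None = None,
    positive: object | None = None,
) -> ClassifierModel:
    """Train LDA or an SVM on centered, globally rescaled reduced features.

    Features are centered and divided by one common scalar (the rms score
    scale), so the radial kernel width gamma refers to a data-wide unit
    while the variance ordering of the principal components — the reason
    for reducing with PCA in the first place — is preserved.  Per-feature
    standardization would instead amplify near-noise components to the
    scale of the leading ones.  The positive class defaults to the
    alphabetically first label.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise RamanTDMError("classification needs at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise RamanTDMError(f"class {c!r} has fewer than 2 members")
    p = dict(DEFAULT_PARAMS[kind])
    if params:
        p.update(params)
    mean = scores.mean(axis=0)
    scale = float(np.sqrt(np.mean(scores.var(axis=0))))
    std = np.full(scores.shape[1], scale if scale > 0 else 1.0)
    Z = (scores - mean) / std
    if kind == "lda":
        est = LinearDiscriminantAnalysis()
    elif kind == "svm_linear":
        est = SVC(kernel="linear", C=p["cost"])
    elif kind == "svm_radial":
        est = SVC(kernel="rbf", C=p["cost"], gamma=p["gamma"])
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(Z, labels)
    pos = positive if positive is not None else sorted(classes)[0]
    return ClassifierModel(kind, est, mean, std, classes, pos)


def decision_scores(model: ClassifierModel, scores: np.ndarray) -> np.ndarray:
    """Continuous decision score oriented so larger means 'positive class'.

    LDA contributes the posterior probability of the positive class; SVMs
    contribute the signed distance to the separating surface.
    """
    Z = (np.asarray(scores, float) - model.feat_mean) / model.feat_std
    est = model.estimator
    if model.kind == "lda":
        proba = est.predict_proba(Z)
        col = list(est.classes_).index(model.positive)
        return proba[:, col]
    d = est.decision_function(Z)
    if d.ndim > 1:
        raise RamanTDMError("multiclass decision scores are not ROC-orientable")
    # sklearn orients decision_function toward classes_[1]
    return d if est.classes_[1] == model.positive else -d


def training_accuracy(model: ClassifierModel, scores: np.ndarray,
                      labels: np.ndarray) -> float:
    Z = (np.asarray(scores, float) - model.feat_mean) / model.feat_std
    return float(np.mean(model.estimator.predict(Z) == np.asarray(labels)))


def cross_validate(
    scores: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    kind: str = "lda",
    params: dict | None = None,
    k: int = 20,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.2,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``k`` repeated stratified 80/20 splits, grouped by donor.

    All spectra of one donor stay on the same side of each split, and the
    held-out set contains at least one donor per class.  Returns the
    held-out (decision score, truth) pairs per repeat.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if rng is None:
        rng = np.random.default_rng(0)
    units = list(dict.fromkeys(groups.tolist()))
    unit_label = {u: labels[groups == u][0] for u in units}
    classes = np.unique(labels)
    out = []
    for _ in range(k):
        for _attempt in range(100):
            held: list = []
            for c in classes:
                members = [u for u in units if unit_label[u] == c]
                n_hold = max(1, int(round(test_fraction * len(members))))
                if n_hold >= len(members):
                    raise RamanTDMError(
                        f"class {c!r} too small for a grouped split"
                    )
                held += list(rng.choice(members, size=n_hold, replace=False))
            te = np.isin(groups, held)
            tr = ~te
            if all((labels[tr] == c).sum() >= 2 for c in classes):
                break
        else:
            raise RamanTDMError("could not build a valid grouped split")
        model = train_classifier(scores[tr], labels[tr], kind, params)
        out.append((decision_scores(model, scores[te]), labels[te]))
    return out


@dataclass
class ROCSummary:
    """Threshold-averaged ROC over CV repeats with per-repeat AUC stats."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    auc_mean: float
    auc_sd: float
    n_repeats: int
    auc_per_repeat: np.ndarray = field(default_factory=lambda: np.array([]))


def threshold_averaged_roc(
    per_repeat: list[tuple[np.ndarray, np.ndarray]],
    positive: object | None = None,
) -> ROCSummary:
    """Average ROC curves across repeats at common decision thresholds.

    The union of all observed scores forms the threshold set; at each
    threshold every repeat contributes its (FPR, TPR), and the mean curve is
    the average of those points.  AUC is computed per repeat on that
    repeat's own curve (trapezoid) and summarized as mean +- sd.
    """
    if not per_repeat:
        raise ValueError("need at least one repeat")
    if positive is None:
        labels = np.unique(np.concatenate([t for _, t in per_repeat]))
        positive = sorted(labels)[0]
    for s, t in per_repeat:
        if np.unique(t).size < 2:
            raise RamanTDMError("a repeat contains only one class")
    thresholds = np.unique(np.concatenate([s for s, _ in per_repeat]))
    thresholds = np.concatenate(([np.inf], thresholds[::-1], [-np.inf]))
    fprs, tprs, aucs = [], [], []
    for s, t in per_repeat:
        pos = np.asarray(t) == positive
        n_pos, n_neg = pos.sum(), (~pos).sum()
        # predicted positive when score >= threshold
        tpr = np.array([(s[pos] >= th).sum() / n_pos for th in thresholds])
        fpr = np.array([(s[~pos] >= th).sum() / n_neg for th in thresholds])
        fprs.append(fpr)
        tprs.append(tpr)
        aucs.append(roc_auc_score(pos.astype(int), s))
    fprs = np.vstack(fprs)
    tprs = np.vstack(tprs)
    aucs = np.asarray(aucs)
    return ROCSummary(
        fpr_grid=fprs.mean(axis=0),
        mean_tpr=tprs.mean(axis=0),
        sd_tpr=tprs.std(axis=0, ddof=1) if len(per_repeat) > 1 else np.zeros(
            thresholds.size),
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        n_repeats=len(per_repeat),
        auc_per_repeat=aucs,
    )


@dataclass
class WeightingVector:
    """Discriminant coefficients mapped back to wavenumber space."""

    wavenumbers: np.ndarray
    weights: np.ndarray               # axes x channels (LD1, LD2, ...)
    extrema: list[list[tuple[float, float]]]  # per axis: (cm^-1, weight)


def discriminant_weighting(
    lda_model: ClassifierModel,
    reduced: ReducedData,
    wavenumbers: np.ndarray,
) -> WeightingVector:
    """Scaled-loading weighting vectors for each LDA discriminant axis.

    weights = loadings^T . discriminant coefficients.  Extrema are local
    maxima of |weight| above the 90th percentile, reported with their
    wavenumber so they can be assigned to chemical bands.
    """
    if lda_model.kind != "lda":
        raise ValueError("weighting vectors are defined for LDA models")
    scalings = np.asarray(lda_model.estimator.scalings_)  # features x axes
    if scalings.shape[0] != reduced.loadings.shape[0]:
        raise ValueError("LDA feature count does not match PCA loadings")
    # undo the feature standardization so coefficients refer to raw scores
    coeffs = scalings / lda_model.feat_std[:, None]
    weights = (reduced.loadings.T @ coeffs).T  # axes x channels
    wavenumbers = np.asarray(wavenumbers, float)
    extrema = []
    for w in weights:
        a = np.abs(w)
        thresh = np.percentile(a, 90)
        local = (a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:]) & (a[1:-1] >= thresh)
        idx = np.flatnonzero(local) + 1
        extrema.append([(float(wavenumbers[i]), float(w[i])) for i in idx])
    return WeightingVector(wavenumbers, weights, extrema)
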