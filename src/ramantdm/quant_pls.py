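"""PLS calibration from spectra to concentration.

The calibration follows common chemometric practice: spectra truncated to
the informative window and vector normalized, then a PLS regression with the
number of latent components (3-5 by default) chosen by minimizing the
cross-validated RMSEP over 50 repeated random 80/20 splits.  Replicates of
one physical sample always stay on the same side of a split, and splits are
stratified so every training partition spans the calibration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .errors import RamanTDMError


@dataclass
class RMSEPValue:
    """Root-mean-square error of prediction, in concentration units (uM)."""

    value: float
    n: int


def rmsep(y_true: np.ndarray, y_pred: np.ndarray) -> RMSEPValue:
    """sqrt(mean((y_true - y_pred)^2))."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 1:
        raise ValueError("rmsep needs at least one point")
    return RMSEPValue(float(np.sqrt(np.mean((y_true - y_pred) ** 2))), y_true.size)


@dataclass
class PLSModel:
    """A fitted PLS calibration.

    ``y`` is standardized internally; predictions are returned in uM.
    ``cv_rmsep_by_ncomp`` is populated by :func:`select_ncomp` when the model
    comes out of the component-selection path.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    y_std: float
    coef: np.ndarray  # (channels,) regression vector on centered X, scaled y
    training_range: tuple[float, float]
    n_channels: int
    cv_rmsep_by_ncomp: dict[int, float] = field(default_factory=dict)


@dataclass
class PredictionResult:
    """Predicted concentrations plus an out-of-training-range flag per row."""

    values: np.ndarray
    out_of_range: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS regression (NIPALS with deflation on X, as in scikit-learn).

    X is column-centered and y standardized internally; no per-channel
    scaling is applied (channels share the same intensity units).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("row count of X must equal length of y")
    if X.shape[0] < n_components + 1:
        raise RamanTDMError(
            f"{X.shape[0]} samples cannot support {n_components} components"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise RamanTDMError(
            f"n_components={n_components} exceeds the centered-data rank {rank}"
        )
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1)) if y.size > 1 else 1.0
    if y_std == 0.0:
        y_std = 1.0
    ys = (y - y_mean) / y_std
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, ys)
    coef = np.asarray(pls.coef_).ravel()
    return PLSModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=y_mean,
        y_std=y_std,
        coef=coef,
        training_range=(float(y.min()), float(y.max())),
        n_channels=X.shape[1],
    )


def predict_pls(model: PLSModel, X: np.ndarray) -> PredictionResult:
    """Predict concentrations; out-of-range rows are flagged, never clipped."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"channel count {X.shape[1]} != training channels {model.n_channels}"
        )
    ys = (X - model.x_mean) @ model.coef
    y = ys * model.y_std + model.y_mean
    lo, hi = model.training_range
    return PredictionResult(values=y, out_of_range=(y < lo) | (y > hi))


def _split_units(
    units: list, unit_conc: np.ndarray, rng: np.random.Generator,
    train_fraction: float = 0.8, max_tries: int = 100,
) -> tuple[list, list]:
    """Hold out ~20% of sample units, keeping the concentration extremes in
    training (stratification so the model always spans the range)."""
    n = len(units)
    n_hold = max(1, int(round((1.0 - train_fraction) * n)))
    if n - n_hold < 2:
        raise RamanTDMError("too few sample units for an 80/20 split")
    cmin, cmax = unit_conc.min(), unit_conc.max()
    for _ in range(max_tries):
        hold = rng.choice(n, size=n_hold, replace=False)
        train = np.setdiff1d(np.arange(n), hold)
        tc = unit_conc[train]
        if tc.min() == cmin and tc.max() == cmax:
            return [units[i] for i in train], [units[i] for i in hold]
    raise RamanTDMError("could not build a range-spanning split")


def select_ncomp(
    X: np.ndarray,
    y: np.ndarray,
    candidates: tuple[int, ...] = (3, 4, 5),
    folds: int = 50,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the component count minimizing mean CV RMSEP.

    Cross-validation is ``folds`` repeated random 80/20 splits at the level
    of sample units (``groups``), so replicate spectra never leak across a
    split.  Ties go to the smaller component count.  Returns the selected
    count and the mean CV RMSEP per candidate.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if rng is None:
        rng = np.random.default_rng(0)
    if groups is None:
        groups = np.arange(y.size)
    groups = np.asarray(groups)
    units = list(dict.fromkeys(groups.tolist()))
    unit_conc = np.array([y[groups == u].mean() for u in units])
    max_cand = max(candidates)
    errors: dict[int, list[float]] = {c: [] for c in candidates}
    for _ in range(folds):
        train_u, test_u = _split_units(units, unit_conc, rng)
        tr = np.isin(groups, train_u)
        te = np.isin(groups, test_u)
        if tr.sum() < max_cand + 1:
            raise RamanTDMError("training partition too small for candidates")
        for c in candidates:
            model = fit_pls(X[tr], y[tr], c)
            pred = predict_pls(model, X[te]).values
            errors[c].append(rmsep(y[te], pred).value)
    mean_err = {c: float(np.mean(v)) for c, v in errors.items()}
    best = min(sorted(candidates), key=lambda c: (mean_err[c], c))
    return best, mean_err


def fit_pls_cv(
    X: np.ndarray,
    y: np.ndarray,
    candidates: tuple[int, ...] = (3, 4, 5),
    folds: int = 50,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> PLSModel:
    """Component selection followed by a final fit on all data."""
    best, mean_err = select_ncomp(X, y, candidates, folds, rng, groups)
    model = fit_pls(X, y, best)
    model.cv_rmsep_by_ncomp = mean_err
    return model
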