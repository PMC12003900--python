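"""Univariate marker-band quantification against a reference urine matrix.

Spectra are maxima-normalized at the ~1605 cm^-1 urea band, the median
reference-matrix spectrum is subtracted, and a Gaussian profile is fitted to
the piperacillin marker band at ~1485 cm^-1.  Fitted amplitudes against
spiked concentrations give a straight-line calibration whose intercept
standard error sigma_n and slope m yield the detection and quantification
limits per the ICH convention:

    LoD = 3.3 * sigma_n / m        LoQ = 10 * sigma_n / m

Reference matrices compositionally distant from the sample (e.g. a male
urine pool for a female sample) leave residual matrix structure in the
difference spectra, curving the calibration and inflating sigma_n, hence a
worse LoD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .core_io import Spectrum, same_axis
from .errors import AxisMismatchError, RamanTDMError, SlopeSignError

#: molar masses of piperacillin, g/mol
MOLAR_MASS_SODIUM_SALT = 539.5
MOLAR_MASS_FREE_ACID = 517.55

MARKER_CENTER = 1485.0
NORM_CENTER = 1605.0
NORM_WINDOW = 15.0


@dataclass
class GaussianFit:
    """One fitted marker band: amplitude * exp(-(w-c)^2 / 2 sigma^2) + offset."""

    amplitude: float
    center: float
    sigma: float
    offset: float
    amplitude_se: float
    converged: bool
    message: str = ""


@dataclass
class CalibrationCurve:
    """OLS line amplitude = m * c + b with ICH detection limits."""

    slope: float                 # m, a.u. per uM
    intercept: float             # b, a.u.
    sigma_n: float               # standard error of the intercept, a.u.
    r_squared: float
    n_points: int
    lod_uM: float
    loq_uM: float


def _assert_normalized(spec: Spectrum, name: str) -> None:
    mask = np.abs(spec.wavenumbers - NORM_CENTER) <= NORM_WINDOW
    if not mask.any():
        raise RamanTDMError(f"{name}: no channels near {NORM_CENTER} cm^-1")
    apex = spec.intensities[mask].max()
    if abs(apex - 1.0) > 1e-9:
        raise RamanTDMError(
            f"{name} is not maxima-normalized at ~{NORM_CENTER} cm^-1 "
            f"(apex = {apex:.6g}); normalize(mode='max_at') first"
        )


def difference_spectrum(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Channel-wise sample minus reference, both maxima-normalized at ~1605."""
    if not same_axis(sample.wavenumbers, reference.wavenumbers):
        raise AxisMismatchError("sample and reference axes differ")
    _assert_normalized(sample, "sample")
    _assert_normalized(reference, "reference")
    return sample.with_intensities(sample.intensities - reference.intensities)


def _gauss(w, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((w - center) / sigma) ** 2) + offset


def fit_marker_band(
    diff: Spectrum,
    center0: float = MARKER_CENTER,
    window: float = 30.0,
    center_tol: float = 10.0,
    with_offset: bool = True,
) -> GaussianFit:
    """Bounded nonlinear least-squares Gaussian fit in ``center0 +- window``.

    The band position is known, so the fitted center is constrained to
    ``center0 +- center_tol``; letting it roam the whole window makes the
    fit bistable when residual matrix structure sits at the window edge.
    The constant offset absorbs residual baseline in the difference
    spectrum.  Non-convergence after restarts is reported in the fit flags,
    never silently.
    """
    mask = np.abs(diff.wavenumbers - center0) <= window
    if mask.sum() < 8:
        raise RamanTDMError("marker window contains fewer than 8 channels")
    w = diff.wavenumbers[mask]
    y = diff.intensities[mask]
    span = float(y.max() - y.min())
    lo = [-np.inf, center0 - center_tol, 1.0, -np.inf]
    hi = [np.inf, center0 + center_tol, window, np.inf]
    if not with_offset:
        lo[3], hi[3] = -1e-12, 1e-12
    starts = [
        (max(span, 1e-12), center0, 8.0, float(np.median(y))),
        (max(span, 1e-12), center0, 4.0, float(y.min())),
        (-max(span, 1e-12), center0, 8.0, float(np.median(y))),
    ]
    last_err = ""
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            popt, pcov = curve_fit(
                _gauss, w, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except RuntimeError as exc:  # no convergence for this start
            last_err = str(exc)
            continue
        se = float(np.sqrt(np.abs(pcov[0, 0])))
        return GaussianFit(
            amplitude=float(popt[0]), center=float(popt[1]),
            sigma=float(popt[2]), offset=float(popt[3]),
            amplitude_se=se, converged=True,
        )
    return GaussianFit(
        amplitude=float("nan"), center=center0, sigma=float("nan"),
        offset=float("nan"), amplitude_se=float("nan"),
        converged=False, message=f"no convergence after restarts: {last_err}",
    )


def lod_loq(sigma_n: float, m: float) -> tuple[float, float]:
    """ICH detection/quantification limits (3.3, 10) * sigma_n / m."""
    if m <= 0:
        raise SlopeSignError("calibration slope must be positive")
    if sigma_n < 0:
        raise ValueError("sigma_n must be >= 0")
    return 3.3 * sigma_n / m, 10.0 * sigma_n / m


def build_calibration(
    concentrations: np.ndarray, amplitudes: np.ndarray
) -> CalibrationCurve:
    """OLS of fitted amplitudes on spiked concentrations, with ICH limits.

    ``sigma_n`` is the classical OLS standard error of the intercept.
    Duplicate concentration levels (replicates) are allowed and counted
    individually in ``n_points``.
    """
    c = np.asarray(concentrations, float)
    a = np.asarray(amplitudes, float)
    if c.shape != a.shape:
        raise ValueError("concentrations and amplitudes differ in length")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    res = sm.OLS(a, sm.add_constant(c)).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise SlopeSignError(
            f"calibration slope {slope:.3g} <= 0; quantification impossible"
        )
    sigma_n = float(res.bse[0])
    lod, loq = lod_loq(sigma_n, float(slope))
    return CalibrationCurve(
        slope=float(slope), intercept=float(intercept), sigma_n=sigma_n,
        r_squared=float(res.rsquared), n_points=int(c.size),
        lod_uM=lod, loq_uM=loq,
    )


def percent_deviation(lod_reference_pool: float, lod_own: float) -> float:
    """Relative LoD penalty of a pooled reference vs the sample's own matrix,
    in percent of the pooled-reference LoD."""
    if lod_reference_pool <= 0:
        raise ValueError("pooled-reference LoD must be positive")
    return 100.0 * (lod_reference_pool - lod_own) / lod_reference_pool


def umol_to_mgL(c_uM: float, molar_mass: float = MOLAR_MASS_SODIUM_SALT) -> float:
    """Convert a concentration in uM to mg/L given a molar mass in g/mol."""
    if c_uM < 0:
        raise ValueError("concentration must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return c_uM * molar_mass / 1000.0
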