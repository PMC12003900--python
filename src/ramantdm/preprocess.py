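"""Spectral conditioning chain.

The quantification pipelines apply, in order: wavenumber calibration,
truncation to the region of interest (1800-800 cm^-1), Savitzky-Golay
smoothing (p=2, n=5), extended multiplicative signal correction (EMSC,
polynomial degree 6) against the per-sample median spectrum, SNIP baseline
removal (20 iterations, second-order clipping filter), and finally a
task-specific truncation plus normalization (vector norm for multivariate
models, maxima normalization at the ~1605 cm^-1 urea band for difference
spectra).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from dataclasses import replace as _dc_replace

from .core_io import Spectrum, same_axis


def _meta_copy(spec: Spectrum):
    return _dc_replace(spec.meta, extra=dict(spec.meta.extra))
from .errors import (
    AxisMismatchError,
    CalibrationError,
    DegenerateFitError,
    NormalizationError,
    RangeError,
)


# ---------------------------------------------------------------------------
# wavenumber calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationMap:
    """Polynomial map from measured to true wavenumbers (cm^-1).

    Fitted against reference band positions of calibration standards
    (e.g. acetonitrile, Teflon, toluene).  The map must be strictly
    increasing over the instrument range it was fitted on.
    """

    coefficients: np.ndarray  # ascending powers
    degree: int
    residual_rms: float
    fitted_range: tuple[float, float]

    def __call__(self, w: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(w, float),
                                                self.coefficients)


def fit_wavenumber_calibration(
    measured_peaks: np.ndarray,
    reference_peaks: np.ndarray,
    degree: int = 2,
) -> CalibrationMap:
    """Least-squares polynomial mapping measured to reference peak positions."""
    measured = np.asarray(measured_peaks, float)
    reference = np.asarray(reference_peaks, float)
    if measured.shape != reference.shape:
        raise ValueError("measured and reference peak lists differ in length")
    if measured.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} peaks for a degree-{degree} fit"
        )
    if np.any(np.diff(measured) <= 0):
        raise ValueError("peak positions must be sorted strictly increasing")
    series = np.polynomial.Polynomial.fit(measured, reference, degree)
    coeffs = series.convert().coef
    coeffs = np.pad(coeffs, (0, degree + 1 - coeffs.size))
    fitted = np.polynomial.polynomial.polyval(measured, coeffs)
    rms = float(np.sqrt(np.mean((fitted - reference) ** 2)))
    cmap = CalibrationMap(coeffs, degree, rms,
                          (float(measured[0]), float(measured[-1])))
    dense = np.linspace(measured[0], measured[-1], 2048)
    if np.any(np.diff(cmap(dense)) <= 0):
        raise CalibrationError("fitted calibration map is not strictly increasing")
    return cmap


def apply_calibration(
    spec: Spectrum, cmap: CalibrationMap, target_grid: np.ndarray
) -> Spectrum:
    """Map the axis through ``cmap`` and linearly resample onto ``target_grid``."""
    target = np.asarray(target_grid, float)
    true_w = cmap(spec.wavenumbers)
    if np.any(np.diff(true_w) <= 0):
        raise CalibrationError("calibrated axis is not strictly increasing")
    tol = 1e-9 * (true_w[-1] - true_w[0])
    if target[0] < true_w[0] - tol or target[-1] > true_w[-1] + tol:
        raise RangeError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond the "
            f"calibrated axis [{true_w[0]:.3f}, {true_w[-1]:.3f}]"
        )
    resampled = np.interp(target, true_w, spec.intensities)
    return Spectrum(target.copy(), resampled, _meta_copy(spec))


# ---------------------------------------------------------------------------
# truncation / smoothing
# ---------------------------------------------------------------------------

def truncate(spec: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with ``lo <= w <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValueError("truncate requires lo < hi")
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if mask.sum() < 2:
        raise RangeError(f"truncation to [{lo}, {hi}] leaves <2 channels")
    return Spectrum(
        spec.wavenumbers[mask].copy(), spec.intensities[mask], _meta_copy(spec)
    )


def savgol_smooth(spec: Spectrum, p: int = 2, n: int = 5) -> Spectrum:
    """Savitzky-Golay smoothing: degree-``p`` fit in a sliding ``n``-point window.

    Edges are handled by evaluating the terminal-window polynomial fit
    (scipy ``mode='interp'``), so polynomials of degree <= p are reproduced
    exactly everywhere including the boundary channels.
    """
    if n % 2 == 0 or n <= p:
        raise ValueError("window length n must be odd and greater than p")
    if spec.n_channels < n:
        raise ValueError(f"spectrum has {spec.n_channels} < n={n} channels")
    return spec.with_intensities(
        savgol_filter(spec.intensities, window_length=n, polyorder=p, mode="interp")
    )


# ---------------------------------------------------------------------------
# EMSC
# ---------------------------------------------------------------------------

def _legendre_basis(wavenumbers: np.ndarray, degree: int) -> np.ndarray:
    """Legendre polynomials P_0..P_degree on the axis rescaled to [-1, 1]."""
    lo, hi = wavenumbers[0], wavenumbers[-1]
    wt = 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0
    return np.polynomial.legendre.legvander(wt, degree)


def emsc_correct(
    spectra: list[Spectrum], reference: Spectrum, degree: int = 6
) -> list[Spectrum]:
    """Extended multiplicative signal correction against a reference spectrum.

    Each spectrum ``x`` is decomposed by least squares as
    ``x = b * reference + sum_k a_k P_k + e`` with Legendre polynomials
    ``P_k`` up to ``degree`` on the rescaled axis; the corrected spectrum is
    ``(x - sum_k a_k P_k) / b``, which removes additive polynomial
    interferents and multiplicative scatter simultaneously.
    """
    axis = reference.wavenumbers
    if np.ptp(reference.intensities) == 0:
        raise DegenerateFitError("EMSC reference spectrum is constant")
    basis = _legendre_basis(axis, degree)
    design = np.column_stack([reference.intensities, basis])
    out = []
    for s in spectra:
        if not same_axis(axis, s.wavenumbers):
            raise AxisMismatchError("EMSC requires a common wavenumber axis")
        coef, *_ = np.linalg.lstsq(design, s.intensities, rcond=None)
        b = coef[0]
        if abs(b) < 1e-8:
            raise DegenerateFitError(
                f"EMSC scale factor collapsed (b={b:.2e}) for sample "
                f"{s.meta.sample_id!r}"
            )
        poly_part = basis @ coef[1:]
        out.append(s.with_intensities((s.intensities - poly_part) / b))
    return out


# ---------------------------------------------------------------------------
# SNIP baseline
# ---------------------------------------------------------------------------

def _lls(v: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(
    spec: Spectrum, iterations: int = 20, order: int = 2
) -> tuple[Spectrum, Spectrum]:
    """SNIP baseline estimation with the log-log-sqrt (LLS) compression.

    The clipping window grows from 1 to ``iterations`` channels.  ``order``
    is the even order of the clipping filter (2 or 4, as in the classic
    peak-clipping literature): order 2 clips to the symmetric two-point mean
    at distance m; order 4 additionally allows the four-point filter
    ``(4*(y[i-m/2]+y[i+m/2]) - (y[i-m]+y[i+m]))/6``, which follows curved
    baselines better at the cost of flattening broad peaks less.

    Returns ``(baseline, corrected)`` with ``corrected = spec - baseline``.
    """
    if order not in (2, 4):
        raise ValueError("clipping filter order must be 2 or 4")
    y = spec.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("SNIP requires finite intensities")
    shift = y.min()
    v = _lls(y - shift)
    n = v.size
    for m in range(1, iterations + 1):
        if 2 * m >= n:
            break
        clip = v.copy()
        sl = slice(m, n - m)
        a1 = 0.5 * (v[: n - 2 * m] + v[2 * m :])
        best = a1
        if order == 4 and m >= 2:
            h = m // 2
            inner = v[m - h : n - m - h] + v[m + h : n - m + h]
            a2 = (4.0 * inner - (v[: n - 2 * m] + v[2 * m :])) / 6.0
            best = np.maximum(a1, a2)
        clip[sl] = np.minimum(v[sl], best)
        v = clip
    baseline = _lls_inv(v) + shift
    base_spec = spec.with_intensities(baseline)
    corrected = spec.with_intensities(y - baseline)
    return base_spec, corrected


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    spec: Spectrum,
    mode: str = "vector",
    center: float | None = None,
    window: float = 15.0,
) -> Spectrum:
    """Normalize a spectrum.

    ``vector``: divide by the Euclidean norm.  ``max_at``: divide by the
    maximum intensity within ``center +- window`` cm^-1 (used with the urea
    C=O band at ~1605 cm^-1 so spectra share the matrix intensity scale).
    """
    if mode == "vector":
        norm = float(np.linalg.norm(spec.intensities))
        if norm == 0.0:
            raise NormalizationError("zero Euclidean norm")
        return spec.with_intensities(spec.intensities / norm)
    if mode == "max_at":
        if center is None:
            raise ValueError("max_at normalization needs a center wavenumber")
        if window <= 0:
            raise ValueError("window must be positive")
        mask = np.abs(spec.wavenumbers - center) <= window
        if not mask.any():
            raise RangeError(f"no channels within {center} +- {window} cm^-1")
        peak = float(spec.intensities[mask].max())
        if peak <= 0:
            raise NormalizationError(
                f"non-positive maximum in the {center} +- {window} window"
            )
        return spec.with_intensities(spec.intensities / peak)
    raise ValueError(f"unknown normalization mode {mode!r}")
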