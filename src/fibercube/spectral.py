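"""Spectrum-level processing.

Implements the iterative modified-polyfit fluorescence baseline (fit a
low-order polynomial, keep the pointwise minimum of data and fit, repeat),
blank-reference subtraction, per-spaxel reference normalization, and
Gaussian peak fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from fibercube.cube import DataCube

__all__ = [
    "BaselineFit",
    "PeakModel",
    "fit_gaussian",
    "lmj_baseline",
    "normalize_by_reference",
    "subtract_reference",
]


@dataclass
class BaselineFit:
    """Result of the iterative modified-polyfit baseline estimate."""

    order: int
    n_iterations: int
    baseline: np.ndarray
    corrected: np.ndarray
    history: list[np.ndarray] | None = None   # working spectra per iteration


def lmj_baseline(spectrum: np.ndarray, axis: np.ndarray | None = None,
                 order: int = 4, n_iter: int = 15,
                 keep_history: bool = False) -> BaselineFit:
    """Iterative modified polynomial fluorescence-baseline removal.

    Each iteration fits a polynomial of the given order to the working
    spectrum and replaces the working spectrum with the pointwise minimum
    of itself and the fit; Raman peaks are progressively clipped away
    while the smooth fluorescence background is retained.  The final
    fitted polynomial is the baseline; ``corrected = input - baseline``.

    The fit is ordinary least squares on the axis rescaled to [-1, 1]
    for numerical conditioning.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if order < 0 or n_iter < 1:
        raise ValueError("order must be >= 0 and n_iter >= 1")
    if y.size <= order + 1:
        raise ValueError(f"spectrum of length {y.size} too short for "
                         f"order-{order} baseline")
    x = np.arange(y.size, dtype=float) if axis is None \
        else np.asarray(axis, dtype=float)
    u = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    work = y.copy()
    history = [work.copy()] if keep_history else None
    baseline = work
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(u, work, order)
        baseline = np.polynomial.polynomial.polyval(u, coeffs)
        work = np.minimum(work, baseline)
        if keep_history:
            history.append(work.copy())
    return BaselineFit(order=order, n_iterations=n_iter, baseline=baseline,
                       corrected=y - baseline, history=history)


def subtract_reference(cube: DataCube, blank: DataCube) -> DataCube:
    """Subtract a blank (no-sample) reference cube channel by channel."""
    if cube.data.shape != blank.data.shape:
        raise ValueError("cube and blank have different shapes")
    if not np.allclose(cube.shift_axis, blank.shift_axis, rtol=0, atol=1e-6):
        raise ValueError("cube and blank are on different shift axes")
    return cube.copy_with(data=cube.data - blank.data,
                          mask=cube.mask | blank.mask)


def normalize_by_reference(cube: DataCube, reference: DataCube,
                           window: tuple[float, float] | None = None,
                           per_channel: bool = False) -> DataCube:
    """Divide each spaxel by its reference intensity to flatten illumination.

    Default mode divides by a per-spaxel scalar (the mean reference
    intensity over ``window``, or over the whole axis); ``per_channel``
    divides channel by channel instead.  Spaxels with non-positive
    reference are masked with a warning.
    """
    if cube.data.shape != reference.data.shape:
        raise ValueError("cube and reference have different shapes")
    if not np.allclose(cube.shift_axis, reference.shift_axis,
                       rtol=0, atol=1e-6):
        raise ValueError("cube and reference are on different shift axes")
    mask = cube.mask | reference.mask
    if per_channel:
        with np.errstate(divide="ignore", invalid="ignore"):
            data = cube.data / reference.data
        bad = ~np.all(reference.data > 0, axis=2) & ~mask
    else:
        sel = np.ones(cube.shift_axis.size, dtype=bool)
        if window is not None:
            lo, hi = window
            sel = (cube.shift_axis >= lo) & (cube.shift_axis <= hi)
            if not sel.any():
                raise ValueError("normalization window is empty")
        summary = reference.data[:, :, sel].mean(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            data = cube.data / summary[:, :, None]
        bad = (summary <= 0) & ~mask
    if bad.any():
        warnings.warn(f"{int(bad.sum())} spaxel(s) with non-positive "
                      f"reference intensity masked", stacklevel=2)
        mask = mask | bad
    data = np.where(mask[:, :, None], 0.0, data)
    data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    return cube.copy_with(data=data, mask=mask)


@dataclass
class PeakModel:
    """Fitted Gaussian peak: amplitude * exp(-(x-c)^2 / 2 sigma^2) + offset."""

    center: float
    amplitude: float
    sigma: float
    offset: float
    window: tuple[float, float] = (0.0, 0.0)
    converged: bool = True
    rms: float = field(default=np.nan)

    @property
    def fwhm(self) -> float:
        return self.sigma * 2.0 * np.sqrt(2.0 * np.log(2.0))


def _gauss(x, amp, center, sigma, offset):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_gaussian(spectrum: np.ndarray, axis: np.ndarray,
                 center_guess: float, window: float = 40.0) -> PeakModel:
    """Nonlinear least-squares Gaussian fit in a window around a peak.

    ``window`` is the full width (same units as ``axis``) of the fit
    region centered on ``center_guess``.  Non-convergence is reported via
    ``converged=False`` with zero amplitude, never as an exception.
    """
    axis = np.asarray(axis, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = center_guess - window / 2.0, center_guess + window / 2.0
    sel = (axis >= lo) & (axis <= hi) & np.isfinite(spectrum)
    if sel.sum() < 5:
        raise ValueError("fit window contains fewer than 5 samples")
    x, y = axis[sel], spectrum[sel]
    i0 = int(np.argmax(y))
    step = np.median(np.diff(x))
    sigma_lo, sigma_hi = float(step), float(hi - lo)
    p0 = (y[i0] - y.min(), x[i0], max((hi - lo) / 8.0, 2 * step), y.min())
    failed = PeakModel(center=center_guess, amplitude=0.0,
                       sigma=max((hi - lo) / 8.0, step), offset=float(np.median(y)),
                       window=(lo, hi), converged=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, x, y, p0=p0, maxfev=5000,
                bounds=([-np.inf, lo, sigma_lo, -np.inf],
                        [np.inf, hi, sigma_hi, np.inf]))
    except (RuntimeError, ValueError):
        return failed
    amp, center, sigma, offset = (float(v) for v in popt)
    # a width pegged at the bounds means the fit latched onto a single
    # sample or the window edge, not a resolved peak
    pegged = sigma <= 1.02 * sigma_lo or sigma >= 0.98 * sigma_hi
    resid = y - _gauss(x, *popt)
    return PeakModel(center=center, amplitude=amp, sigma=sigma, offset=offset,
                     window=(lo, hi), converged=not pegged,
                     rms=float(np.sqrt(np.mean(resid ** 2))))
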