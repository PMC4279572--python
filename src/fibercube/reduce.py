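"""Raw-frame reduction: master bias, trace finding, throughput flat,
wavelength calibration, spectrum extraction and cosmic-ray cleaning.

Output of the chain is a :class:`RowStackedSpectra` object with one row
per pseudo-slit position; dead fibers keep their row and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from fibercube.models import DispersionModel, Frame, TraceModel

__all__ = [
    "CalibrationError",
    "Frame",
    "RowStackedSpectra",
    "ThroughputResult",
    "TraceCountError",
    "clean_cosmics",
    "combine_bias",
    "extract",
    "find_traces",
    "fit_wavelength",
    "measure_throughput",
]


class TraceCountError(RuntimeError):
    """Raised when trace finding does not return the expected count."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(f"found {found} traces, expected {expected}")


class CalibrationError(RuntimeError):
    """Raised when a fiber cannot be wavelength-calibrated."""


@dataclass
class RowStackedSpectra:
    """Extracted 1-D spectra, one row per pseudo-slit position."""

    data: np.ndarray                       # (n_slots, n_pixels)
    live: np.ndarray                       # (n_slots,) quality flag
    throughput: np.ndarray | None = None   # (n_slots,), unit mean over live
    dispersion: DispersionModel | None = None
    header: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.live = np.asarray(self.live, dtype=bool)
        if self.live.size != self.data.shape[0]:
            raise ValueError("one live flag per fiber row required")
        if self.throughput is not None:
            self.throughput = np.asarray(self.throughput, dtype=float)
            if self.throughput.size != self.data.shape[0]:
                raise ValueError("one throughput factor per fiber row required")

    @property
    def n_fibers(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]


def combine_bias(frames: Sequence[Frame]) -> Frame:
    """Per-pixel median of a zero-exposure bias stack."""
    if not frames:
        raise ValueError("need at least one bias frame")
    shape = frames[0].shape
    for f in frames:
        if f.frametype != "bias":
            raise ValueError(f"frame of type {f.frametype!r} in bias stack")
        if f.exptime != 0.0:
            raise ValueError("bias frames must have 0 s exposure time")
        if f.shape != shape:
            raise ValueError("bias frames have mismatched shapes")
    stack = np.stack([f.data for f in frames])
    return Frame(data=np.median(stack, axis=0), frametype="masterbias",
                 exptime=0.0, header={"FRAMTYPE": "MBIAS", "NCOMBINE": len(frames)})


def _centroid(profile: np.ndarray, center: float, halfwidth: int,
              n_iter: int = 2) -> float:
    """Iterated first-moment centroid in a window around ``center``."""
    n = profile.size
    for _ in range(n_iter):
        r0 = max(int(round(center)) - halfwidth, 0)
        r1 = min(int(round(center)) + halfwidth, n - 1)
        rows = np.arange(r0, r1 + 1)
        w = np.clip(profile[r0:r1 + 1], 0, None)
        total = w.sum()
        if total <= 0:
            return center
        center = float((rows * w).sum() / total)
    return center


def find_traces(flat: Frame, expected_n: int | None = None,
                polydeg: int = 2, n_chunks: int = 12,
                min_height_frac: float = 0.05,
                n_slots: int | None = None,
                slot_offset: int = 0) -> TraceModel:
    """Locate fiber traces on a bias-subtracted flat frame.

    Peaks of the column-averaged cross-dispersion profile are refined by
    centroiding, followed per fiber by a low-order polynomial fit of the
    center against dispersion column (chunked centroids).  Slit slots are
    assigned from the trace spacing, so gaps left by dead fibers keep
    their slot; an all-live bundle maps trace k to slot k.

    Raises :class:`TraceCountError` if ``expected_n`` is given and the
    detected count differs.
    """
    data = flat.data
    profile = data.mean(axis=1)
    peaks, _ = find_peaks(profile, height=min_height_frac * profile.max(),
                          distance=3)
    if expected_n is not None and peaks.size != expected_n:
        raise TraceCountError(found=int(peaks.size), expected=expected_n)
    if peaks.size == 0:
        raise TraceCountError(found=0, expected=expected_n or 1)
    centers = np.array([_centroid(profile, p, 3) for p in peaks])

    # profile width from the brightest trace (second moment)
    ref = int(np.argmax(profile[peaks]))
    r0 = max(int(round(centers[ref])) - 3, 0)
    rows = np.arange(r0, min(r0 + 7, profile.size))
    w = np.clip(profile[rows], 0, None)
    sigma = float(np.sqrt(((rows - centers[ref]) ** 2 * w).sum() / w.sum()))
    sigma = max(sigma, 0.5)

    # slit-slot assignment from spacings (dead fibers leave gaps)
    if centers.size > 1:
        spacings = np.diff(centers)
        pitch = float(np.median(spacings))
        steps = np.maximum(np.round(spacings / pitch).astype(int), 1)
        slots = slot_offset + np.concatenate([[0], np.cumsum(steps)])
    else:
        slots = np.array([slot_offset])

    # chunked centroids along dispersion, then per-fiber polynomial
    n_cols = data.shape[1]
    edges = np.linspace(0, n_cols, n_chunks + 1).astype(int)
    mid_cols = 0.5 * (edges[:-1] + edges[1:] - 1)
    coeffs = np.zeros((centers.size, polydeg + 1))
    for i, c0 in enumerate(centers):
        pts = np.empty(n_chunks)
        for j in range(n_chunks):
            chunk = data[:, edges[j]:edges[j + 1]].mean(axis=1)
            pts[j] = _centroid(chunk, c0, 3)
        coeffs[i] = np.polynomial.polynomial.polyfit(mid_cols, pts, polydeg)
    n_total = max(int(slots[-1]) + 1, expected_n or 0, n_slots or 0)
    return TraceModel(coeffs=coeffs, sigma=sigma, slit_indices=slots,
                      n_slots=n_total)


@dataclass
class ThroughputResult:
    """Per-slot relative sensitivity factors (unit mean over live fibers)."""

    factors: np.ndarray
    live: np.ndarray

    def __iter__(self):
        return iter((self.factors, self.live))


def measure_throughput(flat_rss: RowStackedSpectra,
                       dead_threshold_frac: float = 0.05) -> ThroughputResult:
    """Fiber-to-fiber sensitivity from an extracted flat exposure.

    A fiber whose mean flat flux falls below ``dead_threshold_frac`` of
    the median live flux is flagged dead and excluded from the mean.
    """
    means = flat_rss.data.mean(axis=1)
    live = flat_rss.live.copy()
    if not np.any(means[live] > 0):
        raise ValueError("degenerate flat: no live fiber carries flux")
    median_flux = np.median(means[live])
    live &= means > dead_threshold_frac * median_flux
    if not live.any():
        raise ValueError("degenerate flat: all fibers below dead threshold")
    grand = means[live].mean()
    factors = np.where(live, means / grand, 0.0)
    return ThroughputResult(factors=factors, live=live)


def fit_wavelength(arc_rss: RowStackedSpectra, line_list_nm: Sequence[float],
                   degree: int = 3, centroid_halfwidth: int = 4,
                   excitation_nm: float = 785.0,
                   min_height_frac: float = 0.3,
                   strict: bool = True) -> DispersionModel:
    """Per-fiber wavelength solution from an extracted arc exposure.

    Emission-line centroids are matched to the sorted line list in order
    (monotone assignment) and fit with a polynomial lambda(column) of the
    given degree.  Fibers with fewer usable lines than ``degree + 1``
    raise :class:`CalibrationError` (or are flagged when ``strict`` is
    false); dead fibers inherit the nearest calibrated solution so
    downstream resampling stays defined, but remain flagged.
    """
    lines = np.sort(np.asarray(line_list_nm, dtype=float))
    n_slots = arc_rss.n_fibers
    coeffs = np.full((n_slots, degree + 1), np.nan)
    rms = np.full(n_slots, np.nan)
    calibrated = np.zeros(n_slots, dtype=bool)
    failures = []
    for slot in range(n_slots):
        if not arc_rss.live[slot]:
            continue
        spec = arc_rss.data[slot]
        peaks, props = find_peaks(spec, height=min_height_frac * spec.max(),
                                  distance=4)
        if peaks.size > lines.size:
            keep = np.sort(np.argsort(props["peak_heights"])[-lines.size:])
            peaks = peaks[keep]
        if peaks.size < max(degree + 1, lines.size):
            failures.append((slot, int(peaks.size)))
            continue
        cents = np.array([_centroid(spec, p, centroid_halfwidth)
                          for p in peaks])
        coeffs[slot] = np.polynomial.polynomial.polyfit(cents, lines, degree)
        pred = np.polynomial.polynomial.polyval(cents, coeffs[slot])
        rms[slot] = float(np.sqrt(np.mean((pred - lines) ** 2)))
        calibrated[slot] = True
    if failures and strict:
        raise CalibrationError(
            f"{len(failures)} fiber(s) with too few arc lines for a "
            f"degree-{degree} fit: {failures[:5]}")
    if not calibrated.any():
        raise CalibrationError("no fiber could be wavelength-calibrated")
    good = np.flatnonzero(calibrated)
    for slot in np.flatnonzero(~calibrated):
        nearest = good[np.argmin(np.abs(good - slot))]
        coeffs[slot] = coeffs[nearest]
    return DispersionModel(coeffs=coeffs, excitation_nm=excitation_nm,
                           residual_rms_nm=rms, calibrated=calibrated)


def extract(frame: Frame, traces: TraceModel,
            master_bias: Frame | None = None,
            throughput: np.ndarray | None = None,
            half_width_px: float | None = None,
            live: np.ndarray | None = None) -> RowStackedSpectra:
    """Tophat-aperture extraction of all traces into row-stacked spectra.

    Counts are summed over rows within ``half_width_px`` (default
    4 profile sigmas, which keeps aperture truncation below 1e-3) of the
    trace center at every dispersion column, then divided by the fiber's
    throughput factor.  Slit slots without a trace come out as zero rows
    flagged dead.
    """
    data = frame.data - (master_bias.data if master_bias is not None else 0.0)
    if half_width_px is None:
        half_width_px = 4.0 * traces.sigma
    if traces.n_traces > 1:
        sep = np.diff(traces.coeffs[:, 0]).min()
        if sep < half_width_px + 3.0 * traces.sigma:
            warnings.warn(f"adjacent traces {sep:.2f} px apart: extraction "
                          f"apertures pick up cross-talk", stacklevel=2)
    n_rows, n_cols = data.shape
    cols = np.arange(n_cols)
    csum = np.vstack([np.zeros(n_cols), np.cumsum(data, axis=0)])
    out = np.zeros((traces.n_slots, n_cols))
    live_out = np.zeros(traces.n_slots, dtype=bool)
    for i in range(traces.n_traces):
        centers = traces.center(i, cols.astype(float))
        r0 = np.clip(np.ceil(centers - half_width_px).astype(int), 0, n_rows)
        r1 = np.clip(np.floor(centers + half_width_px).astype(int) + 1,
                     0, n_rows)
        slot = int(traces.slit_indices[i])
        out[slot] = csum[r1, cols] - csum[r0, cols]
        live_out[slot] = True
    factors = np.ones(traces.n_slots)
    if throughput is not None:
        factors = np.asarray(throughput, dtype=float)
        good = factors > 0
        out[good] /= factors[good, None]
        live_out &= good
        out[~good] = 0.0
    if live is not None:
        live_out &= np.asarray(live, dtype=bool)
    return RowStackedSpectra(data=out, live=live_out, throughput=factors,
                             header={"EXPTIME": frame.exptime,
                                     "FRAMTYPE": frame.frametype})


def clean_cosmics(rss: RowStackedSpectra, k: float = 6.0, window: int = 5,
                  rel_floor: float = 0.12, max_passes: int = 20,
                  ) -> tuple[RowStackedSpectra, list[tuple[int, int]]]:
    """Sigma-clip narrow positive spikes against a running-median spectrum.

    A sample is replaced by the local median when it exceeds it by more
    than ``k`` times the robust noise, floored at ``rel_floor`` of the
    local signal.  The floor keeps genuine resolved peaks (sigma of a
    grid step or more, whose median residual stays below ~0.35 of the
    peak) out of reach while pixel-scale spikes still tower over it.
    Iterates until no sample is flagged, which makes the operation
    idempotent.  Returns the cleaned spectra and the replaced positions.
    """
    data = rss.data.copy()
    replaced: list[tuple[int, int]] = []
    for slot in np.flatnonzero(rss.live):
        x = data[slot]
        for _ in range(max_passes):
            smooth = median_filter(x, size=window, mode="nearest")
            resid = x - smooth
            sig = 1.4826 * np.median(np.abs(resid))
            thresh = k * np.maximum(sig, rel_floor * np.abs(smooth))
            mask = resid > thresh
            if not mask.any():
                break
            x[mask] = smooth[mask]
            replaced.extend((int(slot), int(c)) for c in np.flatnonzero(mask))
    return (RowStackedSpectra(data=data, live=rss.live.copy(),
                              throughput=None if rss.throughput is None
                              else rss.throughput.copy(),
                              dispersion=rss.dispersion,
                              header=dict(rss.header)),
            replaced)
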