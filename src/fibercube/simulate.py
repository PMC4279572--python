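"""Synthetic raw-frame generator for the fiber-bundle spectrograph.

Forward model: every live fiber deposits its spectrum as a Gaussian
cross-dispersion profile along a trace on the detector; wavelengths map
to dispersion columns through a per-fiber polynomial.  Bias, flat, arc
and science frames (plus cosmic-ray hits) are generated with seeded
Poisson + read noise so the reduction chain can be tested against exact
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from fibercube.cube import to_raman_shift
from fibercube.geometry import BundleLayout
from fibercube.models import DispersionModel, Frame, TraceModel

__all__ = [
    "Bead",
    "DetectorConfig",
    "DispersionModel",
    "Phantom",
    "SpectralLibrary",
    "TraceModel",
    "amplitude_for_snr",
    "default_arc_lines",
    "default_dispersion",
    "default_library",
    "default_traces",
    "fig9_beads",
    "fluorescence_baseline",
    "gaussian_illumination",
    "half_field_phantom",
    "inject_cosmics",
    "make_arc",
    "make_bead_phantom",
    "make_bias",
    "make_blank",
    "make_flat",
    "make_reference",
    "make_science",
    "make_spectrum",
    "optics_background",
    "render_frame",
    "three_phase_phantom",
    "throughput_factors",
    "uniform_phantom",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

# Characteristic peak centers (cm^-1) of the shipped substances; relative
# amplitudes and widths are implementation defaults, only the centers are
# literature values.
_LIBRARY_PEAKS: dict[str, list[float]] = {
    "teflon": [292.0, 385.0, 734.0, 1218.0, 1302.0, 1382.0],
    "pork": [1064.0, 1300.0, 1441.0, 1656.0],
    "PS": [1035.0],
    "PMMA": [600.0],
    "paracetamol": [800.0, 860.0],
    "aspirin": [752.0, 1047.0],
    "caffeine": [1703.0],
}
DEFAULT_FWHM_CM1 = 12.0


def as_rng(seed) -> np.random.Generator:
    """Coerce a seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Peak:
    center: float        # cm^-1
    amplitude: float = 1.0
    fwhm: float = DEFAULT_FWHM_CM1

    def __post_init__(self) -> None:
        if self.center <= 0 or self.amplitude < 0 or self.fwhm <= 0:
            raise ValueError("invalid peak parameters")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_TO_SIGMA


@dataclass
class SpectralLibrary:
    """Named substances, each a list of Gaussian Raman peaks."""

    substances: dict[str, tuple[Peak, ...]]

    def __getitem__(self, name: str) -> tuple[Peak, ...]:
        try:
            return self.substances[name]
        except KeyError:
            raise KeyError(f"substance {name!r} not in library "
                           f"(have {sorted(self.substances)})") from None

    def __contains__(self, name: str) -> bool:
        return name in self.substances

    def names(self) -> list[str]:
        return sorted(self.substances)

    def peak_centers(self, name: str) -> list[float]:
        return [p.center for p in self[name]]

    @classmethod
    def from_dict(cls, spec: Mapping) -> "SpectralLibrary":
        subs = {}
        for name, peaks in spec.items():
            parsed = []
            for p in peaks:
                if isinstance(p, Mapping):
                    parsed.append(Peak(float(p["center"]),
                                       float(p.get("amplitude", 1.0)),
                                       float(p.get("fwhm", DEFAULT_FWHM_CM1))))
                else:
                    parsed.append(Peak(*[float(v) for v in np.atleast_1d(p)]))
            subs[name] = tuple(parsed)
        return cls(subs)


def default_library() -> SpectralLibrary:
    """Library with the shipped substances (unit amplitude, 12 cm^-1 FWHM)."""
    return SpectralLibrary({
        name: tuple(Peak(c) for c in centers)
        for name, centers in _LIBRARY_PEAKS.items()
    })


def make_spectrum(library: SpectralLibrary, mixture: Mapping[str, float],
                  axis: np.ndarray,
                  baseline_coeffs: Sequence[float] | None = None) -> np.ndarray:
    """Render a mixture of library substances on a Raman-shift grid.

    Each substance contributes ``weight * sum_of_Gaussian_peaks``; the
    optional baseline polynomial (ascending coefficients) is evaluated on
    the axis rescaled to [0, 1] and added on top.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be 1-D and strictly increasing")
    out = np.zeros_like(axis)
    for name, weight in mixture.items():
        if weight < 0:
            raise ValueError("mixture weights must be >= 0")
        if weight == 0:
            continue
        for peak in library[name]:
            out += (weight * peak.amplitude
                    * np.exp(-0.5 * ((axis - peak.center) / peak.sigma) ** 2))
    if baseline_coeffs is not None:
        u = (axis - axis[0]) / (axis[-1] - axis[0])
        out += np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs))
    return out


def fluorescence_baseline(axis: np.ndarray, scale: float = 1.0,
                          coeffs: Sequence[float] = (0.8, 0.2, 1.5, -2.2, 1.2),
                          ) -> np.ndarray:
    """Smooth positive 4th-order fluorescence background on a shift grid."""
    axis = np.asarray(axis, dtype=float)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return scale * np.polynomial.polynomial.polyval(u, np.asarray(coeffs))


# --------------------------------------------------------------------------
# phantoms

@dataclass(frozen=True)
class Bead:
    """Circular bead in field coordinates (spaxel units)."""

    substance: str
    row: float
    col: float
    radius: float


@dataclass
class Phantom:
    """Per-spaxel substance weights plus an illumination profile."""

    weights: dict[str, np.ndarray]        # substance -> (n_rows, n_cols)
    illumination: np.ndarray              # (n_rows, n_cols), > 0

    def __post_init__(self) -> None:
        self.illumination = np.asarray(self.illumination, dtype=float)
        if np.any(self.illumination <= 0):
            raise ValueError("illumination factors must be positive")
        for name, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != self.illumination.shape:
                raise ValueError(f"weight map for {name!r} has wrong shape")
            if np.any(w < 0):
                raise ValueError("substance weights must be >= 0")
            self.weights[name] = w

    @property
    def shape(self) -> tuple[int, int]:
        return self.illumination.shape

    def mixture(self, row: int, col: int) -> dict[str, float]:
        return {name: float(w[row, col]) for name, w in self.weights.items()
                if w[row, col] > 0}

    def substance_mask(self, name: str) -> np.ndarray:
        return np.asarray(self.weights.get(name, np.zeros(self.shape))) > 0


def gaussian_illumination(layout: BundleLayout,
                          center_corner_ratio: float = 10.0) -> np.ndarray:
    """Centered 2-D Gaussian illumination with the given center/corner ratio."""
    if center_corner_ratio < 1:
        raise ValueError("ratio must be >= 1")
    r0 = (layout.n_rows - 1) / 2.0
    c0 = (layout.n_cols - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(layout.n_rows), np.arange(layout.n_cols),
                         indexing="ij")
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    if center_corner_ratio == 1.0:
        return np.ones(d2.shape)
    s2 = d2.max() / (2.0 * np.log(center_corner_ratio))
    return np.exp(-0.5 * d2 / s2)


def uniform_phantom(layout: BundleLayout, substance: str, weight: float = 1.0,
                    illumination: np.ndarray | None = None) -> Phantom:
    shape = (layout.n_rows, layout.n_cols)
    illum = np.ones(shape) if illumination is None else illumination
    return Phantom({substance: np.full(shape, float(weight))}, illum)


def make_bead_phantom(layout: BundleLayout, beads: Sequence[Bead],
                      illumination: np.ndarray | None = None) -> Phantom:
    """Place circular beads on the spaxel grid.

    A spaxel belongs to a bead when its center lies inside the bead
    circle.  Beads lying entirely outside the field raise a warning and
    are clipped away.
    """
    shape = (layout.n_rows, layout.n_cols)
    illum = np.ones(shape) if illumination is None else np.asarray(illumination)
    weights: dict[str, np.ndarray] = {}
    rr, cc = np.meshgrid(np.arange(layout.n_rows), np.arange(layout.n_cols),
                         indexing="ij")
    for bead in beads:
        inside = ((rr - bead.row) ** 2 + (cc - bead.col) ** 2
                  <= bead.radius ** 2)
        if not inside.any():
            warnings.warn(f"bead {bead} lies outside the field; clipped",
                          stacklevel=2)
            continue
        w = weights.setdefault(bead.substance, np.zeros(shape))
        np.maximum(w, inside.astype(float), out=w)
    return Phantom(weights, illum)


def fig9_beads() -> list[Bead]:
    """Bead arrangement mimicking the microbead sample: one large PMMA
    bead with a cluster of small PS beads nearby, a few more PS beads
    further out, some only partly inside the field."""
    return [
        Bead("PMMA", 9.0, 8.0, 2.6),
        Bead("PS", 5.5, 11.5, 1.1),
        Bead("PS", 8.0, 12.5, 1.1),
        Bead("PS", 4.0, 14.0, 1.1),
        Bead("PS", 15.0, 4.0, 1.1),
        Bead("PS", 3.0, 3.0, 1.1),
        Bead("PS", 0.0, 16.5, 1.2),
        Bead("PS", 19.5, 6.0, 1.2),
        Bead("PS", 11.0, 19.4, 1.2),
    ]


def half_field_phantom(layout: BundleLayout, top: str = "paracetamol",
                       bottom: str = "aspirin",
                       illumination: np.ndarray | None = None) -> Phantom:
    """Two half-fields split through the center row (tablet-halves sample)."""
    shape = (layout.n_rows, layout.n_cols)
    illum = np.ones(shape) if illumination is None else illumination
    w_top = np.zeros(shape)
    w_top[: layout.n_rows // 2, :] = 1.0
    w_bot = np.zeros(shape)
    w_bot[layout.n_rows // 2:, :] = 1.0
    return Phantom({top: w_top, bottom: w_bot}, illum)


def three_phase_phantom(layout: BundleLayout,
                        substances: Sequence[str] = ("caffeine", "aspirin",
                                                     "paracetamol"),
                        illumination: np.ndarray | None = None) -> Phantom:
    """Three disjoint vertical bands, one substance each."""
    shape = (layout.n_rows, layout.n_cols)
    illum = np.ones(shape) if illumination is None else illumination
    edges = np.linspace(0, layout.n_cols, len(substances) + 1).astype(int)
    weights = {}
    for name, lo, hi in zip(substances, edges[:-1], edges[1:]):
        w = np.zeros(shape)
        w[:, lo:hi] = 1.0
        weights[name] = w
    return Phantom(weights, illum)


# --------------------------------------------------------------------------
# instrument models

@dataclass(frozen=True)
class DetectorConfig:
    """Desk-scale detector stand-in (full-size CCDs are configurable)."""

    n_rows_px: int = 3040
    n_cols_px: int = 600
    bias_level: float = 100.0
    read_noise: float = 3.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows_px < 1 or self.n_cols_px < 1:
            raise ValueError("detector dimensions must be positive")
        if self.read_noise < 0 or self.gain <= 0:
            raise ValueError("invalid noise configuration")


def default_traces(layout: BundleLayout, detector: DetectorConfig,
                   sigma: float = 1.0, margin: float = 22.0,
                   tilt: float = 0.0, curvature: float = 0.0) -> TraceModel:
    """Evenly spaced traces for the live fibers, ordered by slit position.

    Slit slot ``s`` sits at row ``margin + pitch * s``; optional common
    tilt (px/col) and curvature (px/col^2) bend the traces.
    """
    n = layout.n_fibers
    pitch = (detector.n_rows_px - 2 * margin) / max(n - 1, 1)
    if pitch <= 2 * sigma:
        raise ValueError("detector too small: traces would overlap")
    live = layout.live_fibers
    slots = np.array([layout.grid_to_slit(r, c) for r, c in live])
    order = np.argsort(slots)
    slots = slots[order]
    coeffs = np.zeros((slots.size, 3))
    coeffs[:, 0] = margin + pitch * slots
    coeffs[:, 1] = tilt
    coeffs[:, 2] = curvature
    return TraceModel(coeffs=coeffs, sigma=sigma, slit_indices=slots,
                      n_slots=n)


def default_dispersion(layout: BundleLayout, detector: DetectorConfig,
                       lam_start: float = 795.0, lam_end: float = 936.0,
                       fiber_offset_nm: float = 0.25,
                       quad_nm: float = 0.8) -> DispersionModel:
    """Near-linear wavelength solutions with small per-fiber offsets.

    Each slot gets lambda(col) = lam0_i + b*col + q*col^2 with a smooth
    per-slot zero-point wobble (amplitude ``fiber_offset_nm``) and a
    gentle common quadratic term totalling ``quad_nm`` across the chip.
    """
    n = layout.n_fibers
    cols_max = detector.n_cols_px - 1
    q = quad_nm / cols_max**2
    b = (lam_end - lam_start - q * cols_max**2) / cols_max
    coeffs = np.zeros((n, 3))
    slots = np.arange(n)
    coeffs[:, 0] = lam_start + fiber_offset_nm * np.sin(2 * np.pi * slots / n)
    coeffs[:, 1] = b
    coeffs[:, 2] = q
    return DispersionModel(coeffs=coeffs)


def default_arc_lines(n_lines: int = 8, lo: float = 800.0,
                      hi: float = 930.0) -> np.ndarray:
    """Synthetic emission-line list (nm), evenly spaced."""
    return np.linspace(lo, hi, n_lines)


def throughput_factors(n: int, rng, spread: float = 0.08) -> np.ndarray:
    """Fiber-to-fiber sensitivity factors with unit mean."""
    rng = as_rng(rng)
    f = np.clip(1.0 + spread * rng.standard_normal(n), 0.3, None)
    return f / f.mean()


def amplitude_for_snr(snr: float, read_noise: float) -> float:
    """Peak counts A with A / sqrt(A + r^2) = snr (Poisson + read noise)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return 0.5 * (snr**2 + snr * np.sqrt(snr**2 + 4.0 * read_noise**2))


# --------------------------------------------------------------------------
# frame rendering

def _pixel_profile(rows: np.ndarray, centers: np.ndarray,
                   sigma: float) -> np.ndarray:
    """Pixel-integrated Gaussian: fraction of flux in each row pixel."""
    s = sigma * np.sqrt(2.0)
    hi = erf((rows[:, None] + 0.5 - centers[None, :]) / s)
    lo = erf((rows[:, None] - 0.5 - centers[None, :]) / s)
    return 0.5 * (hi - lo)


def render_frame(spectra: np.ndarray, traces: TraceModel,
                 detector: DetectorConfig, noise: bool = True,
                 rng=None, exptime: float = 1.0,
                 frametype: str = "science",
                 header: dict | None = None) -> Frame:
    """Deposit per-column fiber spectra onto the detector.

    ``spectra`` has shape ``(n_traces, n_cols_px)``: photo-counts per
    dispersion column for each trace.  Each column's flux is spread over
    rows as a pixel-integrated Gaussian around the trace center, so the
    full column sum equals the injected flux up to far-tail truncation.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] != traces.n_traces or (
            spectra.size and spectra.shape[1] != detector.n_cols_px):
        raise ValueError(f"expected spectra of shape "
                         f"({traces.n_traces}, {detector.n_cols_px}), "
                         f"got {spectra.shape}")
    cols = np.arange(detector.n_cols_px, dtype=float)
    frame = np.zeros((detector.n_rows_px, detector.n_cols_px))
    pad = 8.0 * traces.sigma
    for i in range(traces.n_traces):
        centers = traces.center(i, cols)
        r0 = max(int(np.floor(centers.min() - pad)), 0)
        r1 = min(int(np.ceil(centers.max() + pad)), detector.n_rows_px - 1)
        rows = np.arange(r0, r1 + 1, dtype=float)
        frame[r0:r1 + 1] += _pixel_profile(rows, centers,
                                           traces.sigma) * spectra[i]
    if noise:
        rng = as_rng(detector.seed if rng is None else rng)
        electrons = rng.poisson(np.clip(frame, 0, None) * detector.gain)
        frame = electrons / detector.gain
        frame = frame + rng.normal(0.0, detector.read_noise, frame.shape)
    data = frame + detector.bias_level
    hdr = {"FRAMTYPE": frametype.upper()[:8], "EXPTIME": exptime}
    hdr.update(header or {})
    return Frame(data=data, frametype=frametype, exptime=exptime, header=hdr)


def make_bias(detector: DetectorConfig, n_frames: int = 3,
              noise: bool = True, rng=None) -> list[Frame]:
    """Zero-exposure frames: bias level plus read noise only."""
    rng = as_rng(detector.seed if rng is None else rng)
    frames = []
    shape = (detector.n_rows_px, detector.n_cols_px)
    for _ in range(n_frames):
        data = np.full(shape, detector.bias_level)
        if noise:
            data = data + rng.normal(0.0, detector.read_noise, shape)
        frames.append(Frame(data=data, frametype="bias", exptime=0.0,
                            header={"FRAMTYPE": "BIAS", "EXPTIME": 0.0}))
    return frames


def flat_continuum(detector: DetectorConfig,
                   amplitude: float = 20000.0) -> np.ndarray:
    """Smooth spectral shape of the integrating-sphere flat signal."""
    cols = np.arange(detector.n_cols_px, dtype=float)
    mid = (detector.n_cols_px - 1) / 2.0
    return amplitude * (1.0 - 0.25 * ((cols - mid) / mid) ** 2)


def make_flat(traces: TraceModel, detector: DetectorConfig,
              throughput: np.ndarray | None = None,
              amplitude: float = 20000.0, noise: bool = True,
              rng=None, exptime: float = 10.0) -> Frame:
    """Continuum-lamp exposure: smooth spectrum times per-trace throughput."""
    cont = flat_continuum(detector, amplitude)
    if throughput is None:
        throughput = np.ones(traces.n_traces)
    throughput = np.asarray(throughput, dtype=float)
    if throughput.size != traces.n_traces:
        raise ValueError("one throughput factor per trace required")
    spectra = throughput[:, None] * cont[None, :]
    return render_frame(spectra, traces, detector, noise=noise, rng=rng,
                        exptime=exptime, frametype="flat")


def make_arc(line_list_nm: Sequence[float], traces: TraceModel,
             dispersion: DispersionModel, detector: DetectorConfig,
             amplitude: float = 30000.0, line_sigma_px: float = 1.3,
             noise: bool = True, rng=None, exptime: float = 5.0) -> Frame:
    """Emission-line lamp exposure at the listed wavelengths (nm)."""
    lines = np.sort(np.asarray(line_list_nm, dtype=float))
    if lines.size == 0:
        raise ValueError("arc line list is empty")
    cols = np.arange(detector.n_cols_px, dtype=float)
    s = line_sigma_px * np.sqrt(2.0)
    spectra = np.zeros((traces.n_traces, detector.n_cols_px))
    for i, slot in enumerate(traces.slit_indices):
        lam = dispersion.wavelength(int(slot), cols)
        for line in lines:
            if not lam[0] <= line <= lam[-1]:
                continue
            cc = np.interp(line, lam, cols)
            spectra[i] += amplitude * 0.5 * (erf((cols + 0.5 - cc) / s)
                                             - erf((cols - 0.5 - cc) / s))
    return render_frame(spectra, traces, detector, noise=noise, rng=rng,
                        exptime=exptime, frametype="arc")


def _fiber_shift_axes(traces: TraceModel, dispersion: DispersionModel,
                      detector: DetectorConfig) -> np.ndarray:
    cols = np.arange(detector.n_cols_px, dtype=float)
    axes = np.empty((traces.n_traces, detector.n_cols_px))
    for i, slot in enumerate(traces.slit_indices):
        axes[i] = to_raman_shift(dispersion.wavelength(int(slot), cols),
                                 dispersion.excitation_nm)
    return axes


def make_science(phantom: Phantom, library: SpectralLibrary,
                 traces: TraceModel, dispersion: DispersionModel,
                 detector: DetectorConfig, layout: BundleLayout,
                 amplitude: float = 4000.0, fluor_scale: float = 800.0,
                 optics_bg_scale: float = 0.0,
                 throughput: np.ndarray | None = None,
                 noise: bool = True, rng=None,
                 exptime: float = 120.0) -> Frame:
    """Sample exposure: phantom mixtures times illumination, plus sample
    fluorescence (scaled with illumination) and an optional additive
    optics background common to all fibers."""
    if phantom.shape != (layout.n_rows, layout.n_cols):
        raise ValueError("phantom shape does not match layout")
    axes = _fiber_shift_axes(traces, dispersion, detector)
    spectra = np.zeros_like(axes)
    for i, slot in enumerate(traces.slit_indices):
        r, c = layout.slit_to_grid(int(slot))
        illum = phantom.illumination[r, c]
        mix = phantom.mixture(r, c)
        sig = make_spectrum(library, mix, axes[i]) if mix else 0.0
        spectra[i] = illum * (amplitude * sig
                              + fluorescence_baseline(axes[i], fluor_scale))
        if optics_bg_scale:
            spectra[i] += optics_background(axes[i], optics_bg_scale)
    if throughput is not None:
        spectra *= np.asarray(throughput, dtype=float)[:, None]
    return render_frame(spectra, traces, detector, noise=noise, rng=rng,
                        exptime=exptime, frametype="science")


def optics_background(axis: np.ndarray, scale: float) -> np.ndarray:
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    return scale * (0.6 + 0.4 * u)


def make_blank(traces: TraceModel, dispersion: DispersionModel,
               detector: DetectorConfig, optics_bg_scale: float = 500.0,
               throughput: np.ndarray | None = None,
               noise: bool = True, rng=None,
               exptime: float = 120.0) -> Frame:
    """Reference exposure without sample: optics background only."""
    axes = _fiber_shift_axes(traces, dispersion, detector)
    spectra = np.stack([optics_background(axes[i], optics_bg_scale)
                        for i in range(traces.n_traces)])
    if throughput is not None:
        spectra *= np.asarray(throughput, dtype=float)[:, None]
    return render_frame(spectra, traces, detector, noise=noise, rng=rng,
                        exptime=exptime, frametype="science",
                        header={"FRAMTYPE": "SCI", "TARGET": "BLANK"})


def make_reference(illumination: np.ndarray, traces: TraceModel,
                   dispersion: DispersionModel, detector: DetectorConfig,
                   layout: BundleLayout, amplitude: float = 6000.0,
                   throughput: np.ndarray | None = None,
                   noise: bool = True, rng=None,
                   exptime: float = 120.0) -> Frame:
    """Broadband reference-plate exposure carrying the illumination profile."""
    axes = _fiber_shift_axes(traces, dispersion, detector)
    spectra = np.zeros_like(axes)
    for i, slot in enumerate(traces.slit_indices):
        r, c = layout.slit_to_grid(int(slot))
        u = (axes[i] - axes[i][0]) / (axes[i][-1] - axes[i][0])
        spectra[i] = illumination[r, c] * amplitude * (0.9 + 0.2 * u)
    if throughput is not None:
        spectra *= np.asarray(throughput, dtype=float)[:, None]
    return render_frame(spectra, traces, detector, noise=noise, rng=rng,
                        exptime=exptime, frametype="science",
                        header={"FRAMTYPE": "SCI", "TARGET": "REFPLATE"})


def inject_cosmics(frame: Frame, n_hits: int, rng=None,
                   amplitude: float = 30000.0
                   ) -> tuple[Frame, list[tuple[int, int]]]:
    """Add seeded cosmic-ray spikes; returns the new frame and hit pixels.

    Each hit deposits ``amplitude`` (+/-20%) in one pixel and, with 30%
    probability, half of that in an adjacent pixel.
    """
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    rng = as_rng(rng)
    data = frame.data.copy()
    nr, nc = data.shape
    hits: list[tuple[int, int]] = []
    for _ in range(n_hits):
        r = int(rng.integers(2, nr - 2))
        c = int(rng.integers(2, nc - 2))
        amp = amplitude * (0.8 + 0.4 * rng.random())
        data[r, c] += amp
        if rng.random() < 0.3:
            dr, dc = ((0, 1), (0, -1), (1, 0), (-1, 0))[int(rng.integers(4))]
            data[r + dr, c + dc] += 0.5 * amp
        hits.append((r, c))
    return Frame(data=data, frametype=frame.frametype, exptime=frame.exptime,
                 header=dict(frame.header)), hits
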