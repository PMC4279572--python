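"""Spectral-axis conversion and data-cube assembly.

Calibrated fiber spectra live on per-fiber wavelength grids; this module
converts wavelengths to Stokes Raman shift, resamples all fibers onto a
common shift axis, and re-indexes the row-stacked spectra into the
``(n_rows, n_cols, n_shift)`` cube via the bundle's slit mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from fibercube.geometry import BundleLayout

__all__ = [
    "DataCube",
    "assemble_cube",
    "default_shift_axis",
    "resample_common_axis",
    "shift_to_wavelength",
    "to_raman_shift",
]

DEFAULT_EXCITATION_NM = 785.0


def to_raman_shift(wavelength_nm, excitation_nm: float = DEFAULT_EXCITATION_NM):
    """Convert wavelength (nm) to Stokes Raman shift (cm^-1).

    shift = 1e7 * (1/excitation - 1/wavelength); strictly increasing in
    wavelength and zero at the laser line.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl < excitation_nm):
        raise ValueError("wavelength below excitation: anti-Stokes side not modeled")
    shift = 1e7 * (1.0 / excitation_nm - 1.0 / wl)
    return float(shift) if np.isscalar(wavelength_nm) else shift


def shift_to_wavelength(shift_cm1, excitation_nm: float = DEFAULT_EXCITATION_NM):
    """Inverse of :func:`to_raman_shift`."""
    sh = np.asarray(shift_cm1, dtype=float)
    if np.any(sh < 0):
        raise ValueError("negative Raman shift: anti-Stokes side not modeled")
    wl = 1e7 / (1e7 / excitation_nm - sh)
    return float(wl) if np.isscalar(shift_cm1) else wl


def default_shift_axis(lo: float = 200.0, hi: float = 2000.0,
                       step: float = 2.0) -> np.ndarray:
    """Default common Raman-shift grid (covers all library peaks)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class DataCube:
    """Spatial-spectral cube: two spatial axes plus one Raman-shift axis.

    ``data[row, col, :]`` is the spectrum of the spaxel at grid position
    ``(row, col)``; ``mask`` is true for dead/unusable spaxels, which are
    kept as placeholders rather than interpolated over.
    """

    data: np.ndarray
    shift_axis: np.ndarray
    mask: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.shift_axis = np.asarray(self.shift_axis, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, shift)")
        if self.data.shape[2] != self.shift_axis.size:
            raise ValueError("spectral axis length mismatch")
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match spatial dimensions")
        steps = np.diff(self.shift_axis)
        if steps.size and (steps.min() <= 0 or
                           np.ptp(steps) > 1e-9 * abs(steps.mean())):
            raise ValueError("shift axis must be strictly increasing and uniform")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def spectrum(self, row: int, col: int) -> np.ndarray:
        return self.data[row, col]

    def copy_with(self, data: np.ndarray | None = None,
                  mask: np.ndarray | None = None) -> "DataCube":
        return DataCube(
            data=self.data.copy() if data is None else data,
            shift_axis=self.shift_axis.copy(),
            mask=self.mask.copy() if mask is None else mask,
            meta=dict(self.meta),
        )


def resample_common_axis(spectra: np.ndarray, source_axes: np.ndarray,
                         target_axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate each fiber spectrum onto a common shift grid.

    Parameters
    ----------
    spectra
        ``(n_fibers, n_samples)`` intensity array.
    source_axes
        ``(n_fibers, n_samples)`` per-fiber shift axes (strictly
        increasing along each row), or a single shared 1-D axis.
    target_axis
        Common strictly increasing grid.

    Returns
    -------
    resampled, valid
        ``(n_fibers, n_target)`` interpolated intensities (NaN outside a
        fiber's coverage) and the matching boolean validity mask.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    target = np.asarray(target_axis, dtype=float)
    axes = np.asarray(source_axes, dtype=float)
    if axes.ndim == 1:
        axes = np.broadcast_to(axes, (spectra.shape[0], axes.size))
    out = np.full((spectra.shape[0], target.size), np.nan)
    valid = np.zeros_like(out, dtype=bool)
    for i in range(spectra.shape[0]):
        src = axes[i]
        if target[0] > src[-1] or target[-1] < src[0]:
            raise ValueError(f"fiber {i}: no overlap between source axis "
                             f"[{src[0]:.1f}, {src[-1]:.1f}] and target grid")
        inside = (target >= src[0]) & (target <= src[-1])
        out[i, inside] = np.interp(target[inside], src, spectra[i])
        valid[i] = inside
    return out, valid


def assemble_cube(spectra: np.ndarray, layout: BundleLayout,
                  shift_axis: np.ndarray,
                  fiber_live: np.ndarray | None = None,
                  meta: dict | None = None) -> DataCube:
    """Re-index row-stacked spectra (one row per slit position) into a cube.

    ``cube[row, col, :] = spectra[layout.grid_to_slit(row, col)]``; spaxels
    listed as dead in the layout, or flagged dead in ``fiber_live``, are
    masked.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] != layout.n_fibers:
        raise ValueError(f"expected {layout.n_fibers} spectra, "
                         f"got shape {spectra.shape}")
    data = np.empty((layout.n_rows, layout.n_cols, spectra.shape[1]))
    mask = np.zeros((layout.n_rows, layout.n_cols), dtype=bool)
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            slit = layout.grid_to_slit(r, c)
            data[r, c] = spectra[slit]
            dead = layout.is_dead(r, c)
            if fiber_live is not None:
                dead = dead or not bool(fiber_live[slit])
            mask[r, c] = dead
    return DataCube(data=data, shift_axis=np.asarray(shift_axis, dtype=float),
                    mask=mask, meta=dict(meta or {}))
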