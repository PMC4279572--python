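"""Shared core data types for the simulator and the reduction chain.

Conventions: detector rows are the cross-dispersion axis (traces are
roughly horizontal lines), columns are the dispersion axis; pixel
coordinates are 0-based.  The trace at the smallest row is pseudo-slit
position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

FRAME_TYPES = ("bias", "flat", "arc", "science", "masterbias")


@dataclass
class Frame:
    """One 2-D detector exposure in counts."""

    data: np.ndarray
    frametype: str
    exptime: float = 0.0
    header: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame contains non-finite values")
        if self.frametype not in FRAME_TYPES:
            raise ValueError(f"unknown frame type {self.frametype!r}")
        if self.exptime < 0:
            raise ValueError("exposure time must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class TraceModel:
    """Cross-dispersion trace centers, one per detected/live fiber.

    ``coeffs[i]`` are ascending polynomial coefficients giving the trace
    center row as a function of dispersion column; ``slit_indices[i]`` is
    the pseudo-slit slot the trace belongs to (gaps mark dead fibers).
    """

    coeffs: np.ndarray          # (n_traces, deg+1), ascending powers
    sigma: float                # cross-dispersion Gaussian profile sigma (px)
    slit_indices: np.ndarray    # (n_traces,) slit slot of each trace
    n_slots: int = 400          # total pseudo-slit positions

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.slit_indices = np.asarray(self.slit_indices, dtype=int)
        if self.sigma <= 0:
            raise ValueError("profile sigma must be positive")
        if self.slit_indices.size != self.coeffs.shape[0]:
            raise ValueError("one slit index per trace required")
        centers0 = self.coeffs[:, 0]
        if np.any(np.diff(centers0) <= 0):
            raise ValueError("traces must be ordered by increasing row")
        if self.coeffs.shape[0] > 1:
            min_sep = np.diff(centers0).min()
            if min_sep <= 2.0 * self.sigma:
                raise ValueError(
                    f"adjacent trace separation {min_sep:.2f} px is not "
                    f"resolvable at sigma {self.sigma:.2f} px")

    @property
    def n_traces(self) -> int:
        return self.coeffs.shape[0]

    def center(self, trace: int, cols: np.ndarray) -> np.ndarray:
        """Trace center row at the given dispersion columns."""
        return np.polynomial.polynomial.polyval(
            np.asarray(cols, dtype=float), self.coeffs[trace])


@dataclass
class DispersionModel:
    """Per-slit-slot wavelength solutions lambda(column) in nm."""

    coeffs: np.ndarray            # (n_slots, deg+1), ascending powers
    excitation_nm: float = 785.0
    residual_rms_nm: np.ndarray | None = None   # per-slot fit residual RMS
    calibrated: np.ndarray | None = None        # per-slot success flag

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.calibrated is None:
            self.calibrated = np.ones(self.coeffs.shape[0], dtype=bool)
        self.calibrated = np.asarray(self.calibrated, dtype=bool)

    @property
    def n_slots(self) -> int:
        return self.coeffs.shape[0]

    def wavelength(self, slot: int, cols: np.ndarray) -> np.ndarray:
        """Wavelength (nm) at the given columns for one slit slot."""
        wl = np.polynomial.polynomial.polyval(
            np.asarray(cols, dtype=float), self.coeffs[slot])
        return wl

    def check_monotone(self, n_cols: int) -> None:
        cols = np.arange(n_cols, dtype=float)
        for i in range(self.n_slots):
            if not self.calibrated[i]:
                continue
            if np.any(np.diff(self.wavelength(i, cols)) <= 0):
                raise ValueError(f"wavelength solution for slot {i} "
                                 "is not strictly increasing")
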