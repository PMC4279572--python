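"""Geometry of the square fiber-bundle probe head.

The probe head is an ``n_rows x n_cols`` matrix of step-index fibers on a
regular pitch; at the spectrograph end the fibers are rearranged into a
single row (pseudo-slit).  This module owns the grid <-> slit mapping and
the simple areal figures of merit (active surface, core area, fill
factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "BundleLayout",
    "active_edge_length",
    "fill_factor",
    "total_core_area",
]

GridCoord = tuple[int, int]


@dataclass(frozen=True)
class BundleLayout:
    """Square fiber-bundle probe head.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions of the probe head (default 20 x 20).
    pitch_mm
        Center-to-center fiber spacing in mm.
    core_um, cladding_um
        Fiber core and cladding diameters in micrometers.
    dead_fibers
        Grid coordinates ``(row, col)`` of damaged fibers.  Dead fibers
        keep their slit position; they are flagged, never deleted.
    slit_order
        Optional explicit mapping ``(row, col) -> slit index``.  Defaults
        to row-major raster order (row 0 left-to-right, then row 1, ...).
    """

    n_rows: int = 20
    n_cols: int = 20
    pitch_mm: float = 0.5
    core_um: float = 110.0
    cladding_um: float = 132.0
    dead_fibers: frozenset[GridCoord] = field(default_factory=frozenset)
    slit_order: Mapping[GridCoord, int] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.core_um <= 0 or self.cladding_um <= 0 or self.pitch_mm <= 0:
            raise ValueError("lengths must be positive")
        if self.core_um >= self.cladding_um:
            raise ValueError("core diameter must be smaller than cladding")
        if self.pitch_mm * 1000.0 <= self.cladding_um:
            raise ValueError("pitch must exceed cladding diameter (fibers overlap)")
        object.__setattr__(self, "dead_fibers", frozenset(self.dead_fibers))
        for rc in self.dead_fibers:
            self._check_coord(*rc)
        if self.slit_order is not None:
            vals = sorted(self.slit_order.values())
            if len(self.slit_order) != self.n_fibers or vals != list(range(self.n_fibers)):
                raise ValueError("slit_order must be a bijection onto 0..n_fibers-1")
            object.__setattr__(self, "slit_order", dict(self.slit_order))

    @property
    def n_fibers(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def live_fibers(self) -> list[GridCoord]:
        """Grid coordinates of live fibers in slit order."""
        coords = sorted(self.grid_coords(), key=lambda rc: self.grid_to_slit(*rc))
        return [rc for rc in coords if rc not in self.dead_fibers]

    def grid_coords(self) -> Iterator[GridCoord]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield (r, c)

    def _check_coord(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"grid coordinate ({row}, {col}) outside "
                             f"{self.n_rows} x {self.n_cols} grid")

    def grid_to_slit(self, row: int, col: int) -> int:
        """Pseudo-slit position of the fiber at grid ``(row, col)``."""
        self._check_coord(row, col)
        if self.slit_order is not None:
            return self.slit_order[(row, col)]
        return row * self.n_cols + col

    def slit_to_grid(self, slit: int) -> GridCoord:
        """Inverse of :meth:`grid_to_slit`."""
        if not 0 <= slit < self.n_fibers:
            raise IndexError(f"slit index {slit} outside [0, {self.n_fibers})")
        if self.slit_order is not None:
            inv = {v: k for k, v in self.slit_order.items()}
            return inv[slit]
        return divmod(slit, self.n_cols)

    def is_dead(self, row: int, col: int) -> bool:
        self._check_coord(row, col)
        return (row, col) in self.dead_fibers

    @classmethod
    def from_dict(cls, spec: Mapping) -> "BundleLayout":
        """Build a layout from a config mapping (YAML-friendly keys)."""
        dead = frozenset(tuple(rc) for rc in spec.get("dead_fibers", ()))
        slit_order = spec.get("slit_order")
        if slit_order is not None:
            slit_order = {tuple(k): v for k, v in slit_order.items()} \
                if isinstance(slit_order, Mapping) \
                else {tuple(entry[0]): entry[1] for entry in slit_order}
        return cls(
            n_rows=int(spec.get("n_rows", 20)),
            n_cols=int(spec.get("n_cols", 20)),
            pitch_mm=float(spec.get("pitch_mm", 0.5)),
            core_um=float(spec.get("core_um", 110.0)),
            cladding_um=float(spec.get("cladding_um", 132.0)),
            dead_fibers=dead,
            slit_order=slit_order,
        )


def active_edge_length(layout: BundleLayout) -> float:
    """Edge length (mm) of the square spanned by the fiber centers.

    For ``n`` fibers per side at pitch ``p`` this is ``(n - 1) * p``:
    the center-to-center span of the array.
    """
    if layout.n_rows != layout.n_cols:
        raise ValueError("active_edge_length requires a square layout")
    return (layout.n_rows - 1) * layout.pitch_mm


def total_core_area(layout: BundleLayout, n_fibers: int | None = None) -> float:
    """Total front-surface area of the fiber cores in mm^2."""
    n = layout.n_fibers if n_fibers is None else n_fibers
    if n < 0:
        raise ValueError("fiber count must be >= 0")
    radius_mm = layout.core_um / 2000.0
    return n * math.pi * radius_mm**2


def fill_factor(layout: BundleLayout, probe_surface_mm2: float | None = None) -> float:
    """Percentage of the probe surface covered by light-collecting cores.

    ``probe_surface_mm2`` defaults to the square of the active edge
    length.  Only a few percent of the image signal reaches the fibers
    for typical multimode-bundle geometries.
    """
    if probe_surface_mm2 is None:
        probe_surface_mm2 = active_edge_length(layout) ** 2
    if probe_surface_mm2 <= 0:
        raise ValueError("probe surface must be positive")
    return 100.0 * total_core_area(layout) / probe_surface_mm2
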