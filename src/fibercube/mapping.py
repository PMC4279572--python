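"""Chemical maps and pseudo-color rendering.

A chemical map is the fitted height of one substance's characteristic
Raman peak across the spaxel grid.  Rendering follows the blue (lowest)
to red (highest) convention with dead fibers shown white; overlays
assign each spaxel the color of the dominant substance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_rgba
from matplotlib.image import imsave

from fibercube.cube import DataCube
from fibercube.spectral import fit_gaussian, lmj_baseline

__all__ = [
    "ChemicalMap",
    "OverlayResult",
    "chemical_map",
    "overlay_maps",
    "render_map",
]

MASK_WHITE = (1.0, 1.0, 1.0, 1.0)
MASK_BROWN = (0.55, 0.27, 0.07, 1.0)


@dataclass
class ChemicalMap:
    """Peak-height image for one substance at one characteristic shift."""

    values: np.ndarray          # (n_rows, n_cols) fitted peak heights
    substance: str
    shift: float                # cm^-1
    mask: np.ndarray            # true on dead/unusable spaxels
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def live_values(self) -> np.ndarray:
        return self.values[~self.mask]


def chemical_map(cube: DataCube, substance: str, shift: float,
                 window: float = 40.0, baseline_order: int = 4,
                 baseline_iters: int = 15, do_baseline: bool = True,
                 mode: str = "fit") -> ChemicalMap:
    """Peak-height map of one substance across the field.

    Per live spaxel the fluorescence baseline is removed and a Gaussian
    is fit at the characteristic shift; the map value is the fitted
    height above the fitted offset (clipped at zero).  ``mode="raw"``
    skips the fit and takes the maximum corrected intensity in the
    window (quick-look mode).
    """
    axis = cube.shift_axis
    if not axis[0] <= shift <= axis[-1]:
        raise ValueError(f"shift {shift} cm^-1 outside cube axis "
                         f"[{axis[0]}, {axis[-1]}]")
    if mode not in ("fit", "raw"):
        raise ValueError("mode must be 'fit' or 'raw'")
    values = np.zeros(cube.data.shape[:2])
    for r in range(cube.n_rows):
        for c in range(cube.n_cols):
            if cube.mask[r, c]:
                continue
            spec = np.nan_to_num(cube.data[r, c])
            if do_baseline:
                spec = lmj_baseline(spec, axis, order=baseline_order,
                                    n_iter=baseline_iters).corrected
            if mode == "raw":
                sel = np.abs(axis - shift) <= window / 2.0
                values[r, c] = max(float(spec[sel].max()), 0.0)
            else:
                pk = fit_gaussian(spec, axis, shift, window)
                values[r, c] = max(pk.amplitude, 0.0) if pk.converged else 0.0
    return ChemicalMap(values=values, substance=substance, shift=shift,
                       mask=cube.mask.copy(),
                       meta={"window": window, "mode": mode})


def render_map(cmap: ChemicalMap, path=None, style: str = "jet",
               vmin: float | None = None,
               vmax: float | None = None) -> np.ndarray:
    """Pseudo-color RGBA image: blue = lowest, red = highest, white = dead.

    Returns the ``(n_rows, n_cols, 4)`` float RGBA array; optionally
    writes a PNG.
    """
    if cmap.mask.all():
        raise ValueError("cannot render an all-masked map")
    live = cmap.live_values()
    lo = live.min() if vmin is None else vmin
    hi = live.max() if vmax is None else vmax
    span = hi - lo
    norm = (cmap.values - lo) / span if span > 0 else np.full(cmap.shape, 0.5)
    rgba = colormaps[style](np.clip(norm, 0.0, 1.0))
    rgba[cmap.mask] = MASK_WHITE
    if path is not None:
        imsave(path, rgba)
    return rgba


@dataclass
class OverlayResult:
    """Multi-substance overlay: RGBA image plus per-spaxel winner index."""

    image: np.ndarray       # (n_rows, n_cols, 4)
    winner: np.ndarray      # (n_rows, n_cols) map index, -1 where neutral


def overlay_maps(maps: Sequence[ChemicalMap],
                 colors: Sequence | None = None,
                 threshold: float = 0.2,
                 neutral=(0.95, 0.95, 0.95, 1.0),
                 mask_color=MASK_BROWN,
                 path=None) -> OverlayResult:
    """Assign each spaxel the color of its dominant substance.

    Each map is normalized by its own maximum; a spaxel takes the color
    of the map with the largest normalized height, provided that height
    exceeds ``threshold``.  Ties go to the earlier map in the list.
    Below-threshold spaxels are neutral; masked spaxels get
    ``mask_color``.
    """
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("maps have mismatched shapes")
    if colors is None:
        colors = ["yellow", "green", "red", "blue", "magenta", "cyan"]
    if len(colors) < len(maps):
        raise ValueError("one color per map required")
    norm = np.zeros((len(maps),) + shape)
    for i, m in enumerate(maps):
        peak = m.live_values().max() if (~m.mask).any() else 0.0
        if peak > 0:
            norm[i] = m.values / peak
    winner = np.argmax(norm, axis=0)              # first index wins ties
    best = np.take_along_axis(norm, winner[None], axis=0)[0]
    winner = np.where(best >= threshold, winner, -1)
    mask = np.zeros(shape, dtype=bool)
    for m in maps:
        mask |= m.mask
    winner = np.where(mask, -1, winner)
    image = np.empty(shape + (4,))
    image[:] = to_rgba(neutral)
    for i in range(len(maps)):
        image[winner == i] = to_rgba(colors[i])
    image[mask] = to_rgba(mask_color)
    if path is not None:
        imsave(path, image)
    return OverlayResult(image=image, winner=winner)
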