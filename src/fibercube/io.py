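"""FITS carriers for frames, row-stacked spectra, cubes and maps."""

from __future__ import annotations

import numpy as np

from fibercube.cube import DataCube
from fibercube.fits import HDU, read_fits, write_fits
from fibercube.mapping import ChemicalMap
from fibercube.models import DispersionModel, Frame
from fibercube.reduce import RowStackedSpectra

__all__ = [
    "read_cube", "read_frame", "read_rss",
    "write_cube", "write_frame", "write_map", "write_rss",
]

_TYPE_CODES = {"bias": "BIAS", "flat": "FLAT", "arc": "ARC",
               "science": "SCI", "masterbias": "MBIAS"}
_CODE_TYPES = {v: k for k, v in _TYPE_CODES.items()}


def write_frame(path, frame: Frame) -> None:
    header = dict(frame.header)
    header["FRAMTYPE"] = _TYPE_CODES[frame.frametype]
    header["EXPTIME"] = frame.exptime
    write_fits(path, HDU(data=frame.data, header=header))


def read_frame(path) -> Frame:
    hdu = read_fits(path)[0]
    code = str(hdu.header.get("FRAMTYPE", "SCI")).strip()
    return Frame(data=hdu.data, frametype=_CODE_TYPES.get(code, "science"),
                 exptime=float(hdu.header.get("EXPTIME", 0.0)),
                 header=hdu.header)


def write_rss(path, rss: RowStackedSpectra) -> None:
    hdus = [HDU(data=rss.data, header=dict(rss.header)),
            HDU(data=rss.live.astype("u1"), name="FLAGS")]
    if rss.throughput is not None:
        hdus.append(HDU(data=rss.throughput, name="THRUPUT"))
    if rss.dispersion is not None:
        hdus.append(HDU(data=rss.dispersion.coeffs, name="WAVECOEF",
                        header={"EXCITNM": rss.dispersion.excitation_nm}))
    write_fits(path, hdus)


def read_rss(path) -> RowStackedSpectra:
    hdus = read_fits(path)
    by_name = {h.name: h for h in hdus[1:]}
    dispersion = None
    if "WAVECOEF" in by_name:
        h = by_name["WAVECOEF"]
        dispersion = DispersionModel(
            coeffs=h.data, excitation_nm=float(h.header.get("EXCITNM", 785.0)))
    throughput = by_name["THRUPUT"].data if "THRUPUT" in by_name else None
    return RowStackedSpectra(data=hdus[0].data,
                             live=by_name["FLAGS"].data.astype(bool),
                             throughput=throughput, dispersion=dispersion,
                             header=hdus[0].header)


def write_cube(path, cube: DataCube) -> None:
    step = float(cube.shift_axis[1] - cube.shift_axis[0]) \
        if cube.shift_axis.size > 1 else 1.0
    header = {"CRVAL3": float(cube.shift_axis[0]), "CDELT3": step,
              "CUNIT3": "cm-1"}
    for key, value in cube.meta.items():
        if isinstance(value, (bool, int, float, str, np.integer, np.floating)):
            header[key[:8].upper()] = value
    write_fits(path, [HDU(data=cube.data, header=header),
                      HDU(data=cube.mask.astype("u1"), name="MASK")])


def read_cube(path) -> DataCube:
    hdus = read_fits(path)
    primary = hdus[0]
    mask = next(h.data for h in hdus[1:] if h.name == "MASK").astype(bool)
    n = primary.data.shape[2]
    axis = (float(primary.header["CRVAL3"])
            + float(primary.header["CDELT3"]) * np.arange(n))
    meta = {k: v for k, v in primary.header.items()
            if k not in ("CRVAL3", "CDELT3", "CUNIT3")}
    return DataCube(data=primary.data, shift_axis=axis, mask=mask, meta=meta)


def write_map(path, cmap: ChemicalMap) -> None:
    header = {"SUBSTANC": cmap.substance, "SHIFT": float(cmap.shift)}
    write_fits(path, [HDU(data=cmap.values, header=header),
                      HDU(data=cmap.mask.astype("u1"), name="MASK")])
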