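"""Minimal FITS image I/O.

Supports exactly what the pipeline needs: primary image HDUs plus named
IMAGE extensions, float64/float32/int data, and scalar header cards
(bool, int, float, string).  Files written here follow the FITS standard
(2880-byte records, 80-character cards, big-endian data) and are
readable by any compliant reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["HDU", "read_fits", "write_fits"]

BLOCK = 2880
CARD = 80

# BITPIX <-> numpy dtype (big-endian on disk)
_BITPIX_DTYPE = {8: ">u1", 16: ">i2", 32: ">i4", 64: ">i8", -32: ">f4", -64: ">f8"}
_DTYPE_BITPIX = {"u1": 8, "i2": 16, "i4": 32, "i8": 64, "f4": -32, "f8": -64}


@dataclass
class HDU:
    """One header-data unit: an image array plus scalar header cards."""

    data: np.ndarray | None = None
    header: dict[str, Any] = field(default_factory=dict)
    name: str = ""


def _format_value(value: Any) -> str:
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return ("T" if value else "F").rjust(20)
    if isinstance(value, (int, np.integer)):
        return str(int(value)).rjust(20)
    if isinstance(value, (float, np.floating)):
        text = f"{float(value):.16G}"
        if "." not in text and "E" not in text and "N" not in text:
            text += "."
        return text.rjust(20)
    text = str(value).replace("'", "''")[:68]
    return f"'{text.ljust(8)}'"


def _card(keyword: str, value: Any, comment: str = "") -> bytes:
    body = f"{keyword.upper():<8}= {_format_value(value)}"
    if comment:
        body += f" / {comment}"
    return body[:CARD].ljust(CARD).encode("ascii")


def _pad(raw: bytes) -> bytes:
    extra = (-len(raw)) % BLOCK
    return raw + b" " * extra


def _header_bytes(data: np.ndarray | None, header: Mapping[str, Any],
                  primary: bool, name: str) -> bytes:
    cards = []
    if primary:
        cards.append(_card("SIMPLE", True, "conforms to FITS standard"))
    else:
        body = f"{'XTENSION':<8}= 'IMAGE   '"
        cards.append(body.ljust(CARD).encode("ascii"))
    if data is None:
        cards.append(_card("BITPIX", 8))
        cards.append(_card("NAXIS", 0))
    else:
        kind = data.dtype.str[1:]
        if kind not in _DTYPE_BITPIX:
            data = data.astype("f8")
            kind = "f8"
        cards.append(_card("BITPIX", _DTYPE_BITPIX[kind]))
        cards.append(_card("NAXIS", data.ndim))
        # NAXIS1 is the fastest-varying (last numpy) axis
        for i, length in enumerate(reversed(data.shape), start=1):
            cards.append(_card(f"NAXIS{i}", length))
    if primary:
        cards.append(_card("EXTEND", True))
    else:
        cards.append(_card("PCOUNT", 0))
        cards.append(_card("GCOUNT", 1))
    if name:
        cards.append(_card("EXTNAME", name))
    reserved = {"SIMPLE", "XTENSION", "BITPIX", "NAXIS", "EXTEND",
                "PCOUNT", "GCOUNT", "EXTNAME"}
    for key, value in header.items():
        key = key.upper()
        if key in reserved or key.startswith("NAXIS"):
            continue
        cards.append(_card(key, value))
    cards.append(b"END".ljust(CARD))
    return _pad(b"".join(cards))


def write_fits(path, hdus: list[HDU] | HDU) -> None:
    """Write one or more HDUs to ``path`` as a FITS file."""
    if isinstance(hdus, HDU):
        hdus = [hdus]
    raw = bytearray()
    for i, hdu in enumerate(hdus):
        raw += _header_bytes(hdu.data, hdu.header, primary=(i == 0), name=hdu.name)
        if hdu.data is not None:
            data = np.ascontiguousarray(hdu.data)
            kind = data.dtype.str[1:]
            if kind not in _DTYPE_BITPIX:
                data = data.astype("f8")
                kind = "f8"
            raw += _pad(data.astype(">" + kind).tobytes())
    with open(path, "wb") as fh:
        fh.write(bytes(raw))


def _parse_card(card: str) -> tuple[str, Any] | None:
    keyword = card[:8].strip()
    if not keyword or keyword in ("END", "COMMENT", "HISTORY") or card[8:10] != "= ":
        return None
    rest = card[10:]
    if "/" in rest and not rest.lstrip().startswith("'"):
        rest = rest.split("/", 1)[0]
    text = rest.strip()
    if text.startswith("'"):
        return keyword, text[1:text.rindex("'")].replace("''", "'").rstrip()
    if text == "T":
        return keyword, True
    if text == "F":
        return keyword, False
    try:
        return keyword, int(text)
    except ValueError:
        pass
    try:
        return keyword, float(text)
    except ValueError:
        return keyword, text


def read_fits(path) -> list[HDU]:
    """Read all image HDUs from a FITS file."""
    with open(path, "rb") as fh:
        raw = fh.read()
    hdus: list[HDU] = []
    pos = 0
    while pos < len(raw):
        header: dict[str, Any] = {}
        done = False
        while not done:
            block = raw[pos:pos + BLOCK]
            if len(block) < BLOCK:
                raise OSError("truncated FITS header")
            pos += BLOCK
            for i in range(0, BLOCK, CARD):
                card = block[i:i + CARD].decode("ascii", errors="replace")
                if card[:8].strip() == "END":
                    done = True
                    break
                parsed = _parse_card(card)
                if parsed:
                    header[parsed[0]] = parsed[1]
        naxis = int(header.get("NAXIS", 0))
        data = None
        if naxis > 0:
            shape = tuple(int(header[f"NAXIS{i}"]) for i in range(naxis, 0, -1))
            dtype = np.dtype(_BITPIX_DTYPE[int(header["BITPIX"])])
            nbytes = int(np.prod(shape)) * dtype.itemsize
            data = np.frombuffer(raw[pos:pos + nbytes], dtype=dtype).reshape(shape)
            data = data.astype(dtype.str[1:])  # native byte order copy
            pos += nbytes + ((-nbytes) % BLOCK)
        name = str(header.pop("EXTNAME", "")).strip()
        for key in ("SIMPLE", "XTENSION", "BITPIX", "NAXIS", "EXTEND",
                    "PCOUNT", "GCOUNT"):
            header.pop(key, None)
        for key in list(header):
            if key.startswith("NAXIS"):
                header.pop(key)
        hdus.append(HDU(data=data, header=header, name=name))
        while pos < len(raw) and not raw[pos:pos + 6] in (b"SIMPLE", b"XTENSI"):
            pos += BLOCK  # skip stray padding
    return hdus
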