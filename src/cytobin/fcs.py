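"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset of the standard that exported, pre-compensated cytometry
event files actually use: a single dataset, list mode ($MODE L), float
($DATATYPE F/D) or unsigned integer ($DATATYPE I, 8/16/32/64-bit) data,
little- or big-endian byte order.  Channel names are taken from the stain
name $PnS when present, else the detector name $PnN.

The writer emits FCS 3.1 little-endian float32, which bounds the read/write
round-trip error at 32-bit precision.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError, InputError

_HEADER_LEN = 58
_DELIM = b"/"


def read_fcs(path: str) -> tuple[np.ndarray, list[str]]:
    """Read one FCS dataset; returns (events x channels float array, names)."""
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read FCS file {path!r}: {exc}") from exc
    if len(raw) < _HEADER_LEN or not raw[:3] == b"FCS":
        raise FormatError(f"{path!r} is not an FCS file (bad magic)")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1", "FCS2.0"):
        raise FormatError(f"{path!r}: unsupported FCS version {version!r}")

    def _off(lo: int, hi: int) -> int:
        txt = raw[lo:hi].decode("ascii", "replace").strip() or "0"
        try:
            return int(txt)
        except ValueError as exc:
            raise FormatError(f"{path!r}: malformed header offset {txt!r}") from exc

    text_beg, text_end = _off(10, 18), _off(18, 26)
    data_beg, data_end = _off(26, 34), _off(34, 42)
    text = _parse_text(raw[text_beg : text_end + 1], path)

    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if data_beg == 0 or data_end == 0:
        raise FormatError(f"{path!r}: no data segment offsets")

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    widths = [int(text[f"$P{k}B"]) for k in range(1, n_par + 1)]
    names = []
    for k in range(1, n_par + 1):
        stain = text.get(f"$P{k}S", "").strip()
        detector = text.get(f"$P{k}N", "").strip()
        names.append(stain or detector or f"P{k}")
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FormatError(f"{path!r}: duplicate channel names: {', '.join(dupes)}")

    seg = raw[data_beg : data_end + 1]
    if datatype == "F":
        dtypes = [np.dtype(endian + "f4")] * n_par
        if any(w != 32 for w in widths):
            raise FormatError(f"{path!r}: $DATATYPE F requires $PnB 32")
    elif datatype == "D":
        dtypes = [np.dtype(endian + "f8")] * n_par
    elif datatype == "I":
        dtypes = []
        for w in widths:
            if w not in (8, 16, 32, 64):
                raise FormatError(f"{path!r}: unsupported integer width {w}")
            dtypes.append(np.dtype(f"{endian}u{w // 8}"))
    else:
        raise FormatError(f"{path!r}: unsupported $DATATYPE {datatype!r}")

    row = np.dtype([(f"f{k}", dt) for k, dt in enumerate(dtypes)])
    need = row.itemsize * n_tot
    if len(seg) < need:
        raise FormatError(
            f"{path!r}: data segment holds {len(seg)} bytes, need {need}"
        )
    rec = np.frombuffer(seg[:need], dtype=row)
    values = np.column_stack(
        [rec[f"f{k}"].astype(np.float64) for k in range(n_par)]
    )
    return values, names


def _parse_text(seg: bytes, path: str) -> dict[str, str]:
    if not seg:
        raise FormatError(f"{path!r}: empty TEXT segment")
    delim = seg[0:1]
    parts = seg[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    out: dict[str, str] = {}
    for key, val in zip(parts[0::2], parts[1::2]):
        out[key.decode("ascii", "replace").strip().upper()] = val.decode(
            "utf-8", "replace"
        )
    return out


def write_fcs(path: str, values: np.ndarray, names: list[str]) -> None:
    """Write an FCS 3.1 single-dataset file (little-endian float32)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.shape[1] != len(names):
        raise FormatError("values must be events x channels matching names")
    for name in names:
        if _DELIM.decode() in name:
            raise FormatError(f"channel name {name!r} contains the delimiter")
    n_tot, n_par = values.shape
    data = values.astype("<f4").tobytes(order="C")

    def build_text(beg: int, end: int) -> bytes:
        pairs = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(beg)),
            ("$ENDDATA", str(end)),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        for k, name in enumerate(names, start=1):
            hi = float(np.abs(values[:, k - 1]).max()) if n_tot else 0.0
            pairs += [
                (f"$P{k}B", "32"),
                (f"$P{k}E", "0,0"),
                (f"$P{k}N", name),
                (f"$P{k}R", str(int(np.ceil(hi)) + 1)),
                (f"$P{k}S", name),
            ]
        body = _DELIM + _DELIM.join(
            k.encode() + _DELIM + v.encode() for k, v in pairs
        ) + _DELIM
        return body

    # data offsets depend on TEXT length; iterate until stable (the offsets
    # are plain decimal so two passes always converge)
    beg = end = 0
    for _ in range(8):
        text = build_text(beg, end)
        new_beg = _HEADER_LEN + len(text)
        new_end = new_beg + len(data) - 1 if data else new_beg
        if (new_beg, new_end) == (beg, end):
            break
        beg, end = new_beg, new_end
    text = build_text(beg, end)

    def fmt(off: int) -> bytes:
        s = str(off)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode()

    header = (
        b"FCS3.1    "
        + fmt(_HEADER_LEN)
        + fmt(_HEADER_LEN + len(text) - 1)
        + fmt(beg if beg <= 99999999 else 0)
        + fmt(end if end <= 99999999 else 0)
        + fmt(0)
        + fmt(0)
    )
    assert len(header) == _HEADER_LEN
    tmp = path + ".tmp"
    with open(tmp, "wb") as fh:
        fh.write(header + text + data)
    os.replace(tmp, path)
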