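"""Minimal reader/writer for list-mode FCS 3.0/3.1 files.

Supports what cytometry event tables actually need: the TEXT keyword
segment, list-mode ($MODE L) data in float ($DATATYPE F), double (D) or
integer (I) encoding, and either byte order.  Analysis segments, multiple
data sets per file and bit-packed integer data are not supported.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

__all__ = ["read_fcs", "write_fcs"]

_DTYPES = {
    ("F", 32): "f4",
    ("D", 64): "f8",
    ("I", 8): "u1",
    ("I", 16): "u2",
    ("I", 32): "u4",
    ("I", 64): "u8",
}


def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise FormatError("empty TEXT segment")
    decoded = raw.decode("latin-1")
    delim = decoded[0]
    body = decoded[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Delimiter escaping (doubled delimiters) is rare; split and re-join empties.
    parts = body.split(delim)
    fields: list[str] = []
    i = 0
    while i < len(parts):
        part = parts[i]
        # an empty part signals an escaped delimiter inside the previous field
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            part = part + delim + parts[i + 2]
            i += 2
        fields.append(part)
        i += 1
    if len(fields) % 2:
        raise FormatError("TEXT segment has an odd number of delimited fields")
    keys = [f.strip().upper() if f.startswith("$") else f.strip() for f in fields[::2]]
    return dict(zip(keys, fields[1::2]))


def read_fcs(path) -> tuple[np.ndarray, list[str]]:
    """Read one list-mode FCS data set.

    Returns the events as a float64 array of shape (n_events, n_params) and
    the parameter names.  The staining label ($PnS) is preferred over the
    short channel name ($PnN) when present, matching how cytometry software
    labels columns.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FormatError(f"not an FCS file: {path}")
    version = blob[:10].decode("latin-1").strip()
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("latin-1").strip() or "0"
        return int(field)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_start : text_end + 1])
    # offsets >99,999,999 live only in the TEXT segment (header holds zeros)
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").strip().upper()
    if text.get("$MODE", "L").strip().upper() != "L":
        raise FormatError("only list-mode ($MODE L) FCS data are supported")
    bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FormatError("per-parameter bit widths differ; not supported")
    key = (datatype, bits.pop())
    if key not in _DTYPES:
        raise FormatError(f"unsupported $DATATYPE/$PnB combination: {key}")
    byteord = text.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(endian + _DTYPES[key])

    names = []
    for i in range(1, n_par + 1):
        label = text.get(f"$P{i}S", "").strip()
        names.append(label or text[f"$P{i}N"].strip())
    if len(set(names)) != len(names):
        raise FormatError("duplicate parameter names in FCS file")

    raw = blob[data_start : data_end + 1]
    needed = n_par * n_tot * dtype.itemsize
    if len(raw) < needed:
        raise FormatError("FCS data segment shorter than $PAR*$TOT events")
    events = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_tot, n_par)
    return events.astype(np.float64), names


def write_fcs(path, events: np.ndarray, names: list[str]) -> None:
    """Write events as a single FCS 3.1 data set ($DATATYPE F, little-endian)."""
    events = np.ascontiguousarray(np.asarray(events, dtype="<f4"))
    n_tot, n_par = events.shape
    if n_par != len(names):
        raise FormatError("number of names does not match number of columns")
    delim = "/"
    for name in names:
        if delim in name:
            raise FormatError(f"parameter name may not contain {delim!r}: {name!r}")

    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(events[:, i - 1].max() if n_tot else 1.0))))

    # fixed-width data offsets so the TEXT length is stable across the two passes
    data_size = events.nbytes
    placeholder = {"$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12}

    def _render(kw: dict) -> bytes:
        parts = [delim]
        for k, v in kw.items():
            parts.append(f"{k}{delim}{v}{delim}")
        return "".join(parts).encode("latin-1")

    text = _render({**placeholder, **keywords})
    text_start = 58
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data_size - 1 if data_size else 0
    final = {
        "$BEGINDATA": str(data_start).rjust(12, "0"),
        "$ENDDATA": str(max(data_end, 0)).rjust(12, "0"),
    }
    text = _render({**final, **keywords})

    def _hdr(value: int) -> bytes:
        s = str(value) if value <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _hdr(text_start) + _hdr(text_end)
    header += _hdr(data_start if data_size else 0) + _hdr(data_end if data_size else 0)
    header += _hdr(0) + _hdr(0)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(events.tobytes())
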