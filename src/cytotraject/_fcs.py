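"""Minimal FCS 3.0/3.1 codec (list-mode numeric data only).

Covers what longitudinal cytometry event tables need and nothing more:

* reading FCS 3.0 / 3.1 files with ``$MODE=L`` and ``$DATATYPE`` F, D or I
  (8/16/32/64-bit unsigned integers), either byte order;
* writing FCS 3.1 files with double-precision data, little-endian;
* only ``$PnN`` (channel name) and ``$PnS`` (stain/marker name) are consulted
  for channel metadata; arbitrary extra TEXT keywords round-trip.

The TEXT-segment delimiter is ``/``; keyword values written by this module
must not contain it (escaped, doubled delimiters are handled on read).
"""

from __future__ import annotations

import numpy as np

DELIM = b"/"
_HEADER_LEN = 58


def _split_text(raw: bytes, delim: bytes) -> dict[str, str]:
    # FCS escapes a literal delimiter by doubling it; an empty token between
    # two delimiters therefore glues its neighbours together.
    parts = raw.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"":
            tok += delim + parts[i + 2] if i + 2 < len(parts) else delim
            i += 2
        tokens.append(tok.decode("utf-8", errors="replace"))
        i += 1
    if tokens and tokens[-1] == "":
        tokens.pop()
    kv: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        key = k.strip()
        if key.startswith("$"):
            key = key.upper()
        kv[key] = v
    return kv


def read_fcs(path) -> tuple[np.ndarray, list[str], list[str], dict[str, str]]:
    """Read an FCS file.

    Returns ``(data, channel_names, marker_names, text_keywords)`` where
    ``data`` is an ``(events, channels)`` float64 array.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < _HEADER_LEN:
        raise ValueError(f"{path}: too short to be an FCS file")
    version = buf[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    text_start = int(buf[10:18])
    text_end = int(buf[18:26])
    delim = buf[text_start:text_start + 1]
    kw = _split_text(buf[text_start + 1:text_end + 1], delim)

    data_start = int(buf[26:34] or b"0")
    data_end = int(buf[34:42] or b"0")
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError(f"{path}: only list-mode ($MODE=L) FCS is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code == "F":
        dt = np.dtype(endian + "f4")
    elif dtype_code == "D":
        dt = np.dtype(endian + "f8")
    elif dtype_code == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise ValueError(f"{path}: unsupported mixed/odd integer widths")
        width = int(kw["$P1B"]) // 8
        dt = np.dtype(f"{endian}u{width}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    raw = buf[data_start:data_end + 1]
    n_vals = n_tot * n_par
    if len(raw) < n_vals * dt.itemsize:
        raise ValueError(f"{path}: data segment truncated")
    data = np.frombuffer(raw[: n_vals * dt.itemsize], dtype=dt)
    data = data.astype(np.float64).reshape(n_tot, n_par)

    channels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    markers = [kw.get(f"$P{i}S", channels[i - 1]) for i in range(1, n_par + 1)]
    return data, channels, markers, kw


def write_fcs(path, data: np.ndarray, channel_names: list[str],
              marker_names: list[str] | None = None,
              extra_keywords: dict[str, str] | None = None) -> None:
    """Write an FCS 3.1 file (double precision, little-endian, list mode)."""
    data = np.asarray(data, dtype="<f8")
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match data columns")
    marker_names = marker_names or list(channel_names)

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$NEXTDATA": "0",
        "$MODE": "L", "$DATATYPE": "D", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    rng_max = np.nanmax(data) if data.size else 0.0
    for i, (cn, mn) in enumerate(zip(channel_names, marker_names), start=1):
        kw[f"$P{i}N"] = cn
        kw[f"$P{i}S"] = mn
        kw[f"$P{i}B"] = "64"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(rng_max)) + 1)
    for k, v in (extra_keywords or {}).items():
        kw[k] = str(v)

    for k, v in kw.items():
        if DELIM.decode() in k or DELIM.decode() in str(v):
            raise ValueError(f"keyword {k!r}={v!r} contains the TEXT delimiter")

    # $BEGINDATA/$ENDDATA depend on the TEXT length; fixed-width fields break
    # the circularity.
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10

    def render(kws: dict[str, str]) -> bytes:
        out = DELIM
        for k, v in kws.items():
            out += k.encode() + DELIM + str(v).encode() + DELIM
        return out

    text = render(kw)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.nbytes else data_start
    kw["$BEGINDATA"] = str(data_start).zfill(10)
    kw["$ENDDATA"] = str(data_end).zfill(10)
    text = render(kw)

    header = b"FCS3.1"
    header += b" " * 4
    for off in (text_start, text_end, data_start, data_end, 0, 0):
        field = str(off).encode()
        if len(field) > 8:  # huge files: offsets live in TEXT only
            field = b"0"
        header += field.rjust(8)
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes(order="C"))
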