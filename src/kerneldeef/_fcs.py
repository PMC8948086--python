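"""Minimal FCS 2.0/3.0/3.1 support.

Only what the package needs: reading event data plus the $PnN/$PnS channel
keywords, and a tiny FCS3.0 float writer used to build test fixtures.  No
compensation, no spillover, no analysis segment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["FcsFormatError", "read_fcs_raw", "write_fcs"]

_SUPPORTED_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")


class FcsFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FcsFormatError("TEXT segment too short")
    delim = raw[0:1]
    # Split on the delimiter; FCS escapes a literal delimiter by doubling it.
    parts = raw[1:].split(delim)
    # Re-join doubled delimiters (empty strings between two splits).
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        piece = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"" and i + 2 < len(parts):
            piece = piece + delim + parts[i + 2]
            i += 2
        tokens.append(piece.decode("utf-8", errors="replace"))
        i += 1
    if tokens and tokens[-1] == "":
        tokens.pop()
    if len(tokens) % 2 != 0:
        tokens.pop()
    return {tokens[j].strip().upper(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def read_fcs_raw(path: str | Path) -> tuple[np.ndarray, dict[str, str]]:
    """Read an FCS file; return (events x channels float array, keyword dict)."""
    path = Path(path)
    try:
        blob = path.read_bytes()
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise FcsFormatError(f"cannot read FCS file {path}: {exc}") from exc
    if len(blob) < 58:
        raise FcsFormatError(f"{path}: file too short to be FCS")
    version = blob[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
        data_start = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError as exc:
        raise FcsFormatError(f"{path}: malformed header offsets") from exc
    if text_end <= text_start or text_end >= len(blob):
        raise FcsFormatError(f"{path}: TEXT segment offsets out of range")
    keywords = _parse_text_segment(blob[text_start : text_end + 1])

    # FCS3.x may put 0 in the header and the real offsets in TEXT.
    if data_start == 0 and "$BEGINDATA" in keywords:
        data_start = int(keywords["$BEGINDATA"])
    if data_end == 0 and "$ENDDATA" in keywords:
        data_end = int(keywords["$ENDDATA"])

    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        datatype = keywords["$DATATYPE"].strip().upper()
        byteord = keywords["$BYTEORD"].strip()
    except KeyError as exc:
        raise FcsFormatError(f"{path}: missing required keyword {exc}") from exc

    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FcsFormatError(f"{path}: mixed integer widths unsupported")
        dtype = np.dtype(order + {8: "u1", 16: "u2", 32: "u4"}[bits.pop()])
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = blob[data_start : data_end + 1]
    if len(raw) < n_values * dtype.itemsize:
        raise FcsFormatError(
            f"{path}: DATA segment truncated "
            f"({len(raw)} bytes, need {n_values * dtype.itemsize})"
        )
    data = np.frombuffer(raw[: n_values * dtype.itemsize], dtype=dtype)
    return data.reshape(n_tot, n_par).astype(np.float64), keywords


def write_fcs(
    path: str | Path,
    data: np.ndarray,
    channel_names: list[str],
    stain_names: list[str] | None = None,
) -> None:
    """Write a minimal FCS3.0 file (float32, little-endian).

    Fixture writer only: `channel_names` go to $PnN, `stain_names` (if given)
    to $PnS.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match number of columns")
    if stain_names is not None and len(stain_names) != n_par:
        raise ValueError("stain_names length must match number of columns")

    payload = data.astype("<f4").tobytes()
    kw: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$MODE", "L"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i in range(n_par):
        kw.append((f"$P{i + 1}N", channel_names[i]))
        kw.append((f"$P{i + 1}B", "32"))
        kw.append((f"$P{i + 1}E", "0,0"))
        kw.append((f"$P{i + 1}R", str(int(np.ceil(np.abs(data).max() + 1)) if data.size else 1)))
        if stain_names is not None:
            kw.append((f"$P{i + 1}S", stain_names[i]))

    delim = "/"

    def render(pairs: list[tuple[str, str]]) -> bytes:
        out = delim
        for k, v in pairs:
            out += f"{k}{delim}{v}{delim}"
        return out.encode("ascii")

    # Offsets depend on TEXT length which depends on the offset digits; fix
    # widths and iterate once.
    header_len = 58
    for _ in range(3):
        text = render(
            kw
            + [
                ("$BEGINDATA", str(0).rjust(8, "0")),
                ("$ENDDATA", str(0).rjust(8, "0")),
            ]
        )
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
        text = render(
            kw
            + [
                ("$BEGINDATA", str(data_start).rjust(8, "0")),
                ("$ENDDATA", str(data_end).rjust(8, "0")),
            ]
        )
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + payload)
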