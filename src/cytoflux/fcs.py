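"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Scope: list-mode (``$MODE L``) float data (``$DATATYPE F``, 32-bit), the
layout produced by modern mass cytometers and by :func:`write_fcs`.  Per-event
annotations are serialized as extra channels prefixed ``meta_`` so that files
stay inside the FCS standard; sample metadata travels in custom TEXT keywords.
"""

from __future__ import annotations

import struct
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .events import (
    ROLE_UNASSIGNED,
    EventTable,
    infer_channel_roles,
)
from .panel import BEAD_CHANNELS, CERIUM_CHANNEL, DNA_CHANNELS, PD_CHANNELS

DELIM = "/"
META_PREFIX = "meta_"
_ROLE_KEY = "CYTOFLUXROLE{n}"
_META_KEY = "CYTOFLUXMETA_{key}"


class FCSParseError(ValueError):
    """Raised for malformed or unsupported FCS files."""


def _escape(value: str) -> str:
    return str(value).replace(DELIM, DELIM + DELIM)


def _keywords_to_text(keywords: Mapping[str, str]) -> bytes:
    parts = [DELIM]
    for k, v in keywords.items():
        v = str(v)
        if v == "":
            v = " "  # FCS forbids zero-length values
        parts.append(_escape(k) + DELIM + _escape(v) + DELIM)
    return "".join(parts).encode("utf-8")


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading delimiter; split handling escaped (doubled) delimiters
    tokens = body[1:].split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        # doubled delimiter shows up as an empty token between two pieces
        while i + 1 < len(tokens) and tokens[i + 1] == "" and i + 2 < len(tokens):
            tok = tok + delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if merged and merged[-1] == "":
        merged.pop()
    if len(merged) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    return {
        merged[j].strip(): merged[j + 1]
        for j in range(0, len(merged), 2)
    }


def write_fcs(table: EventTable, path) -> str:
    """Write an EventTable as an FCS 3.1 file (float32, list mode).

    Numeric per-event annotations (including booleans) are stored as channels
    named ``meta_<annotation>``; non-numeric annotations are skipped with a
    warning.
    """
    table.validate()
    columns = list(table.data.columns)
    matrix = [table.data.to_numpy(dtype=np.float32)]
    names = list(columns)
    for col in table.annotations.columns:
        vals = table.annotations[col]
        if vals.dtype == bool:
            arr = vals.to_numpy().astype(np.float32)
        else:
            try:
                arr = vals.to_numpy(dtype=np.float32)
            except (TypeError, ValueError):
                warnings.warn(
                    f"annotation {col!r} is non-numeric; not written to FCS"
                )
                continue
        names.append(META_PREFIX + col)
        matrix.append(arr.reshape(-1, 1))
    data = (
        np.hstack(matrix) if len(matrix) > 1 else matrix[0]
    ).astype("<f4")
    n_events, n_par = (data.shape[0], data.shape[1]) if data.ndim == 2 else (0, len(names))

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0",
        "$ENDDATA": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}S"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        col_max = float(data[:, i - 1].max()) if n_events else 1.0
        keywords[f"$P{i}R"] = str(int(max(col_max, 1.0)) + 1)
        role = table.roles.get(name, ROLE_UNASSIGNED)
        if name.startswith(META_PREFIX):
            role = "meta"
        keywords[_ROLE_KEY.format(n=i)] = role
    for k, v in table.sample_meta.items():
        if v is not None:
            keywords[_META_KEY.format(key=k)] = str(v)

    header_len = 58
    # the TEXT length depends on the $BEGINDATA/$ENDDATA digit counts;
    # iterate until the offsets are self-consistent
    data_bytes = data.tobytes()
    begin_data = end_data = 0
    for _ in range(8):
        keywords["$BEGINDATA"] = str(begin_data)
        keywords["$ENDDATA"] = str(end_data)
        text = _keywords_to_text(keywords)
        new_begin = header_len + len(text)
        new_end = new_begin + max(len(data_bytes) - 1, 0)
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _keywords_to_text(keywords)
    text_begin = header_len
    text_end = header_len + len(text) - 1

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; keywords carry the offset
        return s.rjust(8).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(b"FCS3.1")
        fh.write(b" " * 4)
        fh.write(_off(text_begin))
        fh.write(_off(text_end))
        fh.write(_off(begin_data if len(data_bytes) else 0))
        fh.write(_off(end_data if len(data_bytes) else 0))
        fh.write(_off(0))
        fh.write(_off(0))
        fh.write(text)
        fh.write(data_bytes)
    return str(path)


def read_fcs(path, panel=None, key=None) -> EventTable:
    """Read an FCS 3.0/3.1 file into an EventTable.

    Channel roles are restored from writer keywords when present, otherwise
    inferred from channel names via the optional panel / barcode key.
    ``meta_``-prefixed channels become per-event annotations.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FCSParseError(f"{path}: truncated header ({len(raw)} bytes)")
    version = raw[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3"):
        raise FCSParseError(f"{path}: unsupported FCS version {version!r}")

    def _header_off(start: int) -> int:
        field = raw[start : start + 8].decode("latin-1").strip()
        return int(field) if field else 0

    try:
        text_begin = _header_off(10)
        text_end = _header_off(18)
        data_begin = _header_off(26)
        data_end = _header_off(34)
    except ValueError as exc:
        raise FCSParseError(f"{path}: malformed header offsets ({exc})") from exc
    if text_end <= text_begin or text_end >= len(raw):
        raise FCSParseError(
            f"{path}: TEXT segment offsets [{text_begin}, {text_end}] invalid"
        )
    keywords = _parse_text(raw[text_begin : text_end + 1])

    if not data_begin:
        data_begin = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    tot = int(keywords["$TOT"])
    n_par = int(keywords["$PAR"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    if datatype != "F":
        raise FCSParseError(
            f"{path}: unsupported $DATATYPE {datatype!r} (only 'F' supported)"
        )
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"

    expected = tot * n_par * 4
    if tot == 0:
        values = np.empty((0, n_par), dtype=np.float32)
    else:
        available = data_end - data_begin + 1
        if data_end >= len(raw) or available < expected:
            raise FCSParseError(
                f"{path}: DATA segment at offset {data_begin} holds "
                f"{max(available, 0)} bytes but $TOT={tot}, $PAR={n_par} "
                f"require {expected}"
            )
        buf = raw[data_begin : data_begin + expected]
        values = (
            np.frombuffer(buf, dtype=endian + "f4").reshape(tot, n_par).copy()
        )

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}N") or keywords.get(f"$P{i}S") or f"P{i}"
        names.append(name.strip())

    stored_roles = {
        names[i - 1]: keywords[_ROLE_KEY.format(n=i)].strip()
        for i in range(1, n_par + 1)
        if _ROLE_KEY.format(n=i) in keywords
    }

    data_cols = [n for n in names if not n.startswith(META_PREFIX)]
    meta_cols = [n for n in names if n.startswith(META_PREFIX)]
    frame = pd.DataFrame(values, columns=names)
    annotations = frame[meta_cols].rename(
        columns={c: c[len(META_PREFIX):] for c in meta_cols}
    )
    data = frame[data_cols]

    if stored_roles and all(n in stored_roles for n in data_cols):
        roles = {n: stored_roles[n] for n in data_cols}
    else:
        roles = infer_channel_roles(
            data_cols,
            panel=panel,
            pd_channels=(key.pd_channels if key is not None else PD_CHANNELS),
            bead_channels=BEAD_CHANNELS,
            dna_channels=DNA_CHANNELS,
            cerium_channel=CERIUM_CHANNEL,
        )
    unknown = [n for n, r in roles.items() if r == ROLE_UNASSIGNED]
    if unknown:
        warnings.warn(f"{path}: unassigned channels {unknown}")

    sample_meta: dict = {}
    prefix = _META_KEY.format(key="")
    for k, v in keywords.items():
        if k.startswith(prefix):
            name = k[len(prefix):]
            try:
                num = float(v)
                sample_meta[name] = int(num) if num.is_integer() else num
            except ValueError:
                sample_meta[name] = v
    return EventTable(data, roles, annotations, sample_meta)
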