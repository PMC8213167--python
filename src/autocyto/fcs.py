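"""FCS file I/O, spillover matrices and compensation.

A compact codec for the Flow Cytometry Standard: reads versions 2.0, 3.0 and
3.1 (list-mode, datatype F/D/I) and writes version 3.1 (float32).  Spillover
is taken from the ``$SPILLOVER`` (3.1), ``SPILL`` or ``$COMP`` (2.0) keyword,
or from a CSV file whose first row and first column carry channel labels.

Compensation is applied at the point of entry: for fluorescence columns ``X``
and spillover matrix ``S`` (unit diagonal, ``S[i, j]`` = fraction of channel
``i``'s signal spilling into channel ``j``), the corrected signal is
``X @ inv(S)``.  Non-fluorescence columns (scatter, time) pass through
unchanged.
"""
from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    NumericalError,
    ParameterError,
    SchemaError,
)

__all__ = [
    "EventMatrix",
    "SpilloverMatrix",
    "read_fcs",
    "write_fcs",
    "read_spillover_csv",
    "compensate",
    "decompensate",
]


@dataclass
class EventMatrix:
    """Events x channels matrix on a linear scale with channel metadata."""

    values: np.ndarray
    channel_names: List[str]
    marker_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("event matrix must be 2-D")
        if self.values.shape[1] != len(self.channel_names):
            raise SchemaError("column count does not match channel names")
        if not self.marker_names:
            self.marker_names = [""] * len(self.channel_names)
        if len(self.marker_names) != len(self.channel_names):
            raise SchemaError("marker names length mismatch")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        return self.values[:, self.column_index(channel)]

    def column_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise SchemaError(f"channel {channel!r} not present") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)

    def copy(self) -> "EventMatrix":
        return EventMatrix(self.values.copy(), list(self.channel_names),
                           list(self.marker_names))


@dataclass
class SpilloverMatrix:
    """k x k spillover matrix over fluorescence channel ``labels``."""

    labels: List[str]
    S: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.labels)
        if self.S.shape != (k, k):
            raise SchemaError("spillover matrix shape does not match labels")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-6):
            raise IntegrityError("spillover matrix diagonal must be 1")
        if not np.all(np.isfinite(self.S)):
            raise NumericalError("spillover matrix contains non-finite entries")

    @staticmethod
    def identity(labels) -> "SpilloverMatrix":
        return SpilloverMatrix(list(labels), np.eye(len(labels)))

    def to_keyword(self) -> str:
        vals = ",".join(repr(float(v)) for v in self.S.ravel())
        return f"{len(self.labels)},{','.join(self.labels)},{vals}"

    @staticmethod
    def from_keyword(text: str) -> "SpilloverMatrix":
        parts = [p.strip() for p in text.split(",")]
        k = int(float(parts[0]))
        labels = parts[1:1 + k]
        vals = np.array([float(v) for v in parts[1 + k:1 + k + k * k]])
        if vals.size != k * k:
            raise IntegrityError("spillover keyword truncated")
        return SpilloverMatrix(labels, vals.reshape(k, k))


# ---------------------------------------------------------------------------
# FCS reading

_SUPPORTED = ("FCS2.0", "FCS3.0", "FCS3.1")


def _parse_text_segment(raw: bytes) -> Dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading/trailing delimiter, split; doubled delimiters (escapes)
    # appear as empty fields and are re-joined below
    parts = body.strip(delim).split(delim)
    merged: List[str] = []
    i = 0
    while i < len(parts):
        seg = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "":
            # escaped delimiter inside a value
            seg += delim + (parts[i + 2] if i + 2 < len(parts) else "")
            i += 2
        merged.append(seg)
        i += 1
    if len(merged) % 2 == 1:
        merged = merged[:-1]
    return {merged[j].strip().upper(): merged[j + 1]
            for j in range(0, len(merged), 2)}


def read_fcs(path, version_hint: Optional[str] = None
             ) -> Tuple[EventMatrix, Optional[SpilloverMatrix], Dict[str, str]]:
    """Read an FCS file.

    Returns ``(matrix, spillover_or_None, metadata)``.  Values are converted
    to a linear scale ($PnE log amplification undone); events containing
    NaN/Inf are dropped and counted in ``metadata['n_dropped']``.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FormatError("file too short for an FCS header")
    version = raw[0:6].decode("latin-1", "replace")
    if version not in _SUPPORTED:
        raise FormatError(f"unsupported FCS version {version!r}")

    def _off(a, b):
        s = raw[a:b].decode("latin-1").strip()
        return int(s) if s else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    if text_end >= len(raw) or text_begin >= text_end:
        raise IntegrityError("TEXT segment offsets out of range")
    text = _parse_text_segment(raw[text_begin:text_end + 1])

    if data_begin == 0:
        data_begin = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        itemsize, np_type = 4, "f4"
    elif datatype == "D":
        itemsize, np_type = 8, "f8"
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FormatError("integer data requires uniform $PnB of 16 or 32")
        itemsize, np_type = bits[0] // 8, f"u{bits[0] // 8}"
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * itemsize
    segment = raw[data_begin:data_end + 1]
    if len(segment) < expected:
        raise IntegrityError(
            f"data segment holds {len(segment)} bytes, "
            f"expected {expected} for $TOT={n_tot}")
    values = np.frombuffer(segment[:expected], dtype=endian + np_type)
    values = values.reshape(n_tot, n_par).astype(float)

    channels, markers = [], []
    for i in range(1, n_par + 1):
        channels.append(text.get(f"$P{i}N", f"P{i}"))
        markers.append(text.get(f"$P{i}S", ""))
        # undo log amplification: stored v in [0, R) maps to f2 * 10^(f1 v / R)
        pne = text.get(f"$P{i}E", "0,0")
        f1, f2 = (float(v) for v in pne.split(",")[:2])
        if f1 != 0:
            r = float(text.get(f"$P{i}R", "1024"))
            f2 = f2 if f2 > 0 else 1.0
            values[:, i - 1] = f2 * np.power(10.0, f1 * values[:, i - 1] / r)

    keep = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~keep).sum())
    values = values[keep]

    spill = None
    for key in ("$SPILLOVER", "SPILL", "$COMP"):
        if key in text:
            spill = SpilloverMatrix.from_keyword(text[key])
            break

    meta = dict(text)
    meta["version"] = version
    meta["n_dropped"] = str(n_dropped)
    return EventMatrix(values, channels, markers), spill, meta


# ---------------------------------------------------------------------------
# FCS 3.1 writing

def write_fcs(matrix: EventMatrix, path,
              spillover: Optional[SpilloverMatrix] = None,
              extra_keywords: Optional[Dict[str, str]] = None) -> None:
    """Write ``matrix`` as an FCS 3.1 list-mode file (float32, little-endian)."""
    if matrix.n_events == 0:
        raise ParameterError("refusing to write an empty event matrix")
    n, p = matrix.values.shape
    data = matrix.values.astype("<f4").tobytes()

    kw: Dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(p), "$TOT": str(n),
    }
    for i in range(p):
        col = matrix.values[:, i]
        kw[f"$P{i + 1}N"] = matrix.channel_names[i]
        if matrix.marker_names[i]:
            kw[f"$P{i + 1}S"] = matrix.marker_names[i]
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        kw[f"$P{i + 1}R"] = str(int(max(1.0, np.ceil(col.max()))) if col.size else 1)
    if spillover is not None:
        kw["$SPILLOVER"] = spillover.to_keyword()
    if extra_keywords:
        kw.update(extra_keywords)
    # fixed-width data offsets so TEXT length is stable
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d):
        out = io.StringIO()
        out.write("/")
        for k, v in d.items():
            out.write(f"{k}/{v}/")
        return out.getvalue()

    header_len = 58
    text = render(kw)
    data_begin = header_len + len(text)
    data_end = data_begin + len(data) - 1
    kw["$BEGINDATA"] = str(data_begin).zfill(12)
    kw["$ENDDATA"] = str(data_end).zfill(12)
    text = render(kw)
    assert header_len + len(text) == data_begin

    text_begin = header_len
    text_end = text_begin + len(text) - 1
    header = "FCS3.1    "
    header += f"{text_begin:>8d}{text_end:>8d}"
    if data_end <= 99_999_999:
        header += f"{data_begin:>8d}{data_end:>8d}"
    else:  # large files defer to $BEGINDATA/$ENDDATA
        header += f"{0:>8d}{0:>8d}"
    header += f"{0:>8d}{0:>8d}"

    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("latin-1"))
        fh.write(data)


# ---------------------------------------------------------------------------
# Spillover CSV

def read_spillover_csv(path) -> SpilloverMatrix:
    """CSV with channel labels in the first row and first column."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != labels:
        raise SchemaError("spillover CSV row labels must match column labels")
    S = df.to_numpy(dtype=float)
    np.fill_diagonal(S, 1.0)  # unit diagonal enforced on load
    return SpilloverMatrix(labels, S)


# ---------------------------------------------------------------------------
# Compensation

def _check_invertible(S: np.ndarray):
    if not np.all(np.isfinite(S)):
        raise NumericalError("spillover matrix not finite")
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError("spillover matrix is singular or near-singular")


def compensate(matrix: EventMatrix, spill: SpilloverMatrix) -> EventMatrix:
    """Return a compensated copy: selected columns become ``X @ inv(S)``."""
    missing = [l for l in spill.labels if l not in matrix.channel_names]
    if missing:
        raise SchemaError(f"spillover labels not in matrix: {missing}")
    _check_invertible(spill.S)
    out = matrix.copy()
    idx = [matrix.column_index(l) for l in spill.labels]
    out.values[:, idx] = np.linalg.solve(spill.S.T, out.values[:, idx].T).T
    return out


def decompensate(matrix: EventMatrix, spill: SpilloverMatrix) -> EventMatrix:
    """Inverse of :func:`compensate` (multiply the columns back by ``S``)."""
    missing = [l for l in spill.labels if l not in matrix.channel_names]
    if missing:
        raise SchemaError(f"spillover labels not in matrix: {missing}")
    out = matrix.copy()
    idx = [matrix.column_index(l) for l in spill.labels]
    out.values[:, idx] = out.values[:, idx] @ spill.S
    return out
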