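"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Flow Cytometry Standard files are a fixed-layout container: an ASCII header
with segment offsets, a delimited TEXT segment of ``$KEY`` / value pairs, and
a binary DATA segment holding the event table.  Reading supports list-mode
(``$MODE L``) data of type ``F`` (float32), ``D`` (float64) and ``I``
(unsigned integer, uniform bit width), in either byte order, which covers
files produced by Helios-class mass cytometers and common exporters.
Writing always produces FCS 3.1, single dataset, little-endian float32
(``$DATATYPE F``) — the layout downstream cytometry tools expect.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Mapping

import numpy as np

from .data import (
    ChannelMap,
    ConfigurationError,
    DataError,
    ExpressionMatrix,
    Stage,
)

__all__ = ["read_fcs", "read_fcs_raw", "write_fcs"]

_DELIM = "/"


class FCSFormatError(IOError):
    """File is not a parsable FCS 3.0/3.1 dataset."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = chr(raw[0])
    body = raw.decode("utf-8", errors="replace")
    # Strip leading delimiter; a trailing delimiter terminates the last value.
    parts = body[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    kw: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        kw[key.strip().upper()] = value.strip()
    return kw


def read_fcs_raw(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file into ``(events, channel_names, keywords)``.

    Channel names come from ``$PnN``; ``$PnS`` (stain name) is used when the
    short name is missing or empty.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58:
            raise FCSFormatError(f"{path}: truncated header")
        version = header[:6].decode("ascii", errors="replace")
        if not version.startswith("FCS3"):
            raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

        def _offset(a: int, b: int) -> int:
            text = header[a:b].decode("ascii", errors="replace").strip()
            return int(text) if text else 0

        text_start, text_end = _offset(10, 18), _offset(18, 26)
        data_start, data_end = _offset(26, 34), _offset(34, 42)

        fh.seek(text_start)
        kw = _parse_text_segment(fh.read(text_end - text_start + 1))

        if data_start == 0 or data_end == 0:
            data_start = int(kw.get("$BEGINDATA", "0"))
            data_end = int(kw.get("$ENDDATA", "0"))
        if data_start <= 0 or data_end <= 0:
            raise FCSFormatError(f"{path}: cannot locate DATA segment")

        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw.get("$DATATYPE", "F").upper()
        mode = kw.get("$MODE", "L").upper()
        if mode != "L":
            raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported")
        byteord = kw.get("$BYTEORD", "1,2,3,4")
        little = byteord.startswith("1")
        order = "<" if little else ">"

        bits = [int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)]
        if len(set(bits)) != 1:
            raise FCSFormatError(f"{path}: mixed $PnB widths are not supported")
        nbytes = bits[0] // 8
        if datatype == "F":
            dtype = np.dtype(f"{order}f4")
        elif datatype == "D":
            dtype = np.dtype(f"{order}f8")
        elif datatype == "I":
            dtype = np.dtype(f"{order}u{nbytes}")
        else:
            raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")
        if dtype.itemsize != nbytes:
            raise FCSFormatError(f"{path}: $PnB={bits[0]} inconsistent with $DATATYPE")

        fh.seek(data_start)
        buf = fh.read(n_tot * n_par * nbytes)
        if len(buf) < n_tot * n_par * nbytes:
            raise FCSFormatError(f"{path}: DATA segment shorter than $TOT*$PAR events")
        events = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", "") or kw.get(f"$P{i}S", "") or f"P{i}"
        names.append(name)
    return events, names, kw


def read_fcs(path, channel_map: ChannelMap, stage: Stage = Stage.RAW) -> ExpressionMatrix:
    """Read an FCS file and bind channels to pipeline roles.

    Returns a matrix containing exactly the channels the map assigns to the
    volume, cell-cycle and functional roles, in the map's deterministic
    column order (volume, then IdU/cyclinB1/pHH3/pRB, then functional),
    regardless of the channel order in the file.  Excluded channels are
    dropped.  A mapped channel missing from the file raises
    :class:`~cytocycle.data.ConfigurationError` naming the channel.
    """
    events, names, _ = read_fcs_raw(path)
    index = {name: i for i, name in enumerate(names)}
    wanted = channel_map.pipeline_channels
    missing = [c for c in wanted if c not in index]
    if missing:
        raise ConfigurationError(
            f"channels {missing} named in the channel map are absent from {path}"
        )
    cols = [index[c] for c in wanted]
    values = events[:, cols]
    if stage is Stage.RAW:
        # float32 round trips can leave -0.0; raw counts are non-negative.
        values = np.maximum(values, 0.0)
    cell_ids = None
    if "cell_id" in index:
        cell_ids = events[:, index["cell_id"]].round().astype(np.int64)
    return ExpressionMatrix(values, wanted, stage, cell_ids)


def write_fcs(
    matrix: ExpressionMatrix,
    path,
    extra_columns: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write an :class:`ExpressionMatrix` as a single-dataset FCS 3.1 file.

    One FCS parameter per matrix column plus one per extra column (e.g. a
    phase label encoded 1-4 or a pseudotime value); the cell ids are always
    written as a ``cell_id`` parameter so exports can be joined back to any
    other stage.  Values are stored as little-endian float32.
    """
    if matrix.n_cells < 1:
        raise DataError("cannot write an empty matrix")
    path = Path(path)
    extra = dict(extra_columns or {})
    if "cell_id" not in extra:
        extra["cell_id"] = matrix.cell_ids
    names = list(matrix.channels) + list(extra)
    columns = [matrix.values[:, j] for j in range(matrix.n_channels)]
    for key, col in extra.items():
        col = np.asarray(col, dtype=float)
        if col.shape != (matrix.n_cells,):
            raise DataError(f"extra column {key!r} must have one value per cell")
        columns.append(col)
    data = np.column_stack(columns).astype("<f4")
    n, m = data.shape

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n),
        "$PAR": str(m),
        "CYTOCYCLE_STAGE": matrix.stage.value,
    }
    for i, name in enumerate(names, start=1):
        if _DELIM in name:
            raise ConfigurationError(
                f"channel name {name!r} contains the TEXT delimiter {_DELIM!r}"
            )
        finite = data[:, i - 1][np.isfinite(data[:, i - 1])]
        rng = float(finite.max()) if finite.size else 0.0
        kw[f"$P{i}N"] = name
        kw[f"$P{i}S"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(max(rng, 1.0))) + 1)

    # Fixed-width data offsets so the TEXT length is known before writing.
    begin_key, end_key = "$BEGINDATA", "$ENDDATA"
    placeholder = "0" * 12

    def render_text(begin: str, end: str) -> bytes:
        items = {begin_key: begin, end_key: end, **kw}
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in items.items()) + _DELIM
        return body.encode("ascii")

    header_len = 58
    text = render_text(placeholder, placeholder)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    text = render_text(str(data_start).rjust(12, "0"), str(data_end).rjust(12, "0"))

    def fmt(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry the offset
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_start) + fmt(text_end)
    header += fmt(data_start if data_end <= 99_999_999 else 0)
    header += fmt(data_end if data_end <= 99_999_999 else 0)
    header += fmt(0) + fmt(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path
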