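"""Event-level list-mode I/O.

Two dialects are supported:

* ``fcs`` — FCS 3.0/3.1 list-mode files (HEADER + TEXT + DATA segments;
  ``$PnN``/``$PnB``/``$PnE``/``$PnR`` keywords honored).  Log-amplified
  channels (``$PnE`` with a positive first field) are decoded to a linear
  relative-fluorescence scale at read time; files written by this module
  always store linear values with linear-gain keywords (``$PnE`` = ``0,0``).
* ``table`` — a plain CSV with the fixed header ``FSC,SSC,FL1,FL2,FL4`` and
  one row per event, values already linear.  Acquisition metadata travels in
  an optional JSON sidecar (``<path>.meta.json``).

The canonical in-memory scale is linear relative fluorescence: geometric
means and the MESF regression downstream are defined on linear intensities,
so decoding happens exactly once, here.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelMappingError, FormatError

#: Canonical channel names (FACSCalibur-class instrument, 5 parameters).
CHANNELS = ("FSC", "SSC", "FL1", "FL2", "FL4")

#: Default mapping from on-disk detector names to canonical names.  FCS
#: channel naming varies by instrument/software; extend via the
#: ``channel_map`` argument of :func:`read_events` rather than editing this.
DEFAULT_CHANNEL_MAP = {
    "FSC": "FSC", "FSC-H": "FSC", "FSC-A": "FSC",
    "SSC": "SSC", "SSC-H": "SSC", "SSC-A": "SSC",
    "FL1": "FL1", "FL1-H": "FL1", "FL1-A": "FL1", "FITC": "FL1",
    "FL2": "FL2", "FL2-H": "FL2", "FL2-A": "FL2", "PE": "FL2",
    "FL4": "FL4", "FL4-H": "FL4", "FL4-A": "FL4", "APC": "FL4",
}


@dataclass(frozen=True)
class ChannelSpec:
    """Amplifier descriptor for one stored channel.

    ``decades`` and ``max_channel`` describe the log amplifier the values
    were digitized under; ``linear`` means the stored values already are
    linear relative fluorescence and pass through undecoded.
    """

    decades: float = 0.0
    max_channel: int = 1024
    linear: bool = True


@dataclass
class EventTable:
    """Per-event channel intensities plus acquisition metadata.

    ``events`` holds one row per event and one named column per channel,
    on a linear relative-fluorescence scale (dimensionless).  ``meta``
    carries acquisition metadata (sample id, conjugate id, lot,
    concentration, timepoint in months, storage condition, acquisition
    date — free-form keys).  ``channel_spec`` records, per channel, the
    amplifier the values were decoded from.
    """

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)
    channel_spec: dict[str, ChannelSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = self.events.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if len(self.events) < 1:
            raise FormatError("event table must contain at least one event")
        values = self.events.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("event intensities must be finite")
        if (values < 0).any():
            raise FormatError("event intensities must be >= 0 after decoding")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.events.columns)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a float array, or raise naming the channel."""
        if name not in self.events.columns:
            raise ChannelMappingError(
                f"channel mapping error: required channel {name!r} not present "
                f"(have {list(self.events.columns)})"
            )
        return self.events[name].to_numpy(dtype=float)

    def subset(self, index: np.ndarray) -> "EventTable":
        """A new table restricted to the given event indices (metadata kept)."""
        return EventTable(
            events=self.events.iloc[np.asarray(index)].reset_index(drop=True),
            meta=dict(self.meta),
            channel_spec=dict(self.channel_spec),
        )


def decode_log_channel(stored, decades: float, max_channel: int):
    """Decode a log-amplified channel value to linear relative intensity.

    A ``decades``-decade log amplifier digitized over ``max_channel``
    channels maps stored value *x* to ``10**(decades * x / max_channel)``:
    channel 0 is 1.0 relative units and full scale is ``10**decades``.
    Accepts scalars or arrays; strictly monotone in ``stored``.
    """
    if decades <= 0:
        raise ValueError("decades must be > 0 for a log channel")
    x = np.asarray(stored, dtype=float)
    if np.any(x < 0) or np.any(x > max_channel):
        raise ValueError(
            f"stored value outside [0, {max_channel}] for a {decades}-decade amplifier"
        )
    out = np.power(10.0, decades * x / float(max_channel))
    return out if out.ndim else float(out)


def _map_channels(names: list[str], channel_map: dict | None) -> dict[str, str]:
    mapping = dict(DEFAULT_CHANNEL_MAP)
    if channel_map:
        mapping.update(channel_map)
    return {raw: mapping[raw] for raw in names if raw in mapping}


def _require_channels(present, required, where: str) -> None:
    for name in required:
        if name not in present:
            raise ChannelMappingError(
                f"channel mapping error: required channel {name!r} missing in {where} "
                f"(mapped channels: {sorted(present)})"
            )


# ---------------------------------------------------------------------------
# table (CSV) dialect
# ---------------------------------------------------------------------------

def _read_table(path: Path, channel_map, required) -> EventTable:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with location info
        raise FormatError(f"{path}: not parseable as CSV table dialect: {exc}") from exc
    rename = _map_channels(list(frame.columns), channel_map)
    frame = frame.rename(columns=rename)
    _require_channels(set(frame.columns), required, str(path))
    frame = frame[[c for c in CHANNELS if c in frame.columns]]
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise FormatError(f"{path}: non-numeric or missing value at line {bad}")
    meta = {}
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spec = {c: ChannelSpec(linear=True) for c in frame.columns}
    return EventTable(events=frame.astype(float), meta=meta, channel_spec=spec)


def _write_table(table: EventTable, path: Path) -> None:
    table.events.to_csv(path, index=False, float_format="%.10g")
    if table.meta:
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(table.meta, indent=1, default=str)
        )


# ---------------------------------------------------------------------------
# FCS dialect (minimal FCS 3.0/3.1: HEADER + TEXT + DATA, list mode)
# ---------------------------------------------------------------------------

_META_KEYWORD = "CONJUQCMETA"  # acquisition metadata embedded as JSON


def _parse_text_segment(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FormatError(f"empty TEXT segment at byte {offset}")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    if len(parts) % 2:
        raise FormatError(f"odd keyword/value count in TEXT segment at byte {offset}")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def _read_fcs(path: Path, channel_map, required) -> EventTable:
    blob = path.read_bytes()
    if len(blob) < 58 or not blob[:6].decode("latin-1").startswith("FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file (bad header at byte 0)")

    def _offset(a: int, b: int) -> int:
        txt = blob[a:b].decode("latin-1").strip()
        try:
            return int(txt) if txt else 0
        except ValueError as exc:
            raise FormatError(f"{path}: bad segment offset at byte {a}") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_start:text_end + 1], text_start)
    if not data_start:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if text.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list mode ($MODE L) is supported")

    names, specs = [], {}
    data = blob[data_start:data_end + 1]
    widths = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N", f"P{i}")
        bits = widths[i - 1]
        rng = int(float(text.get(f"$P{i}R", 1024)))
        amp = text.get(f"$P{i}E", "0,0").split(",")
        decades = float(amp[0])
        if datatype == "F":
            fmt, size = "f", 4
        elif datatype == "D":
            fmt, size = "d", 8
        elif datatype == "I":
            fmt = {16: "H", 32: "I"}.get(bits)
            size = bits // 8
            if fmt is None:
                raise FormatError(f"{path}: unsupported $P{i}B={bits} for $DATATYPE I")
        else:
            raise FormatError(f"{path}: unsupported $DATATYPE {datatype}")
        names.append(name)
        specs[name] = (decades, rng, size, fmt)
    row_size = sum(specs[n][2] for n in names)
    expected = row_size * n_tot
    if len(data) < expected:
        raise FormatError(
            f"{path}: DATA segment truncated at byte {data_start + len(data)} "
            f"(expected {expected} bytes)"
        )
    fmt_row = endian + "".join(specs[n][3] for n in names)
    raw = np.array(
        list(struct.iter_unpack(fmt_row, data[:expected])), dtype=float
    )

    rename = _map_channels(names, channel_map)
    out, out_spec = {}, {}
    for j, name in enumerate(names):
        canon = rename.get(name)
        if canon is None:
            continue
        decades, rng, _, _ = specs[name]
        col = raw[:, j]
        if decades > 0:
            col = decode_log_channel(np.clip(col, 0, rng), decades, rng)
            out_spec[canon] = ChannelSpec(decades=decades, max_channel=rng, linear=False)
        else:
            out_spec[canon] = ChannelSpec(max_channel=rng, linear=True)
        out[canon] = col
    _require_channels(set(out), required, str(path))
    frame = pd.DataFrame({c: out[c] for c in CHANNELS if c in out})
    meta = json.loads(text[_META_KEYWORD]) if _META_KEYWORD in text else {}
    return EventTable(events=frame, meta=meta, channel_spec=out_spec)


def _write_fcs(table: EventTable, path: Path) -> None:
    """Write linear float32 list-mode FCS 3.0 ($PnE 0,0 — no log re-encoding)."""
    channels = list(table.events.columns)
    n_par, n_tot = len(channels), table.n_events
    values = table.events.to_numpy(dtype="<f4")

    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channels, start=1):
        top = float(values[:, i - 1].max()) if n_tot else 1.0
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(top)) + 1)
    if table.meta:
        kw[_META_KEYWORD] = json.dumps(table.meta, default=str)

    delim = "/"
    # Two-pass offset computation: keyword values include $BEGINDATA/$ENDDATA.
    data_bytes = values.tobytes()
    header_len = 58
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data_bytes) - 1
        new = {"$BEGINDATA": str(data_start), "$ENDDATA": str(data_end)}
        if all(kw.get(k) == v for k, v in new.items()):
            break
        kw.update(new)
    header = (
        f"FCS3.0    "
        f"{text_start:>8d}{text_end:>8d}{data_start:>8d}{data_end:>8d}"
        f"{0:>8d}{0:>8d}"
    )
    assert len(header) == 58
    path.write_bytes(header.encode("latin-1") + text.encode("latin-1") + data_bytes)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_events(
    path,
    dialect: str | None = None,
    channel_map: dict | None = None,
    required_channels=CHANNELS,
) -> EventTable:
    """Read list-mode events from ``path`` and decode to the linear scale.

    ``dialect`` is ``"fcs"`` or ``"table"``; when omitted it is inferred
    from the file suffix (``.fcs`` vs anything else).  ``channel_map``
    extends the default instrument-name mapping (e.g. ``{"FL2-H": "FL2"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "fcs" if path.suffix.lower() == ".fcs" else "table"
    if dialect == "fcs":
        return _read_fcs(path, channel_map, required_channels)
    if dialect == "table":
        return _read_table(path, channel_map, required_channels)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events(table: EventTable, path, dialect: str | None = None) -> None:
    """Write ``table`` so that :func:`read_events` round-trips its matrix."""
    path = Path(path)
    if dialect is None:
        dialect = "fcs" if path.suffix.lower() == ".fcs" else "table"
    if dialect == "fcs":
        _write_fcs(table, path)
    elif dialect == "table":
        _write_table(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
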