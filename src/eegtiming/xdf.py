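"""Minimal XDF (Extensible Data Format) reader and writer.

Implements the subset of XDF 1.0 this package needs: file header, stream
headers/footers with per-stream metadata (name, type, channel count, nominal
rate, channel format), and sample chunks with explicit per-sample timestamps.
Supported channel formats: ``double64``, ``float32`` and ``string`` (marker
streams). Clock-offset chunks are skipped on read (clock synchronization is
assumed to be handled by the acquisition layer); boundary chunks are skipped.

Numeric payloads are written as ``double64`` and timestamps as IEEE doubles,
so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
from xml.etree import ElementTree

import numpy as np

__all__ = ["XdfStream", "read_xdf", "write_xdf"]

_MAGIC = b"XDF:"
_TAG_FILE_HEADER = 1
_TAG_STREAM_HEADER = 2
_TAG_SAMPLES = 3
_TAG_CLOCK_OFFSET = 4
_TAG_BOUNDARY = 5
_TAG_STREAM_FOOTER = 6

_FORMATS = {"double64": "<f8", "float32": "<f4", "int32": "<i4", "int16": "<i2"}


@dataclass
class XdfStream:
    """One stream's payload and metadata as stored in an XDF file."""

    name: str
    stream_type: str
    nominal_rate: float
    channel_format: str
    timestamps: np.ndarray
    data: Union[np.ndarray, list[list[str]]]
    channel_labels: list[str] = field(default_factory=list)
    stream_id: int = 0

    @property
    def channel_count(self) -> int:
        if isinstance(self.data, np.ndarray):
            return self.data.shape[1]
        return len(self.data[0]) if self.data else 1


def _write_varlen(out, length: int) -> None:
    if length < 256:
        out.write(struct.pack("<BB", 1, length))
    elif length < 2**32:
        out.write(struct.pack("<B", 4) + struct.pack("<I", length))
    else:
        out.write(struct.pack("<B", 8) + struct.pack("<Q", length))


def _write_chunk(out, tag: int, content: bytes) -> None:
    _write_varlen(out, len(content) + 2)
    out.write(struct.pack("<H", tag))
    out.write(content)


def _header_xml(stream: XdfStream) -> bytes:
    info = ElementTree.Element("info")
    for key, value in (
        ("name", stream.name),
        ("type", stream.stream_type),
        ("channel_count", str(stream.channel_count)),
        ("nominal_srate", repr(float(stream.nominal_rate))),
        ("channel_format", stream.channel_format),
    ):
        ElementTree.SubElement(info, key).text = value
    if stream.channel_labels:
        channels = ElementTree.SubElement(ElementTree.SubElement(info, "desc"), "channels")
        for label in stream.channel_labels:
            ch = ElementTree.SubElement(channels, "channel")
            ElementTree.SubElement(ch, "label").text = label
    return ElementTree.tostring(info, encoding="utf-8", xml_declaration=True)


def write_xdf(path: Union[str, Path], streams: list[XdfStream]) -> None:
    """Write streams to an XDF file with explicit per-sample timestamps."""
    with open(path, "wb") as out:
        out.write(_MAGIC)
        _write_chunk(
            out,
            _TAG_FILE_HEADER,
            b'<?xml version="1.0"?><info><version>1.0</version></info>',
        )
        for i, stream in enumerate(streams, start=1):
            stream.stream_id = i
            _write_chunk(
                out,
                _TAG_STREAM_HEADER,
                struct.pack("<I", i) + _header_xml(stream),
            )
        for stream in streams:
            _write_chunk(out, _TAG_SAMPLES, _samples_payload(stream))
        for stream in streams:
            footer = (
                "<?xml version=\"1.0\"?><info>"
                f"<first_timestamp>{stream.timestamps[0]!r}</first_timestamp>"
                f"<last_timestamp>{stream.timestamps[-1]!r}</last_timestamp>"
                f"<sample_count>{len(stream.timestamps)}</sample_count>"
                "</info>"
                if len(stream.timestamps)
                else "<?xml version=\"1.0\"?><info><sample_count>0</sample_count></info>"
            )
            _write_chunk(
                out,
                _TAG_STREAM_FOOTER,
                struct.pack("<I", stream.stream_id) + footer.encode(),
            )


def _samples_payload(stream: XdfStream) -> bytes:
    ts = np.asarray(stream.timestamps, dtype=np.float64)
    n = ts.shape[0]
    parts = [struct.pack("<I", stream.stream_id)]
    if n < 256:
        parts.append(struct.pack("<BB", 1, n))
    else:
        parts.append(struct.pack("<B", 4) + struct.pack("<I", n))
    if stream.channel_format == "string":
        for k in range(n):
            parts.append(struct.pack("<B", 8) + struct.pack("<d", ts[k]))
            for value in stream.data[k]:
                raw = value.encode("utf-8")
                if len(raw) < 256:
                    parts.append(struct.pack("<BB", 1, len(raw)))
                else:
                    parts.append(struct.pack("<B", 4) + struct.pack("<I", len(raw)))
                parts.append(raw)
    else:
        dtype = np.dtype(_FORMATS[stream.channel_format])
        values = np.ascontiguousarray(stream.data, dtype=dtype)
        row_bytes = values.shape[1] * dtype.itemsize
        raw = values.tobytes()
        for k in range(n):
            parts.append(struct.pack("<B", 8) + struct.pack("<d", ts[k]))
            parts.append(raw[k * row_bytes : (k + 1) * row_bytes])
    return b"".join(parts)


def _read_varlen(buf: memoryview, pos: int) -> tuple[int, int]:
    nbytes = buf[pos]
    pos += 1
    if nbytes == 1:
        return buf[pos], pos + 1
    if nbytes == 4:
        return struct.unpack_from("<I", buf, pos)[0], pos + 4
    if nbytes == 8:
        return struct.unpack_from("<Q", buf, pos)[0], pos + 8
    raise ValueError(f"format error: bad varlen size {nbytes}")


@dataclass
class _StreamState:
    meta: dict
    labels: list[str]
    timestamps: list[float] = field(default_factory=list)
    numeric: list[np.ndarray] = field(default_factory=list)
    strings: list[list[str]] = field(default_factory=list)
    last_timestamp: float = 0.0


def read_xdf(path: Union[str, Path]) -> list[XdfStream]:
    """Read an XDF file into a list of :class:`XdfStream`.

    Samples written without an explicit timestamp are assigned the previous
    timestamp plus the stream's nominal interval, per the format's deduced
    timestamping rule.
    """
    blob = Path(path).read_bytes()
    if blob[:4] != _MAGIC:
        raise ValueError("format error: not an XDF file (bad magic)")
    buf = memoryview(blob)
    pos = 4
    states: dict[int, _StreamState] = {}
    while pos < len(buf):
        length, pos = _read_varlen(buf, pos)
        tag = struct.unpack_from("<H", buf, pos)[0]
        content_start = pos + 2
        content_end = pos + length
        if tag == _TAG_STREAM_HEADER:
            sid = struct.unpack_from("<I", buf, content_start)[0]
            states[sid] = _parse_header(bytes(buf[content_start + 4 : content_end]))
        elif tag == _TAG_SAMPLES:
            _parse_samples(buf, content_start, content_end, states)
        # file header, clock offsets, boundaries and footers carry no samples
        pos = content_end

    streams = []
    for sid, st in states.items():
        fmt = st.meta["channel_format"]
        if fmt == "string":
            data: Union[np.ndarray, list[list[str]]] = st.strings
        else:
            n_ch = int(st.meta["channel_count"])
            data = (
                np.vstack(st.numeric)
                if st.numeric
                else np.empty((0, n_ch), dtype=np.float64)
            )
        streams.append(
            XdfStream(
                name=st.meta["name"],
                stream_type=st.meta["type"],
                nominal_rate=float(st.meta["nominal_srate"]),
                channel_format=fmt,
                timestamps=np.array(st.timestamps, dtype=np.float64),
                data=data,
                channel_labels=st.labels,
                stream_id=sid,
            )
        )
    return streams


def _parse_header(xml: bytes) -> _StreamState:
    root = ElementTree.fromstring(xml.decode("utf-8"))
    meta = {
        key: (root.findtext(key) or "")
        for key in ("name", "type", "channel_count", "nominal_srate", "channel_format")
    }
    labels = [
        ch.findtext("label") or "" for ch in root.findall("./desc/channels/channel")
    ]
    return _StreamState(meta=meta, labels=labels)


def _parse_samples(
    buf: memoryview, pos: int, end: int, states: dict[int, _StreamState]
) -> None:
    sid = struct.unpack_from("<I", buf, pos)[0]
    pos += 4
    if sid not in states:
        raise ValueError(f"format error: samples for unknown stream {sid}")
    st = states[sid]
    n, pos = _read_varlen(buf, pos)
    fmt = st.meta["channel_format"]
    n_ch = int(st.meta["channel_count"])
    rate = float(st.meta["nominal_srate"])
    dt = 1.0 / rate if rate > 0 else 0.0
    for _ in range(n):
        ts_bytes = buf[pos]
        pos += 1
        if ts_bytes == 8:
            ts = struct.unpack_from("<d", buf, pos)[0]
            pos += 8
        elif ts_bytes == 0:
            ts = st.last_timestamp + dt
        else:
            raise ValueError("format error: bad timestamp size")
        st.last_timestamp = ts
        st.timestamps.append(ts)
        if fmt == "string":
            row = []
            for _ in range(max(n_ch, 1)):
                slen, pos = _read_varlen(buf, pos)
                row.append(bytes(buf[pos : pos + slen]).decode("utf-8"))
                pos += slen
            st.strings.append(row)
        else:
            dtype = np.dtype(_FORMATS[fmt])
            row_bytes = n_ch * dtype.itemsize
            values = np.frombuffer(buf, dtype=dtype, count=n_ch, offset=pos)
            st.numeric.append(values.astype(np.float64))
            pos += row_bytes
    if pos != end:
        raise ValueError("format error: sample chunk size mismatch")
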