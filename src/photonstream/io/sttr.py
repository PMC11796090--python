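"""STTR: the project's open reference container for TTTR streams.

Layout (all integers little-endian):

* 6 magic bytes: ``b"STTR1\\x00"``
* unsigned 64-bit header length ``L``
* ``L`` bytes of UTF-8 JSON holding the header: ``macro_time_resolution``,
  ``micro_time_resolution``, ``n_microtime_channels``, ``source_format``
  and the full ``metadata`` map (key order preserved)
* ``n_events`` fixed 16-byte records:
  u64 macro ticks, u32 micro channel, u16 routing channel,
  u8 event type (0 photon, 1 marker), 1 reserved zero byte.

The record section must be an exact multiple of 16 bytes; anything else
is reported as corruption rather than silently truncated.
"""

from __future__ import annotations

import io
import json
import struct
from os import PathLike

import numpy as np

from ..core import EventStream, HeaderInfo
from ..errors import CorruptionError, FormatError

MAGIC = b"STTR1\x00"

RECORD_DTYPE = np.dtype(
    [
        ("macro", "<u8"),
        ("micro", "<u4"),
        ("channel", "<u2"),
        ("etype", "u1"),
        ("reserved", "u1"),
    ]
)
assert RECORD_DTYPE.itemsize == 16

__all__ = ["write_sttr", "read_sttr", "MAGIC", "RECORD_DTYPE"]


def _header_json(header: HeaderInfo) -> bytes:
    doc = {
        "macro_time_resolution": header.macro_time_resolution,
        "micro_time_resolution": header.micro_time_resolution,
        "n_microtime_channels": header.n_microtime_channels,
        "source_format": header.source_format,
        "metadata": header.metadata,
    }
    return json.dumps(doc, ensure_ascii=False).encode("utf-8")


def write_sttr(stream: EventStream, destination) -> None:
    """Write a stream to ``destination`` (path or binary file object)."""
    if isinstance(destination, (str, PathLike)):
        with open(destination, "wb") as fh:
            write_sttr(stream, fh)
        return
    head = _header_json(stream.header)
    destination.write(MAGIC)
    destination.write(struct.pack("<Q", len(head)))
    destination.write(head)
    rec = np.empty(stream.n_events, dtype=RECORD_DTYPE)
    rec["macro"] = stream.macro_times
    rec["micro"] = stream.micro_times
    rec["channel"] = stream.routing_channels
    rec["etype"] = stream.event_types
    rec["reserved"] = 0
    destination.write(rec.tobytes())


def read_sttr(source) -> EventStream:
    """Read a stream from ``source`` (path, binary file object or bytes)."""
    if isinstance(source, (bytes, bytearray)):
        return read_sttr(io.BytesIO(source))
    if isinstance(source, (str, PathLike)):
        with open(source, "rb") as fh:
            return read_sttr(fh)
    magic = source.read(len(MAGIC))
    if magic != MAGIC:
        raise FormatError(f"not an STTR file (magic {magic!r})")
    raw_len = source.read(8)
    if len(raw_len) != 8:
        raise CorruptionError("truncated STTR header length")
    (head_len,) = struct.unpack("<Q", raw_len)
    head_raw = source.read(head_len)
    if len(head_raw) != head_len:
        raise CorruptionError("truncated STTR header")
    try:
        doc = json.loads(head_raw.decode("utf-8"))
        header = HeaderInfo(
            macro_time_resolution=doc["macro_time_resolution"],
            micro_time_resolution=doc["micro_time_resolution"],
            n_microtime_channels=doc["n_microtime_channels"],
            source_format=doc.get("source_format", "sttr"),
            metadata=dict(doc.get("metadata", {})),
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise FormatError(f"invalid STTR header: {exc}") from exc
    payload = source.read()
    if len(payload) % RECORD_DTYPE.itemsize:
        raise CorruptionError(
            f"record section of {len(payload)} bytes is not a multiple of 16"
        )
    rec = np.frombuffer(payload, dtype=RECORD_DTYPE)
    return EventStream(
        rec["macro"].copy(),
        rec["micro"].copy(),
        rec["channel"].copy(),
        rec["etype"].copy(),
        header,
    )
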