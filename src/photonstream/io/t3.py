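"""Generic, table-driven decoder for vendor T3-style TTTR record blocks.

Vendors pack each event into a fixed-width word: a sync (macro) counter,
a TCSPC (micro) counter, a channel field and a special flag.  Because
the sync counter is narrow it overflows; dedicated overflow records tell
the decoder to advance an epoch so that absolute macro times can be
reconstructed.  Markers (scan geometry) are flagged records whose
channel field carries the marker id.

Rather than hard-coding one vendor, :class:`FormatDialect` describes the
bit layout declaratively; the decoder interprets any dialect table.  One
worked PicoQuant-style 32-bit T3 table ships as
:meth:`FormatDialect.picoquant_t3`; further vendor dialects are sidecar
YAML files, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import yaml

from ..core import EventStream, EventType, HeaderInfo
from ..errors import CorruptionError, ParameterError

__all__ = ["BitField", "FormatDialect", "read_t3_records", "encode_t3_records"]


@dataclass(frozen=True)
class BitField:
    """A contiguous little-endian bit range inside a record word."""

    offset: int
    width: int

    @property
    def mask(self) -> int:
        return ((1 << self.width) - 1) << self.offset

    def extract(self, words: np.ndarray) -> np.ndarray:
        return (words >> np.uint64(self.offset)) & np.uint64((1 << self.width) - 1)

    def insert(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=np.uint64) & np.uint64((1 << self.width) - 1)) << np.uint64(self.offset)


@dataclass
class FormatDialect:
    """Declarative bit layout of one vendor T3 record flavour.

    ``overflow_increment`` macro ticks are added per overflow record; if
    the record's sync field is non-zero it multiplies the increment
    (compressed overflow runs).  A record is an overflow when the
    special flag is set and the channel field equals
    ``overflow_channel``; it is a marker when the special flag is set
    and the channel value lies in ``marker_channels``.
    """

    name: str
    record_width: int
    macro_field: BitField
    micro_field: BitField
    channel_field: BitField
    special_field: BitField
    overflow_increment: int
    overflow_channel: int
    marker_channels: tuple = ()

    def __post_init__(self) -> None:
        fields = [self.macro_field, self.micro_field, self.channel_field, self.special_field]
        used = 0
        for f in fields:
            if f.offset < 0 or f.offset + f.width > self.record_width * 8:
                raise ParameterError("bit field outside record word")
            if used & f.mask:
                raise ParameterError("bit fields overlap")
            used |= f.mask

    # -- one worked vendor example ------------------------------------------

    @classmethod
    def picoquant_t3(cls) -> "FormatDialect":
        """PicoQuant HydraHarp-style 32-bit T3 records.

        nsync in bits 0-9, dtime in bits 10-24, channel in bits 25-30,
        special flag bit 31; overflow channel 63 advances the epoch by
        1024 syncs times the nsync field (0 counts as 1); special
        channels 1-15 are frame/line markers.
        """
        return cls(
            name="picoquant-t3",
            record_width=4,
            macro_field=BitField(0, 10),
            micro_field=BitField(10, 15),
            channel_field=BitField(25, 6),
            special_field=BitField(31, 1),
            overflow_increment=1024,
            overflow_channel=63,
            marker_channels=tuple(range(1, 16)),
        )

    # -- sidecar serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "record_width": self.record_width,
            "fields": {
                "macro": [self.macro_field.offset, self.macro_field.width],
                "micro": [self.micro_field.offset, self.micro_field.width],
                "channel": [self.channel_field.offset, self.channel_field.width],
                "special": [self.special_field.offset, self.special_field.width],
            },
            "overflow": {
                "channel": self.overflow_channel,
                "increment": self.overflow_increment,
            },
            "marker_channels": list(self.marker_channels),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FormatDialect":
        f = doc["fields"]
        return cls(
            name=doc["name"],
            record_width=int(doc["record_width"]),
            macro_field=BitField(*f["macro"]),
            micro_field=BitField(*f["micro"]),
            channel_field=BitField(*f["channel"]),
            special_field=BitField(*f["special"]),
            overflow_increment=int(doc["overflow"]["increment"]),
            overflow_channel=int(doc["overflow"]["channel"]),
            marker_channels=tuple(doc.get("marker_channels", ())),
        )

    def to_yaml(self, destination) -> None:
        with open(destination, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "FormatDialect":
        with open(source) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_WORD_DTYPES = {1: "<u1", 2: "<u2", 4: "<u4", 8: "<u8"}


def _words(raw: bytes, dialect: FormatDialect) -> np.ndarray:
    if len(raw) % dialect.record_width:
        raise CorruptionError(
            f"record block of {len(raw)} bytes is not a multiple of "
            f"{dialect.record_width}"
        )
    dt = _WORD_DTYPES.get(dialect.record_width)
    if dt is None:
        raise ParameterError(f"unsupported record width {dialect.record_width}")
    return np.frombuffer(raw, dtype=dt).astype(np.uint64)


def read_t3_records(source, dialect: FormatDialect, header: HeaderInfo | None = None) -> EventStream:
    """Decode a raw T3 record block into an absolute-time event stream.

    Overflow records are consumed to build the macro epoch; photon and
    marker events come out with absolute, overflow-corrected macro
    ticks.  Marker events carry the marker id as routing channel.
    """
    if isinstance(source, (str, PathLike)):
        with open(source, "rb") as fh:
            raw = fh.read()
    elif isinstance(source, (bytes, bytearray)):
        raw = bytes(source)
    else:
        raw = source.read()
    words = _words(raw, dialect)

    special = dialect.special_field.extract(words).astype(bool)
    channel = dialect.channel_field.extract(words)
    nsync = dialect.macro_field.extract(words)
    micro = dialect.micro_field.extract(words)

    is_overflow = special & (channel == dialect.overflow_channel)
    is_marker = special & np.isin(channel, np.asarray(dialect.marker_channels, dtype=np.uint64))
    is_photon = ~special

    # epoch before each record: cumulative overflow ticks seen so far
    mult = np.where(is_overflow, np.maximum(nsync, 1), 0)
    epoch = np.cumsum(mult) - mult  # exclusive cumsum
    epoch = epoch * np.uint64(dialect.overflow_increment)

    keep = is_photon | is_marker
    macro = (epoch + nsync)[keep]
    if macro.size and np.any(np.diff(macro.astype(np.int64)) < 0):
        raise CorruptionError("decoded macro times decrease; overflow records out of order")
    if header is None:
        n_micro = 1 << dialect.micro_field.width
        header = HeaderInfo(
            macro_time_resolution=1e-8,
            micro_time_resolution=1e-8 / n_micro,
            n_microtime_channels=n_micro,
            source_format=dialect.name,
        )
    return EventStream(
        macro,
        np.where(is_photon, micro, 0)[keep].astype(np.uint32),
        channel[keep].astype(np.uint16),
        np.where(is_photon, EventType.PHOTON, EventType.MARKER)[keep].astype(np.uint8),
        header,
    )


def encode_t3_records(stream: EventStream, dialect: FormatDialect) -> bytes:
    """Inverse of :func:`read_t3_records`; emits overflow records as needed.

    Exists so the decoder can be exercised against synthetic blocks with
    a known event content; it is not a supported interchange format.
    """
    period = 1 << dialect.macro_field.width
    out = []
    epoch = 0  # in overflow units
    special_bit = dialect.special_field.insert(np.array([1]))[0]
    for macro, micro, ch, et in zip(
        stream.macro_times.tolist(),
        stream.micro_times.tolist(),
        stream.routing_channels.tolist(),
        stream.event_types.tolist(),
    ):
        target_epoch = macro // dialect.overflow_increment
        nsync_local = macro % dialect.overflow_increment
        if nsync_local >= period:
            raise ParameterError("overflow_increment exceeds sync counter range")
        if target_epoch > epoch:
            jump = target_epoch - epoch
            unit = (1 << dialect.macro_field.width) - 1
            while jump > 0:
                step = min(jump, unit)
                out.append(
                    int(special_bit)
                    | int(dialect.channel_field.insert(np.array([dialect.overflow_channel]))[0])
                    | int(dialect.macro_field.insert(np.array([step]))[0])
                )
                jump -= step
            epoch = target_epoch
        if et == EventType.MARKER:
            word = (
                int(special_bit)
                | int(dialect.channel_field.insert(np.array([ch]))[0])
                | int(dialect.macro_field.insert(np.array([nsync_local]))[0])
            )
        else:
            if micro >= (1 << dialect.micro_field.width):
                raise ParameterError("micro time exceeds dialect field width")
            word = (
                int(dialect.channel_field.insert(np.array([ch]))[0])
                | int(dialect.micro_field.insert(np.array([micro]))[0])
                | int(dialect.macro_field.insert(np.array([nsync_local]))[0])
            )
        out.append(word)
    dt = np.dtype(_WORD_DTYPES[dialect.record_width])
    return np.asarray(out, dtype=dt).tobytes()
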