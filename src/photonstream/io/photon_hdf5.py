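"""PhotonHDF5 transport: the open HDF5 container used by the smFRET community.

Only the mandatory ``/photon_data`` fields are interpreted:

* ``timestamps`` (+ ``timestamps_specs/timestamps_unit``) -> macro times
* ``detectors`` -> routing channels (0 everywhere when absent)
* ``nanotimes`` (+ ``nanotimes_specs``) -> micro times (0, single TCSPC
  channel, when absent)

Everything else in the file — root attributes, ``/setup``,
measurement-type groups — is preserved verbatim as opaque header
metadata so that converting to another container loses nothing.

The writer emits the same minimal layout.  Marker events, which plain
PhotonHDF5 has no slot for, go to an auxiliary ``/photon_data/event_types``
dataset that the reader honours when present; files written elsewhere
simply have all-photon streams.
"""

from __future__ import annotations

from os import PathLike

import h5py
import numpy as np

from ..core import EventStream, HeaderInfo
from ..errors import FormatError

__all__ = ["read_photon_hdf5", "write_photon_hdf5"]

_META_PREFIX = "photon_hdf5/"


def _scalar(value):
    v = value[()] if isinstance(value, h5py.Dataset) else value
    if isinstance(v, bytes):
        return v.decode("utf-8", "replace")
    if isinstance(v, np.generic):
        return v.item()
    return v


def _collect_metadata(fh: h5py.File) -> dict:
    meta: dict = {}
    for key, val in fh.attrs.items():
        meta[f"{_META_PREFIX}attr/{key}"] = _scalar(val)

    def visit(name, obj):
        if name.startswith("photon_data"):
            return
        if isinstance(obj, h5py.Dataset) and obj.shape == ():
            meta[f"{_META_PREFIX}{name}"] = _scalar(obj)
        for key, val in obj.attrs.items():
            meta[f"{_META_PREFIX}{name}@{key}"] = _scalar(val)

    fh.visititems(visit)
    return meta


def read_photon_hdf5(source) -> EventStream:
    """Load a PhotonHDF5 file into an :class:`EventStream`."""
    with h5py.File(source, "r") as fh:
        if "photon_data" not in fh:
            raise FormatError("no /photon_data group")
        pd = fh["photon_data"]
        if "timestamps" not in pd:
            raise FormatError("/photon_data/timestamps missing")
        macro = np.asarray(pd["timestamps"], dtype=np.uint64)
        unit = float(pd["timestamps_specs"]["timestamps_unit"][()])
        n = len(macro)
        if "detectors" in pd:
            channels = np.asarray(pd["detectors"], dtype=np.uint16)
        else:
            channels = np.zeros(n, dtype=np.uint16)
        if "nanotimes" in pd:
            micro = np.asarray(pd["nanotimes"], dtype=np.uint32)
            specs = pd.get("nanotimes_specs", {})
            tcspc_unit = float(specs["tcspc_unit"][()]) if "tcspc_unit" in specs else unit
            if "tcspc_num_bins" in specs:
                n_bins = int(specs["tcspc_num_bins"][()])
            else:
                n_bins = int(micro.max()) + 1 if n else 1
        else:
            micro = np.zeros(n, dtype=np.uint32)
            tcspc_unit = unit
            n_bins = 1
        if "event_types" in pd:
            etypes = np.asarray(pd["event_types"], dtype=np.uint8)
        else:
            etypes = np.zeros(n, dtype=np.uint8)
        header = HeaderInfo(
            macro_time_resolution=unit,
            micro_time_resolution=tcspc_unit,
            n_microtime_channels=n_bins,
            source_format="photon-hdf5",
            metadata=_collect_metadata(fh),
        )
    return EventStream(macro, micro, channels, etypes, header)


def write_photon_hdf5(stream: EventStream, destination) -> None:
    """Write a stream as a minimal PhotonHDF5 file."""
    if not isinstance(destination, (str, PathLike)):
        raise TypeError("destination must be a path")
    with h5py.File(destination, "w") as fh:
        pd = fh.create_group("photon_data")
        pd.create_dataset("timestamps", data=stream.macro_times.astype(np.int64))
        ts = pd.create_group("timestamps_specs")
        ts.create_dataset("timestamps_unit", data=stream.header.macro_time_resolution)
        pd.create_dataset("detectors", data=stream.routing_channels.astype(np.uint8)
                          if stream.routing_channels.size == 0
                          or stream.routing_channels.max() < 256
                          else stream.routing_channels)
        pd.create_dataset("nanotimes", data=stream.micro_times.astype(np.uint16)
                          if stream.header.n_microtime_channels <= 65536
                          else stream.micro_times)
        ns = pd.create_group("nanotimes_specs")
        ns.create_dataset("tcspc_unit", data=stream.header.micro_time_resolution)
        ns.create_dataset("tcspc_num_bins", data=stream.header.n_microtime_channels)
        if np.any(stream.event_types):
            pd.create_dataset("event_types", data=stream.event_types)
        # round-trip the opaque metadata we collected (or were given)
        for key, val in stream.header.metadata.items():
            if not key.startswith(_META_PREFIX):
                fh.attrs[f"user_{key}"] = val
                continue
            tail = key[len(_META_PREFIX):]
            if tail.startswith("attr/"):
                fh.attrs[tail[len("attr/"):]] = val
            elif "@" in tail:
                path, attr = tail.rsplit("@", 1)
                fh.require_group(path).attrs[attr] = val
            else:
                grp, _, name = tail.rpartition("/")
                parent = fh.require_group(grp) if grp else fh
                parent.create_dataset(name, data=val)
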