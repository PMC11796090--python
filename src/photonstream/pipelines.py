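"""End-to-end analysis pipelines.

Two canonical workflows tie the modules together and back the CLI:

* :func:`smfret_pipeline` — single-molecule FRET: read the stream,
  select single-molecule events by sliding-window burst search, compute
  intensity and lifetime FRET indicators plus BVA per burst, correlate
  the donor/acceptor photon traces, and histogram the indicators.
* :func:`fis_pipeline` — image spectroscopy: group photons into pixels
  via scan markers, build intensity and fast-FLIM images, segment into
  pixel classes, compute the per-pixel phasor, and extract pooled
  decays per class.

Both take a plain parameter dictionary (JSON/YAML friendly) and return
in-memory results; ``run_*_to_files`` variants additionally write the
CSV/TIFF artifacts and archive the fully resolved configuration next to
them so a run can be replayed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .burst import (
    burst_dataframe,
    burst_indicators,
    burst_lifetime,
    burst_search,
    bva,
)
from .core import EventStream
from .correlate import gated_correlate
from .errors import DegenerateInputError
from .imaging import (
    build_image_stack,
    class_decay,
    intensity_image,
    mean_microtime_image,
    phasor_image,
    segment_pixels,
)

__all__ = [
    "SMFRET_DEFAULTS",
    "FIS_DEFAULTS",
    "smfret_pipeline",
    "fis_pipeline",
    "run_smfret_to_files",
    "run_fis_to_files",
]

SMFRET_DEFAULTS = {
    "green_channels": [0],
    "red_channels": [1],
    "window": 500e-6,        # s, burst-search window
    "n_min": 10,             # photons within +-window/2
    "l_min": 30,             # minimum photons per burst
    "b_g": 0.0,              # Hz, green background for corrections
    "b_r": 0.0,
    "alpha": 0.0,            # crosstalk
    "gamma": 1.0,            # detection ratio
    "bva_window": 5,         # photons per BVA window
    "lifetime_t0": 0.0,      # s, micro-time offset
    "hist_bins": 41,
    "correlate": True,
    "n_cascades": 20,
    "n_bins_per_cascade": 16,
}

FIS_DEFAULTS = {
    "frame_marker": 4,
    "line_start": 1,
    "line_stop": 2,
    "n_pixels": 32,
    "channels": None,
    "min_photons": 5,
    "harmonic": 1,
    "tau_ref": None,         # s; None = uncalibrated phasor
    "seg_quantiles": [0.5],
    "decay_bins": None,
}


def _merged(defaults: dict, config: dict | None) -> dict:
    cfg = dict(defaults)
    unknown = set(config or ()) - set(defaults)
    if unknown:
        raise KeyError(f"unknown pipeline parameters: {sorted(unknown)}")
    cfg.update(config or {})
    return cfg


def smfret_pipeline(stream: EventStream, config: dict | None = None) -> dict:
    """Run the full single-molecule FRET analysis on one stream.

    Returns a dict with the resolved ``config``, the burst table
    (``bursts`` as a DataFrame), the donor-acceptor cross-correlation
    (``correlation``), and E histograms.
    """
    cfg = _merged(SMFRET_DEFAULTS, config)
    green, red = cfg["green_channels"], cfg["red_channels"]
    channels = list(green) + list(red)
    bursts = burst_search(stream, channels, cfg["window"], cfg["n_min"], cfg["l_min"])
    T_micro = stream.header.micro_time_span
    for b in bursts:
        burst_indicators(
            b, stream, green, red,
            b_g=cfg["b_g"], b_r=cfg["b_r"], alpha=cfg["alpha"], gamma=cfg["gamma"],
        )
        burst_lifetime(b, stream, green, T=T_micro, t0=cfg["lifetime_t0"])
        bva(b, stream, green, red, n_window=cfg["bva_window"])
    table = burst_dataframe(bursts)

    correlation = None
    if cfg["correlate"]:
        try:
            correlation = gated_correlate(
                stream, green, red,
                n_bins_per_cascade=cfg["n_bins_per_cascade"],
                n_cascades=cfg["n_cascades"],
            )
        except DegenerateInputError:
            correlation = None

    e_hist, e_edges = np.histogram(
        table["E_raw"].dropna(), bins=cfg["hist_bins"], range=(0.0, 1.0)
    )
    return {
        "config": cfg,
        "bursts": bursts,
        "burst_table": table,
        "correlation": correlation,
        "e_histogram": (e_hist, e_edges),
    }


def fis_pipeline(stream: EventStream, config: dict | None = None) -> dict:
    """Run the image-spectroscopy analysis on one marker-bearing stream."""
    cfg = _merged(FIS_DEFAULTS, config)
    stack = build_image_stack(
        stream,
        (cfg["frame_marker"], cfg["line_start"], cfg["line_stop"]),
        cfg["n_pixels"],
        channels=cfg["channels"],
    )
    intensity = intensity_image(stack)
    flim = mean_microtime_image(stack, min_photons=cfg["min_photons"])
    labels = segment_pixels(intensity.astype(float), quantiles=cfg["seg_quantiles"])
    phasor = phasor_image(
        stack, harmonic=cfg["harmonic"], min_photons=cfg["min_photons"]
    )
    decays = {
        int(cid): class_decay(stack, labels, int(cid), n_bins=cfg["decay_bins"])
        for cid in np.unique(labels[labels >= 0])
    }
    return {
        "config": cfg,
        "stack": stack,
        "intensity": intensity,
        "flim": flim,
        "labels": labels,
        "phasor": phasor,
        "class_decays": decays,
    }


def _archive_config(cfg: dict, out_prefix: Path, command: str) -> None:
    doc = {"command": command, "parameters": cfg}
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{out_prefix}.config.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_smfret_to_files(stream: EventStream, out_prefix, config: dict | None = None) -> dict:
    """smFRET pipeline + CSV artifacts (burst table, correlation, E histogram)."""
    out_prefix = Path(out_prefix)
    res = smfret_pipeline(stream, config)
    _archive_config(res["config"], out_prefix, "pipeline-smfret")
    res["burst_table"].to_csv(f"{out_prefix}.bursts.csv", index=False, float_format="%.10g")
    if res["correlation"] is not None:
        df = res["correlation"].to_dataframe()
        df.to_csv(f"{out_prefix}.fcs.csv", index=False, float_format="%.10g")
    hist, edges = res["e_histogram"]
    pd.DataFrame({"E_lo": edges[:-1], "E_hi": edges[1:], "count": hist}).to_csv(
        f"{out_prefix}.e_hist.csv", index=False, float_format="%.10g"
    )
    return res


def run_fis_to_files(stream: EventStream, out_prefix, config: dict | None = None) -> dict:
    """FIS pipeline + TIFF planes (intensity, FLIM, g, s, labels) and decay CSVs."""
    import tifffile

    out_prefix = Path(out_prefix)
    res = fis_pipeline(stream, config)
    _archive_config(res["config"], out_prefix, "pipeline-fis")
    tifffile.imwrite(f"{out_prefix}.intensity.tiff", res["intensity"].astype(np.float32))
    tifffile.imwrite(f"{out_prefix}.flim.tiff", res["flim"].astype(np.float32))
    tifffile.imwrite(f"{out_prefix}.phasor_g.tiff", res["phasor"].g.astype(np.float32))
    tifffile.imwrite(f"{out_prefix}.phasor_s.tiff", res["phasor"].s.astype(np.float32))
    tifffile.imwrite(f"{out_prefix}.labels.tiff", res["labels"].astype(np.int32))
    rows = []
    for cid, decay in sorted(res["class_decays"].items()):
        for lo, hi, c in zip(decay.bin_edges[:-1], decay.bin_edges[1:], decay.counts):
            rows.append((cid, lo, hi, int(c)))
    pd.DataFrame(rows, columns=["class_id", "bin_lo", "bin_hi", "count"]).to_csv(
        f"{out_prefix}.decays.csv", index=False, float_format="%.10g"
    )
    return res
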