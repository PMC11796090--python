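"""photonstream: format-agnostic TTTR photon-stream spectroscopy and imaging.

One event data model — parallel macro-time / micro-time / channel /
event-type arrays — underpins both single-molecule spectroscopy (burst
search, FRET indicators, FCS, PDA, BVA) and laser-scanning image
spectroscopy (pixel binning from scan markers, fast FLIM, phasor, pixel
class decays, ICS).  A seedable simulator generates photon streams with
known ground truth so every algorithm is testable without instrument
data.
"""

from .core import (
    EventStream,
    EventType,
    HeaderInfo,
    IndexSelection,
    intensity_trace,
    merge_streams,
    microtime_gate,
    select_channels,
    select_time_window,
    slice_stream,
)
from .correlate import (
    CorrelationCurve,
    FcsFilterSet,
    compute_fcs_filters,
    correlate_pairs,
    gated_correlate,
    multi_tau,
)
from .burst import (
    Burst,
    PdaModel,
    PdaTable,
    burst_dataframe,
    burst_histogram,
    burst_indicators,
    burst_lifetime,
    burst_search,
    bva,
    lifetime_from_microtimes,
    pda_chi2,
    pda_forward,
    select_bursts,
)
from .imaging import (
    CLSMImageStack,
    DecayHistogram,
    PhasorImage,
    build_image_stack,
    class_decay,
    ics_autocorrelation,
    intensity_image,
    mean_microtime_image,
    phasor_image,
    phasor_reference_point,
    phasor_transform,
    segment_pixels,
)
from .simulate import (
    SimGroundTruth,
    default_header,
    simulate_background,
    simulate_bursts,
    simulate_clsm_scan,
)
from . import errors, io

__version__ = "0.1.0"
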