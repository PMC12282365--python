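"""Band-pass filtering and window segmentation of electrograms.

Unipolar EGMs are band-passed 0.5-20 Hz and bipolar EGMs 0.5-40 Hz before
feature extraction.  Filtering is zero-phase (forward-backward 4th-order
Butterworth) so activation/repolarization timings are not delayed; the
acquisition bandwidths of the mapping system are treated as metadata and not
re-applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core_model import Channel, EGMTrace

__all__ = ["FilterSpec", "UNIPOLAR_FILTER", "BIPOLAR_FILTER",
           "bandpass", "bandpass_for", "segment"]


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"filter band ({self.low_hz}, {self.high_hz}) Hz invalid for fs={fs}"
            )


UNIPOLAR_FILTER = FilterSpec(0.5, 20.0)
BIPOLAR_FILTER = FilterSpec(0.5, 40.0)


def bandpass(trace: EGMTrace, spec: FilterSpec) -> EGMTrace:
    """Zero-phase band-pass; same length, windows preserved.

    Uses reflect padding of one filter-impulse length at both ends to avoid
    edge transients leaking into the post-QRS window.
    """
    spec.validate(trace.fs)
    n = trace.n_samples
    if n <= 3 * spec.order:
        raise ValueError(f"trace length {n} too short for order-{spec.order} filter")
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=trace.fs, output="sos")
    if spec.zero_phase:
        padlen = min(n - 1, max(3 * spec.order * 2, int(trace.fs)))
        y = signal.sosfiltfilt(sos, trace.samples, padtype="even", padlen=padlen)
    else:
        y = signal.sosfilt(sos, trace.samples)
    return replace(trace, samples=y)


def bandpass_for(trace: EGMTrace) -> EGMTrace:
    """Apply the channel's default analysis band."""
    spec = UNIPOLAR_FILTER if trace.kind is Channel.UNIPOLAR else BIPOLAR_FILTER
    return bandpass(trace, spec)


def segment(trace: EGMTrace) -> dict[str, tuple[int, int]]:
    """Split a trace into its QRS and post-QRS windows (half-open index pairs).

    The QRS window is [qrs_on, qrs_end).  The post window is the T-wave window
    [qrs_end, t_end) for unipolar traces and [qrs_end, n) for bipolar traces
    (late/fractionated activity can extend to the end of the recording).
    """
    if trace.qrs_end <= trace.qrs_on:
        raise ValueError("empty QRS window")
    post_end = trace.t_end if trace.kind is Channel.UNIPOLAR else trace.n_samples
    if post_end <= trace.qrs_end:
        raise ValueError("empty post-QRS window")
    return {"QRS": (trace.qrs_on, trace.qrs_end), "post": (trace.qrs_end, post_end)}
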