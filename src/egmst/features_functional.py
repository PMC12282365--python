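"""Functional-domain per-point features.

Covers activation/repolarization annotations (LAT, RT, ARI), EGM duration,
peak-to-peak amplitudes, deflection counts, and signal change rates, each
computed inside the QRS or post-QRS analysis window.

Conventions (documented package choices where the operational definition is
not standardized):
  * a "deflection" is a local extremum whose prominence exceeds 20% of the
    window's peak-to-peak amplitude;
  * EGM duration thresholds the rectified signal (smoothed with a 10-ms
    moving average) at 20% of its window maximum;
  * derivatives are central finite differences, one-sided at the ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_model import EGMTrace
from .preprocessing import segment

__all__ = [
    "DEFLECTION_FRACTION",
    "DURATION_FRACTION",
    "DURATION_SMOOTH_MS",
    "detect_lat",
    "detect_rt",
    "compute_ari",
    "egm_duration",
    "amplitude",
    "count_deflections",
    "slope_stats",
    "functional_features",
]

#: Deflections must exceed this fraction of the window peak-to-peak amplitude.
DEFLECTION_FRACTION = 0.2
#: Duration threshold as a fraction of the window's max rectified amplitude.
DURATION_FRACTION = 0.2
#: Moving-average length applied to the rectified signal before thresholding.
DURATION_SMOOTH_MS = 10.0


def _window_slice(trace: EGMTrace, window: str | tuple[int, int]) -> tuple[int, int]:
    if isinstance(window, str):
        return segment(trace)[window]
    return window


def _extrema(x: np.ndarray, prominence: float) -> np.ndarray:
    """Indices of local maxima and minima with at least the given prominence."""
    hi, _ = sps.find_peaks(x, prominence=prominence)
    lo, _ = sps.find_peaks(-x, prominence=prominence)
    return np.sort(np.concatenate([hi, lo]))


def detect_lat(bip_trace: EGMTrace) -> float | None:
    """Local activation time (ms): latest qualifying deflection in the QRS window.

    A deflection qualifies when its absolute value exceeds 20% of the QRS
    window's peak-to-peak amplitude.  Returns None when no deflection
    qualifies (e.g. a flat signal).
    """
    a, b = _window_slice(bip_trace, "QRS")
    x = bip_trace.samples[a:b]
    p2p = float(np.ptp(x))
    if p2p <= 0:
        return None
    idx = _extrema(x, prominence=1e-12)
    idx = idx[np.abs(x[idx]) > DEFLECTION_FRACTION * p2p]
    if idx.size == 0:
        # extremum may sit on the window edge; fall back to the largest sample
        k = int(np.argmax(np.abs(x)))
        if np.abs(x[k]) <= DEFLECTION_FRACTION * p2p:
            return None
        return bip_trace.ms_of(a + k)
    return bip_trace.ms_of(a + int(idx[-1]))


def detect_rt(uni_trace: EGMTrace) -> float | None:
    """Repolarization time (ms): max dV/dt of the unipolar T-wave window."""
    a, b = _window_slice(uni_trace, "post")
    if b - a < 2:
        return None
    x = uni_trace.samples[a:b]
    dv = np.gradient(x)  # per-sample; argmax is scale-invariant
    return uni_trace.ms_of(a + int(np.argmax(dv)))


def compute_ari(rt_ms: float | None, lat_ms: float | None) -> float | None:
    """Activation recovery interval: ARI = RT - LAT (ms); None if either missing.

    A negative value (RT earlier than LAT) is retained — it flags an
    implausible annotation rather than being silently dropped.
    """
    if rt_ms is None or lat_ms is None:
        return None
    return rt_ms - lat_ms


def egm_duration(trace: EGMTrace, window: str | tuple[int, int]) -> float:
    """EGM duration (ms): first-to-last threshold crossing of the rectified signal."""
    a, b = _window_slice(trace, window)
    x = np.abs(trace.samples[a:b])
    k = max(1, int(round(DURATION_SMOOTH_MS * trace.fs / 1000.0)))
    if k > 1:
        x = np.convolve(x, np.ones(k) / k, mode="same")
    mx = float(np.max(x)) if x.size else 0.0
    if mx <= 0:
        return 0.0
    above = np.nonzero(x >= DURATION_FRACTION * mx)[0]
    return trace.ms_of(int(above[-1]) - int(above[0]))


def amplitude(trace: EGMTrace, window: str | tuple[int, int]) -> float:
    """Peak-to-peak amplitude (mV) within the window."""
    a, b = _window_slice(trace, window)
    return float(np.ptp(trace.samples[a:b]))


def count_deflections(trace: EGMTrace, window: str | tuple[int, int]) -> int:
    """Number of negative deflections deeper than 20% of the window amplitude.

    Depth is measured as peak prominence of the inverted signal, i.e. relative
    to the adjacent local maxima, making the count scale-invariant.
    """
    a, b = _window_slice(trace, window)
    x = trace.samples[a:b]
    p2p = float(np.ptp(x))
    if p2p <= 0:
        return 0
    lo, _ = sps.find_peaks(-x, prominence=DEFLECTION_FRACTION * p2p)
    return int(lo.size)


def slope_stats(trace: EGMTrace, window: str | tuple[int, int]) -> tuple[float, float]:
    """(max, mean) of |dV/dt| in mV/ms within the window."""
    a, b = _window_slice(trace, window)
    x = trace.samples[a:b]
    if x.size < 2:
        return 0.0, 0.0
    dv = np.abs(np.gradient(x)) * trace.fs / 1000.0
    return float(np.max(dv)), float(np.mean(dv))


@dataclass
class FunctionalFeatures:
    """Per-point functional feature values keyed by registry names."""

    values: dict[str, float | None]


def functional_features(uni: EGMTrace, bip: EGMTrace) -> dict[str, float | None]:
    """All functional-domain registry features for one mapping point.

    Durations: bipolar duration spans the whole trace (captures late
    components); unipolar duration is the QRS (ventricular activation)
    duration, mirroring how the yellow duration markers differ per channel
    on clinical displays.
    """
    lat = detect_lat(bip)
    rt = detect_rt(uni)
    ari = compute_ari(rt, lat)
    b_qrs = segment(bip)["QRS"]
    b_post = segment(bip)["post"]
    u_qrs = segment(uni)["QRS"]
    u_post = segment(uni)["post"]

    max_bq, mean_bq = slope_stats(bip, b_qrs)
    max_bp, mean_bp = slope_stats(bip, b_post)
    max_uq, mean_uq = slope_stats(uni, u_qrs)
    max_ut, mean_ut = slope_stats(uni, u_post)

    return {
        "LAT_B": lat,
        "RT": rt,
        "ARI_B": ari,
        "D_B": egm_duration(bip, (bip.qrs_on, bip.n_samples)),
        "D_U": egm_duration(uni, u_qrs),
        "A_B": amplitude(bip, b_qrs),
        "A_Bp": amplitude(bip, b_post),
        "A_U": amplitude(uni, u_qrs),
        "A_UT": amplitude(uni, u_post),
        "Def_B": float(count_deflections(bip, b_qrs)),
        "Def_U": float(count_deflections(uni, u_qrs)),
        "max_dBQRSdt": max_bq,
        "mean_dBQRSdt": mean_bq,
        "max_dBpdt": max_bp,
        "mean_dBpdt": mean_bp,
        "max_dUQRSdt": max_uq,
        "mean_dUQRSdt": mean_uq,
        "max_dUTdt": max_ut,
        "mean_dUTdt": mean_ut,
    }
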