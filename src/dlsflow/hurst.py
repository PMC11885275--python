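"""Hurst-exponent analysis of blood-flow signals.

The flow signal is decomposed into a pulsatile AC component and a
non-pulsatile DC component with complementary second-order Butterworth
filters at 0.5 Hz, and the Hurst exponent of the full, AC, and DC signals is
estimated in 180-s moving windows with 90-s steps by first-order detrended
fluctuation analysis (DFA).

The input is treated as noise-like: DFA integrates the mean-centred segment
before detrending, so serially uncorrelated samples give H = 0.5, persistent
fluctuations H > 0.5, and anti-persistent fluctuations H < 0.5.  Estimates
above 1 indicate smooth, drift-dominated (fBm-like) flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import BloodFlowSeries, HurstSeries

AC_DC_CUTOFF_HZ = 0.5
AC_DC_ORDER = 2

#: Estimates outside this open interval are reported as missing.
HURST_VALID_RANGE = (0.0, 2.5)


@dataclass
class ACDCDecomposition:
    """Pulsatile (AC, > cutoff) and non-pulsatile (DC, < cutoff) components."""

    ac: BloodFlowSeries
    dc: BloodFlowSeries
    cutoff: float = AC_DC_CUTOFF_HZ
    filter_order: int = AC_DC_ORDER


def split_ac_dc(flow: BloodFlowSeries, cutoff: float = AC_DC_CUTOFF_HZ,
                order: int = AC_DC_ORDER) -> ACDCDecomposition:
    """Split a flow series into AC and DC components.

    Complementary high-pass/low-pass Butterworth filters of the given order
    are applied forward-backward (zero phase).

    Parameters
    ----------
    flow
        Input flow series; ``flow.fs`` must exceed ``2 * cutoff``.
    cutoff
        Filter cutoff in Hz (default 0.5 Hz, the pulse-rate floor).
    order
        Butterworth order of each one-way filter (default 2).
    """
    if flow.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {flow.fs} Hz cannot resolve a {cutoff} Hz cutoff"
        )
    sos_hp = sps.butter(order, cutoff, btype="highpass", fs=flow.fs, output="sos")
    sos_lp = sps.butter(order, cutoff, btype="lowpass", fs=flow.fs, output="sos")
    ac = sps.sosfiltfilt(sos_hp, flow.samples)
    dc = sps.sosfiltfilt(sos_lp, flow.samples)
    mk = lambda x: BloodFlowSeries(x, flow.fs, flow.start_time, flow.site,
                                   "raw_flow", dict(flow.meta))
    return ACDCDecomposition(mk(ac), mk(dc), cutoff, order)


def _dfa_scales(n: int, min_scale: int = 16, factor: float = np.sqrt(2.0)) -> np.ndarray:
    """Log-spaced box sizes from ``min_scale`` to ``n // 4`` (factor ~ sqrt 2)."""
    max_scale = n // 4
    if max_scale < min_scale:
        return np.array([], dtype=int)
    scales = [float(min_scale)]
    while scales[-1] * factor <= max_scale:
        scales.append(scales[-1] * factor)
    return np.unique(np.round(scales).astype(int))


def _fluctuation(profile: np.ndarray, scale: int) -> float:
    """RMS of linearly detrended profile in non-overlapping boxes.

    Boxes are taken from both the start and the end of the profile so the
    tail of a segment that is not a multiple of the box size still counts.
    """
    n = profile.size
    m = n // scale
    segs = np.concatenate([
        profile[: m * scale].reshape(m, scale),
        profile[n - m * scale:].reshape(m, scale),
    ])
    t = np.arange(scale, dtype=float)
    design = np.column_stack([np.ones(scale), t])
    coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
    resid = segs.T - design @ coef
    return float(np.sqrt(np.mean(resid ** 2)))


def estimate_hurst(segment, min_scale: int = 16) -> float:
    """Hurst exponent of a noise-like segment by first-order DFA.

    The mean-centred segment is cumulatively summed, the integrated profile
    is linearly detrended in log-spaced boxes from ``min_scale`` samples to a
    quarter of the segment length, and the exponent is the least-squares
    slope of log RMS fluctuation against log box size.  The default minimum
    box size of 16 samples avoids the well-known small-box bias of
    first-order DFA (linear detrending absorbs too much fluctuation in very
    short boxes, flattening the scaling curve below ~16 samples).

    Parameters
    ----------
    segment
        1-D array-like or :class:`BloodFlowSeries` of at least 512 samples.

    Returns
    -------
    float
        The estimate, or NaN when fewer than four usable box sizes exist,
        when the segment is constant, or when the estimate falls outside
        the plausible range ``(0, 2.5)``.
    """
    x = segment.samples if isinstance(segment, BloodFlowSeries) else np.asarray(segment, float)
    if x.size < 512:
        raise ValueError(f"segment too short for DFA ({x.size} < 512 samples)")
    scales = _dfa_scales(x.size, min_scale=min_scale)
    if scales.size < 4:
        return float("nan")
    profile = np.cumsum(x - x.mean())
    fluct = np.array([_fluctuation(profile, s) for s in scales])
    usable = fluct > 0
    if usable.sum() < 4:
        return float("nan")
    slope = np.polyfit(np.log(scales[usable]), np.log(fluct[usable]), 1)[0]
    lo, hi = HURST_VALID_RANGE
    return float(slope) if lo < slope < hi else float("nan")


def windowed_hurst(flow: BloodFlowSeries, component: str = "full",
                   window_s: float = 180.0, step_s: float = 90.0) -> HurstSeries:
    """Hurst estimate per moving window (default 180-s window, 90-s step).

    ``component`` selects the full signal or its AC/DC part (obtained via
    :func:`split_ac_dc` on the whole series before windowing).  Windows start
    at 0, ``step_s``, 2 * ``step_s``, ... while they fit inside the series.
    """
    if component not in ("full", "ac", "dc"):
        raise ValueError(f"unknown component {component!r}")
    span = flow.duration
    if span < window_s:
        warnings.warn(
            f"series spans {span:.1f} s < window {window_s:.1f} s; no windows",
            stacklevel=2,
        )
        return HurstSeries(np.array([]), np.array([]), component, window_s, step_s)
    if component == "full":
        x = flow
    else:
        dec = split_ac_dc(flow)
        x = dec.ac if component == "ac" else dec.dc
    wlen = int(round(window_s * flow.fs))
    step = int(round(step_s * flow.fs))
    starts, ests = [], []
    i = 0
    while i + wlen <= x.samples.size:
        seg = x.samples[i:i + wlen]
        starts.append(flow.start_time + i / flow.fs)
        ests.append(estimate_hurst(seg))
        i += step
    return HurstSeries(np.array(starts), np.array(ests), component, window_s, step_s)
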