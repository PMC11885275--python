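"""Heart-rate variability from the pulsatile blood-flow component.

The pulse wave is isolated with a zero-phase second-order Butterworth
high-pass at 0.5 Hz, beats are picked as local maxima with an adaptive
amplitude threshold and a refractory interval, and the normalized LF and HF
components are the fractions of inter-beat-interval (tachogram) spectral
power in 0.04-0.15 Hz and 0.15-0.40 Hz relative to the full HRV band
0.005-0.400 Hz.  LF mixes sympathetic and parasympathetic drive; HF is a
parasympathetic proxy; both are unitless with LF + HF <= 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import interpolate, ndimage
from scipy import signal as sps

from .hurst import split_ac_dc
from .signals import BeatSeries, BloodFlowSeries

HRV_BAND = (0.005, 0.400)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

REFRACTORY_S = 0.25          # minimum inter-beat interval for peak picking
IBI_VALID_S = (0.2, 2.0)     # physiological inter-beat-interval range
TACHOGRAM_FS = 4.0           # resampling rate of the interpolated IBI series


def extract_pulsatile(flow: BloodFlowSeries) -> BloodFlowSeries:
    """Pulsatile (AC) component: zero-phase 2nd-order high-pass at 0.5 Hz."""
    if flow.fs < 10:
        raise ValueError("pulsatile extraction needs fs >= 10 Hz")
    if flow.duration < 10 * (1.0 / 0.5):
        raise ValueError("series shorter than 10 filter time-constants (20 s)")
    return split_ac_dc(flow).ac


def detect_beats(ac: BloodFlowSeries) -> BeatSeries:
    """Pick pulse peaks from the AC component.

    Local maxima above 0.3x the rolling 5-s peak envelope, separated by at
    least the 0.25-s refractory interval, are beat candidates.  Two quality
    gates reject non-pulsatile inputs whose residual (e.g. vasomotion
    leaking through the high-pass) still produces local maxima: the peak
    train must be roughly regular (inter-beat-interval coefficient of
    variation <= 0.35) and the peaks must be systole-sharp (median width at
    half prominence <= 0.25 s).  Failing either gate returns an empty beat
    series with a warning.
    """
    x = ac.samples
    if x.size == 0 or not np.any(np.abs(x) > 0):
        warnings.warn("no pulsatile activity found; empty beat series",
                      stacklevel=2)
        return BeatSeries(np.array([]), ac.site)
    env_len = int(round(5 * ac.fs)) | 1
    envelope = ndimage.maximum_filter1d(x, size=env_len, mode="nearest")
    height = 0.3 * np.maximum(envelope, 1e-12)
    peaks, _ = sps.find_peaks(x, height=height,
                              distance=max(int(round(REFRACTORY_S * ac.fs)), 1))
    if peaks.size < 3:
        warnings.warn("fewer than 3 peaks found; empty beat series",
                      stacklevel=2)
        return BeatSeries(np.array([]), ac.site)
    times = ac.start_time + peaks / ac.fs
    ibis = np.diff(times)
    cv = ibis.std() / ibis.mean() if ibis.mean() > 0 else np.inf
    if cv > 0.35:
        warnings.warn(
            f"peak train too irregular to be pulsatile (IBI CV {cv:.2f}); "
            "empty beat series", stacklevel=2)
        return BeatSeries(np.array([]), ac.site)
    widths = sps.peak_widths(x, peaks, rel_height=0.5)[0] / ac.fs
    if np.median(widths) > 0.25:
        warnings.warn(
            f"peaks too broad to be systolic (median width "
            f"{np.median(widths):.2f} s); empty beat series", stacklevel=2)
        return BeatSeries(np.array([]), ac.site)
    return BeatSeries(times, ac.site)


def _band_power(freqs: np.ndarray, pxx: np.ndarray, band) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return 0.0
    return float(np.trapezoid(pxx[sel], freqs[sel]))


def compute_lf_hf(beats: BeatSeries) -> tuple[float, float]:
    """Normalized LF and HF powers of the inter-beat-interval spectrum.

    The IBI tachogram is cleaned (intervals outside 0.2-2.0 s or deviating
    more than 30% from the local rhythm dropped),
    cubic-interpolated onto a uniform 4-Hz grid, mean-removed, and its Welch
    spectrum integrated over the LF, HF, and full 0.005-0.400 Hz bands.

    Returns ``(nan, nan)`` with a warning when the tachogram carries no
    variability (zero denominator).

    Raises
    ------
    ValueError
        If fewer than 60 beats or less than 200 s span are available — the
        0.005 Hz lower band edge is unresolvable on shorter records.
    """
    t = beats.beat_times
    if t.size < 60 or (t.size and (t[-1] - t[0]) < 200.0):
        raise ValueError(
            "need >= 60 beats spanning >= 200 s to resolve the 0.005-Hz "
            "lower edge of the HRV band"
        )
    ibis = np.diff(t)
    valid = (ibis >= IBI_VALID_S[0]) & (ibis <= IBI_VALID_S[1])
    # missed/ectopic beats leave intervals far from the local rhythm; the
    # usual artifact rule drops intervals deviating > 30% from the running
    # 11-beat median and bridges them by interpolation
    run_med = ndimage.median_filter(ibis, size=11, mode="nearest")
    valid &= np.abs(ibis - run_med) <= 0.3 * run_med
    if valid.sum() < 10:
        raise ValueError("too few physiological inter-beat intervals")
    # tachogram samples sit at the end of each valid interval; excluded
    # (ectopic/missed) intervals are bridged by the interpolation
    tt, vv = t[1:][valid], ibis[valid]
    if np.allclose(vv, vv[0]):
        warnings.warn("constant inter-beat intervals; LF/HF undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    grid = np.arange(tt[0], tt[-1], 1.0 / TACHOGRAM_FS)
    tacho = interpolate.interp1d(tt, vv, kind="cubic",
                                 fill_value="extrapolate")(grid)
    tacho = tacho - tacho.mean()
    nper = min(tacho.size, int(round(256 * TACHOGRAM_FS)))
    freqs, pxx = sps.welch(tacho, fs=TACHOGRAM_FS, nperseg=nper,
                           noverlap=nper // 2, window="hann")
    total = _band_power(freqs, pxx, HRV_BAND)
    if total <= 0:
        warnings.warn("no HRV-band power; LF/HF undefined", stacklevel=2)
        return float("nan"), float("nan")
    lf = _band_power(freqs, pxx, LF_BAND) / total
    hf = _band_power(freqs, pxx, HF_BAND) / total
    return float(lf), float(hf)


def lf_hf_from_flow(flow: BloodFlowSeries) -> dict:
    """Convenience chain: AC extraction -> beat detection -> LF/HF.

    Returns a dict with ``lf``, ``hf`` and ``n_beats``; LF/HF are NaN when
    no usable beat train is found.
    """
    beats = detect_beats(extract_pulsatile(flow))
    if beats.n_beats < 60:
        return {"lf": float("nan"), "hf": float("nan"), "n_beats": beats.n_beats}
    lf, hf = compute_lf_hf(beats)
    return {"lf": lf, "hf": hf, "n_beats": beats.n_beats}
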