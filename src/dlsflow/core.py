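"""Derived DLS parameters: band powers, relHIs, TBF/RBV, median filtering.

The five relative hemodynamic indices (relHI1..relHI5) are the fractions of
speckle-signal power in five contiguous frequency bands
(0.5-1,000, 1,000-2,000, 2,000-4,000, 4,000-10,000, 10,000-15,000 Hz),
normalised by the five-band total so sensor placement and skin coupling
cancel.  Lower bands correspond to slower scatterer dynamics (smaller
vessels), higher bands to faster dynamics (larger vessels).

TBF (total blood flow) and RBV (relative blood velocity) are spectral
surrogates of perfusion and flow speed:

* TBF is the first spectral moment of the zero-mean trace,
  ``sum f * S(f) df`` over 0.5-15,000 Hz — it grows with both fluctuation
  power (blood volume) and spectral speed, so it scales with the square of
  trace amplitude;
* RBV is the mean spectral frequency ``sum f * S(f) df / sum S(f) df`` —
  a speed surrogate that is invariant to trace amplitude.

Both are reported in arbitrary units at 1 Hz and smoothed with a 30-s
moving-median filter.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .signals import (DEFAULT_BAND_EDGES, BandPowerSeries, BloodFlowSeries,
                      RawSpeckleTrace, RelHISeries)


def _check_edges(edges, fs: float):
    edges = tuple(float(e) for e in edges)
    if len(edges) != 6:
        raise ValueError("band scheme needs six edges (five bands)")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly ascending")
    if edges[-1] > fs / 2:
        raise ValueError(
            f"band edge {edges[-1]} Hz exceeds Nyquist frequency {fs / 2} Hz"
        )
    return edges


def _band_matrix(freqs: np.ndarray, edges) -> np.ndarray:
    """(n_bands, n_freqs) indicator matrix for half-open bands [lo, hi)."""
    return np.stack([(freqs >= lo) & (freqs < hi)
                     for lo, hi in zip(edges[:-1], edges[1:])]).astype(float)


def band_power_decomposition(trace: RawSpeckleTrace, edges=DEFAULT_BAND_EDGES,
                             window_s: float = 0.25,
                             hop_s: float | None = None) -> BandPowerSeries:
    """Per-window integrated spectral power in each of the five bands.

    Each analysis window is mean-removed, Hann-tapered, and its periodogram
    summed over the band bins.  The default 0.25-s window with a 0.01-s hop
    emits band-power vectors at a nominal 100 Hz when the sampling rate
    permits; otherwise one vector per window is emitted.

    Parameters
    ----------
    trace
        Fast speckle trace; must span at least one window.
    edges
        Six ascending band edges in Hz; the top edge must not exceed
        ``trace.fs / 2``.
    window_s, hop_s
        Window length and hop in seconds.  ``hop_s=None`` selects 0.01 s
        (100 vectors/s) when ``trace.fs >= 100``, else one hop per window.
    """
    edges = _check_edges(edges, trace.fs)
    n = trace.samples.size
    wlen = int(round(window_s * trace.fs))
    if wlen < 8:
        raise ValueError("window too short for spectral estimation")
    if n < wlen:
        raise ValueError("trace shorter than one analysis window")
    if hop_s is None:
        hop_s = 0.01 if trace.fs >= 100 else window_s
    hop = max(int(round(hop_s * trace.fs)), 1)

    taper = sps.windows.hann(wlen, sym=False)
    # periodogram normalisation such that band powers sum to signal variance
    norm = 1.0 / np.sum(taper ** 2)
    freqs = np.fft.rfftfreq(wlen, d=1.0 / trace.fs)
    bmat = _band_matrix(freqs, edges)

    starts = np.arange(0, n - wlen + 1, hop)
    powers = np.empty((starts.size, 5))
    chunk = 256
    for c0 in range(0, starts.size, chunk):
        idx = starts[c0:c0 + chunk]
        frames = np.stack([trace.samples[i:i + wlen] for i in idx])
        frames = frames - frames.mean(axis=1, keepdims=True)
        spec = np.fft.rfft(frames * taper, axis=1)
        pxx = (np.abs(spec) ** 2) * norm
        pxx[:, 1:-1] *= 2.0          # one-sided spectrum
        powers[c0:c0 + idx.size] = pxx @ bmat.T
    times = trace.start_time + (starts + wlen / 2) / trace.fs
    return BandPowerSeries(times, powers, edges, window_s)


def compute_relhis(band_powers: BandPowerSeries) -> RelHISeries:
    """Normalise band powers to relative hemodynamic indices.

    Each five-band vector is divided by its five-band total, so the indices
    are unitless fractions summing to 1.  Windows with zero total power are
    emitted as missing rows (never zeros) with a warning.
    """
    p = band_powers.powers
    if np.any(p < 0):
        raise ValueError("band powers must be non-negative")
    total = p.sum(axis=1)
    frac = np.full_like(p, np.nan)
    ok = total > 0
    frac[ok] = p[ok] / total[ok, None]
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} all-zero band-power windows "
                      "emitted as missing relHI vectors", stacklevel=2)
    return RelHISeries(band_powers.times, frac)


def _welch_psd(seg: np.ndarray, fs: float):
    nper = min(seg.size, 8192)
    return sps.welch(seg - seg.mean(), fs=fs, nperseg=nper,
                     noverlap=nper // 2, window="hann")


def _spectral_moments(trace: RawSpeckleTrace, window_s: float,
                      f_lo: float, f_hi: float):
    """Per-window (first moment, total power) over [f_lo, f_hi)."""
    wlen = int(round(window_s * trace.fs))
    if trace.samples.size < wlen:
        raise ValueError("trace shorter than one analysis window")
    if wlen < 16:
        raise ValueError("window too short for spectral-moment estimation")
    n_windows = trace.samples.size // wlen
    m1 = np.empty(n_windows)
    m0 = np.empty(n_windows)
    times = np.empty(n_windows)
    for i in range(n_windows):
        seg = trace.samples[i * wlen:(i + 1) * wlen]
        f, pxx = _welch_psd(seg, trace.fs)
        df = f[1] - f[0]
        sel = (f >= f_lo) & (f < f_hi)
        m0[i] = np.sum(pxx[sel]) * df
        m1[i] = np.sum(f[sel] * pxx[sel]) * df
        times[i] = trace.start_time + (i + 0.5) * window_s
    return times, m1, m0


def estimate_tbf(trace: RawSpeckleTrace, window_s: float = 1.0,
                 edges=DEFAULT_BAND_EDGES) -> BloodFlowSeries:
    """Total-blood-flow surrogate at 1 value per window (default 1 Hz).

    First spectral moment of the zero-mean trace over the full 0.5-15,000 Hz
    analysis range, estimated from an averaged modified periodogram (Welch)
    per window.  Scales with squared trace amplitude.
    """
    edges = _check_edges(edges, trace.fs)
    _, m1, _ = _spectral_moments(trace, window_s, edges[0], edges[-1])
    return BloodFlowSeries(m1, fs=1.0 / window_s, start_time=trace.start_time,
                           kind="TBF", meta={"window_s": window_s})


def estimate_rbv(trace: RawSpeckleTrace, window_s: float = 1.0,
                 edges=DEFAULT_BAND_EDGES) -> BloodFlowSeries:
    """Relative-blood-velocity surrogate: per-window mean spectral frequency.

    ``sum f S(f) df / sum S(f) df`` over 0.5-15,000 Hz; invariant to trace
    amplitude.  Zero-power windows are emitted as missing values.
    """
    edges = _check_edges(edges, trace.fs)
    _, m1, m0 = _spectral_moments(trace, window_s, edges[0], edges[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rbv = np.where(m0 > 0, m1 / m0, np.nan)
    if np.any(m0 <= 0):
        warnings.warn("zero-power windows emitted as missing RBV values",
                      stacklevel=2)
    return BloodFlowSeries(rbv, fs=1.0 / window_s, start_time=trace.start_time,
                           kind="RBV", meta={"window_s": window_s})


def moving_median(series: BloodFlowSeries, window_s: float = 30.0) -> BloodFlowSeries:
    """Centred moving-median filter (default 30-s window), length-preserving.

    The window length in samples is rounded to the nearest odd count; at the
    edges the available partial window is used, so no samples are lost.
    """
    x = series.samples
    if x.size == 0:
        raise ValueError("cannot median-filter an empty series")
    w = max(int(round(window_s * series.fs)), 1)
    if w % 2 == 0:
        w += 1
    h = w // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo, hi = max(0, i - h), min(x.size, i + h + 1)
        win = x[lo:hi]
        win = win[np.isfinite(win)]
        out[i] = np.median(win) if win.size else np.nan
    return BloodFlowSeries(out, series.fs, series.start_time, series.site,
                           series.kind, {**series.meta, "median_window_s": window_s})
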