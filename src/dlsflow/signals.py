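"""Signal containers shared across the pipeline.

All signals are plain numpy arrays wrapped with their sampling rate and
light provenance metadata.  Times are seconds from recording start; analysis
windows are half-open ``[t, t + w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SITES = ("central", "peripheral")
TIMEPOINTS = ("T0", "T1", "T2", "T3")
GROUPS = ("control", "LPS", "resuscitation")

#: Band edges (Hz) of the five relative hemodynamic index (relHI) bands,
#: lowest band ~ smallest vessels, highest band ~ largest vessels.
DEFAULT_BAND_EDGES = (0.5, 1_000.0, 2_000.0, 4_000.0, 10_000.0, 15_000.0)


def _as_finite_1d(samples, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite samples")
    return arr


@dataclass
class RawSpeckleTrace:
    """Fast speckle-intensity trace (arbitrary units).

    The fluctuation spectrum of this trace carries the band-power content
    from which the hemodynamic indices and the TBF/RBV perfusion surrogates
    are derived.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = _as_finite_1d(self.samples, "samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BloodFlowSeries:
    """Slow blood-flow signal (AU): raw 100-Hz flow, or derived 1-Hz TBF/RBV.

    ``kind`` distinguishes the raw pulsatile flow stream from the derived
    total-blood-flow (TBF) and relative-blood-velocity (RBV) series.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    site: str | None = None
    kind: str = "raw_flow"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        # derived series may carry missing values (NaN); raw flow may not
        if self.kind == "raw_flow" and not np.all(np.isfinite(arr)):
            raise ValueError("raw flow samples must be finite")
        self.samples = arr
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.kind not in ("raw_flow", "TBF", "RBV"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BandPowerSeries:
    """Per-window integrated spectral power in each of the five bands."""

    times: np.ndarray          # window-centre times, s
    powers: np.ndarray         # (n_windows, 5), AU^2
    edges: tuple = DEFAULT_BAND_EDGES
    window_s: float = 0.25

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.atleast_2d(np.asarray(self.powers, dtype=float))
        if self.powers.shape[0] != self.times.size:
            raise ValueError("times and powers disagree in length")
        if self.powers.shape[1] != len(self.edges) - 1:
            raise ValueError("powers must have one column per band")


@dataclass
class RelHISeries:
    """Normalized band-power fractions (relHI1..relHI5) over time.

    Each row sums to 1; rows from windows with zero total power are NaN.
    """

    times: np.ndarray
    fractions: np.ndarray      # (n_windows, 5), unitless

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        ok = np.all(np.isfinite(self.fractions), axis=1)
        sums = self.fractions[ok].sum(axis=1)
        if ok.any() and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("relHI rows must sum to 1")

    def median(self) -> np.ndarray:
        """Per-band median fraction over time, ignoring missing rows."""
        return np.nanmedian(self.fractions, axis=0)


@dataclass
class BeatSeries:
    """Detected (or ground-truth) beat times, strictly increasing, in s."""

    beat_times: np.ndarray
    site: str | None = None
    timepoint: str | None = None

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


@dataclass
class HurstSeries:
    """Windowed Hurst-exponent estimates for one signal component."""

    window_starts: np.ndarray
    estimates: np.ndarray      # unitless (AU); NaN where not estimable
    component: str = "full"    # full | ac | dc
    window_s: float = 180.0
    step_s: float = 90.0

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.window_starts.size != self.estimates.size:
            raise ValueError("window_starts and estimates disagree in length")
        if self.component not in ("full", "ac", "dc"):
            raise ValueError(f"unknown component {self.component!r}")

    def median(self) -> float:
        if self.estimates.size == 0 or np.all(np.isnan(self.estimates)):
            return float("nan")
        return float(np.nanmedian(self.estimates))
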