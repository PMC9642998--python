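"""Beat-series and ECG fiducial analytics.

Implements the rhythm definitions used for sick-sinus-syndrome phenotyping:
standard interval measurements (PP, RR, PR, QRS, QT, heart rate), sinus-arrest
(SA) episode calling from PP pauses, atrioventricular-block (AVB) calling from
non-conducted P waves, sinoatrial-node recovery time (SANRT) after rapid
pacing, cycle-length variation, and R-peak detection from sampled ECG-like
waveforms.

Conventions: all times are seconds, zero-based from the start of the
recording. The SA threshold of 1.5 s is the zebrafish definition (resting
heart rate ~100 bpm); for mouse-like recordings (~500 bpm) the default
threshold is 2x the median PP interval of the recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as _spsig

__all__ = [
    "FiducialSeries",
    "EpisodeCall",
    "PacingResult",
    "IntervalSummary",
    "compute_intervals",
    "detect_sa_episodes",
    "detect_avb_episodes",
    "sanrt",
    "cl_variation",
    "detect_r_peaks",
]

#: default SA thresholds by species tag; None means "2x median PP"
SA_THRESHOLD_S = {"zebrafish": 1.5, "mouse": None}


def _check_series(name: str, t: np.ndarray, duration: float) -> None:
    if t.size and not np.all(np.diff(t) > 0):
        raise ValueError(f"{name} times must be strictly increasing")
    if t.size and (t[0] < 0 or t[-1] > duration):
        raise ValueError(f"{name} times must lie within [0, duration]")


@dataclass
class FiducialSeries:
    """Time-stamped cardiac fiducial points for one recording.

    ``p_times`` are atrial (P-wave) activations, ``r_times`` ventricular
    (R-peak) activations; QRS onset/offset and T-end series are optional and
    only used when present (never inferred).
    """

    p_times: np.ndarray
    r_times: np.ndarray
    duration: float
    species: str = "zebrafish"
    qrs_onsets: Optional[np.ndarray] = None
    qrs_offsets: Optional[np.ndarray] = None
    t_ends: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.p_times = np.asarray(self.p_times, dtype=float)
        self.r_times = np.asarray(self.r_times, dtype=float)
        _check_series("P", self.p_times, self.duration)
        _check_series("R", self.r_times, self.duration)
        for name in ("qrs_onsets", "qrs_offsets", "t_ends"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                _check_series(name, v, self.duration)


@dataclass(frozen=True)
class EpisodeCall:
    """A detected rhythm abnormality.

    ``kind`` is ``"SA"`` (sinus arrest: a long PP pause) or ``"AVB"``
    (atrioventricular block: a P wave without a ventricular response).
    ``evidence`` carries the triggering PP interval (SA) or the index of the
    orphan P wave (AVB).
    """

    kind: Literal["SA", "AVB"]
    onset: float
    offset: float
    evidence: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("episode offset must exceed onset")


@dataclass(frozen=True)
class PacingResult:
    """Sinus node recovery time measurement after an S1S1 pacing train."""

    last_pace_time: float
    first_spontaneous_time: float
    resting_cycle_length: float
    sanrt: float
    csanrt: float


@dataclass
class IntervalSummary:
    """Per-recording ECG interval summary; absent fiducials yield None."""

    heart_rate_bpm: Optional[float]
    mean_rr: Optional[float]
    mean_pp: Optional[float]
    mean_pr: Optional[float]
    mean_qrs: Optional[float]
    mean_qt: Optional[float]
    rr: np.ndarray = field(default_factory=lambda: np.empty(0))
    pp: np.ndarray = field(default_factory=lambda: np.empty(0))
    pr: np.ndarray = field(default_factory=lambda: np.empty(0))


def _pair_p_to_r(
    p_times: np.ndarray, r_times: np.ndarray, window: float
) -> list[tuple[int, Optional[int]]]:
    """Greedy one-to-one P->R pairing in time order.

    Each P takes the earliest unused R that follows it within ``window``
    seconds; Ps left without an R are orphans (conduction failures).
    """
    pairs: list[tuple[int, Optional[int]]] = []
    j = 0
    for i, p in enumerate(p_times):
        while j < r_times.size and r_times[j] <= p:
            j += 1
        # a conducted response must precede the next atrial activation
        bound = p_times[i + 1] if i + 1 < p_times.size else math.inf
        if j < r_times.size and r_times[j] - p <= window and r_times[j] < bound:
            pairs.append((i, j))
            j += 1
        else:
            pairs.append((i, None))
    return pairs


def compute_intervals(f: FiducialSeries, pr_window: float = 0.5) -> IntervalSummary:
    """Per-beat and mean ECG intervals plus heart rate.

    Heart rate is 60 / mean(RR) in bpm. PR intervals come from greedy P->R
    pairing within ``pr_window`` s. QRS duration and QT need onset/offset/T-end
    fiducials and are reported only when those are present.
    """
    rr = np.diff(f.r_times)
    pp = np.diff(f.p_times)
    hr = 60.0 / rr.mean() if rr.size >= 1 else None
    mean_rr = float(rr.mean()) if rr.size else None
    mean_pp = float(pp.mean()) if pp.size else None

    pr = np.empty(0)
    if f.p_times.size and f.r_times.size:
        pairs = _pair_p_to_r(f.p_times, f.r_times, pr_window)
        pr = np.array([f.r_times[j] - f.p_times[i] for i, j in pairs if j is not None])
    mean_pr = float(pr.mean()) if pr.size else None

    mean_qrs = None
    if f.qrs_onsets is not None and f.qrs_offsets is not None:
        n = min(f.qrs_onsets.size, f.qrs_offsets.size)
        if n:
            mean_qrs = float(np.mean(f.qrs_offsets[:n] - f.qrs_onsets[:n]))
    mean_qt = None
    if f.qrs_onsets is not None and f.t_ends is not None:
        n = min(f.qrs_onsets.size, f.t_ends.size)
        if n:
            mean_qt = float(np.mean(f.t_ends[:n] - f.qrs_onsets[:n]))

    return IntervalSummary(
        heart_rate_bpm=float(hr) if hr is not None else None,
        mean_rr=mean_rr,
        mean_pp=mean_pp,
        mean_pr=mean_pr,
        mean_qrs=mean_qrs,
        mean_qt=mean_qt,
        rr=rr,
        pp=pp,
        pr=pr,
    )


def resolve_sa_threshold(f: FiducialSeries, threshold: Optional[float] = None) -> float:
    """SA pause threshold: explicit value, species default, or 2x median PP."""
    if threshold is not None:
        return threshold
    preset = SA_THRESHOLD_S.get(f.species, None)
    if preset is not None:
        return preset
    base = f.p_times if f.p_times.size >= 2 else f.r_times
    gaps = np.diff(base)
    if gaps.size == 0:
        raise ValueError("cannot derive an SA threshold from fewer than 2 beats")
    return 2.0 * float(np.median(gaps))


def detect_sa_episodes(
    f: FiducialSeries, threshold: Optional[float] = None
) -> list[EpisodeCall]:
    """Sinus-arrest calls: one per PP interval strictly greater than threshold.

    The zebrafish definition is PP > 1.5 s; a PP of exactly the threshold is
    not called. When P fiducials are absent the RR series is used as a proxy
    (with a warning), since atrial activations are the defining series.
    """
    thr = resolve_sa_threshold(f, threshold)
    if thr <= 0:
        raise ValueError("SA threshold must be positive")
    base = f.p_times
    if base.size < 2:
        if f.r_times.size >= 2:
            warnings.warn(
                "no P fiducials; detecting SA on RR intervals as a proxy",
                stacklevel=2,
            )
            base = f.r_times
        else:
            return []
    gaps = np.diff(base)
    calls = []
    for i, g in enumerate(gaps):
        if g > thr:
            calls.append(
                EpisodeCall("SA", float(base[i]), float(base[i + 1]), float(g))
            )
    return calls


def detect_avb_episodes(
    f: FiducialSeries, pr_window: Optional[float] = None
) -> list[EpisodeCall]:
    """Atrioventricular-block calls: P waves with no R within the PR window.

    The pairing is greedy one-to-one in time order. The default window is
    median(PR) + 4*SD(PR) of the conducted beats; this detection rule is a
    package convention (published studies report AVB as observed counts
    without an algorithmic definition).
    """
    if f.p_times.size == 0 or f.r_times.size == 0:
        raise ValueError("AVB detection requires both P and R series")
    if pr_window is None:
        # conducted-beat PR statistics from a generous provisional window
        provisional = _pair_p_to_r(f.p_times, f.r_times, 0.5 * 60.0)
        pr = np.array(
            [f.r_times[j] - f.p_times[i] for i, j in provisional if j is not None]
        )
        if pr.size == 0:
            raise ValueError("no conducted beats to estimate the PR window from")
        pr_window = float(np.median(pr) + 4.0 * pr.std(ddof=1 if pr.size > 1 else 0))
    pairs = _pair_p_to_r(f.p_times, f.r_times, pr_window)
    calls = []
    for i, j in pairs:
        if j is None:
            p = float(f.p_times[i])
            offset = float(f.p_times[i + 1]) if i + 1 < f.p_times.size else f.duration
            if offset <= p:
                offset = p + pr_window
            calls.append(EpisodeCall("AVB", p, offset, float(i)))
    return calls


def sanrt(
    pace_times: Sequence[float],
    spontaneous_beats: Sequence[float],
    resting_cl: float,
) -> PacingResult:
    """Sinus node recovery time after an S1S1 pacing train.

    SANRT is the interval from the last paced beat to the first spontaneous
    beat strictly after it; corrected SANRT subtracts the pre-pacing resting
    cycle length.
    """
    pace = np.asarray(pace_times, dtype=float)
    spont = np.asarray(spontaneous_beats, dtype=float)
    if pace.size == 0:
        raise ValueError("no pacing beats supplied")
    last = float(pace.max())
    after = spont[spont > last]
    if after.size == 0:
        raise ValueError("no spontaneous beat after the last paced beat (suppressed pacemaker)")
    first = float(after.min())
    t = first - last
    return PacingResult(last, first, resting_cl, t, t - resting_cl)


def cl_variation(beat_times: Sequence[float], metric: str = "sd") -> float:
    """Cycle-length variation of a beat train.

    Default metric: sample SD (n-1 denominator) of successive cycle lengths;
    ``metric="cv"`` returns the coefficient of variation SD/mean.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 3:
        raise ValueError("cycle-length variation needs at least 3 beats")
    cls_ = np.diff(t)
    sd = float(cls_.std(ddof=1))
    if metric == "sd":
        return sd
    if metric == "cv":
        return sd / float(cls_.mean())
    raise ValueError(f"unknown metric {metric!r}")


def detect_r_peaks(
    waveform: Sequence[float],
    fs: float,
    band: tuple[float, float] = (0.5, 200.0),
    refractory: float = 0.05,
    threshold_fraction: float = 0.3,
) -> np.ndarray:
    """R-peak times from a sampled ECG-like trace.

    Pipeline: zero-phase Butterworth band-pass (0.5-200 Hz by default, upper
    edge capped below Nyquist), squared derivative envelope (polarity
    invariant), light smoothing, then peak picking at a threshold set as a
    fraction of the 98th envelope percentile with a refractory lockout.
    Returns peak times in seconds.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    x = np.asarray(waveform, dtype=float)
    if x.size < 8:
        return np.empty(0)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = _spsig.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = _spsig.sosfiltfilt(sos, x)
    env = np.gradient(filt) ** 2
    win = max(int(0.01 * fs), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")
    ceiling = np.percentile(env, 98)
    if ceiling <= 0:
        return np.empty(0)
    thr = threshold_fraction * ceiling
    dist = max(int(refractory * fs), 1)
    idx, _ = _spsig.find_peaks(env, height=thr, distance=dist)
    # refine each detection to the absolute extremum of the filtered trace nearby
    half = max(int(0.01 * fs), 1)
    refined = []
    for i in idx:
        sl = slice(max(i - half, 0), min(i + half + 1, x.size))
        refined.append(sl.start + int(np.argmax(np.abs(filt[sl]))))
    times = np.unique(np.asarray(refined)) / fs
    if times.size > 1:
        keep = [0]
        for k in range(1, times.size):
            if times[k] - times[keep[-1]] >= refractory:
                keep.append(k)
        times = times[keep]
    return times
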