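"""Synthetic data generators with machine-readable ground truth.

Three generators support pipeline testing without any recorded data:

* :func:`gen_beat_train` - fiducial beat series emulating zebrafish
  (~100 bpm) or mouse (~500 bpm) ECG recordings, with programmable sinus
  pauses and dropped ventricular beats, emitting the injected events as
  ground truth.
* :func:`gen_ecg_waveform` - a stylized sampled ECG (Gaussian P/QRS/T
  deflections plus white noise) rendered from a fiducial series, for
  exercising the R-peak detector. The morphology is deliberately schematic,
  not biophysical.
* :class:`SurrogatePacemaker` - an analytic stand-in for the sinoatrial-node
  cell model in which log firing rate is a known linear function of the
  log parameter scalings. It is exactly invertible, so population-screen
  behavior can be checked against closed-form/brute-force expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .rhythm import FiducialSeries

__all__ = [
    "BeatTrainSpec",
    "SurrogateSpec",
    "SurrogatePacemaker",
    "gen_beat_train",
    "gen_ecg_waveform",
    "surrogate_rates",
    "DEFAULT_SURROGATE_SPEC",
]

_SPECIES_PRESETS = {
    # mean HR bpm, PR mean s, PR sd s, QRS half-duration s, QT span s
    "zebrafish": dict(hr=100.0, pr_mean=0.10, pr_sd=0.005, qrs_half=0.02, qt=0.25),
    "mouse": dict(hr=500.0, pr_mean=0.035, pr_sd=0.002, qrs_half=0.006, qt=0.05),
}


@dataclass
class BeatTrainSpec:
    """Recipe for a synthetic fiducial beat train.

    ``sa_pauses`` is a list of (beat index, extra pause length s) pairs; the
    PP gap following that beat becomes base cycle length + pause. ``avb_drops``
    lists beat indices whose ventricular (R) response is omitted.
    """

    hr_bpm: float = 100.0
    n_beats: int = 200
    cl_jitter_sd: float = 0.0
    sa_pauses: Sequence[tuple[int, float]] = field(default_factory=list)
    avb_drops: Sequence[int] = field(default_factory=list)
    pr_mean: Optional[float] = None
    pr_sd: Optional[float] = None
    species: str = "zebrafish"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if any(p <= 0 for _, p in self.sa_pauses):
            raise ValueError("pause lengths must be positive")
        if any(not 0 <= i < self.n_beats for i, _ in self.sa_pauses):
            raise ValueError("pause index out of range")
        if any(not 0 <= i < self.n_beats for i in self.avb_drops):
            raise ValueError("AVB drop index out of range")
        preset = _SPECIES_PRESETS.get(self.species, _SPECIES_PRESETS["zebrafish"])
        if self.pr_mean is None:
            self.pr_mean = preset["pr_mean"]
        if self.pr_sd is None:
            self.pr_sd = preset["pr_sd"]


def gen_beat_train(spec: BeatTrainSpec) -> tuple[FiducialSeries, dict]:
    """Generate a fiducial series plus ground-truth injected events.

    P times accumulate cycle lengths (60/HR + Gaussian jitter, plus the
    programmed pauses); R times are P + a sampled PR interval except at the
    dropped indices. The returned truth dict lists every injected SA gap
    (onset, offset, gap length) and every dropped-beat P index.
    """
    rng = np.random.default_rng(spec.seed)
    base_cl = 60.0 / spec.hr_bpm
    cls_ = base_cl + rng.normal(0.0, spec.cl_jitter_sd, spec.n_beats - 1)
    cls_ = np.clip(cls_, 0.2 * base_cl, None)
    pause_at = dict(spec.sa_pauses)
    truth_sa = []
    p_times = np.empty(spec.n_beats)
    p_times[0] = 0.5 * base_cl
    for i in range(1, spec.n_beats):
        gap = cls_[i - 1]
        if (i - 1) in pause_at:
            gap += pause_at[i - 1]
        p_times[i] = p_times[i - 1] + gap
        if (i - 1) in pause_at:
            truth_sa.append(
                dict(onset=float(p_times[i - 1]), offset=float(p_times[i]), gap=float(gap))
            )

    pr = rng.normal(spec.pr_mean, spec.pr_sd, spec.n_beats)
    pr = np.clip(pr, 0.2 * spec.pr_mean, None)
    dropped = sorted(set(spec.avb_drops))
    keep = np.setdiff1d(np.arange(spec.n_beats), dropped)
    r_times = p_times[keep] + pr[keep]

    preset = _SPECIES_PRESETS.get(spec.species, _SPECIES_PRESETS["zebrafish"])
    qrs_on = r_times - preset["qrs_half"]
    qrs_off = r_times + preset["qrs_half"]
    t_ends = qrs_on + preset["qt"]
    duration = float(p_times[-1] + base_cl)
    series = FiducialSeries(
        p_times=p_times,
        r_times=r_times,
        duration=duration,
        species=spec.species,
        qrs_onsets=qrs_on,
        qrs_offsets=qrs_off,
        t_ends=t_ends,
    )
    truth = dict(sa_events=truth_sa, avb_drop_indices=[int(i) for i in dropped])
    return series, truth


def gen_ecg_waveform(
    f: FiducialSeries,
    fs: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    r_amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a stylized sampled ECG from a fiducial series.

    Gaussian deflections are placed at the fiducial times: a small P wave, a
    tall narrow R (with small opposing Q/S lobes), and a broad T wave; white
    Gaussian noise of ``noise_sd`` mV is added. Returns ``(time_s, mv)``.
    """
    preset = _SPECIES_PRESETS.get(f.species, _SPECIES_PRESETS["zebrafish"])
    r_width = max(preset["qrs_half"] / 2.0, 1e-4)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if fs * r_width < 2.0:
        raise ValueError(
            f"sampling rate {fs} Hz too low to place QRS deflections of width {r_width} s"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, f.duration, 1.0 / fs)
    x = np.zeros_like(t)

    def bump(center: np.ndarray, amp: float, width: float) -> None:
        for c in np.atleast_1d(center):
            lo = np.searchsorted(t, c - 5 * width)
            hi = np.searchsorted(t, c + 5 * width)
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)

    if f.p_times.size:
        bump(f.p_times, 0.15 * r_amplitude, 2.0 * r_width)
    if f.r_times.size:
        bump(f.r_times - 2.5 * r_width, -0.12 * r_amplitude, r_width)  # Q
        bump(f.r_times, r_amplitude, r_width)
        bump(f.r_times + 2.5 * r_width, -0.18 * r_amplitude, r_width)  # S
        bump(f.r_times + 6.0 * r_width, 0.25 * r_amplitude, 4.0 * r_width)  # T
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.size)
    return t, x


# ---------------------------------------------------------------------------
# Analytic surrogate pacemaker population
# ---------------------------------------------------------------------------

#: elasticities of log baseline rate w.r.t. log scaling, per varied parameter.
#: Signs are chosen so that selecting slow-baseline variants shifts each
#: parameter in the direction reported for the sick-sinus-like subpopulation
#: (down for g_na, g_cal, g_to, g_sus, g_bna, g_bca, v_ryr; up for g_cat,
#: g_ks, v_ncx; g_kach moves only through the carbachol-response criterion).
#: Magnitudes are order-of-magnitude plausible but otherwise arbitrary.
_BASE_ELASTICITY = {
    "g_na": 0.10,
    "g_cal": 0.35,
    "g_cat": -0.08,
    "g_to": 0.06,
    "g_sus": 0.06,
    "g_ks": -0.06,
    "g_kach": 0.0,
    "g_bna": 0.10,
    "g_bca": 0.08,
    "v_ryr": 0.15,
    "v_ncx": -0.20,
}


def _default_coefficients() -> dict[str, dict[str, float]]:
    coeffs: dict[str, dict[str, float]] = {}
    for name, c in _BASE_ELASTICITY.items():
        coeffs[name] = {
            "baseline": c,
            # beta-adrenergic response saturates: weaker intrinsic drive
            # leaves more headroom, so ISO elasticities are compressed
            "ISO": 0.75 * c,
            "CCh": c,
        }
    # stronger acetylcholine-activated K+ conductance deepens CCh slowing
    coeffs["g_kach"]["CCh"] = -0.35
    return coeffs


@dataclass
class SurrogateSpec:
    """Analytic surrogate: log rate_c = log base_c + sum_j coeff[j][c] log s_j."""

    base_rates: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 350.0, "ISO": 440.0, "CCh": 270.0}
    )
    coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_coefficients
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.base_rates.values()):
            raise ValueError("base rates must be positive")


def surrogate_rates(
    spec: SurrogateSpec,
    scalings: Mapping[str, float],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Firing rates (bpm) per condition for one scaling vector.

    Deterministic and analytically invertible when ``spec.noise_sd == 0``.
    Raises ``KeyError`` when a scaling names a parameter the coefficient
    matrix does not cover.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shift = {c: 0.0 for c in spec.base_rates}
    for name, s in scalings.items():
        if name not in spec.coefficients:
            raise KeyError(f"no surrogate coefficients for parameter {name!r}")
        if s <= 0:
            raise ValueError("scalings must be positive")
        for cond in shift:
            shift[cond] += spec.coefficients[name].get(cond, 0.0) * np.log(s)
    out = {}
    for cond, base in spec.base_rates.items():
        eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        out[cond] = float(base * np.exp(shift[cond] + eps))
    return out


DEFAULT_SURROGATE_SPEC = SurrogateSpec()


class SurrogatePacemaker:
    """Population-screen model interface over :func:`surrogate_rates`.

    Duck-type compatible with the ODE pacemaker for population runs: exposes
    ``varied_params``, ``rates(scalings, rng)`` and ``reference_rates()``.
    """

    def __init__(self, spec: Optional[SurrogateSpec] = None) -> None:
        self.spec = spec if spec is not None else SurrogateSpec()
        self.varied_params = list(self.spec.coefficients)
        self.metadata = "analytic log-linear surrogate pacemaker"

    def rates(
        self,
        scalings: Mapping[str, float],
        rng: Optional[np.random.Generator] = None,
    ) -> dict[str, float]:
        return surrogate_rates(self.spec, scalings, rng)

    def reference_rates(self) -> dict[str, float]:
        """Rates of the nominal (all scalings = 1) cell, noise off."""
        noiseless = SurrogateSpec(
            base_rates=self.spec.base_rates,
            coefficients=self.spec.coefficients,
            noise_sd=0.0,
        )
        return surrogate_rates(noiseless, {p: 1.0 for p in self.varied_params})
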