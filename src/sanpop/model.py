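"""Mouse sinoatrial-node pacemaker cell model with autonomic pharmacology.

A compact Hodgkin-Huxley-type formulation of a spontaneously firing mouse SAN
myocyte, authored for this package. The current set matches the vocabulary of
population-of-models screens of SAN automaticity: fast Na+ (Nav1.5, ``g_na``),
L- and T-type Ca2+ (``g_cal``, ``g_cat``), transient-outward and sustained K+
(``g_to``, ``g_sus``), rapid and slow delayed rectifiers (``g_kr``, ``g_ks``),
funny current (``g_f``), acetylcholine-activated K+ (``g_kach``, engaged by
carbachol), background Na+/Ca2+ (``g_bna``, ``g_bca``), Na+/K+ pump
(``p_nak``), Na+/Ca2+ exchanger (``v_ncx``), and a two-compartment Ca2+
subsystem with ryanodine-receptor release (``v_ryr``) and SERCA uptake
(``v_up``) - a minimal membrane-clock + calcium-clock pacemaker.

Autonomic conditions are expressed as parameter transforms: isoproterenol
(beta-adrenergic) scales the Ca2+ currents, I_Ks, the Na+/K+ pump and SERCA
and right-shifts funny-current activation; carbachol (muscarinic) engages the
acetylcholine-activated K+ current through a Hill-type dose dependence.

Units: time s, membrane potential mV, currents pA, conductances nS,
concentrations mM, rates of firing bpm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "PacemakerModel",
    "ConditionTransform",
    "SimResult",
    "CONDITIONS",
    "default_model",
    "default_transforms",
    "load_model_config",
    "apply_condition",
    "simulate",
    "extract_beats",
]

CONDITIONS = ("baseline", "ISO", "CCh")

# physical constants
_RTF = 26.73  # RT/F at 310 K, mV
_F = 96485.0  # C/mol

# fixed ionic milieu (mM); intracellular Na+/K+ are clamped, a standard
# reduction for single-cell SAN automaticity studies
_NAO, _NAI, _KO, _KI, _CAO = 140.0, 8.0, 5.4, 140.0, 1.8
_E_NA = _RTF * math.log(_NAO / _NAI)
_E_K = _RTF * math.log(_KO / _KI)
_E_KS = -71.0  # mixed-permeability apparent reversal
_E_CA_APP = 45.0  # apparent reversal of the Ca2+ channel currents
_E_F = -30.0  # funny-current reversal

_V_I = 2.0e-12  # myoplasmic volume, L
_V_SR = 0.12e-12  # SR volume, L
_B_CAI = 0.045  # rapid-buffering fraction for free myoplasmic Ca2+
_KM_FCA = 0.00035  # Ca2+-dependent I_CaL inactivation, mM
_K_REL = 0.0012  # RyR release activation, mM
_K_UP = 0.0006  # SERCA half-activation, mM
_KACH_K05_NM = 125.0  # carbachol half-activation of I_KACh, nM
_KACH_HILL = 1.5

STATE_NAMES = (
    "em", "m", "h", "d_l", "f_l", "d_t", "f_t",
    "q", "r", "p_k", "n", "y", "cai", "casr",
)

PARAM_NAMES = (
    "c_m", "g_na", "g_cal", "g_cat", "g_to", "g_sus", "g_kr", "g_ks",
    "g_f", "g_kach", "g_bna", "g_bca", "p_nak", "v_ncx", "v_ryr", "v_up",
    "f_shift", "ca_shift", "cch_nm",
)

#: baseline parameter values; conductances nS, p_nak pA, v_ncx a pA scale,
#: v_ryr 1/s, v_up mM/s, f_shift mV, cch_nm nM
DEFAULT_PARAMS: dict[str, float] = {
    "c_m": 25.0,
    "g_na": 4.0,
    "g_cal": 14.0,
    "g_cat": 9.0,
    "g_to": 3.5,
    "g_sus": 0.7,
    "g_kr": 13.0,
    "g_ks": 0.7,
    "g_f": 6.0,
    "g_kach": 1.0,
    "g_bna": 0.04,
    "g_bca": 0.02,
    "p_nak": 150.0,
    "v_ncx": 1.6e5,
    "v_ryr": 8.0,
    "v_up": 1.0,
    "f_shift": 0.0,
    "ca_shift": 0.0,
    "cch_nm": 0.0,
}

#: parameters randomized in population screens (maximal conductances and
#: transport/flux rates)
VARIED_PARAMS = (
    "g_na", "g_cal", "g_cat", "g_to", "g_sus", "g_ks",
    "g_kach", "g_bna", "g_bca", "v_ryr", "v_ncx",
)


def _expm1_safe(x: float) -> float:
    return math.exp(x)


def kach_activation(dose_nm: float) -> float:
    """Hill-type fractional activation of I_KACh by carbachol (dose in nM)."""
    if dose_nm <= 0.0:
        return 0.0
    d = dose_nm ** _KACH_HILL
    return d / (d + _KACH_K05_NM ** _KACH_HILL)


def rhs(t: float, yv: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Time derivative of the pacemaker state (autonomous; no pacing)."""
    (em, m, h, d_l, f_l, d_t, f_t, q, r, p_k, n, y, cai, casr) = yv
    (c_m, g_na, g_cal, g_cat, g_to, g_sus, g_kr, g_ks, g_f, g_kach,
     g_bna, g_bca, p_nak, v_ncx, v_ryr, v_up, f_shift, ca_shift, cch_nm) = p

    cai = max(cai, 1e-8)
    casr = max(casr, 1e-8)

    # --- membrane currents (pA) ---
    i_na = g_na * m ** 3 * h * (em - _E_NA)
    f_ca = _KM_FCA / (_KM_FCA + cai)
    i_cal = g_cal * d_l * f_l * f_ca * (em - _E_CA_APP)
    i_cat = g_cat * d_t * f_t * (em - _E_CA_APP)
    i_to = g_to * q * r * (em - _E_K)
    i_sus = g_sus * r * (em - _E_K)
    p_i = 1.0 / (1.0 + math.exp((em + 28.0) / 17.0))
    i_kr = g_kr * p_k * p_i * (em - _E_K)
    i_ks = g_ks * n * n * (em - _E_KS)
    i_f = g_f * y * (em - _E_F)
    rect = 1.0 / (1.0 + math.exp((em + 40.0) / 20.0))
    a_ach = 0.0
    if cch_nm > 0.0:
        d15 = cch_nm ** _KACH_HILL
        a_ach = d15 / (d15 + _KACH_K05_NM ** _KACH_HILL)
    i_kach = g_kach * a_ach * rect * (em - _E_K)
    e_ca = 0.5 * _RTF * math.log(_CAO / cai)
    i_bna = g_bna * (em - _E_NA)
    i_bca = g_bca * (em - e_ca)
    i_nak = (
        p_nak
        * (_KO / (_KO + 1.4))
        * (_NAI ** 1.5 / (_NAI ** 1.5 + 14.0 ** 1.5))
        * ((em + 150.0) / (em + 200.0))
    )
    ex1 = math.exp(0.35 * em / _RTF)
    ex2 = math.exp(-0.65 * em / _RTF)
    i_ncx = (
        v_ncx
        * (_NAI ** 3 * _CAO * ex1 - _NAO ** 3 * cai * ex2)
        / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO) * (1.0 + 0.1 * ex2))
    )

    i_tot = (
        i_na + i_cal + i_cat + i_to + i_sus + i_kr + i_ks + i_f
        + i_kach + i_bna + i_bca + i_nak + i_ncx
    )

    # --- gating kinetics (tau in s) ---
    m_inf = 1.0 / (1.0 + math.exp(-(em + 36.0) / 5.5))
    tau_m = 2.0e-4
    h_inf = 1.0 / (1.0 + math.exp((em + 66.0) / 5.0))
    tau_h = 0.0015 + 0.015 / (1.0 + math.exp((em + 50.0) / 5.0))
    # beta-adrenergic stimulation left-shifts Ca2+ channel activation
    dl_inf = 1.0 / (1.0 + math.exp(-(em + 25.0 - ca_shift) / 5.5))
    tau_dl = 0.002
    fl_inf = 1.0 / (1.0 + math.exp((em + 38.0) / 7.0))
    tau_fl = 0.025
    dt_inf = 1.0 / (1.0 + math.exp(-(em + 37.0 - ca_shift) / 6.8))
    tau_dt = 0.002
    ft_inf = 1.0 / (1.0 + math.exp((em + 58.0) / 3.8))
    tau_ft = 0.015
    q_inf = 1.0 / (1.0 + math.exp((em + 49.0) / 13.0))
    tau_q = 0.02
    r_inf = 1.0 / (1.0 + math.exp(-(em - 2.0) / 13.0))
    tau_r = 0.0015
    pk_inf = 1.0 / (1.0 + math.exp(-(em + 21.5) / 7.5))
    tau_pk = 0.05 + 0.15 * math.exp(-((em + 20.0) / 25.0) ** 2)
    n_inf = 1.0 / (1.0 + math.exp(-(em - 1.0) / 11.0))
    tau_n = 0.3
    y_inf = 1.0 / (1.0 + math.exp((em + 70.0 - f_shift) / 9.0))
    tau_y = 0.05 + 0.25 / math.cosh((em + 70.0) / 12.0)

    # --- calcium subsystem (mM, mM/s) ---
    j_rel = v_ryr * (casr - cai) * cai * cai / (cai * cai + _K_REL * _K_REL)
    j_up = v_up * cai * cai / (cai * cai + _K_UP * _K_UP)
    i_ca_net = i_cal + i_cat + i_bca - 2.0 * i_ncx
    # pA -> mM/s: I*1e-12 C/s / (2F) mol/s, /V_i L, *1e3 mmol/mol
    dcai = _B_CAI * (-i_ca_net * 1e-9 / (2.0 * _F * _V_I) + j_rel - j_up)
    dcasr = (j_up - j_rel) * (_V_I / _V_SR)

    out = np.empty(14)
    out[0] = -1000.0 * i_tot / c_m
    out[1] = (m_inf - m) / tau_m
    out[2] = (h_inf - h) / tau_h
    out[3] = (dl_inf - d_l) / tau_dl
    out[4] = (fl_inf - f_l) / tau_fl
    out[5] = (dt_inf - d_t) / tau_dt
    out[6] = (ft_inf - f_t) / tau_ft
    out[7] = (q_inf - q) / tau_q
    out[8] = (r_inf - r) / tau_r
    out[9] = (pk_inf - p_k) / tau_pk
    out[10] = (n_inf - n) / tau_n
    out[11] = (y_inf - y) / tau_y
    out[12] = dcai
    out[13] = dcasr
    return out


#: stored resting state: a point on the default cell's limit cycle after
#: 100 s of equilibration (regenerate after structural model changes)
DEFAULT_Y0 = np.array([
    -4.69163486e+01, 1.17592231e-01, 7.97116094e-02, 1.42493794e-02,
    8.88354562e-01, 1.58333695e-01, 3.03905586e-01, 6.02503349e-01,
    2.08246422e-02, 8.18210082e-02, 9.68294972e-02, 9.16580900e-02,
    1.85132012e-04, 3.46926305e-01,
])


@dataclass(frozen=True)
class ConditionTransform:
    """Autonomic condition as a parameter transform.

    ``effects`` are (parameter, kind, value) triples with kind ``"scale"``
    (multiplicative) or ``"shift"`` (additive, e.g. a gating half-activation
    shift in mV). ``kach_nm`` sets the carbachol dose (nM) engaging the
    acetylcholine-activated K+ current; 0 leaves it off.
    """

    condition: Literal["baseline", "ISO", "CCh"]
    effects: tuple[tuple[str, str, float], ...] = ()
    kach_nm: float = 0.0

    def __post_init__(self) -> None:
        for name, kind, value in self.effects:
            if kind not in ("scale", "shift"):
                raise ValueError(f"unknown effect kind {kind!r} for {name}")
            if kind == "scale" and value <= 0:
                raise ValueError(f"scale factor for {name} must be positive")
        if self.kach_nm < 0:
            raise ValueError("carbachol dose must be non-negative")


@dataclass(frozen=True)
class SimResult:
    """Outcome of one pacemaker simulation.

    ``firing_rate`` (bpm) is 60 / mean terminal cycle length; it is ``nan``
    (never a silent division) unless ``status == "ok"``.
    """

    time: np.ndarray
    em_trace: np.ndarray
    beat_times: np.ndarray
    firing_rate: float
    cycle_lengths: np.ndarray
    steady: bool
    status: Literal["ok", "no_firing", "integration_failure"]


@dataclass
class PacemakerModel:
    """Parameterized SAN pacemaker cell: parameter table, resting state, RHS."""

    param_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    y0: np.ndarray = field(default_factory=lambda: DEFAULT_Y0.copy())
    state_names: tuple[str, ...] = STATE_NAMES
    varied_params: tuple[str, ...] = VARIED_PARAMS
    metadata: str = (
        "sanpop reduced mouse SAN myocyte model "
        "(membrane + calcium clock, Hill-type I_KACh)"
    )

    def param_vector(self, params: Optional[Mapping[str, float]] = None) -> np.ndarray:
        table = self.param_table if params is None else params
        return np.array([table[k] for k in PARAM_NAMES])


def apply_condition(
    params: Mapping[str, float], transform: ConditionTransform
) -> dict[str, float]:
    """Return a new parameter map with the condition's effects applied.

    The input map is not modified; untargeted entries are copied unchanged.
    Unknown parameter names raise ``KeyError`` naming the offender.
    """
    out = dict(params)
    for name, kind, value in transform.effects:
        if name not in out:
            raise KeyError(
                f"condition {transform.condition!r} targets unknown parameter {name!r}"
            )
        out[name] = out[name] * value if kind == "scale" else out[name] + value
    if transform.kach_nm > 0.0:
        if "cch_nm" not in out:
            raise KeyError("parameter table lacks 'cch_nm' for carbachol dosing")
        out["cch_nm"] = transform.kach_nm
    return out


def default_transforms() -> dict[str, ConditionTransform]:
    """Baseline/ISO/CCh transforms from the packaged configuration file."""
    return load_model_config()[1]


def load_model_config(path: Optional[str] = None):
    """Load (param_table, transforms) from a YAML config.

    Without ``path`` the packaged default (``data/mouse_san.yaml``) is used.
    The file carries the baseline parameter table (value + units) and the
    ISO/CCh effect lists, keeping the pharmacology auditable configuration
    data rather than code.
    """
    if path is None:
        text = resources.files("sanpop.data").joinpath("mouse_san.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    params = {k: float(v["value"]) for k, v in cfg["parameters"].items()}
    transforms = {"baseline": ConditionTransform("baseline")}
    for cond, spec in cfg.get("conditions", {}).items():
        effects = tuple(
            (e["parameter"], e["kind"], float(e["value"]))
            for e in spec.get("effects", [])
        )
        transforms[cond] = ConditionTransform(
            cond, effects=effects, kach_nm=float(spec.get("kach_nm", 0.0))
        )
    return params, transforms


def default_model() -> PacemakerModel:
    """The default mouse SAN cell with the packaged parameter table."""
    params, _ = load_model_config()
    return PacemakerModel(param_table=params)


def extract_beats(
    time: np.ndarray,
    em_trace: np.ndarray,
    threshold: float = -20.0,
    refractory: float = 0.03,
) -> np.ndarray:
    """Upstroke times: upward threshold crossings with a refractory floor.

    The crossing time is linearly interpolated between samples, so beat
    timing is sub-sample accurate. Traces shorter than 2 samples yield an
    empty result.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(em_trace, dtype=float)
    if t.size != v.size:
        raise ValueError("time and trace must have equal length")
    if t.size < 2:
        return np.empty(0)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    beats = []
    last = -math.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            beats.append(tc)
            last = tc
    return np.asarray(beats)


def simulate(
    model: PacemakerModel,
    scalings: Optional[Mapping[str, float]] = None,
    transform: Optional[ConditionTransform] = None,
    duration: float = 30.0,
    analysis_window: float = 10.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    sample_hz: float = 2000.0,
    beat_threshold: float = -20.0,
    steady_cv: float = 0.02,
    min_beats: int = 3,
) -> SimResult:
    """Integrate the cell and measure terminal firing.

    The stiff initial-value problem starts from the model's stored resting
    state; beats, cycle lengths, rate and the steadiness flag are computed on
    the terminal ``analysis_window`` seconds only. ``steady`` is true when the
    coefficient of variation of the last up-to-10 cycle lengths is below
    ``steady_cv``. Integrator failures are reported through ``status``, never
    raised, so population runs survive individual variants.
    """
    if not duration > analysis_window > 0:
        raise ValueError("require duration > analysis_window > 0")
    params = dict(model.param_table)
    if scalings:
        for name, s in scalings.items():
            if name not in params:
                raise KeyError(f"scaling targets unknown parameter {name!r}")
            if s <= 0:
                raise ValueError(f"scaling for {name!r} must be positive")
            params[name] = params[name] * s
    if transform is not None:
        params = apply_condition(params, transform)
    p = model.param_vector(params)

    t_split = duration - analysis_window
    empty = np.empty(0)

    def _fail() -> SimResult:
        return SimResult(empty, empty, empty, math.nan, empty, False, "integration_failure")

    try:
        y_start = model.y0
        if t_split > 0:
            sol1 = solve_ivp(
                rhs, (0.0, t_split), model.y0, args=(p,),
                method="LSODA", rtol=rtol, atol=atol, dense_output=False,
            )
            if not sol1.success:
                return _fail()
            y_start = sol1.y[:, -1]
        t_eval = np.arange(t_split, duration, 1.0 / sample_hz)
        sol2 = solve_ivp(
            rhs, (t_split, duration), y_start, args=(p,),
            method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol2.success:
            return _fail()
    except Exception:
        return _fail()

    time = sol2.t
    em = sol2.y[0]
    beats = extract_beats(time, em, threshold=beat_threshold)
    if beats.size < max(min_beats, 2):
        return SimResult(time, em, beats, math.nan, empty, False, "no_firing")
    cls_ = np.diff(beats)
    rate = 60.0 / float(cls_.mean())
    tail = cls_[-10:]
    steady = bool(tail.size >= 2 and tail.std(ddof=1) / tail.mean() < steady_cv)
    return SimResult(time, em, beats, rate, cls_, steady, "ok")
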