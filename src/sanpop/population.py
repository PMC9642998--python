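"""Population-of-models screen of sinoatrial pacemaker variants.

The screen follows the standard population-of-models recipe for mapping
parameter-phenotype relationships in cardiac cells:

1. sample multiplicative scaling factors for selected maximal conductances
   and transport rates, one log-normal draw per parameter per variant
   (sigma is the SD of the underlying normal on the log scale);
2. run every variant under baseline, isoproterenol (ISO) and carbachol (CCh)
   conditions and record steady firing rates;
3. discard variants with non-physiological behavior (no firing, integration
   failure, unsteady rhythm, or rate outside broad bounds) in any condition;
4. label the remainder: variants that are slower at baseline, respond more
   strongly to ISO and more weakly to CCh than the nominal (unscaled) cell
   are the sick-sinus-like ("SSS_like") subpopulation; the rest are WT_like;
5. compare the per-parameter scaling distributions of the two groups with
   two-sided Wilcoxon rank-sum tests and boxplot notch intervals.

Per-variant random substreams are derived from (seed, variant id), so results
are independent of execution order and worker count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import stats as _stats
from .model import CONDITIONS, ConditionTransform, PacemakerModel, simulate

__all__ = [
    "PopulationConfig",
    "ScalingVector",
    "VariantRecord",
    "ParameterComparison",
    "GroupComparison",
    "sample_scalings",
    "run_population",
    "filter_physiological",
    "classify",
    "compare_groups",
    "reference_triplet",
    "records_to_frame",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling configuration for the randomized model population."""

    varied_params: tuple[str, ...]
    n_variants: int = 10_000
    sigma: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be at least 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if len(self.varied_params) == 0:
            raise ValueError("varied_params must name at least one parameter")


@dataclass(frozen=True)
class ScalingVector:
    """Per-parameter multiplicative scaling factors of one population member."""

    variant_id: int
    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.factors.values()):
            raise ValueError("scaling factors must be positive")


@dataclass
class VariantRecord:
    """One population member's scalings, rates, status and phenotype label.

    ``delta_iso``/``delta_cch`` are fractional rate changes relative to the
    variant's own baseline rate.
    """

    scalings: ScalingVector
    rate_baseline: float = float("nan")
    rate_iso: float = float("nan")
    rate_cch: float = float("nan")
    delta_iso: float = float("nan")
    delta_cch: float = float("nan")
    status: Literal["ok", "discarded"] = "ok"
    label: Literal["WT_like", "SSS_like", "unlabeled"] = "unlabeled"


@dataclass(frozen=True)
class ParameterComparison:
    """Group contrast for one scaled parameter."""

    parameter: str
    median_wt: float
    median_sss: float
    notch_wt: tuple[float, float]
    notch_sss: tuple[float, float]
    p_value: float
    direction: int  # sign(median_SSS - median_WT)
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """Per-parameter statistics contrasting SSS-like vs WT-like variants."""

    alpha: float
    n_wt: int
    n_sss: int
    parameters: tuple[ParameterComparison, ...]

    def __getitem__(self, parameter: str) -> ParameterComparison:
        for pc in self.parameters:
            if pc.parameter == parameter:
                return pc
        raise KeyError(parameter)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                parameter=pc.parameter,
                median_wt=pc.median_wt,
                median_sss=pc.median_sss,
                notch_wt_lo=pc.notch_wt[0],
                notch_wt_hi=pc.notch_wt[1],
                notch_sss_lo=pc.notch_sss[0],
                notch_sss_hi=pc.notch_sss[1],
                p_value=pc.p_value,
                direction=pc.direction,
                significant=pc.significant,
            )
            for pc in self.parameters
        ]
        return pd.DataFrame(rows)


def variant_rng(seed: int, variant_id: int) -> np.random.Generator:
    """Counter-based substream for one variant: independent of run order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(variant_id,)))


def sample_scalings(config: PopulationConfig) -> list[ScalingVector]:
    """Draw the population's scaling vectors.

    Each factor is exp(eps) with eps ~ Normal(0, sigma), independently per
    parameter per variant; the median factor is 1. Reproducible given the
    seed, with one substream per variant.
    """
    out = []
    for vid in range(config.n_variants):
        rng = variant_rng(config.seed, vid)
        eps = rng.normal(0.0, config.sigma, len(config.varied_params))
        out.append(
            ScalingVector(vid, dict(zip(config.varied_params, np.exp(eps))))
        )
    return out


def _evaluate_ode_variant(
    model: PacemakerModel,
    transforms: Mapping[str, ConditionTransform],
    sv: ScalingVector,
    sim_kwargs: Mapping,
) -> VariantRecord:
    rec = VariantRecord(scalings=sv)
    rates: dict[str, float] = {}
    all_ok = True
    for cond in CONDITIONS:
        res = simulate(model, scalings=sv.factors, transform=transforms[cond], **sim_kwargs)
        if res.status != "ok" or not res.steady:
            all_ok = False
            rates[cond] = float("nan")
        else:
            rates[cond] = res.firing_rate
    rec.rate_baseline = rates["baseline"]
    rec.rate_iso = rates["ISO"]
    rec.rate_cch = rates["CCh"]
    if all_ok:
        rec.delta_iso = (rec.rate_iso - rec.rate_baseline) / rec.rate_baseline
        rec.delta_cch = (rec.rate_cch - rec.rate_baseline) / rec.rate_baseline
    else:
        rec.status = "discarded"
    return rec


def _evaluate_surrogate_variant(model, sv: ScalingVector, seed: int) -> VariantRecord:
    rec = VariantRecord(scalings=sv)
    try:
        rates = model.rates(sv.factors, rng=variant_rng(seed, sv.variant_id))
    except Exception:
        rec.status = "discarded"
        return rec
    rec.rate_baseline = rates["baseline"]
    rec.rate_iso = rates["ISO"]
    rec.rate_cch = rates["CCh"]
    rec.delta_iso = (rec.rate_iso - rec.rate_baseline) / rec.rate_baseline
    rec.delta_cch = (rec.rate_cch - rec.rate_baseline) / rec.rate_baseline
    return rec


def run_population(
    model,
    scalings: Sequence[ScalingVector],
    transforms: Optional[Mapping[str, ConditionTransform]] = None,
    sim_kwargs: Optional[Mapping] = None,
    n_jobs: int = 1,
    noise_seed: int = 0,
) -> list[VariantRecord]:
    """Evaluate every variant under the three autonomic conditions.

    ``model`` is either an ODE :class:`~sanpop.model.PacemakerModel` (with
    ``transforms``) or any object exposing ``rates(scalings, rng)`` such as
    the analytic surrogate. The work is embarrassingly parallel; per-variant
    substreams keep results identical for any ``n_jobs``.
    """
    if isinstance(model, PacemakerModel):
        if transforms is None:
            raise ValueError("ODE population runs need condition transforms")
        kw = dict(sim_kwargs or {})
        jobs = (
            delayed(_evaluate_ode_variant)(model, transforms, sv, kw)
            for sv in scalings
        )
    else:
        jobs = (
            delayed(_evaluate_surrogate_variant)(model, sv, noise_seed)
            for sv in scalings
        )
    return list(Parallel(n_jobs=n_jobs)(jobs))


def filter_physiological(
    records: Sequence[VariantRecord],
    rate_bounds: tuple[float, float] = (60.0, 900.0),
) -> list[VariantRecord]:
    """Mark non-physiological variants as discarded (in place; also returned).

    A variant is discarded when any condition failed (no firing, integration
    failure, unsteady terminal rhythm - already flagged during evaluation) or
    when any of its rates falls outside ``rate_bounds`` bpm.
    """
    lo, hi = rate_bounds
    for rec in records:
        if rec.status == "discarded":
            continue
        rates = (rec.rate_baseline, rec.rate_iso, rec.rate_cch)
        if any(not np.isfinite(r) or not lo <= r <= hi for r in rates):
            rec.status = "discarded"
    return list(records)


def reference_triplet(
    model,
    transforms: Optional[Mapping[str, ConditionTransform]] = None,
    sim_kwargs: Optional[Mapping] = None,
) -> tuple[float, float, float]:
    """(baseline rate, delta_iso, delta_cch) of the nominal unscaled cell."""
    if isinstance(model, PacemakerModel):
        if transforms is None:
            raise ValueError("reference triplet for an ODE model needs transforms")
        kw = dict(sim_kwargs or {})
        rates = {
            c: simulate(model, transform=transforms[c], **kw).firing_rate
            for c in CONDITIONS
        }
    else:
        rates = model.reference_rates()
    base = rates["baseline"]
    return (
        base,
        (rates["ISO"] - base) / base,
        (rates["CCh"] - base) / base,
    )


def classify(
    records: Sequence[VariantRecord],
    reference: tuple[float, float, float],
) -> list[VariantRecord]:
    """Label surviving variants SSS_like or WT_like (in place; also returned).

    SSS_like requires all three, with strict inequalities (ties go WT_like):
    baseline rate below the reference, a larger fractional ISO response, and
    a smaller-magnitude CCh response. Discarded variants stay unlabeled.
    """
    ref_rate, ref_diso, ref_dcch = reference
    if not all(np.isfinite(v) for v in reference):
        raise ValueError("classification reference contains non-finite entries")
    for rec in records:
        if rec.status != "ok":
            rec.label = "unlabeled"
            continue
        sss = (
            rec.rate_baseline < ref_rate
            and rec.delta_iso > ref_diso
            and abs(rec.delta_cch) < abs(ref_dcch)
        )
        rec.label = "SSS_like" if sss else "WT_like"
    return list(records)


def compare_groups(
    records: Sequence[VariantRecord],
    alpha: float = 0.05,
) -> GroupComparison:
    """Contrast parameter scaling distributions of SSS-like vs WT-like groups.

    Per parameter: group medians, notch intervals, two-sided Wilcoxon
    rank-sum p, direction = sign(median_SSS - median_WT), and a significance
    flag at ``alpha``.
    """
    wt = [r for r in records if r.label == "WT_like"]
    sss = [r for r in records if r.label == "SSS_like"]
    if not wt or not sss:
        empty = "WT_like" if not wt else "SSS_like"
        raise ValueError(f"cannot compare groups: {empty} group is empty")
    params = list(wt[0].scalings.factors)
    comparisons = []
    for name in params:
        x_sss = np.array([r.scalings.factors[name] for r in sss])
        x_wt = np.array([r.scalings.factors[name] for r in wt])
        p = _stats.wilcoxon_rank_sum(x_sss, x_wt)
        med_s, med_w = float(np.median(x_sss)), float(np.median(x_wt))
        comparisons.append(
            ParameterComparison(
                parameter=name,
                median_wt=med_w,
                median_sss=med_s,
                notch_wt=_stats.notch_interval(x_wt),
                notch_sss=_stats.notch_interval(x_sss),
                p_value=p,
                direction=int(np.sign(med_s - med_w)),
                significant=bool(p < alpha),
            )
        )
    return GroupComparison(alpha, len(wt), len(sss), tuple(comparisons))


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Flatten variant records to a table: one row per variant."""
    rows = []
    for r in records:
        row = dict(variant_id=r.scalings.variant_id)
        row.update({f"scale_{k}": v for k, v in r.scalings.factors.items()})
        row.update(
            rate_baseline=r.rate_baseline,
            rate_iso=r.rate_iso,
            rate_cch=r.rate_cch,
            delta_iso=r.delta_iso,
            delta_cch=r.delta_cch,
            status=r.status,
            label=r.label,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_manifest(config: PopulationConfig, model_metadata: str) -> str:
    """JSON manifest of a population run (seed, config, model provenance)."""
    return json.dumps(
        dict(
            seed=config.seed,
            n_variants=config.n_variants,
            sigma=config.sigma,
            varied_params=list(config.varied_params),
            model=model_metadata,
        ),
        indent=2,
    )
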