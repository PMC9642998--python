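"""Population sampling, screening, classification and group comparison."""

import numpy as np
import pytest

from sanpop.model import simulate
from sanpop.population import (
    PopulationConfig,
    ScalingVector,
    VariantRecord,
    classify,
    compare_groups,
    filter_physiological,
    reference_triplet,
    run_population,
    sample_scalings,
)
from sanpop.synth import SurrogatePacemaker, SurrogateSpec

PARAMS = ("g_na", "g_cal", "v_ncx")


class TestSampling:
    def test_sigma_zero_gives_unit_factors(self):
        cfg = PopulationConfig(varied_params=PARAMS, n_variants=50, sigma=0.0, seed=1)
        for sv in sample_scalings(cfg):
            assert all(v == 1.0 for v in sv.factors.values())

    def test_seed_reproducibility(self):
        cfg = PopulationConfig(varied_params=PARAMS, n_variants=100, sigma=0.26, seed=5)
        a = sample_scalings(cfg)
        b = sample_scalings(cfg)
        for x, y in zip(a, b):
            assert x.factors == y.factors

    def test_log_sd_matches_sigma_at_scale(self):
        cfg = PopulationConfig(
            varied_params=PARAMS, n_variants=10_000, sigma=0.26, seed=2
        )
        scalings = sample_scalings(cfg)
        for p in PARAMS:
            logs = np.log([sv.factors[p] for sv in scalings])
            assert abs(logs.std(ddof=1) - 0.26) < 0.01
            assert abs(np.median(np.exp(logs)) - 1.0) < 0.02

    def test_empty_varied_params_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(varied_params=(), n_variants=10)

    def test_positive_factor_invariant(self):
        with pytest.raises(ValueError):
            ScalingVector(0, {"g_na": -0.5})


class TestRunPopulation:
    def test_record_count_conserved(self, surrogate_population):
        cfg, records = surrogate_population
        assert len(records) == cfg.n_variants

    def test_surrogate_population_all_ok(self, surrogate_population):
        _, records = surrogate_population
        assert all(r.status == "ok" for r in records)

    def test_worker_count_invariance(self):
        surr = SurrogatePacemaker(SurrogateSpec(noise_sd=0.05))
        cfg = PopulationConfig(varied_params=tuple(surr.varied_params),
                               n_variants=50, sigma=0.26, seed=3)
        scalings = sample_scalings(cfg)
        serial = run_population(surr, scalings, noise_seed=3, n_jobs=1)
        parallel = run_population(surr, scalings, noise_seed=3, n_jobs=2)
        for a, b in zip(serial, parallel):
            assert a.rate_baseline == b.rate_baseline
            assert a.rate_iso == b.rate_iso

    def test_order_independence(self):
        surr = SurrogatePacemaker(SurrogateSpec(noise_sd=0.05))
        cfg = PopulationConfig(varied_params=tuple(surr.varied_params),
                               n_variants=40, sigma=0.26, seed=4)
        scalings = sample_scalings(cfg)
        fwd = {r.scalings.variant_id: r.rate_baseline
               for r in run_population(surr, scalings, noise_seed=4)}
        rev = {r.scalings.variant_id: r.rate_baseline
               for r in run_population(surr, scalings[::-1], noise_seed=4)}
        assert fwd == rev

    def test_ode_single_variant_matches_direct_simulate(self, san_model, transforms):
        sv = ScalingVector(0, {k: 1.0 for k in san_model.varied_params})
        kw = dict(duration=6.0, analysis_window=3.0)
        (rec,) = run_population(san_model, [sv], transforms=transforms, sim_kwargs=kw)
        direct = simulate(san_model, transform=transforms["baseline"], **kw)
        assert rec.rate_baseline == pytest.approx(direct.firing_rate)


class TestFilterAndClassify:
    def make_record(self, vid, base, diso, dcch, status="ok"):
        rec = VariantRecord(ScalingVector(vid, {"g_cal": 1.0}))
        rec.rate_baseline = base
        rec.rate_iso = base * (1 + diso)
        rec.rate_cch = base * (1 + dcch)
        rec.delta_iso = diso
        rec.delta_cch = dcch
        rec.status = status
        return rec

    def test_out_of_bounds_rate_discarded(self):
        recs = [self.make_record(0, 30.0, 0.2, -0.2),
                self.make_record(1, 350.0, 0.2, -0.2)]
        filter_physiological(recs)
        assert [r.status for r in recs] == ["discarded", "ok"]

    def test_nan_rate_discarded(self):
        rec = self.make_record(0, float("nan"), 0.0, 0.0)
        filter_physiological([rec])
        assert rec.status == "discarded"

    def test_partition_counts(self, surrogate_population):
        cfg, records = surrogate_population
        labels = [r.label for r in records]
        n = (labels.count("SSS_like"), labels.count("WT_like"),
             labels.count("unlabeled"))
        assert sum(n) == cfg.n_variants

    def test_strictly_dominating_record_is_sss(self):
        ref = (400.0, 0.20, -0.25)
        rec = self.make_record(0, 350.0, 0.30, -0.10)
        classify([rec], ref)
        assert rec.label == "SSS_like"

    def test_tie_on_any_criterion_goes_wt(self):
        ref = (400.0, 0.20, -0.25)
        rec = self.make_record(0, 400.0, 0.30, -0.10)  # tie on baseline
        classify([rec], ref)
        assert rec.label == "WT_like"

    def test_conjunction_required(self):
        ref = (400.0, 0.20, -0.25)
        rec = self.make_record(0, 350.0, 0.10, -0.10)  # slower but weak ISO
        classify([rec], ref)
        assert rec.label == "WT_like"

    def test_discarded_stay_unlabeled(self):
        rec = self.make_record(0, 350.0, 0.30, -0.10, status="discarded")
        classify([rec], (400.0, 0.20, -0.25))
        assert rec.label == "unlabeled"

    def test_nonfinite_reference_rejected(self):
        with pytest.raises(ValueError):
            classify([], (float("nan"), 0.1, -0.1))


def _group_records(values_by_param, label):
    n = len(next(iter(values_by_param.values())))
    recs = []
    for i in range(n):
        rec = VariantRecord(
            ScalingVector(i, {k: float(v[i]) for k, v in values_by_param.items()})
        )
        rec.status = "ok"
        rec.label = label
        recs.append(rec)
    return recs


class TestCompareGroups:
    def test_constructed_shift_flagged_with_direction(self):
        rng = np.random.default_rng(0)
        wt = _group_records({"g_cal": np.exp(rng.normal(0, 0.26, 300))}, "WT_like")
        sss = _group_records(
            {"g_cal": np.exp(rng.normal(-0.3, 0.26, 300))}, "SSS_like"
        )
        gc = compare_groups(wt + sss)
        pc = gc["g_cal"]
        assert pc.significant and pc.direction == -1

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        flags = 0
        reps = 400
        for _ in range(reps):
            wt = _group_records({"p": np.exp(rng.normal(0, 1, 40))}, "WT_like")
            sss = _group_records({"p": np.exp(rng.normal(0, 1, 40))}, "SSS_like")
            flags += compare_groups(wt + sss)["p"].significant
        assert abs(flags / reps - 0.05) < 0.025

    def test_monotone_alpha(self, surrogate_population):
        _, records = surrogate_population
        strict = {p.parameter for p in compare_groups(records, alpha=0.01).parameters
                  if p.significant}
        loose = {p.parameter for p in compare_groups(records, alpha=0.05).parameters
                 if p.significant}
        assert strict <= loose

    def test_shuffling_changes_nothing(self, surrogate_population):
        _, records = surrogate_population
        rng = np.random.default_rng(1)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = compare_groups(records).to_frame()
        b = compare_groups(shuffled).to_frame()
        assert np.allclose(a["p_value"], b["p_value"])

    def test_empty_group_is_an_error(self):
        recs = _group_records({"p": np.ones(5)}, "WT_like")
        with pytest.raises(ValueError, match="SSS_like"):
            compare_groups(recs)


class TestSelectionShiftOracle:
    """Brute-force enumeration on a gridded noise-free surrogate population."""

    def grid_population(self, surr, n_grid=21):
        from itertools import product

        values = np.exp(np.linspace(-0.5, 0.5, n_grid))
        names = ("g_cal", "g_na", "v_ncx")
        scalings = [
            ScalingVector(i, dict(zip(names, combo)))
            for i, combo in enumerate(product(values, repeat=len(names)))
        ]
        return names, scalings

    def test_pipeline_matches_enumeration_exactly(self):
        spec = SurrogateSpec(noise_sd=0.0)
        surr = SurrogatePacemaker(spec)
        names, scalings = self.grid_population(surr, n_grid=9)
        records = run_population(surr, scalings)
        ref = reference_triplet(surr)
        classify(records, ref)

        # independent closed-form oracle
        def oracle_label(factors):
            logs = {k: np.log(v) for k, v in factors.items()}
            rates = {}
            for cond, base in spec.base_rates.items():
                s = sum(spec.coefficients[k][cond] * logs[k] for k in factors)
                rates[cond] = base * np.exp(s)
            base = rates["baseline"]
            diso = (rates["ISO"] - base) / base
            dcch = (rates["CCh"] - base) / base
            is_sss = (
                base < ref[0] and diso > ref[1] and abs(dcch) < abs(ref[2])
            )
            return "SSS_like" if is_sss else "WT_like"

        for rec in records:
            assert rec.label == oracle_label(rec.scalings.factors)

    def test_slow_selection_shifts_positive_couplings_down(self):
        spec = SurrogateSpec(noise_sd=0.0)
        surr = SurrogatePacemaker(spec)
        names, scalings = self.grid_population(surr, n_grid=13)
        records = run_population(surr, scalings)
        base_ref = spec.base_rates["baseline"]
        slow = [r for r in records if r.rate_baseline < base_ref]
        for name in names:
            coeff = spec.coefficients[name]["baseline"]
            med_all = np.median([r.scalings.factors[name] for r in records])
            med_slow = np.median([r.scalings.factors[name] for r in slow])
            if coeff > 0:
                assert med_slow < med_all
            elif coeff < 0:
                assert med_slow > med_all
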