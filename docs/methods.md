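# Methods

## The pacemaker cell model

`sanpop.model` implements a compact Hodgkin-Huxley-type model of a mouse
sinoatrial-node myocyte, authored for this package as a minimal
membrane-clock + calcium-clock pacemaker. Fourteen state variables: membrane
potential `E_m` (mV) and gates for fast Na+ (`m`, `h`), L-type Ca2+
(`d_L`, `f_L`, plus instantaneous Ca2+-dependent inactivation), T-type Ca2+
(`d_T`, `f_T`), transient-outward K+ (`q`, `r`, with the `r` activation gate
shared by the sustained K+ current), rapid delayed rectifier (`p_k`, with
instantaneous inward rectification), slow delayed rectifier (`n`) and funny
current (`y`); plus free myoplasmic and SR Ca2+ (`cai`, `casr`) coupled by
ryanodine-receptor release and SERCA uptake. Intracellular Na+ and K+ are
clamped (140/8/5.4/140/1.8 mM for Na_o/Na_i/K_o/K_i/Ca_o), a standard
reduction for single-cell automaticity studies. The Na+/Ca2+ exchanger uses
a standard single-energy-barrier formulation and dominates diastolic
depolarization together with the funny current, the T-type window and the
deactivating I_Kr tail.

Assumptions and deliberate simplifications: no pacing stimulus (the model is
autonomous by construction), no Na+/K+ concentration dynamics, a single
myoplasmic Ca2+ pool with rapid-buffering scaling rather than subspace
compartments, and stylized gating kinetics chosen for robustness across the
log-normal parameter variation used by the population screen. The default
cell fires at ~420 bpm with a maximum diastolic potential near −62 mV and an
overshoot near +6 mV — in the range of isolated mouse SAN cells.

### Autonomic pharmacology

Conditions are parameter transforms loaded from `data/mouse_san.yaml`, kept
as configuration so the pharmacology is auditable and editable without code
changes:

* **Isoproterenol (ISO)** — the beta-adrenergic/PKA fingerprint: L-type
  Ca2+ conductance ×1.45, T-type ×1.10, I_Ks ×1.30, Na+/K+ pump ×1.20,
  SERCA ×1.40, a +7 mV depolarizing shift of funny-current activation and a
  −3 mV (hyperpolarizing) shift of Ca2+-channel activation. Net effect on
  the default cell: +21.5% firing rate.
* **Carbachol (CCh)** — engages the acetylcholine-activated K+ current
  through a Hill-type dose dependence (half-activation 125 nM, coefficient
  1.5) with an inwardly rectifying voltage profile. The default modeling
  dose is 300 nM, the same dose used for ex vivo superfused-atria
  pharmacology; it slows the default cell by 14.2%.

### Numerics

`scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-6`, `atol = 1e-8`
(configurable). Simulations start from a stored point on the default cell's
limit cycle (pre-equilibrated for 100 s) and run 30 s by default, with
beats, cycle lengths and rate measured on the terminal 10 s only; tests use
shorter horizons (6–20 s) since the stored state is already periodic. Beats
are upward crossings of −20 mV with sub-sample linear interpolation and a
30 ms refractory floor. `steady` requires the coefficient of variation of
the last ≤10 cycle lengths to be below 2%. Integrator failures and silent
cells are reported as status flags, never exceptions, so population sweeps
survive individual variants; rates are `nan` (never 0-divided) when
undefined.

## The population screen

`sanpop.population` samples one multiplicative scaling factor per varied
parameter per variant, `s = exp(eps)` with `eps ~ N(0, sigma)`. `sigma` is
the SD of the underlying normal on the log scale (so the median factor is
exactly 1); the default is 0.26 with 10,000 variants. Eleven parameters are
varied: `g_na, g_cal, g_cat, g_to, g_sus, g_ks, g_kach, g_bna, g_bca,
v_ryr, v_ncx`. Per-variant RNG substreams derive from `(seed, variant_id)`
via `SeedSequence` spawn keys, so results are invariant to execution order
and worker count (`joblib` parallelism).

Filtering discards a variant when any condition yields no firing, an
integrator failure, an unsteady terminal rhythm, or a rate outside broad
physiological bounds (default 60–900 bpm, configurable; the screen's purpose
is to drop non-physiological cells, not to sculpt the distribution).

Classification labels a surviving variant SSS-like when **all three** hold
strictly against the nominal (unscaled) cell's own triplet: lower baseline
rate, larger fractional ISO response, smaller-magnitude CCh response; ties
go WT-like. The reference is the deterministic default cell rather than a
population statistic — a documented design choice where the alternative
(population medians) would make labels depend on the sampled cohort.
Fractional responses are relative to each variant's own baseline.

Group comparison reports, per parameter: group medians, notch intervals
(see below), two-sided Wilcoxon rank-sum p, direction
`sign(median_SSS − median_WT)` and a significance flag at `alpha = 0.05`.

## Statistics

* `incidence_percent` — 100·k/n with half-up rounding to one decimal,
  matching published table formatting.
* `chi2_2x2` — Pearson chi-square, 1 df, **continuity correction off by
  default**: the zebrafish 1/20-vs-4/10 incidence comparison is significant
  only without Yates correction, so the uncorrected variant is what the
  targeted significance calls used; the correction remains available as a
  flag.
* `ttest_from_summary` — pooled-variance unpaired t from
  (mean, dispersion, n) summaries, df = n_a + n_b − 2; SEM dispersions are
  converted to SD by ×√n. Note a documented source ambiguity: the
  echocardiography table's "±" values reproduce the printed p = 0.0017 only
  when read as SDs, although sibling tables label "±" as SEM. Both kinds
  are supported; the package does not resolve the discrepancy.
* `wilcoxon_rank_sum` — exact enumeration when the smaller sample has ≤10
  observations and the pooled sample is tie-free; otherwise the normal
  approximation with midranks, tie-corrected variance and continuity
  correction. Empirical type-I error at alpha = 0.05 is 0.046–0.051 for
  group sizes 20–30 (checked over 5,000 null pairs in the test suite).
* `notch_interval` — `q50 ± 1.57 (q75 − q25)/sqrt(n)`, an approximate 95%
  confidence band for the median; quartiles use linear interpolation
  between order statistics, fixed so the worked examples are exact.

## Rhythm analytics

All times are seconds from the start of the recording. Sinus-arrest calls
are PP intervals **strictly greater** than the threshold: 1.5 s for
zebrafish; for mouse-like recordings the threshold defaults to 2× the
median PP of the recording (a package convention — the 1.5 s rule is
species-specific). When P fiducials are absent, detection falls back to RR
with a warning. AV-block calls use greedy one-to-one P→R pairing in time
order, where a conducted R must both fall within the PR window (default:
median PR + 4·SD of conducted beats) and precede the next P wave; the rule
is a package convention, since published counts come without an algorithmic
definition. SANRT is the interval from the last paced beat to the first
spontaneous beat strictly after it; cSANRT subtracts the pre-pacing resting
cycle length. Cycle-length variation defaults to the sample SD (n−1) of
successive cycle lengths, with CV as an option. The R-peak detector
band-passes at 0.5–200 Hz (upper edge capped below Nyquist), uses a squared
derivative envelope (polarity invariant), a threshold at a fraction of the
98th envelope percentile, and a refractory lockout.

## Synthetic data and what passing tests mean

`sanpop.synth` generates beat trains from cumulative cycle lengths
(60/HR + Gaussian jitter) with pauses added to specified cycles and
ventricular responses dropped at specified beats, emitting every injected
event as machine-readable ground truth; ECG waveforms are stylized Gaussian
P/QRS/T deflections plus white noise, sufficient for exercising the
detector, not for emulating electrode noise spectra or real morphology.
The surrogate pacemaker makes log firing rate an exactly known linear
function of log scalings; its coefficient signs mirror the parameter-shift
directions the ODE screen is expected to produce (positive baseline-rate
coupling for `g_cal`, `g_na`, `v_ryr` and the backgrounds; negative for
`v_ncx`, `g_cat`, `g_ks`; a CCh-specific negative coupling for `g_kach`),
while the magnitudes are order-of-magnitude plausible and otherwise
arbitrary and documented as such. Detector tests on separable trains
(jitter ≤5% of CL, pauses ≥2× CL) therefore demonstrate algorithmic
correctness, not performance on noisy recordings; population tests on the
surrogate demonstrate pipeline correctness (partition, order-invariance,
selection-induced median shifts verified against brute-force enumeration),
not ODE-level biophysics, which is covered separately at single-variant
scale.

## Problem sizes

The statistics and rhythm examples run in milliseconds. The default-cell
condition triplet is three stiff 30 s integrations (~12 s total). The
full-size 10,000-variant screen is run through the analytic surrogate; an
ODE screen at that scale is ~30,000 stiff simulations — a parallel
cluster-scale computation that the package supports through the same
`run_population` interface (`n_jobs`, order-invariant substreams) but is
not part of the routine test or reproduction runs. Published subgroup
counts from such screens are sensitive to the sampling seed and to the
exact classification-reference convention, so the reproduction tracks the
partition structure (a WT-like large majority with a non-empty SSS-like
minority) and the parameter-shift directions rather than exact counts.

## Known limitations

* The ODE model is a reduced formulation; absolute conductance values are
  tuned for mouse-like behavior rather than fitted to voltage-clamp data,
  and Na+/K+ accumulation, subspace Ca2+ gradients and stochastic channel
  gating are out of scope.
* CCh effects are confined to the acetylcholine-activated K+ current; the
  muscarinic shifts of I_f and I_CaL are not modeled, which makes the CCh
  slowing conservative.
* QT/QRS measures require onset/offset/T-end fiducials and are never
  inferred from R peaks alone.
* No frequency-domain heart-rate-variability analysis, no clinical ECG
  delineation, and no tissue-level (2-D) simulation.
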