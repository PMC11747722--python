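# Methods

## The experiment being modelled

A two-sequence crossover in 12 anesthetized pigs with healthy lungs and normal
ICP. Each animal is ventilated through a PEEP staircase (5, 10, 15, 20, back
to 5 cmH₂O; 20 min per level; volume control, VT 7.5 mL/kg, I:E 1:2, 20%
end-inspiratory pause) in two position blocks — prone and supine, order
randomized per animal by lot — separated by a washout at baseline settings.
Multimodal monitoring yields arterial, central venous, intracranial, airway
and esophageal pressures plus flow/volume; occlusion holds at each level give
the respiratory-mechanics inputs.

## Synthetic physiology

The generator is phenomenological: it reproduces the statistical structure the
analysis assumes, not organ-level dynamics (no Windkessel or heart–lung ODEs,
no thermodilution or blood-gas physics).

**Slow waves and reactivity.** Two independent standardized processes
`z_abp(t)` and `z_ind(t)` are each a sum of 4 sinusoids with frequencies drawn
uniformly from 0.005–0.05 Hz (the band the pressure reactivity index responds
to) and random phases. ABP adds `abp_slow_sd · z_abp` (default 2.5 mmHg) to a
85 mmHg mean with a 15 mmHg cardiac component (96 bpm) and a small respiratory
component. The slow part of ICP is
`icp_slow_sd · (g·z_abp + sqrt(1−g²)·z_ind)`, so the population correlation
between slow ABP and slow ICP is exactly the reactivity coefficient `g`, and
PRx ≈ g in the noise-free limit. Intact autoregulation is `g ≤ 0`; the default
`g ~ N(−0.12, 0.20)` (clipped to [−1, 1]) matches a healthy baseline PRx of
about −0.13.

**ICP level.** Per-animal baseline ICP ~ N(6, 3²) mmHg (prone reference), a
+5 mmHg supine offset (in pigs the frontal ICP probe reads higher supine), and
a PEEP effect `slope · (PEEP − 5)/5` with population slope 1.0 mmHg per
5 cmH₂O — the magnitude class reported for healthy-lung animals. The
animal-specific slope is modified by baseline covariates (see below) plus a
residual N(0, 0.35²).

**Pulse amplitude and compensatory reserve.** The ICP pulse amplitude follows
`AMP = a₀ + a₁·max(ICP − threshold, 0)` with a₀ = 1 mmHg, a₁ = 0.12 per mmHg,
threshold 15 mmHg. Below the threshold AMP is flat (RAP windows are degenerate
or near 0 — ample compensatory reserve); above it AMP rises linearly with ICP
and RAP → 1, reproducing the exhausted-reserve interpretation.

**Ventilator channels and holds.** Volume is a per-breath ramp–pause–
exponential; `Paw = PEEP + E_rs·V + R_aw·flow⁺`, `Pes = Pes_ee(PEEP) +
E_cw·V + R_cw·flow⁺`, with per-animal elastances E_cw ~ N(19, 4²) and
E_l ~ N(33, 6²) cmH₂O/L (baseline-table magnitudes) and a pleural PEEP
transmission fraction of 0.35. Hold measurements are generated directly from
the same parameters, so that before measurement noise
`Paw_ei − PEEPtot = VT·E_rs` and `Pes_ei − Pes_ee = VT·E_cw` hold exactly —
this is what makes noise-free elastance recovery a machine-precision identity.

**Covariate effect structure.** The PEEP→ICP slope depends on the deviation of
five baseline covariates from their cohort means: +0.06 per mmHg baseline ICP,
+0.15 per mmHg CVP, −0.03 per cmH₂O/L E_rs, −0.15 per cmH₂O TPP_ei, −0.12 per
cmH₂O TPP_ee. These slopes are free parameters chosen once so the induced
marginal correlations with ΔICP fall in the weak range (|r| ≈ 0.2–0.4)
reported for this preparation. At n = 12 animals such weak effects are
recoverable in sign only ~75–90% of the time — a power limit of the design.
Recovery tests therefore inject one identifiable effect at a time (e.g. CVP
+0.25, or E_rs −0.06, with the others zeroed), because chance collinearity
among covariates across 12 animals can flip a marginal sign when several
effects compete.

**Two generators, one parameter draw.** `simulate_animal` produces full
waveforms; `simulate_summary_table` draws the same per-animal parameters and
emits per-period study-table rows directly, adding N(0, 0.35²) mmHg summary
noise per period. The fast path exists for repeated-run calibration and power
studies; it shares the effect structure but not waveform-level noise details.

**What the generator does not emulate.** Real ABP/ICP waveform morphology,
nonstationary slow-wave power, respiratory ICP modulation, measurement drift,
hemodynamic reactions to PEEP (beyond linear CVP/PAP/CO trends), and
pathological states. Passing tests demonstrate that the *pipeline* recovers
known structure, not that the simulated signals are clinically realistic.

## Trend processing

Channels are downsampled to 0.1 Hz by 10-s non-overlapping averages; a block
needs ≥ 50% valid raw samples. Threshold rejection is applied to block values
(ICP outside [−10, 60] mmHg; CPP = ABP − ICP outside [0, 150] mmHg rejects the
ICP block too), matching a workflow where thresholds are listed under the
downsampling step; raw-sample-level thresholding is available via
`artifact_level="raw"`. Because thresholds act on block means, "exact"
mask-recovery holds for block-aligned artifact intervals; a short spike inside
an otherwise clean block may survive averaging.

AMP is estimated per block by joint least squares onto
{1, t, cos 2πf_c t, sin 2πf_c t}: the linear term keeps slow drift out of the
cardiac component, and a pure sinusoid of amplitude A returns exactly 2A
(peak-to-peak convention). The cardiac frequency comes from the configuration
or from the strongest ABP spectral peak in 0.5–5 Hz. A per-beat peak-to-peak
median is available as `amp_method="beat"`.

PRx/RAP: Pearson r over the trailing 30-block (5-min) window, updated every
minute, first value 300 s after start. Windows need ≥ 24/30 jointly valid
pairs and nonzero variance on both sides; z = atanh(r) with |r| clamped at
0.99 to keep z finite. Period summaries average indices on the z scale using
only windows lying entirely inside the period (no cross-boundary
contamination) and report both mean z and tanh(mean z). Change-from-baseline
columns are taken against the first PEEP-5 period of the same position block.

Choosing tanh(mean z) as the tabled reactivity value is a deliberate
resolution of an ambiguity: published tables print PRx on the r scale while
stating that Fisher transformation preceded analysis; both scales are exposed.

## Statistics

All tests use α = 0.05, no multiple-comparison correction.

* **Crossover assumptions.** Mixed model
  `Δoutcome ~ C(PEEP) + sequence + period + C(PEEP):sequence` with a random
  intercept per animal and a position-within-animal variance component
  (position as a crossed 2-level random factor is not estimable; this is the
  documented substitute). Carry-over is the joint Wald F on the interaction
  block with **between-within denominator df** (animals − sequence groups):
  the carry-over contrast compares response profiles between sequence groups,
  for which the animal is the experimental unit; with residual df the Wald
  test is measurably anticonservative at n = 12 (no Kenward–Roger correction
  is available in the stack). Model fitting degrades gracefully (drop variance
  component → drop random intercept → OLS) when variance estimates hit the
  boundary. A paired two-tailed t-test compares the two blocks' baselines.
* **Baseline comparisons** use first-block baselines only; Shapiro–Wilk per
  group (n ≥ 3) selects Welch t-test vs Mann–Whitney; summaries are mean ± SD
  or median (IQR) accordingly.
* **Two-way ANOVA** (PEEP × position) is the plain fixed-effects
  decomposition (type II) on the change scores, as in the original strategy.
  Note that change scores within a block share the baseline estimate, which
  makes the interaction F conservative on Δ data; its type-I calibration is
  therefore assessed on data satisfying the exchangeability assumption.
* **Repeated-measures ANOVA** pools positions by averaging each animal's two
  blocks per PEEP level; classical within-subject F, sphericity assumed (no
  Greenhouse–Geisser), since the original analysis reports plain ANOVA.
* **Exploratory screen**: per covariate, `ΔICP ~ baseline covariate` with
  animal random intercept (REML, default optimizer — L-BFGS demonstrably
  misconverges on these small problems) reporting the slope and Wald p, plus
  the marginal Pearson r on pooled per-period rows. Both are reported because
  the derivation of published r values is ambiguous.

Estimation defaults: REML throughout; Wald (z) p-values for single
coefficients; the carry-over F as above.

## Problem sizes, tolerances, numerical choices

* Tests and the acceptance script sample at 32 Hz: ≥ 20× the cardiac
  frequency, integer samples per 10-s block, and an integer number of cardiac
  cycles per block at 96 bpm (so pulse components average out exactly).
  Defaults remain 100 Hz / 20-min periods.
* PRx-vs-g recovery uses 60-min single-level periods: a 5-min window over a
  0.005–0.05 Hz band has only ~13 effective degrees of freedom, so single
  windows scatter by ~0.25; averaging ~2 h of windows brings the estimate
  within 0.1 of g. Null-calibration checks use 200 seeded replicates and the
  binomial 95% band around 5%.
* Degenerate inputs: zero-variance windows are flagged invalid rather than
  producing NaN correlations; constant covariates are skipped with a warning;
  identical paired baselines flag the carry-over t-test as degenerate;
  constant ANOVA outcomes return F = 0, p = 1.
* Elapsed-seconds time convention; period intervals are half-open [start,
  end); CSV dialect fixed (comma, dot decimal, UTF-8); CSV reads use
  round-trip float parsing so write/read is lossless at float64.

## Known limitations

* The carry-over df rule and the z-based single-coefficient p-values are
  pragmatic small-sample choices, not exact finite-sample inference.
* The plain two-way ANOVA inherits the conservativeness of change-score data;
  a mixed-model alternative is the primary inference path.
* AMP's spectral definition uses only the fundamental cardiac component;
  waveform-morphology metrics (e.g. harmonic content) are out of scope.
* The generator's defaults aim at one specific healthy-lung preparation;
  nothing here validates transfer to injured-lung or raised-ICP states.
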