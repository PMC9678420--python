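# Methods

## The system and the models

Electrical field stimulation (EFS) of an isolated detrusor strip evokes
neurotransmitter release from intramural parasympathetic nerves: ATP
acting on P2X receptors carries the contraction at low stimulation
frequencies (≲ 4 Hz), ACh at muscarinic receptors carries it at high
frequencies.  The package models the frequency dependence of tension and
of ATP release as the sum of two saturating Hill-type components with a
shared steepness exponent `m`, ACh release as a single component, and
the percentage reduction of tension by an intervention as a sigmoid
interpolating between low- and high-frequency plateaus
`T(f) = T_Lf − (T_Lf − T_Hf)·f^m/(k^m + f^m)`.  The reduction model is
written in this interpolating form because its parameters then mean
exactly what they are called: the curve equals `T_Lf` at `f = 0`, tends
to `T_Hf` as `f → ∞`, and passes through their midpoint at `f = k` for
any `m`.  All three models are zero at zero frequency and monotone in
frequency; composite parameters are `T_max` (sum of the component
amplitudes) and `f_1/2` (frequency at `T_max/2`, obtained by bracketed
root finding on [10⁻³, 10⁴] Hz to 10⁻⁶ relative tolerance — the curve is
strictly increasing, so the root is unique).

## Fitting

All fits are bounded nonlinear least squares solved with scipy's
trust-region reflective algorithm (the bounded analogue of
Levenberg–Marquardt damping) from a deterministic, data-driven set of up
to 20 starting points (amplitudes from the observed maximum,
half-frequencies from the frequency percentiles, exponents from
{0.5, 1, 2, 4}; the grid is padded with seeded uniform draws).  The
two-component search is additionally seeded at the one-component
optimum with zero high-frequency amplitude, which guarantees the
nested-model ordering `SSE₂ ≤ SSE₁` on any data set.  Identical data and
options give bit-identical results.

Three numerical constraints stabilise the five-parameter fit, which is
otherwise ill-conditioned on an 8-point grid:

- **Component boxes.** The low-frequency (purinergic) half-frequency is
  confined below 4 Hz and the high-frequency (cholinergic) one above it.
  Four hertz is the frequency divide between ATP-dominated and
  ACh-dominated responses; without the split, measurement noise lets the
  two components merge or swap roles, and the derived `f_1/2` becomes
  multimodal across refits.
- **No-extrapolation cap.** Half-frequencies may not exceed the highest
  stimulated frequency.  The stimulation protocol is designed to reach
  the response plateau; a component whose own half-maximum lies beyond
  the tested range makes `T_max` (and hence `f_1/2`) an uncontrolled
  extrapolation.  Amplitudes are bounded by ten times the largest
  observed value and exponents by [0.2, 10].
- **Boundary flags.** A solution pinned at the component split, the
  extrapolation cap, or an exponent bound is flagged `at_bounds`.  Such
  fits are genuine least-squares optima for their noise draw (multistart
  does not escape them — they are global), but their derived parameters
  are unreliable; the cohort pipeline excludes those pairs from the
  derived-parameter comparisons and reports the reduced `n`.

### Paired joint fits

For the paired design — the same preparation measured under control and
intervention — tension and ATP curves are fitted jointly for the two
conditions with shared `(f*_Lf, f*_Hf, m)` and per-condition amplitudes
(the shared-parameter "global fit" of pharmacological curve analysis).
The shape of a preparation's frequency-response curve is a property of
its innervation and muscle; the interventions modelled here act on
component amplitudes.  Sharing the shape parameters roughly halves the
effective parameter count per curve and determines the paired change of
`T_max` and `f_1/2` far more precisely than two independent fits, whose
five-parameter optima have a heavy-tailed error distribution at
realistic noise (independent fits detected the adenosine `f_1/2` shift
in only a quarter of simulated cohorts; joint fits with boundary
exclusion detect it in essentially all).  Independent single-curve fits
remain available (`fit_two_component`) and are used for ACh, for model
selection, and wherever no pairing exists.

Model selection between the nested one- and two-component fits uses the
extra-sum-of-squares F-test,
`F = ((SSE₁−SSE₂)/(p₂−p₁)) / (SSE₂/(n−p₂))`, two-component preferred at
p < 0.05.  The selection is conservative when amplitudes sit at the
non-negativity boundary; its type-I rate is verified by simulation in
the acceptance suite.

## Assay calibration

ATP luminescence is calibrated by least squares in log10–log10 space
(the transform linearises the luciferin-luciferase response over the
100 fM–1 µM working range); choline fluorescence by an ordinary linear
line.  Inverting a signal below the 100 fM ATP detection limit returns
the limit with a `below_detection` flag — flooring, not discarding, so
that low-frequency samples remain usable, and flagged rather than
silent.  ACh is total minus free choline; negative estimates (assay
noise) are kept and flagged, never clamped, to keep cohort averages
unbiased.  Net nerve-mediated release is (during-EFS − pre-EFS)/weight.
Percentage reductions are computed per preparation and then averaged;
the alternative (ratio of cohort means) is a different number whenever
preparations differ in magnitude, and the per-preparation convention is
what paired tests require.

## Synthetic cohorts

The generator emulates the paired study design: each preparation owns a
wet weight (log-normal, mean 10 mg, CV 20%) and true tension, ATP and
ACh curves; the same preparation is "measured" under control and
intervention at every grid frequency with additive Gaussian noise of SD
= 10% of the true value (so a nerve-blocked zero signal stays exactly
zero).  The default grid {1, 2, 4, 8, 12, 16, 20, 40} Hz spans the
experimental 1–40 Hz range with enough interior points to identify the
five-parameter model.

Population means are anchored to the cohort summaries the analysis is
meant to recover: control `T_max` = 2.2 mN·mg⁻¹ with `f_1/2` = 5.1 Hz
and `f*_Lf` = 0.7 Hz (tension: amplitudes 0.8 + 1.4, `f*_Hf` solved as
9.469 Hz, m = 2); ATP release 73.6 fmol·µL⁻¹·mg⁻¹ at 8 Hz (60 + 41.5,
half-frequencies 0.7 and 10 Hz, m = 1); ACh release 140 fmol·µL⁻¹·mg⁻¹
at 20 Hz and under 5% of maximum at 2 Hz (y_max 154.2, f_1/2 8 Hz,
m = 2.5).  The tension amplitude split places the half-crossing on the
rising cholinergic limb: a crossing on the inter-limb plateau would make
`f_1/2` ill-determined, which the narrow cohort spread of `f_1/2`
(≈ 25% CV against ≈ 30% for `T_max`) rules out.

Between-preparation variation is structured, not one blanket CV: a
common responsiveness factor per curve (log-normal, CV 30%) scales both
component amplitudes together — whole-tissue excitability — with
smaller component-ratio jitter (CV 10%) and half-frequency jitter
(CV 20%).  This reproduces the observed pattern in which `T_max`
disperses more than `f_1/2`; independent per-parameter draws at 30%
would quadruple the `f_1/2` spread.

Interventions are multiplicative on component amplitudes only;
half-frequencies are never touched.  Presets encode the cohort-level
effect sizes: adenosine scales the purinergic tension limb by 0.70 and
ATP release by 0.66; CPA, NECA, the PKA inhibitor cAMPS-Rp and
forskolin scale analogously (0.49/0.56, 0.31/0.48, 0.54/0.645,
0.38/1.0); the A1 antagonist DPCPX alone or with adenosine has no
effect; TTX zeroes everything; ACh is never affected except by nerve
block.  When the purinergic limb is suppressed, the cholinergic
amplitude is scaled up so that the population `T_max` is conserved
(`y_hf ← y_hf + (1−s)·y_lf`).  This encodes the cholinergic ceiling
seen in tissue — high-frequency contractions are unaffected even when
low-frequency ones fall by a third — and is what makes the generated
data reproduce the empirical signature "T_max unchanged, f_1/2
increased" rather than a spurious fall in `T_max`.

What the generator does **not** emulate: time-dependent drift and
run-down, train-to-train variability within a frequency, nonlinear
summation of the two transmitter systems at the muscle (the generated
curves are exactly additive), baseline-tension effects (forskolin's
direct muscle action), and any within-preparation correlation of noise
across frequencies.  Passing tests therefore demonstrate that the
analysis chain recovers what it assumes — paired, amplitude-scaled,
proportional-noise data — not that it is robust to every failure mode of
real organ-bath recordings.

## Statistics

Paired comparisons use Student's paired t-test computed in closed form;
the repeated-measures one-way ANOVA partitions sums of squares into
condition, subject and error terms from first principles (no sphericity
correction — condition counts are small), with Holm-adjusted paired-t
post hocs against the reference condition.  Holm was chosen over
Bonferroni as uniformly at least as powerful at the same family-wise
guarantee.  Pearson correlations use the t-transform p-value.  The
sample-size routine iterates exact noncentral-t power for a two-sided
paired design from the minimum analyzable n of 2 upward.  All tests are
two-sided at α = 0.05 unless configured otherwise.

In cohort tables, tension and ATP intervention effects are reported as
per-preparation percentage reductions averaged over the 1 and 2 Hz
points (where the purinergic component carries ≳ 95% of the response);
ACh effects are reported at 20 Hz, and marked "not recorded" when the
20 Hz point is absent.  Chained conditions are compared against the
immediately preceding condition; with three or more conditions the
repeated-measures ANOVA with Holm post hocs is run alongside.

## Problem sizes and reproducibility

Simulated cohorts use n = 12 preparations for the adenosine arm and
n = 6 elsewhere, matching the study design; the acceptance suite uses
20 seeded replicates for cohort-level properties, 200 simulations for
model-selection calibration and 2000 for t-test calibration.  One global
seed drives a per-preparation substream (`numpy` `SeedSequence.spawn`),
so cohorts of different sizes share their first preparations and every
table is bit-reproducible for a fixed seed.  Run records log the full
configuration and seed; identical CLI invocations produce byte-identical
CSVs.

## Known limitations

- The two-component decomposition is phenomenological; it does not
  model receptor kinetics, vesicle pools, or the nonlinear interaction
  of the two transmitter systems at the muscle.
- Derived parameters from boundary-pinned fits are excluded rather than
  re-estimated; with very noisy data this can shrink the effective n of
  derived-parameter comparisons (the exclusion count is reported).
- The error model (proportional Gaussian) is a stand-in for an unstated
  experimental error structure; sensitivity to it has not been mapped
  beyond the defaults.
- Weighted least squares, profile-likelihood confidence intervals and
  Bayesian fitting are out of scope.
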