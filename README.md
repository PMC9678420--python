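# detrusorfit

Quantitative analysis of purinergic/cholinergic cotransmission at the
bladder neuromuscular junction.

Nerve-mediated contractions of detrusor smooth muscle are driven by two
cotransmitters released from parasympathetic terminals: ATP, which
dominates at low stimulation frequencies, and acetylcholine (ACh), which
dominates at high frequencies.  Interventions acting on presynaptic
adenosine A1 receptors and the downstream cAMP/PKA pathway suppress ATP
release — and with it the low-frequency part of the contraction — while
leaving ACh release intact.  This package implements the analysis chain
used to quantify that selectivity: curve decomposition, assay
calibration, paired cohort statistics, and a synthetic-cohort generator
that emulates the paired experimental design so the whole chain is
testable end to end.

## Models

Tension or ATP release versus stimulation frequency *f* (Hz) is the sum
of two saturating Hill-type components,

    Y(f) = Y_Lf,max · f^m / (f*_Lf^m + f^m)  +  Y_Hf,max · f^m / (f*_Hf^m + f^m)

with component amplitudes `Y_Lf,max`, `Y_Hf,max`, component
half-frequencies `f*_Lf ≤ f*_Hf`, and a shared steepness exponent `m`.
Derived summaries are `T_max = Y_Lf,max + Y_Hf,max` and `f_1/2`, the
frequency at which the curve reaches `T_max/2`.  ACh release follows a
single component,

    [ACh](f) = Y_max · f^m / (f_1/2^m + f^m)

and the percentage reduction of tension by an intervention follows

    T(f) = T_Lf − (T_Lf − T_Hf) · f^m / (k^m + f^m)

interpolating between a low-frequency plateau `T_Lf` and a
high-frequency plateau `T_Hf` with half-transition at `k`.

Fits are bounded multi-start least squares (trust-region reflective,
the bounded analogue of Levenberg–Marquardt).  For paired
control/intervention curves of the same preparation the two conditions
are fitted jointly with shared `(f*_Lf, f*_Hf, m)` and per-condition
amplitudes.  One- versus two-component selection uses the
extra-sum-of-squares F-test.  Release assays are calibrated with a
log10–log10 luminescence line for ATP (100 fM detection limit, flagged
flooring) and a linear fluorescence line for choline; ACh is total minus
free choline, and net release is the during-EFS minus pre-EFS
concentration difference normalised to preparation weight.

## Worked example

```bash
detrusorfit simulate --preset adenosine --n 12 --seed 1 --out-dir sim
detrusorfit analyze --tension sim/tension.csv --release sim/release.csv --out-dir out
detrusorfit report --run-dir out
```

prints (seed 1):

```
Force-frequency curve parameters (T_max mN·mg⁻¹, f_1/2 Hz)
  adenosine          vs control    n=12  T_max 2.16 ± 0.80 (p=0.972)  f_1/2 7.8 ± 2.9 (p=0.0130)
Percentage reductions (tension/ATP at 1-2 Hz, ACh at 20 Hz)
  adenosine          tension 24.5 ± 10.2 (p=0.0000)  ATP 35.9 ± 5.9 (p=0.0000)  ACh -2.7 ± 11.9 (p=0.516)
```

Reading: adenosine leaves the maximal tension `T_max` unchanged
(p = 0.97) but shifts the half-maximal frequency `f_1/2` upward
(p = 0.013) — the fingerprint of a selective low-frequency suppression.
The same cohort shows tension and ATP release falling together at 1–2 Hz
(both p < 0.001) while ACh release at 20 Hz is untouched.

The numbered scripts under `analysis/` run the same pipeline as a
narrative sequence — simulation of all intervention presets, curve
fitting, assay calibration, the intervention tables, and the pooled
tension-versus-ATP reduction correlation (r ≈ 0.97 across adenosine,
CPA, NECA, cAMPS-Rp and DPCPX cohorts) — writing their outputs under
`results/`.

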