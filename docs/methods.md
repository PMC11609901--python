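# Methods

`isoreduce` reduces raw triple stable isotope runs — δ²H, δ¹³C and δ¹⁸O
measured in a single high-temperature conversion (HTC) analysis of
carbohydrates or bulk organic matter — from per-analysis instrument deltas
to calibrated values on the VSMOW (H, O) and VPDB (C) scales, including
the correction for exchangeable hydrogen that makes δ²H of organics
interpretable. This note records the model, the conventions the package
commits to, and what the bundled simulator does and does not emulate.

## The measurement model

A run is an ordered sequence of analyses: an opening block of calibration
standards (plus a quality-control standard), samples with a QC analysis
every ~12 positions, and a closing standard block. Each analysis yields
raw permil deltas per isotope channel. The package models four instrument
effects on top of the true values, and removes them in the inverse order
of their physical action:

1. **Exchange mixing (δ²H).** Hydroxyl-bound hydrogen equilibrates with
   the equilibration water vapor. The measured equilibrated delta is the
   two-pool mixture
   `δ2H_e = (1 − x_e)·δ2H_ne + x_e·(α·δ2H_w + 1000·(α − 1))`,
   with `x_e` the exchangeable fraction and `α = α_e−w` the equilibrium
   fractionation factor between exchangeable H and water.
2. **Reactor-carbon mixing (δ¹³C, glassy-carbon reactor).** A roughly
   constant fraction `f ≈ 0.15` of the CO carbon comes from the reactor
   and its filling rather than the sample:
   `δ13C_raw = (1 − f)·δ13C_sample + f·δ13C_reactor`. Because this is
   affine with constant coefficients, it is absorbed — and corrected — by
   the two-point calibration; the fitted gain implies `f = 1 − 1/gain`.
3. **Linear drift** in run position.
4. **Memory**: a small fraction of the previous analysis's signal carries
   over into the current one.

A chromium-filled reactor binds sample oxygen as Cr₂O₃; no CO is formed,
so such runs carry δ²H only. Chromium also scavenges nitrogen, which in a
glassy-carbon reactor can divert hydrogen into HCN and bias δ²H of
N-rich materials — the package flags this (see *Interference flags*).

## Correction pipeline

Per isotope channel, in fixed order: **memory → drift → two-point scale
calibration**, then for δ²H the **exchange correction**. Memory and drift
act on the measured sequence and must precede the affine scale map; the
exchange algebra is written in VSMOW-scale water deltas and therefore
operates on calibrated values.

**Memory correction** uses the first-order difference form
`corrected_i = measured_i + m·(measured_i − measured_{i−1})`, first
element unchanged. The memory fraction `m` is fitted per isotope by grid
search over 0–5% in 0.1% steps (typical instruments sit at 1–3%),
minimising the pooled within-material standard deviation of the
standard-role analyses; ties break toward smaller `m`. The grid objective
removes a provisional drift estimate before computing the scatter —
otherwise a genuine drift of ~0.01 ‰/position biases the fitted memory by
several grid steps. The pipeline applies the correction exactly once; the
operation is deliberately not idempotent.

**Drift** is estimated as a linear-in-position slope from the difference
between end-block and start-block means of each standard material
analysed in both blocks, averaged across materials. It is applied only
when |slope| exceeds a gate (default 0.005 ‰/position), since drift
correction is only warranted "if necessary"; below the gate the series is
passed through and the run report notes "no drift applied". With 3 ‰
noise on δ²H the slope estimate itself scatters by ~0.02 ‰/position, so
spurious small corrections on quiet runs are expected and harmless — they
add variance well below the analytical noise.

**Two-point calibration** maps per-material mean measured values (QC and
pre-steady-state analyses excluded) onto expected values by an affine
least-squares line — exact with two standards. For δ¹³C and δ¹⁸O the
expected value is the certified value. For δ²H the certified values refer
to the nonexchangeable pool while the instrument sees equilibrated
material, and the map between the two scales is material-specific through
`x_e`; the package therefore calibrates δ²H against each standard's
*expected equilibrated* value (forward two-pool mixing of its certified
δ2H_ne with the run's water at its registered `x_e`) and then applies the
exchange correction uniformly to all calibrated records. This keeps the
hydrogen calibration well defined, is exact at zero noise, and leaves the
two-water `x_e` estimate computable from the calibrated equilibrated
deltas of any material measured in two runs.

**Exchange correction.** With a known `x_e`,
`δ2H_ne = (δ2H_e − x_e·α·δ2H_w − 1000·x_e·(α − 1)) / (1 − x_e)`.
With two equilibration waters, `x_e = (δ2H_e1 − δ2H_e2) /
(α·(δ2H_w1 − δ2H_w2))` per material. Estimates outside [0, 1) are
returned unclamped and flagged rather than truncated or raised, so batch
reduction completes. Defaults: `α = 1.082` for all carbohydrates
(exchangeable H sits on hydroxyl groups in all of them; the factor should
be revisited for compounds with other functional groups — it is a
per-call parameter). Class-default exchange fractions when only one
equilibration exists: cellulose 0.20, wood 0.15, sugar 0.36; a
material-specific registry value takes precedence, an explicit per-run
override takes precedence over both. Polyethylene foil does not exchange
(`x_e = 0`).

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `alpha_ew` | – | 1.082 | equilibrium fractionation, carbohydrate OH vs water |
| class `x_e` | – | 0.20 / 0.15 / 0.36 | typical cellulose / wood / sugar values |
| memory grid | – | 0–0.05 step 0.001 | instruments typically show 1–3% |
| drift gate | ‰/position | 0.005 | correct only when clearly present |
| noise SD | ‰ | 3.0 / 0.2 / 0.3 (H/C/O) | typical triple-analysis precision |
| reactor fraction `f` | – | 0.15 | typical glassy-carbon CO contribution |
| reactor δ¹³C | ‰ | −25 | typical glassy carbon |
| steady-state window | min | 120 | cellulose equilibration loss on an argon hood |
| QC interval | analyses | 12 | one QC per ~12 samples |

Equilibration waters default to δ²H = −160 ‰ and −412 ‰ (±1 ‰), an
isotopically distant pair that conditions the two-water estimator well.

## The synthetic-run generator

`simulate.generate_run` produces raw runs with known truth: standard
blocks of four calibration materials × 3 replicates plus 3 QC replicates
(materials chosen to span ≥50 ‰ in δ²H and ≥5 ‰ in δ¹³C/δ¹⁸O), samples
with interleaved QC, and the four effects above applied in physical
order. Everything is driven by one seeded NumPy generator; runs are
reproducible from `(config, seed)` and the seed is embedded in the output.

Conventions worth stating explicitly:

* **Memory form.** The generator carries over a fraction of the previous
  *measured* signal, parameterised as
  `measured_i = (value_i + m·measured_{i−1})/(1 + m)` (carry fraction
  `m/(1+m)`). This recursive form is the exact conjugate of the
  difference-form correction with the same `m`: the standard correction
  inverts it identically, so noise-free closure tests are exact rather
  than first-order, and the fitted `m` estimates the same quantity the
  correction consumes.
* **Noise semantics.** `noise_sd` is the precision of the final
  *calibrated* value — the scale on which instrument precision is quoted.
  Internally the injection on the raw scale is divided by the expected
  calibration gain (for δ¹³C, multiplied by `1 − f`), so reduced QC
  standard deviations reproduce the configured values rather than
  `σ/(1−f)`.
* **Sample truth** is drawn uniformly within the calibration span, as a
  properly bracketed batch would be; samples default to cellulose with
  the class `x_e`.
* **Equilibration loss** (optional) models the relaxation of the
  effective `x_e` of cellulose on an argon-flushed autosampler,
  `x_e(t) = x_ss + (x_0 − x_ss)·e^{−t/τ}` with `τ` = window/3 (≈95%
  relaxed at the window, default 120 min; defaults `x_0 = 0.13`,
  `x_ss = 0.07`). The exponential shape and τ are package conventions —
  the phenomenon is only characterised by its endpoints and the ~2 h
  window. Sugars do not show the effect and are untouched. The reduction
  flags cellulose analyses inside the window as `pre-steady-state` and
  excludes them from all fits.

What the generator does **not** emulate: heavy-tailed or drifting noise,
signal-size (linearity) effects, blank contributions, mechanistic
HCN/H₂S chemistry (nitrogen bias enters only through the stored empirical
regression used for flagging), within-run changes of equilibration
conditions, and chromatogram-level artefacts. Passing closure tests
therefore demonstrates the correctness of the correction algebra and its
implementation, not the adequacy of these corrections for any particular
instrument's misbehaviour.

## QC statistics and comparisons

* `qc_precision` is the n−1 standard deviation of the calibrated QC
  replicates per isotope, computed on the pre-exchange (calibrated
  equilibrated) δ²H: this is the precision of the measurement; the
  exchange correction further scales δ2H_ne scatter by `1/(1 − x_e)`.
* `reactor_difference_table` compares per-material mean δ2H_ne between a
  glassy-carbon and a chromium run; the difference is fixed as
  carbon − chromium, displayed rounded to 0.1 ‰, kept unrounded
  internally.
* `nitrogen_bias_regression` is unweighted OLS (with intercept) of that
  difference on N content, via statsmodels; no inference is attached —
  the fit is descriptive and feeds the interference flags.
* `interference_flags` warns, on glassy-carbon runs only, for N > 5 %
  (with the predicted bias from the regression stored from the bundled
  five-material comparison dataset, `data/table2.csv`) and for S > 1 %
  (possible H₂S formation).

## Numerical choices and degenerate inputs

Ties in the memory grid go to the smaller `m` (first argmin on the
ascending grid). Calibration requires ≥2 standards spanning a
non-degenerate range, else the channel is skipped and every record is
flagged. Identical equilibration waters raise a degenerate-waters error.
`x_e ≥ 1` is a hard error in the exchange correction; negative estimates
proceed with a flag. Missing channels (chromium runs, PEF oxygen) are
absent, never zero, and are skipped per channel. Memory/drift fits fall
back to `m = 0` / no correction with warnings when replicates or terminal
blocks are missing. Problem sizes used in the test suite — runs of 55–90
analyses, 100-repetition precision studies — keep the full suite in a few
seconds while leaving ≥10 QC replicates and 6 replicates per standard,
enough for every estimator to be well conditioned.

## Known limitations

* With equilibration loss active, the registered `x_e` of cellulose
  standards no longer matches their effective state, so δ²H calibration
  of in-window analyses is biased; the package's answer is exclusion and
  flagging, not correction — matching the practice of waiting out the
  window.
* The reactor-carbon fraction is identified from the δ¹³C gain only when
  no other gain distortion is present; with an additional scale
  distortion the two multiply and cannot be separated within one run.
* Run-level two-water `x_e` estimation requires a paired run; within a
  single run the class defaults are the best available statement.
* The memory model is first-order (one predecessor); long memory tails
  are not represented.
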