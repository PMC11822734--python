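# Methods

## The problem

Blood samples collected for NMR metabolomics keep metabolizing after the
draw. While a tube waits at room temperature before centrifugation,
blood cells consume glucose and excrete lactate; after centrifugation,
slower processes continue in the separated plasma or serum until the
aliquot is frozen. In a centralized biobank these two delays — the
*precentrifugation* delay (collection → centrifugation) and the
*postcentrifugation* delay (end of centrifugation → freezing) — can
stretch to hours and differ sample by sample. metabodrift models the
resulting concentration drift, summarizes it per parameter as a
*stability time point*, and applies the models to cohort timestamp
tables to flag samples whose metabolic profile is expected to have
shifted beyond a tolerable error.

## Drift model

For one metabolic parameter measured in one material (EDTA plasma,
lithium-heparin plasma, or serum) and one delay phase, concentrations
from a controlled timecourse experiment (donors' tubes held at room
temperature for fixed delays, by default 0, 2, 4, 6 and 8 h) are
modeled with a linear mixed model:

    y_ij = β₀ + β₁ · t_ij + b_i + ε_ij,   b_i ~ N(0, σ²_donor),
                                           ε_ij ~ N(0, σ²_resid)

where `i` indexes donors and `t` is the delay in hours. β₀ is the
population concentration at zero delay, β₁ the drift rate in
concentration units per hour, and the donor random intercept `b_i`
absorbs between-donor baseline differences. Estimation is REML via
`statsmodels`' `MixedLM` (LBFGS with a BFGS fallback, one restart from
a perturbed variance start before declaring failure). A singular or
non-convergent stratum falls back to pooled ordinary least squares
with `σ²_donor = 0` and is flagged `degraded`; a single-donor stratum
reduces to simple regression directly, because the donor intercept is
not identifiable there.

**Cell-count variant.** Drift before centrifugation is driven by the
cellular component, so richer models include the donor's blood cell
count. Because cell count is constant within donor, a donor-grouped
random slope on it is not identifiable alongside the donor random
intercept; the `cellcount` variant therefore puts cell count in the
mean structure as a time interaction, `value ~ time_h +
time_h:cell_count`, keeping donor random intercepts. The reported β₁
is then the drift rate at the stratum's mean cell count, with a
standard error propagated through that linear combination (covariance
between the two time terms is ignored, which is conservative). The
formula is a configuration string (`ModelSpec.formula`), so other
readings of the cell-count term can be fitted without code changes.
The default variant is `auto`: `cellcount` when complete cell counts
are present, else `base`.

**Model quality** is summarized by the Nakagawa decomposition:
marginal r² = var(fixed predictions) / (var(fixed) + σ²_donor +
σ²_resid); conditional r² adds σ²_donor to the numerator. Conditional
r² ≥ marginal r² by construction.

**Filtering.** Within each material × phase stratum, a parameter whose
fraction of missing values strictly exceeds 30% is removed before
fitting (the threshold is configurable); remaining missing values are
dropped listwise. No imputation is performed. A donor-level 2/3–1/3
model/validation split utility (`split_donors`) is provided for
held-out validation; the split is by donor so validation donors are
entirely unseen.

## Stability time point

The stability time point of a parameter is the delay at which its
modeled concentration departs from the zero-delay value by a threshold
fraction θ (default 0.20):

    t* = θ · β₀ / |β₁|

Choices baked into this definition:

- the **population intercept** β₀ is the baseline, not per-donor
  intercepts — one stability time point per parameter;
- the **sign of drift is ignored** — a 20% rise and a 20% fall are
  equally disqualifying;
- |β₁| < 1e-12 (model units/h) counts as no measurable drift and the
  parameter is **censored**, as is any t* beyond the reporting horizon
  (default 48 h);
- t* is linear in θ and invariant to rescaling the concentration units.

Timeline tables sort parameters by t* ascending (censored last) and
label each with the SPREC letter of the delay bin containing its t*.
Counting "parameters stable within the first H hours" uses an
**inclusive** boundary (t* ≤ H).

## SPREC delay coding

The Standard PREanalytical Code assigns letters to processing delays.
Only the two room-temperature delay letters (positions 2 and 6 of the
seven-element code) are computed. The built-in ladders are:

- precentrifugation: A1 [0, 0.5 h), A [0.5, 2), C [2, 4), E [4, 8),
  G [8, 12);
- postcentrifugation: B [0, 1 h), D [1, 2), F [2, 8).

Bins are left-closed, right-open; A1 is carved out of A's range because
the two are reported as disjoint categories. Delays beyond the last bin
map to an explicit overflow letter `X` rather than a guessed SPREC
letter, since the standard's longer-delay assignments are not encoded
here. Ladders are plain data (`SPRECLadder`), so cold-chain or custom
category schemes can be supplied without code changes.

**Delay computation.** `pre = centrifugation − collection`; `post =
freezing − centrifugation − spin duration`. Whether the recorded
centrifugation timestamp marks the start or the end of the spin varies
between laboratory systems, so the spin duration is configurable: pass
`default_centrifugation_min=10` (a typical 2,000 × g protocol spin)
when timestamps mark the start, or leave the default 0 when they mark
the end. An optional per-material offset supports conventions such as
counting serum time from the end of clotting; it defaults to 0 and is
not applied to cohort data. Records with missing or unparseable
timestamps or negative delays are flagged invalid with a reason and
listed in the exclusion log, never silently dropped; cohort
preparation also excludes delays beyond a configurable maximum
(default 6 h, the conventional cutoff for extreme processing times).

## Prediction and validation

The expected percent change of a sample processed with delays
(t_pre, t_post) combines the two phase models of each parameter:

    Δ% = 100 · (β₁,pre · t_pre + β₁,post · t_post) / β₀,pre

The precentrifugation intercept normalizes both components because it
estimates the concentration at blood draw; this baseline choice is
configurable. Predictions whose |Δ%| strictly exceeds the tolerable
error (default 15%) are flagged. A parameter with a model in only one
phase yields a partial total, flagged as such.

Validation on held-out timecourses anchors each donor at their time-0
observation: `pred_i(t) = obs_i(0) + β₁ · t`. The mean percentage
error per parameter × time is the signed mean over donors,

    MPE(t) = (100 / n) · Σ_i (pred_i(t) − obs_i(t)) / obs_i(t)

and is reported alongside its absolute value (heat-map displays use
the absolute value). Signed-then-absolute, not mean-of-absolutes:
donors' over- and under-predictions may cancel in MPE, which is the
intended reading; per-donor errors remain available for diagnostics.
Donors lacking a time-0 value, or with a zero observation in the
denominator, are excluded from that cell with a warning.

## Synthetic data

The generators make every stage testable with known ground truth.

`simulate_timecourse` emulates the controlled delay experiment: donor
baselines are lognormal around each parameter's population mean c₀
with a stated between-donor CV (concentrations stay positive by
construction; the lognormal mean is corrected to equal c₀ exactly);
values follow each donor's line plus Gaussian noise with a stated
residual CV (default 5% of c₀); cell counts are uniform in a
physiological leukocyte window (3.5–9.5 × 10⁹/L); missing values are
injected completely at random. The default experiment uses 30 donors —
matching a design of ~20 model donors plus a held-out validation third
— at times 0, 2, 4, 6, 8 h. The default parameter set spans the
qualitative drift regimes: a fast glycolysis-driven riser
(`lactate_like`, c₀ = 1.8 mmol/L, up to +0.88/h before
centrifugation), a medium consumer (`glucose_like`), a slow amino acid
(`alanine_like`) and a nearly inert lipoprotein parameter
(`ldl_cholesterol_like`). These values are illustrative, chosen for
physiological plausibility — they are not fitted coefficients from any
measured dataset. `truth_stability` returns the implied analytic
t* = θ·c₀/|slope| for every stratum, the oracle for end-to-end tests.

`simulate_cohort` emulates a biobank timestamp table: pre- and
postcentrifugation delays are drawn from lognormal mixtures (defaults
put roughly 60% of precentrifugation mass below 2 h with a heavy 2–4 h
shoulder, and most postcentrifugation mass below 2 h, resembling the
right-skewed delay spreads of centralized biobanks), then timestamps
are constructed forward from the sampled delays so every intact row
satisfies the ordering invariants. Timestamps are written at minute
resolution, like real laboratory systems. `mixture_bin_mass` gives the
analytic probability of each SPREC bin for comparison with observed
fractions. A configurable fraction of rows can have a timestamp
blanked to exercise exclusion logic.

What the synthetic data does *not* emulate: nonlinear drift (real
glucose departs from linearity at late times), heteroscedastic or
parameter-correlated measurement error, NMR quantification artifacts,
cell-count-dependent drift rates (cell count is generated but does not
modulate the simulated slope), and freeze–thaw or cold-chain effects.
Passing tests therefore demonstrate correct estimation under the
linear-drift assumptions, not that real metabolite kinetics are linear.

## Numerical choices

- REML with `maxiter=2000`; convergence judged by the optimizer flag
  plus finiteness of all estimates; one restart from a perturbed
  variance start before the OLS fallback.
- Noise-free (perfectly collinear) data makes the residual-variance
  likelihood degenerate; fixed effects are then accurate only to the
  optimizer's flat-likelihood resolution (~1e-5), not machine
  precision. With any realistic noise, fixed effects agree with the
  balanced-design OLS equivalence to ~1e-13.
- Model stores serialize to versioned JSON; Python's float repr
  round-trips IEEE doubles exactly, so coefficients reload bit-exact.
- Histogram bin width defaults to 0.25 h; the hexbin grid defaults to
  30 cells across the pre-delay axis; binning is deterministic given
  the grid parameters, and all bin counts conserve the retained sample
  number. HTML reports embed SVG with a fixed hash salt and a
  suppressible timestamp, so regeneration is byte-identical.
- Sorting of single-sample tables is total: |Δ%| descending, ties
  broken by parameter name.

## Problem sizes

The test suite and the acceptance script run everything on simulated
data at moderate sizes chosen to make the statistical checks sharp but
quick: 50 degenerate instances for the regression-oracle comparison,
200 replicates of the 20-donor design for slope and t* recovery,
a 30-donor fit/validation split for MPE behavior, and cohorts of
500–10,000 samples for the SPREC distribution checks.

## Known limitations

- Drift is strictly linear in time; curvature (late-time glucose) is
  visible only as reduced r², not modeled.
- No confidence intervals on t* (a delta-method extension would be
  straightforward).
- The SPREC overflow letter `X` is a placeholder, not part of the
  standard.
- Only the two delay letters of the SPREC code are computed, and only
  room-temperature ladders ship built in.
- Cohort predictions assume the fitted models transfer to the cohort's
  population; storage, freeze–thaw and cooling effects are out of
  scope.
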