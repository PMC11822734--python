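# metabodrift

Quality control for the *preanalytical phase* of blood-based NMR
metabolomics. Between blood draw and the freezer, two room-temperature
delays alter metabolite concentrations: the **precentrifugation delay**
(cells still in contact with plasma/serum keep metabolizing — glucose
falls, lactate rises) and the **postcentrifugation delay** (slower
drift in the separated fraction before aliquots are frozen). In
centralized biobanks these delays vary sample by sample and can reach
hours. metabodrift is for biobank operators and metabolomics analysts
who need to know *which* parameters in *which* samples can still be
trusted.

The package:

- fits per-parameter **linear mixed drift models**
  `y_ij = β₀ + β₁·t_ij + b_i + ε_ij` (donor random intercepts,
  REML, optional cell-count term) to controlled delay-timecourse
  experiments;
- derives each parameter's **stability time point**
  `t* = θ·β₀/|β₁|` — the delay at which the modeled concentration has
  changed by a threshold fraction θ (default 20%) from its zero-delay
  value;
- parses cohort **timestamp tables** into exact pre/post delays and
  **SPREC** delay-category letters (A1/A/C/E/G before, B/D/F after
  centrifugation);
- **predicts per-sample percent changes**
  `Δ% = 100·(β₁,pre·t_pre + β₁,post·t_post)/β₀` and flags samples
  beyond a tolerable error (default 15%);
- **validates** models on held-out timecourses by mean percentage
  error (MPE), anchored at each donor's time-0 observation;
- renders self-contained **HTML performance reports** (delay
  histograms, hexbin densities, SPREC distributions, prediction
  tables);
- ships a **synthetic-data module** that generates timecourse
  experiments and biobank cohorts with known ground truth, so the
  whole pipeline is testable end to end.

See `docs/methods.md` for the model, its assumptions and the design
choices.

## Worked example

Simulate a 30-donor delay experiment (times 0, 2, 4, 6, 8 h; three
materials; both phases), fit all drift models, and read off the EDTA
precentrifugation timeline:

```python
from metabodrift import (SyntheticTimecourseConfig, simulate_timecourse,
                         fit_all, ModelSpec, timeline_table, PRE_LADDER)
from metabodrift.stability import timeline_frame

cfg = SyntheticTimecourseConfig(n_donors=30, seed=7)
data, truth = simulate_timecourse(cfg)
store, skipped = fit_all(data, ModelSpec())

print(store.get("lactate_like", "EDTA", "pre").summary())
```

```
Drift model: lactate_like | EDTA | precentrifugation
  variant: cellcount
  n_obs = 150, n_donors = 30
  beta0 (intercept)  = 1.77952
  beta1 (slope /h)   = 0.881091  (SE 0.0133)
  var(donor)         = 0.111061
  var(residual)      = 0.00711451
  r2 marginal        = 0.9813
  r2 conditional     = 0.9989
```

The fitted baseline is ≈1.78 mmol/L rising at ≈0.88 mmol/L per hour —
lactate-like kinetics: the donor random intercept absorbs the large
between-donor baseline spread (var 0.111 vs residual 0.007), and the
high marginal r² says time alone explains most of the drift.

```python
results = timeline_table(store.subset(material="EDTA", phase="pre"),
                         threshold=0.20, ladder=PRE_LADDER)
print(timeline_frame(results).to_string(index=False))
```

```
           parameter material phase  threshold  t_star_h letter  censored
        lactate_like     EDTA   pre        0.2  0.403936     A1     False
        glucose_like     EDTA   pre        0.2  3.265571      C     False
        alanine_like     EDTA   pre        0.2  7.453070      E     False
ldl_cholesterol_like     EDTA   pre        0.2       NaN   None      True
```

The lactate-like parameter crosses 20% change after only 0.40 h
(within SPREC category A1, < 30 min) — any precentrifugation delay
compromises it — while the lipid-like parameter never reaches 20%
within the 48 h horizon and is censored. The simulation's analytic
truth for the first row is θ·c₀/|slope| = 0.2·1.8/0.88 ≈ 0.409 h,
recovered here from noisy data within ~1%.

The same workflow from the shell:

```sh
metabodrift simulate timecourse --donors 30 --seed 7 --out tc.csv
metabodrift fit --input tc.csv --out models.json
metabodrift stability --models models.json --threshold 0.20 --out stability.csv
metabodrift simulate cohort --samples 500 --seed 7 --out cohort.csv
metabodrift classify --input cohort.csv --centrifugation-min 10 --out records.csv
metabodrift predict --records records.csv --models models.json --tolerable 15 --out predictions.csv
metabodrift report --records records.csv --models models.json --out report.html
metabodrift single --pre 2.5 --post 1.0 --models models.json
```

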