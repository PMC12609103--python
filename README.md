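# ttemu — target-trial emulation on claims data

`ttemu` is a biostatistics pipeline for emulating a randomized trial from
administrative claims, built around a concrete question: among men aged
≥ 66 diagnosed with advanced prostate cancer in 2008–2019 and treated with
androgen-deprivation therapy (ADT), does initiating metformin within six
months of diagnosis change all-cause or prostate-cancer-specific mortality
within three years?  The real registry–claims linkage behind that question
is access-restricted, so the package ships a synthetic claims generator
with known causal structure; every analysis stage is validated against the
generator's ground truth.

It is aimed at pharmacoepidemiologists and biostatisticians who want a
tested, reusable implementation of the new-user / active-comparator
target-trial workflow:

* **Eligibility screening with time-zero alignment** (`ttemu.cohort`):
  trial-specification criteria, first-failure attrition flow, strategy
  assignment (initiator iff first metformin fill within 183 days of
  diagnosis), time zero = max(ADT start, first fill) for initiators.
* **Prescription-gap exposure** (`ttemu.exposure`): day-level on-drug
  coverage from fills and days-of-supply (no stockpiling), discontinuation
  at the first uncovered run longer than the gap allowance (30 days
  primary, 60 sensitivity), protocol deviations with contraindication /
  indication exemptions.
* **Person-month expansion** (`ttemu.persontime`): 30-day bins from time
  zero, truncated by the diagnosis-anchored 3-year date and the
  administrative end of study, with month-boundary time-varying covariates.
* **Stabilized inverse-probability weights** (`ttemu.weights`): treatment
  (baseline logistic propensity), adherence and loss-to-follow-up
  (cumulative-ratio pooled-logistic weights, fit per strategy), 99th-
  percentile truncation, diagnostics.
* **Effect estimation** (`ttemu.estimators`): the intention-to-treat analog
  as a weighted Cox model (Efron ties, robust SE, delayed entry), the
  per-protocol analog as a weighted pooled logistic model of monthly death
  with patient-clustered sandwich SEs, cause-specific handling of
  cancer-specific mortality, and the two sensitivity variants (added LTFU
  weights; 60-day gap).
* **Descriptives** (`ttemu.descriptives`): baseline table with Pearson
  chi-square / t tests and small-cell suppression below 11 with
  complementary bounds.

## Model

For strategy indicator $A$ (initiate vs not), baseline covariates $L$, and
time-varying covariates $L_m$, the per-protocol analog fits the pooled
logistic discrete-time hazard

$$\operatorname{logit}\, \Pr(D_m = 1 \mid D_{m-1}=0)
  = \alpha + \gamma A + \beta' L + \theta_1 m + \theta_2 m^2,$$

on person-months censored at protocol deviation and weighted by
$sw^{\text{trt}} \times sw^{\text{adh}}_m$ (each stabilized and truncated at
its 99th percentile), where
$sw^{\text{adh}}_m = \prod_{k < m} \Pr(C_k = 0 \mid L)/\Pr(C_k = 0 \mid L, L_k)$
is the inverse-probability-of-adherence weight.  With rare monthly events
$e^{\gamma}$ is the hazard-ratio analog.  The ITT analog is a weighted Cox
model of time from time zero with the same adjustment set.

## Worked example

Simulate a 20,000-patient claims population under the default (null-effect)
study conditions, run the full emulation, and print the estimate grid:

```python
from ttemu import PipelineConfig, SimulationConfig, run_pipeline, emulation_report

cfg = PipelineConfig(seed=1, simulation=SimulationConfig(n_patients=20000, seed=1))
report = run_pipeline(cfg)
print(emulation_report(report))
```

Output (abridged):

```
- population: 20000; eligible cohort: 15751
- deviators: 514 (30-day gap), 505 (60-day gap)

| analysis | outcome | HR | 95% CI | events | deviators |
|---|---|---|---|---|---|
| itt | allcause | 0.873 | 0.692–1.103 | 6127 | 0 |
| itt | pca_specific | 0.991 | 0.754–1.302 | 3870 | 0 |
| per_protocol | allcause | 0.848 | 0.599–1.200 | 5775 | 508 |
| per_protocol | pca_specific | 0.960 | 0.631–1.459 | 3635 | 508 |
| per_protocol_ltfu | allcause | 0.848 | 0.599–1.200 | 5775 | 508 |
| per_protocol_gap60 | allcause | 0.942 | 0.683–1.300 | 5781 | 499 |
...
- baseline_treatment: mean 1.0001, max 3.616, 1.0% truncated
```

Read: 15,751 of 20,000 simulated patients survive the seven eligibility
criteria (the attrition flow in the report lists each removal); under the
generating null (true HR 1 for both outcomes) every analysis gives a hazard
ratio whose 95% CI covers 1, the stabilized treatment weights average ≈ 1,
and widening the allowed refill gap from 30 to 60 days reclassifies a
handful of deviators.

The same pipeline runs from the shell:

```bash
ttemu simulate --config sim.yaml --out claims/
ttemu build-cohort --claims claims/ --out cohort/
ttemu run-all --config pipeline.yaml --out report/
```

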