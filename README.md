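# costutility

Trial-based cost-utility analysis for cluster-randomized trials, built around
the economic evaluation of a collaborative and stepped care (CSC) model for
the four most common mental disorders — depressive, anxiety, somatoform and
alcohol-related — against treatment as usual (TAU) in primary care, over a
12-month horizon from the societal perspective.

It is written for health economists and trial statisticians who need the
whole chain as reusable, tested code rather than a one-off script:

* **Health effects** — EQ-5D-5L profile scoring against pluggable value sets
  (3,125 states, anchored 1 to −0.661), trapezoid QALYs over T0/T1/T2
  (`QALY = 0.25·u_T0 + 0.5·u_T1 + 0.25·u_T2`), EQ-VAS and SF-6D variants,
  response (≥ 50% symptom improvement) and remission (PHQ-9 < 5, GAD-7 < 5,
  PHQ-15 < 9, AUDIT < 4/5 by sex).
* **Costs** — unit-cost valuation of six-month utilization quantities in
  2019 euros with CPI inflation, replacement-cost informal care,
  human-capital absenteeism and presenteeism
  (`(1 − performance/10) × days at work × daily wage`), intervention-cost
  loading, societal and payer perspectives, 95th-percentile winsorization,
  mental-health-only subsets.
* **Missing data** — seeded MICE with predictive mean matching (m = 20,
  5 donors, 10 iterations), LOCF and complete-case sensitivity paths.
* **Estimation** — two-part (logit × gamma-log) and gamma GLM cost models
  with recycled predictions, practice-level resampling SEs (delete-one-
  cluster jackknife by default, cluster bootstrap optional), robust
  covariances, Rubin pooling with Barnard–Rubin degrees of freedom.
* **Cost-effectiveness** — ICUR with dominance flags, net-benefit-regression
  CEACs over a 0–50,000€ WTP grid (probability `1 − p/2` / `p/2` by the sign
  of the pooled arm coefficient), bootstrap cost-effectiveness planes.
* **Synthetic trials** — a seeded generator reproducing the study structure
  (307/308 patients in 20 practices per arm, baseline imbalance, skewed
  hurdle costs, MAR missingness with a retained complete-data copy), so the
  entire pipeline is testable end to end without patient-level data.

## Worked example

```python
import costutility as cu

trial = cu.generate_trial(cu.TrialConfig.default(seed=3))   # 615 patients
config = cu.AnalysisConfig(m=3, iterations=4, n_boot=40, seed=3)
bundle = cu.run_analysis(trial.observed, config)

row = bundle.adjusted_table.set_index("outcome").loc["cost_outpatient_mental_health_12m"]
print(f"outpatient mental health: +{row['difference']:.0f}€ (p={row['p_value']:.3f})")
print(f"ICUR flag: {bundle.icur_result.flag}")
print(f"CEAC: {bundle.ceac_curve.probability_at(0):.2f} at 0€, "
      f"{bundle.ceac_curve.probability_at(50_000):.2f} at 50,000€")
```

prints, with these seeds:

```
outpatient mental health: +443€ (p=0.051)
ICUR flag: dominated
CEAC: 0.20 at 0€, 0.33 at 50,000€
```

Read: on this synthetic replicate the intervention arm incurs about 440€
more outpatient mental-health cost over 12 months (its one clear cost
signal, by construction), brings no QALY gain, and is therefore unlikely to
be cost-effective at any willingness-to-pay on the grid — the probability of
cost-effectiveness stays far below 50%.

A command-line interface wraps the same pipeline:

```bash
costutility generate --seed 1 --out data/
costutility analyze --data data/trial_observed.csv --out run/
costutility variants --data data/trial_observed.csv --out runs/
costutility report --bundle run/
```

`analyze` writes baseline, unadjusted and adjusted tables as CSV, the CEAC
curve and cost-effectiveness plane (CSV + PNG), and a manifest with config
hash and output checksums. `variants` additionally runs the payer
perspective, alternative effect measures (EQ-VAS, SF-6D, response,
remission), diagnosis subgroups, winsorized and mental-health-only costs,
and the LOCF/complete-case strategies.

Unit costs, wages, CPI and the EQ-5D-5L value set ship as documented
placeholder tables and load from YAML/CSV for real analyses
(`UnitCostTable.from_yaml`, `ValueSet.from_csv`).

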