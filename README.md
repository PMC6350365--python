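# pdxtrial

Drug-response analysis and visualization for preclinical trials on
patient-derived xenograft (PDX) models.

PDX trials measure tumor volume repeatedly in cohorts of engrafted mice
under one or more treatments and a vehicle control. Unlike cell-line
xenografts, PDX animals start treatment at heterogeneous volumes and
growth rates, and trial designs vary from a single tumor with many
replicate arms to a "mouse clinical trial" with one animal per tumor-arm
pair. `pdxtrial` classifies a trial into the four common designs — **1AN**
(one tumor, several arms, several animals), **T1N**, **TA1**, **TAN** —
and runs the analyses each design supports:

- **Between-arm statistics** — one-way ANOVA and Kruskal–Wallis on
  endpoint volumes or per-animal log growth rates, the Scheirer–Ray–Hare
  two-factor rank test, balanced mixed-design (split-plot) ANOVA, linear
  mixed models with random intercept and slope per animal, and a
  growth-curve permutation test (per-day pooled t or rank-sum statistic
  averaged over days, animal labels permuted with whole trajectories,
  exact enumeration when feasible, Holm-adjusted over all arm pairs).
- **Tumor growth inhibition** — TGI(t) = (1 − F(V_T)/F(V_C)) · 100 % for
  F = V̄_t − V̄_0, F = V̄_t/V̄_0 or F = AUC of the arm center curve.
- **Response labeling** — per-animal CR/PR/SD/PD under the
  PDX-encyclopedia (BestResponse / BestAvgResponse), pediatric-testing
  -program (relative tumor volume) or volume-adapted RECIST criteria, all
  cutoffs adjustable; arm-level response rate RR = (nCR+nPR)/n and disease
  control rate DCR = (nCR+nPR+nSD)/n with efficacy ranking.
- **Simulation** — a seeded generator of all four designs with exponential
  growth kernels, inter- and intra-tumor heterogeneity and lognormal
  measurement noise, used for the built-in calibration studies.
- **Figures** — arm growth curves (mean ± SEM), per-animal spaghetti
  plots, TGI-over-time, stacked response-level bars and waterfall plots.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate the default single-tumor trial (five treatments plus vehicle,
eight animals per arm, measured every 3 days for three weeks) and run the
full pipeline:

```sh
pdxtrial simulate --seed 4 --out demo.csv
# wrote demo.csv (384 rows)
pdxtrial run --input demo.csv --control Vehicle --n-perm 200 --out demo_out
# pattern 1AN: 11 artifacts in demo_out
```

`demo_out/stats.tsv` holds the between-arm tests on per-animal log growth
rates — here the six arms differ massively, as designed:

```
tumor_id  method          term  statistic            df        p
PDX_01    one_way_anova   arm   67.889089            5.0/42.0  5.05e-19
PDX_01    kruskal_wallis  arm   41.586735            5.0       7.14e-08
```

`demo_out/tgi.tsv` gives the day-21 TGI of each arm against vehicle
(F = V̄_t − V̄_0). Values above 100 % mean net regression below baseline:

```
        arm  tgi_percent
Treatment_1    18.121266
Treatment_2    66.688675
Treatment_3    83.919556
Treatment_4   104.020354
Treatment_5   108.967121
```

`demo_out/response_summary.tsv` ranks arms by disease control, then
response rate — the strongest simulated effect (Treatment_5, 0.12/day
reduction in log growth) converts 3 of 8 animals to partial responses:

```
tumor_id  arm          n  CR  PR  SD  PD  rr_pct  dcr_pct
PDX_01    Treatment_5  8  0   3   5   0   37.5    100.0
PDX_01    Treatment_4  8  0   0   8   0   0.0     100.0
```

The same steps are available from Python:

```python
from pdxtrial import SimConfig, simulate_trial, compute_tgi, label_dataset

ds = simulate_trial(SimConfig(seed=4))
tgi = compute_tgi(ds, f_kind="diff")          # one TGISeries per arm
calls = label_dataset(ds, standard="npdxe")   # one ResponseCall per animal
```

External tables load via `read_trial(path, column_map=...)`; the
`"nibr-pdxe"` preset maps the published PDX-encyclopedia export columns
(`Model`, `Tumor Type`, `Treatment`, `Days Post T0`, `Volume`).

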