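# Methods

## Scope and data model

The package analyzes repeated tumor-volume measurements from xenograft
trials run on patient-derived tumor models (PDX). The unit of observation is
one animal at one day; the canonical table is long-format with columns
`tumor_id, tumor_type, arm, animal_id, day, volume, body_weight` (mm³, g,
days since treatment start). No unit conversion is performed. Wide-format
input is out of scope. Baselines are taken at day 0; an animal whose
earliest measurement is not day 0 is flagged rather than shifted, because
percent-change metrics are only meaningful relative to the enrollment
volume. Animals removed early simply contribute the days they have; no
censoring model is applied.

Trial designs are classified by three counts — number of tumor models,
number of treatment arms (max over tumors, excluding the vehicle arm) and
the median number of animals per tumor-by-arm cell:

| code | tumors | treatment arms | animals/cell | typical use |
|------|--------|----------------|--------------|-------------|
| 1AN  | 1      | several        | several      | pick a drug for one patient's tumor |
| T1N  | several| 1              | several      | one treatment across tumors |
| TA1  | several| several        | 1            | mouse-clinical-trial screens |
| TAN  | several| several        | several      | full factorial efficacy studies |

Degenerate layouts map to the nearest code with a warning flag. The
pipeline routes analyses accordingly: between-arm statistics need replicate
animals per arm (1AN, TAN); TGI needs a vehicle arm per tumor (1AN, T1N,
TAN); response labeling applies everywhere, including single-animal arms.

The vehicle arm is identified by an explicit flag, else by case-insensitive
match against `vehicle` / `control` / `untreated`; TGI refuses to run
without one, labeling does not need one.

## Between-arm statistics

**Endpoints.** PDX tumors start treatment at heterogeneous volumes, so the
default scalar endpoint is a per-animal growth rate rather than the raw
terminal volume: the least-squares slope of ln V versus day (`slope_log`),
with `ratio_log` (ln of the end/baseline fold change per day) and `diff`
(linear rate) as alternatives. The log-slope uses every timepoint and is
exact when growth is exponential. Endpoint tests are one-way fixed-effects
ANOVA and Kruskal–Wallis (mid-ranks, tie-corrected, chi-square reference).

**Scheirer–Ray–Hare.** The two-factor rank test ranks all N observations
together, computes two-way ANOVA sums of squares on the ranks and refers
H = SS_term / (SS_total/(N−1)) to chi-square on the term's usual df.
Dividing by the empirical total mean square of the mid-ranks makes the tie
correction automatic, and a single-level second factor then reproduces the
tie-corrected Kruskal–Wallis statistic exactly. Incomplete A×B grids are
rejected; the factor pairing (arm×tumor or arm×day) is the caller's choice.

**Mixed-design ANOVA.** Balanced split-plot decomposition computed from cell
means: the arm effect is tested against subjects-within-arm, day and
arm×day against the day-by-subject residual. Animals are restricted to the
days all animals share (no interpolation — the intersection-of-days rule is
used everywhere in the package, because interpolating volumes would invent
data). A term with exactly zero sum of squares reports F = 0 even when its
error stratum is degenerate, so noise-free constructed datasets remain
analyzable. Greenhouse–Geisser corrected p-values for the within terms are
attached when sphericity estimation succeeds and NaN otherwise.

**Linear mixed model.** REML fit of ln(V+1) (the +1 shift keeps fully
regressed tumors with V = 0 in the model; a raw-scale option exists) on
day, arm and day×arm with vehicle as the reference level, random intercept
and slope per animal. The day×arm coefficient is each treatment's change in
log growth rate versus vehicle and is reported with Wald z and p; an
omnibus Wald chi-square covers all arm-involving terms. If the optimizer
fails or the random-effects covariance is singular (smallest eigenvalue ≤
1e-10 of the largest), the model downgrades to a random intercept and says
so in the result notes.

**Growth-curve permutation test.** For each arm pair, a two-sample statistic
is computed at every shared day — pooled-variance t by default, or a
tie-corrected Wilcoxon rank-sum z — and averaged across days; animal labels
are then permuted with whole trajectories moving together. The raw p-value
is the plain proportion of relabelings whose |mean statistic| reaches the
observed one (an add-one smoothed option exists but is off by default).
When the number of distinct assignments C(n, n1) is at most 20,000 the null
set is enumerated exhaustively and the p-value is exact; otherwise the
requested number of Monte-Carlo relabelings (default 1000) is drawn from
the seed. Days where both groups have zero variance are skipped with a
note. Pairwise p-values are adjusted across all pairs, Holm by default
(Bonferroni and Benjamini–Hochberg available). Results are bit-reproducible
given (seed, n_perm) and invariant to row order.

## Tumor growth inhibition

TGI(t) = (1 − F(V_T)/F(V_C)) · 100 %, computed on the per-day center (mean
by default, median available) volume curve of each arm, on the days the
treatment and control arms share. Three F functions: `diff` (V̄_t − V̄_0),
`ratio` (V̄_t / V̄_0) and `auc` (trapezoidal area of the center curve from
day 0 to t, without baseline subtraction — documented choice). Day 0 is
reported only for `ratio` (where TGI is identically 0); for `diff`/`auc`
the control F is 0 there and the row is omitted. When the control arm fails
to grow (F_C ≤ 0 under diff/auc) the ratio is uninterpretable and the row
is flagged undefined with the note "control not growing" rather than
reported with a flipped sign. TGI above 100 % (regression below baseline
under `diff`) is reported as is. The AUC variant integrates the arm center
curve rather than averaging per-animal AUCs, for consistency with the
arm-mean convention of the other two F functions.

## Response labeling

Per-animal percent change from baseline ΔV%(t) = 100·(V_t − V_0)/V_0 feeds
three labeling standards, all with adjustable cutoffs (`Thresholds`):

- **npdxe** — BestResponse = min ΔV% over days ≥ an eligibility day
  (default 10, inclusive), BestAvgResponse = min over eligible t of the
  running mean of ΔV% over (0, t] (day 0 excluded). Defaults: CR if
  best < −95 and avg < −40; else PR if best < −50 and avg < −20; else SD if
  best < 35 and avg < 30; else PD. Trajectories ending before the
  eligibility day are labeled PD with an "insufficient follow-up" note
  rather than dropped.
- **pptp** — relative tumor volume RTV = V_t/V_0: CR if the tumor ever
  drops below the measurable size (default 100 mm³ — the one absolute-scale
  cutoff in the package); else PR if min RTV ≤ 0.5; else PD if final
  RTV > 1.25; else SD. The time-to-event PD subclasses and the maintained-CR
  distinction of the original scheme are deliberately collapsed to PD and CR.
- **rc** — volume-adapted RECIST on the final ΔV%: CR ≤ −95, PR ≤ −65,
  PD ≥ +73, SD otherwise.

BestAvgResponse ≥ BestResponse is guaranteed when every post-baseline day
is eligible (a running mean can never fall below the running minimum); with
a later eligibility day an early transient dip can break the inequality, so
the property is asserted under min_day = 0.

Arm-level indices: RR = (nCR + nPR)/n, DCR = (nCR + nPR + nSD)/n, printed
as percentages rounded to 2 decimals. Arms are ranked by DCR then RR by
default (or RR then DCR), ties broken alphabetically.

## Synthetic trials

The generator draws V_a(t) = V_a(0) · exp((g_tumor + g_animal − e_arm)·t) ·
ε_a(t): lognormal baseline (mean 200 mm³, CV 0.25), per-tumor growth rate
g_tumor ~ N(0.09, 0.02²)/day (inter-tumor heterogeneity; 0.09/day doubles a
tumor in ~8 days), per-animal deviation g_animal ~ N(0, 0.02²)
(intra-tumor heterogeneity), an additive per-day reduction e_arm of the log
growth rate per treatment arm (0 for vehicle; defaults grade five
treatments from 0.01 to 0.12, the strongest inducing regression), and
multiplicative lognormal noise with CV 0.08. The baseline measurement
itself is noise-free (enrollment volumes are measured carefully); body
weight drifts mildly around 20 g with a small treatment-dependent trend.
The default layout is one tumor, five treatments plus vehicle, eight
animals per arm, measured every 3 days for 3 weeks. `simulate_null` zeroes
all arm effects, making arms exchangeable for type-I-error studies.

The exponential kernel was chosen over Gompertz for analytic tractability:
the log-slope endpoint recovers g − e exactly in the noiseless limit, which
anchors the recovery tests. What the generator does not emulate: growth
deceleration at large volumes, dropout correlated with tumor burden,
measurement schedules differing across animals, and caliper floor effects —
so calibration results here speak to the statistics under the stated model,
not to every feature of real trial data.

## Numerical choices

- Permutation tie handling: a relabeling counts as reaching the observed
  statistic if it is within a relative 1e-9, so the mirror assignment of a
  symmetric split is never lost to floating-point noise.
- Exhaustive-enumeration threshold: 20,000 assignments (~a few ms with the
  vectorized statistic kernels).
- Mixed-ANOVA and SRH degenerate inputs: zero sums of squares report F = 0,
  H = 0, p = 1 instead of NaN where the term is exactly null.
- Sizes of the built-in simulation studies: 1,000 null trials for the
  calibration study and 200 replicates for mixed-model recovery, chosen to
  put the binomial Monte-Carlo error well below the effects being checked.
- Seeds: every stochastic routine takes an explicit seed; derived seeds are
  drawn below 2³¹.

## Limitations

Volume-based readouts only — bioluminescence and hematologic burden data
are out of scope, as are dose–response/IC50 fitting, survival endpoints and
drug-combination response-surface models. The permutation test requires ≥ 2
animals per arm; single-animal designs are served by labeling and ranking
only. Unbalanced repeated-measures layouts fall back to the shared-day
intersection for the mixed ANOVA; severely ragged schedules are better
served by the LMM.
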