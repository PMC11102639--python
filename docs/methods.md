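# Methods

## Problem and pipeline

`crowddx` estimates how much pooling independent diagnostic judgments
improves accuracy. The unit of data is one rater's (GP's) free-text
diagnosis of one case under one condition, with an ordinal confidence
rating and years of experience. The pipeline is:

1. **Standardize** free text to canonical labels (case-fold, trim, collapse
   internal whitespace, then look up a synonym map; unmapped terms keep
   their normalized form). Manual synonym grouping by a clinical team is not
   reproducible from the outside, so the deterministic normalization layer
   plus an explicit, auditable map file is the substitute. Scoring is exact
   string equality of the standardized label with a one-label-per-case
   answer key — deliberately no fuzzy matching, so correctness is binary and
   deterministic.
2. **Exclude** any GP missing one or more confidence or seniority values —
   at the GP level, never row-level, because a virtual group needs every
   member's weight on every case.
3. **Build virtual groups** per (condition, group size k): all C(n, k)
   unique member combinations, or 6,000 distinct combinations sampled
   uniformly without replacement when C(n, k) exceeds that cap. Groups are
   formed within a condition only; in a within-subject design each
   condition's groups decide that condition's own case set. The cap is
   drawn independently per cell.
4. **Aggregate** each group's diagnoses per case with five rules (plurality,
   best-confidence, best-seniority, and 3-person plurality among the most
   confident / most senior members). All ties break uniformly at random at
   the member level (for weight rules) or label level (for plurality).
   Confidence is only ever compared within a group — never across studies,
   whose scales differ (1–8 vs 1–10).
5. **Evaluate**: accuracy-vs-k curves per rule × condition; case-level
   diagnostics; gains over the control-condition individual baseline (the
   DSS conditions' k = 1 rows are the DSS baselines); plurality × DSS
   synergy; and binned accuracy-by-confidence / accuracy-by-seniority-band
   summaries (bands ≤10, 11–20, ≥21 years).

Averaging order is groups → per-case mean → unweighted mean over cases, so
each case counts equally regardless of group count; pooled weighting is
available as a sensitivity option (`weighting="pooled"`). Every curve point
carries a Monte-Carlo standard error because capped cells are sampled.

## Exact oracle

For i.i.d. votes from a categorical distribution with the first label
correct, `exact_plurality_accuracy` enumerates all count vectors over labels
summing to k and accumulates multinomial probability × 1/|argmax| when the
correct label attains the maximum — the expectation of the randomized tie
break. The enumeration (vectorized log-space multinomial pmf) is guarded at
10⁷ count vectors, far above the m ≤ 10, k ≤ 25 sizes used here.
`binary_majority_accuracy` is the closed-form Condorcet special case (odd k
only; even k is rejected rather than given an arbitrary tie rule). The
oracle is the independent reference for the Monte-Carlo engine: the test
suite checks agreement within 3 binomial standard errors across randomized
scenarios, and checks the engine against the scalar reference rules.

## Randomness and reproducibility

Everything is a pure function of explicit seeds. Data generation derives all
streams from the config seed. In group simulation, each (condition, k, rule,
case) cell gets a generator seeded by those coordinates plus the master
seed and is consumed over groups in canonical sorted-member order, so
decisions are invariant to the ordering of input records. Tie-breaking in
the vectorized engine uses sub-integer jitter on vote counts (uniform over
tied labels) and random-shuffle-then-stable-sort for top-m selection
(uniform over boundary ties, members strictly above the boundary always
included).

## Synthetic-data generator

Correctness is logistic-additive on the log-odds scale:
P(correct) = logistic(e_c + s_g + δ_cond), with case easiness e_c, condition
effect δ (control ≡ 0), and GP skill s_g ~ Normal(γ·(years − mean years),
σ_g). This is the simplest generative model consistent with a mixed-logistic
view of rater × case data and reproduces all the qualitative phenomena the
pipeline measures. Its remaining pieces:

- **Errors.** An incorrect response draws from a per-case wrong-answer
  alphabet with weights w. Concentration of w is the error-correlation dial:
  weight 1 on one label makes all errors identical (worst case for
  plurality); uniform weights disperse them (best case). Per-condition
  overrides allow a DSS that also de-correlates errors.
- **Confidence.** A latent Normal(conf_mean + Δconf·correct, conf_sd),
  rounded and clamped to the design's scale. A high conf_mean reproduces the
  empirical skew toward high ratings; Δconf = 0 produces a null
  confidence–accuracy association, Δconf > 0 a weak positive one.
- **Seniority.** Years are drawn from a three-band mixture (≤10 / 11–20 /
  ≥21), integer-uniform within band, with band weights matching the
  published demographic mix; γ < 0 makes experience weakly *negatively*
  predictive of accuracy.

### Presets

Two packaged presets stand in for the undeposited datasets. They are
frozen YAML snapshots of `build_preset`, which calibrates a common easiness
offset (and then each DSS effect δ) by monotone bisection with common
random numbers at 50,000 simulated responses, to within ±0.01 of the target
mean individual accuracy:

| | vignette_like | actor_patient_like |
|---|---|---|
| design | between-subject, 3 conditions | within-subject, 2 conditions |
| cases | 9 shared | 6 per condition |
| GPs | 87 per condition | 30 total |
| confidence scale | 1–8, Δconf = 0.6 | 1–10, Δconf = 0 |
| seniority mix | 64.6 / 18.1 / 17.3 % | 56.7 / 16.6 / 26.7 % |
| γ (per year) | −0.01 | −0.03 |
| σ_g | 0.6 | 0.6 |
| accuracy targets | 63% control, 69% early DSS | 48% control, 57% early DSS |
| errors | 5 wrong labels, weights 0.30…0.10 | 3 wrong labels; alternating 0.60/0.25/0.15 and 0.40/0.35/0.25 |

Choices the published record does not pin down, made once as modeling
choices: the per-case easiness spread (linspace ±1.1 / ±1.0 log-odds — no
per-case accuracy table exists), the late-DSS target 0.66 (printed figures
show it between control and early DSS), σ_g = 0.6 (plausible rater
heterogeneity), and the preset diagnosis vocabulary (illustrative chest
pain / abdominal pain / dyspnea differentials, not a reconstruction).

### What the generator does and does not emulate

It reproduces: per-case difficulty spread, between- vs within-subject
assignment, a DSS accuracy shift, heterogeneous skill, skewed ordinal
confidence weakly (or not) associated with correctness, seniority weakly
negatively associated with accuracy, and tunable error concentration. It
does not emulate free-text vocabulary variation (labels are emitted already
standardized; the standardization layer is exercised by its own tests),
information-search behavior, case-order effects, or rater correlation
beyond the shared-wrong-label mechanism. Passing tests on synthetic data
therefore validate the machinery and the qualitative mechanisms, not any
real-world effect size.

## Numerical and degenerate-input choices

- Vote-count jitter for tie-breaking is < 0.5, below the unit spacing of
  integer counts, so it can never reorder distinct counts.
- Weight ties are detected by exact equality; weights are data (ordinal
  confidence, years), not computed floats.
- Group sampling under the cap uses rejection sampling on canonical sorted
  member tuples — exactly uniform over distinct sets; the cap (6,000) is
  orders of magnitude below the cell counts where rejection would slow down.
- Empty ballots, k > n, missing weights, unknown conditions/rules,
  out-of-scale confidence, and cases absent from the answer key are hard
  errors; unmapped diagnosis terms are not (they standardize to themselves
  and are logged).
- A case with zero wrong responses has an undefined modal-wrong share
  (reported missing); its modal-correct flag is true. "Modal correct" means
  strictly most frequent.
- `calibrate_easiness` rejects targets unreachable within ±12 log-odds
  offset given the configured skill spread.

## Problem sizes

Defaults mirror the study conditions: group sizes 3–9 plus the k = 1
baseline, 6,000-group cap, full preset populations. A complete two-preset
run (all five rules, all conditions) is ~5.7 M + 2.5 M decisions and takes
seconds on one core, thanks to the vectorized per-cell engine. The
expectation test for the null confidence rule averages 60 replicate
actor-patient studies because a single 30-GP dataset carries ~6.5-point
dataset-level noise in that statistic.

## Known limitations

- The mixed-effects regression view of confidence/seniority associations is
  replaced by descriptive binned summaries; coefficient-level comparisons
  would require the original data.
- The error-correlation statistic (modal-wrong share) is one reasonable
  operationalization; other dependence measures (pairwise kappa, entropy of
  the wrong-label distribution) are not implemented.
- With 30 GPs, weight-based rules at large k concentrate on few members, so
  single-dataset estimates of those rules are noisy by construction; report
  Monte-Carlo standard errors or replicate.
- No interacting-group or deliberation models: judgments are aggregated
  statistically, as collected.
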