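# Methods

## Scope and data model

The package reproduces the analysis shape of a single-centre external
validation of trauma mortality scores: one row per admission with age, sex,
mechanism (blunt / penetrating / blast), a list of AIS injuries
(region + grade), first-recorded physiology (RR, SBP, GCS) and the
in-hospital outcome. Inclusion follows the adult-registry rule *age > 13*;
age ≤ 13 is a fatal validation issue. Clinical exclusions that the schema
cannot express (pathological fractures, hanging, drowning, burns, isolated
head injury without haemodynamic compromise) are the caller's
responsibility and are deliberately not encoded.

## Scores

ISS/NISS, RTS and the two TRISS variants are implemented exactly as their
published coefficient sets state (see README for the equations). Decisions
where the conventions are not universal:

- **AIS 6**: any currently-untreatable injury forces ISS = NISS = 75, the
  standard registry convention; the record is kept and the promotion is
  logged as a non-fatal validation issue.
- **Blast mechanism**: MTOS-TRISS defines only blunt and penetrating
  coefficient sets; blast is mapped to blunt (the conservative default).
  The coefficient set actually used is recorded per patient
  (`coefficient_set_used`) so users can override.
- **Age < 15**: the blunt MTOS set is applied regardless of mechanism, and
  AgeIndex (defined for 15–54 vs ≥ 55) is taken as 0. Because the cohort
  excludes age ≤ 13, only age-14 records are affected. NTrD-TRISS reuses
  the same AgeIndex definition.
- Coefficients are used at exactly their printed precision; survival
  probabilities are strictly inside (0, 1) for all admissible inputs.

## Discrimination analysis

The AUC is the concordance probability (ties one half), computed from
midrank placement values; it equals the trapezoidal area under the
empirical ROC curve by construction, and the test-suite verifies both
identities against brute-force pair counting and scikit-learn.

Standard errors and the paired comparison of correlated AUCs use the
DeLong (1988) structural components: for events *i* and controls *j*,
placements `V10_i` (fraction of controls ranked below event *i*) and
`V01_j`, with `var(AUC) = S10/n1 + S01/n0` and the paired covariance
defined analogously. The comparison statistic is
`z = (AUC_a − AUC_b) / sqrt(var_a + var_b − 2 cov_ab)` with a two-sided
normal p-value. A zero-variance difference with equal AUCs (e.g. a score
compared with itself) degenerates to z = 0, p = 1 by contract. Confidence
intervals are normal-approximation, truncated to [0, 1], with no logit
transform. The DeLong p-values were checked against a within-patient
score-swap permutation test (10⁴ replicates, n = 60): agreement is within
0.01 on all ten fixtures, against a pre-set 0.06 bound that reflects the
normal-approximation error at that sample size.

**Cutoffs.** The Youden index J = sensitivity + specificity − 1 is
maximised by exhaustive scan over every achievable confusion table:
classification is strict (`value > c` for severity-up scores, `value < c`
for survival-probability-like scores), candidates are the distinct observed
values plus the all-positive extreme, and ties in J break toward higher
specificity (fewer false positives). The reported cutoff is an observed
score value, so operating points read naturally ("NISS > 24"). PPV/NPV at
an empty margin are reported as NaN with a warning, never as 0 or 1.
`metrics_from_rates` exposes the analytic identities
`acc = se·p + sp·(1−p)`, `ppv = se·p / (se·p + (1−sp)(1−p))`,
`npv = sp(1−p) / (sp(1−p) + (1−se)p)` used to cross-check published
operating-point tables.

## Synthetic cohort generator

The generator emulates the study population, not any individual patient
record. A latent severity factor `z ~ N(0,1)` drives four coupled
components:

| parameter | default | meaning |
|---|---|---|
| `n` | 2208 | cohort size (the study's) |
| `age_mean`, `age_sd` | 32.5, 16 y | untruncated normal; resampled until ≥ 14, realised mean ≈ 36 |
| `male_fraction` | 0.886 | study sex mix |
| `mechanism_probs` | 0.905 / 0.093 / 0.002 | blunt / penetrating / blast |
| `injury_count_mean`, `count_tilt` | 2.0, 0.2 | extra injuries ~ Poisson(λ·e^{0.2 z}) |
| `severity_weights`, `severity_tilt` | (.26,.36,.25,.10,.03), 0.45 | AIS 1–5 weights, tilted ×e^{0.45·g·z} |
| `region_concentration` | 0.85 | P(injury lands in the patient's primary region) |
| `physiology_coupling` | 0.9 | corr. of the physiologic latent d with z |
| `phys_noise` | 0.4 | per-vital noise on d before banding |
| `band_probs` | (.845,.078,.043,.020,.014) | marginal RTS-band frequencies per vital |
| `outcome_intercept/niss_coef/phys_coef` | −5.0, 0.085, 0.28 | death logit on NISS and physiologic deficit |

Death is Bernoulli with logit
`b = −5.0 + 0.085·NISS + 0.28·(12 − RRs − SBPs − GCSs)`: mortality depends
on anatomy and physiology through two correlated channels, so the
physiology-based scores retain discrimination while NISS, which sits in
the outcome model directly, discriminates best. Region clustering makes
ISS diverge from NISS (correlation ≈ 0.88) the way multiply-injured
regions do in practice; without it the ISS-based MTOS-TRISS ties NISS.
AIS 6 is never generated (observed anatomic scores stay within the tuned
1–5 profile); ages below 14 are never generated, and the floor is 14
rather than 15 precisely to exercise the age-14 TRISS edge case.

Calibration (`scripts/calibrate.py`, coarse grid over the outcome
coefficients and physiology coupling, then a 20-seed re-score) targets the
study population's summaries: crude mortality 0.108 ± 0.015, NISS mean
19.39 ± 1.0, RTS mean 7.384 ± 0.15, NISS AUC 0.878 ± 0.03 with NISS
maximal among the four scores in ≥ 80% of seeds. The packaged defaults
meet all of these; the published TRISS means and non-NISS AUCs are treated
as soft targets only (the defaults land at RTS ≈ 0.77, MTOS ≈ 0.85,
NTrD ≈ 0.84).

What the generator does **not** emulate: registry-specific exclusion
mixes, missing or miscoded physiology, correlated vitals beyond one latent
factor, secular trends, and the particular realisations behind published
cutoffs (a cutoff of 24 with sensitivity 86.6% is a property of one
dataset, not of the model). Passing the calibrated-simulation tests
therefore shows the pipeline recovers the *structure* of the published
analysis under realistic marginals — not that it reproduces the original
registry.

Reproducibility: a cohort is a pure function of (config, seed); each
patient draws from a seed-sequence child keyed by row index, so record *i*
is independent of cohort size.

## Numerical choices and degenerate inputs

- Midrank placements make AUC and DeLong components exact under ties;
  mergesort is used wherever order must be stable.
- Degenerate outcome vectors (all deaths or all survivors) are hard errors
  naming the empty class, at both the metric and pipeline level.
- Youden's scan tolerates exact float ties in J via a 1e-12 margin before
  the specificity tie-break.
- Report CSVs carry six decimals; display rounding (AUC to 3 decimals,
  p-values below 0.001 printed "< 0.001") is applied only at the CLI.
- End-to-end runs are deterministic: identical seed and config produce
  byte-identical CSV tables and logs.

## Problem sizes used in the checks

Oracle-equivalence suites run at n ≤ 200 (AUC, 500 instances), n ≤ 120
(Youden, 200 instances) and n = 60 (DeLong vs 10⁴-replicate permutation,
10 fixtures); the calibrated-simulation checks use 20 cohorts at the full
study size n = 2208, and the null-model check (outcome decoupled, all AUCs
≈ 0.5) uses one cohort of n = 20 000. The parameter-recovery check refits
the outcome logistic on n = 20 000 and recovers the NISS coefficient
within 15%.

## Known limitations

- The generator's injury profile is an emulation tuned to summary
  statistics, not an inference from patient-level data.
- MTOS/NTrD coefficient sets are taken as published; no re-estimation or
  recalibration (e.g. Hosmer–Lemeshow) is provided.
- No imputation: records with missing physiology cells fail loudly at
  read time.
- Only region + grade AIS encoding is supported, which is all ISS/NISS
  need; full AIS code dictionaries are out of scope.
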