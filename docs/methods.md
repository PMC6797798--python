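# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-cohort generator used to validate it, the numerical conventions,
and the design choices that were genuinely open.

## Plate scaling

Kit-based targeted assays show multiplicative between-plate batch effects:
extraction efficiency, spray stability and calibration transfer shift all
concentrations on a plate by a common factor per analyte. The correction
anchors on a reference material measured on every plate. With reference
values r for analyte *a*, the factor for plate *p* is

    factor(p, a) = mean(r_a over all plates) / mean(r_a on plate p)

applied multiplicatively to every cell of the plate. Means are arithmetic
on the concentration scale (a geometric-mean mode is available and is
arguably more natural under a multiplicative error model; the arithmetic
form is the default because it is the conventional "average of the pool"
correction). Censored reference wells are excluded from the means rather
than imputed — imputing them would feed the later LOD/2 rule back into the
scaling anchor. A plate with no usable reference value for an analyte gets
factor 1 and a warning by default (configurable to a hard error): silently
guessing a correction is worse than not correcting.

Consequences used as invariants: after scaling, every per-plate reference
mean equals the global reference mean to ~1e-9 relative error; scaling a
second time yields factors of exactly 1; within-plate sample ratios are
unchanged.

## Analyte filters

Filters run on the scaled (level-2) data, using the blinded replicate
groups — the same serum draw injected 2–3 times under different blinded
identifiers, scattered across plates.

**Replicate CV.** Each group with at least two VALID values contributes
sample SD / mean; the per-analyte statistic aggregates group CVs (mean by
default; median and RMS available). An analyte passes if CV < `cv_max`
(default 0.30). Note that for duplicate pairs the group-CV estimator is
biased low (E[s] ≈ 0.80 σ at k = 2), so an analyte whose true replicate CV
sits just above the threshold is rejected with limited power; this is a
property of the estimator, not of the implementation. The threshold is a
precision criterion: high replicate CV means technical noise, not
biological signal. (The alternative reading — filtering analytes with
*limited variation* — contradicts CV being a noise measure; we implement
the standard precision reading.)

**Replicate ICC.** One-way random-effects intraclass correlation from the
ANOVA decomposition,

    ICC = (MSB − MSW) / (MSB + (k0 − 1)·MSW),
    k0  = (N − Σ k_i²/N) / (g − 1),

the single-rater form appropriate for technical replicates with no rater
structure; k0 reduces to the group size for balanced designs and is the
standard correction otherwise. Pass requires ICC > `icc_min` (default
0.6, strict: a design sitting exactly at 0.6 fails). Censored members are
substituted at LOD/2 by default (`icc_lod_policy="half_lod"`) so the group
remains usable; an `exclude_group` policy is provided since it is unstated
whether substitution should precede the reliability computation.

**Censoring filter.** The fraction of *cohort* cells flagged below the
LOD; QC wells are excluded from the denominator. An analyte fails only
when strictly above `lod_frac_max` (default 0.40): exactly 40% passes.

An analyte with no usable replicate group fails the CV criterion with
reason `NO_REPLICATES`; an all-identical degenerate design fails ICC with
reason `DEGENERATE`. Reports carry every input analyte with its
statistics, pass flags and reasons.

## Imputation, exclusion, averaging, outlier screen, log2

**LOD/2.** Left-censored concentrations are replaced by half the
plate-specific limit of detection — the conventional substitution for
below-detection targeted data. Flags are retained as provenance, so a
level-4 table still records which cells were imputed.

**Metadata exclusions.** Non-fasting draws (bile acids are strongly
meal-responsive), samples without BMI, and samples without a baseline
medication record are *flagged* at level 4 and physically removed only at
level 5, keeping the flagged intermediate available. If any injection of
a blinded replicate group is flagged, the whole subject is excluded
(conservative; the alternative — averaging the surviving member — would
mix exclusion semantics).

**Averaging.** Replicate groups collapse to the arithmetic per-analyte
mean, one row per subject.

**PCA screen.** Analytes are standardized (mean 0, SD 1), components
computed, and the smallest leading set whose cumulative explained variance
strictly exceeds `cum_var_threshold` (default 0.90, minimum one component)
is screened. A subject is flagged when its Mahalanobis distance within
the selected subspace — equivalently the root sum of squared
per-component z-scores — exceeds `sd_cutoff` (default 7).

Two design points deserve justification:

- *Distance, not per-component z.* The simplest reading of "more than
  7 SD from the mean" is a per-component test, and it is available
  (`method="per_component"`). It is, however, provably insensitive at
  cohort scale: for n = 500 samples and p = 15 standardized analytes the
  sampling spread of covariance eigenvalues (Marchenko–Pastur edge
  (1 + √(p/n))² ≈ 1.37) exceeds the eigenvalue a single 12-SD outlier
  contributes (≈ 1.22), so the outlier direction mixes across several
  components and its largest per-component z lands near 6 — below a
  7-SD cutoff. The subspace Mahalanobis distance is invariant to that
  rotation, detects the same outlier at distance ≈ 9.5, and keeps nominal
  specificity (P(χ²₁₃ > 49) ≈ 3 × 10⁻⁶ per subject).
- *Log2 scale.* By default the screen runs on log2-transformed values
  (`pca_after_log2=True`). Concentrations are log-normal; on the raw
  scale the heavy right tail alone pushes clean subjects to distances
  ≈ 9 and any "k SD" rule loses its calibration. On the log scale scores
  are near-Gaussian and the 7-SD rule means what it says. The
  concentration-scale mode remains available.

The screen is single-pass (not iterated after removals).

**log2.** Final values are base-2 logarithms; positivity is guaranteed by
LOD/2 imputation and checked.

## Synthetic cohorts

The generator emulates the plate design end to end so that every stage is
testable against known truth. Per cohort injection of analyte *a* on
plate *p* for subject *s*:

    y = exp(mu_a + sigma_subj * Z_s) × f_pa × exp(sigma_rep * Z_inj)

- `mu_a`: log-median per analyte, drawn log-uniform over 0.05–5 µM
  (order-of-magnitude plausible for serum bile acids; configurable).
- `sigma_subj` (default 0.5): between-subject log-SD, i.e. ≈ 53%
  between-subject CV — bile acids are highly variable across people.
- `f_pa = exp(N(0, 0.05))`: multiplicative plate effect (default 5%,
  matching corrections that are "typically less than 10%").
- `sigma_rep = sqrt(log(1 + CV²))`: replicate noise calibrated to an 8%
  technical CV by default.
- LOD per (analyte, plate): the analyte's 2% quantile of the plate-level
  marginal, perturbed ±10% per plate; values below are censored.
  LLOQ sits 15% above the largest plate LOD; values between LOD and LLOQ
  are flagged but keep their number (they are quantifiable, merely below
  the lowest calibrator).

Layout per plate: 75 cohort wells (default) plus 3 SPQC, 3 NIST,
1 GoldenWest and kit low/mid/high QC wells, drawn from fixed pool levels
with the same noise model. Kit QC wells are generated for layout fidelity
but not consumed by the pipeline. Presets: 18 blinded duplicates (first
cohort) or 15 blinded triplicates (follow-on cohort), scattered randomly
across plates.

Planted defects define ground truth for recovery tests:

- `HIGH_CV`: replicate CV raised to 0.5;
- `LOW_ICC`: between-subject log-SD collapsed to 0.01 (no reproducible
  subject signal);
- `HIGH_CENSORING`: censoring quantile raised to 0.6;
- outlier subjects: the whole profile is displaced to
  mean + d × SD on every analyte (default d = 12) — the signature of a
  sample-level artifact such as a dilution or handling error. A
  whole-profile shift is used deliberately: a spike on a single analyte
  vanishes whenever that analyte is filtered, and several equal
  single-analyte spikes create a degenerate eigenvalue whose components
  mix the outliers together, masking them from any componentwise rule.

What the generator does **not** model: injection-order drift, carry-over,
calibration-curve error, correlated analyte panels (conjugated bile acids
co-vary in reality; here analytes are independent given the subject), or
non-random placement of replicates. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated noise
model, not performance on every pathology of real data.

A companion generator emits free-text medication tables (brand/generic
names with dosage/casing noise) together with the true Boolean class
matrix, for round-trip tests of the mapping stage.

## Medication mapping

Normalization lowercases, strips punctuation and removes dosage/unit/form
tokens ("10mg", "tab", "po"...). Lookup is exact first, then
longest-prefix at a token boundary (resolving salt suffixes such as
"atorvastatin calcium"). The bundled dictionary (~60 entries, 12 classes,
versioned CSV) is an offline stand-in for a live terminology service; the
`TerminologyAdapter` protocol documents how such a service would populate
a `DrugDictionary`. Ambiguous names set every class of every matching
ingredient and are reported. Matched plus unmatched record counts always
equal the input count; unmatched strings are listed, never dropped.

## Numerical conventions

- Group SDs use ddof = 1 throughout.
- Artifact CSVs are written at full float precision (shortest
  round-trip representation), so read(write(M)) reproduces M exactly and
  identical runs are byte-identical; provenance JSON stores stage
  parameters and the parent matrix SHA-256 rather than timestamps.
- Censoring markers are parsed case- and whitespace-insensitively
  (`<LOD`, `< lod`, ...) and emitted canonically (`<LOD`, `<LLOQ`).
  A marker read from an external file carries no number, so a `<LLOQ`
  cell from a raw export is treated as missing; generator-produced
  matrices keep the reported value alongside the flag.
- Cumulative-variance selection is strict (> threshold) with minimum one
  component; zero-variance inputs yield an empty outlier report with a
  warning.
- Test problem sizes (11 × 75-well cohorts, 20-seed sweeps, 500 × 15
  screening cohorts) were chosen to make planted effects statistically
  unambiguous while keeping the full suite fast.

## Known limitations

- The reference-pool scaling estimator uses 3 wells per plate; its
  relative SE (~CV/√3 ≈ 4.6%) is comparable to a 5% batch effect, so
  individual factor estimates are noisy even when the anchor invariant
  holds exactly. Aggregate behavior (ratio preservation, idempotence) is
  the reliable contract.
- Rejection of an analyte whose true replicate CV is 0.5 against a 0.30
  threshold with 18 duplicate pairs has ≈ 96% power per analyte; a
  borderline analyte will occasionally be retained. This is intrinsic to
  the design (few replicate groups), not tunable away.
- The medication dictionary is illustrative, not a clinical terminology;
  coverage of real free-text records requires a populated adapter.
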