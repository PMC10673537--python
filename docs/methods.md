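# Methods

This note documents the models, defaults and numerical choices behind the
package, and what its synthetic-data tests do and do not demonstrate.

## MME standardization

Daily morphine milligram equivalents are computed as

    MME = Σ_over_opioid_records  strength_mg × doses_per_day × factor ,

with factors from the packaged CDC oral-MME reference table
(`data/mme_conversion_factors_v1.csv`, version tag `cdc-oral-v1`,
recorded in every report): codeine 0.15, tramadol 0.1, hydrocodone 1.0,
oxycodone 1.5, morphine 1.0 (the definition of the unit), hydromorphone
4.0, oxymorphone 3.0, tapentadol 0.4, fentanyl transdermal 2.4 per
mcg/hr (a single documented factor row; full patch conversion is out of
scope). Methadone is tiered on the drug's pooled daily mg: ×4 up to
20 mg/day, ×8 to 40, ×10 to 60, ×12 above — so methadone records are
summed per drug before the factor is chosen.

Conventions: for combination products (hydrocodone–acetaminophen,
codeine–acetaminophen) only the opioid component's mg is entered;
over-the-counter records always contribute 0 MME; occasional (as-needed)
users report their typical daily count in `doses_per_day`, because
occasional narcotic use still corresponds to a nonzero daily MME.
MME is kept at full float precision internally; reports display 2
decimals. No proration of partial fills over days is attempted — the
computation works from stated daily dosing.

## Classification

Operational class cutoffs are continuous half-open intervals that cover
all non-negative reals with no gaps or overlaps:

    A: MME = 0, no medication        B: MME = 0, OTC only
    C: (0, 30]      D: (30, 80)      E: [80, ∞)

The published integer guide ("1–30 / 31–79 / 80+") is honored at every
integer; the half-open continuous form decides the values in between and
keeps the classifier a partition (both 30 → C and 80 → E by
inclusivity). A zero-MME visit with an opioid on file, or a positive MME
with no opioid, is rejected as inconsistent rather than guessed.

Class membership is MME-driven. The occasional/consistent usage pattern
is carried on each prescription and reported, but does not override the
MME interval: a patient at 25 MME taken consistently is class C with a
usage-pattern mismatch visible in the data, not class D.

### Cluster-derived boundaries

`derive_boundaries` re-derives the C/D/E cutoffs from observed narcotic
MMEs: a hierarchical pass (Ward linkage, Euclidean distance, cluster
count chosen by maximum silhouette over k = 2..6) proposes k; K-means
(scikit-learn, 10 restarts, default seed 1976) fixes the centers; each
cluster's observed raw min/max become the cutoff points. Input values
are sorted before clustering, which makes the result invariant to input
order for a fixed seed. Only k = 3 maps onto the three-class boundary
type; other k return the clustering result alone. Outliers are not
trimmed before taking extremes — the raw per-cluster min/max is used.

## Scoring

Efficiency score per period = 100 × |{IPA ≤ 1}| / n over surveyed
patients; patients missing an IPA response at a period are excluded from
that period's denominator, not imputed. An equivalent identity used as a
test oracle: the score equals 100 minus the percentage of IPA = 2
responses. `mean_mme` averages over *all* visits (classes A/B contribute
zeros); a narcotics-only mean is emitted separately because the
all-responses basis of a longitudinal mean-MME trace is a reporting
convention, not a mathematical necessity. When raw dates rather than
nominal periods are supplied, visits are binned into windows 10–21 d
(2wk), 35–56 d (6wk), 75–105 d (3mo), 160–200 d (6mo).

## Statistical battery

Shapiro–Wilk (normality per narcotic class), Kruskal–Wallis with tie
correction (C/D/E separation), Mann–Whitney U (first-vs-last-period
narcotic share, on the binary on-narcotics indicator), and Spearman ρ
with average-rank ties (class letter as ordinal A=0..E=4 vs MME, and
total daily dose frequency vs MME). All p-values are two-sided. The
numerical engines are scipy.stats; the exact small-sample Mann–Whitney
null (both n ≤ 8, no ties) is additionally verified in the test suite
against an independent brute-force enumeration of all C(n₁+n₂, n₁) rank
assignments. The gender-vs-pain-tolerability comparison defaults to
Mann–Whitney on IPA by gender, with a 2×3 chi-square alternative behind
a flag, since the ordinal-by-binary design admits either. Kendall τ-b is
emitted in verbose mode as a companion rank correlation. No
multiple-testing correction is applied.

## Synthetic cohort generator

The generator emulates the structure of a 502-patient post-operative
orthopedic cohort followed at four periods. Defaults:

| parameter | default | basis |
|---|---|---|
| n_patients | 502 | study cohort size |
| gender | 225 M / 277 F | study demographics |
| age | truncated normal, mean 50, SD 16, bounds 18–87 | study demographics |
| procedures | 210 fracture / 138 spine / 154 joint | study demographics |
| satisfaction P(IPA≤1) | 62.5 / 80.5 / 75.65 / 60.9 % per period | published scores |
| narcotic share | 65.2% (2wk) → 32.6% (6mo), linear in period index | endpoints published; interpolation is an invented default |
| within-narcotic mix C:D:E | 0.60 / 0.30 / 0.10 | invented default (unpublished); reflects predominantly occasional short-acting use |
| A:B split of non-narcotic | 0.50 / 0.50 | invented default (unpublished) |
| IPA 0-vs-1 split when satisfied | 0.50 | unidentifiable from period scores; configurable |
| class MME | truncated normals: C 16.34 on [2.3, 30], D 45.39 on [33.75, 67.5], E 94.09 on [80, 135] | published means and ranges |

The "± x" figures attached to the published class means are treated as
standard errors, not SDs (an SD of 0.08 is incompatible with a 2.3–30
range); each class SD is instead set to `min(mean − low, high − mean) /
2.576` so ≈99% of the truncated normal's mass lies inside the published
range.

**Stratified assignment.** Class membership, satisfaction, gender and
procedure are apportioned exactly to the configured proportions
(largest-remainder rounding) and randomly permuted across patients,
rather than drawn independently per visit. This is a deliberate design
choice: the generator's job is to realize the configured marginals, and
exact apportionment recovers them to rounding precision (±1 count)
instead of with binomial noise (±6 percentage points at 3 SE for the
two-week narcotic share at n = 502). Within-class MME values and the
IPA 0/1 split remain independent draws.

Each narcotic visit's prescription list is back-filled to be consistent
with its sampled MME: one class-appropriate drug is chosen (short-acting
agents for C/D, morphine/hydromorphone/oxycodone for E; methadone is
never back-filled because its tiered factor makes dose-solving
non-unique) and `doses_per_day` is solved from MME = strength × doses ×
factor, with a one-ulp inward nudge if float round-off would cross a
class cutoff. Re-running the MME engine on the generated prescriptions
therefore reproduces the sampled class for every visit — a
consistency-by-construction invariant the tests assert.

All randomness flows from a single `numpy` Generator seeded from the
config; identical seeds give byte-identical CSVs. Options exist for
per-period attrition and for a cross-sectional design (each patient
surveyed at one random period), both off by default.

**What passing tests show — and don't.** Tests on this generator
demonstrate that the pipeline (MME → class → rating → period scores →
statistics → report) is internally consistent and recovers configured
parameters. They do not validate the clinical claims: real registry data
have within-patient longitudinal correlation, class-dependent
satisfaction, attrition, mis-reported dosing and multi-drug regimens
that the generator's independence assumptions deliberately omit.

## Numerical choices and limitations

- Cluster seeds default to 1976 with 10 K-means restarts; silhouette
  decides auto-k; ties in largest-remainder apportionment break by
  larger fractional part, then category order (deterministic).
- Two-sided p-values throughout; exact Mann–Whitney only for untied
  samples with both n ≤ 8, asymptotic with continuity and tie correction
  otherwise.
- The type-I calibration suite runs each test at α = 0.05 over 2000 null
  replicates at n = 25–50 per group, sizes at which the discrete rank
  null distributions are dense enough for the nominal level to be
  meaningful; at very small n exact rank tests are conservative by
  construction.
- Degenerate inputs fail loudly: empty samples, constant samples for
  Shapiro–Wilk, fewer distinct values than clusters, mixed periods in
  one summary, opioid flags contradicting MME.
- The acceptance script's problem sizes (200 values per class for
  cluster recovery; one 502 × 4 cohort for the pipeline) match the study
  scale and run in seconds.
- Out of scope: live registry integration, fill-date overlap logic,
  risk adjustment of the efficiency score, pediatric validation,
  model-based clustering.
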