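# Methods

## The data model

One record is one *occurrence*: a taxon at a locality at a time.  Fields:
taxon (one of three theropod clades), stratigraphic unit, epoch (Jurassic
/ Early Cretaceous / Late Cretaceous), broad paleoenvironment
(terrestrial / coastal / marine), taphonomic category, a dubious flag,
and an optional curator-assigned paralogy group.  Paralogy is *not*
inferred from geography: deciding that two localities sample the same
ancient ecosystem takes stratigraphic judgment that the available fields
cannot encode, so the group identifier is an input.  A group must be
homogeneous in taxon, environment and epoch; this is validated and is
slightly stricter than leaving mixed-age groups to curator discretion.

Taphonomic categories operationalize transport: category 1 means the
occurrence includes (semi)articulated or associated cranial/postcranial
remains, category 2 only isolated fragments.  Records whose sources do
not describe the material are "unspecified"; they are treated as dubious
and are excluded from every category-based design (but kept in the
taxon-level designs).

## Curation rules

Synonymization collapses each paralogy group to one occurrence:

* merged dubious flag = AND over members (one valid member rescues the
  occurrence);
* merged category = best present, with precedence category 1 > category 2
  > unspecified.  Only the promotion to category 1 is forced by the
  merge semantics; extending the same "best documented member" rule to
  unspecified members is this package's generalization;
* the merged record keeps its first member's identifiers and position,
  making the operation deterministic and idempotent.

Variants: I = all records, II = synonymize, III = drop dubious,
IV = synonymize *then* drop dubious.  The order in IV matters: because of
the rescue rule, |IV| is generally larger than |I| minus paralogous minus
dubious, and tests verify merge-then-filter semantics against a
brute-force oracle over all member-state combinations.

## Test designs

Marine occurrences are always excluded (7 of 220 in the study system —
too few to support expected counts).  Ten concrete designs cover the
eight test families: taxa × coastal and taxa × terrestrial (3×1), taxa ×
both environments (3×2), taxon-by-category × one environment (6×1, two
designs), taxon-by-category × both (6×2), category × environment within
each taxon (three 2×2), and Early/Late Cretaceous × environment (2×2,
Jurassic excluded, each locality-time counted once however many taxa
occur there).

One-column designs are goodness-of-fit tests with a uniform expectation
E = n/k; they deliberately ignore that some taxa are more widespread than
others, which is why the two-column designs (product-margin expectation)
are run alongside.

## Statistics

* Pearson chi-square with **no continuity correction** anywhere — the 2×2
  epoch design only reproduces published behaviour without Yates'
  correction.  df = k−1 for one-column designs, (r−1)(c−1) otherwise.
* **Monte-Carlo p-values** whenever min expected < 5 (the classical
  warning threshold).  Two-column null tables are drawn with both margins
  fixed by filling rows sequentially from multivariate-hypergeometric
  draws on the remaining column totals — exactly the conditional
  distribution under independence, equivalent in law to Patefield-style
  samplers (cross-checked in tests against scipy's implementation).
  One-column nulls are uniform multinomials.  p = (1+m)/(B+1) with
  B = 2000 replicates; both asymptotic and Monte-Carlo p-values are kept
  in results so the trigger rule is auditable.  The replicate comparison
  uses `χ²_rep ≥ χ²_obs − 1e−9` to keep ties (replicates reproducing the
  observed table) counted despite float jitter.
* **Fisher's exact test** (2×2 designs only): two-sided p by probability
  ordering with relative tolerance 1e−7 — the convention under which
  published exact p-values from standard software reproduce.  One-sided
  tail probabilities are also reported: when the observed table is the
  modal one the two-sided p is exactly 1 and carries no direction, while
  the upper tail still does (and is the quantity some published tables
  print in that situation).  The odds ratio is the conditional MLE under
  the noncentral hypergeometric likelihood, found by Brent root-finding
  on the log-odds scale (xtol 1e−10) with hypergeometric weights computed
  through log-gamma for overflow safety; it is 0 or ∞ exactly when the
  observed cell sits at the minimum or maximum of its conditional
  support.
* **Significance and signs**: the operative p-value is the Monte-Carlo
  one when triggered, else asymptotic; a design is significant iff
  operative p < α (strict, α = 0.05).  Signs are the signs of the
  Pearson residuals, assigned only in significant designs; a residual of
  exactly zero stays `n/a`.  Fisher results never gate signs.
* **Concordance** between two significant designs counts equal signs over
  the (row label, environment) keys present and signed in both; designs
  with disjoint keys (different row schemes, or different single
  environments) are incomparable.  No multiple-testing correction is
  applied across the battery, matching the source analysis.

## Synthetic generator

`SyntheticConfig` draws a locality pool (environment and epoch mixtures),
then per-taxon occurrences: environment from the taxon's preference
vector, locality sampled without replacement within the environment
stratum (extra localities are created when a stratum is exhausted),
taphonomic category from a per-(taxon, environment) completeness mixture,
dubious flags independently (unspecified-category records are always
dubious).  Paralogy clusters partition each (taxon, environment, epoch)
cell into geometric-size groups with mean 1 + rate; members share a group
id and stratigraphic unit.

The paper-like preset fixes the study's marginal structure: 198
localities at 166/25/7 terrestrial/coastal/marine, occurrence totals
82/72/66 (spinosaurids/abelisaurids/carcharodontosaurids), environment
and completeness proportions from the variant-I counts, dubious
probability 60/213 ≈ 0.28 (variant I vs III sizes), cluster rate 0.97
(variant I's 213 non-marine occurrences collapse to 108 in variant II,
mean cluster ≈ 2).  The generator emulates marginal structure only: no
spatial geometry, no stratigraphic architecture, no preservation-rate
model, and locality sharing between taxa arises only by collision.
Passing calibration tests therefore validate the pipeline's statistical
machinery, not any claim about the real locality list.

`recovery_experiment` replicates generate → curate → test.  With equal
environment preferences across taxa the rejection rate of the
taxa-vs-environments design estimates the type-I error (the calibration
test uses the asymptotic p-value and 500 replicates at study-like sizes:
nominal 5% within 3 binomial standard errors); with a taxon given a
strong coastal preference, rejection estimates power and the residual
sign of that taxon's coastal cell recovers the direction.

## Numerical and design notes

* The packaged fixture encodes the published per-variant counts; battery
  runs on the fixture bypass curation and exercise the engine on exact
  in-study inputs.  Totals (29 coastal / 184 terrestrial in variant I)
  are asserted in tests.
* In the published epoch-design table the dataset II and III columns are
  interchanged relative to the counts table (the statistics recompute
  from the opposite labels); engine-level checks therefore anchor to the
  unambiguous variants I and IV.
* Monte-Carlo p-values are reproducible under a fixed seed; the battery
  consumes one generator in fixed (test id, variant) order, so a single
  seed pins all 40 results.
* Degenerate designs (empty table, zero margin, <2 rows) are reported as
  skipped rather than erroring the battery.
* Sizes used by the verification scripts — 2000 Monte-Carlo replicates
  per triggered design, 50k–100k sampler draws for the hypergeometric
  goodness-of-fit check, 500 calibration replicates — were chosen so
  sampling error is small against the tolerances being checked.

## Limitations

* Paralogy detection itself is out of scope: groups are inputs, and
  "paralogy in time" (one long-lived environment spread over several
  stratigraphic levels) is not operationalized.
* The spreadsheet importer maps arbitrary headers onto the strict CSV
  schema on a best-effort basis and is excluded from the verified path.
* Monte-Carlo p-values can only be matched to published values within
  sampling error; published runs did not report replicate counts or
  seeds.
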