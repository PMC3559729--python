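# Methods

This note records the statistical model, the numeric choices behind every
configurable threshold, what the synthetic-data generator does and does
not emulate, and the known limitations.

## The association model

The unit of observation is a (sample, probe, CNV type) carrier indicator:
a sample carries a deletion at a probe if any of its copy-state-0/1 calls
covers the probe position (duplications: states 3/4), with overlapping
calls from one sample counted once.  Cohort denominators are the full
post-QC cohort sizes at every probe; there is no per-probe missingness
model, matching the single-pair-of-Ns design of array CNV scans.

Per-probe inference is the two-sided Fisher exact test under the
minimum-likelihood convention (the convention of R's `fisher.test` and
scipy): the p-value sums hypergeometric probabilities of all tables with
the observed margins whose probability is at most that of the observed
table, with a relative tolerance of 1e-7 on the comparison to keep exact
ties stable in floating point.  The test is implemented directly on a
cached log-factorial table because genome scans and the simulation suites
evaluate millions of tables; it is verified in the test suite against
both scipy and an exhaustive exact-integer enumeration over all cohort
sizes up to 40.  Two properties of this convention are worth knowing:
it is symmetric under swapping the cohorts, and it is *not* monotone step
by step in the carrier count (for case-only carriers at cohort sizes
7313/2701, p(3,0)=0.568 < p(4,0)=0.580, because the opposite tail's
inclusion set changes discretely); it is strictly decreasing at stride 2.

## Segmentation

Significant probes (p < `alpha_probe`, default 0.05) of one type and one
enrichment direction are chained while consecutive significant probes lie
within `max_gap_bp` (default 1 Mb); intervening non-significant probes do
not break a chain, only distance does.  Each chain is a CNVR reported at
its p-value local minimum; ties break to the leftmost probe,
deterministically.  Chains never cross chromosomes.  A chain is kept only
if its best-probe carrier count in the enriched cohort reaches
`min_case_carriers` (default 3) — the rare-variant analogue of a
minor-allele-frequency floor.  Because carrier boundaries are jittered by
the calling process, the local minimum can land on a flanking probe whose
carrier ratio is more extreme than the planted interior (e.g. 65:1
beating 87:4); this is correct behaviour of the local-minimum rule, not
an error, and the recovery checks in the acceptance script therefore
verify carrier counts at interior probes.

### The multiple-testing denominator

The Bonferroni bar divides `alpha_multiple` (default 0.05) by the number
of *testable* regions: probes harbouring at least `min_case_carriers`
case carriers, collapsed with the same 1 Mb rule, with overlapping
deletion/duplication regions counted once (`effective_test_count`).
Dividing by the number of *significant* chains instead would be
anti-conservative — a run with a single nominally significant CNVR would
face a bar of 0.05 and always pass.  With the testable-region
denominator, 100 seeded null simulations (500/500 samples, 5,000 probes)
produce no bar-clearing CNVR in every run in our test suite.

## False-positive screens

All four screens flag rather than delete, so the audit trail survives.
The thresholds quantify qualitative failure modes and are all exposed in
`FilterParams`:

* **telomere_centromere** — ≥1 bp overlap with an exclusion track
  (BED input; the demo uses chromosome ends and midpoints as stand-ins).
* **peninsula** — ≥ `peninsula_fraction` (default 0.5, boundary
  inclusive) of the CNVR's contributing calls cover at least
  `peninsula_extension_probes` (default 5) non-significant probes beyond
  a CNVR boundary.  This operationalises the boundary-truncation artefact
  of common CNVs: the significant subregion is an edge of a larger call
  cloud.  Boundary-uncertainty artefacts are subsumed by this rule; no
  separate flag exists.
* **gc_extreme / gc_unknown** — mean probe GC over the span outside
  [`gc_low`, `gc_high`] = [0.25, 0.75]; unknown GC is flagged rather than
  guessed.
* **low_coverage** — probe density below `min_probe_density` = 1 per
  100 kb.
* **sample_bias** — samples contributing to more than
  `max_cnvrs_per_sample` (default 3) CNVRs are discounted as carriers;
  a CNVR is flagged iff the discounted table loses nominal significance
  or drops below the carrier floor.  Cohort denominators are kept: bias
  samples are discounted as carriers, not excluded from the study.

## Sample QC

Inclusion requires call rate > 0.98, LRR SD < 0.30, |GCWF| < 0.05 and
CNV call count < 100 — all strict comparisons, so boundary values fail —
plus duplicate resolution (one lexicographically-smallest survivor per
connected cluster of pairs above the identity threshold) and an ancestry
rule: within 6 SD of the included-set centroid on PC1 and PC2, recomputed
once after the first pass (two rounds total).  The 6-SD centroid rule is
a documented stand-in for an ancestry call made by eye on PCA plots in
array studies; it is configurable (`pca_sd_limit`).  Exclusions carry the
first failing reason in the order call_rate, lrr_sd, gcwf, cnv_count,
duplicate, pca_outlier.

## Replication and combination

Replication carrier status is evaluated over the discovery span with
any-overlap semantics.  The test is a logistic regression of cohort label
on carrier status plus the first three PCs; the reported p is a two-sided
Wald test on the carrier coefficient (likelihood-ratio available via
`test="lr"`).  Zero-variance covariates are dropped, so constant PCs
reproduce the covariate-free fit exactly.  Monotone likelihoods — all
carriers in one cohort, common for rare CNVs — are detected up front and
refit with a hand-rolled Firth (Jeffreys-prior) penalised likelihood,
reported via `separation_detected`/`method`, never silently.  A locus
counts as replicated only when the replication enrichment direction
matches discovery *and* p < 0.05; Fisher's method combines the discovery
and replication p-values only behind that direction gate, with p floored
at 1e-300 before the logarithm.

For genome-wide inflation diagnostics, `logistic_score_pvalues` evaluates
the same model as a vectorised score test (one null fit, closed-form 1-df
statistics per locus) — the standard shortcut when thousands of loci
share one covariate design.

## Gene annotation and enrichment

Gene spans include introns.  A CNVR is annotated with every gene it
overlaps by ≥1 bp, in genomic order; a CNVR overlapping nothing gets the
single nearest gene by edge distance (ties to the smaller start), marked
proximal.  Enrichment is a one-sided hypergeometric over-representation
test against a supplied background (the array-covered gene universe),
with at most one gene per locus counting toward a category's hits — the
guard against one locus spanning a clustered gene family — and
Benjamini–Hochberg correction across categories.  This is a transparent
replacement for web-service annotation clustering tools; it preserves the
one-gene-per-locus restriction but not any proprietary annotation
content, so category labels are only as good as the supplied table.

## Synthetic data: what it does and does not emulate

`simulate_dataset` builds a marker map (default 10 kb spacing, the
density of a ~300k-probe genome-wide array), smooth GC around 0.45 with
extreme-GC blocks placed off the planted spans, samples with realistic QC
metrics and three Gaussian PCs, and four call layers: planted rare CNVRs
with exact carrier counts and uniform boundary jitter; peninsula
constructs (a common CNV, equal carrier frequency in both cohorts, whose
case calls extend 5–25 probes into one flank while control calls truncate
at the core); common-CNV regions with symmetric truncation jitter; and
uniform background calls of 3–25 probes.

Numbers behind the demo (`demo_discovery_config`): cohort sizes
7,313/2,701 mirror a large discovery design; planted carrier tables
(26/0, 87/4, 42/0) sit at the carrier frequencies (0.15–1.2%) typical of
rare recurrent CNVRs; bias loci use 11/0 — the smallest case-only table
that is nominally significant at these cohort sizes — sharing one
carrier, so discounting it leaves 10/0 (p = 0.066) and the flag fires;
jitter is 2 probes (below the 5-probe peninsula extension, so clean loci
are never misflagged).  The background rate of 0.05 calls/sample is
calibrated so the per-probe deletion-carrier count has mean ≈ 0.6 across
the cohorts, matching the per-probe carrier-frequency regime of real
intersected arrays (where ~14% of probes show a deletion in at least two
of ~10,000 individuals).  A uniform background cannot simultaneously
match real per-sample call counts (~30 genome-wide) and per-probe carrier
rates, because real calls concentrate in polymorphic hotspots; per-probe
rates are what the association scan sees, so they are what is calibrated.
Consequences: passing tests demonstrate correct counting, chaining,
flagging and calibration under label-independent noise — they do not
demonstrate robustness to hotspot clustering, linkage disequilibrium
between probes, batch-correlated call artefacts, or caller-specific
boundary-error distributions, none of which the generator models.

`simulate_null_dataset` defaults to a per-probe carrier rate of 0.002,
the rare-CNV frequency regime (carrier frequency ≥0.15% is the common
inclusion bound for recurrent CNVRs).  `simulate_structured_dataset`
implements the classic confounding geometry — control PC1 shifted by 1
SD, carrier probability logistic in PC1 (slope 0.5) — under which naive
association inflates to λ ≈ 10 while PC-corrected tests return λ ≈ 1.

## Study sizes and estimator choices

The stratification study pools score-test p-values over 10 independent
cohort draws of 400/400 samples × 4,000 regions (40,000 tests): the
median-based λ estimator has sampling SD ≈ 0.09 at 1,000 tests, so tens
of thousands of tests are needed before a ±0.05 statement about λ is
about the method rather than about estimator noise; pooling independent
draws also removes the within-draw correlation from sharing one sample
design.  The null type-I study uses 100 runs of 500/500 samples × 5,000
probes.  The packaged demo runs at full cohort scale (10,014 samples)
because the per-probe scan is linear and fast; the whole test suite
completes in about a minute on one core.

## Numerical and degenerate-input conventions

Floats serialise via `repr` (shortest round-trip form) and parse with
round-trip precision, so write→read is the identity and reruns are
byte-identical.  Internal coordinates are 1-based inclusive (call-file
convention); BED converts at the boundary.  Empty carrier tables give
p = 1; a CNVR with no overlapping genes falls back to the nearest gene;
logistic association refuses all-carrier/no-carrier inputs with a
dedicated error; Fisher's method refuses p = 0 and callers floor instead;
the inflation factor refuses p outside (0, 1].

## Limitations

* CNV calling from intensities (LRR/BAF), PC computation from genotypes,
  and identity/IBD estimation are out of scope; their outputs are inputs
  here.
* Cohort-level region counts and replication p-values of any particular
  published study depend on individual-level data and are not
  reproduction targets; the package's claims are the property and
  recovery suites described above.
* The peninsula, GC, coverage and bias thresholds quantify qualitative
  criteria; defaults separate the synthetic confounders cleanly and are
  starting points, not biology.
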