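# Methods

## Correlation and significance

Pearson product-moment correlations are computed over pairwise-complete
observations. Array-platform features are complete by contract, so the bulk
of the matrix is computed by standardising each complete row to zero mean
and unit norm and accumulating block outer products (BLAS matrix products
over row blocks, default block size 512). Any pair touching a feature with
missing cells (PCR features) falls back to an explicitly masked
pairwise-complete computation. The blockwise and per-pair routes agree to
~1e-12 in float64; the store persists r as float32, which perturbs r by at
most ~6e-8 — negligible against sampling error at n = 105.

The raw p-value uses the classical t transform of r (two-sided, df = n − 2).
The test form is a modelling choice: it is exact under bivariate normality
and is the standard default for product-moment correlation. |r| within 1e-15
of 1 is reported as p = 0 rather than overflowing the transform.

A pair needs at least `min_n` complete observations (default 20) to be
"detected"; below that it is stored with r = NaN and excluded from queries.
Zero-variance features are excluded at build time with a logged warning so
the store never holds undefined records.

### Multiplicity families

Two corrections are reported per record:

* **Bonferroni** over a family `m`, default the whole matrix
  m = F(F − 1)/2 — the natural family for "is this pair significant among
  everything the matrix contains". A per-seed family (m = F − 1) is
  available by flag.
* **Benjamini–Hochberg** q-values computed over the seed's neighbor family
  (its detected neighbors) — FDR is a property of a result list, and the
  result lists this tool emits are per-seed neighbor scans. BH adjustment is
  delegated to statsmodels; tests verify it against the textbook step-up
  definition independently. For a bare pair lookup the BH family is anchored
  on the lexicographically first member so that lookup(a, b) = lookup(b, a)
  exactly.

Only (r, n_obs) are persisted; all p/q are recomputed at query time. This
halves storage at the 150-million-pair scale and lets the family choice vary
per query without rebuilding.

### Ranking and ties

Top-k queries rank by raw p ascending, breaking ties by larger |r| and then
lexicographic partner ID, making output ordering fully deterministic. For
fixed n, ranking by p is identical to ranking by |r| descending; the tie
rules only matter across different n_obs or exact-tie pairs.

## PCR (Ct) features

Cycle-threshold values are orientation-reversed at load time as −Ct, so
larger always means more abundant and correlation signs are comparable
across platforms. Negation (rather than 1/Ct) is a monotone reversal that
preserves the spacing of the log-like Ct scale. A PCR feature is "detected"
when Ct < 35 in at least 50% of samples (both thresholds configurable);
failing features are dropped before the build, with a per-feature report.

## Validation procedures

**Enrichment.** The observed statistic is the fraction of the seed's top-k
partners (deduplicated to gene level through the annotation, so multiple
probe sets per gene cannot double-count) that carry the annotation. The
baseline is R = 1,000 (configurable) independent draws of k genes without
replacement from the supplied universe excluding the seed gene; the mean and
SD of the draw fractions are reported, mirroring how such baselines are
usually quoted ("x% (SD = y%)"), together with an empirical p with the +1
correction, (1 + #{draws ≥ observed})/(R + 1), which is never zero. Note the
universe legitimately contains the enriched genes themselves, so the
baseline mean sits slightly above the background annotation rate whenever
enriched genes are a noticeable fraction of the universe.

**Replication.** Pairs with either member absent from the replication
matrix — or with fewer than min_n complete observations — are classed
undetected; the rest are correlated and Bonferroni-corrected over the
carried-forward family (default: the number of tested pairs, the most
conservative defensible reading of "followed by Bonferroni correction").
The three counts partition the discovery list by a hard assertion.

**miRNA recall.** "Nominal" means raw p < α (default 0.05), uncorrected, as
appropriate for recalling externally validated interactions rather than
discovering new ones. The negative-r subset is reported separately because
miRNA-mediated degradation predicts anti-correlation, but the headline
fraction is sign-agnostic.

## Synthetic cohorts

The generator exists so that every stage is testable against known ground
truth. Each hub h has a latent factor z_h ~ N(0, 1) per sample; the hub is
observed as z_h itself and each of its responders as

    λ·z_h + sqrt(1 − λ²)·noise_sd·ε,   ε ~ N(0, 1).

At noise_sd = 1 (the default) every feature has unit population variance and
the hub–responder correlation is exactly λ (λ² between co-responders), so
recovery can be checked in closed form. Observing the hub as its latent
factor rather than a noisy copy is what makes the planted correlation
exactly λ; adding hub noise would shrink it by a known factor and buy no
extra realism worth the lost analytic transparency. Background features are
independent N(0, 1).

Default design parameters mirror the cohort scale the engine targets:
discovery n = 105 samples, test preset F = 2,000 features with one hub and
200 responders at λ = 0.8; a full-scale preset (F = 17,328, 341 miRNAs) is
provided but slow to build. The replication preset uses n = 1,204 with 7%
random feature dropout emulating transcripts undetected on the replication
platform; hub features are exempt from dropout because the replication
analysis conditions on the seed transcript being measured in both cohorts.
The annotation layer labels responder genes at rate 0.91 and other genes at
0.483, reproducing a strong TF binding-site enrichment gap over a high
background rate. The miRNA layer couples each miRNA to a designated target
with loading β = −0.6, mapped onto a Ct-like scale ct = 27 − 3·value
(spanning [18, 36] over ±3 SD) with 5% random cell dropout.

All randomness flows from a single spec-level seed through named
SeedSequence streams (cohort / replication / annotation / mirna), so
sub-simulations are independently reproducible and two runs with the same
spec are bit-identical.

What the generator does **not** emulate: probe-level microarray noise,
batch effects, heteroscedastic Ct noise, correlated annotation errors, or
clinical covariates. Passing tests therefore demonstrate correctness of the
computation and calibration of the statistics under a clean factor model,
not robustness to real-data artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced but structurally faithful
scales chosen as the smallest sizes at which the statistical claims are
meaningful: 2,000-feature cohorts (≈2 million pairs) for recovery and
global-null FDR checks, 200 (tests) / 50 (script) replicates for the null
simulation, 10–20 simulation seeds for averaged recovery. The global-null
check asserts mean false-discovery proportion ≤ α + 3·(Monte-Carlo SE).

Degenerate inputs: constant features raise a distinct error in the scalar
API and are excluded (logged) at build time; pairs whose complete-case
subset is constant are marked undetected; empty p-vectors yield empty BH
output; k = 0 queries return empty lists with the header still emitted at
the CLI.

HDF5 stores are written with object/dataset timestamps disabled, so builds
from identical inputs are byte-identical — determinism is testable by file
hash, and the payload SHA-256 recorded in the metadata supports integrity
checks across copies.

## Known limitations

* The whole condensed payload is held in memory on open; the 17,328-feature
  store needs ~1.2 GB. Out-of-core queries are out of scope.
* BH q-values assume independent or positively dependent tests; neighbor
  scans of a hub violate independence mildly. No Benjamini–Yekutieli option
  is offered.
* GO filtering is plain substring matching on term text, not
  ontology-aware expansion.
* Identifier resolution is tiered exact matching; it does not attempt fuzzy
  or versioned-accession matching.
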