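# Methods

This note documents the statistical procedures implemented in `ctscreen`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was genuinely
open.

## Testis-bias screen

Each source atlas contributes one aggregated expression value per gene per
tissue (replicate samples are collapsed by arithmetic mean; the sources'
units — TPM, FPKM, RSEM — are never mixed, since the proportional score is
scale-invariant within a gene and comparisons only ever happen within one
source). The proportional score divides the testis value by the row sum over
all tissues; a gene whose row sum is zero has an undefined score and fails
every tier, avoiding a 0/0. Tier thresholds (default 0.9; stringent 0.99)
are **inclusive**: a gene at exactly 0.9 passes. The cross-source consensus
is the **union** of per-source passing sets — the working set is the
non-redundant total across atlases — with intersection mode available in
config. Genes absent from a source simply contribute no result there. Venn
region counts over the per-source membership table are exact set
enumerations, so overlap structure is auditable.

## CT calling

A tumor sample counts as expressing a gene iff its value is **strictly
greater** than the expression cutoff (default 1, in the tumor matrix's
declared unit); the prevalence threshold (10%, stringent 15%) is
**inclusive**. The denominator is the number of *informative* samples —
samples with a non-missing value for that gene — so missingness can never
inflate prevalence. The prevalence comparison is done on exact rationals
(`n_expressing / n_informative` against the decimal threshold), because at
cohort sizes like 60 the product `0.1 × 60` is not representable in binary
floating point and a naive comparison misclassifies the boundary. These
choices make two structural laws hold on *any* input, both enforced as
always-on tests: raising either threshold never adds a catalog gene, and the
four-cell stringency grid nests,
catalog(0.99, 15%) ⊆ catalog(0.99, 10%) ⊆ catalog(0.9, 10%) and
catalog(0.99, 15%) ⊆ catalog(0.9, 15%) ⊆ catalog(0.9, 10%).

## Monte Carlo cancer-gene enrichment

S-scores are consumed, never computed. Classification cutoffs are inclusive
(≥ +3 oncogene-like, ≤ −3 suppressor-like; a strict mode is exposed in
config). The null for "how many cancer genes would a random set this size
contain" is built by drawing gene sets of the query's size uniformly
**without replacement** from the universe of genes with a non-missing
S-score in that tumor — so the exact null is the hypergeometric law, which
the test suite uses as an independent closed-form oracle (agreement within
3 Monte Carlo standard errors at 50,000 draws). The three category tests
(oncogene, suppressor, both) share the same simulated draws within a tumor
for coherence. Empirical p-values use the add-one correction
p = (1 + #{null ≥ observed}) / (n_sims + 1), so no p-value is ever zero;
the two-sided call doubles the smaller tail (capped at 1) at α = 0.05, and
both one-sided values are always reported. Default n_sims = 10,000.

## Survival screen

The Kaplan–Meier estimator and the unweighted two-group log-rank test are
implemented in-package because the screen needs two quantities standard
library interfaces do not expose together: the signed O−E of the expresser
group (which sets the prognosis direction) and the curve itself for
restricted-mean integration. Both are verified against a naive O(n²)
reference and against lifelines to 1e-10 in the test suite. The variance
term uses the standard hypergeometric form with the (n−d)/(n−1) tie
correction; a comparison with zero total events, or zero variance, is
flagged undefined rather than reported as a test.

Per tumor, every catalog gene with at least 30 expressers among samples
having clinical data is tested (expressers vs non-expressers, expression
strictly > 1). p-values are converted to q-values **within tumor type**
(pooling available in config) by Storey's method: π₀ estimated on the λ
grid 0.05…0.95 (step 0.05) via a cubic smoother evaluated at λ = 0.95,
falling back to π₀ = 1 — plain Benjamini–Hochberg — when fewer than 100
p-values are available or the estimate leaves (0, 1]. The significance
cutoff is q ≤ 0.05, inclusive. Direction is "good" when the expresser group
has fewer deaths than expected (O−E < 0).

The three-tier dose–response check replaces a manual inspection of tiered
survival plots with an explicit, testable surrogate: patients split into
no-expression / below-median / above-median (the median over expressing
samples only; ties at the median fall below), and the restricted mean
survival time (area under each tier's KM curve up to the largest event time
common to all tiers) must be strictly ordered consistently with the
two-group direction. A tier smaller than 10 patients (configurable) or
without events makes the pattern undefined rather than false. This is a
surrogate with its own operating characteristics, not a reproduction of any
manual procedure; the two-group result is always reported independently.

## CD8+ infiltration association

The CD8 score scale is unknown a priori (it is an upstream estimate), so all
tests are rank-based and therefore invariant to monotone transforms of the
score: two-sided Wilcoxon rank-sum for two tiers (exact null enumeration
when both groups are ≤ 25 and tie-free, normal approximation otherwise),
Kruskal–Wallis plus a Spearman trend over the ordered tier index for three.
The aggregate signal per sample is the **count** of good-prognosis CT genes
expressed above the cutoff, median-split into high/low (ties low); the
alternative operationalization (mean expression z-score) was considered and
rejected to keep the aggregate unit-free and robust to one gene's scale.
Sample sets are inner-joined on IDs; a constant score or constant aggregate
is untestable and flagged.

## Synthetic data

The generator emulates the statistical structure the screen assumes, at a
desk scale chosen once: 1,000 genes, 16 tissues, 3 source atlases, 50
planted testis-restricted genes laid out on a known Venn design (40% in the
all-source region, remainder spread over pairs and singles); 3 tumor types
of 120 samples; planted CT prevalences 0.2–0.5 against background sporadic
expression at rate 0.01; S-scores N(0, 1) with planted oncogenes/suppressors
at N(±4.5, 0.5) in 5% + 5% of genes, planted only *outside* the testis set
so the depletion the enrichment stage should detect is built in (5% makes
the expected null cancer-gene count in a 50-gene query ≈ 5, large enough
that an observed count of 0 is significant; at 2% it would not be);
exponential survival with baseline hazard 1/1000 per day, independent
exponential censoring at 1/2000 per day, and hazard multiplied by 3 (poor)
or 1/3 (good) for samples expressing a planted prognostic gene; CD8 scores
1.5 × (count of designated genes expressed) + N(0, 1).

Deliberate idealizations: expression values are i.i.d. log-normal with no
gene–gene or sample–sample correlation, no batch effects, no shared
multi-gene programs; CT planting is exact-count (not Bernoulli) so boundary
tests are deterministic; hazards are exactly proportional. Passing tests
therefore demonstrates correctness of the *procedures* under the assumed
model — thresholds, tests, multiplicity control, orderings — not robustness
to the correlation structure, dropout or annotation noise of real atlas and
tumor data. One global seed expands into fixed per-component substreams, so
identical seeds give byte-identical bundles and any component can be
regenerated independently.

## Numerical and I/O choices

All tables are UTF-8 TSV with `NA` for missing; floats are written with the
shortest round-tripping representation and parsed back through Python's
exact `float()` (pandas' fast numeric coercion is off by one ulp on some
values, which would break byte-level round-trip guarantees). Gene
identifiers are opaque strings; harmonization across sources is an upstream
precondition. Survival time is fixed to days. Every pipeline run writes a
manifest with input SHA-256 digests, config snapshot, seed and per-stage
timings.

## Known limitations

No Cox regression or multivariate adjustment; no GO enrichment; no
comparison against external CT catalogs; no expression normalization across
sources; the manual-inspection surrogate (RMST ordering) has no published
reference behavior to calibrate against; and the generator's independence
assumptions mean power estimates here are upper bounds for correlated real
data.
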