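# Methods

This note documents the models, numerical choices and known limitations of
the package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Supervised admixture estimation

An individual's genotype dosages g ∈ {0,1,2} at L biallelic loci are modelled
as independent Binomial(2, p_j) draws with p_j = Σ_k q_k F_kj, where F is a
fixed K×L matrix of ancestral allele frequencies and q lies on the
K-simplex. The log-likelihood includes the binomial coefficient term
log C(2, g_j) — constant in q, so irrelevant to the maximiser, but it makes
the reported value the genuine log-probability of the data.

The maximiser is the classical multiplicative EM update

    q_k ← q_k/(2L′) · Σ_j [ g_j F_kj/p_j + (2−g_j)(1−F_kj)/(1−p_j) ],

with L′ the number of non-missing loci. The update preserves the simplex
exactly (the new coordinates sum to 1 by construction) and increases the
likelihood monotonically, which the test suite asserts along the EM path.
Defaults: `tol=1e-7` on the relative log-likelihood change, `max_iter=2000`,
frequency clamping to [1e-6, 1−1e-6] so fixed loci cannot produce infinite
logs. Missing genotypes are dropped per locus, not imputed. If every row of
F is identical the likelihood is flat in q; the estimator returns the
uniform vector and sets an `unidentifiable` flag rather than reporting an
arbitrary interior point. Near-degenerate F (rows differing by ~1e-3 or
less) makes the likelihood nearly flat and EM, like any first-order method,
converges to the tolerance before reaching the crest of an almost-level
ridge; the grid-search equivalence checks therefore require at least one
locus separating the components by 0.1.

The multiplicative EM was chosen over projected gradient or SQP because
feasibility and monotonicity come for free and its per-iteration cost is a
pair of matrix products, which lets the implementation estimate all
individuals of a cohort simultaneously.

LD pruning follows the standard sliding-window rule: windows of 50 SNPs
advancing by 5, removing the later-indexed member of any still-retained pair
with squared Pearson dosage correlation above 0.2. Monomorphic loci have
undefined correlation and are never removed (they are counted and logged).

## Coordinate prediction

Admixture vectors are compared by plain Euclidean distance. Geographic
distance is the haversine great circle on a sphere of radius 6371.0088 km;
coordinates are WGS84 decimal degrees.

Prediction against a reference panel (populations with recorded sampling
locations and admixture centroids — centroid matching, i.e. the arithmetic
mean of member vectors re-normalised, is used rather than nearest-member
matching) proceeds as:

1. rank populations by centroid distance GEN_i, ties broken by
   lexicographic population label; take the nearest M (default 10);
2. weights w_i = (GEN_best/GEN_i)^p with p = 4; if GEN_best = 0 the
   prediction is exactly the best population's location;
3. λ = slope of the least-squares regression *through the origin* of
   great_circle_km(best, i) on (GEN_i − GEN_best) over the selected
   non-best populations — the local conversion from genetic to geographic
   distance;
4. the candidate point is the weighted spherical mean of the selected
   locations, computed on 3-D unit vectors (robust at the dateline and
   poles); the final prediction moves from the best population's location
   toward that candidate by at most λ·Σ ŵ_i·GEN_i (normalised weights),
   whichever of the cap and the full displacement is smaller.

The displacement cap is the package's own resolution of a genuinely open
design point: the cap must vanish as GEN_best → 0 (so exact matches stay
fixed points) yet must not collapse for symmetric mixtures whose two parents
sit at equal genetic distance (so 50/50 mixtures can reach the parental
midpoint). The weighted mean genetic distance satisfies both; a cap based on
deviations from the best match (GEN_i − GEN_best) would fail the second
requirement. The sharpening exponent p = 4 keeps predictions anchored near
the best-matching population, which is what makes panel-level leave-one-out
accuracy meaningful at country scale.

Assignment accuracy at a threshold t counts predictions whose distance to
their true region is ≤ t. The default region oracle measures distance to
the region's recorded population sites (0 at a site); a polygon oracle
reading GeoJSON country geometries is provided as an optional alternative
and is an approximation in a different direction (political borders, planar
distance converted at the query latitude). Site distance systematically
overstates the distance of a prediction that is inside a country but far
from any sampling site; this is documented rather than corrected.

## Panel curation

Each round: (1) every individual is predicted with its entire parent
population (all subpopulations) removed from the panel; (2) individuals
predicted inside their region or strictly less than 200 km outside it are
retained ("within t km" accuracy is inclusive; the 200 km retention rule is
strict, mirroring its "less than" phrasing); (3) retained populations are
re-split by k-means (k = 2, five replications, best inertia); (4) the loop
stops when the round's correct-assignment rate — same oracle, same 200 km —
exceeds the 80% target, or at `max_rounds`. Populations keep more than four
members or are dropped when recompiled.

The split-acceptance ratio is between-cluster sum of squares over total sum
of squares (the explained-variance ratio). Its direction is configurable:
`accept_above` (default) accepts splits explaining ≥ 0.9 of the variance,
which matches the procedure's purpose of isolating genuinely distinct
subgroups; `accept_below` implements the literal "< 0.9" reading of the
printed rule the procedure descends from, whose ambiguity is flagged in the
curation report (`ratio_mode`). Clusters of three or fewer members are
removed when a split is accepted; populations under four members are never
split.

Retention is monotone (each round's survivors are a subset of the previous
round's), and the loop is a strict fixed point on its own output whenever it
converged at accuracy 1.0 — the regime the synthetic worlds reach; when it
stops between 80% and 100% a re-run may remove a few more individuals, which
is inherent to a threshold stopping rule and documented rather than hidden.

## Synthetic worlds

The generator emulates the one assumption the whole pipeline rests on:
admixture signatures vary smoothly with geography. K ancestral components
are anchored at source coordinates; the expected admixture at location x is
α_k(x) ∝ exp(−d(x, s_k)/τ) with τ the decay scale in km; individuals draw
q ~ Dirichlet(c·α(x)), so c (the concentration) controls within-population
dispersion; ancestral allele frequencies draw Beta(0.5, 0.5) per component
and locus (a U-shaped spectrum giving well-differentiated components);
genotypes draw Binomial(2, Σ_k q_k f_kj) independently per locus.

Defaults are the package's standard study conditions: 30 populations × 20
individuals, K = 9, τ = 1000 km, c = 50, L = 10,000 loci. Populations sit on
a deterministic grid inside a bounding box of latitude 10–50°, longitude
20–80° — a continental-scale span (~4500 × 5000 km) placing populations
roughly 1000 km apart, a realistic sampling density for a panel of 30
populations. Grid populations are grouped into 2×2 blocks serving as
multi-site "countries" for the region oracle; individuals sit exactly at
their population's site. A single integer seed drives one generator stream
with deterministically spawned per-entity substreams, so equal seeds give
byte-identical worlds.

What the generator does *not* emulate: linkage disequilibrium (loci are
independent, so the LD pruner is exercised on duplicated/correlated columns
constructed in tests, not on realistic haplotype structure), ascertainment
bias of genotyping arrays, uneven sample sizes, population structure that
violates the smooth-decay assumption (recent migration, isolates), and
pseudo-haploid ancient genotypes (all inputs are treated as diploid
dosages). Passing tests therefore demonstrate correctness of the machinery
and recoverability under the model's own assumptions, not performance on
real cohorts.

## Distance, haplogroup and IBD statistics

* The genetic distance *d* of an individual to a population is the minimum
  Euclidean distance to its members; within-population medians exclude the
  focal individual (its self-distance would be identically 0). Distances
  live on [0, √2] and are additionally printed as percentages.
* The distance graph connects individuals with pairwise distance strictly
  below the threshold (default 0.3); it is undirected with no self-edges.
* Component comparisons use the two-sample Kolmogorov–Smirnov test with the
  asymptotic two-sided p (scipy); at the sample sizes used in calibration
  (n = 100 per group) the asymptotic null is accurate, which the type-I
  error experiment verifies.
* Fisher's exact test is two-sided by the point-probability rule (sum of
  hypergeometric outcomes no more probable than the observed table), the
  convention of standard statistical software; the odds ratio is the sample
  odds ratio ad/bc, flagged infinite when bc = 0. The "most common"
  haplogroup rule is boundary-inclusive at 5%. Collapse rules (e.g. "R
  excluding R1a" as one unit) are declarative and applied before
  tabulation. Pooled and per-population comparison modes are both provided
  because published phrasing alternates between them.
* IBD post-processing is the fixed pipeline combine → concatenate → filter.
  Scores pass strictly below e⁻¹⁰ (lower = stronger evidence). Marker
  indexes are 0-based inclusive; the gap between [a,b] and [c,d] is
  c − b − 1 markers, joined when strictly under 50. Centimorgan lengths of
  merged intervals use the pooled cM-per-marker density of the contributors;
  the gap contribution interpolates the mean flanking density
  (`gap_mode="ignore"` adds nothing instead). The paper-trail for the
  combination of detector runs does not restate the original algorithm, so
  the union-then-merge reading is adopted and noted here.
* Admixture dates convert generations to years at 25 years/generation:
  midpoint = generations × 25, half-width = se × 25, calendar interval
  anchored at a configurable reference year.

## Bundled example data

`biogps.datasets` ships two *synthetic* haplogroup count tables for a
Druze-like Levantine community (mtDNA n = 320, Y n = 343). The Druze
marginal counts are integers chosen to reproduce frequencies characteristic
of published Israeli Druze uniparental surveys (e.g. mtDNA H 31.88%,
K 12.81%, X 12.81%; Y most-common set 94.17%, K+L 14.58%, J1+J2 33.53%);
the within-aggregate splits and all comparison populations are invented.
They exist as worked examples and fixtures, not as data.

## Problem sizes and determinism

The validation experiments (package module `biogps.validation`, used by the
test suite and the reproduction script) run at: 15 populations for the
fixed-point check; 25 symmetric-panel trials for the midpoint contract; the
default 600-individual × 10,000-locus world for end-to-end recovery (the EM
fit dominates the runtime at a couple of minutes on one CPU); 100 random
2×2 tables for Fisher-vs-enumeration agreement; 1000 replicates of n = 100
samples for KS calibration. All take explicit seeds; every stochastic
default in the package is reproducible from a single integer.

## Known limitations

* The genetic-to-geographic conversion assumes the panel's gen–geo scaling
  is locally linear; predictions for individuals whose true origin lies far
  outside the panel hull saturate at the cap and are biased toward the
  best-matching reference population. This is by design (biogeographic
  affinity, not birthplace).
* Site-distance regions are a stand-in for political borders; accuracy
  numbers under the two oracles are not directly comparable.
* The curation stopping rule measures accuracy at the retention threshold;
  panels converging just above the target are near- but not exact fixed
  points.
* Supervised admixture treats ancient reference frequencies as known
  constants; uncertainty in F is not propagated.
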