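# Methods

## The problem

Traditional crop landraces are heterogeneous populations maintained by
farmers; a germplasm survey collects many accessions (seed lots) and asks
two questions: which accessions carry unusual allelic content worth
prioritising for conservation, and what is the smallest subset of
accessions that still contains every allele observed in the whole
collection. `rareset` implements a complete analysis chain for surveys that
genotype accessions as pooled-DNA **bulks** at SSR (microsatellite) loci:
binary bulk scoring, a per-accession **coefficient of rareness**, a
deterministic greedy **core-collection** selector, and the supporting
diversity and marker–trait association analyses.

## Data model

Each accession is genotyped as `B` bulks (default 3) of `n` plants
(default 10). A bulk is scored 1 for a marker/allele combination when the
allele was detected in the pooled DNA, 0 otherwise; columns are labelled
`MARKER_allele` (the allele part is a string, so failed-PCR "null" alleles
are ordinary columns, never missing data). Collapsing the bulks of one
accession by summation gives the integer z-score in `0..B`: the number of
bulks presenting the combination. Because DNA is pooled, presence means
only that at least one of the `n × ploidy` haplotypes in the bulk carries
the allele; within-accession allele frequencies are *not* estimable from
bulk scores, and the package deliberately offers no such estimator. The
per-bulk detection probability of an allele at within-accession frequency
`p` is

    P(detect) = 1 − (1 − p)^(n · ploidy)

so with 10 diploid plants per bulk an allele at p = 0.1 is seen in a bulk
with probability 1 − 0.9²⁰ ≈ 0.878, and across 3 bulks is almost never
missed entirely.

## Coefficient of rareness

For accession *i* over M columns with collection-wide column means z̄_j,

    R_i = (1/M) Σ_j (z_ij − z̄_j)²

Column means include the focal accession (a leave-one-out variant exists
behind `include_self=False` but is not the default). R_i is large for
accessions whose allele content deviates from the collection average —
carriers of rare, private or unusually combined alleles. Accessions are
binned into five ordered classes (very common, common, average, rare,
very rare) at the empirical quantiles of R; the default levels
(0.40, 0.60, 0.77, 0.97) put roughly 77% of a typical collection in the
three common classes, 20% in "rare" and 3% in "very rare", and are fully
configurable. A value tied with a class boundary goes to the rarer class,
so a degenerate all-equal R distribution collapses deterministically into
the single rarest-consistent label. R may be computed on any accession
subset (e.g. with or without outgroup material); the caller controls the
subset simply by what the matrix contains.

## AMA core selection

AMA ("All Marker Alleles") is a greedy set cover with rarity
prioritisation. A column counts as covered by accession *i* when
z_ij ≥ 1 — one witnessing bulk suffices. The loop:

1. seed with the accession of maximal R_i;
2. repeatedly add the unselected accession covering the most not-yet-covered
   columns, breaking gain ties by higher R_i;
3. stop when every coverable column is covered.

All remaining ties break on the lexicographically smallest accession id, so
the algorithm is fully deterministic — two runs on the same matrix give
byte-identical cores, in contrast to stochastic core-selection searches.
Columns present in no accession (possible after subsetting) are excluded
from the target with a warning rather than blocking termination. Greedy set
cover is not optimal but obeys the classical bound
|greedy| ≤ (1 + ln M)·|optimum|; an exhaustive minimum-cover search
(size-ordered subset enumeration, capped at N ≤ 20, no ILP dependency)
serves as the optimality oracle, and on 200 random instances the measured
mean size ratio is ≈ 1.1 with the bound never violated.

## Diversity analyses

*Distances.* Euclidean, at bulk level on the binary profiles and at
accession level on z profiles. Bulk entities are labelled `accession·bulk`.

*Within/between statistics.* Bulk-pair distances split into pairs sharing
an accession vs pairs across accessions; summary means/medians, their
ratio, and a Welch two-sample t-test. Pair distances are not independent
observations, so the parametric p-value is anti-conservative; a label-true
permutation p-value is available via `permutations > 0`. If every pair
distance is identical the test is undefined and reported as missing with a
note.

*UPGMA.* Size-weighted average-linkage clustering implemented directly so
the tie-break is pinned: among minimal-distance pairs, merge the pair whose
sorted member-label tuples are lexicographically smallest, and emit
children in lexicographic order. The result is therefore invariant (up to
cophenetic equality) to input row order. Trees are returned as scikit-bio
`TreeNode` objects and serialize to Newick; on tie-free inputs the
cophenetic distances match SciPy's average-linkage exactly (cross-checked
in tests).

*Jackknife.* Leave-one-column-out sensitivity of the accession dendrogram:
sensitivity_j = 1 − Pearson correlation between the cophenetic vectors of
the full tree and the tree rebuilt without column j. A zero-variance column
has sensitivity exactly 0. Excluding one copy of a duplicated column is
*not* a no-op for Euclidean distances (it removes that column's squared
contribution from every pair), but the two copies are interchangeable and
always receive identical sensitivities; that equivalence, not a zero, is
the redundancy property the tests assert.

*Geography.* Collection-site distances are great-circle (haversine,
Earth radius 6371 km) on decimal lat/lon — at the intra-state scale of a
landrace survey this is equivalent to planar projected distances. The
genetic-vs-geographic association is a Mantel permutation test (seeded,
via scikit-bio) on the two condensed distance vectors.

## Association analyses

*Group screens.* For a categorical grouping (race, kernel color), each
group with at least `min_size` accessions (default 10) is tested against
all others, per column, two ways: a Welch t-test on z, and a G-statistic
(likelihood-ratio) contingency test, by default on the 2×2 table of
presence (z ≥ 1) vs absence, optionally on the full 2×(B+1) table of z
levels (`dichotomize=False`). G = 2 Σ O ln(O/E) with a chi-square tail.
Columns that are constant (t-test) or have a degenerate margin (G-test)
are reported untested with a note. Benjamini–Hochberg q-values are
computed over the whole group×column family of one run; the default
screening level is FDR ≤ 0.001. The reported direction is the sign of
(in-group mean − out-group mean), which the two tests agree on for
well-separated groups.

*Altitude regression.* Forward-stepwise OLS of meters above sea level on
the z columns: starting from the intercept, the candidate most improving
the criterion is added until no candidate improves (criterion `bic` by
default; `aic`, or `pvalue` with entry threshold 0.05). Candidates that
would make the design rank-deficient are skipped with a note, and
selection stops early once the residual sum of squares is numerically
exhausted (an exact fit). The full selection path is returned. This is a
generic variable-selection screen, not an inference-grade model — forward
selection invalidates naive post-selection p-values, which are reported
as descriptive quantities only.

## Synthetic collections

The simulator generates study-shaped data for validation and power
experiments. Defaults mirror a realistic landrace survey: 185 accessions,
14 SSR markers whose allele universe totals 278 marker/allele
combinations, 16 races, 3 bulks of 10 diploid plants per accession.
Frequencies follow a three-level Dirichlet hierarchy: collection base
vectors per marker; race vectors drawn around the base with divergence
parameter `race_frequency_divergence` (0 disables race structure; default
0.5); accession vectors drawn around their race with concentration
`accession_concentration` (default 20, giving realistic within-race
heterogeneity). Each bulk draws `n × ploidy` haplotypes per marker from
the accession's frequencies; presence = drawn at least once. Optional
features:

* **planted rare accessions** — private alleles inserted at a chosen
  within-accession frequency; `private_allele_plan` plants one private
  allele per marker, the allele content of a fully distinct
  (outgroup-like) genotype, which is the scenario the recovery experiments
  use (a single private allele at one locus barely moves R_i and is not,
  by itself, a rare accession);
* **altitude effects** — a column's frequency weight is multiplied by
  `exp(slope · (masl − 1900 m)/1000)` and the marker renormalized;
* **false negatives** — per bulk-call drop-out rate, off by default; 0.005
  emulates the ~0.5% missed-call rate typical of repeated-PCR designs;
* race-clustered coordinates and race-correlated altitudes, so geographic
  and altitude analyses have signal.

What the simulator does *not* emulate: linkage between markers, stepwise
SSR mutation/homoplasy, fragment-size binning artefacts, or real
geography. Passing recovery tests therefore demonstrates the statistical
machinery under the stated sampling model, not robustness to genotyping
artefacts beyond the false-negative knob.

Experiment design note: the altitude-effect recovery experiment disables
race divergence, because with race-structured genotypes and
race-correlated altitude many columns genuinely track altitude through
shared ancestry and forward selection may legitimately pick them first;
setting `race_frequency_divergence=0` isolates the planted effect.

The `survey_shape` fixture (240 accessions × 3 bulks × 278 columns, 36 race
labels) additionally pins any never-drawn allele into one bulk so the full
column universe is witnessed; it is a shape/scale fixture, not a
re-creation of any real dataset.

## Problem sizes and numerics

Validation experiments use sizes chosen to make the oracles exact and the
runs quick: the rareness oracle sweep uses 100 random matrices up to
50×100 (agreement to 1e-12); the cover comparison 200 instances with
N ≤ 15, M ≤ 30 (exhaustive search stays trivial); recovery experiments 50
seeded replicates of 100-accession collections; ultrametricity is checked
to 1e-9. Branch lengths are serialized at full float precision. All
randomness flows through `numpy.random.Generator` seeds; fixtures and
simulations are bit-reproducible from their seed.

## Known limitations

* The within/between t-test treats pair distances as independent samples
  (they are not); use the permutation option when the p-value matters.
* Forward selection is a screen; selected-term p-values are
  post-selection and optimistic.
* The brute-force cover oracle is exponential and hard-capped at N = 20.
* Rareness quantile classes are relative to the analysed collection;
  adding or removing outgroup accessions changes every class label, which
  is why the matrix subset is the caller's explicit choice.
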