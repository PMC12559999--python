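# Methods

This note documents the models implemented in `phyloconflict`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter when reproducing output.

## Multispecies coalescent simulator

`simulate_gene_trees` samples one haploid lineage per species tip and runs
the standard coalescent within each species-tree branch: with *k* lineages
present, the waiting time to the next coalescence is exponential with rate
k(k−1)/2, time is capped at the branch's length in coalescent units, and
surviving lineages are handed to the parent population. The root population
has unlimited time, so every gene tree is fully resolved with exactly
n_tips − 1 coalescences. Population sizes are absorbed into the
coalescent-unit scale; there is no separate Nₑ parameter, no migration and
no sequence evolution. Gene-tree branch lengths (coalescent units) are
retained for inspection but downstream analyses consume topologies.

The simulator's independent oracle is the closed-form quartet law: an
unrooted quartet whose internal branch has length *t* shows the concordant
topology with probability 1 − (2/3)e^(−t) and each discordant topology with
probability (1/3)e^(−t). The test suite checks convergence at t = 0.1 and
t = 1.0 with 10,000 loci (three Monte-Carlo standard errors), and the
anomaly-zone prediction — modal gene tree ≠ species tree inside the zone —
at 50,000 loci on a 5-taxon caterpillar. These sizes keep the full suite
under half a minute while leaving Monte-Carlo error well below the effect
sizes being verified.

## Estimation-error and pseudo-support model

Real gene trees are estimates. The error model perturbs each internal
branch by a random nearest-neighbour interchange with probability
`base_nni_prob · exp(−length/length_scale)` (default 0.4 and 1.0 coalescent
units), choosing uniformly between the two alternative configurations: the
shorter the branch, the likelier it is mis-resolved. Pseudo-supports on
0–100 are drawn around `100·(1 − exp(−length/support_scale))` (default
scale 0.5), multiplied by 0.45 on perturbed branches, with Gaussian noise
(sd 15) and clipping to [0, 100]. The defaults were picked once so that
short internodes show mostly weak, occasionally strong, conflicting
branches — the qualitative pattern seen in empirical UFBoot2 supports —
and are deliberately not fitted to any dataset. The model does not emulate
alignment length, model misspecification, or correlated errors across loci;
a conflict signature reproduced under it demonstrates the pipeline's logic,
not the error process of any particular dataset.

## Conflict classification

For a species-tree bipartition B and a gene tree G, B is first restricted
to the taxa shared between the two; if either restricted side has fewer
than two taxa the gene is *missing* for that branch. Otherwise G's splits
are induced on the same shared taxon set. If the restricted B appears among
them, the gene supports the branch — strongly iff the displaying split's
support is at least the threshold (default 95). If not, the gene conflicts
— strongly iff some induced split *incompatible* with restricted B (all
four side intersections nonempty) reaches the threshold. Absent supports
count as 0. When several gene-tree edges induce the same split after
restriction, the maximum support is used (a gene displaying a split
strongly anywhere displays it strongly).

Percentages are computed over the full gene count (missing included) for
pie-chart style summaries and over scored genes only for regressions; both
denominators are exposed because published analyses are ambiguous on this
point. Regressions use the natural log of branch length — the base only
rescales the slope and leaves the p-value invariant. A constant response is
returned as slope 0 with p = 1 rather than NaN.

## Anomaly zone

The boundary function a(x) = ln[2/3 + (3e^{2x} − 2)/(18(e^{3x} − e^{2x}))]
is evaluated in natural logs; it is strictly decreasing, diverges as
x → 0⁺ and tends to ln(2/3) < 0, so long parent branches are never
anomalous. x > 30 short-circuits to "not in zone" (a(x) is already far
below 0; e^{3x} would overflow). A zero-length parent branch is treated by
the x → 0⁺ limit: a = +∞, every descendant in zone. The two root-incident
edges of a rooted binary tree are merged into one unrooted branch with
summed length, because quartet-based species-tree methods define
coalescent-unit lengths on the unrooted topology; this convention also
determines branch adjacency for clustering, where anomalous internodes are
grouped into maximal sets of branches sharing a tree node, numbered in
preorder.

## Quartet tests

Counts (n₁,n₂,n₃) per quartet are multinomial. The star test is the
likelihood-ratio statistic 2Σnᵢln(3nᵢ/n) against χ²₂. The T3 test
constrains the MLE to the model {p_major ≥ 1/3, equal minors} with the
major coordinate at the largest count, statistic 2Σnᵢln(nᵢ/(n·p̂ᵢ)) against
χ²₁. The T3 null is a one-dimensional submodel whose asymptotics hold at
interior points but degrade at the center of the simplex where the three
model segments meet; within |p̂_major − 1/3| < 2/√n the p-value therefore
comes from a parametric bootstrap at the constrained MLE (10,000 replicates
by default). The bootstrap implementation is cross-checked in tests against
an independently coded oracle, and the χ² route against the bootstrap away
from the center (agreement within 0.02).

Decision rule (NANUQ convention): reticulate iff p_T3 < α (default 10⁻⁶ —
a small α is appropriate when weakly supported conflict, i.e. gene-tree
error, is prevalent); otherwise star-like iff p_star ≥ β (default 0.1);
otherwise tree-like with the majority topology, ties conservatively
star-like. Summaries always include the α sensitivity grid
{10⁻², 10⁻³, 10⁻⁵, 10⁻⁶}.

NANUQ distances: tree-like quartets contribute 0 to their two cherry pairs
and 1 to the four separated pairs; star-like and reticulate quartets
contribute ½ to all six pairs. The ½ weight for both unresolved classes is
an approximation of the published NANUQ weighting and is configurable.
Exhaustive quartet enumeration is capped (default 500,000) with seeded
uniform sampling beyond the cap.

## ANI analytics

Reciprocal FastANI directions are averaged (asymmetries above one
percentage point warn; one-direction-only pairs are kept with a warning).
Clustering is single linkage — connected components of the ANI ≥ threshold
graph — the minimal rule consistent with threshold clustering; complete
linkage is available for comparison. Cluster ids are assigned by smallest
member label, making output invariant to row order. Gap detection scans
sorted unique pairwise values for consecutive differences ≥ `min_width`
(default 0.5 points); this is exact and equivalent to a grid scan at any
resolution, so the `resolution` parameter (default 0.1) only affects
reported rounding. The ANI generator maps divergence time to expected ANI
through piecewise-linear anchors (100% at 0 My declining to 78% at 750 My),
adds Gaussian noise (sd 0.4), resamples values landing in an imposed gap,
and emits both directions with small asymmetry (sd 0.03). It emulates the
block-plus-gap structure of real ANI mosaics, not fragment-level alignment
statistics.

## Co-occurrence statistics

Pair universes are exact: n_A·n_B cross pairs for distinct OTUs,
n(n−1)/2 within an OTU. Co-occurrence is exact site-id equality (the
sampling design uses fixed 1-ha sites; no distance-based notion is
implemented). Specimens without a fungal-partner identification are
excluded from all counts by default (a flag keeps them in pair totals,
where they can never share). Printed percentages are truncated — not
rounded — to two decimals, matching every cell of the published summary
table (e.g. 26/107 → 24.29); full-precision values are emitted alongside.
The specimen generator assigns each specimen a uniform site and either
copies a co-occurring specimen's partner (with probability
`sharing_elevation`, emulating local vertical transmission of the
symbiont) or draws uniformly from its OTU's partner pool; at elevation 0,
sharing is independent of co-occurrence by construction.

## SNV filter

A (genome, locus) pair is flagged when its maximum non-consensus allele
frequency is ≥ 0.1 (strain-heterogeneity signal); flagged loci are dropped,
and a genome is dropped outright when strictly more than 20% of its loci
are flagged. The strict inequality follows the rule's "more than" wording.

## Problem sizes and determinism

Test and acceptance runs use 4–19-taxon trees, 300–50,000 loci, 2,000
simulated quartets and 10,000-replicate bootstraps — sizes chosen so each
check's Monte-Carlo error is small against the effect it verifies while
the whole suite runs in well under a minute of simulation time. Every
stochastic routine takes an explicit seed and is reproducible
byte-for-byte; `scripts/acceptance.py` derives all sub-seeds from its
`--seed` argument.

## Known limitations

- No network generative model: reticulation is only ever the *alternative*
  hypothesis, never simulated, so power against specific gene-flow
  scenarios is exercised qualitatively (two-tree mixtures), not calibrated.
- The estimation-error model is a stand-in; conclusions about real
  gene-tree error processes require the user's own support values.
- Site concordance factors, divergence dating, ANI computation itself and
  splits-graph layout are upstream/downstream of this package by design.
- The anomaly scan implements the two-branch (parent, descendant)
  criterion only; higher-order anomaly conditions are out of scope.
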