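# Methods

## Model and assumptions

Human mtDNA evolves clonally along maternal lineages; recombination is
absent. The worldwide genealogy is represented as a rooted tree whose
root is the rCRS baseline state and whose edges carry *motifs* — the
variants acquired on that branch. A haplogroup's **expected profile** is
the union of motifs on its root path; a back mutation (an edge entry
flagged `!`) removes the ancestral entry at its position, so reversions
present in real haplogroup trees are modelled explicitly rather than by
token convention. The package assumes:

* variants are point changes (SNVs) or single-base deletions anchored to
  the 16 569-bp rCRS; insertions are rejected at parse time;
* the position-3107 reference placeholder is treated as an ordinary
  coordinate, and circularity is ignored (irrelevant to point variants);
* a sample's true haplogroup is a node of the supplied tree. Calls on
  lineages absent from the tree degrade gracefully to the nearest
  represented ancestor but cannot be more specific than the tree.

Position-only tokens (`12519`) and lowercase transversion tokens carry
unknown alleles; matching treats an unknown allele as a wildcard at its
position. This is exactly how heteroplasmic position-only calls in
published tables are linked to motif variants, and it is deliberately
symmetric and reflexive. Heteroplasmy flags never affect matching; they
are evidence about the sample, not about the lineage.

## Haplogroup scoring

For profile P, haplogroup expected set E (both after removing hotspot
positions — default mask 146, 152, 195, 310, 16182, 16183, 16189, 16519,
configurable), and weighted match count M:

    score = 1/2 * M/|E| + 1/2 * M/|P|

with an empty-denominator ratio defined as 1, so the empty profile
scores 1.0 at the root (rCRS-identical sample) and 0.5 anywhere else.
The two-way (Kulczynski) form rewards completeness of the motif *and*
parsimony of the profile; one-way coverage would let every ancestor of
the truth score 1. M counts expected entries matched by the profile; an
entry matched only by heteroplasmic calls contributes
`heteroplasmy_weight` (default 1.0 — heteroplasmic calls are full
lineage evidence; lower it to discount unstable positions). Ranking is
total and deterministic: score descending, then node depth descending —
prefer the most derived, most specific label — then name. The
monotonicity this buys (extra private variants never raise a node's
score; supplying a missing expected variant never lowers it) holds at
the default weight and is property-tested.

## Pair concordance (mix-up test)

Both profiles are classified; the pair's **somatic differences** are the
symmetric difference of the two variant sets under wildcard matching.
The differences are partitioned against the variant set separating the
two called haplogroups (symmetric difference of their expected
profiles), giving the `lineage_explained_fraction`. Verdicts:

* `CONCORDANT` — calls identical or ancestor/descendant. A tumor may
  legitimately appear one sub-branch deeper or shallower than its
  normal (somatic hits on a motif position, missed calls), so vertical
  displacement is never flagged.
* `SUSPECT_MIXUP` — calls on divergent branches, separated by at least
  `min_divergent_branches` edges (default 2) with at least
  `min_explained_fraction` (default 0.7) of the differences on the
  inter-lineage path. One shared branch can be a genuine somatic hit at
  a phylogenetically recurrent site; the published mix-up cases all span
  whole multi-branch pathways, which these defaults flag with margin.
* `INDETERMINATE` — divergent calls below threshold, or no usable data
  (both profiles empty). No quantitative boundary between "extensive
  somatic homoplasy" and mix-up exists in the literature; the defaults
  are engineering choices, exposed in `QcConfig`.

The verdict and the difference set are symmetric in the two samples.
Raising either threshold can only retract flags, never create them.

## Mixture detection

For a single profile, `k1` is the best fraction of variants explained by
one haplogroup (over all nodes); `k2` the best fraction explained by the
union of two expected profiles. Pairs are searched over the top
`candidate_pool` (default 10) single-lineage calls — with the best
single-coverage node always included, so `k2 ≥ k1` holds by
construction — or over all node pairs with `exhaustive=True`; at fixture
scale the pooled and exhaustive optima coincide (tested), the pool
existing for large external trees. A sample is a mixture when
`gain = k2 − k1 ≥ min_gain` (default 0.2) **and** each component
uniquely explains ≥ `min_unique_support` variants (default 3) — the
second condition prevents a handful of homoplasic matches from
manufacturing a second component. Each variant is assigned to the
component that explains it (ties to the higher-scoring component),
else `residual`. Components beyond two are out of scope: pairwise
unions are what contaminated or swapped material produces, and the
published mixed-ancestry evidence is pairwise. The report exposes the
ranked candidate pairs, because sister haplogroups (e.g. a second
component equally placeable on adjacent sub-branches of the same
lineage) can be near-equivalent explanations; the flag does not depend
on which of them is printed first.

## The bundled fixture tree

No machine-readable worldwide phylogeny ships with the package. The
bundled subtree (40 nodes) contains every haplogroup needed by the
worked examples: the L1b/L1b1a3a and L2/L2a/L2c motifs carry exactly the
variants documented for those lineages (so the case-11 worked example is
exact), while the remaining haplogroups carry plausible,
implementer-chosen motifs of realistic size (2–5 variants per edge) —
they are **fixtures, not biological truth**, and are not claimed to
match any published phylogeny build. One back mutation (position 14766
on the HV branch, reverting a variant acquired on the N branch) is
included so reversion semantics are exercised on the default tree.
Analyses of real data should load a current motif-annotated tree via
`load_phylogeny_file`.

## Synthetic cohorts

`simulate_study` emulates a paired-tissue resequencing study: per
patient a haplogroup drawn uniformly from the tree's **leaves** (real
individuals carry terminal haplogroups), a normal profile equal to the
expected profile (no noise), and a tumor profile adding
Poisson(`somatic_rate`, default λ = 3) private variants — transitions
with probability 0.9 — at positions carried by no motif anywhere in the
tree. Restricting privates to off-tree positions keeps planted truth
and lineage signal disjoint, so truth tables are unambiguous; real
somatic hits at phylogenetically recurrent sites are deliberately not
emulated. Planted artifacts:

* **swaps** exchange tumor profiles between patients from distinct
  root-level clades (paired greedily across the two largest remaining
  clades, so requested counts are met whenever a cross-clade matching
  exists). Distinct-clade swaps are detectable in principle: the
  inter-lineage divergence (≥ ~24 variants between cross-clade leaves
  of the fixture tree) dominates Poisson(3) somatic noise in the
  explained fraction.
* **mixtures** replace a tumor with the union of the patient's lineage
  and a random distinct-clade lineage, marking allele collisions
  heteroplasmic.
* **phantoms** inject recurrent fixed-position calls (alleles fixed per
  study) into a share of tumors; `phantom_fraction` controls the share.

Everything derives from a single integer seed; identical seeds give
byte-identical profiles and truth tables. Not emulated: read-level data,
heteroplasmy allele fractions, sequencing-error models, homoplasy between
planted privates and tree motifs, and partial (sub-motif) contamination
— passing the synthetic benchmarks therefore demonstrates the decision
logic under clean lineage signal, not robustness to every failure mode
of real array or sequencing data.

## Validation problem sizes and results reported

The acceptance script (`scripts/acceptance.py`) recomputes, at run time:
the case-11 normal (6 variants → 4 L1b / 2 L2) and tumor (22 variants,
mixture flag, two-lineage explained fraction) analyses; the A7146G
attribution; the flag rate over the six published cross-lineage pair
scenarios; haplogroup recovery on 200 clean λ = 3 profiles; swap
sensitivity on 100 planted swaps (400-patient cohort, swap fraction
0.25); false-flag count on 100 null pairs; and mixture recall on 50
planted mixtures. These sizes keep the whole validation under a few
seconds on one CPU while leaving the stochastic margins (e.g. ≥ 95 %
recovery, ≥ 90 % recall) statistically meaningful.

## Numerical and degenerate-input choices

* Ratios with empty denominators are 1 in the classifier (see above);
  the lineage-explained fraction of an empty difference set is 0 (such
  pairs are concordant anyway).
* All orderings (ranking ties, report rows, assignment iteration) are
  fixed; reports contain no timestamps, so identical inputs give
  byte-identical output.
* Duplicate (position, allele) calls within one profile row collapse
  with a logged warning; duplicate haplogroup names, per-edge duplicate
  positions, orphan back mutations and malformed tokens are hard errors
  naming the offending line or row.
* Profile scoring never mutates inputs; all public containers are
  frozen dataclasses.

## Known limitations

Calls are only as specific as the supplied tree; the wildcard matching
that links position-only calls to motifs assumes the derived allele of
the motif variant, which published position-only listings do not state;
coding- vs control-region evidence is weighted equally; and the mix-up
and mixture thresholds, while conservative on the worked examples and
synthetic benchmarks, have no claim to optimality on real cohorts with
heavy phantom-call contamination — for such data, extend the hotspot
mask with assay-specific recurrent artifact positions.
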