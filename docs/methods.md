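# Methods

## The inference problem

An allopolyploid genome is a mosaic of subgenomes inherited from distinct
diploid donor lineages.  With single-copy nuclear gene families, each
polyploid contributes one gene copy per retained subgenome to each family,
and the placement of that copy in the family's ML tree identifies its
donor.  `polyorigin` formalizes the per-tree step (origin tagging), the
cross-tree aggregation (node census, type classification, consensus), and
two companion analyses: molecular dating from synonymous-substitution
(Ks) distributions, and detection of plastome recombination, which can
make organellar and nuclear signals disagree about the maternal donor.

## Origin tagging

Trees are rooted on the single outgroup leaf (an error if zero or several
are present).  A diploid section is *monophyletic* in a tree iff the MRCA
of its diploid leaves subtends no diploid leaf of another section;
polyploid and outgroup leaves nested inside the clade are ignored, because
a nested homeolog is the expected signal of allopolyploidy, not evidence
against the section.  Tagging walks from each polyploid leaf toward the
root and stops at the first ancestor with at least one diploid descendant;
the tag is the set of sections of the diploid leaves under that ancestor.
Consequences of this rule:

* a leaf nested inside a clean section clade, or sister to it, gets that
  section as a singleton tag;
* a leaf attaching above the common ancestor of two sections gets the
  multi-origin tag (sorted alphabetically for a canonical form) — ties
  are reported as such, never broken arbitrarily;
* a leaf whose first diploid-bearing ancestor is the root, or whose tag
  would span a non-monophyletic section, is tagged `unresolved`
  (an explicit value that propagates into type signatures, never silently
  dropped).

## Node census

Every internal node (the root included) of every rooted tree yields the
set of section labels under it, with polyploid leaves contributing
pseudo-sections named by species.  Combinations of ≥ 2 labels accumulate
a raw count of 1 and a weight of `1 / n_leaves_under_node`.  The
normalization is a design choice — it penalizes deep nodes whose label
combinations are uninformative — and both raw and normalized tallies are
reported so users can re-weight.  Nodes are counted per occurrence, not
deduplicated within a tree (both tallies make this immaterial to the
ordering of the dominant combinations in practice).

## Type classification and consensus

A tree's signature is, per polyploid species (sorted), the sorted multiset
of its leaf tags, e.g. `Nben:{Alatae},{Noctiflorae}|Ntab:{Sylvestres},{Tomentosae}`.
The control filter keeps a tree iff the control polyploid's singleton tags
all lie in its known parent set and every known parent is covered by some
tag; coverage through a multi-origin tag keeps the tree but flags it, and
an unresolved control tag discards it.  Types are numbered by descending
tree count (`Type001`, ...); groups below `min_trees` (default 3) are
reported but excluded.  The per-type consensus relabels gene copies as
`species_<origin suffix>` (suffix = section initial, or the full name on
initial collision) and applies greedy majority-rule over the member
trees: clades are counted once per tree on complete composite taxa,
candidates with frequency ≥ 0.5 are added in decreasing-frequency order
when compatible with those already accepted, and internal labels carry
the clade frequency.  A quartet-based consensus (ASTRAL) can be run
externally on the emitted per-type tree files and mapping files; the
internal consensus keeps the test suite free of external binaries.

## Ks dating

Ks values are truncated to (0, 2.0] before density estimation (a
saturation guard; configurable), and at least 10 usable values are
required.  The density is a Gaussian KDE with the normal-reference
(Silverman) bandwidth on a 512-point grid over [0, ks_max], renormalized
to unit trapezoid integral; the *peak* is the global argmax within the
search range (default lower bound 0.01), flagged when it hits a range
boundary.  Peak-location accuracy is limited by the grid spacing
(2.0/511 ≈ 0.004 Ks) plus KDE bias, which at the study's peak values
(0.05–0.28) stays well inside ±0.01.

Two dating routes share the calibration `29.5 Mya at Ks = 0.279`
(Solanum–Nicotiana split):

* linear: `age = Ks · 29.5 / 0.279`; the calibration pair maps to its age
  exactly and everything else scales linearly;
* UPGMA: average-linkage clustering of the symmetric Ks-peak matrix
  (node height = merge distance / 2, hence ultrametric and exact on
  additive ultrametric inputs), then all heights rescaled so the
  calibration node sits at the calibration age.

## Phi recombination scan

A column is parsimony-informative iff ≥ 2 states each occur in ≥ 2 taxa
(gaps and N excluded).  Two informative columns are incompatible (score 1)
iff their state intersection graph is cyclic — the exact multistate
criterion, reducing to the four-gamete test for binary columns.  Taxa
with missing data at either column are dropped from that pair; a pair
with < 4 remaining taxa is *not evaluable* and is skipped, a distinct
outcome from compatibility.  Φ is the mean score over informative-site
pairs within `w = 100` alignment columns (distances in original columns,
so reported coordinates stay in alignment space).  Significance comes
from permuting the ordering of informative columns, with the add-one
estimator `p = (1 + #{Φ_perm ≤ Φ_obs}) / (n_perm + 1)`; the analytic
normal approximation of the null is deliberately not implemented, so
p-values are bounded below by `1/(n_perm+1)`.  The sliding scan
(1000-column windows, step 250 by default) merges overlapping or adjacent
windows with p < 0.01 and reports merged intervals longer than 5 kb, in
1-based inclusive coordinates (BED output converts to 0-based half-open).
Plastome alignments can first be partitioned into LSC/SSC/IR regions.

## Chromosome painting

Per-chromosome origin percentages are computed over loci with a resolved
origin (unresolved loci are excluded from the denominator); ancestor
combinations such as `Noctiflorae-Petunioides` are first-class origin
categories.  A chromosome's enrichment label is the sorted join of
origins strictly above the threshold (default 20%), or the single
dominant origin when fewer than two exceed it.  Genome-wide totals use
the same resolved-locus denominator.

## Synthetic data: what it emulates and what it does not

The generator fixes a scenario: donor sections and their diploid species,
polyploids with true donor sections per subgenome, per-donor retention
probabilities (the *origin mixture*), an outgroup, and true Ks modes.

* **Gene trees** are built on a fixed section backbone (ladder of sorted
  sections, ladder of species within sections, outgroup at the root) with
  homeolog leaves grafted sister to — or, with probability
  `nest_prob = 0.2`, inside — their true donor clade.  Branch lengths are
  the 0.1 base multiplied by a mean-one lognormal factor with log-sd
  `noise`; supports are uniform in `support_range`.  Discordance is
  injected through homeolog retention (the mixture), not through
  coalescent simulation: the pipeline consumes trees, and this gives
  direct control of the truth tags.  Consequently topology noise never
  contradicts the recorded truth, so tagging accuracy on clean
  simulations is a correctness check of the MRCA logic, not a statement
  about tagging error rates on empirical trees with genuine gene-tree
  estimation error.
* **Ks samples** are lognormal with log-sd `sd` (default 0.2) and the
  *mode* placed at the scenario's true peak, since the mode is exactly
  what the KDE + argmax step estimates.  (Equivalently the median sits at
  `peak · exp(sd²)`.)  Real Ks clouds are mixtures with saturation tails;
  the generator is deliberately unimodal.
* **Mosaic alignments** contain two parent groups diverged by
  `parent_divergence` and evolved internally at per-branch rate
  `mut_rate = 0.01` on a random bifurcating descent, plus recombinants
  that copy one randomly chosen A lineage outside the breakpoint
  intervals and one B lineage inside them, plus private mutations.
  Because each recombinant shares within-group clade mutations on both
  sides, informative-site pairs that straddle a breakpoint are
  four-gamete incompatible while same-region pairs remain tree-like —
  exactly the distance-structured signal Φ tests.  An empty breakpoint
  list gives the clonal null (iid mutations across positions, so the
  permutation null is exact).  Indels, rate heterogeneity and inverted
  repeats are not modeled.
* **Locus tables** place genes uniformly on chromosomes (apportioned by
  length) with per-chromosome origin mixtures; fixed 1 kb gene length.

All generators are deterministic byte-for-byte under a fixed seed; the
CLI defaults to seed 42 while the library API requires seeds explicitly.

## Numerical choices and degenerate inputs

* Support exactly equal to the threshold is rejected (strict `>`), and a
  node with *absent* support fails the support criterion; root and leaf
  branches are exempt.
* Zero-variance Ks samples degenerate to a point mass at the nearest grid
  point; calibration at Ks = 0 or a zero-height calibration node is an
  error.
* Distance matrices must be symmetric within 1e-9; ultrametricity is
  asserted to the same tolerance.
* Φ on an alignment with no evaluable near pair raises a *not evaluable*
  error rather than returning 0.
* Merged region length uses the 1-based inclusive convention
  (`end − start + 1`) with a strict `> 5000` cut, and window significance
  is strict `p < 0.01`.

## Problem sizes used by tests and the acceptance script

Tagging accuracy uses 200 simulated families (jitter 0.3, supports
90–100); the census and monophyly oracles use 50 trees and 500 random
12-leaf trees; Φ calibration uses 2 kb / 10-taxon clonal alignments
(200 replicates in tests, 100 in the script) and 10 kb mosaics with a
single 2 kb tract at divergence 0.05 (100 / 50 replicates), all at
`n_perm = 199`; KDE recovery uses Ks tables of 5000 values per pair;
painting uses 10,000 loci.  These sizes give stable Monte-Carlo
estimates (binomial s.e. ≤ ~2 points on the reported rates) while
keeping the full suite around a minute.

## Known limitations

* The tagging rule is topology-only; branch lengths do not influence
  origin calls, so a misrooted or poorly resolved tree degrades to
  multi-origin or unresolved tags rather than probabilistic assignments.
* The census weight `1/n_leaves` is one reasonable normalization among
  several; raw counts are provided for re-analysis.
* Linear Ks dating assumes rate constancy across lineages; UPGMA
  inherits the same assumption through its ultrametric form.
* The permutation Φ test cannot produce p-values below `1/(n_perm+1)`;
  detecting marginal recombination needs more permutations, not a
  different statistic.
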