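# Methods

This note documents the models and procedures implemented in `parbid`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic tests demonstrate.

## In-silico diagnostic PCR

**Hybridization model.** The real assay runs all four reactions at a
fixed annealing temperature; no thermodynamic model is attempted.
Instead, a primer binds a template site when (i) the total number of
mismatches is at most `max_mismatch` (default 2) and (ii) the
`clamp_len` 3′-terminal bases (default 3) carry at most `clamp_mismatch`
mismatches (default 0). Matching is IUPAC-aware: a primer base matches a
template base whenever the two codes' base sets intersect, so degenerate
primer positions count as matches and a template `N` matches everything
(optionally chargeable as half a mismatch via `count_n_as_half`). The
strict 3′ clamp with a small total-mismatch budget is the conventional
surrogate for polymerase extension failure at 3′ mispairs. All three
knobs are configurable per panel.

**Amplicons and the decision table.** Products are enumerated over both
primer arrangements (forward on plus with reverse on minus, and the
mirror) with inward-facing 3′ ends, up to `max_product` (default 3000 bp
— rIGS regions run to ~1.8 kb, so 3000 leaves headroom). A reaction is
*positive* when at least one product exists and, if the pair declares an
expected size, some product is within `size_tolerance` (default ±15%) of
it — mirroring how "products of expected apparent length" are scored on a
gel. Multiple products for one pair still count as a single positive;
all products are reported. The species call follows the exactly-one
rule; with shared primers across pairs (mani-ID and mhyb-ID share their
forward primer) this rule is what carries the discrimination.

**Marker extraction** is virtual amplification that demands exactly one
product; zero and multiple products raise distinct errors. Anchor
primer sequences (e.g., for the full rIGS or the rIGS-ID800 sub-region)
are assay configuration supplied by the user, not packaged data.

## Alignment

Pairwise alignment is optimal affine-gap dynamic programming (Biopython's
`PairwiseAligner`); `semi_global` mode scores terminal gaps of either
sequence as 0, which is the mode used both for read placement and for
BLAST-style query coverage (fraction of query positions aligned to
subject residues; the ≥90% retention boundary is inclusive). Default
scoring is match +1, mismatch −1, gap open −4, gap extend −1 —
conventional nucleotide values; a length-L gap scores
`open + (L−1)·extend`.

The multiple aligner is a plain progressive scheme: k-mer distances
(k=6, one minus the shared-k-mer fraction over the smaller set),
average-linkage guide order with lowest-index tie-breaks, and
profile–profile merges scored by expected match/mismatch over per-column
A/C/G/T frequencies (gaps and ambiguity weigh zero), with the same affine
penalties. It is deterministic for fixed input order and parameters. It
targets the regime that matters here — marker sequences under ~10%
divergence, where any reasonable aligner agrees — and an externally
aligned FASTA can be supplied instead at every entry point that takes an
alignment. Equal-length records produced by the substitution-only
simulator are accepted directly as alignment rows.

## Phylogeny core

**p-distance, pairwise deletion.** For each pair of rows, sites where
either row carries anything other than A/C/G/T (gap, `N`, IUPAC
ambiguity) are excluded; the distance is mismatches over comparable
sites. Ambiguity codes are treated as missing rather than fractionally
matched — the simpler reading of "gaps and missing data", at the cost of
possible minor discrepancies with tools that resolve ambiguities. A pair
with zero comparable sites is an error naming the pair. The
implementation is vectorized (indicator-matrix products); tests check it
against per-site counting.

**Neighbor joining.** Saitou–Nei agglomeration on the Q-criterion with
the standard branch-length formulas. Ties in Q break to the lowest index
pair in the current node ordering (determinism; the choice is otherwise
arbitrary). Negative branch-length estimates are clamped to zero with
the deficit transferred to the sister edge, preserving the pair's path
length. Output is an unrooted tree with one degree-3 basal node.

**Bootstrap.** Pseudo-replicates resample alignment columns with
replacement; each replicate rebuilds the NJ tree and the supports of the
full-data topology's bipartitions are the percentage of replicates
containing them (bipartition matching, not majority-rule consensus).
Replicate *r* draws from an independent deterministic substream of the
seed, so runs are reproducible and replicate-parallelizable. Rows are
sorted by id internally so tie-breaking — and therefore supports —
cannot depend on caller row order. A replicate that leaves some pair
with no comparable sites is redrawn (logged), up to 100 times.
Rerooting reorients nodes, so supports are re-attached to the rooted
tree by bipartition matching (`attach_supports`) rather than trusting
node labels through a reroot.

**Rooting.** The root bisects the edge separating the designated
outgroup from the ingroup; a non-monophyletic outgroup is an error in
the strict API. The assignment pipeline adds a fallback for the one
situation where strictness is wrong: unlabeled queries that genuinely
belong to the outgroup nest inside it, so the pipeline then roots on the
smallest clade containing every outgroup reference.

## Species assignment and mining

A query's *minimal clade* is the smallest rooted clade containing it and
at least one panel record. The query is assigned when that clade's
ingroup references belong to exactly one species and no outgroup
reference intrudes; queries falling in the outgroup are always
unassigned. The *delineating clade* — the largest ancestor still
containing only that species' references — is what "unambiguous
delineation" from sibling species means, so the bootstrap gate applies
to its support (a query–reference cherry inside a species clade has
arbitrarily low support even when the species delineation is at 100%,
which is why the gate does not apply to the minimal clade). The gate
defaults to 70% when supports were computed and is off (topology-only)
otherwise; both the threshold and its presence are configurable, since
reasonable practice varies.

The mining pipeline filters candidates by ≥90% coverage of the marker
query sequence (inclusive), aligns survivors with the panel, builds the
rooted (optionally bootstrapped) NJ tree, assigns each survivor, and
tabulates counts by prior label, marker, geographic origin and substrate
from an optional metadata sidecar; summary counts always sum to the
retained-query total. Panel-versus-clade reconciliation never drops a
discordance silently: an inconclusive panel with a clade call reports
the clade call as provisional.

## Read recruitment and consensus

Reads are aligned semi-globally to the bait in both orientations and
recruited when the better orientation reaches `min_identity` (default
0.90) over at least `min_overlap` aligned bases (default 50) — chosen to
mimic megablast-like recruitment of same-species reads. An optional
exact-16-mer prefilter can skip alignment; it is off by default because
strict behavior-neutrality is guaranteed only when every matching read
retains an exact 16-mer (true at low error rates, asserted on simulated
data, not provable in general).

The consensus is a per-bait-column plurality vote: the winning base is
emitted, a gap plurality deletes the column, and ties resolve to the
bait base (conservative reference bias, logged as contested). An
insertion is emitted at a junction when more junction-spanning reads
carry one identical inserted string than carry none. Uncovered bait
columns emit `N` and are annotated. Indel calls can be corroborated by
counting reads containing the exact joint flanking sequence (2×25 bp by
default) across the junction in either orientation; windows at sequence
ends are truncated and logged. This deterministic reference-guided
pileup replaces interactive BLAST-plus-Clustal assembly; it is not a de
novo assembler and inherits reference bias at contested columns.

## Synthetic data

The panel simulator draws a random ancestral marker, mutates it once per
species to a species consensus (expected per-site substitution fraction
`inter`, default 5%), and mutates that consensus independently per
reference/query (`intra`, default 0.5%); outgroup records derive from
the ancestor at 15%. The defaults echo a tight species cluster while
keeping assignments unambiguous; the default study condition is 7
species × (3 references + 20 queries) on an 800 bp marker. Mutation is
substitution-only by default (so simulated sets are columnwise
homologous); a small-indel mode (geometric lengths, p=0.5) exercises
pairwise-deletion behavior. Read simulation uses uniform or tiling
starts, per-base substitution errors, and reverse-complements half the
reads. A separate generator produces random unrooted binary trees and
their exact additive distance matrices as ground truth for
tree-reconstruction oracles.

What the generator does *not* emulate: rate variation across sites,
transition/transversion bias, recombination or hybrid ancestry, indel
hotspots, paired-end structure or quality-score error profiles.
Passing tests therefore demonstrate algorithmic correctness under clean,
well-separated divergence structure — not robustness to every artifact
of real survey data, where support values can sink well below the
defaults and the configurable gate matters.

## Problem sizes and numerics

The shipped verification runs use: 1000 randomized cognate templates per
primer pair; 100 random additive matrices on 5–8 taxa; 1000 random
gapped pairs for the p-distance oracle; the 7-species panel above with
200 bootstrap replicates; and 1.5 kb read-recruitment templates at 10×
(error-free) and 30× (1% error) with a 12 bp planted deletion. These
sizes make every probabilistic claim exact (counts, not estimates) while
keeping a full run in tens of seconds. Distance computations are exact
up to float64; matrix symmetry is enforced by averaging against
round-off, and the distance diagonal is pinned to zero.

## Known limitations

- No thermodynamic (Tm/ΔG) primer model; stringency is mismatch counts.
- The progressive MSA has no iterative refinement; column-level
  agreement with any particular external aligner is not promised.
- Bayesian inference is out of scope; NJ + bootstrap is the in-repo
  phylogeny (externally computed trees can be supplied as Newick).
- Mining operates on locally supplied candidate files; there is no live
  database client, so survey-scale counts depend on the user's snapshot.
- The consensus caller has no paired-end awareness and resolves ties
  toward the bait.
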