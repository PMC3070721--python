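# Methods

`abyssotu` re-implements, as a tested pipeline, an OTU-based analysis of
eukaryotic 18S rRNA V9 amplicons produced by 454 pyrosequencing of
deep-sea sediment DNA: primer-anchored quality filtering, strict
dereplication, abundance-greedy clustering under a homopolymer-insensitive
alignment distance, BLAST-style consensus taxonomy, planktonic-origin
classification, and cross-sample occupancy summaries.  Every stage is
exercised end-to-end on synthetic data with known ground truth.

## The homopolymer-insensitive distance

454 sequencing reads homopolymer runs from light intensity, so the
platform's dominant error is a run called one base too long or short.
Treating those miscalls as real differences inflates OTU richness, and
flowgram denoisers that trim reads to a common length sacrifice the
orthologous 3' end of the amplicon.  Instead, the distance used here is a
global (Needleman–Wunsch-style) alignment score in which a column is free
when it only changes the length of a homopolymer run:

* substitution column, `a_i != b_j`: cost 1;
* indel column: cost 0 iff the inserted/deleted base equals the most
  recently consumed base of the opposite sequence (the indel lengthens or
  shortens a run shared by both sequences at that point), else cost 1;
* an indel before any opposite base has been consumed: cost 1.

The distance is the minimum total cost over all global alignments.  Under
this rule `ATGTGGGGTAT` vs `ATGTGGGTAT` is 0, while the presence versus
absence of an entire run remains counted (`ATGGGGAT` vs `ATAT` is 4).
Two provable consequences anchor the test-suite: the distance is 0
exactly when the two sequences have identical run-length-compressed
forms, and it never exceeds the Levenshtein distance.

Because every move into dynamic-programming cell `(i, j)` costs
`[a[i-1] != b[j-1]]` (boundaries aside), an O(nm) DP computes the exact
minimum.  An independent oracle re-derives the minimum by recursion over
alignment columns carrying the last consumed base of each sequence as
explicit state, and a brute-force enumeration of all gapped alignments
(lengths <= 5) validates the oracle itself.  The clustering path uses a
numba-compiled rolling-row kernel with two exact shortcuts: equality of
run-length-compressed forms (distance 0), and early termination once a
full DP row exceeds k (valid because cell values never decrease along an
alignment path).  Neither shortcut changes any boolean the clustering
sees.

The rule's one genuinely open point is the precise context in which the
original implementation considered an indel "inside a homopolymer"; the
column rule above is the reading that reproduces the published worked
example, keeps run presence/absence a counted difference, and admits the
quadratic DP.  It is documented as this package's definition, not as a
claim about the original code.

## Dereplication and greedy clustering

Reads are pooled across samples (cross-sample OTU identity is required by
the occupancy analyses), collapsed to unique tags with per-sample counts,
and sorted by decreasing abundance with lexicographic tie-breaks so runs
are reproducible.  Clustering is a single greedy pass: the most abundant
unassigned tag seeds an OTU; every later unassigned tag within `k`
(default 3) of that seed joins it; tags join the first seed they match
and are never re-assigned to a closer later seed.  Because the distance
is not a metric (free indels are context-dependent), a tag can be within
k of an OTU member yet farther than k from its seed; the greedy contract
deliberately compares seeds only.  OTUs consisting of a single unique
sequence observed once ("single-singletons") are likely artifacts; they
are kept by default and can be dropped by flag.

Rarefaction curves subsample reads without replacement (default 100
permutations, seed 1) and report mean and sd of distinct OTUs observed.

## Similarity, consensus assignment and triage

Queries are searched against the reference database either by the
built-in engine (7-mer seeding, then best local alignment per candidate
under blastn-like scoring +5/−4, gap open 8, extend 6) or by parsing
external BLAST XML; both produce the same hit structure.  Because hits
are local, per-hit similarity is

    similarity = sum(identities − gaps) / query length

summed over a maximal-score set of HSPs chosen greedily by descending
score without query-coordinate overlap, floored at 0.  This is stricter
than identity-over-alignment-length and cannot be inflated by
conserved-domain-only HSPs.  Hits below 0.50 are discarded as noise: on
random 130-bp queries the best spurious local hit reaches ~0.40–0.47
under this scoring, while genuine rRNA relatives sit well above 0.7; the
floor stands in for an E-value cutoff.

Assignment: good hits are those at or above the 80% floor (`>=` by
choice; the source tables write ">80%").  Walking genus → family → … →
domain, the first rank at which >= 75% of the good hits naming that rank
agree supplies the label; hits with no name at the rank leave the
denominator.  No good hits → *unassigned*; no rank ever reaching
consensus → *undetermined* (tabulated inside the assigned subtotal, as in
the source's tables).  A threshold ladder (70, 75, 80, 85, 90, 92, 95,
96, 97, 98, 99, 100% — the misprinted middle entry read as 90) supports
per-clade sensitivity analyses; raising the threshold can only move
queries from assigned toward unassigned.

Domain triage precedes clustering: each unique tag is classed by the
domain-rank consensus of its good hits (fallback: the best hit's domain
when nothing clears the floor, so weak eukaryotic tags are counted as
unassigned eukaryotes rather than non-rRNA); tags with no hits at all are
counted non-rRNA.  Only eukaryotic tags are clustered.

Major-group rollup maps the deepest lineage name with a rule to one of 18
reporting categories (Ciliophora, Dinophyceae, other Alveolata, …, CCTH,
other Eukarya, Undetermined); the shipped table reproduces the source's
category scheme and deepest-match-wins resolves e.g. Ciliophora inside
Alveolata.

The resolution-profile experiment clusters the reference V9 sequences
greedily at 85–99% similarity (global-alignment identity via edlib, or
the homopolymer-insensitive variant with k ≈ (1−level)·median length) and
reports, per level, the fraction of sequences in clusters whose lineage
consensus reaches each rank.

## Planktonic-origin classification

An OTU is putatively planktonic if (a) its assignment lineage contains a
listed phototrophic/planktonic taxon (the shipped table carries the
group-level list: Plantae sensu Chlorophyta/Rhodophyta/Glaucophyta,
Haptophyta, Picobiliphyta, Radiolaria, Bacillariophyta and the other
phototrophic stramenopiles; phototrophic Dinophyceae genera are
user-supplied), or (b) its seed sequence is >= 90% similar to an
environmental sequence labelled marine plankton.  Habitat labels are a
required column of the environmental database — the original mining of
collection-site metadata from publications is out of scope.  The summary
excludes phototrophic OTUs from the environmental marine-plankton row so
no OTU is counted twice, and percentages are over assigned OTUs only.

## Occupancy and region sharing

Presence is >= 1 read.  Occupancy classes count OTUs (and their reads) by
the number of samples occupied, and partition both exactly.  Region
sharing splits OTUs into both-regions versus single-region sets under an
"all samples" and a "min 1 sample" rule; the min-1 sets partition all
OTUs.  Outputs are invariant under sample reordering (regions are
processed in sorted order).  Exactly two regions are required, matching
the two-ocean design; the region map comes from configuration.

## The synthetic survey

The generator emulates the study's data regime; its defaults are the
package's study conditions:

| parameter | default | rationale |
|---|---|---|
| samples | 6 (2 regions × 3) | the two-ocean, three-sample design |
| reads/sample | 10,000 | low end of the per-sample depth regime |
| V9 length | 130 ± 10 bp | short hypervariable region |
| community genera | 120, 3 reference species each | resolvable taxon pool with congeneric structure |
| sibling divergence | species 2%, genus 45%, family 70% | congeners near-identical in V9; genera resolvable at the 80% floor and at k=3 |
| abundances | lognormal, σ = 1.5 | skewed, many rare taxa |
| shared ("bipolar") genera | 40% | both-region taxa exist at every occupancy level |
| planktonic genera | 40% (half phototroph-listed, half via env db) | two-route planktonic ground truth |
| homopolymer miscall | p·(L−1), cap 0.5, p = 0.01 | probability grows with run length, the platform's physics, qualitatively |
| substitutions | 0.001 /base | minor secondary error mode |
| contaminants | 3.5% archaeal, 9.1% bacterial, 0.25% non-rRNA | broad-specificity primer capture rates |
| damaged reads | 1% missing distal primer, 0.2% with N | exercises the primer-anchoring filter |

Reads are full amplicons (proximal primer + noisy insert + distal
primer); the primer sequences are configuration inputs with generator
defaults, never hard-coded in the pipeline.  Lineages reuse real
higher-rank taxon names (Ciliophora, Bacillariophyta, …) so the shipped
grouping and phototroph tables apply to synthetic assignments; genus and
species names are synthetic.

What the generator does *not* emulate: chimeras (the source pipeline did
not screen reads for them; left as an extension hook), quality scores and
flowgram-level structure, intra-genus community mixtures (one species per
genus sheds reads), length variation within a phylum, and any real
phylogenetic signal beyond the divergence ladder.  Passing tests
therefore demonstrate the pipeline's internal correctness and its
behaviour under the stated error model — not recovery performance on real
V9 surveys, where reference incompleteness dominates assignment quality.

## Numerical and design choices

* Distances are computed on primer-trimmed inserts over {A,C,G,T}; reads
  with N anywhere in the insert are rejected at the filter.
* Abundance ties in dereplication break lexicographically by sequence;
  any minimum-cost alignment may be reported by the distance routine
  (only the distance is contractual).
* `>= 0.80`, `>= 0.75`, `>= 0.90` boundaries are all inclusive and
  config-overridable.
* The internal search engine emits one HSP per hit (its best local
  alignment); multi-HSP hits arise from parsed BLAST XML and flow through
  the same non-overlapping-HSP similarity.
* Greedy HSP selection by descending score is the defined behaviour, not
  an approximation contract; on disjoint or duplicated-interval HSP sets
  it provably equals the max-score subset (tested by enumeration).
* Clustering of the reference in the resolution profile orders sequences
  longest-first (ties by id), the conventional centroid-ordering choice.
* Problem sizes in the test-suite: the full-survey checks run one
  six-sample, 60,000-read simulation; distance-oracle agreement uses
  10,000 pairs of length <= 10; smaller fixtures cover everything else.
  These sizes were chosen to exercise the study conditions while keeping
  a laptop run of the suite in minutes.

## Known limitations

* The homopolymer-insensitive distance is not a metric; OTU membership
  depends on seed order (by design, matching the greedy procedure).
* The internal search engine is seeded heuristically (7-mer candidates,
  capped); extremely divergent true hits can be missed where BLAST would
  find them.  The BLAST-XML path exists for exact parity with an external
  engine.
* Consensus assignment counts hits, not distinct reference taxa, so
  heavily redundant references can dominate a consensus.
* The two-region sharing analysis is hard-wired to exactly two regions.
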