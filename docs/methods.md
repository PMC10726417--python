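# Methods

`ohnotype` decides how duplicated homeobox genes arose in a clade that
experienced one whole-genome duplication (WGD): as ohnologues (retained WGD
copies), ancient tandem duplicates (small-scale duplication predating the
WGD), recent tandem duplicates (post-WGD or outgroup), or single-copy
survivors; it places ohnologue losses on species-tree branches, quantifies
the integrity and asymmetry of duplicated gene clusters, maps chromosome-level
macrosynteny, and measures pairwise selection pressure. This note documents
the models, parameters and design choices.

## Duplicate typing

**Timing by reconciliation.** Gene trees are rooted binary trees with
`(species, gene)` leaves; they are inputs (or simulator truth), never
inferred here. Standard LCA reconciliation maps each gene-tree node to the
MRCA of its leaf species; a node is a duplication when its mapping equals
one child's mapping. The family's category is set by the **oldest retained
duplication** — the duplication node closest to the root (preorder
tie-break) whose both children retain at least one surviving, non-pseudogene
descendant:

* mapping **equal to** the WGD branch's child node → WGD-compatible → `O`;
* mapping **strictly ancestral** to it → `AT`;
* mapping below it or on an outgroup branch → `RT`;
* no retained duplication → `SC`.

This is the sharpest operationalization of "duplicated before the WGD": a
duplication on the WGD-bearing branch itself is indistinguishable from the
WGD by LCA mapping, so such (rare) pre-WGD tandem events are absorbed into
`O` with a linkage conflict flag (see below).

**Linkage as secondary evidence.** For each species carrying copies from
both sides of the duplication, the earliest gene of each side is classified
as `clustered` (≤ 10 intervening genes *and* ≤ 1 Mb intergenic distance,
both configurable), `linked` (same chromosome) or `dispersed` (different
chromosomes). Intergenic distance is `downstream.start − upstream.end` on
0-based half-open coordinates. When the majority relation (threshold 0.7 —
the field says "most"/"consistently" without a number; configurable)
contradicts the reconciliation timing (a WGD-dated duplication that is
mostly clustered, or a tandem-dated one that is mostly dispersed), the
reconciliation wins and the call carries a `CONFLICT` flag: tree timing is
the primary criterion, linkage the corroborating one.

**Dollo loss mapping.** Each ohnologue lineage is a presence/absence
character gained exactly once, at the WGD, and losable arbitrarily often.
The minimum-loss placement is unique: one loss on each maximal all-absent
subtree of the WGD clade. A lineage absent from all spiders but present in
the scorpion refines `O` to `SOL`; absent from all entelegynes but present
in a non-entelegyne spider refines to `EOL`; the clades are resolved from
named internal nodes of the species tree. Other loss patterns stay `O`
(species-specific losses) or are reported as `LOSS_other` by
`infer_losses`. A pre-WGD dispersed duplication has no bucket of its own in
this vocabulary; it is categorized by timing (pre-WGD → `AT`) with the
mechanism retained in the evidence.

Pseudogenes — genes whose homeodomain is disrupted by an internal stop
codon — are excluded from copy counts, presence characters and cluster
membership, but stay in all outputs with a flag.

## Family assignment

Similarity is ungapped identity against a fixed 60-column family consensus;
homeodomains are effectively fixed-length, so no affine alignment is used.
Sequences of 55–65 aa are fitted to the consensus by the best trimming
offset (a longer sequence slides over the consensus, a shorter one inside
it; equal lengths compare position-wise). Ranking is (diagnostic residues
all matching, similarity, family name); assignment requires similarity
≥ 0.55. Both thresholds (0.55 assignment, 0.8 single-linkage grouping of
unassigned genes into candidate new `*-un` families shared by ≥ 2 species)
are package defaults — the literature states none — and are surfaced in the
configuration and outputs. Raising the threshold can only shrink the
assigned set (tested as a monotonicity property).

## Cluster integrity

A cluster is a maximal run of template-family genes on one chromosome with
per-step gaps of at most 10 intervening genes and 5 Mb (defaults chosen so
that described ~1 Mb-scale clusters hold together while "linked but not
clustered" separations of tens of Mb split; both configurable and echoed in
outputs). Non-template genes never break a cluster; they only consume gap
budget, since real Hox clusters carry interleaved unrelated genes. Scores:

* `completeness` = fraction of template families present;
* `order_score` = LCS(observed order or its reversal, canonical order) /
  number of members — reversal-tolerant because a wholly inverted cluster
  is still organized; the reordered three-gene case R-H-O vs canonical
  H-R-O scores 2/3;
* `orientation_score` = largest single-strand fraction.

Ohnologous cluster copies are paired by maximal mutual gene-level ohnology
(greedy, deterministic). The more intact copy (completeness, then order,
then chromosome id) is labelled `A` unless a per-template convention names
it otherwise (the naming of intact copies as "A" or "B" is conventional in
the literature, e.g. the intact Hox copy is called B). There is no numeric
definition of "intact" in the source domain; the (completeness, order,
orientation) triple is this package's operationalization and is reported,
not asserted, for real data.

## Macrosynteny

Chromosome orthology is content-based: a contingency table of shared
orthogroups per chromosome pair, then greedy assignment by descending count
(ties by chromosome id, minimum 10 shared orthogroups). Greedy assignment
rather than optimal matching mirrors the visual block-stacking such figures
use and keeps the mapping deterministic; fusions/fissions surface as 2:1 or
1:2 assignments. Orthogroup inference itself is out of scope — orthogroups
are inputs (for simulated data the simulator's stable lineage ids serve).
Collinear chains are extracted by O(m²) dynamic programming over matches,
monotone in both genomes in either orientation with positional gaps ≤ 25,
greedily removing the best chain (length ≥ 5) until exhaustion.

## Selection (NG86)

Pairwise dN/dS uses the Nei–Gojobori counting method with Jukes–Cantor
correction, built in-house so that it is exactly testable against
brute-force enumeration. Site counts split each codon position by the
fraction of sense single-nucleotide changes that are synonymous (so
S + N = 3L exactly); multi-difference codons average over all orderings of
single steps, excluding paths through stop codons (with an all-paths
fallback in the degenerate all-blocked case); ω is reported as NA, never
infinity, when dS = 0 or a log argument saturates. NG86 replaces
likelihood-based codon models (codeML/aBSREL are external tools and out of
scope); in the low-divergence regime the two agree in rank and order of
magnitude, but numerical divergence from ML estimates on real data is
expected. Gap columns of a supplied protein alignment are dropped during
backtranslation; no aligner is bundled, so unequal-length CDS pairs without
an alignment are skipped with a warning.

## The simulator

The synthetic-data generator is first-class, tested code: a forward
simulator along the 14-taxon arthropod tree (three mandibulates, tick,
harvestman; then scorpion + eight spiders, whose stem carries the WGD; all
branch lengths 1). Defaults define the study conditions:

| parameter | default | unit / rationale |
|---|---|---|
| families | 200 | matches the scale of a homeobox superclass survey |
| chromosomes | 7 | doubles to 14 at the WGD, the spider range |
| cluster templates | Hox 10, NK 6, NK2 4, HRO 3, Irx 3, SINE 3 | the six conserved cluster types, instantiated at the root as contiguous canonical-order runs with alternating strands |
| tandem duplication | 0.008 /gene/unit | a handful of AT families, more RT |
| dispersed duplication | 0.002 /gene/unit | rare non-WGD dispersal |
| gene loss | 0.015 /gene/unit | yields realistic SOL/EOL counts (~5–15 per run) |
| inversion / translocation | 0.3 / 0.1 per genome/unit | visible rearrangement without destroying clusters |
| fusion / fission | 0.02 per branch | occasional 2:1 synteny signals |
| CDS substitution | 0.01 /nt/unit, κ = 2, ω-scale 0.25 | ≈ 95 % homeodomain identity at the leaves; purifying, as for developmental regulators |
| pseudogenization | 0.002 per branch | a few stop-disrupted copies per run, as observed |

Sequence evolution proposes Poisson-distributed substitutions, κ-weights
transitions, never creates stop codons, and realizes nonsynonymous changes
with probability `omega_scale`, so the realized dN/dS of a simulated pair is
close to `omega_scale` by construction. Pseudogenization places exactly one
stop inside the homeodomain and freezes it. Coordinates sit on a fixed
10 kb spacing grid (tandem copies at a configurable 1–9 kb offset) rather
than in continuous coordinates, keeping intergenic-distance semantics simple
and deterministic. The WGD is modeled as a single simultaneous doubling at
the branch midpoint. One global seeded stream drives everything; identical
seeds give byte-identical fixtures.

Every event is logged with enough payload that **replaying the log from the
root genome reconstructs each leaf exactly** (asserted in tests), and true
gene trees are grown alongside. Truth categories are computed from the
lineage trees by the same *definitions* the inference uses (oldest retained
duplication; Dollo placement for the lost side's true presence) but from
the log, not the data — so recovery tests measure the inference chain, not
a shared implementation. What the simulator does **not** emulate: intronic
and intergenic sequence, unsequenced/fragmented assemblies, annotation
error, gene-tree estimation error (trees are true topologies), variable
branch lengths, and multiple or lineage-overlapping WGDs. Passing recovery
tests therefore demonstrates the correctness of the inference logic under
clean inputs, not robustness to noisy real annotations.

## Validation design and problem sizes

* Oracle equivalence, all exact (≤ 1e−12 where fractional): reconciliation
  vs a brute-force LCA/clade-overlap oracle on 1,000 random gene trees of
  ≤ 8 leaves; Dollo loss counts vs exhaustive minimum over all loss-branch
  subsets for all 63 presence patterns on a 6-leaf tree; cluster detection
  vs an interval-scan oracle on 500 random layouts; chain length vs
  brute-force chaining on ≤ 15-gene instances (200 cases); NG86 site and
  difference counts vs pathway enumeration on all 61×61 sense-codon pairs.
* Event recovery: default configuration (200 families, 14 leaves, seed
  20231103); the blind chain (assign → flag pseudogenes → reconcile →
  Dollo) recovers ≥ 95 % of categories with ≤ 2 % O↔RT confusion and ≥ 90 %
  of SOL/EOL placements (observed: 100 % at the default seed, ≥ 99 % across
  spot-checked seeds).
* Selection sanity: 50 replicate pairs of 300 codons at divergence 0.2
  subs/site, κ = 1 (the no-bias regime NG86's counting assumes — at κ = 2
  NG86 is known to be mildly downward-biased); neutral median ω ∈
  [0.8, 1.2], purifying (ω-scale 0.1) median < 0.2.
* The published per-species repertoire table ships as a packaged fixture;
  its headline statistics (WGD/outgroup mean-count ratio 1.4; retained
  ohnologue families 37–46) are recomputed from the stored per-species
  values, never stored themselves. Genome-scale re-annotation of the real
  assemblies is out of scope.

## Numerical and degenerate-input choices

0-based half-open coordinates internally; GFF3 converts at the boundary.
Strand must be `+`/`-` (`.` rejected — orientation scoring needs a defined
strand). BED-like input may omit chromosome lengths (default: max gene end).
Species trees may contain polytomies; gene trees must be binary. Empty
clusters are errors; singleton template genes are size-1 clusters. ω = NA
when undefined; ratios over empty species sets are NA. All tie-breaks are
lexicographic and documented at the call site, so identical inputs always
give identical outputs regardless of iteration order.

## Known limitations

LCA reconciliation cannot separate a duplication on the WGD branch from the
WGD itself; rate heterogeneity across branches is not modeled; the linkage
majority uses one representative gene pair per species per duplication;
`summarize_repertoire`'s per-species AT/RT columns count a family by its
global category and that species' copy number, so a lineage-specific tandem
expansion inside an `O` family is visible in copy counts but not in the RT
column; NG86 underestimates ω when transition/transversion bias is strong.
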