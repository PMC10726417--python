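"""Detect homeobox gene clusters and quantify integrity and A/B asymmetry.

A cluster is a maximal run of template-family genes on one chromosome in
which no two consecutive members are separated by more than a configurable
number of intervening (non-template) genes or a configurable distance in bp.
Non-template genes interleaved in a cluster do not break it — they only
count toward the gap limits — mirroring how unrelated genes sit inside real
Hox clusters without disrupting them.

Integrity is a triple in [0, 1]:

* ``completeness``  — fraction of template families present;
* ``order_score``   — reversal-tolerant longest-common-subsequence of the
  observed family order against the canonical order, divided by the number
  of members (whole-cluster inversions are treated as organized);
* ``orientation_score`` — largest fraction of members on one strand.

Ohnologous cluster copies (post-WGD "A" and "B") are paired by mutual
gene-level ohnology and their asymmetry reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import GeneRecord, SpeciesGenome

DEFAULT_MAX_GAP_GENES = 10
DEFAULT_MAX_GAP_BP = 5_000_000


@dataclass
class ClusterReport:
    species: str
    chromosome: str
    genes: list[GeneRecord]  # members in genomic order
    template: str
    completeness: float | None = None
    order_score: float | None = None
    orientation_score: float | None = None
    span_bp: int | None = None
    label: str | None = None  # A | B | unpaired

    @property
    def families(self) -> list[str]:
        return [g.family_id for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)


def detect_clusters(
    genome: SpeciesGenome,
    template_families: list[str],
    template_name: str = "",
    max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    include_pseudogenes: bool = False,
) -> list[ClusterReport]:
    """Maximal gap-bounded runs of template-family genes per chromosome.

    Singleton members are reported as clusters of size 1. Output order is by
    (chromosome, start), independent of gene input order.
    """
    template = set(template_families)
    reports: list[ClusterReport] = []
    for chrom, genes in sorted(genome.genes_by_chromosome().items()):
        members = [
            (i, g)
            for i, g in enumerate(genes)
            if g.family_id in template and (include_pseudogenes or not g.pseudogene)
        ]
        run: list[tuple[int, GeneRecord]] = []
        for item in members:
            if run:
                prev_i, prev_g = run[-1]
                gap_genes = item[0] - prev_i - 1
                gap_bp = item[1].start - prev_g.end
                if gap_genes > max_gap_genes or gap_bp > max_gap_bp:
                    reports.append(
                        ClusterReport(
                            genome.species_id, chrom, [g for _, g in run],
                            template_name,
                        )
                    )
                    run = []
            run.append(item)
        if run:
            reports.append(
                ClusterReport(
                    genome.species_id, chrom, [g for _, g in run], template_name
                )
            )
    return reports


def _lcs_length(a: list[str], b: list[str]) -> int:
    """Classic dynamic-programming longest common subsequence length."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[n]


def score_integrity(
    cluster: ClusterReport, template_order: list[str]
) -> ClusterReport:
    """Fill in completeness, order, orientation and span for a cluster.

    ``order_score`` compares the observed family order (or its reversal,
    whichever matches better) against the canonical order by LCS, divided by
    the number of members present; a member from a family absent from the
    template can never match, so supernumerary genes dilute the score.
    """
    if not cluster.genes:
        raise ValueError("cannot score an empty cluster")
    observed = cluster.families
    present = set(observed) & set(template_order)
    completeness = len(present) / len(template_order)
    lcs = max(
        _lcs_length(observed, template_order),
        _lcs_length(observed[::-1], template_order),
    )
    order_score = lcs / len(observed)
    strands = [g.strand for g in cluster.genes]
    orientation = max(strands.count("+"), strands.count("-")) / len(strands)
    cluster.completeness = completeness
    cluster.order_score = order_score
    cluster.orientation_score = orientation
    cluster.span_bp = cluster.genes[-1].end - cluster.genes[0].start
    return cluster


@dataclass
class ClusterPair:
    """An ohnologous cluster pair with its asymmetry summary."""

    cluster_a: ClusterReport
    cluster_b: ClusterReport
    delta_completeness: float = 0.0
    delta_order: float = 0.0
    shared_ohnologues: int = 0

    @property
    def more_intact(self) -> ClusterReport:
        return self.cluster_a if self.cluster_a.label == "A" else self.cluster_b


def _mutual_ohnologue_count(
    c1: ClusterReport, c2: ClusterReport, ohnology: dict[str, set[str]]
) -> int:
    ids2 = {g.gene_id for g in c2.genes}
    return sum(1 for g in c1.genes if ohnology.get(g.gene_id, set()) & ids2)


def pair_ohnologous_clusters(
    clusters: list[ClusterReport],
    ohnology: dict[str, set[str]],
    convention: dict[str, str] | None = None,
) -> tuple[list[ClusterPair], list[ClusterReport]]:
    """Pair the cluster copies of one template within one species.

    ``ohnology`` maps gene_id to the set of its ohnologous gene_ids in the
    same species (derived from the family calls). Clusters are paired by
    maximal mutual-ohnologue count (greedy, deterministic); leftovers are
    returned unpaired. Within a pair the more intact copy (higher
    completeness, then order, ties broken by chromosome id) is labelled "A"
    unless a template-specific ``convention`` names the label of the more
    intact copy (e.g. ``{"Hox": "B"}`` when the intact Hox copy is called B
    by convention).
    """
    clusters = sorted(
        clusters, key=lambda c: (c.chromosome, c.genes[0].start if c.genes else 0)
    )
    scores = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            n = _mutual_ohnologue_count(clusters[i], clusters[j], ohnology)
            if n > 0:
                scores.append((-n, i, j))
    scores.sort()
    used: set[int] = set()
    pairs: list[ClusterPair] = []
    for neg_n, i, j in scores:
        if i in used or j in used:
            continue
        used.update((i, j))
        c1, c2 = clusters[i], clusters[j]
        for c in (c1, c2):
            if c.completeness is None:
                raise ValueError("clusters must be scored before pairing")
        key = lambda c: (c.completeness, c.order_score, c.chromosome)
        intact, other = (c1, c2) if key(c1) >= key(c2) else (c2, c1)
        intact_label = (convention or {}).get(c1.template, "A")
        intact.label = intact_label
        other.label = "B" if intact_label == "A" else "A"
        pair = ClusterPair(
            cluster_a=intact if intact.label == "A" else other,
            cluster_b=other if intact.label == "A" else intact,
            delta_completeness=intact.completeness - other.completeness,
            delta_order=intact.order_score - other.order_score,
            shared_ohnologues=-neg_n,
        )
        pairs.append(pair)
    unpaired = [c for k, c in enumerate(clusters) if k not in used]
    for c in unpaired:
        c.label = "unpaired"
    return pairs, unpaired


def ohnology_from_calls(calls: dict, species_id: str) -> dict[str, set[str]]:
    """Gene-level ohnology map for one species from family calls: genes on
    opposite sides of a retained WGD duplication are mutual ohnologues."""
    out: dict[str, set[str]] = {}
    for call in calls.values():
        if call.category not in ("O", "SOL", "EOL"):
            continue
        sides = call.evidence.get("side_genes")
        if not sides:
            continue
        a = {g for s, g in sides[0] if s == species_id}
        b = {g for s, g in sides[1] if s == species_id}
        for g in a:
            out.setdefault(g, set()).update(b)
        for g in b:
            out.setdefault(g, set()).update(a)
    return out
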