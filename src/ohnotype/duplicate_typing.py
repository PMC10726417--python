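"""Classify each family's duplication history into ohnologue/tandem categories.

This is the central inference of the pipeline. Combining two signals —

* **timing** from gene-tree/species-tree reconciliation (standard LCA
  mapping: a node is a duplication when one child's mapping equals or is
  ancestral to the other's), and
* **linkage** of paralogue pairs on the chromosomes (clustered / linked /
  dispersed),

each family is placed into one category:

===========  ============================================================
O            ohnologues retained: the oldest retained duplication maps to
             the WGD branch's child node (WGD-compatible)
SOL / EOL    an ohnologue retained outside but lost on the spider /
             entelegyne stem (Dollo parsimony on each ohnologue lineage)
AT           ancient tandem duplication: the duplication node is strictly
             ancestral to the WGD
RT           recent tandem duplication: post-WGD or on an outgroup branch
SC           single copy retained: no duplication survives
===========  ============================================================

Timing is the primary criterion and linkage the secondary one; when they
disagree (a WGD-compatible duplication whose copies are mostly clustered,
or a tandem-dated duplication whose copies are mostly dispersed) the
reconciliation wins and the call carries a CONFLICT flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .genome_model import GeneRecord, GeneTree, SpeciesGenome, SpeciesTreeWGD

DEFAULT_MAX_CLUSTER_GAP_GENES = 10
DEFAULT_MAX_CLUSTER_GAP_BP = 1_000_000
DEFAULT_MAJORITY_FRACTION = 0.7

CATEGORIES = ("O", "AT", "RT", "SC", "SOL", "EOL", "LOSS_other")


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------


@dataclass
class LinkageCall:
    gene_a: str
    gene_b: str
    relation: str  # clustered | linked | dispersed
    intervening_gene_count: int | None
    distance_bp: int | None


def classify_linkage(
    gene_a: str | GeneRecord,
    gene_b: str | GeneRecord,
    genome: SpeciesGenome,
    max_cluster_gap_genes: int = DEFAULT_MAX_CLUSTER_GAP_GENES,
    max_cluster_gap_bp: int = DEFAULT_MAX_CLUSTER_GAP_BP,
) -> LinkageCall:
    """Classify the genomic relation of two paralogues in one genome.

    Different chromosomes: dispersed. Same chromosome: linked, and
    additionally clustered when the intervening gene count and the
    intergenic distance (downstream.start − upstream.end) both stay within
    the gap bounds.
    """
    a = genome.get(gene_a) if isinstance(gene_a, str) else gene_a
    b = genome.get(gene_b) if isinstance(gene_b, str) else gene_b
    if a.gene_id == b.gene_id:
        raise ValueError(f"cannot classify linkage of {a.gene_id} with itself")
    if a.chromosome_id != b.chromosome_id:
        return LinkageCall(a.gene_id, b.gene_id, "dispersed", None, None)
    chrom = genome.genes_by_chromosome()[a.chromosome_id]
    ids = [g.gene_id for g in chrom]
    ia, ib = ids.index(a.gene_id), ids.index(b.gene_id)
    if ia > ib:
        ia, ib = ib, ia
        a, b = b, a
    intervening = ib - ia - 1
    distance = max(0, b.start - a.end)
    relation = (
        "clustered"
        if intervening <= max_cluster_gap_genes and distance <= max_cluster_gap_bp
        else "linked"
    )
    return LinkageCall(a.gene_id, b.gene_id, relation, intervening, distance)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


@dataclass
class ReconNode:
    event: str  # leaf | speciation | duplication
    species_node: dendropy.Node
    wgd_compatible: bool = False
    species_set: frozenset[str] = frozenset()


def reconcile(
    gene_tree: GeneTree, species_tree: SpeciesTreeWGD
) -> dict[dendropy.Node, ReconNode]:
    """LCA-map every gene-tree node onto the species tree.

    A node maps to the MRCA of its leaves' species; it is a duplication when
    its mapping coincides with a child's mapping. A duplication mapping to
    the WGD branch's child node is tagged WGD-compatible.
    """
    species_leaves = set(species_tree.species)
    recon: dict[dendropy.Node, ReconNode] = {}
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            sp = GeneTree.leaf_species(label)
            if sp not in species_leaves:
                raise ValueError(
                    f"gene-tree leaf species {sp!r} is not in the species tree"
                )
            recon[node] = ReconNode(
                "leaf", species_tree.mrca({sp}), species_set=frozenset([sp])
            )
            continue
        kids = node.child_nodes()
        sset = recon[kids[0]].species_set | recon[kids[1]].species_set
        mapped = species_tree.mrca(sset)
        is_dup = any(recon[c].species_node is mapped for c in kids)
        recon[node] = ReconNode(
            "duplication" if is_dup else "speciation",
            mapped,
            wgd_compatible=is_dup and mapped is species_tree.wgd_node,
            species_set=frozenset(sset),
        )
    return recon


# ---------------------------------------------------------------------------
# Dollo loss mapping
# ---------------------------------------------------------------------------


def dollo_loss_branches(
    present_species: set[str] | frozenset[str],
    species_tree: SpeciesTreeWGD,
    gain_node: dendropy.Node,
    node_labels: dict[dendropy.Node, str] | None = None,
) -> list[str]:
    """Minimum loss placements under Dollo parsimony.

    The character is gained once, on the branch above ``gain_node``, and can
    only be lost. The unique minimum placement puts one loss on every
    maximal subtree of the gain clade that contains no present species.
    Returns sorted branch ids (id of each lost subtree's root node).
    """
    if node_labels is None:
        node_labels = _default_node_labels(species_tree)
    present = frozenset(present_species)
    losses: list[str] = []

    def walk(node) -> bool:
        if not species_tree.leafset[node] & present:
            return False
        for c in node.child_nodes():
            if not walk(c):
                losses.append(node_labels[c])
        return True

    if not species_tree.leafset[gain_node] & present:
        return [node_labels[gain_node]]
    walk(gain_node)
    return sorted(losses)


def _default_node_labels(stree: SpeciesTreeWGD) -> dict[dendropy.Node, str]:
    ids = {}
    for k, node in enumerate(stree.tree.preorder_node_iter()):
        if node.is_leaf():
            ids[node] = node.taxon.label if node.taxon else node.label
        elif node.label:
            ids[node] = node.label
        else:
            ids[node] = f"N{k}"
    return ids


def infer_losses(
    presence: pd.DataFrame,
    species_tree: SpeciesTreeWGD,
) -> pd.DataFrame:
    """Dollo loss mapping for ohnologue-lineage presence/absence characters.

    ``presence``: rows are characters (one per ohnologue lineage), columns
    species, values copy counts (>0 means present). Each character is gained
    once at the WGD and lost along the minimum set of branches. A lineage
    absent from all spiders but present outside them (the scorpion) refines
    to SOL; absent from all entelegynes but present in a non-entelegyne
    spider refines to EOL; other loss patterns are LOSS_other.
    """
    labels = _default_node_labels(species_tree)
    try:
        spiders = species_tree.named_clade("spiders")
    except KeyError:
        spiders = None
    try:
        enteleg = species_tree.named_clade("entelegynes")
    except KeyError:
        enteleg = None
    wgd_sp = species_tree.wgd_species
    rows = []
    for character, row in presence.iterrows():
        present = {sp for sp, v in row.items() if v > 0}
        extra = present - wgd_sp
        present = present & wgd_sp
        losses = dollo_loss_branches(
            present, species_tree, species_tree.wgd_node, labels
        )
        category = ""
        if losses:
            category = "LOSS_other"
            if spiders is not None and not (present & spiders) and (
                present & (wgd_sp - spiders)
            ):
                category = "SOL"
            elif (
                enteleg is not None
                and spiders is not None
                and not (present & enteleg)
                and (present & (spiders - enteleg))
            ):
                category = "EOL"
        rows.append(
            {
                "character": character,
                "n_losses": len(losses),
                "loss_branches": ";".join(losses),
                "refined_category": category,
                "outside_wgd_species": ";".join(sorted(extra)),
            }
        )
    return pd.DataFrame(rows).set_index("character")


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------


@dataclass
class FamilyCall:
    family_id: str
    category: str
    duplication_branch: str
    copy_counts: dict[str, int] = field(default_factory=dict)
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES + ("EXTINCT",):
            raise ValueError(f"unknown category {self.category!r}")


def _coding_leaves(
    node: dendropy.Node, indexes: dict[str, dict[str, GeneRecord]]
) -> list[tuple[str, str]]:
    """(species, gene_id) of non-pseudogene leaves under a gene-tree node."""
    out = []
    for leaf in node.leaf_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        sp, gid = GeneTree.leaf_species(label), GeneTree.leaf_gene(label)
        rec = indexes.get(sp, {}).get(gid)
        if rec is None or not rec.pseudogene:
            out.append((sp, gid))
    return out


def classify_family(
    family_id: str,
    genomes: dict[str, SpeciesGenome],
    gene_tree: GeneTree | None,
    species_tree: SpeciesTreeWGD,
    majority_fraction: float = DEFAULT_MAJORITY_FRACTION,
    max_cluster_gap_genes: int = DEFAULT_MAX_CLUSTER_GAP_GENES,
    max_cluster_gap_bp: int = DEFAULT_MAX_CLUSTER_GAP_BP,
) -> FamilyCall:
    """Produce the family's category call with its supporting evidence.

    The oldest retained duplication node (both children with surviving
    coding descendants; ties broken towards the root, then preorder) sets
    the timing; linkage of the duplicated pair across species is recorded
    as secondary evidence and conflicts are flagged, not resolved in favour
    of linkage.
    """
    labels = _default_node_labels(species_tree)
    indexes = {
        sp: {g.gene_id: g for g in genome.genes} for sp, genome in genomes.items()
    }
    copy_counts = {
        sp: sum(
            1
            for g in genome.genes
            if g.family_id == family_id and not g.pseudogene
        )
        for sp, genome in genomes.items()
    }
    pseudo = sorted(
        (sp, g.gene_id)
        for sp, genome in genomes.items()
        for g in genome.genes
        if g.family_id == family_id and g.pseudogene
    )
    evidence: dict = {"pseudogenes": pseudo}

    if gene_tree is None or gene_tree.n_leaves() < 2:
        return FamilyCall(family_id, "SC", "", copy_counts, evidence)

    recon = reconcile(gene_tree, species_tree)
    # oldest retained duplication
    depth: dict[dendropy.Node, int] = {}
    order: dict[dendropy.Node, int] = {}
    for k, node in enumerate(gene_tree.tree.preorder_node_iter()):
        p = node.parent_node
        depth[node] = 0 if p is None else depth[p] + 1
        order[node] = k
    candidates = []
    for node in gene_tree.tree.preorder_node_iter():
        if node.is_leaf() or recon[node].event != "duplication":
            continue
        kids = node.child_nodes()
        sides = [_coding_leaves(c, indexes) for c in kids]
        if all(sides):
            candidates.append((depth[node], order[node], node, sides))
    evidence["n_duplication_nodes"] = len(candidates)
    if not candidates:
        return FamilyCall(family_id, "SC", "", copy_counts, evidence)

    _, _, dup, sides = min(candidates, key=lambda c: (c[0], c[1]))
    mapped = recon[dup].species_node
    duplication_branch = labels[mapped]
    wgd_node = species_tree.wgd_node
    if mapped is wgd_node:
        category = "O"
    elif species_tree.is_ancestor(mapped, wgd_node):
        category = "AT"
    else:
        category = "RT"
    evidence["wgd_compatible"] = recon[dup].wgd_compatible

    # linkage of the duplicated pair across species carrying both copies
    side_species = [sorted({sp for sp, _ in s}) for s in sides]
    counts = {"clustered": 0, "linked": 0, "dispersed": 0}
    for sp in sorted(set(side_species[0]) & set(side_species[1])):
        if sp not in genomes:
            continue
        ga = min(g for s, g in sides[0] if s == sp)
        gb = min(g for s, g in sides[1] if s == sp)
        try:
            call = classify_linkage(
                ga,
                gb,
                genomes[sp],
                max_cluster_gap_genes=max_cluster_gap_genes,
                max_cluster_gap_bp=max_cluster_gap_bp,
            )
        except KeyError:
            continue
        counts[call.relation] += 1
    n_pairs = sum(counts.values())
    evidence["linkage_counts"] = counts
    evidence["majority_relation"] = (
        max(counts, key=lambda r: (counts[r], r)) if n_pairs else ""
    )
    conflict = False
    if n_pairs:
        linked_frac = (counts["clustered"] + counts["linked"]) / n_pairs
        dispersed_frac = counts["dispersed"] / n_pairs
        if category == "O" and linked_frac >= majority_fraction:
            conflict = True
        if category in ("AT", "RT") and dispersed_frac >= majority_fraction:
            conflict = True
    evidence["conflict"] = conflict

    loss_branches: list[str] = []
    if category == "O":
        presence = [frozenset(s) for s in side_species]
        evidence["side_presence"] = [sorted(s) for s in presence]
        evidence["side_genes"] = [sorted(sides[0]), sorted(sides[1])]
        try:
            spiders = species_tree.named_clade("spiders")
        except KeyError:
            spiders = None
        try:
            enteleg = species_tree.named_clade("entelegynes")
        except KeyError:
            enteleg = None
        wgd_sp = species_tree.wgd_species
        refined = None
        for side in presence:
            if spiders is not None and not (side & spiders) and (
                side & (wgd_sp - spiders)
            ):
                refined = "SOL"
                loss_branches = dollo_loss_branches(
                    side, species_tree, wgd_node, labels
                )
                break
        if refined is None and spiders is not None and enteleg is not None:
            for side in presence:
                if not (side & enteleg) and (side & (spiders - enteleg)):
                    refined = "EOL"
                    loss_branches = dollo_loss_branches(
                        side, species_tree, wgd_node, labels
                    )
                    break
        if refined:
            category = refined
        # consistency: dispersed copy numbers beyond what the retained
        # duplications can explain are flagged
        max_copies = max((copy_counts.get(sp, 0) for sp in wgd_sp), default=0)
        if max_copies > 2 ** max(1, evidence["n_duplication_nodes"]):
            evidence["inconsistent_copies"] = True
    evidence["loss_branches"] = loss_branches
    return FamilyCall(family_id, category, duplication_branch, copy_counts, evidence)


def classify_all(
    genomes: dict[str, SpeciesGenome],
    gene_trees: dict[str, GeneTree],
    species_tree: SpeciesTreeWGD,
    **kwargs,
) -> dict[str, FamilyCall]:
    """Classify every family that is assigned in at least one genome."""
    families = sorted(
        {
            g.family_id
            for genome in genomes.values()
            for g in genome.genes
            if g.family_id != "UNASSIGNED"
        }
    )
    return {
        fam: classify_family(
            fam, genomes, gene_trees.get(fam), species_tree, **kwargs
        )
        for fam in families
    }


# ---------------------------------------------------------------------------
# Repertoire summary
# ---------------------------------------------------------------------------


def summarize_repertoire(
    genomes: dict[str, SpeciesGenome],
    calls: dict[str, FamilyCall],
    species_tree: SpeciesTreeWGD,
) -> tuple[pd.DataFrame, dict]:
    """Per-species repertoire table plus the derived WGD/outgroup statistics.

    Columns mirror the per-species summary of the study: total genes
    (pseudogenes excluded), families present, families with ancient/recent
    tandem paralogues in that species, single-copy families and (for WGD
    species) families with both ohnologues retained. The stats dict carries
    the ratio of mean totals (WGD / outgroup species, 1 decimal) and the
    min/max of the retained-ohnologue column.
    """
    wgd_sp = species_tree.wgd_species
    rows = []
    for sp in sorted(genomes):
        genome = genomes[sp]
        coding = genome.coding_genes()
        fams_present = {g.family_id for g in coding if g.family_id != "UNASSIGNED"}
        n_at = sum(
            1
            for f in fams_present
            if calls.get(f) is not None
            and calls[f].category == "AT"
            and calls[f].copy_counts.get(sp, 0) >= 2
        )
        n_rt = sum(
            1
            for f in fams_present
            if calls.get(f) is not None
            and calls[f].category == "RT"
            and calls[f].copy_counts.get(sp, 0) >= 2
        )
        n_single = sum(
            1
            for f in fams_present
            if calls.get(f) is not None and calls[f].copy_counts.get(sp, 0) == 1
        )
        n_ohno = None
        if sp in wgd_sp:
            n_ohno = 0
            for f in fams_present:
                call = calls.get(f)
                if call is None or call.category not in ("O", "SOL", "EOL"):
                    continue
                sidep = call.evidence.get("side_presence")
                if sidep and all(sp in side for side in sidep):
                    n_ohno += 1
        rows.append(
            {
                "species": sp,
                "wgd": sp in wgd_sp,
                "total_genes": len(coding),
                "families_present": len(fams_present),
                "families_AT": n_at,
                "families_RT": n_rt,
                "families_single_copy": n_single,
                "families_retained_ohnologues": n_ohno,
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    stats = repertoire_stats(table)
    return table, stats


def repertoire_stats(table: pd.DataFrame) -> dict:
    """Derived statistics from a repertoire table with 'wgd' and
    'total_genes' columns: WGD/outgroup mean-count ratio (1 decimal) and the
    min/max of the retained-ohnologue column over WGD species."""
    wgd = table[table["wgd"]]
    out = table[~table["wgd"]]
    ratio = None
    if len(wgd) and len(out) and out["total_genes"].mean() > 0:
        ratio = round(
            float(wgd["total_genes"].mean()) / float(out["total_genes"].mean()), 1
        )
    col = wgd["families_retained_ohnologues"].dropna()
    return {
        "wgd_outgroup_ratio": ratio,
        "retained_ohnologues_max": int(col.max()) if len(col) else None,
        "retained_ohnologues_min": int(col.min()) if len(col) else None,
    }
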