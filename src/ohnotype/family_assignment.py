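"""Assign genes to homeobox families from homeodomain sequences.

Classification follows the similarity-plus-diagnostic-residues approach used
for homeodomain surveys: similarity is ungapped identity against a 60-column
family consensus (homeodomains are essentially fixed length, so no affine
alignment is needed), diagnostic residues are per-family positional filters,
and ties rank diagnostic-passing families first. Genes whose homeodomain is
disrupted by an internal stop codon are flagged as pseudogenes and excluded
from repertoire counts. Unassigned genes shared by several species can be
grouped into new lineage-specific ("un") families by single-linkage
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genome_model import (
    UNASSIGNED,
    FamilyCatalog,
    SpeciesGenome,
)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
# '*' (stop, pseudogenes) and 'X' (unknown) are tolerated but never match.
TOLERATED = AA_ALPHABET | {"*", "X"}

DEFAULT_MIN_SIMILARITY = 0.55
DEFAULT_CROSS_SIMILARITY = 0.8


@dataclass
class FamilyScore:
    family_id: str
    similarity: float
    diagnostic_pass: bool


def _check_sequence(seq: str) -> None:
    bad = set(seq.upper()) - TOLERATED
    if bad:
        raise ValueError(f"non-amino-acid characters in homeodomain: {sorted(bad)}")


def _best_fit(seq: str, consensus: str) -> tuple[int, int]:
    """Ungapped best fit of ``seq`` against ``consensus``.

    A longer sequence is trimmed: the consensus slides fully inside it; a
    shorter sequence slides fully inside the consensus. Returns (identical
    positions, offset), where offset is the position of consensus column 0
    within ``seq`` (negative when the sequence starts inside the consensus).
    Equal lengths admit only offset 0.
    """
    n, m = len(seq), len(consensus)
    offsets = range(0, n - m + 1) if n >= m else range(-(m - n), 1)
    best = (-1, 0)
    for off in offsets:
        ident = 0
        for j in range(m):
            i = off + j
            if 0 <= i < n and seq[i] == consensus[j]:
                ident += 1
        if ident > best[0]:
            best = (ident, off)
    return best


def _aligned_residue(seq: str, offset: int, column: int) -> str | None:
    i = offset + column
    if 0 <= i < len(seq):
        return seq[i]
    return None


def score_family(hd_seq: str, catalog: FamilyCatalog) -> list[FamilyScore]:
    """Rank all catalog families for one homeodomain sequence.

    Similarity is the fraction of consensus columns with an identical
    residue under the best ungapped fit; ``diagnostic_pass`` requires every
    diagnostic residue to match (families without diagnostics pass
    vacuously). Ranking: diagnostic_pass desc, similarity desc, family asc.
    """
    seq = hd_seq.upper()
    _check_sequence(seq)
    if not 55 <= len(seq) <= 65:
        raise ValueError(
            f"homeodomain length {len(seq)} outside the accepted 55-65 aa range"
        )
    scores = []
    for fam in catalog:
        ident, off = _best_fit(seq, fam.consensus)
        sim = ident / len(fam.consensus)
        diag = True
        for pos, allowed in fam.diagnostics:
            residue = _aligned_residue(seq, off, pos - 1)
            if residue is None or residue not in allowed:
                diag = False
                break
        scores.append(FamilyScore(fam.family_id, sim, diag))
    scores.sort(key=lambda s: (not s.diagnostic_pass, -s.similarity, s.family_id))
    return scores


def assign_families(
    genome: SpeciesGenome,
    catalog: FamilyCatalog,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> SpeciesGenome:
    """Return a copy of the genome with family calls set from homeodomains.

    The top-ranked family is assigned when its similarity reaches
    ``min_similarity``; genes below threshold (or without a homeodomain)
    stay UNASSIGNED. Deterministic and independent of gene input order.
    """
    # vectorized fast path for sequences matching the consensus length
    fams = sorted(catalog, key=lambda f: f.family_id)
    lengths = {len(f.consensus) for f in fams}
    cons_mat = None
    if len(lengths) == 1:
        width = lengths.pop()
        cons_mat = np.frombuffer(
            "".join(f.consensus for f in fams).encode(), dtype=np.uint8
        ).reshape(len(fams), width)

    def top_call(seq: str) -> tuple[str, float] | None:
        seq = seq.upper()
        if cons_mat is not None and len(seq) == cons_mat.shape[1]:
            _check_sequence(seq)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            sims = (cons_mat == arr).mean(axis=1)
            hits = [i for i in np.flatnonzero(sims >= min_similarity)]
            if not hits:
                return None
            scored = []
            for i in hits:
                fam = fams[i]
                diag = all(
                    seq[pos - 1] in allowed for pos, allowed in fam.diagnostics
                )
                scored.append((not diag, -sims[i], fam.family_id))
            scored.sort()
            best = min(scored)
            return best[2], -best[1]
        ranked = score_family(seq, catalog)
        if ranked and ranked[0].similarity >= min_similarity:
            return ranked[0].family_id, ranked[0].similarity
        return None

    new_genes = []
    for g in genome.genes:
        fam = UNASSIGNED
        if g.homeodomain_seq:
            call = top_call(g.homeodomain_seq)
            if call is not None:
                fam = call[0]
        new_genes.append(g.copy(family_id=fam))
    return SpeciesGenome(genome.species_id, dict(genome.chromosomes), new_genes)


def flag_pseudogenes(genome: SpeciesGenome) -> SpeciesGenome:
    """Flag genes whose homeodomain is disrupted by an internal stop codon.

    With a homeodomain sequence the rule is exact: any ``*`` inside it. With
    only a CDS, the translated sequence is checked for internal stops (the
    terminal stop codon is ignored). Pseudogenes stay in the genome but are
    excluded from repertoire counts downstream.
    """
    new_genes = []
    for g in genome.genes:
        flag = g.pseudogene
        if g.homeodomain_seq is not None:
            flag = "*" in g.homeodomain_seq
        elif g.cds_seq is not None:
            from .synthetic_data import translate

            aa = translate(g.cds_seq[: len(g.cds_seq) - len(g.cds_seq) % 3])
            flag = "*" in aa[:-1]
        new_genes.append(g.copy(pseudogene=flag))
    return SpeciesGenome(genome.species_id, dict(genome.chromosomes), new_genes)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped best-fit identity between two homeodomain sequences,
    normalized by the shorter length."""
    if len(a) < len(b):
        a, b = b, a
    ident, _off = _best_fit(a, b)
    return ident / len(b)


@dataclass
class NewFamily:
    family_id: str
    hd_class: str
    members: list[tuple[str, str]]  # (species, gene_id)


def detect_new_families(
    genomes: dict[str, SpeciesGenome],
    catalog: FamilyCatalog,
    min_species: int = 2,
    cross_similarity: float = DEFAULT_CROSS_SIMILARITY,
) -> tuple[list[NewFamily], list[tuple[str, str]]]:
    """Group unassigned genes across species into candidate new families.

    Single-linkage grouping (connected components of the pairwise-similarity
    graph at ``cross_similarity``); groups spanning at least ``min_species``
    species become families named ``<CLASS>-unK`` after the class of the
    nearest catalog consensus. Genes in groups confined to one species stay
    unclassified (returned as the second element).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two species to detect shared new families")
    nodes: list[tuple[str, str, str]] = []  # species, gene, hd
    for sp in sorted(genomes):
        for g in genomes[sp].genes:
            if g.family_id == UNASSIGNED and g.homeodomain_seq and not g.pseudogene:
                nodes.append((sp, g.gene_id, g.homeodomain_seq.upper()))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if pairwise_identity(nodes[i][2], nodes[j][2]) >= cross_similarity:
                graph.add_edge(i, j)

    new_families: list[NewFamily] = []
    singletons: list[tuple[str, str]] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (nodes[c[0]][0], nodes[c[0]][1]),
    )
    class_counter: dict[str, int] = {}
    for comp in components:
        species = {nodes[i][0] for i in comp}
        members = sorted((nodes[i][0], nodes[i][1]) for i in comp)
        if len(species) < min_species:
            singletons.extend(members)
            continue
        # infer the class from the nearest catalog consensus over members
        best_class, best_sim = "MISC", -1.0
        for i in comp:
            for fam in catalog:
                sim = pairwise_identity(nodes[i][2], fam.consensus)
                if sim > best_sim:
                    best_sim, best_class = sim, fam.hd_class
        k = class_counter.get(best_class, 0) + 1
        class_counter[best_class] = k
        new_families.append(NewFamily(f"{best_class}-un{k}", best_class, members))
    return new_families, singletons
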