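"""Chromosome-level orthology mapping and collinear block detection.

Macrosynteny between two genomes is summarized as a contingency table of
shared orthogroups per chromosome pair; chromosomes are then assigned
greedily by descending shared count. Fusions and fissions surface naturally
as 2:1 / 1:2 assignments. Microsynteny is captured by chaining orthogroup
matches that are monotone in both genomes (either orientation) with bounded
positional gaps. Orthogroup inference itself is out of scope: orthogroups
are inputs (simulation truth, or a user-supplied table for real data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster_analysis import ClusterReport
from .genome_model import SpeciesGenome

DEFAULT_MIN_SHARED = 10
DEFAULT_MIN_CHAIN = 5
DEFAULT_MAX_GAP = 25


OrthogroupMap = dict[tuple[str, str], str]  # (species, gene_id) -> orthogroup


def _gene_orthogroup(og: OrthogroupMap | None, species: str, gene_id: str) -> str:
    if og is None:
        # lineage ids double as orthogroups for simulated data
        return gene_id
    return og.get((species, gene_id), "")


@dataclass
class ChromosomeOrthology:
    species_x: str
    species_y: str
    contingency: pd.DataFrame  # chromosomes of x (rows) vs y (columns)
    mapping_xy: dict[str, str] = field(default_factory=dict)
    mapping_yx: dict[str, str] = field(default_factory=dict)

    def multiplicity(self) -> dict[str, list[str]]:
        """y-chromosomes mapped to by >=2 x-chromosomes (fusions in y /
        fissions in x) and vice versa are visible here."""
        inv: dict[str, list[str]] = {}
        for cx, cy in self.mapping_xy.items():
            inv.setdefault(cy, []).append(cx)
        return {cy: sorted(cxs) for cy, cxs in inv.items() if len(cxs) > 1}


def chromosome_orthology(
    genome_x: SpeciesGenome,
    genome_y: SpeciesGenome,
    orthogroups: OrthogroupMap | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> ChromosomeOrthology:
    """Contingency of shared orthogroups per chromosome pair, plus greedy
    chromosome assignment (ties by chromosome id; below ``min_shared``
    unassigned). Content-based: gene order does not matter."""
    def og_by_chrom(genome: SpeciesGenome) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in genome.chromosomes}
        for g in genome.genes:
            o = _gene_orthogroup(orthogroups, genome.species_id, g.gene_id)
            if o:
                out[g.chromosome_id].add(o)
        return out

    ogx, ogy = og_by_chrom(genome_x), og_by_chrom(genome_y)
    rows = sorted(ogx)
    cols = sorted(ogy)
    table = pd.DataFrame(
        [[len(ogx[cx] & ogy[cy]) for cy in cols] for cx in rows],
        index=rows,
        columns=cols,
        dtype=int,
    )

    def greedy(axis_from: list[str], lookup) -> dict[str, str]:
        mapping = {}
        for c in axis_from:
            counts = lookup(c)
            if counts.empty:
                continue
            best = counts.sort_values(ascending=False, kind="stable")
            # deterministic tie-break by chromosome id
            top = best.iloc[0]
            if top < min_shared:
                continue
            winners = sorted(best[best == top].index)
            mapping[c] = winners[0]
        return mapping

    mapping_xy = greedy(rows, lambda cx: table.loc[cx])
    mapping_yx = greedy(cols, lambda cy: table[cy])
    return ChromosomeOrthology(
        genome_x.species_id, genome_y.species_id, table, mapping_xy, mapping_yx
    )


# ---------------------------------------------------------------------------
# Collinear chains
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    orientation: str  # forward | reverse
    matches: list[tuple[int, int]]  # (index in x, index in y), monotone

    def __len__(self) -> int:
        return len(self.matches)


def _best_chain(
    matches: list[tuple[int, int]], max_gap: int, reverse: bool
) -> list[tuple[int, int]]:
    """Longest chain monotone increasing in x and increasing (forward) or
    decreasing (reverse) in y, consecutive positional gaps <= max_gap.
    O(m^2) dynamic programming over matches sorted by x."""
    if not matches:
        return []
    pts = sorted(matches)
    n = len(pts)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        xi, yi = pts[i]
        for j in range(i):
            xj, yj = pts[j]
            if not (0 < xi - xj <= max_gap + 1):
                continue
            step = yj - yi if reverse else yi - yj
            if not (0 < step <= max_gap + 1):
                continue
            if best[j] + 1 > best[i] or (
                best[j] + 1 == best[i] and prev[i] == -1
            ):
                best[i] = best[j] + 1
                prev[i] = j
        # favour the lexicographically earliest optimum deterministically
    k = max(range(n), key=lambda i: (best[i], -pts[i][0], -pts[i][1]))
    chain = []
    while k != -1:
        chain.append(pts[k])
        k = prev[k]
    return chain[::-1]


def collinear_chains(
    genes_x: list[str],
    genes_y: list[str],
    min_chain: int = DEFAULT_MIN_CHAIN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Chain]:
    """Greedy extraction of collinear chains between two ordered orthogroup
    lists: repeatedly take the longest remaining forward or reverse chain
    until none reaches ``min_chain``."""
    pos_y: dict[str, list[int]] = {}
    for j, og in enumerate(genes_y):
        pos_y.setdefault(og, []).append(j)
    matches = [
        (i, j) for i, og in enumerate(genes_x) for j in pos_y.get(og, [])
    ]
    chains: list[Chain] = []
    remaining = set(matches)
    while True:
        pool = sorted(remaining)
        fwd = _best_chain(pool, max_gap, reverse=False)
        rev = _best_chain(pool, max_gap, reverse=True)
        cand, orient = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
        if len(cand) < min_chain:
            break
        chains.append(Chain(orient, cand))
        remaining -= set(cand)
    return chains


# ---------------------------------------------------------------------------
# Cluster placement on macrosynteny blocks
# ---------------------------------------------------------------------------


def locate_clusters(
    clusters: dict[str, list[ClusterReport]],
    orthologies: dict[str, ChromosomeOrthology],
    reference_species: str,
) -> pd.DataFrame:
    """Place each named cluster on its macrosynteny block per species.

    ``orthologies`` maps species to its chromosome orthology against the
    reference (the reference species itself maps identically). A cluster is
    flagged relocated when its chromosome maps to a different reference
    chromosome than the same (template, label) cluster occupies in the
    reference species.
    """
    ref_location: dict[tuple[str, str], str] = {}
    for c in clusters.get(reference_species, []):
        ref_location[(c.template, c.label or "")] = c.chromosome
    rows = []
    for sp in sorted(clusters):
        ortho = orthologies.get(sp)
        for c in clusters[sp]:
            if sp == reference_species:
                block = c.chromosome
            elif ortho is not None:
                block = ortho.mapping_xy.get(c.chromosome, "")
            else:
                block = ""
            ref_chrom = ref_location.get((c.template, c.label or ""), "")
            relocated = bool(block and ref_chrom) and block != ref_chrom
            rows.append(
                {
                    "species": sp,
                    "template": c.template,
                    "label": c.label or "",
                    "chromosome": c.chromosome,
                    "reference_block": block,
                    "reference_chromosome": ref_chrom,
                    "relocated": relocated,
                }
            )
    return pd.DataFrame(rows)
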