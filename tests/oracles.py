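"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
definitions — and shares no code with the implementations it checks.
"""

from __future__ import annotations

import itertools

from ohnotype.synthetic_data import CODON_TABLE, NUCS, STOP_CODONS


# -- reconciliation ---------------------------------------------------------


def species_ancestors(stree, species: str) -> list:
    """Path of species-tree nodes from the leaf up to the root."""
    node = next(
        n
        for n in stree.tree.leaf_node_iter()
        if (n.taxon.label if n.taxon else n.label) == species
    )
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    return path


def brute_lca(stree, species: set[str]):
    """LCA by intersecting root-ward ancestor paths."""
    paths = [species_ancestors(stree, sp) for sp in species]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # the LCA is the common ancestor encountered first on any leaf path
    for node in paths[0]:
        if node in common:
            return node
    raise AssertionError("no common ancestor")


def brute_reconcile(gene_tree, stree):
    """Node -> (event, mapped species node), by the clade-overlap definition:
    a node is a duplication iff the leafsets of its children's mapped clades
    intersect."""
    out = {}

    def leafset(node):
        return {
            (l.taxon.label if l.taxon else l.label) for l in node.leaf_iter()
        }

    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            sp = label.split("|", 1)[0]
            out[node] = ("leaf", brute_lca(stree, {sp}))
            continue
        kids = node.child_nodes()
        species = {
            (l.taxon.label if l.taxon else l.label).split("|", 1)[0]
            for l in node.leaf_iter()
        }
        mapped = brute_lca(stree, species)
        sets = []
        for c in kids:
            csp = {
                (l.taxon.label if l.taxon else l.label).split("|", 1)[0]
                for l in c.leaf_iter()
            }
            sets.append(leafset(brute_lca(stree, csp)))
        event = "duplication" if sets[0] & sets[1] else "speciation"
        out[node] = (event, mapped)
    return out


# -- Dollo losses -----------------------------------------------------------


def brute_min_dollo_losses(stree, gain_node, present: set[str]) -> int:
    """Exhaustive minimum number of loss branches below the gain node that
    reproduce the presence pattern."""
    subtree_nodes = [n for n in gain_node.preorder_iter() if n is not gain_node]
    leaves = {
        (l.taxon.label if l.taxon else l.label): l
        for l in gain_node.leaf_iter()
    }
    if not present:
        return 1  # loss of the whole gain clade

    def pattern(loss_set) -> set[str]:
        out = set()
        for sp, leaf in leaves.items():
            node = leaf
            lost = False
            while node is not gain_node:
                if node in loss_set:
                    lost = True
                    break
                node = node.parent_node
            if not lost:
                out.add(sp)
        return out

    for k in range(0, len(subtree_nodes) + 1):
        for combo in itertools.combinations(subtree_nodes, k):
            if pattern(set(combo)) == present:
                return k
    raise AssertionError("unreachable")


# -- cluster detection ------------------------------------------------------


def brute_clusters(genes, template: set[str], max_gap_genes: int, max_gap_bp: int):
    """Interval-scan oracle: member index lists per chromosome, split where
    either gap bound is violated. ``genes`` is a coordinate-sorted list of
    (gene_id, chrom, start, end, family)."""
    out = []
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g[1], []).append(g)
    for chrom in sorted(by_chrom):
        row = by_chrom[chrom]
        members = [i for i, g in enumerate(row) if g[4] in template]
        cur = []
        for i in members:
            if cur:
                j = cur[-1]
                if (i - j - 1) > max_gap_genes or (
                    row[i][2] - row[j][3]
                ) > max_gap_bp:
                    out.append([row[k][0] for k in cur])
                    cur = []
            cur.append(i)
        if cur:
            out.append([row[k][0] for k in cur])
    return out


def brute_lcs(a, b) -> int:
    """LCS by exhaustive subsequence enumeration (tiny inputs only)."""
    best = 0
    for k in range(len(a), 0, -1):
        for sub in itertools.combinations(a, k):
            if _is_subsequence(sub, b):
                return k
    return best


def _is_subsequence(sub, seq) -> bool:
    it = iter(seq)
    return all(x in it for x in sub)


# -- collinear chains -------------------------------------------------------


def brute_best_chain_length(matches, max_gap: int) -> int:
    """Longest monotone chain (either orientation) by memoized DFS."""
    best = 0
    matches = sorted(matches)

    for reverse in (False, True):
        memo: dict[int, int] = {}

        def follow(i) -> int:
            if i in memo:
                return memo[i]
            xi, yi = matches[i]
            out = 1
            for j in range(len(matches)):
                xj, yj = matches[j]
                dy = yi - yj if reverse else yj - yi
                if 0 < xj - xi <= max_gap + 1 and 0 < dy <= max_gap + 1:
                    out = max(out, 1 + follow(j))
            memo[i] = out
            return out

        for i in range(len(matches)):
            best = max(best, follow(i))
    return best


# -- NG86 -------------------------------------------------------------------


def brute_codon_sites(codon: str) -> tuple[float, float]:
    syn = non = 0.0
    for pos in range(3):
        changes = []
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS:
                changes.append(CODON_TABLE[alt] == CODON_TABLE[codon])
        if changes:
            syn += sum(changes) / len(changes)
            non += (len(changes) - sum(changes)) / len(changes)
        else:
            non += 1.0
    return syn, non


def brute_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        for order in itertools.permutations(diff):
            cur, syn, non = ca, 0, 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            results.append((syn, non))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


# -- random gene trees ------------------------------------------------------


def random_gene_tree_newick(rng, species: list[str], n_leaves: int) -> str:
    """Random rooted binary gene tree over random species assignments."""
    labels = []
    for k in range(n_leaves):
        sp = species[int(rng.integers(len(species)))]
        labels.append(f"'{sp}|g{k}'")

    def build(items):
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        idx = list(rng.permutation(len(items)))
        left = [items[i] for i in idx[:k]]
        right = [items[i] for i in idx[k:]]
        return f"({build(left)},{build(right)})"

    return build(labels) + ";"
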