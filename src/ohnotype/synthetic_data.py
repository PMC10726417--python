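"""Forward simulator of genome evolution along a WGD-bearing species tree.

The simulator emulates the scenario behind the arachnopulmonate homeobox
study design: a multi-chromosome ancestral genome carrying conserved gene
clusters descends through a rooted species tree on which one branch carries
a whole-genome duplication (WGD). Along every branch, genes tandem- or
dispersed-duplicate, are lost, and chromosomes invert, translocate, fuse and
fission; coding sequences accumulate codon substitutions and occasionally
pseudogenize (an internal stop inside the homeodomain). Everything is logged,
so every downstream inference stage can be scored against exact truth:

* per-leaf :class:`~ohnotype.genome_model.SpeciesGenome` with coordinates,
* the true gene tree of every family,
* an :class:`EventLog` whose replay reconstructs each leaf genome exactly,
* per-family truth categories in the O/AT/RT/SC/SOL/EOL vocabulary.

One global seeded random stream drives the whole simulation; events within a
branch are applied in draw order, so output is byte-reproducible per seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .duplicate_typing import dollo_loss_branches
from .genome_model import (
    FamilyCatalog,
    FamilyEntry,
    GeneRecord,
    GeneTree,
    SpeciesGenome,
    SpeciesTreeWGD,
    read_gene_tree,
    read_species_tree,
    write_catalog,
    write_fasta,
    write_gene_table,
    write_tree,
)

# ---------------------------------------------------------------------------
# Genetic code helpers (standard code)
# ---------------------------------------------------------------------------

NUCS = "ACGT"
_BASES = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
CODON_TABLE = dict(_BASES)
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def is_transition(a: str, b: str) -> bool:
    return _TRANSITION[a] == b


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_TEMPLATES = {"Hox": 10, "NK": 6, "NK2": 4, "HRO": 3, "Irx": 3, "SINE": 3}


@dataclass
class SimulationConfig:
    """All tunables of the simulator; the defaults define the study scenario.

    Rates are per branch-length unit: duplication/loss rates are per gene,
    inversion/translocation rates per genome, fusion/fission probabilities
    per branch. ``cds_substitution_rate`` is the neutral substitution rate
    per nucleotide site; nonsynonymous changes are accepted with probability
    ``omega_scale`` (so the realized dN/dS of simulated sequences is close
    to ``omega_scale``).
    """

    seed: int = 20231103
    n_chromosomes: int = 7
    n_families: int = 200
    cluster_templates: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    tandem_duplication_rate: float = 0.008
    dispersed_duplication_rate: float = 0.002
    gene_loss_rate: float = 0.015
    inversion_rate: float = 0.3
    translocation_rate: float = 0.1
    fusion_prob: float = 0.02
    fission_prob: float = 0.02
    cds_substitution_rate: float = 0.01
    ts_tv_ratio: float = 2.0
    omega_scale: float = 0.25
    pseudogenize_prob: float = 0.002
    flank_codons: int = 30  # codons either side of the 60-codon homeodomain
    homeodomain_len: int = 60
    spacing_bp: int = 10_000
    tandem_offset_bp: tuple[int, int] = (1_000, 9_000)
    max_genes: int = 1_000_000

    def __post_init__(self) -> None:
        for name in (
            "tandem_duplication_rate",
            "dispersed_duplication_rate",
            "gene_loss_rate",
            "inversion_rate",
            "translocation_rate",
            "fusion_prob",
            "fission_prob",
            "cds_substitution_rate",
            "pseudogenize_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.omega_scale <= 1:
            raise ValueError("omega_scale must be in [0, 1]")

    @property
    def cds_len_nt(self) -> int:
        return 3 * (self.homeodomain_len + 2 * self.flank_codons)

    @property
    def hd_span_codons(self) -> tuple[int, int]:
        return self.flank_codons, self.flank_codons + self.homeodomain_len

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "tandem_offset_bp" in d:
            d["tandem_offset_bp"] = tuple(d["tandem_offset_bp"])
        return cls(**d)


#: Newick encoding of the study's 14-taxon arthropod tree: three mandibulates
#: and the tick/harvestman outgroups, then the arachnopulmonates (scorpion +
#: eight spiders) whose stem branch carries the WGD. All branch lengths 1.
_ENTELEGYNES = (
    "(Dpla:1,((Lele:1,Ptep:1):1,(Hgra:1,(Abru:1,(Tant:1,Tcla:1):1):1):1):1)"
    "entelegynes"
)
_SPIDERS = f"(Dsil:1,{_ENTELEGYNES}:1)spiders"
_ARACH = f"(Cscu:1,{_SPIDERS}:1)WGD"
DEFAULT_SPECIES_TREE = (
    f"(((Dmel:1,Tcas:1):1,Smar:1):1,"
    f"(Isca:1,(Popi:1,{_ARACH}:1):1):1);"
)


def default_species_tree() -> SpeciesTreeWGD:
    return read_species_tree(data=DEFAULT_SPECIES_TREE)


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

EVENT_TYPES = (
    "speciation",
    "wgd",
    "tandem_dup",
    "dispersed_dup",
    "loss",
    "inversion",
    "translocation",
    "fusion",
    "fission",
)


@dataclass
class Event:
    type: str
    branch: str  # species-tree node id of the branch's child node
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


class EventLog:
    """Ordered list of events; replaying it from the root genome reproduces
    every leaf genome structure (gene ids, order, strands, gaps) exactly."""

    def __init__(self, events: list[Event] | None = None):
        self.events: list[Event] = events or []

    def append(self, ev: Event) -> None:
        self.events.append(ev)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_branch(self) -> dict[str, list[Event]]:
        out: dict[str, list[Event]] = {}
        for ev in self.events:
            out.setdefault(ev.branch, []).append(ev)
        return out

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.type] = out.get(ev.type, 0) + 1
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(
                    json.dumps(
                        {"type": ev.type, "branch": ev.branch, **ev.payload},
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def from_json(cls, path: str) -> "EventLog":
        events = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                t, b = d.pop("type"), d.pop("branch")
                events.append(Event(t, b, d))
        return cls(events)


# ---------------------------------------------------------------------------
# Structural genome state (used by both the simulator and log replay)
# ---------------------------------------------------------------------------


@dataclass
class StructGene:
    uid: str
    family: str
    strand: str
    gap_bp: int  # intergenic gap preceding this gene on its chromosome


class GenomeState:
    """Ordered chromosomes of ordered genes; purely structural."""

    def __init__(self):
        self.chrom_order: list[str] = []
        self.chroms: dict[str, list[StructGene]] = {}

    def clone(self) -> "GenomeState":
        g = GenomeState()
        g.chrom_order = list(self.chrom_order)
        g.chroms = {
            c: [StructGene(x.uid, x.family, x.strand, x.gap_bp) for x in genes]
            for c, genes in self.chroms.items()
        }
        return g

    def n_genes(self) -> int:
        return sum(len(v) for v in self.chroms.values())

    def all_genes(self) -> list[tuple[str, int, StructGene]]:
        out = []
        for c in self.chrom_order:
            for i, g in enumerate(self.chroms[c]):
                out.append((c, i, g))
        return out

    def find(self, uid: str) -> tuple[str, int]:
        for c in self.chrom_order:
            for i, g in enumerate(self.chroms[c]):
                if g.uid == uid:
                    return c, i
        raise KeyError(uid)

    # -- event application (shared by simulation and replay) -------------
    def apply(self, ev: Event) -> None:
        p = ev.payload
        if ev.type == "tandem_dup":
            c, i = self.find(p["parent"])
            parent = self.chroms[c][i]
            child = StructGene(p["child"], parent.family, parent.strand, p["offset"])
            self.chroms[c].insert(i + 1, child)
        elif ev.type == "dispersed_dup":
            c, i = self.find(p["parent"])
            parent = self.chroms[c][i]
            child = StructGene(
                p["child"], parent.family, p["strand"], p["offset"]
            )
            self.chroms[p["target_chrom"]].insert(p["target_index"], child)
        elif ev.type == "loss":
            c, i = self.find(p["gene"])
            del self.chroms[c][i]
        elif ev.type == "inversion":
            genes = self.chroms[p["chrom"]]
            i, j = p["first"], p["last"]
            seg = genes[i : j + 1][::-1]
            for g in seg:
                g.strand = "+" if g.strand == "-" else "-"
            genes[i : j + 1] = seg
        elif ev.type == "translocation":
            src = self.chroms[p["src_chrom"]]
            i, n = p["first"], p["count"]
            seg = src[i : i + n]
            del src[i : i + n]
            dst = self.chroms[p["dst_chrom"]]
            dst[p["dst_index"] : p["dst_index"]] = seg
        elif ev.type == "fusion":
            a, b = p["chrom_a"], p["chrom_b"]
            merged = self.chroms[a] + self.chroms[b]
            new = p["new_chrom"]
            idx = self.chrom_order.index(a)
            self.chrom_order.remove(a)
            self.chrom_order.remove(b)
            del self.chroms[a], self.chroms[b]
            self.chrom_order.insert(idx, new)
            self.chroms[new] = merged
        elif ev.type == "fission":
            c, k = p["chrom"], p["index"]
            left, right = self.chroms[c][:k], self.chroms[c][k:]
            na, nb = p["new_a"], p["new_b"]
            idx = self.chrom_order.index(c)
            del self.chroms[c]
            self.chrom_order[idx : idx + 1] = [na, nb]
            self.chroms[na], self.chroms[nb] = left, right
        elif ev.type == "wgd":
            for pair in p["chromosomes"]:
                src, new = pair["chrom"], pair["copy"]
                uid_map = dict(zip(pair["genes"], pair["copies"]))
                copy = [
                    StructGene(uid_map[g.uid], g.family, g.strand, g.gap_bp)
                    for g in self.chroms[src]
                ]
                self.chrom_order.append(new)
                self.chroms[new] = copy
        elif ev.type == "speciation":
            pass
        else:  # pragma: no cover
            raise ValueError(ev.type)


def layout_genome(
    state: GenomeState, species_id: str, cfg: SimulationConfig
) -> SpeciesGenome:
    """Assign bp coordinates on the spacing grid; gaps come from each gene's
    recorded intergenic offset."""
    gene_len = cfg.cds_len_nt
    genes: list[GeneRecord] = []
    chrom_lengths: dict[str, int] = {}
    for chrom in state.chrom_order:
        pos = 0
        for g in state.chroms[chrom]:
            start = pos + g.gap_bp
            genes.append(
                GeneRecord(
                    gene_id=g.uid,
                    species_id=species_id,
                    chromosome_id=chrom,
                    start=start,
                    end=start + gene_len,
                    strand=g.strand,
                )
            )
            pos = start + gene_len
        chrom_lengths[chrom] = pos + cfg.spacing_bp
    return SpeciesGenome(species_id, chrom_lengths, genes)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_cds(
    cds: str,
    t: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Evolve one CDS for time ``t``; returns (sequence, substitutions).

    Substitution events arrive at ``cds_substitution_rate`` per site; the
    target base is drawn kappa-weighted among alternatives that do not create
    a stop codon, and nonsynonymous events are realized with probability
    ``omega_scale``. Existing stop codons (pseudogenes) are frozen.
    """
    seq = list(cds)
    L = len(seq)
    n_events = rng.poisson(cfg.cds_substitution_rate * L * t)
    kappa = cfg.ts_tv_ratio
    applied = 0
    for _ in range(n_events):
        pos = int(rng.integers(L))
        ci = pos - pos % 3
        codon = "".join(seq[ci : ci + 3])
        if codon in STOP_CODONS:
            continue
        old = seq[pos]
        choices, weights = [], []
        for nt in NUCS:
            if nt == old:
                continue
            alt = codon[: pos - ci] + nt + codon[pos - ci + 1 :]
            if alt in STOP_CODONS:
                continue
            choices.append(nt)
            weights.append(kappa if is_transition(old, nt) else 1.0)
        if not choices:
            continue
        w = np.asarray(weights) / sum(weights)
        new = choices[int(rng.choice(len(choices), p=w))]
        alt = codon[: pos - ci] + new + codon[pos - ci + 1 :]
        if CODON_TABLE[alt] != CODON_TABLE[codon] and rng.random() > cfg.omega_scale:
            continue
        seq[pos] = new
        applied += 1
    return "".join(seq), applied


def pseudogenize(cds: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Place exactly one internal stop inside the homeodomain span."""
    lo, hi = cfg.hd_span_codons
    codon_idx = int(rng.integers(lo, hi))
    stop = sorted(STOP_CODONS)[int(rng.integers(len(STOP_CODONS)))]
    return cds[: 3 * codon_idx] + stop + cds[3 * codon_idx + 3 :]


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_divergent_pair(
    n_codons: int,
    t: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Two CDSs evolved independently for time ``t`` from a common random
    ancestor; the workhorse for dN/dS estimator checks."""
    root = random_cds(n_codons, rng)
    a, _ = evolve_cds(root, t, cfg, rng)
    b, _ = evolve_cds(root, t, cfg, rng)
    return a, b


def evolve_sequences(
    root_seqs: dict[str, str],
    tree: SpeciesTreeWGD | GeneTree | str,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> dict[str, dict[str, str]]:
    """Evolve each root CDS independently down a rooted tree.

    Returns ``{leaf_label: {seq_name: sequence}}``. Branch lengths of the
    tree are the time units; a missing length counts as 1.
    """
    if isinstance(tree, str):
        t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    else:
        t = tree.tree
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out: dict[str, dict[str, str]] = {}

    def label(node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    def walk(node, seqs: dict[str, str]) -> None:
        if node.parent_node is not None:
            blen = node.edge.length if node.edge.length is not None else 1.0
            seqs = {
                name: evolve_cds(s, blen, cfg, rng)[0] for name, s in seqs.items()
            }
        kids = node.child_nodes()
        if not kids:
            out[label(node)] = seqs
            return
        for c in kids:
            walk(c, dict(seqs))

    walk(t.seed_node, dict(root_seqs))
    return out


# ---------------------------------------------------------------------------
# Gene lineage trees (true gene trees)
# ---------------------------------------------------------------------------


class LineageNode:
    """Node of a growing true gene tree."""

    __slots__ = (
        "children",
        "parent",
        "event",
        "branch",
        "blen",
        "leaf_label",
        "wgd_side",
        "extinct",
    )

    def __init__(self, event: str, branch: str):
        self.children: list[LineageNode] = []
        self.parent: LineageNode | None = None
        self.event = event  # root | speciation | wgd | tandem_dup | dispersed_dup
        self.branch = branch  # species-tree node id where the event happened
        self.blen = 0.0
        self.leaf_label: str | None = None
        self.wgd_side: str | None = None  # 'A'/'B' under the focal WGD
        self.extinct = False

    def add_child(self, child: "LineageNode") -> None:
        child.parent = self
        self.children.append(child)

    def surviving_leaves(self) -> list["LineageNode"]:
        if not self.children:
            return [] if self.extinct or self.leaf_label is None else [self]
        out = []
        for c in self.children:
            out.extend(c.surviving_leaves())
        return out


def _prune_newick(node: LineageNode) -> str | None:
    """Newick of the surviving part of a lineage tree (unifurcations
    suppressed, branch lengths summed)."""

    def rec(n: LineageNode, extra: float) -> str | None:
        if not n.children:
            if n.extinct or n.leaf_label is None:
                return None
            return f"'{n.leaf_label}':{n.blen + extra:g}"
        subs = [rec(c, 0.0) for c in n.children]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            # re-attach the child with this node's branch length added
            child = [c for c in n.children if rec(c, 0.0) is not None]
            return rec(child[0], extra + n.blen) if child else None
        return f"({','.join(subs)}):{n.blen + extra:g}"

    s = rec(node, 0.0)
    if s is None:
        return None
    # strip the root branch length
    return s.rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    species_tree: SpeciesTreeWGD
    genomes: dict[str, SpeciesGenome]
    gene_trees: dict[str, GeneTree]
    event_log: EventLog
    truth: pd.DataFrame  # family, category, duplication_branch, loss_branches
    catalog: FamilyCatalog
    root_state: GenomeState
    homeodomains: dict[str, dict[str, str]]  # species -> gene -> aa
    cds: dict[str, dict[str, str]]  # species -> gene -> nt


def node_ids(stree: SpeciesTreeWGD) -> dict[dendropy.Node, str]:
    """Stable id per species-tree node: leaf name, label, or preorder N#."""
    ids = {}
    for k, node in enumerate(stree.tree.preorder_node_iter()):
        if node.is_leaf():
            ids[node] = node.taxon.label if node.taxon else node.label
        elif node.label:
            ids[node] = node.label
        else:
            ids[node] = f"N{k}"
    return ids


class _Simulator:
    def __init__(self, stree: SpeciesTreeWGD, cfg: SimulationConfig):
        self.stree = stree
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.log = EventLog()
        self.node_id = node_ids(stree)
        self.uid_counter: dict[str, int] = {}
        self.chrom_counter = 0
        self.families: list[str] = []
        self.roots: dict[str, LineageNode] = {}
        self.catalog = FamilyCatalog()
        self.leaf_states: dict[str, GenomeState] = {}
        self.leaf_seqs: dict[str, dict[str, str]] = {}
        self.leaf_tips: dict[str, dict[str, LineageNode]] = {}

    # -- id helpers -------------------------------------------------------
    def new_uid(self, family: str) -> str:
        k = self.uid_counter.get(family, 0)
        self.uid_counter[family] = k + 1
        return f"{family}.{k}"

    def new_chrom(self) -> str:
        self.chrom_counter += 1
        return f"x{self.chrom_counter}"

    # -- root genome ------------------------------------------------------
    def build_root(self) -> tuple[GenomeState, dict[str, str], dict[str, LineageNode]]:
        cfg = self.cfg
        template_total = sum(cfg.cluster_templates.values())
        if template_total > cfg.n_families:
            raise ValueError(
                f"cluster templates use {template_total} families but "
                f"n_families={cfg.n_families}"
            )
        fams: list[tuple[str, str | None, int | None]] = []
        for cname, k in cfg.cluster_templates.items():
            for i in range(k):
                fams.append((f"{cname}{i:02d}", cname, i))
        for i in range(cfg.n_families - template_total):
            fams.append((f"FAM{i:03d}", None, None))
        self.families = [f[0] for f in fams]

        state = GenomeState()
        for i in range(cfg.n_chromosomes):
            c = f"c{i + 1}"
            state.chrom_order.append(c)
            state.chroms[c] = []

        seqs: dict[str, str] = {}
        tips: dict[str, LineageNode] = {}
        root_id = self.node_id[self.stree.tree.seed_node]

        # cluster templates: contiguous runs in canonical order, alternating
        # strands, one cluster per chromosome round-robin
        by_cluster: dict[str, list[tuple[str, int]]] = {}
        singles: list[str] = []
        for fam, cl, order in fams:
            if cl is None:
                singles.append(fam)
            else:
                by_cluster.setdefault(cl, []).append((fam, order))
        for ci, (cl, members) in enumerate(sorted(by_cluster.items())):
            chrom = state.chrom_order[ci % cfg.n_chromosomes]
            for fam, order in sorted(members, key=lambda m: m[1]):
                uid = self.new_uid(fam)
                strand = "+" if order % 2 == 0 else "-"
                state.chroms[chrom].append(
                    StructGene(uid, fam, strand, cfg.spacing_bp)
                )
                self._register_root_gene(fam, uid, seqs, tips, root_id)
        for fam in singles:
            chrom = state.chrom_order[int(self.rng.integers(cfg.n_chromosomes))]
            pos = int(self.rng.integers(len(state.chroms[chrom]) + 1))
            uid = self.new_uid(fam)
            strand = "+" if self.rng.random() < 0.5 else "-"
            state.chroms[chrom].insert(
                pos, StructGene(uid, fam, strand, cfg.spacing_bp)
            )
            self._register_root_gene(fam, uid, seqs, tips, root_id)

        # catalog entries: consensus = root homeodomain; three diagnostic
        # positions fixed to the consensus residue
        for fam, cl, order in fams:
            uid = f"{fam}.0"
            lo, hi = cfg.hd_span_codons
            hd = translate(seqs[uid])[lo:hi]
            dpos = sorted(
                int(p) + 1
                for p in self.rng.choice(cfg.homeodomain_len, size=3, replace=False)
            )
            self.catalog.add(
                FamilyEntry(
                    fam,
                    cl if cl is not None else "MISC",
                    hd,
                    [(p, {hd[p - 1]}) for p in dpos],
                    cluster=cl,
                    cluster_order=order,
                )
            )
        return state, seqs, tips

    def _register_root_gene(self, fam, uid, seqs, tips, root_id) -> None:
        seqs[uid] = random_cds(self.cfg.cds_len_nt // 3, self.rng)
        node = LineageNode("root", root_id)
        self.roots[fam] = node
        tips[uid] = node

    # -- per-branch evolution --------------------------------------------
    def run(self) -> None:
        root_state, root_seqs, root_tips = self.build_root()
        self.root_state = root_state
        self._descend(
            self.stree.tree.seed_node, root_state, root_seqs, root_tips
        )

    def _descend(self, node, state, seqs, tips) -> None:
        kids = node.child_nodes()
        if not kids:
            sp = self.node_id[node]
            self.leaf_states[sp] = state
            self.leaf_seqs[sp] = seqs
            self.leaf_tips[sp] = tips
            for uid, tip in tips.items():
                tip.leaf_label = f"{sp}|{uid}"
            return
        branch_id = self.node_id[node]
        self.log.append(Event("speciation", branch_id))
        for child in kids:
            cs = state.clone()
            cseqs = dict(seqs)
            ctips = {}
            for uid, tip in tips.items():
                t = LineageNode("speciation", branch_id)
                tip.add_child(t)
                ctips[uid] = t
            self._evolve_branch(child, cs, cseqs, ctips)
            self._descend(child, cs, cseqs, ctips)

    def _evolve_branch(self, child, state, seqs, tips) -> None:
        blen = child.edge.length if child.edge.length is not None else 1.0
        branch = self.node_id[child]
        is_wgd = child is self.stree.wgd_node
        if is_wgd:
            self._structural_events(branch, state, seqs, tips, blen / 2)
            self._sequence_events(branch, state, seqs, tips, blen / 2)
            self._apply_wgd(branch, state, seqs, tips)
            self._structural_events(branch, state, seqs, tips, blen / 2)
            self._sequence_events(branch, state, seqs, tips, blen / 2)
        else:
            self._structural_events(branch, state, seqs, tips, blen)
            self._sequence_events(branch, state, seqs, tips, blen)
        if state.n_genes() > self.cfg.max_genes:
            raise RuntimeError(
                f"simulation exceeded {self.cfg.max_genes} genes; lower the "
                "duplication rates"
            )

    def _structural_events(self, branch, state, seqs, tips, t) -> None:
        cfg, rng = self.cfg, self.rng
        n = state.n_genes()
        for _ in range(rng.poisson(cfg.tandem_duplication_rate * n * t)):
            self._tandem_dup(branch, state, seqs, tips)
        for _ in range(rng.poisson(cfg.dispersed_duplication_rate * n * t)):
            self._dispersed_dup(branch, state, seqs, tips)
        for _ in range(rng.poisson(cfg.gene_loss_rate * n * t)):
            self._loss(branch, state, seqs, tips)
        for _ in range(rng.poisson(cfg.inversion_rate * t)):
            self._inversion(branch, state)
        for _ in range(rng.poisson(cfg.translocation_rate * t)):
            self._translocation(branch, state)
        if rng.random() < cfg.fusion_prob and len(state.chrom_order) >= 2:
            self._fusion(branch, state)
        if rng.random() < cfg.fission_prob:
            self._fission(branch, state)

    def _sequence_events(self, branch, state, seqs, tips, t) -> None:
        cfg, rng = self.cfg, self.rng
        p_pseudo = 1.0 - np.exp(-cfg.pseudogenize_prob * t)
        for _chrom, _i, g in state.all_genes():
            seqs[g.uid], _ = evolve_cds(seqs[g.uid], t, cfg, rng)
            lo, hi = cfg.hd_span_codons
            already = "*" in translate(seqs[g.uid])[lo:hi]
            if not already and rng.random() < p_pseudo:
                seqs[g.uid] = pseudogenize(seqs[g.uid], cfg, rng)
            tips[g.uid].blen += t

    def _pick_gene(self, state) -> tuple[str, int, StructGene]:
        genes = state.all_genes()
        return genes[int(self.rng.integers(len(genes)))]

    def _split_tip(self, uid, new_uid, event, branch, tips) -> None:
        tip = tips[uid]
        a = LineageNode(event, branch)
        b = LineageNode(event, branch)
        tip.add_child(a)
        tip.add_child(b)
        tips[uid] = a
        tips[new_uid] = b

    def _tandem_dup(self, branch, state, seqs, tips) -> None:
        chrom, i, g = self._pick_gene(state)
        child_uid = self.new_uid(g.family)
        lo, hi = self.cfg.tandem_offset_bp
        offset = int(self.rng.integers(lo, hi + 1))
        ev = Event(
            "tandem_dup", branch, {"parent": g.uid, "child": child_uid, "offset": offset}
        )
        state.apply(ev)
        self.log.append(ev)
        seqs[child_uid] = seqs[g.uid]
        self._split_tip(g.uid, child_uid, "tandem_dup", branch, tips)

    def _dispersed_dup(self, branch, state, seqs, tips) -> None:
        chrom, i, g = self._pick_gene(state)
        child_uid = self.new_uid(g.family)
        target = state.chrom_order[int(self.rng.integers(len(state.chrom_order)))]
        idx = int(self.rng.integers(len(state.chroms[target]) + 1))
        strand = "+" if self.rng.random() < 0.5 else "-"
        ev = Event(
            "dispersed_dup",
            branch,
            {
                "parent": g.uid,
                "child": child_uid,
                "target_chrom": target,
                "target_index": idx,
                "strand": strand,
                "offset": self.cfg.spacing_bp,
            },
        )
        state.apply(ev)
        self.log.append(ev)
        seqs[child_uid] = seqs[g.uid]
        self._split_tip(g.uid, child_uid, "dispersed_dup", branch, tips)

    def _loss(self, branch, state, seqs, tips) -> None:
        if state.n_genes() == 0:
            return
        _chrom, _i, g = self._pick_gene(state)
        ev = Event("loss", branch, {"gene": g.uid})
        state.apply(ev)
        self.log.append(ev)
        tips[g.uid].extinct = True
        del tips[g.uid], seqs[g.uid]

    def _inversion(self, branch, state) -> None:
        eligible = [c for c in state.chrom_order if len(state.chroms[c]) >= 2]
        if not eligible:
            return
        chrom = eligible[int(self.rng.integers(len(eligible)))]
        n = len(state.chroms[chrom])
        span = int(self.rng.integers(2, min(n, 8) + 1))
        first = int(self.rng.integers(0, n - span + 1))
        ev = Event(
            "inversion", branch, {"chrom": chrom, "first": first, "last": first + span - 1}
        )
        state.apply(ev)
        self.log.append(ev)

    def _translocation(self, branch, state) -> None:
        eligible = [c for c in state.chrom_order if len(state.chroms[c]) >= 1]
        if len(state.chrom_order) < 2 or not eligible:
            return
        src = eligible[int(self.rng.integers(len(eligible)))]
        others = [c for c in state.chrom_order if c != src]
        dst = others[int(self.rng.integers(len(others)))]
        n = len(state.chroms[src])
        count = int(self.rng.integers(1, min(n, 3) + 1))
        first = int(self.rng.integers(0, n - count + 1))
        dst_index = int(self.rng.integers(0, len(state.chroms[dst]) + 1))
        ev = Event(
            "translocation",
            branch,
            {
                "src_chrom": src,
                "first": first,
                "count": count,
                "dst_chrom": dst,
                "dst_index": dst_index,
            },
        )
        state.apply(ev)
        self.log.append(ev)

    def _fusion(self, branch, state) -> None:
        i, j = self.rng.choice(len(state.chrom_order), size=2, replace=False)
        a, b = state.chrom_order[int(i)], state.chrom_order[int(j)]
        ev = Event(
            "fusion", branch, {"chrom_a": a, "chrom_b": b, "new_chrom": self.new_chrom()}
        )
        state.apply(ev)
        self.log.append(ev)

    def _fission(self, branch, state) -> None:
        eligible = [c for c in state.chrom_order if len(state.chroms[c]) >= 2]
        if not eligible:
            return
        chrom = eligible[int(self.rng.integers(len(eligible)))]
        k = int(self.rng.integers(1, len(state.chroms[chrom])))
        ev = Event(
            "fission",
            branch,
            {
                "chrom": chrom,
                "index": k,
                "new_a": self.new_chrom(),
                "new_b": self.new_chrom(),
            },
        )
        state.apply(ev)
        self.log.append(ev)

    def _apply_wgd(self, branch, state, seqs, tips) -> None:
        pairs = []
        for chrom in list(state.chrom_order):
            copies, originals = [], []
            for g in state.chroms[chrom]:
                child_uid = self.new_uid(g.family)
                originals.append(g.uid)
                copies.append(child_uid)
            pairs.append(
                {"chrom": chrom, "copy": self.new_chrom(), "genes": originals,
                 "copies": copies}
            )
        ev = Event("wgd", branch, {"chromosomes": pairs})
        state.apply(ev)
        self.log.append(ev)
        for pair in pairs:
            for uid, new_uid in zip(pair["genes"], pair["copies"]):
                seqs[new_uid] = seqs[uid]
                self._split_tip(uid, new_uid, "wgd", branch, tips)
                tips[uid].wgd_side = "A"
                tips[new_uid].wgd_side = "B"


# ---------------------------------------------------------------------------
# Truth labels
# ---------------------------------------------------------------------------


def _oldest_retained_duplication(root: LineageNode, is_coding) -> LineageNode | None:
    """First (closest to the root, preorder) duplication node both of whose
    children have surviving coding descendants."""

    def retained(n: LineageNode) -> bool:
        return any(is_coding(l.leaf_label) for l in n.surviving_leaves())

    def walk(n: LineageNode, depth: int, acc: list):
        if n.children and n.children[0].event in ("wgd", "tandem_dup", "dispersed_dup"):
            if all(retained(c) for c in n.children):
                acc.append((depth, len(acc), n))
        for c in n.children:
            walk(c, depth + 1, acc)

    acc: list = []
    walk(root, 0, acc)
    if not acc:
        return None
    return min(acc)[2]


def _post_wgd_lineage(node: LineageNode) -> bool:
    """True if the lineage leading to ``node`` already passed through the WGD."""
    n: LineageNode | None = node
    while n is not None:
        if n.event == "wgd":
            return True
        n = n.parent
    return False


def _truth_table(sim: _Simulator, pseudo: dict[str, set[str]]) -> pd.DataFrame:
    stree = sim.stree
    ids = sim.node_id
    spiders = stree.named_clade("spiders") if _has_clade(stree, "spiders") else None
    enteleg = (
        stree.named_clade("entelegynes") if _has_clade(stree, "entelegynes") else None
    )
    wgd_sp = stree.wgd_species

    def is_coding(leaf_label: str) -> bool:
        sp = GeneTree.leaf_species(leaf_label)
        return GeneTree.leaf_gene(leaf_label) not in pseudo.get(sp, set())

    rows = []
    for fam in sim.families:
        root = sim.roots[fam]
        leaves = root.surviving_leaves()
        coding = [l for l in leaves if is_coding(l.leaf_label)]
        if not coding:
            rows.append((fam, "EXTINCT", "", ""))
            continue
        dup = _oldest_retained_duplication(root, is_coding)
        category, dup_branch, loss_branches = "SC", "", []
        if dup is not None:
            kind = dup.children[0].event
            dup_branch = dup.children[0].branch
            if kind == "wgd":
                category = "O"
                sides = []
                for child in dup.children:
                    sp = {
                        GeneTree.leaf_species(l.leaf_label)
                        for l in child.surviving_leaves()
                        if GeneTree.leaf_gene(l.leaf_label)
                        not in pseudo.get(GeneTree.leaf_species(l.leaf_label), set())
                    }
                    sides.append(sp)
                if spiders is not None:
                    scorp = wgd_sp - spiders
                    for sp in sides:
                        if not (sp & spiders) and (sp & scorp):
                            category = "SOL"
                            loss_branches = dollo_loss_branches(
                                sp, stree, stree.wgd_node, ids
                            )
                            break
                    else:
                        if enteleg is not None:
                            for sp in sides:
                                if not (sp & enteleg) and (sp & (spiders - enteleg)):
                                    category = "EOL"
                                    loss_branches = dollo_loss_branches(
                                        sp, stree, stree.wgd_node, ids
                                    )
                                    break
            else:
                wgd_node = stree.wgd_node
                dup_snode = _branch_node(stree, ids, dup_branch)
                if dup_snode is wgd_node:
                    # on the WGD branch itself: pre-WGD unless the lineage
                    # already carries the WGD
                    pre_wgd = not _post_wgd_lineage(dup)
                else:
                    pre_wgd = stree.is_ancestor(dup_snode, wgd_node)
                category = "AT" if pre_wgd else "RT"
        rows.append((fam, category, dup_branch, ";".join(loss_branches)))
    return pd.DataFrame(
        rows, columns=["family", "category", "duplication_branch", "loss_branches"]
    )


def _has_clade(stree: SpeciesTreeWGD, name: str) -> bool:
    try:
        stree.named_clade(name)
        return True
    except KeyError:
        return False


def _branch_node(stree, ids, branch_id) -> dendropy.Node:
    for node, nid in ids.items():
        if nid == branch_id:
            return node
    raise KeyError(branch_id)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def simulate(
    species_tree: SpeciesTreeWGD | None = None,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Run the forward simulation and package genomes, trees, log and truth."""
    stree = species_tree or default_species_tree()
    cfg = config or SimulationConfig()
    sim = _Simulator(stree, cfg)
    sim.run()

    lo, hi = cfg.hd_span_codons
    genomes: dict[str, SpeciesGenome] = {}
    homeodomains: dict[str, dict[str, str]] = {}
    cds: dict[str, dict[str, str]] = {}
    pseudo: dict[str, set[str]] = {}
    for sp, state in sim.leaf_states.items():
        genome = layout_genome(state, sp, cfg)
        seqs = sim.leaf_seqs[sp]
        hd = {uid: translate(s)[lo:hi] for uid, s in seqs.items()}
        pseudo[sp] = {uid for uid, h in hd.items() if "*" in h}
        genome.genes = [
            g.copy(
                family_id=g.gene_id.split(".")[0],
                pseudogene=g.gene_id in pseudo[sp],
                homeodomain_seq=hd[g.gene_id],
                cds_seq=seqs[g.gene_id],
            )
            for g in genome.genes
        ]
        genome.sort()
        genomes[sp] = genome
        homeodomains[sp] = hd
        cds[sp] = dict(seqs)

    gene_trees: dict[str, GeneTree] = {}
    for fam in sim.families:
        nwk = _prune_newick(sim.roots[fam])
        if nwk is None or "," not in nwk:
            continue
        gene_trees[fam] = read_gene_tree(data=nwk)

    truth = _truth_table(sim, pseudo)
    return SimulationResult(
        config=cfg,
        species_tree=stree,
        genomes=genomes,
        gene_trees=gene_trees,
        event_log=sim.log,
        truth=truth,
        catalog=sim.catalog,
        root_state=sim.root_state,
        homeodomains=homeodomains,
        cds=cds,
    )


def replay(
    root_state: GenomeState, stree: SpeciesTreeWGD, log: EventLog
) -> dict[str, GenomeState]:
    """Reapply the event log to the root genome; returns per-leaf states."""
    ids = node_ids(stree)
    per_branch = {}
    for ev in log:
        per_branch.setdefault(ev.branch, []).append(ev)
    out: dict[str, GenomeState] = {}

    def walk(node, state: GenomeState) -> None:
        if not node.child_nodes():
            out[ids[node]] = state
            return
        for child in node.child_nodes():
            cs = state.clone()
            for ev in per_branch.get(ids[child], []):
                cs.apply(ev)
            walk(child, cs)

    walk(stree.tree.seed_node, root_state.clone())
    return out


def write_fixture(result: SimulationResult, directory: str) -> None:
    """Emit GFF3 + FASTA + Newick + truth/catalog TSVs; deterministic per seed."""
    os.makedirs(directory, exist_ok=True)
    result.config.to_json(os.path.join(directory, "config.json"))
    write_tree(result.species_tree, os.path.join(directory, "species_tree.nwk"))
    for sp, genome in sorted(result.genomes.items()):
        stripped = SpeciesGenome(
            sp,
            dict(genome.chromosomes),
            [g.copy(family_id="UNASSIGNED", pseudogene=False) for g in genome.genes],
        )
        write_gene_table(stripped, os.path.join(directory, f"{sp}.gff3"), "gff3")
        write_fasta(
            dict(sorted(result.homeodomains[sp].items())),
            os.path.join(directory, f"{sp}.hd.faa"),
        )
        write_fasta(
            dict(sorted(result.cds[sp].items())),
            os.path.join(directory, f"{sp}.cds.fna"),
        )
    os.makedirs(os.path.join(directory, "gene_trees"), exist_ok=True)
    for fam, gt in sorted(result.gene_trees.items()):
        write_tree(gt, os.path.join(directory, "gene_trees", f"{fam}.nwk"))
    result.truth.to_csv(
        os.path.join(directory, "truth.tsv"), sep="\t", index=False
    )
    write_catalog(result.catalog, os.path.join(directory, "catalog.tsv"))
    result.event_log.to_json(os.path.join(directory, "events.jsonl"))
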