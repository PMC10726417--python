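"""Core data model and I/O shared by all pipeline stages.

Conventions
-----------
* Gene coordinates are 0-based half-open internally; GFF3 I/O converts at the
  boundary (GFF3 is 1-based inclusive), so ``end - start`` is always the gene
  length in bp.
* Strand is strictly ``+`` or ``-``; undefined strands are rejected because
  orientation scoring downstream requires a defined strand.
* Trees are rooted. The species tree carries exactly one branch annotated as
  the whole-genome duplication (WGD); the annotation is an internal node label
  token (default ``WGD``) on the node *below* that branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNASSIGNED = "UNASSIGNED"

VALID_STRANDS = ("+", "-")

#: label used to mark genes with no family call
__all__ = [
    "UNASSIGNED",
    "GeneRecord",
    "SpeciesGenome",
    "SpeciesTreeWGD",
    "GeneTree",
    "FamilyCatalog",
    "FamilyEntry",
    "GenomeValidationError",
    "TableParseError",
    "read_gene_table",
    "write_gene_table",
    "read_species_tree",
    "read_gene_tree",
    "read_tree",
    "write_tree",
    "read_fasta",
    "write_fasta",
    "read_catalog",
    "write_catalog",
]


class GenomeValidationError(ValueError):
    """Raised when a genome, tree or catalog violates a structural invariant."""


class TableParseError(ValueError):
    """Raised on malformed tabular input; message names the offending line."""


@dataclass
class GeneRecord:
    """One gene's genomic placement plus its family call and sequences."""

    gene_id: str
    species_id: str
    chromosome_id: str
    start: int
    end: int
    strand: str
    family_id: str = UNASSIGNED
    pseudogene: bool = False
    homeodomain_seq: str | None = None
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise GenomeValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if (
            self.cds_seq is not None
            and len(self.cds_seq) % 3 != 0
            and not self.pseudogene
        ):
            raise GenomeValidationError(
                f"gene {self.gene_id}: CDS length {len(self.cds_seq)} not a "
                "multiple of 3 for a non-pseudogene"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def copy(self, **changes) -> "GeneRecord":
        return replace(self, **changes)


@dataclass
class SpeciesGenome:
    """All annotated genes of one species on an ordered set of chromosomes.

    ``chromosomes`` maps chromosome id to length in bp (insertion order is
    the display order). Genes are kept sorted by (chromosome, start, gene_id).
    """

    species_id: str
    chromosomes: dict[str, int] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.chromosome_id, g.start, g.gene_id))

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeValidationError(
                    f"{self.species_id}: duplicate gene_id {g.gene_id}"
                )
            seen.add(g.gene_id)
            if g.chromosome_id not in self.chromosomes:
                raise GenomeValidationError(
                    f"{self.species_id}: gene {g.gene_id} on unknown "
                    f"chromosome {g.chromosome_id}"
                )
            if g.end > self.chromosomes[g.chromosome_id]:
                raise GenomeValidationError(
                    f"{self.species_id}: gene {g.gene_id} extends past the end "
                    f"of {g.chromosome_id}"
                )

    # -- convenience accessors -------------------------------------------
    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_chromosome(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {c: [] for c in self.chromosomes}
        for g in self.genes:
            out[g.chromosome_id].append(g)
        return out

    def coding_genes(self) -> list[GeneRecord]:
        """Genes counted in repertoires: everything not flagged pseudogene."""
        return [g for g in self.genes if not g.pseudogene]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _read_dendropy(source: str, from_path: bool) -> dendropy.Tree:
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if from_path:
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise GenomeValidationError(f"duplicate leaf labels in tree: {e}") from e
    tree.is_rooted = True
    return tree


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


class SpeciesTreeWGD:
    """Rooted species tree with exactly one branch marked as the WGD.

    The WGD mark is the label token ``wgd_label`` on the internal node whose
    incoming branch carries the duplication; the WGD clade is that node's
    leaf set (here, the arachnopulmonates).
    """

    def __init__(self, tree: dendropy.Tree, wgd_label: str = "WGD"):
        self.tree = tree
        self.wgd_label = wgd_label
        self._index()
        marked = [
            n
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and (n.label or "").split("|")[0] == wgd_label
        ]
        if len(marked) != 1:
            raise GenomeValidationError(
                f"species tree must carry exactly one '{wgd_label}' branch "
                f"label, found {len(marked)}"
            )
        self.wgd_node: dendropy.Node = marked[0]

    def _index(self) -> None:
        self.leafset: dict[dendropy.Node, frozenset[str]] = {}
        self.depth: dict[dendropy.Node, int] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self.leafset[node] = frozenset([_node_name(node)])
            else:
                s: frozenset[str] = frozenset()
                for c in node.child_nodes():
                    s |= self.leafset[c]
                self.leafset[node] = s
        for node in self.tree.preorder_node_iter():
            p = node.parent_node
            self.depth[node] = 0 if p is None else self.depth[p] + 1

    # -- queries ----------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return sorted(self.leafset[self.tree.seed_node])

    @property
    def wgd_species(self) -> frozenset[str]:
        return self.leafset[self.wgd_node]

    def mrca(self, species: set[str] | frozenset[str]) -> dendropy.Node:
        species = frozenset(species)
        best = self.tree.seed_node
        descended = True
        while descended:
            descended = False
            for c in best.child_nodes():
                if species <= self.leafset[c]:
                    best = c
                    descended = True
                    break
        return best

    def is_ancestor(self, anc: dendropy.Node, node: dendropy.Node) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of ``node``."""
        while node is not None:
            if node is anc:
                return True
            node = node.parent_node
        return False

    def named_clade(self, name: str) -> frozenset[str]:
        """Leaf set of the internal node labelled ``name`` (labels may be
        '|'-joined tokens, e.g. ``WGD|arachnopulmonates``)."""
        for n in self.tree.preorder_node_iter():
            if n.is_leaf():
                continue
            tokens = (n.label or "").split("|")
            if name in tokens:
                return self.leafset[n]
        raise KeyError(f"no internal node named {name!r}")

    def validate_genomes(self, genomes: dict[str, SpeciesGenome]) -> list[str]:
        """Return warnings for species present in only one of tree/genomes."""
        warnings = []
        tree_sp = set(self.species)
        for sp in sorted(tree_sp - set(genomes)):
            warnings.append(f"tree leaf {sp} has no genome")
        for sp in sorted(set(genomes) - tree_sp):
            warnings.append(f"genome {sp} is not a leaf of the species tree")
        return warnings


LEAF_SEP = "|"


class GeneTree:
    """Rooted binary gene tree; leaves are labelled ``species|gene_id``."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = []
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise GenomeValidationError(
                    "gene trees must be strictly binary (polytomy or "
                    "unrooted input encountered)"
                )
            if not kids:
                labels.append(_node_name(node))
        if len(labels) != len(set(labels)):
            raise GenomeValidationError("duplicate leaf labels in gene tree")
        self.leaf_labels = labels

    @staticmethod
    def leaf_species(label: str) -> str:
        return label.split(LEAF_SEP, 1)[0]

    @staticmethod
    def leaf_gene(label: str) -> str:
        return label.split(LEAF_SEP, 1)[1]

    @property
    def species(self) -> set[str]:
        return {self.leaf_species(l) for l in self.leaf_labels}

    def n_leaves(self) -> int:
        return len(self.leaf_labels)


def read_tree(
    path: str, wgd_label: str = "WGD", data: str | None = None
) -> SpeciesTreeWGD | GeneTree:
    """Read a Newick tree; dispatch on the presence of the WGD label."""
    tree = _read_dendropy(data if data is not None else path, data is None)
    has_wgd = any(
        not n.is_leaf() and wgd_label in (n.label or "").split("|")
        for n in tree.preorder_node_iter()
    )
    if has_wgd:
        return SpeciesTreeWGD(tree, wgd_label=wgd_label)
    return GeneTree(tree)


def read_species_tree(
    path: str | None = None, wgd_label: str = "WGD", data: str | None = None
) -> SpeciesTreeWGD:
    tree = _read_dendropy(data if data is not None else path, data is None)
    return SpeciesTreeWGD(tree, wgd_label=wgd_label)


def read_gene_tree(path: str | None = None, data: str | None = None) -> GeneTree:
    tree = _read_dendropy(data if data is not None else path, data is None)
    return GeneTree(tree)


def write_tree(tree: SpeciesTreeWGD | GeneTree | dendropy.Tree, path: str) -> None:
    t = tree.tree if isinstance(tree, (SpeciesTreeWGD, GeneTree)) else tree
    t.write(
        path=path,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


# ---------------------------------------------------------------------------
# Family catalog
# ---------------------------------------------------------------------------


@dataclass
class FamilyEntry:
    family_id: str
    hd_class: str  # ANTP / PRD / LIM / SINE / TALE / ...
    consensus: str  # 60 aa homeodomain consensus
    diagnostics: list[tuple[int, set[str]]] = field(default_factory=list)
    cluster: str | None = None  # Hox / NK / NK2 / HRO / Irx / SINE / None
    cluster_order: int | None = None  # canonical index within cluster

    def __post_init__(self) -> None:
        for pos, _aa in self.diagnostics:
            if not 1 <= pos <= len(self.consensus):
                raise GenomeValidationError(
                    f"{self.family_id}: diagnostic position {pos} outside "
                    f"1..{len(self.consensus)}"
                )


@dataclass
class FamilyCatalog:
    """Reference catalog: consensus homeodomains, diagnostic residues and
    canonical cluster membership/order for each family."""

    families: dict[str, FamilyEntry] = field(default_factory=dict)

    def add(self, entry: FamilyEntry) -> None:
        self.families[entry.family_id] = entry

    def __contains__(self, fam: str) -> bool:
        return fam in self.families

    def __getitem__(self, fam: str) -> FamilyEntry:
        return self.families[fam]

    def __iter__(self):
        return iter(self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def cluster_template(self, cluster: str) -> list[str]:
        """Family ids of one cluster in canonical order."""
        members = [f for f in self if f.cluster == cluster]
        members.sort(key=lambda f: (f.cluster_order, f.family_id))
        orders = [f.cluster_order for f in members]
        if sorted(orders) != list(range(len(members))):
            raise GenomeValidationError(
                f"cluster {cluster}: canonical orders must be a permutation "
                f"of 0..{len(members) - 1}"
            )
        return [f.family_id for f in members]

    def clusters(self) -> list[str]:
        return sorted({f.cluster for f in self if f.cluster is not None})


def read_catalog(path: str) -> FamilyCatalog:
    """Catalog TSV: family, class, consensus, diagnostics ('pos:aa|aa;...'),
    cluster, cluster_order. Empty fields allowed for the last three."""
    cat = FamilyCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableParseError(f"{path}:{lineno}: expected >=3 columns")
            fam, cls, cons = parts[0], parts[1], parts[2]
            diags: list[tuple[int, set[str]]] = []
            if len(parts) > 3 and parts[3]:
                for token in parts[3].split(";"):
                    pos_s, aas = token.split(":")
                    diags.append((int(pos_s), set(aas.split("|"))))
            cluster = parts[4] if len(parts) > 4 and parts[4] else None
            order = int(parts[5]) if len(parts) > 5 and parts[5] != "" else None
            cat.add(FamilyEntry(fam, cls, cons, diags, cluster, order))
    return cat


def write_catalog(cat: FamilyCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tclass\tconsensus\tdiagnostics\tcluster\tcluster_order\n")
        for f in sorted(cat, key=lambda e: e.family_id):
            diag = ";".join(
                f"{pos}:{'|'.join(sorted(aa))}" for pos, aa in f.diagnostics
            )
            fh.write(
                f"{f.family_id}\t{f.hd_class}\t{f.consensus}\t{diag}\t"
                f"{f.cluster or ''}\t"
                f"{'' if f.cluster_order is None else f.cluster_order}\n"
            )


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_BED_COLUMNS = "species gene_id chromosome start end strand family pseudogene".split()


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes")


def read_gene_table(
    path: str, format: str = "gff3", species_id: str | None = None
) -> SpeciesGenome:
    """Read a per-species gene coordinate table.

    ``gff3``: only feature type ``gene`` rows are used; coordinates are
    converted from 1-based inclusive to 0-based half-open. ``bed_tsv``: the
    tab-separated layout (species, gene_id, chromosome, start, end, strand,
    family[, pseudogene]) already 0-based half-open. Chromosome lengths come
    from ``##sequence-region`` pragmas when present, else default to the max
    gene end per chromosome.
    """
    if format not in ("gff3", "bed_tsv"):
        raise ValueError(f"unknown format {format!r}")
    genes: list[GeneRecord] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if format == "gff3" and line.startswith("##sequence-region"):
                try:
                    _, chrom, _start, end = line.split()
                    chrom_lengths[chrom] = int(end)
                except ValueError as e:
                    raise TableParseError(
                        f"{path}:{lineno}: bad ##sequence-region pragma"
                    ) from e
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if format == "gff3":
                    if len(parts) != 9:
                        raise ValueError("expected 9 columns")
                    if parts[2] != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    if "ID" not in attrs:
                        raise ValueError("gene row lacks ID attribute")
                    rec = GeneRecord(
                        gene_id=attrs["ID"],
                        species_id=species_id or attrs.get("species", parts[1]),
                        chromosome_id=parts[0],
                        start=int(parts[3]) - 1,
                        end=int(parts[4]),
                        strand=parts[6],
                        family_id=attrs.get("family", UNASSIGNED),
                        pseudogene=_parse_bool(attrs.get("pseudogene", "false")),
                    )
                else:
                    if len(parts) < 7:
                        raise ValueError("expected >=7 columns")
                    rec = GeneRecord(
                        gene_id=parts[1],
                        species_id=parts[0],
                        chromosome_id=parts[2],
                        start=int(parts[3]),
                        end=int(parts[4]),
                        strand=parts[5],
                        family_id=parts[6] or UNASSIGNED,
                        pseudogene=_parse_bool(parts[7]) if len(parts) > 7 else False,
                    )
            except (ValueError, GenomeValidationError) as e:
                raise TableParseError(f"{path}:{lineno}: {e}") from e
            genes.append(rec)

    species = species_id
    if species is None:
        species = genes[0].species_id if genes else "unknown"
    for g in genes:
        chrom_lengths.setdefault(g.chromosome_id, 0)
        chrom_lengths[g.chromosome_id] = max(chrom_lengths[g.chromosome_id], g.end)
    genome = SpeciesGenome(
        species_id=species,
        chromosomes=dict(sorted(chrom_lengths.items())),
        genes=genes,
    )
    genome.validate()
    return genome


def write_gene_table(genome: SpeciesGenome, path: str, format: str = "gff3") -> None:
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for chrom, length in genome.chromosomes.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for g in genome.genes:
                attrs = f"ID={g.gene_id};family={g.family_id}"
                if g.pseudogene:
                    attrs += ";pseudogene=true"
                fh.write(
                    f"{g.chromosome_id}\tohnotype\tgene\t{g.start + 1}\t{g.end}\t"
                    f".\t{g.strand}\t.\t{attrs}\n"
                )
        elif format == "bed_tsv":
            fh.write("#" + "\t".join(_BED_COLUMNS) + "\n")
            for g in genome.genes:
                fh.write(
                    f"{g.species_id}\t{g.gene_id}\t{g.chromosome_id}\t{g.start}\t"
                    f"{g.end}\t{g.strand}\t{g.family_id}\t{int(g.pseudogene)}\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def attach_sequences(
    genome: SpeciesGenome,
    homeodomains: dict[str, str] | None = None,
    cds: dict[str, str] | None = None,
) -> None:
    """Attach sequences to gene records in place, keyed by gene id."""
    for i, g in enumerate(genome.genes):
        changes = {}
        if homeodomains and g.gene_id in homeodomains:
            changes["homeodomain_seq"] = homeodomains[g.gene_id]
        if cds and g.gene_id in cds:
            changes["cds_seq"] = cds[g.gene_id]
        if changes:
            genome.genes[i] = g.copy(**changes)
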