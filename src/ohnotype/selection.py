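"""Pairwise dN/dS by the Nei–Gojobori (1986) counting method.

Sites: each codon position contributes 1 site, split into synonymous and
nonsynonymous fractions according to the proportion of sense (non-stop)
single-nucleotide changes at that position that are synonymous, so S + N is
exactly 3 x the number of compared codons. Site counts are averaged over
the two sequences.

Differences: codons differing at d positions are resolved by averaging the
synonymous/nonsynonymous step counts over all d! orderings of single-step
paths; paths passing through a stop codon are excluded (the classic NG86
convention). In the degenerate case where every path crosses a stop, the
average falls back to all paths.

Rates: Jukes–Cantor correction, dS = -3/4 ln(1 - 4/3 pS) (same for dN);
omega = dN/dS is reported as NA — never infinity — when dS = 0 or the log
argument is non-positive (saturation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import log

from .genome_model import SpeciesGenome
from .synthetic_data import CODON_TABLE, NUCS, STOP_CODONS, translate


@dataclass
class DnDsResult:
    S: float  # synonymous sites (fractional)
    N: float  # nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    note: str = ""
    n_codons: int = 0


# -- per-codon site fractions (cached over the 61 sense codons) -------------

_SITE_CACHE: dict[str, tuple[float, float]] = {}


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon; sums to 3."""
    if codon in _SITE_CACHE:
        return _SITE_CACHE[codon]
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        sense, s = 0, 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            sense += 1
            if CODON_TABLE[alt] == aa:
                s += 1
        if sense:
            syn += s / sense
    _SITE_CACHE[codon] = (syn, 3.0 - syn)
    return _SITE_CACHE[codon]


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over single-step mutational pathways that avoid stop codons."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[int, int] | None:
        cur = codon_a
        syn = non = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                # necessarily an intermediate: both endpoints are sense
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [walk(order) for order in itertools.permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every path crosses a stop: fall back to all paths
        valid = [p for p in (
            _walk_through_stops(codon_a, codon_b, order)
            for order in itertools.permutations(diff)
        )]
    syn = sum(p[0] for p in valid) / len(valid)
    non = sum(p[1] for p in valid) / len(valid)
    return syn, non


def _walk_through_stops(codon_a, codon_b, order) -> tuple[int, int]:
    cur = codon_a
    syn = non = 0
    for pos in order:
        nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
        if CODON_TABLE[nxt] == CODON_TABLE[cur]:
            syn += 1
        else:
            non += 1
        cur = nxt
    return syn, non


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * log(arg)


def ng86(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei–Gojobori dN/dS for an aligned, gap-free, stop-free codon pair."""
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3 or not cds_a:
        raise ValueError("alignment length must be a positive multiple of 3")
    codons_a = [cds_a[i : i + 3].upper() for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3].upper() for i in range(0, len(cds_b), 3)]
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon in alignment: {ca}/{cb}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s, n = _pathway_differences(ca, cb)
        Sd += s
        Nd += n
        n_codons += 1
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    note = ""
    omega: float | None = None
    if dS is None:
        note = "dS saturated (Jukes-Cantor log argument <= 0)"
    elif dN is None:
        note = "dN saturated (Jukes-Cantor log argument <= 0)"
    elif dS == 0.0:
        note = "omega undefined (dS = 0)"
    else:
        omega = dN / dS
    return DnDsResult(S, N, Sd, Nd, pS, pN, dS, dN, omega, note, n_codons)


# ---------------------------------------------------------------------------
# Codon alignment from a protein alignment
# ---------------------------------------------------------------------------


def backtranslate_align(
    prot_aln_a: str,
    prot_aln_b: str,
    cds_a: str,
    cds_b: str,
) -> tuple[str, str]:
    """Expand an aligned protein pair to a codon alignment.

    Each aligned residue becomes its codon; columns with a gap or an
    ambiguous base are dropped, so the result is gap-free and a multiple of
    3. The ungapped protein must equal the CDS translation (standard code).
    """
    if len(prot_aln_a) != len(prot_aln_b):
        raise ValueError("protein alignment rows differ in length")

    def check(prot_aln: str, cds: str, which: str) -> None:
        prot = prot_aln.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"sequence {which}: CDS length {len(cds)} does not match "
                f"{len(prot)} residues"
            )
        trans = translate(cds.upper())
        for i, (x, y) in enumerate(zip(trans, prot.upper())):
            if x != y:
                raise ValueError(
                    f"sequence {which}: translation mismatch at residue "
                    f"{i + 1} ({x} vs {y})"
                )

    check(prot_aln_a, cds_a, "a")
    check(prot_aln_b, cds_b, "b")
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ra, rb in zip(prot_aln_a, prot_aln_b):
        ca = cds_a[3 * ia : 3 * ia + 3].upper() if ra != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3].upper() if rb != "-" else None
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
        if ca is None or cb is None:
            continue
        if set(ca + cb) - set(NUCS):
            continue  # ambiguous bases: drop the column
        out_a.append(ca)
        out_b.append(cb)
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Pair scans over genomes
# ---------------------------------------------------------------------------


@dataclass
class PairResult:
    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    category: str  # 1-1 | 1-2 | O | T
    result: DnDsResult | None
    warning: str = ""


def pairwise_scan(
    genomes: dict[str, SpeciesGenome],
    pairs: list[tuple[str, str, str, str, str]],
) -> list[PairResult]:
    """Compute dN/dS for labelled gene pairs.

    ``pairs`` rows are (species_a, gene_a, species_b, gene_b, category)
    using the orthologue/ohnologue labelling scheme: ``1-1`` direct
    orthology, ``1-2`` outgroup gene vs one of two ohnologues, ``O``
    between ohnologues, ``T`` between tandem paralogues. Pairs with a
    missing CDS (or unalignable lengths, absent an external aligner) are
    skipped with a warning.
    """
    out = []
    for sa, ga, sb, gb, category in pairs:
        try:
            ra = genomes[sa].get(ga)
            rb = genomes[sb].get(gb)
        except KeyError as e:
            out.append(PairResult(sa, ga, sb, gb, category, None, f"missing gene {e}"))
            continue
        if not ra.cds_seq or not rb.cds_seq:
            out.append(PairResult(sa, ga, sb, gb, category, None, "missing CDS"))
            continue
        if len(ra.cds_seq) != len(rb.cds_seq):
            out.append(
                PairResult(
                    sa, ga, sb, gb, category, None,
                    "CDS lengths differ; supply a protein alignment",
                )
            )
            continue
        res = ng86(ra.cds_seq, rb.cds_seq)
        out.append(PairResult(sa, ga, sb, gb, category, res))
    return out


def pairs_from_call(
    call,
    genomes: dict[str, SpeciesGenome],
    focal_species: str,
    outgroup_species: str,
) -> list[tuple[str, str, str, str, str]]:
    """Derive labelled comparison pairs for one family call.

    Emits the pairs of the standard scheme: O between the focal species'
    two ohnologues, 1-2 from the outgroup copy to each focal ohnologue, or
    1-1 outgroup-to-focal when the focal species has a single copy; T
    between focal tandem paralogues of AT/RT families.
    """
    def coding(sp: str) -> list[str]:
        return sorted(
            g.gene_id
            for g in genomes[sp].genes
            if g.family_id == call.family_id and not g.pseudogene
        )

    focal = coding(focal_species)
    outg = coding(outgroup_species)
    pairs: list[tuple[str, str, str, str, str]] = []
    if call.category in ("O", "SOL", "EOL"):
        sides = call.evidence.get("side_genes", [])
        focal_sides = [
            [g for s, g in side if s == focal_species] for side in sides
        ]
        if all(focal_sides):
            a, b = sorted(focal_sides[0])[0], sorted(focal_sides[1])[0]
            pairs.append((focal_species, a, focal_species, b, "O"))
            for g in (a, b):
                if outg:
                    pairs.append((outgroup_species, outg[0], focal_species, g, "1-2"))
        elif focal and outg:
            pairs.append((outgroup_species, outg[0], focal_species, focal[0], "1-1"))
    elif call.category in ("AT", "RT") and len(focal) >= 2:
        pairs.append((focal_species, focal[0], focal_species, focal[1], "T"))
        if outg:
            pairs.append((outgroup_species, outg[0], focal_species, focal[0], "1-2"))
    elif focal and outg:
        pairs.append((outgroup_species, outg[0], focal_species, focal[0], "1-1"))
    return pairs
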