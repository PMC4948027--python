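"""Gene models on scaffolds: intron phases, microsynteny, duplication typing.

Implements the duplicated-block rule used in plant gene-family surveys:
a duplicated block is a region where three or more conserved homologs
lie within a 15-gene window up- and down-stream between two scaffolds.
"Within 15 genes" is read as a rank distance of at most 15 between
anchors on *both* scaffolds; anchors chainable under that bound are
grouped (connected components of the within-window relation), and groups
with >= 3 anchors are reported as blocks. Paralog pairs are then typed
tandem (same scaffold, few intervening genes), WGD (supported by an
inter-scaffold block), or dispersed.

Coordinates follow GFF3: 1-based, inclusive. Gene rank on a scaffold is
the 0-based ordinal by start coordinate (ties broken by id),
strand-agnostic.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene in transcript (5'->3') order.

    ``exons`` are genomic (start, end) 1-based inclusive spans ordered in
    transcript order; ``cds_lengths`` gives the coding length contributed
    by each exon (0 for pure-UTR exons).
    """

    id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_lengths: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        if len(self.exons) != len(self.cds_lengths) or not self.exons:
            raise ValidationError("need one CDS length per exon, >= 1 exon")
        for (s, e), c in zip(self.exons, self.cds_lengths):
            if s > e or c < 0 or c > e - s + 1:
                raise ValidationError(f"bad exon ({s},{e}) cds {c}")


def intron_phases(model: GeneModel) -> list[Optional[int]]:
    """Phase of each intron: cumulative upstream CDS length mod 3.

    Introns lying entirely in UTR (no coding sequence upstream, or the
    full CDS already upstream and none downstream of the donor exon) are
    flagged with ``None`` rather than a phase.
    """
    total = sum(model.cds_lengths)
    if total % 3:
        raise ValidationError("total CDS length must be divisible by 3")
    phases: list[Optional[int]] = []
    cum = 0
    for i in range(len(model.exons) - 1):
        cum += model.cds_lengths[i]
        if cum == 0 or cum == total:
            phases.append(None)  # UTR-only intron
        else:
            phases.append(cum % 3)
    return phases


@dataclass(frozen=True)
class GeneLocus:
    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    rank: int = -1  # filled by rank_loci

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValidationError(f"bad locus span for {self.id}")


def rank_loci(loci: Iterable[GeneLocus]) -> dict[str, GeneLocus]:
    """Assign per-scaffold ordinal ranks (0-based, by start, ties by id)."""
    by_scaffold: dict[str, list[GeneLocus]] = defaultdict(list)
    seen = set()
    for loc in loci:
        if loc.id in seen:
            raise ValidationError(f"duplicate gene id {loc.id}")
        seen.add(loc.id)
        by_scaffold[loc.scaffold].append(loc)
    ranked = {}
    for scaffold, genes in by_scaffold.items():
        genes.sort(key=lambda g: (g.start, g.id))
        for rank, g in enumerate(genes):
            ranked[g.id] = GeneLocus(g.id, g.scaffold, g.start, g.end, g.strand, rank)
    return ranked


@dataclass(frozen=True)
class SyntenyBlock:
    """An inter-scaffold chain of >= 3 homolog anchors."""

    scaffold_a: str
    scaffold_b: str
    anchors: tuple[tuple[str, str], ...]  # (gene_a, gene_b), ordered by rank on a


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    dup_type: str  # tandem | WGD | dispersed
    evidence: str


def find_duplicated_blocks(
    loci: dict[str, GeneLocus],
    homologs: Sequence[tuple[str, str]],
    window: int = 15,
    min_anchors: int = 3,
) -> list[SyntenyBlock]:
    """Detect duplicated blocks between scaffolds.

    Homolog pairs whose genes sit on two different scaffolds become
    anchors; two anchors of the same scaffold pair are chainable when
    their rank distance is <= ``window`` on both scaffolds. Blocks are
    the connected components of the chainable relation with at least
    ``min_anchors`` anchors, so every anchor belongs to at most one
    block. Output is ordered by (scaffold_a, scaffold_b, first rank).
    """
    anchors_by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = (
        defaultdict(list)
    )
    for ga, gb in homologs:
        if ga not in loci or gb not in loci:
            missing = ga if ga not in loci else gb
            raise ValidationError(f"homolog gene {missing!r} not in loci")
        la, lb = loci[ga], loci[gb]
        if la.scaffold == lb.scaffold:
            continue  # intra-scaffold pairs cannot anchor a duplicated block
        if (la.scaffold, la.id) > (lb.scaffold, lb.id):
            la, lb = lb, la
        anchors_by_pair[(la.scaffold, lb.scaffold)].append(
            (la.rank, lb.rank, la.id, lb.id)
        )

    blocks = []
    for (sa, sb), anchors in sorted(anchors_by_pair.items()):
        anchors = sorted(set(anchors))
        n = len(anchors)
        # connected components under the "within window on both scaffolds" relation
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    abs(anchors[i][0] - anchors[j][0]) <= window
                    and abs(anchors[i][1] - anchors[j][1]) <= window
                ):
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = defaultdict(list)
        for i in range(n):
            comps[find(i)].append(i)
        for comp in comps.values():
            if len(comp) < min_anchors:
                continue
            chain = sorted(anchors[i] for i in comp)
            blocks.append(
                SyntenyBlock(sa, sb, tuple((ga, gb) for _, _, ga, gb in chain))
            )
    blocks.sort(
        key=lambda b: (b.scaffold_a, b.scaffold_b, b.anchors[0][0], b.anchors[0][1])
    )
    return blocks


def classify_duplication(
    pair: tuple[str, str],
    blocks: Sequence[SyntenyBlock],
    loci: dict[str, GeneLocus],
    tandem_max_intervening: int = 5,
    window: int = 15,
) -> DuplicationCall:
    """Type one paralog pair as tandem, WGD, or dispersed.

    Tandem: same scaffold with at most ``tandem_max_intervening`` genes
    between the two ranks. WGD: the pair anchors an inter-scaffold block,
    or both genes lie within ``window`` ranks of some anchor of a block
    joining their two scaffolds. Otherwise dispersed.
    """
    ga, gb = pair
    for g in pair:
        if g not in loci:
            raise ValidationError(f"gene {g!r} not in loci")
    la, lb = loci[ga], loci[gb]
    if la.scaffold == lb.scaffold:
        intervening = abs(la.rank - lb.rank) - 1
        if intervening <= tandem_max_intervening:
            return DuplicationCall(
                ga, gb, "tandem", f"same scaffold, {intervening} intervening genes"
            )
    else:
        key = tuple(sorted([la.scaffold, lb.scaffold]))
        if (la.scaffold, la.id) > (lb.scaffold, lb.id):
            la, lb = lb, la
        for bi, block in enumerate(blocks):
            if (block.scaffold_a, block.scaffold_b) != key:
                continue
            if (la.id, lb.id) in block.anchors:
                return DuplicationCall(ga, gb, "WGD", f"anchor of block {bi}")
            ranks_a = [loci[x].rank for x, _ in block.anchors]
            ranks_b = [loci[y].rank for _, y in block.anchors]
            if any(abs(la.rank - r) <= window for r in ranks_a) and any(
                abs(lb.rank - r) <= window for r in ranks_b
            ):
                return DuplicationCall(ga, gb, "WGD", f"flanked by block {bi}")
    return DuplicationCall(ga, gb, "dispersed", "no tandem or block support")
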