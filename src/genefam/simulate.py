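"""Synthetic-data generators with machine-readable ground truth.

Every analysis stage in this package can be exercised without external
downloads: codon-aligned paralog pairs evolved to a target Ks and omega
(Ka/Ks), scaffold layouts with planted duplicated blocks and tandem
arrays, 2-kb promoters with planted cis-elements on a match-free
background, replicate qPCR Ct tables with planted fold changes, and
proteins with planted DBD/HR-A/B geometries per Hsf class.

All generators draw every random number from one
``numpy.random.default_rng(seed)``, so identical parameters and seed
reproduce identical outputs. Each returns its ground truth alongside
the data.

Codon-pair simulation is substitution-count-targeted rather than
continuous-time: the number of synonymous (nonsynonymous) events is
Poisson with mean Ks*S (omega*Ks*N), and each event is placed uniformly
over the currently available one-step changes of its class, so repeated
hits at one site occur at the rate the Jukes-Cantor correction assumes.
This keeps the realized event and difference counts exactly recoverable
and makes the NG86 estimator approximately unbiased at the target, at
the cost of not modelling per-branch rate variation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .molevol import (
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignmentPair,
    kaks_ng86,
    ng86_sites,
)
from .genomevol import GeneLocus, rank_loci
from .promoters import (
    PROMOTER_LENGTH,
    CisElementCatalog,
    IUPAC,
    PromoterSequence,
    scan_elements,
)
from .seqprops import VALID_RESIDUES, ProteinRecord
from .domains import ClassThresholds

# ---------------------------------------------------------------------------
# codon pairs


@lru_cache(maxsize=None)
def _one_step_changes(codon: str) -> tuple[tuple, tuple]:
    """(synonymous, nonsynonymous) one-step changes of a sense codon.

    Each change is (position, new_base, new_codon); changes creating a
    stop codon are excluded from both classes.
    """
    from .molevol import _translate

    syn, non = [], []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if _translate(alt) == _translate(codon):
                syn.append((pos, base, alt))
            else:
                non.append((pos, base, alt))
    return tuple(syn), tuple(non)


@dataclass(frozen=True)
class CodonPairTruth:
    omega: float
    ks_target: float
    n_codons: int
    n_syn_events: int
    n_nonsyn_events: int
    realized_Sd: float
    realized_Nd: float


def _inverse_jc(k: float) -> float:
    """Proportion p with -(3/4)ln(1 - 4p/3) = k."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    ks_target: float,
    seed: int,
    ids: tuple[str, str] = ("sim_a", "sim_b"),
) -> tuple[CodonAlignmentPair, CodonPairTruth]:
    """Evolve one codon-aligned pair to a target Ks at a target omega."""
    if omega <= 0 or ks_target < 0 or n_codons < 1:
        raise ValidationError("require omega > 0, ks_target >= 0, n_codons >= 1")
    # guard on the *expected observed* difference proportions
    if _inverse_jc(ks_target) > 0.7 or _inverse_jc(omega * ks_target) > 0.7:
        raise ValidationError(
            "target divergence too close to saturation for reliable simulation"
        )
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    S = sum(ng86_sites(c)[0] for c in ancestor)
    N = 3.0 * n_codons - S

    # events target the substitution counts Ks*S and Ka*N; repeated hits at
    # one site then yield the smaller difference proportion that the
    # Jukes-Cantor correction re-expands at estimation time
    n_syn = int(rng.poisson(ks_target * S))
    n_non = int(rng.poisson(omega * ks_target * N))
    events = ["S"] * n_syn + ["N"] * n_non
    rng.shuffle(events)

    derived = list(ancestor)
    for kind in events:
        idx = 0 if kind == "S" else 1
        counts = np.fromiter(
            (len(_one_step_changes(c)[idx]) for c in derived), dtype=np.int64
        )
        total = int(counts.sum())
        if total == 0:
            continue  # no change of this class available anywhere (degenerate)
        flat = int(rng.integers(0, total))
        codon_i = int(np.searchsorted(np.cumsum(counts), flat, side="right"))
        offset = flat - int(np.cumsum(counts)[codon_i - 1]) if codon_i else flat
        _, _, new_codon = _one_step_changes(derived[codon_i])[idx][offset]
        derived[codon_i] = new_codon

    pair = CodonAlignmentPair(ids[0], ids[1], "".join(ancestor), "".join(derived))
    res = kaks_ng86(pair)
    truth = CodonPairTruth(
        omega, ks_target, n_codons, n_syn, n_non, res.Sd, res.Nd
    )
    return pair, truth


# ---------------------------------------------------------------------------
# genome layouts


@dataclass(frozen=True)
class LayoutTruth:
    blocks: tuple[tuple[tuple[str, str], ...], ...]  # planted anchor chains
    tandem_pairs: tuple[tuple[str, str], ...]
    decoy_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class LayoutSpec:
    """Planted-layout parameters.

    n_blocks inter-scaffold duplicated blocks (each on its own scaffold
    pair, anchors_per_block anchors with rank gaps <= window), n_tandem
    adjacent same-scaffold pairs, and n_decoys two-anchor chains that a
    correct detector must NOT report.
    """

    n_scaffolds: int = 8
    genes_per_scaffold: int = 60
    n_blocks: int = 2
    anchors_per_block: int = 3
    n_tandem: int = 1
    n_decoys: int = 1
    window: int = 15
    max_gap: int = 5


def simulate_genome_layout(
    spec: LayoutSpec, seed: int
) -> tuple[dict[str, GeneLocus], list[tuple[str, str]], LayoutTruth]:
    """Scaffold layout with planted blocks, tandem pairs, and decoys.

    Blocks and decoys are placed on disjoint scaffold pairs, and decoy
    anchors are separated by more than ``window`` ranks from each other,
    so planted truth is exactly what the 3-in-window rule recovers.
    """
    need = max(2 * spec.n_blocks + 2 * spec.n_decoys, 1)
    if spec.n_scaffolds < need:
        raise ValidationError(
            f"need >= {need} scaffolds for disjoint block/decoy placement"
        )
    span = spec.anchors_per_block * spec.max_gap + 2 * spec.window
    if spec.genes_per_scaffold < span:
        raise ValidationError("genes_per_scaffold too small for planted geometry")
    rng = np.random.default_rng(seed)

    scaffolds = [f"scaffold{i + 1}" for i in range(spec.n_scaffolds)]
    loci_raw = []
    for s in scaffolds:
        for k in range(spec.genes_per_scaffold):
            start = 100 + k * 2000
            loci_raw.append(
                GeneLocus(
                    f"{s}_g{k:03d}", s, start, start + 999,
                    "+" if k % 2 == 0 else "-",
                )
            )
    loci = rank_loci(loci_raw)
    gene_at = lambda s, r: f"{s}_g{r:03d}"  # rank == index by construction

    homologs: list[tuple[str, str]] = []
    blocks = []
    pair_idx = 0
    for _ in range(spec.n_blocks):
        sa, sb = scaffolds[pair_idx], scaffolds[pair_idx + 1]
        pair_idx += 2
        ra = int(rng.integers(0, spec.window))
        rb = int(rng.integers(0, spec.window))
        chain = []
        for _ in range(spec.anchors_per_block):
            chain.append((gene_at(sa, ra), gene_at(sb, rb)))
            ra += int(rng.integers(1, spec.max_gap + 1))
            rb += int(rng.integers(1, spec.max_gap + 1))
        blocks.append(tuple(chain))
        homologs.extend(chain)

    decoys = []
    for _ in range(spec.n_decoys):
        sa, sb = scaffolds[pair_idx], scaffolds[pair_idx + 1]
        pair_idx += 2
        ra, rb = int(rng.integers(0, 3)), int(rng.integers(0, 3))
        first = (gene_at(sa, ra), gene_at(sb, rb))
        second = (
            gene_at(sa, ra + int(rng.integers(1, spec.window + 1))),
            gene_at(sb, rb + int(rng.integers(1, spec.window + 1))),
        )
        decoys.extend([first, second])
        homologs.extend([first, second])

    tandems = []
    for t in range(spec.n_tandem):
        s = scaffolds[t % spec.n_scaffolds]
        r = spec.genes_per_scaffold - 2 - 3 * (t // spec.n_scaffolds)
        pair = (gene_at(s, r), gene_at(s, r + 1))
        tandems.append(pair)
        homologs.append(pair)

    order = rng.permutation(len(homologs))
    homologs = [homologs[i] for i in order]
    return loci, homologs, LayoutTruth(tuple(blocks), tuple(tandems), tuple(decoys))


# ---------------------------------------------------------------------------
# promoters


@dataclass(frozen=True)
class PlantedElement:
    gene_id: str
    element_name: str
    start: int
    matched_text: str


def _realize_iupac(pattern: str, rng) -> str:
    out = []
    for code in pattern:
        choices = sorted(IUPAC[code] - {"N"})
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def _random_background(length: int, gc: float, rng) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=p)])


def _match_free_background(
    length: int, gc: float, catalog: CisElementCatalog, rng, max_rounds: int = 300
) -> str:
    """Background sequence with zero catalog matches, by local repair."""
    seq = _random_background(length, gc, rng)
    for _ in range(max_rounds):
        hits = scan_elements(PromoterSequence("bg", seq), catalog)
        if not hits:
            return seq
        chars = list(seq)
        for h in hits:
            for i in range(h.start - 1, h.start - 1 + len(h.matched_text)):
                chars[i] = "ACGT"[int(rng.integers(0, 4))]
        seq = "".join(chars)
    raise ValidationError("could not generate a match-free background")


def simulate_promoters(
    planted: Mapping[str, Sequence[int]],
    n: int,
    length: int = PROMOTER_LENGTH,
    gc: float = 0.40,
    seed: int = 0,
    catalog: Optional[CisElementCatalog] = None,
    max_attempts: int = 60,
) -> tuple[list[PromoterSequence], list[PlantedElement]]:
    """Promoters with exactly the planted element counts.

    ``planted`` maps element name -> per-gene planted counts (padded with
    zeros up to ``n`` genes). Backgrounds are repaired until free of any
    chance catalog match, elements are inserted at non-overlapping
    positions, and the final promoter is re-scanned: the generator
    retries until the scan recovers exactly the planted counts for every
    element, so truth positions equal scan positions.
    """
    catalog = catalog or CisElementCatalog.default()
    patterns = {e.name: e.iupac for e in catalog.entries}
    for name, counts in planted.items():
        if name not in patterns:
            raise ValidationError(f"planted element {name!r} not in catalog")
        if len(counts) > n:
            raise ValidationError("more per-gene counts than promoters")
    rng = np.random.default_rng(seed)

    promoters, truth = [], []
    for g in range(n):
        gene = f"gene{g + 1:03d}"
        want = {
            name: counts[g]
            for name, counts in planted.items()
            if g < len(counts) and counts[g] > 0
        }
        for _ in range(max_attempts):
            seq = _match_free_background(length, gc, catalog, rng)
            chars = list(seq)
            occupied: list[tuple[int, int]] = []
            placements = []
            ok = True
            for name, k in sorted(want.items()):
                pat = patterns[name]
                for _ in range(k):
                    for _ in range(200):
                        pos = int(rng.integers(0, length - len(pat) + 1))
                        if all(
                            pos + len(pat) <= s or pos >= e for s, e in occupied
                        ):
                            break
                    else:
                        ok = False
                        break
                    text = _realize_iupac(pat, rng)
                    chars[pos : pos + len(pat)] = text
                    occupied.append((pos, pos + len(pat)))
                    placements.append(PlantedElement(gene, name, pos + 1, text))
                if not ok:
                    break
            if not ok:
                continue
            candidate = PromoterSequence(gene, "".join(chars))
            hits = scan_elements(candidate, catalog)
            got = {}
            for h in hits:
                got[h.element_name] = got.get(h.element_name, 0) + 1
            if got == want:
                promoters.append(candidate)
                truth.extend(placements)
                break
        else:
            raise ValidationError(f"could not plant elements into {gene}")
    return promoters, truth


# ---------------------------------------------------------------------------
# qPCR tables


@dataclass(frozen=True)
class QpcrSimSpec:
    """Planted qPCR cohort.

    ``effects`` maps gene_id -> condition -> timepoint -> linear fold
    change vs the 0-h control; unlisted combinations are null (fold 1).
    ``genes``/``conditions``/``timepoints`` fix the full design grid.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    effects: Mapping[str, Mapping[str, Mapping[float, float]]]
    timepoints: tuple[float, ...] = (0.0, 1.0, 6.0, 12.0)
    n_replicates: int = 3
    sigma_ct: float = 0.2
    baseline_ct: float = 24.0
    reference_ct: float = 18.0


def simulate_qpcr(spec: QpcrSimSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table and truth labels for a planted induction cohort.

    Target Ct = baseline - log2(fold) + Normal(0, sigma_ct) per
    replicate; the reference-gene Ct is constant. Truth rows carry the
    planted fold and the planted induction label (fold >= 2, i.e. log2
    fold change >= 1).
    """
    if spec.n_replicates < 2:
        raise ValidationError("need >= 2 replicates")
    if 0.0 not in spec.timepoints:
        raise ValidationError("the design grid must include the 0-h control")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for gene in spec.genes:
        for cond in spec.conditions:
            for tp in spec.timepoints:
                fold = float(
                    spec.effects.get(gene, {}).get(cond, {}).get(tp, 1.0)
                )
                if fold <= 0:
                    raise ValidationError("fold changes must be positive")
                for rep in range(1, spec.n_replicates + 1):
                    noise = float(rng.normal(0.0, spec.sigma_ct)) if spec.sigma_ct else 0.0
                    rows.append(
                        {
                            "gene_id": gene,
                            "condition": cond,
                            "timepoint_h": tp,
                            "replicate": rep,
                            "ct_target": spec.baseline_ct - math.log2(fold) + noise,
                            "ct_reference": spec.reference_ct,
                        }
                    )
                if tp != 0.0:
                    truth_rows.append(
                        {
                            "gene_id": gene,
                            "condition": cond,
                            "timepoint_h": tp,
                            "fold": fold,
                            "induced_truth": fold >= 2.0,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# proteins with planted domain geometry


@dataclass(frozen=True)
class ProteinTruth:
    gene_id: str
    hsf_class: str
    dbd: tuple[int, int]
    hr: tuple[int, int]


def simulate_proteins(
    n_per_class: int,
    seed: int,
    thresholds: ClassThresholds = ClassThresholds(),
    margin: int = 5,
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """Random proteins with planted DBD / HR-A/B geometry per Hsf class.

    Geometries are kept ``margin`` residues away from the class
    thresholds so every planted protein is a non-boundary case.
    """
    rng = np.random.default_rng(seed)
    residues = sorted(VALID_RESIDUES)
    records, truths = [], []
    for cls in "ABC":
        for i in range(n_per_class):
            dbd_start = int(rng.integers(5, 40))
            dbd_len = int(rng.integers(90, 100))
            dbd_end = dbd_start + dbd_len - 1
            if cls == "A":
                span = thresholds.a_insert_min + margin + int(rng.integers(0, 15))
                linker = int(rng.integers(10, thresholds.b_linker_min - margin))
            elif cls == "B":
                span = int(rng.integers(20, thresholds.a_insert_min - margin))
                linker = thresholds.b_linker_min + margin + int(rng.integers(1, 30))
            else:
                span = int(rng.integers(20, thresholds.a_insert_min - margin))
                linker = int(rng.integers(10, thresholds.b_linker_min - margin))
            hr_start = dbd_end + linker + 1
            hr_end = hr_start + span - 1
            total = hr_end + int(rng.integers(30, 120))
            seq = "".join(
                residues[j] for j in rng.integers(0, len(residues), total)
            )
            gid = f"sim{cls}{i + 1:02d}"
            records.append(ProteinRecord(gid, seq, class_label=cls))
            truths.append(ProteinTruth(gid, cls, (dbd_start, dbd_end), (hr_start, hr_end)))
    return records, truths
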