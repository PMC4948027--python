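"""Independent brute-force oracles used by the test suite.

Deliberately naive re-derivations (full enumeration, no caching or
shortcuts) kept separate from the package implementation so agreement is
a genuine dual-route check.
"""
from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Per-codon (s, n) by explicit enumeration of all nine neighbours."""
    s = 0.0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt not in STOPS and translate(alt) == translate(codon):
            s += 1.0
    return s / 3.0, 3.0 - s / 3.0


def oracle_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by full minimal-path enumeration."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_positions):
        cur, sd, nd, through_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                through_stop = True
            if (
                cur not in STOPS
                and nxt not in STOPS
                and translate(cur) == translate(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    usable = [(s, n) for s, n, blocked in results if not blocked]
    if not usable:
        usable = [(s, n) for s, n, _ in results]
    return (
        sum(s for s, _ in usable) / len(usable),
        sum(n for _, n in usable) / len(usable),
    )


def oracle_ng86(seq_a: str, seq_b: str):
    """Whole-pair NG86 with Jukes-Cantor correction, from scratch.

    Returns (S, N, Sd, Nd, Ks, Ka) or raises ValueError on saturation.
    """
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = oracle_pair_diffs(ca, cb)
        Sd += ds
        Nd += dn
    pS, pN = Sd / S, Nd / N
    if pS >= 0.75 or pN >= 0.75:
        raise ValueError("saturated")
    ks = 0.0 if pS == 0 else -0.75 * math.log(1 - 4 * pS / 3)
    ka = 0.0 if pN == 0 else -0.75 * math.log(1 - 4 * pN / 3)
    return S, N, Sd, Nd, ks, ka


def oracle_blocks(anchors, window):
    """Connected grouping of (rank_a, rank_b) anchors by naive repeated
    scanning; returns frozensets of anchor indices with >= 3 members.

    Also validates, by exhaustive simple-path enumeration, that every
    reported group really contains a 3-anchor chain.
    """
    n = len(anchors)
    within = lambda i, j: (
        abs(anchors[i][0] - anchors[j][0]) <= window
        and abs(anchors[i][1] - anchors[j][1]) <= window
    )
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if i != j and within(i, j) and labels[j] < labels[i]:
                    labels[i] = labels[j]
                    changed = True
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    out = []
    for members in groups.values():
        if len(members) < 3:
            continue
        # exhaustive chain check: some simple path of length >= 3 exists
        found = False
        for a, b, c in itertools.permutations(members, 3):
            if within(a, b) and within(b, c):
                found = True
                break
        assert found, "component >= 3 without a 3-chain (should be impossible)"
        out.append(frozenset(members))
    return out


def random_mutated_pair(rng, n_codons: int, n_mutations: int):
    """Ancestor plus a copy with point mutations that never create stops."""
    sense = [
        a + b + c
        for a, b, c in itertools.product(BASES, repeat=3)
        if a + b + c not in STOPS
    ]
    anc = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
    der = list(anc)
    applied = 0
    while applied < n_mutations:
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        base = BASES[int(rng.integers(0, 4))]
        cand = der[ci][:pos] + base + der[ci][pos + 1 :]
        if cand != der[ci] and cand not in STOPS:
            der[ci] = cand
            applied += 1
    return "".join(anc), "".join(der)
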