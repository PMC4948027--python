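"""Hsf functional-motif scanning and class assignment.

Heat shock transcription factors carry, besides the DNA-binding domain
(DBD) and the HR-A/B oligomerization region, several short functional
motifs: basic nuclear localization signals (NLS), leucine-rich nuclear
export signals (NES), aromatic/acidic AHA activator motifs (class A),
and the LFGV-type repressor tetrapeptide (RD, class B).

DBD and HR-A/B coordinates are *inputs* here (profile-HMM and coiled-coil
detection are upstream tools); this module scans for the short motifs
with transparent window rules and assigns the A/B/C class from the
linker length between DBD and HR-A/B and the HR-A/B extent. The window
rules are deliberately simple, fully configurable plumbing: class A Hsfs
are recognized by the amino-acid insertion that extends their HR-A/B
region, class B by the long DBD-to-HR-A/B linker, class C by neither.

All coordinates are 1-based inclusive residue positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .seqprops import validate_sequence

RD_PATTERNS_DEFAULT = ("LFGV", "IFGV")


@dataclass(frozen=True)
class DomainSpan:
    """One motif/domain occurrence: kind, 1-based inclusive span, text."""

    kind: str
    start: int
    end: int
    matched_text: str

    def validate_against(self, seq: str) -> "DomainSpan":
        if not (1 <= self.start <= self.end <= len(seq)):
            raise ValidationError(
                f"{self.kind} span {self.start}-{self.end} outside 1..{len(seq)}"
            )
        if seq[self.start - 1 : self.end] != self.matched_text:
            raise ValidationError(
                f"{self.kind} matched_text does not equal the sequence slice"
            )
        return self


@dataclass(frozen=True)
class HsfClassification:
    """A/B/C class call with the geometry it was derived from."""

    hsf_class: str
    linker_len: int
    hr_span_len: int
    rationale: str


@dataclass(frozen=True)
class ClassThresholds:
    """Geometry thresholds for the A/B/C rule (configuration, not dogma).

    a_insert_min: minimum HR-A/B extent (residues) for class A — class A
    proteins carry an insertion (~21 aa) inside HR-A/B that stretches the
    region; b_linker_min: linker length strictly above which a non-A
    protein is called class B.
    """

    a_insert_min: int = 40
    b_linker_min: int = 44


def _merge_windows(hits: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) windows, 1-based inclusive."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(hits):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def find_rd_motif(
    seq: str, patterns: Sequence[str] = RD_PATTERNS_DEFAULT
) -> list[DomainSpan]:
    """Non-overlapping occurrences of the repressor tetrapeptide, leftmost first."""
    validate_sequence(seq)
    hits = []
    i = 0
    while i <= len(seq) - 4:
        window = seq[i : i + 4]
        if window in patterns:
            hits.append(DomainSpan("RD", i + 1, i + 4, window))
            i += 4
        else:
            i += 1
    return hits


def find_nls(seq: str, min_basic: int = 4, window: int = 8) -> list[DomainSpan]:
    """Basic-cluster NLS scan.

    Reports maximal merged spans of length-``window`` windows containing
    at least ``min_basic`` Lys/Arg residues.
    """
    validate_sequence(seq)
    if not (window >= min_basic >= 2):
        raise ValidationError("require window >= min_basic >= 2")
    raw = []
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if w.count("K") + w.count("R") >= min_basic:
            raw.append((i + 1, i + window))
    return [
        DomainSpan("NLS", s, e, seq[s - 1 : e]) for s, e in _merge_windows(raw)
    ]


def find_aha_motifs(
    seq: str, window: int = 10, min_acidic: int = 2
) -> list[DomainSpan]:
    """AHA (aromatic-hydrophobic-acidic) activator-motif scan.

    A length-``window`` window is a hit when its central residue (position
    window//2, 0-based within the window) is aromatic (W/F) and the window
    contains at least ``min_acidic`` acidic residues (D/E). Overlapping
    hit windows are merged into maximal spans.
    """
    validate_sequence(seq)
    center = window // 2
    raw = []
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if w[center] in "WF" and w.count("D") + w.count("E") >= min_acidic:
            raw.append((i + 1, i + window))
    return [
        DomainSpan("AHA", s, e, seq[s - 1 : e]) for s, e in _merge_windows(raw)
    ]


def find_nes(seq: str, patterns: Sequence[str] = ()) -> list[DomainSpan]:
    """NES scan against a user-supplied exact-pattern list (no default rule)."""
    validate_sequence(seq)
    hits = []
    for pat in patterns:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            hits.append(DomainSpan("NES", i + 1, i + len(pat), pat))
            start = i + 1
    return sorted(hits, key=lambda h: (h.start, h.end))


def classify_hsf(
    dbd: DomainSpan,
    hr: DomainSpan,
    thresholds: ClassThresholds = ClassThresholds(),
) -> HsfClassification:
    """Assign Hsf class A/B/C from DBD and HR-A/B geometry.

    Class A iff the HR-A/B extent is at least ``a_insert_min`` residues
    (the class A insertion stretches it); otherwise class B iff the
    DBD-to-HR-A/B linker exceeds ``b_linker_min``; otherwise class C.
    """
    if dbd.end >= hr.start:
        raise ValidationError("DBD must end before HR-A/B starts")
    linker = hr.start - dbd.end - 1
    span = hr.end - hr.start + 1
    if span >= thresholds.a_insert_min:
        cls = "A"
        why = f"HR-A/B span {span} >= {thresholds.a_insert_min}"
    elif linker > thresholds.b_linker_min:
        cls = "B"
        why = (
            f"HR-A/B span {span} < {thresholds.a_insert_min} and linker "
            f"{linker} > {thresholds.b_linker_min}"
        )
    else:
        cls = "C"
        why = (
            f"HR-A/B span {span} < {thresholds.a_insert_min} and linker "
            f"{linker} <= {thresholds.b_linker_min}"
        )
    return HsfClassification(cls, linker, span, why)


def scan_protein(
    seq: str,
    nes_patterns: Sequence[str] = (),
    nls_min_basic: int = 4,
    nls_window: int = 8,
) -> list[DomainSpan]:
    """All motif scans for one protein, spans validated and sorted."""
    spans = (
        find_nls(seq, nls_min_basic, nls_window)
        + find_aha_motifs(seq)
        + find_rd_motif(seq)
        + find_nes(seq, nes_patterns)
    )
    for sp in spans:
        sp.validate_against(seq)
    return sorted(spans, key=lambda s: (s.start, s.end, s.kind))
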