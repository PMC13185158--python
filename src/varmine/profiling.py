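"""Reference-anchored mutation calling and composition statistics.

Each variant CDS is compared position-by-position to the reference (after
global alignment when lengths differ).  Every mismatching comparable
position becomes a :class:`Mutation`, classified by base change
(transition/transversion), codon effect (silent/missense/nonsense) in the
reference frame, and position-derived region (active domain / envelope /
other).  Per-profile summaries include identity, per-60-nt-line mutation
densities and the alt-base preference spectrum.

Coordinates are 1-based and intervals closed throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import SubstitutionMatrix, needleman_wunsch
from .records import NUCLEOTIDE, SequenceError, SequenceRecord, translate_codon

TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})

SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
AMBIGUOUS = "ambiguous"

ACTIVE_DOMAIN = "active_domain"
ENVELOPE = "envelope"
OTHER = "other"

LINE_LENGTH = 60  # nt per FASTA line; the unit of per-line mutation rates


@dataclass(frozen=True)
class Mutation:
    """One reference-anchored nucleotide difference."""

    pos_nt: int            # 1-based position in the reference CDS
    ref_base: str
    alt_base: str
    change_class: str      # transition | transversion | ambiguous
    codon_index: int       # 1-based codon number
    effect: str            # silent | missense | nonsense | ambiguous
    ref_aa: str
    alt_aa: str
    region: str = OTHER


@dataclass(frozen=True)
class CompositionSummary:
    a: int
    c: int
    g: int
    t: int
    n: int
    gc_percent: float
    at_percent: float

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.n


@dataclass
class MutationProfile:
    """All mutations of one variant against the shared reference."""

    seq_id: str
    reference_id: str
    ref_length: int
    mutations: list[Mutation]
    identity_percent: float
    frame_lost: bool = False
    line_len: int = LINE_LENGTH

    @property
    def total_mutation_percent(self) -> float:
        return 100.0 * len(self.mutations) / self.ref_length

    @property
    def per_line_percent(self) -> np.ndarray:
        return per_line_rates(self, self.line_len)

    @property
    def base_preference(self) -> dict[str, float]:
        """Fraction of mutations whose alt base is A/C/G/T (N-calls excluded)."""
        informative = [m for m in self.mutations if m.alt_base in "ACGT"]
        total = len(informative)
        return {b: (sum(1 for m in informative if m.alt_base == b) / total
                    if total else 0.0)
                for b in "ACGT"}

    def effect_counts(self) -> dict[str, int]:
        counts = {SILENT: 0, MISSENSE: 0, NONSENSE: 0, AMBIGUOUS: 0}
        for m in self.mutations:
            counts[m.effect] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"seq_id": self.seq_id, "pos": m.pos_nt, "ref": m.ref_base,
                 "alt": m.alt_base, "class": m.change_class, "codon": m.codon_index,
                 "effect": m.effect, "ref_aa": m.ref_aa, "alt_aa": m.alt_aa,
                 "region": m.region} for m in self.mutations]
        return pd.DataFrame(rows, columns=["seq_id", "pos", "ref", "alt", "class",
                                           "codon", "effect", "ref_aa", "alt_aa",
                                           "region"])


@dataclass(frozen=True)
class RegionInterval:
    name: str
    start_nt: int
    end_nt: int            # closed interval
    region_class: str      # active_domain | envelope | other


class RegionTable:
    """Interval lookup for region assignment.

    Precedence when intervals overlap: active_domain > envelope > other;
    positions in no interval are "other".
    """

    _PRECEDENCE = {ACTIVE_DOMAIN: 0, ENVELOPE: 1, OTHER: 2}

    def __init__(self, intervals: list[RegionInterval] | None = None):
        self.intervals = list(intervals or [])
        for iv in self.intervals:
            if iv.start_nt < 1 or iv.end_nt < iv.start_nt:
                raise ValueError(f"bad interval {iv}")
            if iv.region_class not in self._PRECEDENCE:
                raise ValueError(f"unknown region class {iv.region_class!r}")

    def region_of(self, pos_nt: int) -> str:
        hits = [iv.region_class for iv in self.intervals
                if iv.start_nt <= pos_nt <= iv.end_nt]
        if not hits:
            return OTHER
        return min(hits, key=self._PRECEDENCE.__getitem__)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        df = pd.read_csv(path, sep="\t")
        intervals = [RegionInterval(r["name"], int(r["start_nt"]), int(r["end_nt"]),
                                    r["class"]) for _, r in df.iterrows()]
        return cls(intervals)

    @classmethod
    def with_envelopes(cls, domains: list[tuple[str, int, int]], flank_nt: int = 30,
                       seq_length: int | None = None) -> "RegionTable":
        """Build active-domain intervals plus +/- ``flank_nt`` envelope flanks."""
        intervals = []
        for name, start, end in domains:
            intervals.append(RegionInterval(name, start, end, ACTIVE_DOMAIN))
            lo = max(1, start - flank_nt)
            hi = end + flank_nt if seq_length is None else min(seq_length, end + flank_nt)
            if lo < start:
                intervals.append(RegionInterval(f"{name}_env5", lo, start - 1, ENVELOPE))
            if hi > end:
                intervals.append(RegionInterval(f"{name}_env3", end + 1, hi, ENVELOPE))
        return cls(intervals)


def composition(record: SequenceRecord) -> CompositionSummary:
    """Base counts and GC/AT percentages (Ns excluded from the denominator)."""
    if record.kind != NUCLEOTIDE:
        raise SequenceError(f"{record.id}: composition requires a nucleotide record")
    counts = {b: record.seq.count(b) for b in "ACGTN"}
    informative = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if informative == 0:
        raise SequenceError(f"{record.id}: no informative (non-N) bases")
    gc = 100.0 * (counts["G"] + counts["C"]) / informative
    return CompositionSummary(a=counts["A"], c=counts["C"], g=counts["G"],
                              t=counts["T"], n=counts["N"],
                              gc_percent=gc, at_percent=100.0 - gc)


def classify_change(ref_base: str, alt_base: str) -> str:
    if "N" in (ref_base, alt_base):
        return AMBIGUOUS
    pair = {ref_base, alt_base}
    return "transition" if pair in TRANSITION_PAIRS else "transversion"


def classify_effect(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """Codon-level effect of a single-base change in the reference frame."""
    if "N" in ref_codon or "N" in alt_codon:
        ref_aa = translate_codon(ref_codon) if "N" not in ref_codon else "X"
        alt_aa = translate_codon(alt_codon) if "N" not in alt_codon else "X"
        if "X" in (ref_aa, alt_aa):
            return AMBIGUOUS, ref_aa, alt_aa
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        return NONSENSE, ref_aa, alt_aa
    if ref_aa == alt_aa:
        return SILENT, ref_aa, alt_aa
    return MISSENSE, ref_aa, alt_aa


def call_mutations(reference: SequenceRecord, query: SequenceRecord,
                   regions: RegionTable | None = None,
                   matrix: SubstitutionMatrix | None = None) -> MutationProfile:
    """Call all reference-anchored mutations of ``query``.

    Same-length inputs are compared position-by-position; unequal lengths
    are first globally aligned and gap columns excluded from the
    comparable positions.  When an internal gap run has a length not
    divisible by 3 the reading frame downstream is lost and every codon
    effect is flagged "ambiguous".
    """
    if reference.kind != NUCLEOTIDE or query.kind != NUCLEOTIDE:
        raise SequenceError("call_mutations requires nucleotide records")
    if not query.seq:
        raise SequenceError("empty query")
    regions = regions or RegionTable()

    if len(reference.seq) == len(query.seq):
        aligned_ref, aligned_qry = reference.seq, query.seq
        comparable = len(aligned_ref)
        matches = sum(a == b for a, b in zip(aligned_ref, aligned_qry))
        identity = 100.0 * matches / comparable
        frame_lost = False
    else:
        aln = needleman_wunsch(reference, query, matrix)
        aligned_ref, aligned_qry = aln.aligned_a, aln.aligned_b
        identity = aln.identity_percent
        frame_lost = _frame_lost(aligned_ref, aligned_qry)

    mutations: list[Mutation] = []
    ref_pos = 0
    for a, b in zip(aligned_ref, aligned_qry):
        if a != "-":
            ref_pos += 1
        if a == "-" or b == "-":
            continue  # gap columns are not comparable positions
        if a == b:
            continue
        codon_index = (ref_pos - 1) // 3 + 1
        codon_start = (codon_index - 1) * 3
        ref_codon = reference.seq[codon_start:codon_start + 3]
        offset = (ref_pos - 1) % 3
        if len(ref_codon) == 3:
            alt_codon = ref_codon[:offset] + b + ref_codon[offset + 1:]
            effect, ref_aa, alt_aa = classify_effect(ref_codon, alt_codon)
        else:  # trailing partial codon
            effect, ref_aa, alt_aa = AMBIGUOUS, "X", "X"
        if frame_lost:
            effect = AMBIGUOUS
        mutations.append(Mutation(
            pos_nt=ref_pos, ref_base=a, alt_base=b,
            change_class=classify_change(a, b),
            codon_index=codon_index, effect=effect,
            ref_aa=ref_aa, alt_aa=alt_aa,
            region=regions.region_of(ref_pos)))
    return MutationProfile(seq_id=query.id, reference_id=reference.id,
                           ref_length=len(reference.seq), mutations=mutations,
                           identity_percent=identity, frame_lost=frame_lost)


def _frame_lost(aligned_ref: str, aligned_qry: str) -> bool:
    """True if any internal gap run has length not divisible by 3."""
    for s in (aligned_ref, aligned_qry):
        run = 0
        for i, ch in enumerate(s):
            if ch == "-":
                run += 1
            else:
                if run and run % 3:
                    return True
                run = 0
        # terminal run ignored: it does not shift the frame of compared columns
    return False


def premature_stops(query: SequenceRecord) -> list[int]:
    """1-based codon indices of in-frame stops strictly before the terminal codon."""
    if query.kind != NUCLEOTIDE:
        raise SequenceError(f"{query.id}: premature_stops requires a nucleotide record")
    if len(query.seq) % 3:
        raise SequenceError(
            f"{query.id}: length {len(query.seq)} not divisible by 3")
    n_codons = len(query.seq) // 3
    stops = []
    for idx in range(n_codons - 1):  # exclude terminal codon
        codon = query.seq[idx * 3:idx * 3 + 3]
        if codon in ("TAA", "TGA", "TAG"):
            stops.append(idx + 1)
    return stops


def per_line_rates(profile: MutationProfile, line_len: int = LINE_LENGTH) -> np.ndarray:
    """Mutation percentage per ``line_len``-nt line of the reference.

    The terminal line uses its true (possibly shorter) length as the
    denominator.
    """
    if line_len <= 0:
        raise ValueError(f"line_len must be positive, got {line_len}")
    n_lines = math.ceil(profile.ref_length / line_len)
    counts = np.zeros(n_lines)
    for m in profile.mutations:
        counts[(m.pos_nt - 1) // line_len] += 1
    lengths = np.full(n_lines, line_len, dtype=float)
    remainder = profile.ref_length % line_len
    if remainder:
        lengths[-1] = remainder
    return 100.0 * counts / lengths


def profiles_to_dataframe(profiles: list[MutationProfile]) -> pd.DataFrame:
    if not profiles:
        return pd.DataFrame(columns=["seq_id", "pos", "ref", "alt", "class",
                                     "codon", "effect", "ref_aa", "alt_aa", "region"])
    return pd.concat([p.to_dataframe() for p in profiles], ignore_index=True)
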