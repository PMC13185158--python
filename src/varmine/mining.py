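"""Mutational hotspot and mismatch-motif mining across a repository.

A *hotspot* is one exact nucleotide change (position + alt base) shared by
at least ``min_share`` sequences (default 4, inclusive).  A *pattern
motif* is a recurring group of >= 2 substitutions with bounded spacing,
canonicalised to (offsets from the first substitution, alt bases); motifs
are "consecutive" when all inter-offset gaps are 1 and "separated"
otherwise.  Motifs are reported when carried by more than four sequences
(default ``min_support`` 5), anywhere in the CDS; a same-site support
counter (sequences sharing the motif at one identical reference position)
is emitted alongside.

The mismatch matrix tabulates per-sequence mutation counts per 60-nt line
for heatmap rendering and sequence categorisation.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .profiling import LINE_LENGTH, MutationProfile


@dataclass(frozen=True)
class Hotspot:
    pos_nt: int
    alt_base: str
    effect: str
    support: int


@dataclass(frozen=True)
class PatternMotif:
    offsets: tuple[int, ...]       # strictly increasing, starts at 0
    alt_bases: tuple[str, ...]     # one per offset
    shape: str                     # consecutive | separated
    gaps: tuple[int, ...]          # inter-offset distances
    support_same_site: int         # max sequences sharing one ref position
    support_any_site: int          # sequences carrying the motif anywhere
    leftmost_pos: int              # smallest reference start observed

    @property
    def length(self) -> int:
        return len(self.offsets)

    @property
    def span(self) -> int:
        return self.offsets[-1] + 1


def _check_shared_reference(profiles: list[MutationProfile]) -> None:
    refs = {p.reference_id for p in profiles}
    if len(refs) > 1:
        raise ValueError(f"profiles span multiple references: {sorted(refs)}")


def find_hotspots(profiles: list[MutationProfile], min_share: int = 4) -> list[Hotspot]:
    """Exact (position, alt base) changes shared by >= ``min_share`` sequences.

    Sorted by support descending, then position ascending.  The effect
    label is the majority effect among the supporting calls (ties broken
    by first appearance).
    """
    if not profiles:
        raise ValueError("find_hotspots requires at least one profile")
    if min_share < 1:
        raise ValueError("min_share must be positive")
    _check_shared_reference(profiles)
    support: Counter[tuple[int, str]] = Counter()
    effects: dict[tuple[int, str], Counter[str]] = defaultdict(Counter)
    for prof in profiles:
        seen: set[tuple[int, str]] = set()
        for m in prof.mutations:
            key = (m.pos_nt, m.alt_base)
            if key in seen:
                continue
            seen.add(key)
            support[key] += 1
            effects[key][m.effect] += 1
    hotspots = [Hotspot(pos, alt, effects[(pos, alt)].most_common(1)[0][0], n)
                for (pos, alt), n in support.items() if n >= min_share]
    hotspots.sort(key=lambda h: (-h.support, h.pos_nt))
    return hotspots


def _group_positions(positions: list[int], max_gap: int, max_span: int) -> list[list[int]]:
    """Greedy left-to-right grouping: extend while the gap to the previous
    position is <= max_gap and the group span stays <= max_span."""
    groups: list[list[int]] = []
    current: list[int] = []
    for pos in positions:
        if not current:
            current = [pos]
        elif pos - current[-1] <= max_gap and pos - current[0] + 1 <= max_span:
            current.append(pos)
        else:
            groups.append(current)
            current = [pos]
    if current:
        groups.append(current)
    return groups


def find_patterns(profiles: list[MutationProfile], min_support: int = 5,
                  max_gap: int = 4, max_span: int = 10) -> list[PatternMotif]:
    """Enumerate recurring substitution motifs across the repository.

    Per sequence, mutated positions are grouped greedily (consecutive gaps
    <= ``max_gap``, span <= ``max_span``); each group of >= 2 positions is
    canonicalised to (offsets, alt bases).  Motifs with
    ``support_any_site >= min_support`` are reported, sorted by support
    descending then leftmost position ascending.
    """
    if not profiles:
        raise ValueError("find_patterns requires at least one profile")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if max_span < 2:
        raise ValueError("max_span must be >= 2")
    _check_shared_reference(profiles)
    # motif key -> {seq_id -> set of start positions}
    occurrences: dict[tuple[tuple[int, ...], tuple[str, ...]],
                      dict[str, set[int]]] = defaultdict(lambda: defaultdict(set))
    for prof in profiles:
        by_pos = {m.pos_nt: m.alt_base for m in prof.mutations if m.alt_base in "ACGT"}
        positions = sorted(by_pos)
        for group in _group_positions(positions, max_gap, max_span):
            if len(group) < 2:
                continue
            start = group[0]
            offsets = tuple(p - start for p in group)
            alts = tuple(by_pos[p] for p in group)
            occurrences[(offsets, alts)][prof.seq_id].add(start)
    motifs: list[PatternMotif] = []
    for (offsets, alts), per_seq in occurrences.items():
        support_any = len(per_seq)
        if support_any < min_support:
            continue
        start_counts: Counter[int] = Counter()
        for starts in per_seq.values():
            for s in starts:
                start_counts[s] += 1
        gaps = tuple(b - a for a, b in zip(offsets, offsets[1:]))
        motifs.append(PatternMotif(
            offsets=offsets, alt_bases=alts,
            shape="consecutive" if all(g == 1 for g in gaps) else "separated",
            gaps=gaps,
            support_same_site=max(start_counts.values()),
            support_any_site=support_any,
            leftmost_pos=min(start_counts)))
    motifs.sort(key=lambda m: (-m.support_any_site, m.leftmost_pos, m.offsets, m.alt_bases))
    return motifs


def mismatch_matrix(profiles: list[MutationProfile],
                    line_len: int = LINE_LENGTH) -> pd.DataFrame:
    """Per-sequence mismatch counts per ``line_len``-nt line.

    Rows are sequence ids, columns 1-based line indices; row sums equal
    each profile's total mutation count.
    """
    if line_len <= 0:
        raise ValueError("line_len must be positive")
    if not profiles:
        return pd.DataFrame(dtype=int)
    _check_shared_reference(profiles)
    ref_length = profiles[0].ref_length
    n_lines = math.ceil(ref_length / line_len)
    data = {}
    for prof in profiles:
        row = [0] * n_lines
        for m in prof.mutations:
            row[(m.pos_nt - 1) // line_len] += 1
        data[prof.seq_id] = row
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=list(range(1, n_lines + 1)))


def hotspots_to_dataframe(hotspots: list[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame([{"pos": h.pos_nt, "alt": h.alt_base, "effect": h.effect,
                          "support": h.support} for h in hotspots],
                        columns=["pos", "alt", "effect", "support"])


def patterns_to_dataframe(motifs: list[PatternMotif]) -> pd.DataFrame:
    return pd.DataFrame([{"offsets": ",".join(map(str, m.offsets)),
                          "alts": "".join(m.alt_bases), "shape": m.shape,
                          "support_same": m.support_same_site,
                          "support_any": m.support_any_site,
                          "leftmost_pos": m.leftmost_pos} for m in motifs],
                        columns=["offsets", "alts", "shape", "support_same",
                                 "support_any", "leftmost_pos"])
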