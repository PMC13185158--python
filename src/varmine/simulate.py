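"""Synthetic CDS reference and variant-repository generator with ground truth.

Emulates the statistical structure the mining pipeline assumes for a
high-GC bacterial glycosyltransferase gene: a 1,281-nt reference CDS
(426 codons) at ~67.9% GC; a repository of independent variants at
95-99.2% identity; G/C-biased substitutions (alt-base spectrum defaulting
to 70% G/C with A rarest at 5%); a controllable silent/missense split;
and optional planted substitution motifs with 1-4-nt gaps for
pattern-mining round trips.  Every emitted mutation is recorded in a
truth table so the profiler and miner can be verified exactly.

Mutations are placed one per codon (motif templates may span codons),
never in the start or terminal-stop codon, and never create internal
stops unless stop injection is requested explicitly.  Identity targeting
is satisfied by mutation count (identity = 1 - n_mut/length), not by
rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiling import classify_effect
from .records import NUCLEOTIDE, Repository, SequenceRecord, translate_codon

_STOPS = ("TAA", "TGA", "TAG")
_BASES = "ACGT"


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic repository.

    Defaults reproduce the study conditions of the worked rhlB case:
    1,281 nt (426 aa + stop), 67.9% GC, 20 variants at 95-99.2% identity,
    ~75% silent mutations, alt bases drawn 5% A / 35% C / 35% G / 25% T.
    """

    length_nt: int = 1281
    gc_target: float = 0.679
    n_variants: int = 20
    identity_range: tuple[float, float] = (0.95, 0.992)
    n_mutations: int | None = None          # overrides identity_range when set
    silent_fraction: float = 0.75
    base_bias: dict[str, float] = field(
        default_factory=lambda: {"A": 0.05, "C": 0.35, "G": 0.35, "T": 0.25})
    motif_templates: list[tuple[tuple[int, ...], tuple[str, ...]]] = field(
        default_factory=list)
    motif_support: int = 5                  # variants carrying each template
    inject_stops: int = 0                   # variants given a premature stop
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_nt % 3:
            raise ValueError("length_nt must be a multiple of 3")
        if self.length_nt < 9:
            raise ValueError("length_nt must cover at least 3 codons")
        lo, hi = self.identity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("identity_range must satisfy 0 < lo <= hi <= 1")
        if not (0.0 <= self.silent_fraction <= 1.0):
            raise ValueError("silent_fraction must be in [0, 1]")
        total = sum(self.base_bias.get(b, 0.0) for b in _BASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("base_bias must sum to 1 over A/C/G/T")
        for offsets, alts in self.motif_templates:
            if len(offsets) != len(alts) or len(offsets) < 2:
                raise ValueError("motif template needs >= 2 (offset, alt) pairs")
            if offsets[0] != 0 or any(b <= a for a, b in zip(offsets, offsets[1:])):
                raise ValueError("motif offsets must start at 0 and increase")


@dataclass(frozen=True)
class TruthEntry:
    pos: int          # 1-based nt position in the reference
    ref: str
    alt: str
    effect: str       # silent | missense | nonsense (vs the single-base ref codon edit)
    planted_motif: int | None = None   # index of the template that placed it


@dataclass
class TruthTable:
    """Ground-truth mutation table keyed by variant id."""

    entries: dict[str, list[TruthEntry]] = field(default_factory=dict)
    motif_placements: list[dict] = field(default_factory=list)
    # each: {"template": int, "offsets": ..., "alts": ..., "start": int,
    #        "variants": [ids]}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"seq_id": vid, "pos": e.pos, "ref": e.ref, "alt": e.alt,
                 "effect": e.effect,
                 "planted_motif": "" if e.planted_motif is None else e.planted_motif}
                for vid, ents in self.entries.items() for e in ents]
        return pd.DataFrame(rows, columns=["seq_id", "pos", "ref", "alt",
                                           "effect", "planted_motif"])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path


def _rng_from(spec_seed: int) -> np.random.Generator:
    return np.random.default_rng(spec_seed)


def generate_reference(spec: GeneratorSpec) -> SequenceRecord:
    """A synthetic reference CDS: ATG start, single terminal stop, no
    internal stops, GC within 0.5 percentage points of the target."""
    rng = _rng_from(spec.seed)
    n = spec.length_nt
    # achievable GC window given the fixed start and stop codons
    min_gc = 1 / n            # ATG contributes one G; stop TAA contributes none
    max_gc = (n - 6 + 1 + 2) / n   # all middle GC (no stop risk if e.g. GGC), ATG 1, TAG 1
    if not (min_gc - 1e-9 <= spec.gc_target <= max_gc + 1e-9):
        raise ValueError(
            f"gc_target {spec.gc_target} unattainable for length {n} "
            f"(achievable about [{min_gc:.3f}, {max_gc:.3f}])")
    n_codons = n // 3
    p_gc = spec.gc_target
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])  # A C G T
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3, p=probs))
            if codon not in _STOPS:
                codons.append(codon)
                break
    codons.append("TAA" if p_gc < 0.5 else "TGA")
    seq = list("".join(codons))

    def gc_percent(s: list[str]) -> float:
        return 100.0 * sum(c in "GC" for c in s) / len(s)

    target_pct = 100.0 * spec.gc_target
    # nudge random middle positions toward the target without creating stops
    for _ in range(20 * n):
        diff = gc_percent(seq) - target_pct
        if abs(diff) <= 0.45:
            break
        pos = int(rng.integers(3, n - 3))
        base = seq[pos]
        if diff > 0 and base in "GC":
            new = "A" if rng.random() < 0.5 else "T"
        elif diff < 0 and base in "AT":
            new = "G" if rng.random() < 0.5 else "C"
        else:
            continue
        old = seq[pos]
        seq[pos] = new
        codon_i = pos // 3
        if "".join(seq[codon_i * 3:codon_i * 3 + 3]) in _STOPS:
            seq[pos] = old
    if abs(gc_percent(seq) - target_pct) > 0.5:
        raise ValueError("failed to reach gc_target; widen the tolerance or length")
    return SequenceRecord(id="reference", seq="".join(seq), kind=NUCLEOTIDE,
                          source="synthetic")


def _silent_options(codon: str) -> list[tuple[int, str]]:
    """(offset, alt base) single-base edits that preserve the amino acid."""
    aa = translate_codon(codon)
    opts = []
    for off in range(3):
        for alt in _BASES:
            if alt == codon[off]:
                continue
            new = codon[:off] + alt + codon[off + 1:]
            if new not in _STOPS and translate_codon(new) == aa:
                opts.append((off, alt))
    return opts


def _missense_options(codon: str) -> list[tuple[int, str]]:
    aa = translate_codon(codon)
    opts = []
    for off in range(3):
        for alt in _BASES:
            if alt == codon[off]:
                continue
            new = codon[:off] + alt + codon[off + 1:]
            if new not in _STOPS and translate_codon(new) != aa:
                opts.append((off, alt))
    return opts


def _nonsense_options(codon: str) -> list[tuple[int, str]]:
    opts = []
    for off in range(3):
        for alt in _BASES:
            if alt == codon[off]:
                continue
            new = codon[:off] + alt + codon[off + 1:]
            if new in _STOPS:
                opts.append((off, alt))
    return opts


def _pick_biased(rng: np.random.Generator, options: list[tuple[int, str]],
                 bias: dict[str, float]) -> tuple[int, str]:
    weights = np.array([max(bias.get(alt, 0.0), 1e-9) for _, alt in options])
    weights = weights / weights.sum()
    idx = int(rng.choice(len(options), p=weights))
    return options[idx]


def generate_variants(reference: SequenceRecord, spec: GeneratorSpec
                      ) -> tuple[Repository, TruthTable]:
    """Generate ``spec.n_variants`` independent variants plus ground truth."""
    rng = _rng_from(spec.seed + 1)
    ref = reference.seq
    n = len(ref)
    n_codons = n // 3
    truth = TruthTable()
    members: list[SequenceRecord] = []

    # deterministic per-template placements, shared across carrying variants
    template_starts: list[int] = []
    blocked_nt: set[int] = set()     # 1-based positions barred to random singles
    buffer = 5                        # > max pattern gap, isolates planted motifs
    for t_idx, (offsets, alts) in enumerate(spec.motif_templates):
        span = offsets[-1] + 1
        for _attempt in range(1000):
            start = int(rng.integers(4, n - 3 - span))   # avoid start/stop codons
            positions = [start + off for off in offsets]
            if any(p < 4 or p > n - 3 for p in positions):
                continue
            trial = list(ref)
            ok = True
            for p, alt in zip(positions, alts):
                if trial[p - 1] == alt:
                    ok = False   # template alt equals the reference base here
                    break
                trial[p - 1] = alt
            if not ok:
                continue
            codon_idxs = {(p - 1) // 3 for p in positions}
            if any("".join(trial[c * 3:c * 3 + 3]) in _STOPS for c in codon_idxs):
                continue
            lo = max(1, start - buffer)
            hi = min(n, start + span - 1 + buffer)
            zone = set(range(lo, hi + 1))
            if zone & blocked_nt:
                continue
            template_starts.append(start)
            blocked_nt |= zone
            break
        else:
            raise ValueError(f"could not place motif template {t_idx} "
                             "without collisions")
        truth.motif_placements.append({
            "template": t_idx, "offsets": offsets, "alts": alts,
            "start": template_starts[t_idx], "variants": []})

    blocked_codons = {(p - 1) // 3 for p in blocked_nt}

    for v in range(spec.n_variants):
        vid = f"var{v + 1:03d}"
        if spec.n_mutations is not None:
            n_mut = spec.n_mutations
        else:
            ident = rng.uniform(*spec.identity_range)
            n_mut = int(round(n * (1.0 - ident)))
        entries: list[TruthEntry] = []
        seq = list(ref)
        used_codons: set[int] = set()

        carries_motifs = [t for t in range(len(spec.motif_templates))
                          if v < spec.motif_support]
        for t_idx in carries_motifs:
            offsets, alts = spec.motif_templates[t_idx]
            start = template_starts[t_idx]
            for off, alt in zip(offsets, alts):
                pos = start + off
                codon_i = (pos - 1) // 3
                ref_codon = ref[codon_i * 3:codon_i * 3 + 3]
                in_codon = (pos - 1) % 3
                alt_codon = ref_codon[:in_codon] + alt + ref_codon[in_codon + 1:]
                effect, _, _ = classify_effect(ref_codon, alt_codon)
                entries.append(TruthEntry(pos, ref[pos - 1], alt, effect, t_idx))
                seq[pos - 1] = alt
                used_codons.add(codon_i)
            truth.motif_placements[t_idx]["variants"].append(vid)

        n_remaining = max(0, n_mut - len(entries))
        n_silent = int(round(n_remaining * spec.silent_fraction))
        n_missense = n_remaining - n_silent
        inject_stop = v < spec.inject_stops
        if inject_stop and n_missense > 0:
            n_missense -= 1

        candidate_codons = [c for c in range(1, n_codons - 1)
                            if c not in blocked_codons]
        order = rng.permutation(len(candidate_codons))

        def draw(count: int, option_fn, kind_label: str) -> None:
            placed = 0
            for k in order:
                if placed == count:
                    return
                codon_i = candidate_codons[k]
                if codon_i in used_codons:
                    continue
                codon = ref[codon_i * 3:codon_i * 3 + 3]
                options = option_fn(codon)
                if not options:
                    continue
                off, alt = _pick_biased(rng, options, spec.base_bias)
                pos = codon_i * 3 + off + 1
                alt_codon = codon[:off] + alt + codon[off + 1:]
                effect, _, _ = classify_effect(codon, alt_codon)
                entries.append(TruthEntry(pos, codon[off], alt, effect, None))
                seq[pos - 1] = alt
                used_codons.add(codon_i)
                placed += 1
            if placed < count:
                raise ValueError(
                    f"{vid}: could only place {placed}/{count} {kind_label} "
                    f"mutations (shortfall {count - placed})")

        draw(n_silent, _silent_options, "silent")
        draw(n_missense, _missense_options, "missense")
        if inject_stop:
            draw(1, _nonsense_options, "nonsense")

        entries.sort(key=lambda e: e.pos)
        truth.entries[vid] = entries
        members.append(SequenceRecord(id=vid, seq="".join(seq), kind=NUCLEOTIDE,
                                      source="synthetic"))

    return Repository(reference, members), truth


def generate_repository(spec: GeneratorSpec) -> tuple[Repository, TruthTable]:
    """Convenience wrapper: reference + variants in one call."""
    reference = generate_reference(spec)
    return generate_variants(reference, spec)
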