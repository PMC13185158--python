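"""Data-cleansing rules applied to a repository before mining.

Members are removed when they are too similar (identity > 99%) or too
dissimilar (< 75%) to the reference, contain a premature in-frame stop
codon, or duplicate an earlier member at the nucleotide or
translated-protein level.  Rules are applied in that order and the first
matching rule is recorded.  Thresholds are strict inequalities, so a
member at exactly 99.0% or 75.0% identity is kept.  The reference itself
is never removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import SubstitutionMatrix
from .profiling import call_mutations
from .records import Repository, SequenceRecord

TOO_SIMILAR = "too_similar"
TOO_DISSIMILAR = "too_dissimilar"
PREMATURE_STOP = "premature_stop"
DUPLICATE_NT = "duplicate_nt"
DUPLICATE_PROTEIN = "duplicate_protein"

_STOPS = ("TAA", "TGA", "TAG")


@dataclass
class FilterReport:
    kept_ids: list[str]
    removed: list[tuple[str, str]]  # (id, rule)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"id": i, "rule": "kept"} for i in self.kept_ids]
        rows += [{"id": i, "rule": r} for i, r in self.removed]
        return pd.DataFrame(rows, columns=["id", "rule"])


def _has_premature_stop(seq: str) -> bool:
    """In-frame stop among complete codons, excluding a terminal stop."""
    n_codons = len(seq) // 3
    last_complete_is_terminal = len(seq) % 3 == 0
    limit = n_codons - 1 if last_complete_is_terminal else n_codons
    return any(seq[i * 3:i * 3 + 3] in _STOPS for i in range(limit))


def _protein_key(seq: str) -> str:
    """Translation up to (excluding) the first stop, for duplicate detection."""
    from .records import translate_codon
    residues = []
    for i in range(len(seq) // 3):
        aa = translate_codon(seq[i * 3:i * 3 + 3])
        if aa == "*":
            break
        residues.append(aa)
    return "".join(residues)


def filter_repository(repo: Repository, hi: float = 0.99, lo: float = 0.75,
                      matrix: SubstitutionMatrix | None = None,
                      identities: dict[str, float] | None = None
                      ) -> tuple[Repository, FilterReport]:
    """Apply the cleansing rules; returns the filtered repository and report.

    ``identities`` may carry precomputed identity percents (by member id)
    to avoid re-aligning; missing entries are computed against
    ``repo.reference``.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    identities = dict(identities or {})
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str]] = []
    seen_nt: set[str] = {repo.reference.seq}
    seen_prot: set[str] = {_protein_key(repo.reference.seq)}
    for rec in repo.members:
        ident = identities.get(rec.id)
        if ident is None:
            ident = call_mutations(repo.reference, rec, matrix=matrix).identity_percent
        if ident > 100.0 * hi:
            removed.append((rec.id, TOO_SIMILAR))
            continue
        if ident < 100.0 * lo:
            removed.append((rec.id, TOO_DISSIMILAR))
            continue
        if _has_premature_stop(rec.seq):
            removed.append((rec.id, PREMATURE_STOP))
            continue
        if rec.seq in seen_nt:
            removed.append((rec.id, DUPLICATE_NT))
            continue
        prot = _protein_key(rec.seq)
        if prot in seen_prot:
            removed.append((rec.id, DUPLICATE_PROTEIN))
            continue
        seen_nt.add(rec.seq)
        seen_prot.add(prot)
        kept.append(rec)
    report = FilterReport(kept_ids=[r.id for r in kept], removed=removed)
    return Repository(repo.reference, kept), report
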