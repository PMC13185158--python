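"""Needleman-Wunsch global alignment with a user-supplied substitution matrix.

Used for unequal-length comparison against the reference CDS and for
identity computation.  The default nucleotide scheme is match +1 /
mismatch -3 with a linear gap penalty of -2; an affine model (Gotoh
three-state recursion) is available when ``gap_open != gap_extend``.

Traceback ties are broken deterministically: diagonal > up (gap in the
second sequence) > left (gap in the first sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import SequenceRecord

_NEG_INF = float("-inf")


@dataclass
class SubstitutionMatrix:
    """Symmetric substitution scores over an alphabet, plus gap penalties.

    ``gap_open == gap_extend`` selects the linear gap model (every gap
    column costs ``gap_extend``); otherwise the affine model is used and a
    gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    alphabet: str
    scores: dict[tuple[str, str], float]
    gap_open: float = -2.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ValueError(f"score undefined for pair ({a}, {b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValueError(f"matrix not symmetric at ({a}, {b})")

    @property
    def is_linear(self) -> bool:
        return self.gap_open == self.gap_extend

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise ValueError(f"symbol pair ({a!r}, {b!r}) outside matrix alphabet") from None

    @classmethod
    def from_match_mismatch(cls, alphabet: str = "ACGTN", match: float = 1.0,
                            mismatch: float = -3.0, gap: float = -2.0,
                            gap_extend: float | None = None) -> "SubstitutionMatrix":
        scores = {(a, b): (match if a == b else mismatch)
                  for a in alphabet for b in alphabet}
        return cls(alphabet, scores, gap_open=gap,
                   gap_extend=gap if gap_extend is None else gap_extend)

    @classmethod
    def from_file(cls, path: str | Path, gap: float = -2.0,
                  gap_extend: float | None = None) -> "SubstitutionMatrix":
        """Read a whitespace-delimited square table with header symbols
        (NCBI matrix dialect; ``#`` comment lines ignored)."""
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.lstrip().startswith("#")]
        header = lines[0].split()
        alphabet = "".join(header)
        scores: dict[tuple[str, str], float] = {}
        for line in lines[1:]:
            parts = line.split()
            row_sym, values = parts[0], parts[1:]
            if len(values) != len(header):
                raise ValueError(f"matrix row {row_sym!r} has {len(values)} values, "
                                 f"expected {len(header)}")
            for col_sym, v in zip(header, values):
                scores[(row_sym, col_sym)] = float(v)
        return cls(alphabet, scores, gap_open=gap,
                   gap_extend=gap if gap_extend is None else gap_extend)


DEFAULT_NT_MATRIX = SubstitutionMatrix.from_match_mismatch()


@dataclass
class Alignment:
    """A global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float = field(default=0.0)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


def identity_from_aligned(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over comparable (both non-gap) columns, with
    terminal gap columns excluded from the comparison."""
    n = len(aligned_a)
    start, end = 0, n
    while start < n and ("-" in (aligned_a[start], aligned_b[start])):
        start += 1
    while end > start and ("-" in (aligned_a[end - 1], aligned_b[end - 1])):
        end -= 1
    comparable = matches = 0
    for a, b in zip(aligned_a[start:end], aligned_b[start:end]):
        if a != "-" and b != "-":
            comparable += 1
            if a == b:
                matches += 1
    return 100.0 * matches / comparable if comparable else 0.0


def needleman_wunsch(a: SequenceRecord | str, b: SequenceRecord | str,
                     matrix: SubstitutionMatrix | None = None) -> Alignment:
    """Optimal global alignment of ``a`` and ``b``.

    Linear gaps use the classic single-matrix recursion; affine gaps use
    the Gotoh three-state recursion.  The traceback is deterministic
    (diagonal preferred over up, up over left).
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    if isinstance(a, SequenceRecord) and isinstance(b, SequenceRecord) and a.kind != b.kind:
        raise ValueError("cannot align records of different kinds")
    m = matrix if matrix is not None else DEFAULT_NT_MATRIX
    for s in (sa, sb):
        for ch in s:
            if ch not in m.alphabet:
                raise ValueError(f"symbol {ch!r} outside matrix alphabet {m.alphabet!r}")
    if m.is_linear:
        aligned_a, aligned_b, score = _nw_linear(sa, sb, m)
    else:
        aligned_a, aligned_b, score = _nw_affine(sa, sb, m)
    return Alignment(aligned_a, aligned_b, score,
                     identity_percent=identity_from_aligned(aligned_a, aligned_b))


# traceback codes
_DIAG, _UP, _LEFT = 0, 1, 2


def _nw_linear(sa: str, sb: str, m: SubstitutionMatrix):
    n1, n2 = len(sa), len(sb)
    gap = m.gap_extend
    sub = np.empty((n1, n2))
    for i, ca in enumerate(sa):
        for j, cb in enumerate(sb):
            sub[i, j] = m.score(ca, cb)
    F = np.empty((n1 + 1, n2 + 1))
    tb = np.empty((n1 + 1, n2 + 1), dtype=np.int8)
    F[0, :] = np.arange(n2 + 1) * gap
    F[:, 0] = np.arange(n1 + 1) * gap
    tb[0, :] = _LEFT
    tb[:, 0] = _UP
    for i in range(1, n1 + 1):
        row_prev, row = F[i - 1], F[i]
        for j in range(1, n2 + 1):
            diag = row_prev[j - 1] + sub[i - 1, j - 1]
            up = row_prev[j] + gap
            left = row[j - 1] + gap
            # tie order: diagonal > up > left
            best, code = diag, _DIAG
            if up > best:
                best, code = up, _UP
            if left > best:
                best, code = left, _LEFT
            row[j] = best
            tb[i, j] = code
    return _traceback(sa, sb, tb) + (float(F[n1, n2]),)


def _nw_affine(sa: str, sb: str, m: SubstitutionMatrix):
    n1, n2 = len(sa), len(sb)
    go, ge = m.gap_open, m.gap_extend
    M = np.full((n1 + 1, n2 + 1), _NEG_INF)
    Ix = np.full((n1 + 1, n2 + 1), _NEG_INF)   # gap in sb (consumes sa) -> "up"
    Iy = np.full((n1 + 1, n2 + 1), _NEG_INF)   # gap in sa (consumes sb) -> "left"
    ptr = {}
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        Ix[i, 0] = go + (i - 1) * ge
    for j in range(1, n2 + 1):
        Iy[0, j] = go + (j - 1) * ge
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = m.score(sa[i - 1], sb[j - 1])
            # M: best of the three previous states, diagonal move
            cand = ((M[i - 1, j - 1], "M"), (Ix[i - 1, j - 1], "Ix"), (Iy[i - 1, j - 1], "Iy"))
            best, src = max(cand, key=lambda t: t[0])
            M[i, j] = best + s
            ptr[("M", i, j)] = src
            # Ix: gap in sb, vertical move (may open after an Iy gap)
            cand_ix = ((M[i - 1, j] + go, "M"), (Ix[i - 1, j] + ge, "Ix"),
                       (Iy[i - 1, j] + go, "Iy"))
            Ix[i, j], ptr[("Ix", i, j)] = max(cand_ix, key=lambda t: t[0])
            # Iy: gap in sa, horizontal move (may open after an Ix gap)
            cand_iy = ((M[i, j - 1] + go, "M"), (Iy[i, j - 1] + ge, "Iy"),
                       (Ix[i, j - 1] + go, "Ix"))
            Iy[i, j], ptr[("Iy", i, j)] = max(cand_iy, key=lambda t: t[0])
    finals = ((M[n1, n2], "M"), (Ix[n1, n2], "Ix"), (Iy[n1, n2], "Iy"))
    score, state = max(finals, key=lambda t: t[0])
    out_a, out_b = [], []
    i, j = n1, n2
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(sa[i - 1]); out_b.append(sb[j - 1])
            state = ptr.get(("M", i, j), "M")
            i, j = i - 1, j - 1
        elif state == "Ix":
            out_a.append(sa[i - 1]); out_b.append("-")
            state = ptr.get(("Ix", i, j), "Ix")
            i -= 1
        else:
            out_a.append("-"); out_b.append(sb[j - 1])
            state = ptr.get(("Iy", i, j), "Iy")
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def _traceback(sa: str, sb: str, tb: np.ndarray):
    out_a, out_b = [], []
    i, j = len(sa), len(sb)
    while i > 0 or j > 0:
        code = tb[i, j]
        if code == _DIAG and i > 0 and j > 0:
            out_a.append(sa[i - 1]); out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif code == _UP and i > 0:
            out_a.append(sa[i - 1]); out_b.append("-")
            i -= 1
        else:
            out_a.append("-"); out_b.append(sb[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
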