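"""Protein-level analysis of variant substitutions.

Maps amino-acid substitutions onto structural annotations (domains,
helices, sheets, turns, loops), computes physicochemical deltas
(Kyte-Doolittle hydropathy, formal charge at pH 7, polarity class),
charge-patterning descriptors (FCR, NCPR and the Das-Pappu kappa), and
scores substitutions by proximity to substrate / product / energy-
nucleotide binding sites.  Sequences substituting a substrate-site
residue itself are flagged as potentially dysfunctional and excluded from
candidate ranking; product (M-RL) sites are carried as annotation only
and never trigger exclusion.

Proximity codes follow the heatmap convention: +1 marks a binding-site
position in the reference row, 0 means no mismatch within the window, -1
a substitution exactly on the site residue, and -(d+1) a substitution at
distance d (so distances 1..3 map to -2..-4).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mining import Hotspot
from .profiling import MutationProfile
from .records import PROTEIN, SequenceError, SequenceRecord

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Formal side-chain charge at pH 7; histidine neutral by default.
CHARGE_AT_PH7 = {"D": -1, "E": -1, "K": +1, "R": +1}

POLARITY_CLASS = {
    **{aa: "nonpolar" for aa in "GAVLIPFMW"},
    **{aa: "polar" for aa in "STCYNQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
}

SUBSTRATE_LIGANDS = ("substrate_sugar", "substrate_lipid")
NUCLEOTIDE_LIGANDS = ("atp", "gtp")
ALL_LIGANDS = SUBSTRATE_LIGANDS + ("product",) + NUCLEOTIDE_LIGANDS


# ---------------------------------------------------------------------------
# annotations

@dataclass(frozen=True)
class LabeledInterval:
    label: str
    start: int
    end: int            # 1-based closed

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class AnnotationSet:
    """Structural annotation intervals over the reference protein.

    Element lookup precedence: helix/sheet > turn > loop > primary.
    Overlaps across categories are allowed; within one category they are
    rejected.
    """

    domains: list[LabeledInterval] = field(default_factory=list)
    helices: list[LabeledInterval] = field(default_factory=list)
    sheets: list[LabeledInterval] = field(default_factory=list)
    turns: list[LabeledInterval] = field(default_factory=list)
    loops: list[LabeledInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("domains", "helices", "sheets", "turns", "loops"):
            ivs = sorted(getattr(self, name), key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping {name} intervals: {a} / {b}")

    def element_of(self, pos: int) -> str:
        for category in (self.helices, self.sheets, self.turns, self.loops):
            for iv in category:
                if pos in iv:
                    return iv.label
        return "primary"

    def domain_of(self, pos: int) -> str | None:
        for iv in self.domains:
            if pos in iv:
                return iv.label
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        buckets = {"domain": [], "helix": [], "sheet": [], "turn": [], "loop": []}
        for _, row in df.iterrows():
            cat = str(row["category"]).lower()
            if cat not in buckets:
                raise ValueError(f"unknown annotation category {cat!r}")
            buckets[cat].append(LabeledInterval(str(row["label"]),
                                                int(row["start"]), int(row["end"])))
        return cls(domains=buckets["domain"], helices=buckets["helix"],
                   sheets=buckets["sheet"], turns=buckets["turn"],
                   loops=buckets["loop"])


@dataclass(frozen=True)
class BindingSite:
    residue_pos: int
    ligand: str                  # substrate_sugar | substrate_lipid | product | atp | gtp
    source: str                  # docking | motif
    note: str = ""
    ac_score: float | None = None
    swissparam_score: float | None = None


@dataclass
class BindingSiteConfig:
    sites: list[BindingSite]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sites:
            if s.ligand not in ALL_LIGANDS:
                raise ValueError(f"unknown ligand {s.ligand!r}")
            key = (s.residue_pos, s.ligand, s.source)
            if key in seen:
                raise ValueError(f"duplicate binding site {key}")
            seen.add(key)

    def positions(self, ligand: str | None = None) -> list[int]:
        return sorted({s.residue_pos for s in self.sites
                       if ligand is None or s.ligand == ligand})

    def ligands_at(self, pos: int) -> set[str]:
        return {s.ligand for s in self.sites if s.residue_pos == pos}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingSiteConfig":
        df = pd.read_csv(path, sep="\t", comment="#")
        sites = []
        for _, row in df.iterrows():
            sites.append(BindingSite(
                residue_pos=int(row["pos"]), ligand=str(row["ligand"]),
                source=str(row["source"]), note=str(row.get("note", "") or ""),
                ac_score=None if pd.isna(row.get("ac_score")) else float(row["ac_score"]),
                swissparam_score=(None if pd.isna(row.get("swissparam_score"))
                                  else float(row["swissparam_score"]))))
        return cls(sites)


def load_packaged_binding_sites() -> BindingSiteConfig:
    """The bundled RhlB binding-site configuration (docking/motif residues)."""
    with resources.as_file(resources.files("varmine.data") / "binding_sites.tsv") as p:
        return BindingSiteConfig.from_tsv(p)


def load_packaged_annotations() -> AnnotationSet:
    """The bundled RhlB structural annotation (approximate, user-editable)."""
    with resources.as_file(resources.files("varmine.data") / "annotations.tsv") as p:
        return AnnotationSet.from_tsv(p)


# ---------------------------------------------------------------------------
# substitutions and property deltas

@dataclass
class SubstitutionAnnotation:
    pos_aa: int
    ref_aa: str
    alt_aa: str
    element: str = "primary"
    domain: str | None = None
    hydropathy_delta: float | None = None
    charge_delta: int | None = None
    polarity_change: tuple[str, str] | None = None
    proximity_codes: dict[str, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.pos_aa}{self.alt_aa}"


def property_delta(ref_aa: str, alt_aa: str) -> tuple[float, int, tuple[str, str]]:
    """(hydropathy delta, charge delta, (polarity class of ref, of alt))."""
    for aa in (ref_aa, alt_aa):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"non-canonical amino acid {aa!r}")
    hyd = KYTE_DOOLITTLE[alt_aa] - KYTE_DOOLITTLE[ref_aa]
    charge = CHARGE_AT_PH7.get(alt_aa, 0) - CHARGE_AT_PH7.get(ref_aa, 0)
    return hyd, charge, (POLARITY_CLASS[ref_aa], POLARITY_CLASS[alt_aa])


def map_substitutions(ref_protein: SequenceRecord, var_protein: SequenceRecord,
                      annotations: AnnotationSet | None = None
                      ) -> list[SubstitutionAnnotation]:
    """One annotated entry per differing residue of two equal-length proteins."""
    if ref_protein.kind != PROTEIN or var_protein.kind != PROTEIN:
        raise SequenceError("map_substitutions requires protein records")
    if not ref_protein.seq or not var_protein.seq:
        raise SequenceError("empty protein sequence")
    if len(ref_protein.seq) != len(var_protein.seq):
        raise SequenceError(
            f"length mismatch ({len(ref_protein.seq)} vs {len(var_protein.seq)}); "
            "align the proteins first")
    annotations = annotations or AnnotationSet()
    subs = []
    for pos, (r, v) in enumerate(zip(ref_protein.seq, var_protein.seq), start=1):
        if r == v:
            continue
        sub = SubstitutionAnnotation(pos_aa=pos, ref_aa=r, alt_aa=v,
                                     element=annotations.element_of(pos),
                                     domain=annotations.domain_of(pos))
        if r in KYTE_DOOLITTLE and v in KYTE_DOOLITTLE:
            sub.hydropathy_delta, sub.charge_delta, sub.polarity_change = \
                property_delta(r, v)
        subs.append(sub)
    return subs


# ---------------------------------------------------------------------------
# charge patterning (FCR / NCPR / kappa)

@dataclass(frozen=True)
class ChargePatternSummary:
    fcr: float
    ncpr: float
    kappa: float
    no_charges: bool = False       # flag: kappa degenerate (no charged residues
                                   # or charge pattern invariant under permutation)


def _charges(seq: str, his_charge: int = 0) -> np.ndarray:
    table = dict(CHARGE_AT_PH7)
    table["H"] = his_charge
    return np.array([table.get(aa, 0) for aa in seq], dtype=float)


def _sigma(charges: np.ndarray) -> float:
    n = len(charges)
    fplus = np.count_nonzero(charges > 0) / n
    fminus = np.count_nonzero(charges < 0) / n
    fcr = fplus + fminus
    if fcr == 0:
        return 0.0
    return (fplus - fminus) ** 2 / fcr


def _delta(charges: np.ndarray, g: int) -> float:
    """Mean squared deviation of blob charge asymmetry from the sequence's."""
    sigma_seq = _sigma(charges)
    n_blobs = len(charges) - g + 1
    windows = np.lib.stride_tricks.sliding_window_view(charges, g)
    fplus = (windows > 0).sum(axis=1) / g
    fminus = (windows < 0).sum(axis=1) / g
    fcr = fplus + fminus
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(fcr > 0, (fplus - fminus) ** 2 / np.where(fcr > 0, fcr, 1), 0.0)
    return float(np.mean((sig - sigma_seq) ** 2)) if n_blobs > 0 else 0.0


_EXHAUSTIVE_NEUTRAL_LIMIT = 24
_SPLIT_FRACTIONS = tuple(i / 8 for i in range(9))


def _segregated_family(charges: np.ndarray) -> list[np.ndarray]:
    """Candidate maximally segregated permutations of the same composition.

    Each candidate keeps all negatives in one block and all positives in
    another, distributing the neutral residues before, between and after
    the blocks.  The classic all-negatives / all-neutrals / all-positives
    arrangement is the ``between = all`` member; interior placements are
    needed because charges at the sequence ends are covered by fewer
    sliding blobs, so edge-anchored blocks can understate the attainable
    segregation.  The split is enumerated exhaustively for short neutral
    stretches and on a fraction grid otherwise.
    """
    neg = int(np.count_nonzero(charges < 0))
    zero = int(np.count_nonzero(charges == 0))
    pos = int(np.count_nonzero(charges > 0))
    if zero <= _EXHAUSTIVE_NEUTRAL_LIMIT:
        splits = {(pre, mid, zero - pre - mid)
                  for mid in range(zero + 1) for pre in range(zero - mid + 1)}
    else:
        splits = set()
        for f_mid in _SPLIT_FRACTIONS:
            mid = round(f_mid * zero)
            for f_pre in _SPLIT_FRACTIONS:
                pre = round(f_pre * (zero - mid))
                splits.add((pre, mid, zero - mid - pre))
    return [np.concatenate([np.zeros(pre), np.full(neg, -1.0), np.zeros(mid),
                            np.full(pos, 1.0), np.zeros(post)])
            for pre, mid, post in sorted(splits)]


@lru_cache(maxsize=4096)
def _family_delta_max(neg: int, zero: int, pos: int, g: int) -> float:
    """delta of the best block arrangement for a composition (cached;
    delta is invariant under a global sign flip, so the key is
    canonicalised to neg <= pos)."""
    if neg > pos:
        neg, pos = pos, neg
    charges = np.concatenate([np.full(neg, -1.0), np.zeros(zero),
                              np.full(pos, 1.0)])
    return max(_delta(arr, g) for arr in _segregated_family(charges))


def _delta_max(charges: np.ndarray, g: int) -> float:
    """Largest delta over the segregated family and the observed arrangement.

    Including the observed arrangement makes the normalisation a true
    bound (kappa <= 1 by construction): for compositions with few,
    same-sign charges a dispersed placement can exceed every block
    arrangement, in which case the sequence itself is the most segregated
    permutation the search knows and its kappa is 1.
    """
    neg = int(np.count_nonzero(charges < 0))
    pos = int(np.count_nonzero(charges > 0))
    zero = len(charges) - neg - pos
    return max(_family_delta_max(neg, zero, pos, g), _delta(charges, g))


def charge_pattern(protein: SequenceRecord | str, his_charge: int = 0,
                   blob_sizes: tuple[int, ...] = (5, 6)) -> ChargePatternSummary:
    """FCR, NCPR and the Das-Pappu charge-patterning parameter kappa.

    kappa is the blob-wise charge-asymmetry deviation delta_g, normalised
    by delta_max — the largest delta over a family of maximally segregated
    permutations of the same composition (charge blocks with the neutral
    residues split before/between/after them) — averaged over blob sizes
    g in {5, 6}.  Well-mixed
    sequences score near 0; fully blocky sequences score 1.  Sequences
    with no charged residues (or a charge pattern invariant under
    permutation, e.g. uniformly charged) have kappa reported as 0 with
    the ``no_charges`` flag set.
    """
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein.upper()
    seq = seq.rstrip("*")
    if len(seq) < 6:
        raise ValueError("charge_pattern requires length >= 6")
    charges = _charges(seq, his_charge)
    n = len(charges)
    n_pos = int(np.count_nonzero(charges > 0))
    n_neg = int(np.count_nonzero(charges < 0))
    fcr = (n_pos + n_neg) / n
    ncpr = (n_pos - n_neg) / n
    if fcr == 0:
        return ChargePatternSummary(fcr=0.0, ncpr=0.0, kappa=0.0, no_charges=True)
    ratios = []
    for g in blob_sizes:
        d_max = _delta_max(charges, g)
        if d_max > 0:
            ratios.append(_delta(charges, g) / d_max)
    if not ratios:
        return ChargePatternSummary(fcr=fcr, ncpr=ncpr, kappa=0.0, no_charges=True)
    return ChargePatternSummary(fcr=fcr, ncpr=ncpr,
                                kappa=float(np.mean(ratios)), no_charges=False)


# ---------------------------------------------------------------------------
# binding-site proximity scoring

ON_SITE = -1


def _window_for(ligand: str, substrate_window: int, nucleotide_window: int) -> int:
    return nucleotide_window if ligand in NUCLEOTIDE_LIGANDS else substrate_window


def proximity_code(distance: int, window: int) -> int:
    """Heatmap code for a substitution at ``distance`` residues from a site."""
    if distance == 0:
        return ON_SITE
    if 1 <= distance <= window:
        return -(distance + 1)
    return 0


def proximity_scores(subs_by_seq: dict[str, list[SubstitutionAnnotation]],
                     sites: BindingSiteConfig,
                     substrate_window: int = 5, nucleotide_window: int = 3
                     ) -> tuple[dict[str, list[SubstitutionAnnotation]],
                                pd.DataFrame, list[str]]:
    """Score every substitution by proximity to each ligand's binding sites.

    Returns the substitution lists with ``proximity_codes`` filled in, the
    penalty matrix (rows: reference then sequences; columns: site
    residues; +1 marks site positions in the reference row), and the ids
    of sequences excluded as potentially dysfunctional (a substitution
    exactly on a substrate-site residue).  Product sites are annotated but
    never cause exclusion.
    """
    if substrate_window < 0 or nucleotide_window < 0:
        raise ValueError("windows must be non-negative")
    site_pos_by_ligand = {lig: np.array(sites.positions(lig), dtype=int)
                          for lig in ALL_LIGANDS if sites.positions(lig)}
    excluded: list[str] = []
    for seq_id, subs in subs_by_seq.items():
        hit_substrate_site = False
        for sub in subs:
            for lig, positions in site_pos_by_ligand.items():
                d = int(np.min(np.abs(positions - sub.pos_aa)))
                window = _window_for(lig, substrate_window, nucleotide_window)
                code = proximity_code(d, window)
                sub.proximity_codes[lig] = code
                if code == ON_SITE and lig in SUBSTRATE_LIGANDS:
                    hit_substrate_site = True
        if hit_substrate_site:
            excluded.append(seq_id)

    all_site_pos = sites.positions()
    columns = [f"p{p}" for p in all_site_pos]
    rows: dict[str, list[int]] = {"reference": [1] * len(all_site_pos)}
    for seq_id, subs in subs_by_seq.items():
        row = []
        for pos in all_site_pos:
            # most severe (most negative) code over this sequence's
            # substitutions, using the tightest applicable ligand window
            windows = [_window_for(lig, substrate_window, nucleotide_window)
                       for lig in sites.ligands_at(pos)]
            window = max(windows)
            codes = [proximity_code(abs(sub.pos_aa - pos), window) for sub in subs]
            row.append(min(codes) if codes else 0)
        rows[seq_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    matrix.attrs["substrate_window"] = substrate_window
    matrix.attrs["nucleotide_window"] = nucleotide_window
    return subs_by_seq, matrix, excluded


# ---------------------------------------------------------------------------
# candidate selection

def adjacent_count(subs: list[SubstitutionAnnotation]) -> int:
    """Substitutions spatially adjacent (codes -2..-(w+1)) to any binding site."""
    return sum(1 for sub in subs
               if any(code < ON_SITE for code in sub.proximity_codes.values()))


def hotspot_overlap(profile: MutationProfile, hotspots: list[Hotspot]) -> int:
    keys = {(h.pos_nt, h.alt_base) for h in hotspots}
    return sum(1 for m in profile.mutations if (m.pos_nt, m.alt_base) in keys)


def region_group(profile: MutationProfile) -> str:
    """Majority mutation region; ties broken active_domain > envelope > other."""
    if not profile.mutations:
        return "other"
    counts = Counter(m.region for m in profile.mutations)
    order = {"active_domain": 0, "envelope": 1, "other": 2}
    return max(counts, key=lambda r: (counts[r], -order[r]))


def select_candidates(profiles: list[MutationProfile],
                      subs_by_seq: dict[str, list[SubstitutionAnnotation]] | None = None,
                      excluded: list[str] | None = None,
                      hotspots: list[Hotspot] | None = None) -> pd.DataFrame:
    """Deterministic candidate ranking.

    Default keys: not excluded first; count of adjacent-to-site
    substitutions descending; hotspot overlap descending; identity
    ascending (more divergent but intact sequences explore more of the
    landscape); stable id tie-break.
    """
    if not profiles:
        raise ValueError("select_candidates requires at least one profile")
    subs_by_seq = subs_by_seq or {}
    excluded_set = set(excluded or [])
    hotspots = hotspots or []
    rows = []
    for prof in profiles:
        subs = subs_by_seq.get(prof.seq_id, [])
        rows.append({
            "seq_id": prof.seq_id,
            "excluded": prof.seq_id in excluded_set,
            "n_adjacent": adjacent_count(subs),
            "hotspot_overlap": hotspot_overlap(prof, hotspots),
            "identity": prof.identity_percent,
            "n_mutations": len(prof.mutations),
            "region_group": region_group(prof),
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["excluded", "n_adjacent", "hotspot_overlap", "identity", "seq_id"],
        ascending=[True, False, False, True, True],
        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
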