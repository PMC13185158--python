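"""Structural mapping, property deltas, charge patterning and proximity scoring."""

import numpy as np
import pytest

from varmine.protein import (AnnotationSet, BindingSite, BindingSiteConfig,
                             LabeledInterval, SubstitutionAnnotation,
                             charge_pattern, load_packaged_annotations,
                             load_packaged_binding_sites, map_substitutions,
                             property_delta, proximity_code, proximity_scores,
                             select_candidates)
from varmine.profiling import call_mutations
from varmine.records import PROTEIN, SequenceRecord

from conftest import make_record

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein_rec(seq: str, rec_id: str = "p") -> SequenceRecord:
    return SequenceRecord(rec_id, seq, PROTEIN)


def random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list(AA), size=n))


# ---------------------------------------------------------------------------
# substitution mapping

class TestMapSubstitutions:
    def test_element_assignment_in_helix(self):
        ann = AnnotationSet(helices=[LabeledInterval("alpha1", 18, 30)])
        ref = protein_rec("M" + "A" * 29, "ref")
        var = protein_rec("M" + "A" * 19 + "V" + "A" * 9, "var")
        subs = map_substitutions(ref, var, ann)
        assert len(subs) == 1
        assert subs[0].label == "A21V"
        assert subs[0].element == "alpha1"

    def test_identical_proteins(self):
        ref = protein_rec("MAVLK", "ref")
        assert map_substitutions(ref, protein_rec("MAVLK", "v")) == []

    def test_unannotated_position_is_primary(self):
        ref = protein_rec("MAVLK", "ref")
        var = protein_rec("MAVIK", "v")
        subs = map_substitutions(ref, var, AnnotationSet())
        assert subs[0].element == "primary"

    def test_precedence_helix_over_loop(self):
        ann = AnnotationSet(helices=[LabeledInterval("h", 2, 4)],
                            loops=[LabeledInterval("l", 1, 5)])
        subs = map_substitutions(protein_rec("MAVLK", "r"),
                                 protein_rec("MAILK", "v"), ann)
        assert subs[0].element == "h"

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="align"):
            map_substitutions(protein_rec("MAVLK", "r"), protein_rec("MAVL", "v"))


class TestPropertyDelta:
    def test_proline_to_arginine_gains_charge(self):
        hyd, charge, polarity = property_delta("P", "R")
        assert polarity == ("nonpolar", "basic")
        assert charge == +1

    def test_leucine_to_glutamine_polarity_only(self):
        hyd, charge, polarity = property_delta("L", "Q")
        assert polarity == ("nonpolar", "polar")
        assert charge == 0

    def test_isoleucine_to_valine_minor_hydropathy_drop(self):
        hyd, charge, _ = property_delta("I", "V")
        assert hyd == pytest.approx(-0.3)

    def test_histidine_neutral_at_ph7(self):
        _, charge, polarity = property_delta("H", "R")
        assert charge == +1  # R is +1, H is 0
        assert polarity == ("basic", "basic")

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            property_delta("A", "X")


# ---------------------------------------------------------------------------
# charge patterning

def kappa_bruteforce(seq: str, his_charge: int = 0) -> float:
    """Independent loop-level transcription of the blob-deviation kappa."""
    chg = []
    for aa in seq:
        if aa in "DE":
            chg.append(-1)
        elif aa in "KR":
            chg.append(+1)
        elif aa == "H":
            chg.append(his_charge)
        else:
            chg.append(0)

    def sigma(block):
        fp = sum(1 for c in block if c > 0) / len(block)
        fm = sum(1 for c in block if c < 0) / len(block)
        return 0.0 if fp + fm == 0 else (fp - fm) ** 2 / (fp + fm)

    def delta(block, g):
        s_all = sigma(block)
        vals = [(sigma(block[i:i + g]) - s_all) ** 2
                for i in range(len(block) - g + 1)]
        return sum(vals) / len(vals)

    if all(c == 0 for c in chg):
        return 0.0
    neg = sum(1 for c in chg if c < 0)
    pos = sum(1 for c in chg if c > 0)
    zero = len(chg) - neg - pos
    candidates = [list(chg)]   # the observed arrangement bounds the ratio
    if zero <= 24:
        splits = [(pre, mid) for mid in range(zero + 1)
                  for pre in range(zero - mid + 1)]
    else:
        fractions = [i / 8 for i in range(9)]
        splits = []
        for f_mid in fractions:
            mid = round(f_mid * zero)
            for f_pre in fractions:
                splits.append((round(f_pre * (zero - mid)), mid))
    for pre, mid in splits:
        candidates.append([0] * pre + [-1] * neg + [0] * mid
                          + [+1] * pos + [0] * (zero - pre - mid))
    ratios = []
    for g in (5, 6):
        dmax = max(delta(c, g) for c in candidates)
        if dmax > 0:
            ratios.append(delta(chg, g) / dmax)
    return sum(ratios) / len(ratios) if ratios else 0.0


class TestChargePattern:
    def test_alternating_is_well_mixed(self):
        cp = charge_pattern("EKEKEKEKEKEK")
        assert cp.kappa < 0.02
        assert cp.fcr == 1.0
        assert cp.ncpr == 0.0

    def test_fully_segregated_is_one(self):
        assert charge_pattern("EEEEEEKKKKKK").kappa == pytest.approx(1.0)

    def test_unchargeable_sequence_flagged(self):
        cp = charge_pattern("AAAAAAAA")
        assert cp.fcr == 0.0
        assert cp.kappa == 0.0
        assert cp.no_charges

    def test_bounds_and_symmetries(self, rng):
        swap = str.maketrans("DEKR", "KRDE")
        for _ in range(120):
            seq = random_protein(rng, int(rng.integers(8, 80)))
            cp = charge_pattern(seq)
            assert 0.0 <= cp.kappa <= 1.0
            assert abs(cp.ncpr) <= cp.fcr
            assert charge_pattern(seq[::-1]).kappa == pytest.approx(cp.kappa)
            assert charge_pattern(seq.translate(swap)).kappa == \
                pytest.approx(cp.kappa)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            seq = random_protein(rng, int(rng.integers(10, 60)))
            assert charge_pattern(seq).kappa == pytest.approx(
                kappa_bruteforce(seq), abs=1e-6)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            charge_pattern("EKEKE")


# ---------------------------------------------------------------------------
# proximity scoring

def sub(pos: int, ref="A", alt="V") -> SubstitutionAnnotation:
    return SubstitutionAnnotation(pos_aa=pos, ref_aa=ref, alt_aa=alt)


SITES = BindingSiteConfig([
    BindingSite(260, "substrate_sugar", "docking"),
    BindingSite(263, "atp", "motif"),
    BindingSite(228, "substrate_lipid", "docking"),
    BindingSite(333, "product", "docking"),
])


class TestProximityScores:
    def test_on_site_excludes_sequence(self):
        subs, matrix, excluded = proximity_scores({"s1": [sub(260)]}, SITES)
        assert subs["s1"][0].proximity_codes["substrate_sugar"] == -1
        assert excluded == ["s1"]

    def test_nucleotide_window_distance_three(self):
        subs, _, excluded = proximity_scores({"s1": [sub(266)]}, SITES)
        assert subs["s1"][0].proximity_codes["atp"] == -4  # distance 3 from 263
        assert excluded == []

    def test_outside_window_is_zero(self):
        subs, _, _ = proximity_scores({"s1": [sub(270)]}, SITES)
        assert subs["s1"][0].proximity_codes["substrate_sugar"] == 0

    def test_product_site_never_excludes(self):
        subs, _, excluded = proximity_scores({"s1": [sub(333)]}, SITES)
        assert subs["s1"][0].proximity_codes["product"] == -1
        assert excluded == []

    def test_reference_row_marks_sites(self):
        _, matrix, _ = proximity_scores({"s1": [sub(100)]}, SITES)
        assert (matrix.loc["reference"] == 1).all()
        assert list(matrix.columns) == ["p228", "p260", "p263", "p333"]

    def test_matches_bruteforce_min_distance(self, rng):
        sites = load_packaged_binding_sites()
        windows = {"substrate_sugar": 5, "substrate_lipid": 5, "product": 5,
                   "atp": 3, "gtp": 3}
        subs_by_seq = {f"s{i}": [sub(int(p))
                                 for p in rng.choice(np.arange(1, 427),
                                                     size=6, replace=False)]
                       for i in range(10)}
        scored, _, excluded = proximity_scores(subs_by_seq, sites)
        substrate_hits = set()
        for sid, subs in scored.items():
            for s in subs:
                for lig, code in s.proximity_codes.items():
                    d = min(abs(p - s.pos_aa) for p in sites.positions(lig))
                    if d == 0:
                        expect = -1
                        if lig in ("substrate_sugar", "substrate_lipid"):
                            substrate_hits.add(sid)
                    elif d <= windows[lig]:
                        expect = -(d + 1)
                    else:
                        expect = 0
                    assert code == expect, (sid, s.pos_aa, lig)
        assert set(excluded) == substrate_hits

    def test_code_mapping(self):
        assert proximity_code(0, 5) == -1
        assert proximity_code(1, 5) == -2
        assert proximity_code(3, 3) == -4
        assert proximity_code(4, 3) == 0

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            proximity_scores({}, SITES, substrate_window=-1)


class TestSelectCandidates:
    def _profiles(self):
        ref = make_record("ATG" + "GCT" * 20 + "TAA", "ref")
        out = []
        for vid, pos_alt in [("adj", {10: "A"}), ("excl", {20: "A"}),
                             ("plain", {30: "A"})]:
            seq = list(ref.seq)
            for p, a in pos_alt.items():
                seq[p - 1] = a
            out.append(call_mutations(ref, make_record("".join(seq), vid)))
        return out

    def test_excluded_ranked_last(self):
        profiles = self._profiles()
        subs_by_seq = {"adj": [sub(4)], "excl": [sub(7)], "plain": []}
        subs_by_seq["adj"][0].proximity_codes["atp"] = -3
        subs_by_seq["excl"][0].proximity_codes["substrate_sugar"] = -1
        ranked = select_candidates(profiles, subs_by_seq, excluded=["excl"])
        assert ranked["seq_id"].tolist()[0] == "adj"
        assert ranked["seq_id"].tolist()[-1] == "excl"

    def test_stable_id_tiebreak(self):
        profiles = self._profiles()
        ranked = select_candidates(profiles)
        # identical keys for adj/excl/plain (1 mutation each, no protein info)
        assert ranked["seq_id"].tolist() == sorted(ranked["seq_id"].tolist())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_candidates([])


class TestPackagedFixtures:
    def test_binding_sites_load_and_cover_quoted_residues(self):
        sites = load_packaged_binding_sites()
        assert set(sites.positions("substrate_lipid")) >= {228, 229, 231, 233}
        assert set(sites.positions("substrate_sugar")) == \
            {9, 10, 13, 231, 259, 260, 306, 309, 324, 325, 346, 347}
        assert {10, 13, 260, 306, 346, 347} <= set(sites.positions("atp"))

    def test_annotations_load(self):
        ann = load_packaged_annotations()
        assert ann.element_of(263) == "medium_loop_258_266"
        assert ann.element_of(306) == "alpha_turn_305_308"
        assert ann.domain_of(260) == "B"
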