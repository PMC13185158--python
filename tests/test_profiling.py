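"""Mutation calling, codon-effect classification and composition statistics."""

import numpy as np
import pytest

from varmine.profiling import (AMBIGUOUS, MISSENSE, NONSENSE, SILENT,
                               RegionTable, RegionInterval, call_mutations,
                               classify_change, composition, per_line_rates,
                               premature_stops)
from varmine.records import NUCLEOTIDE, SequenceError, SequenceRecord
from varmine.simulate import GeneratorSpec, generate_repository

from conftest import make_record


class TestComposition:
    def test_equal_bases(self):
        c = composition(make_record("ATGC"))
        assert (c.a, c.c, c.g, c.t) == (1, 1, 1, 1)
        assert c.gc_percent == 50.0
        assert c.at_percent == 50.0

    def test_all_gc(self):
        assert composition(make_record("GGCC")).gc_percent == 100.0

    def test_n_excluded_from_denominator(self):
        c = composition(make_record("GGNN"))
        assert c.gc_percent == 100.0
        assert c.n == 2

    def test_all_n_rejected(self):
        with pytest.raises(SequenceError):
            composition(make_record("NNNN"))

    def test_generator_hits_gc_target(self):
        repo, _ = generate_repository(GeneratorSpec(length_nt=1278,
                                                    gc_target=0.679, seed=5,
                                                    n_variants=1))
        assert abs(composition(repo.reference).gc_percent - 67.9) <= 1.0


class TestChangeClassification:
    def test_exhaustive_twelve_pair_oracle(self):
        purines, pyrimidines = {"A", "G"}, {"C", "T"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                expected = ("transition"
                            if ({ref, alt} <= purines or {ref, alt} <= pyrimidines)
                            else "transversion")
                assert classify_change(ref, alt) == expected

    def test_n_is_ambiguous(self):
        assert classify_change("A", "N") == AMBIGUOUS


class TestCallMutations:
    def test_missense_call(self):
        prof = call_mutations(make_record("ATGGCGCTG", "ref"),
                              make_record("ATGGTGCTG", "q"))
        assert len(prof.mutations) == 1
        m = prof.mutations[0]
        assert (m.pos_nt, m.ref_base, m.alt_base) == (5, "C", "T")
        assert m.change_class == "transition"
        assert m.codon_index == 2
        assert m.effect == MISSENSE
        assert (m.ref_aa, m.alt_aa) == ("A", "V")

    def test_silent_call(self):
        prof = call_mutations(make_record("ATGCTGTAA", "ref"),
                              make_record("ATGCTCTAA", "q"))
        m = prof.mutations[0]
        assert (m.pos_nt, m.ref_base, m.alt_base) == (6, "G", "C")
        assert m.change_class == "transversion"
        assert m.effect == SILENT
        assert m.ref_aa == m.alt_aa == "L"

    def test_nonsense_call(self):
        prof = call_mutations(make_record("ATGTGGCTG", "ref"),
                              make_record("ATGTGACTG", "q"))
        assert prof.mutations[0].effect == NONSENSE

    def test_identical_sequences(self):
        prof = call_mutations(make_record("ATGCTG", "ref"),
                              make_record("ATGCTG", "q"))
        assert prof.mutations == []
        assert prof.identity_percent == 100.0

    def test_matches_bruteforce_same_length(self, rng):
        for _ in range(15):
            n = 60
            ref = "".join(rng.choice(list("ACGT"), size=n))
            qry = list(ref)
            k = int(rng.integers(0, 8))
            positions = rng.choice(n, size=k, replace=False)
            for p in positions:
                choices = [b for b in "ACGT" if b != qry[p]]
                qry[p] = choices[int(rng.integers(0, 3))]
            prof = call_mutations(make_record(ref, "ref"),
                                  make_record("".join(qry), "q"))
            brute = [(i + 1, r, v) for i, (r, v) in enumerate(zip(ref, qry))
                     if r != v]
            assert [(m.pos_nt, m.ref_base, m.alt_base)
                    for m in prof.mutations] == brute

    def test_effect_count_conservation(self, small_repo):
        repo, _ = small_repo
        for rec in repo.members:
            prof = call_mutations(repo.reference, rec)
            counts = prof.effect_counts()
            assert sum(counts.values()) == len(prof.mutations)

    def test_inframe_indel_keeps_effects(self):
        ref = make_record("ATGGCGAAACTGTAA", "ref")
        qry = make_record("ATGGCGCTGTAA", "q")  # clean 3-nt deletion
        prof = call_mutations(ref, qry)
        assert not prof.frame_lost
        assert all(m.effect != AMBIGUOUS for m in prof.mutations)

    def test_frameshift_flags_effects_ambiguous(self):
        ref = make_record("ATGGCGAAACTGGGGTAA", "ref")
        qry = make_record("ATGGCGAACTGGGGTAC", "q")  # 1-nt deletion: frame lost
        prof = call_mutations(ref, qry)
        assert prof.frame_lost
        assert all(m.effect == AMBIGUOUS for m in prof.mutations)

    def test_n_calls_marked_ambiguous(self):
        prof = call_mutations(make_record("ATGCTG", "ref"),
                              make_record("ATGNTG", "q"))
        m = prof.mutations[0]
        assert m.change_class == AMBIGUOUS
        assert m.effect == AMBIGUOUS
        assert prof.base_preference == {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}

    def test_empty_query_rejected(self):
        with pytest.raises(SequenceError):
            SequenceRecord("q", "", NUCLEOTIDE)


class TestRegions:
    def test_interval_lookup_with_precedence(self):
        table = RegionTable([RegionInterval("d", 10, 20, "active_domain"),
                             RegionInterval("e", 15, 30, "envelope")])
        assert table.region_of(12) == "active_domain"
        assert table.region_of(17) == "active_domain"  # overlap: domain wins
        assert table.region_of(25) == "envelope"
        assert table.region_of(40) == "other"

    def test_envelope_flanks(self):
        table = RegionTable.with_envelopes([("A", 100, 160)], flank_nt=30,
                                           seq_length=300)
        assert table.region_of(100) == "active_domain"
        assert table.region_of(80) == "envelope"
        assert table.region_of(185) == "envelope"
        assert table.region_of(50) == "other"

    def test_region_assigned_to_mutations(self):
        table = RegionTable([RegionInterval("d", 4, 6, "active_domain")])
        prof = call_mutations(make_record("ATGGCGCTG", "ref"),
                              make_record("ATGGTGCTG", "q"), regions=table)
        assert prof.mutations[0].region == "active_domain"


class TestPrematureStops:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGTAAGCGTGA", [2]),
        ("ATGGCGTGA", []),          # terminal stop only
        ("ATGTAGTAATGA", [2, 3]),
    ])
    def test_stop_indices(self, seq, expected):
        assert premature_stops(make_record(seq)) == expected

    def test_frame_error(self):
        with pytest.raises(SequenceError):
            premature_stops(make_record("ATGT"))


class TestPerLineRates:
    def test_three_in_one_line(self):
        ref = make_record("A" * 120, "ref")
        qry = list(ref.seq)
        for p in (5, 20, 55):
            qry[p - 1] = "G"
        prof = call_mutations(ref, make_record("".join(qry), "q"))
        rates = per_line_rates(prof)
        assert rates[0] == pytest.approx(5.0)   # 3/60
        assert rates[1] == 0.0

    def test_no_mutations(self):
        ref = make_record("A" * 90, "ref")
        prof = call_mutations(ref, make_record("A" * 90, "q"))
        assert np.all(per_line_rates(prof) == 0.0)

    def test_terminal_short_line_uses_true_length(self):
        ref = make_record("A" * 78, "ref")  # 60 + 18
        qry = list(ref.seq)
        qry[70] = "G"
        prof = call_mutations(ref, make_record("".join(qry), "q"))
        rates = per_line_rates(prof)
        assert len(rates) == 2
        assert rates[1] == pytest.approx(100.0 / 18.0)

    def test_bad_line_length(self):
        ref = make_record("A" * 60, "ref")
        prof = call_mutations(ref, make_record("A" * 60, "q"))
        with pytest.raises(ValueError):
            per_line_rates(prof, 0)
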