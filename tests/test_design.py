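import random

import pytest

from oracles import brute_force_duplex_run, hand_summed_tm
from specprime.design import (
    DesignConfig,
    cross_dimer_score,
    enumerate_candidates,
    melting_temperature,
    pair_and_rank,
    specificity_profile,
    structure_scores,
    validate_candidate,
)
from specprime.profile import (
    alignment_from_rows,
    hypervariable_windows,
    site_profile,
)
from specprime.seqio import reverse_complement


class TestMeltingTemperature:
    def test_matches_hand_summed_oracle(self):
        """NN summation equals an independently re-typed term-by-term oracle
        to 0.01 degC on random 20-mers."""
        rng = random.Random(99)
        for _ in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(20))
            assert melting_temperature(seq) == pytest.approx(
                hand_summed_tm(seq), abs=0.01)

    def test_matches_published_parameter_oracle_across_conditions(self):
        rng = random.Random(100)
        for _ in range(50):
            n = rng.randint(8, 30)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            salt = rng.choice([25.0, 50.0, 100.0])
            conc = rng.choice([200.0, 500.0, 1000.0])
            assert melting_temperature(seq, salt, conc) == pytest.approx(
                hand_summed_tm(seq, salt, conc), abs=0.01)

    def test_biopython_independent_cross_check(self):
        """Same unified table + entropy salt correction in Biopython agrees."""
        from Bio.SeqUtils.MeltingTemp import DNA_NN3, Tm_NN
        rng = random.Random(7)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 28)))
            ref = Tm_NN(seq, nn_table=DNA_NN3, Na=50, dnac1=250, dnac2=250,
                        saltcorr=5)
            assert melting_temperature(seq) == pytest.approx(ref, abs=0.01)

    def test_at_duplex_melts_below_gc_duplex(self):
        assert melting_temperature("ATATATATATATATATAT") < \
            melting_temperature("GCGCGCGCGCGCGCGCGC")

    def test_reverse_complement_symmetry(self):
        rng = random.Random(13)
        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(20))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(reverse_complement(seq)), abs=1e-6)

    def test_rejects_short_or_ambiguous(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGNACGT")


class TestStructureScores:
    def test_homopolymer_has_no_structure(self):
        assert structure_scores("AAAAAAAAAAAAAAAAAA") == (0, 0)

    def test_palindromic_duplex_self_dimer(self):
        hairpin, self_dimer = structure_scores("GGGGGGGGCCCCCCCC")
        assert self_dimer == 16

    def test_constructed_stem_loop(self):
        hairpin, _ = structure_scores("GCGCGC" + "TTTT" + "GCGCGC")
        assert hairpin == 6

    def test_loop_shorter_than_three_not_a_hairpin(self):
        # complementary arms but only a 2-nt loop between them
        hairpin, _ = structure_scores("GGGGGG" + "TT" + "CCCCCC")
        assert hairpin < 6

    def test_self_dimer_equals_brute_force(self):
        rng = random.Random(55)
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 24)))
            _, self_dimer = structure_scores(seq)
            assert self_dimer == brute_force_duplex_run(seq, seq)


class TestCrossDimer:
    def test_non_complementary_oligos_score_zero(self):
        assert cross_dimer_score("AAAAAAAA", "CCCCCCCC") == 0

    def test_perfect_duplex_scores_full_length(self):
        rng = random.Random(8)
        for _ in range(20):
            s = "".join(rng.choice("ACGT") for _ in range(20))
            assert cross_dimer_score(s, reverse_complement(s)) == 20

    def test_equals_brute_force_scan(self):
        rng = random.Random(56)
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(20))
            b = "".join(rng.choice("ACGT") for _ in range(20))
            assert cross_dimer_score(a, b) == brute_force_duplex_run(a, b)


def _diag_alignment():
    """20-column alignment: col 10 diagnostic for S, col 18 diagnostic for S."""
    t = "ACGGATCCTAGCATGGATCA"
    o = t[:9] + "G" + t[10:17] + "G" + t[18:]
    return alignment_from_rows([
        ("s1", "S", t), ("u1", "U", o), ("v1", "V", o),
    ])


class TestSpecificityProfile:
    def test_conserved_region_has_no_specificity(self, family_alignment):
        from specprime.design import PrimerCandidate
        # copy a conserved span: find 20 consecutive monomorphic columns
        prof = site_profile(family_alignment)
        poly = set(prof.polymorphic_coords)
        start = next(s for s in range(1, family_alignment.n_columns - 20)
                     if not any(c in poly for c in range(s, s + 20)))
        seq = family_alignment.rows[0][2][start - 1: start + 19]
        cand = PrimerCandidate(
            sequence=seq, orientation="forward",
            target_species=family_alignment.rows[0][1],
            alignment_span=(start, start + 19), tm=55.0, gc=40.0,
            diagnostic_offsets=(), hairpin_score=0, self_dimer_score=0)
        out = specificity_profile(cand, family_alignment)
        assert out.nontarget_min_mismatches == 0
        assert out.nontarget_3prime_mismatch is False

    def test_fields_equal_brute_force_comparison(self, family_alignment):
        """Worst-case mismatch aggregates equal a direct per-row recount."""
        from specprime.design import PrimerCandidate
        rng = random.Random(21)
        config = DesignConfig()
        rows = family_alignment.rows
        for _ in range(50):
            start = rng.randint(1, family_alignment.n_columns - 21)
            end = start + 19
            orientation = rng.choice(["forward", "reverse"])
            target = rng.choice(rows)[1]
            plus = next(seq for _, sp, seq in rows if sp == target)[start - 1: end]
            primer = plus if orientation == "forward" else reverse_complement(plus)
            cand = PrimerCandidate(
                sequence=primer, orientation=orientation, target_species=target,
                alignment_span=(start, end), tm=55.0, gc=40.0,
                diagnostic_offsets=(), hairpin_score=0, self_dimer_score=0)
            out = specificity_profile(cand, family_alignment, config)
            w = config.diagnostic_3prime_window
            totals, flags = [], []
            for _, sp, seq in rows:
                if sp == target:
                    continue
                mm = [seq[c - 1] != plus[c - start] or seq[c - 1] not in "ACGT"
                      for c in range(start, end + 1)]
                totals.append(sum(mm))
                window = mm[-w:] if orientation == "forward" else mm[:w]
                flags.append(any(window))
            assert out.nontarget_min_mismatches == min(totals)
            assert out.nontarget_3prime_mismatch == all(flags)


class TestEnumerateCandidates:
    def test_no_diagnostic_sites_warns_and_returns_empty(self):
        aln = alignment_from_rows([
            ("a", "A", "ACGTACGTACGTACGTACGTACGT"),
            ("b", "B", "ACGTACGTACGTACGTACGTACGT"),
        ])
        with pytest.warns(UserWarning, match="no diagnostic sites"):
            out = enumerate_candidates(aln, "A", windows=[], config=DesignConfig())
        assert out == []

    def test_candidates_respect_planted_anchor(self):
        """With one diagnostic column and strict 3' anchoring, every candidate
        terminates on that column; the set equals brute-force enumeration."""
        aln = _diag_alignment()
        prof = site_profile(aln)
        config = DesignConfig(
            primer_length_range=(8, 10), tm_range=(-50.0, 90.0),
            gc_range=(0.0, 100.0), min_nontarget_mismatches=1,
            max_hairpin=10, max_self_dimer=20, restrict_to_windows=False)
        cands = enumerate_candidates(aln, "S", None, config, profile=prof)
        assert cands
        for c in cands:
            assert 0 in c.diagnostic_offsets
            assert c.three_prime_column in (10, 18)
        # brute force: all spans x orientations, same filters
        expected = set()
        diag = {10, 18}
        seq = aln.rows[0][2]
        for start in range(1, 21):
            for length in (8, 9, 10):
                end = start + length - 1
                if end > 20:
                    continue
                for orientation in ("forward", "reverse"):
                    three_prime = end if orientation == "forward" else start
                    if three_prime not in diag:
                        continue
                    expected.add((orientation, start, end))
        assert {(c.orientation, *c.alignment_span) for c in cands} == expected

    def test_emitted_candidates_pass_independent_validation(
            self, family_alignment, family_profile):
        """Closure: every emitted candidate re-validates against the config."""
        config = DesignConfig()
        wins = hypervariable_windows(family_profile)
        species = family_alignment.species[0]
        cands = enumerate_candidates(family_alignment, species, wins, config,
                                     profile=family_profile)
        assert cands
        for c in cands:
            assert validate_candidate(c, config)

    def test_reverse_candidates_are_revcomp_of_consensus(
            self, family_alignment, family_profile):
        from specprime.profile import species_consensus
        config = DesignConfig()
        wins = hypervariable_windows(family_profile)
        species = family_alignment.species[1]
        cons = species_consensus(family_alignment, species)
        for c in enumerate_candidates(family_alignment, species, wins, config,
                                      profile=family_profile):
            span = cons[c.alignment_span[0] - 1: c.alignment_span[1]]
            if c.orientation == "reverse":
                assert c.sequence == reverse_complement(span)
            else:
                assert c.sequence == span


class TestPairAndRank:
    def test_pairs_respect_amplicon_range_and_span_order(self):
        n = 700
        t = ("ACGGATCCTAGCATGGATCAT" * 40)[:n]
        o = t[:19] + "C" + t[20:660] + ("C" if t[660] != "C" else "G") + t[661:]
        aln = alignment_from_rows([("s1", "S", t), ("u1", "U", o), ("v1", "V", o)])
        prof = site_profile(aln)
        config = DesignConfig(
            primer_length_range=(18, 20), amplicon_length_range=(550, 800),
            tm_range=(-50.0, 90.0), max_pair_tm_diff=100.0,
            gc_range=(0.0, 100.0), min_nontarget_mismatches=1,
            max_hairpin=10, max_self_dimer=20, max_cross_dimer=20,
            restrict_to_windows=False, top_n=100)
        cands = enumerate_candidates(aln, "S", None, config, profile=prof)
        forwards = [c for c in cands if c.orientation == "forward"]
        reverses = [c for c in cands if c.orientation == "reverse"]
        assert forwards and reverses
        pairs = pair_and_rank(cands, aln, config)
        assert pairs
        for p in pairs:
            assert 550 <= p.predicted_amplicon_length <= 800
            assert p.forward.alignment_span[1] < p.reverse.alignment_span[0]

    def test_top_n_limits_output(self, family_alignment, family_profile):
        config = DesignConfig()
        wins = hypervariable_windows(family_profile)
        species = family_alignment.species[0]
        cands = enumerate_candidates(family_alignment, species, wins, config,
                                     profile=family_profile)
        pairs = pair_and_rank(cands, family_alignment, config, top_n=3)
        assert len(pairs) <= 3
        assert [p.rank for p in pairs] == list(range(1, len(pairs) + 1))

    def test_ranking_invariant_under_input_permutation(
            self, family_alignment, family_profile):
        config = DesignConfig()
        wins = hypervariable_windows(family_profile)
        species = family_alignment.species[2]
        cands = enumerate_candidates(family_alignment, species, wins, config,
                                     profile=family_profile)
        reference = pair_and_rank(cands, family_alignment, config)
        rng = random.Random(17)
        for _ in range(3):
            shuffled = cands[:]
            rng.shuffle(shuffled)
            assert pair_and_rank(shuffled, family_alignment, config) == reference

    def test_empty_candidates_empty_result(self, family_alignment):
        assert pair_and_rank([], family_alignment, DesignConfig()) == []


class TestDesignConfig:
    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError, match="tm_range"):
            DesignConfig(tm_range=(65.0, 55.0))

    def test_config_file_round_trip(self, tmp_path):
        path = tmp_path / "design.cfg"
        path.write_text(
            "primer_length_range = 20, 26\n"
            "tm_range = 52, 60  # degC\n"
            "strict_terminal = false\n"
            "top_n = 5\n"
        )
        config = DesignConfig.from_file(path)
        assert config.primer_length_range == (20, 26)
        assert config.tm_range == (52.0, 60.0)
        assert config.strict_terminal is False
        assert config.top_n == 5

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "design.cfg"
        path.write_text("primer_len = 18,24\n")
        with pytest.raises(ValueError, match="unknown key"):
            DesignConfig.from_file(path)
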