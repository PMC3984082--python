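"""Unit tests for the SNP-string decomposition and phasing passes."""

import pytest

from snpstring import phasing as ph


class TestComplement:
    def test_single_het_subtraction(self):
        assert ph.complement("20000022221", "10000011110") == "10000011111"

    def test_all_zero_identity(self):
        assert ph.complement("0" * 11, "0" * 11) == "0" * 11

    def test_negative_entry_is_illegitimate(self):
        assert ph.complement("02202200000", "10000000000") is None

    def test_entry_two_is_illegitimate(self):
        # leaving a 2 in the residual means the "haplotype" was not binary
        assert ph.complement("22000000000", "00000000000") is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            ph.complement("202", "01")


class TestBruteForceEnumeration:
    def test_homozygous_vector_has_single_pair(self):
        pairs = ph.enumerate_pairs_bruteforce("02202200000")
        assert pairs == {("01101100000", "01101100000")}

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_pair_count_is_2_to_k_minus_1(self, k):
        v = "1" * k + "0" * (11 - k)
        assert len(ph.enumerate_pairs_bruteforce(v)) == 2 ** (k - 1)

    def test_conflict_vector_contains_both_published_pairs(self):
        pairs = ph.enumerate_pairs_bruteforce("11111011110")
        assert len(pairs) == 256
        assert ("01111000000", "10000011110") in pairs  # a8-a7
        assert ("01111001110", "10000010000") in pairs  # a13-a20

    def test_guard_refuses_large_het_count(self):
        with pytest.raises(ValueError, match="het sites"):
            ph.enumerate_pairs_bruteforce("1" * 21)

    def test_every_pair_sums_to_vector(self):
        v = "21011020110"
        for h1, h2 in ph.enumerate_pairs_bruteforce(v):
            assert ph.complement(v, h1) == h2


class TestFindUnambiguous:
    def test_homozygote_yields_halved_string(self):
        inv = ph.find_unambiguous(["02202200000"])
        assert inv.strings == {"01101100000"}

    def test_single_het_yields_both_strings(self):
        inv = ph.find_unambiguous(["20000022221"])
        assert inv.strings == {"10000011110", "10000011111"}

    def test_multi_het_cohort_yields_nothing(self):
        inv = ph.find_unambiguous(["11000000000", "20110000000"])
        assert inv.strings == set()

    def test_statuses_are_unambiguous(self):
        inv = ph.find_unambiguous(["02202200000", "20000022221"])
        assert set(inv.status.values()) == {"unambiguous"}


class TestDecompose:
    def test_conflicted_against_published_inventory(self, drb1_strings):
        strings = frozenset(drb1_strings.values())
        rec = ph.decompose("11111011110", strings)
        assert rec.classification == "conflicted"
        assert set(rec.candidates) == {
            ("01111000000", "10000011110"),
            ("01111001110", "10000010000"),
        }

    def test_homozygote_with_listed_half_is_unique(self):
        rec = ph.decompose("02202200000", frozenset({"01101100000"}))
        assert rec.classification == "unique"
        assert rec.candidates == (("01101100000", "01101100000"),)

    def test_empty_inventory_is_unresolved(self):
        rec = ph.decompose("11000000000", frozenset())
        assert rec.classification == "unresolved"

    def test_single_novel_completion_is_indeterminate_unique(self):
        rec = ph.decompose("21000000000", frozenset({"10000000000"}))
        assert rec.classification == "indeterminate-unique"
        assert rec.candidates == (("10000000000", "11000000000"),)

    def test_several_novel_completions_are_indeterminate_conflicted(self):
        strings = frozenset({"10000000000", "01000000000"})
        rec = ph.decompose("11100000000", strings)
        assert rec.classification == "indeterminate-conflicted"
        assert len(rec.candidates) == 2


class TestIterateIdentification:
    def test_promotes_unique_novel_complement(self):
        # homozygote seeds 10000000000; (21100000000) then forces 11100000000
        inv, rounds = ph.iterate_identification(["20000000000", "21100000000"])
        assert "11100000000" in inv.strings
        assert inv.status["11100000000"] == "identified"
        assert rounds == 1

    def test_fully_explained_cohort_is_a_fixed_point(self):
        inv, rounds = ph.iterate_identification(["02202200000", "20000022221"])
        assert rounds == 0

    def test_iteration_cap_limits_promotion_chain(self):
        # each vector's unique completion needs the string promoted by the
        # previous round, so identification takes 5 rounds uncapped
        vectors = [
            "20000000000",   # seeds 10000000000
            "21100000000",   # -> 11100000000
            "22211000000",   # -> 11111000000
            "22222110000",   # -> 11111110000
            "22222221100",   # -> 11111111100
            "22222222211",   # -> 11111111111
        ]
        inv_capped, rounds = ph.iterate_identification(
            vectors, ph.AlgorithmConfig(iteration_cap=2)
        )
        inv_full, rounds_full = ph.iterate_identification(
            vectors, ph.AlgorithmConfig(iteration_cap=10)
        )
        assert rounds == 2
        assert rounds_full == 5
        assert inv_capped.strings < inv_full.strings


class TestEstimateFrequencies:
    def test_counts_non_conflicted_haplotypes(self):
        recs = [
            ph.DecompositionRecord("s1", "22000000000", "unambiguous",
                                   selected=("11000000000", "11000000000")),
            ph.DecompositionRecord("s2", "21000000000", "unique",
                                   (("10000000000", "11000000000"),)),
        ]
        inv = ph.HaplotypeInventory(status={
            "11000000000": "unambiguous",
            "10000000000": "unambiguous",
            "00000000001": "novel",
        })
        ph.estimate_frequencies(recs, inv)
        assert inv.frequencies["11000000000"] == pytest.approx(0.75)
        assert inv.frequencies["10000000000"] == pytest.approx(0.25)
        assert inv.n_observations == 4

    def test_unobserved_string_gets_nominal_floor(self):
        recs = [
            ph.DecompositionRecord("s1", "22000000000", "unambiguous",
                                   selected=("11000000000", "11000000000")),
        ]
        inv = ph.HaplotypeInventory(status={
            "11000000000": "unambiguous", "00000000001": "novel",
        })
        ph.estimate_frequencies(recs, inv)
        assert inv.frequencies["00000000001"] == pytest.approx(0.5 / 2)
        assert inv.nominal_frequency == pytest.approx(0.25)

    def test_observed_frequencies_sum_to_one(self, null_results):
        inv = null_results.inventory
        observed = [
            f for f in inv.frequencies.values() if f > inv.nominal_frequency
        ]
        assert sum(observed) == pytest.approx(1.0)

    def test_no_non_conflicted_records_raises(self):
        inv = ph.HaplotypeInventory(status={"10000000000": "identified"})
        with pytest.raises(ValueError, match="H = 0"):
            ph.estimate_frequencies([], inv)


class TestResolveConflicts:
    def test_most_likely_pair_wins(self, drb1_strings, drb1_control_frequencies):
        inv = ph.HaplotypeInventory(
            status={s: "identified" for s in drb1_strings.values()},
            frequencies=drb1_control_frequencies,
        )
        rec = ph.decompose("11111011110", inv)
        resolved = ph.resolve_conflicts(rec, inv)
        assert set(resolved.selected) == {
            drb1_strings["a7"], drb1_strings["a8"],
        }
        assert resolved.likelihood == pytest.approx(0.16 * 0.06)

    def test_exact_tie_breaks_lexicographically(self):
        strings = ["00000", "01000", "10000", "11000"]
        inv = ph.HaplotypeInventory(
            status={s: "identified" for s in strings},
            frequencies={s: 0.25 for s in strings},
        )
        rec = ph.decompose("11000", inv)
        assert set(rec.candidates) == {
            ("00000", "11000"), ("01000", "10000"),
        }
        resolved = ph.resolve_conflicts(rec, inv)
        # equal products: the lexicographically smaller concatenation wins
        assert resolved.selected == ("00000", "11000")

    def test_single_candidate_is_kept(self):
        inv = ph.HaplotypeInventory(
            status={"10000000000": "identified"},
            frequencies={"10000000000": 1.0},
        )
        rec = ph.decompose("20000000000", inv)
        resolved = ph.resolve_conflicts(rec, inv)
        assert resolved.selected == ("10000000000", "10000000000")

    def test_homozygous_pair_uses_squared_frequency(self):
        inv = ph.HaplotypeInventory(
            status={"11000000000": "identified"},
            frequencies={"11000000000": 0.3},
        )
        rec = ph.decompose("22000000000", inv)
        resolved = ph.resolve_conflicts(rec, inv)
        assert resolved.likelihood == pytest.approx(0.09)


class TestCompleteListAndPruning:
    def test_never_selected_strings_are_pruned(self):
        # one subject forces 11000000000 homozygote; another is explained
        # by it plus a novel; spurious candidates must vanish.
        vectors = ["22000000000", "22000000000", "21100000000"]
        result = ph.phase_vectors(vectors)
        for h in result.inventory.status:
            carried = any(
                r.selected is not None and h in r.selected
                for r in result.records
            )
            assert carried, f"{h} survived pruning but is never selected"

    def test_frequent_novel_string_is_promoted(self):
        # the novel complement 10100000000 appears in many subjects: well
        # above the 1% promotion threshold.
        vectors = ["22000000000"] * 5 + ["21100000000"] * 5
        result = ph.phase_vectors(vectors)
        assert result.inventory.status["10100000000"] == "identified"

    def test_two_novel_genotype_is_unresolved(self):
        vectors = ["22000000000", "00000001111"]
        result = ph.phase_vectors(vectors)
        by_vec = {r.vector: r for r in result.records}
        assert by_vec["00000001111"].classification == "unresolved"
        assert by_vec["00000001111"].selected is None


class TestReassessRare:
    def test_m_equal_one_is_a_noop(self):
        vectors = ["22000000000"] * 3 + ["21100000000"]
        cfg = ph.AlgorithmConfig(rare_threshold=1)
        result = ph.phase_vectors(vectors, config=cfg)
        base = ph.phase_vectors(vectors)
        assert result.pairs == base.pairs

    def test_rare_reassessment_prefers_commoner_alternative(self):
        # a conflicted vector whose rare-string reading would otherwise
        # survive must end up on the commoner identified pair
        vectors = (
            ["02202200000"] * 30          # a2 homozygotes
            + ["20000022220"] * 30        # a7 homozygotes
            + ["22222200000"] * 4         # forces 11111100000
            + ["11111011110"]             # a7+a8-style conflict analogue
        )
        result = ph.phase_vectors(vectors)
        rec = next(r for r in result.records if r.vector == "11111011110")
        assert rec.selected is not None
        h1, h2 = rec.selected
        assert ph.complement(rec.vector, h1) == h2


class TestPhaseVectors:
    def test_all_homozygote_cohort_recovered_exactly(self):
        vectors = ["02202200000", "22000022220", "00000000000"]
        result = ph.phase_vectors(vectors)
        assert result.classification_counts == {"unambiguous": 3}
        for rec in result.records:
            h1, h2 = rec.selected
            assert h1 == h2
            assert ph.complement(rec.vector, h1) == h2

    def test_sum_conservation_for_every_resolved_subject(self, null_results):
        for rec in null_results.records:
            if rec.selected is not None:
                h1, h2 = rec.selected
                assert ph.complement(rec.vector, h1) == h2

    def test_subject_order_does_not_matter(self, null_cohort):
        from snpstring import genotype_io as gio

        svs, _ = gio.build_subject_vectors(null_cohort.matrix)
        vectors = [s.codes for s in svs]
        ids = [s.subject_id for s in svs]
        fwd = ph.phase_vectors(vectors, ids)
        rev = ph.phase_vectors(vectors[::-1], ids[::-1])
        assert fwd.pairs == rev.pairs
        assert fwd.inventory.status == rev.inventory.status
        assert fwd.inventory.frequencies == rev.inventory.frequencies

    def test_classification_accounting(self, null_results):
        counts = null_results.result.classification_counts
        assert sum(counts.values()) == len(null_results.records)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            ph.phase_vectors([])


class TestAlgorithmConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"iteration_cap": 0},
            {"rare_threshold": 0},
            {"promotion_threshold": 0.0},
            {"promotion_threshold": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ph.AlgorithmConfig(**kwargs)
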