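import dataclasses
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mshrna.sequence_io import Alphabet, NucleotideSequence, _revcomp_str
from mshrna.sirna_design import (
    CORE_LEN,
    FOOTPRINT_LEN,
    GUIDE_5,
    SENSE_5,
    STRAND_LEN,
    DesignError,
    NearestNeighborTable,
    SirnaCandidate,
    apply_filters,
    end_free_energy,
    enumerate_candidates,
    score_asymmetry,
    select_by_position,
    select_top_nonoverlapping,
)

rna = lambda s, i="t": NucleotideSequence(id=i, residues=s, alphabet=Alphabet.RNA)
rna_core = st.text(alphabet="ACGU", min_size=CORE_LEN, max_size=CORE_LEN)


class TestNearestNeighborTable:
    def test_shipped_table_shape(self, nn_table):
        assert len(nn_table.stacks) == 16
        assert nn_table.init_penalty == pytest.approx(4.09)
        assert "1998" in nn_table.source_label

    def test_watson_crick_symmetry(self, nn_table):
        for stack, value in nn_table.stacks.items():
            mirror = _revcomp_str(stack, Alphabet.RNA)
            assert value == pytest.approx(nn_table.stacks[mirror], abs=1e-12)

    def test_symmetry_violation_rejected(self, nn_table):
        broken = dict(nn_table.stacks)
        broken["AA"] = broken["AA"] + 0.5  # mirror UU now disagrees
        with pytest.raises(ValueError, match="symmetry"):
            NearestNeighborTable(broken, 4.09, "broken")

    def test_checksum_is_content_addressed(self, nn_table):
        same = NearestNeighborTable(dict(nn_table.stacks), 4.09, "other label")
        assert same.checksum() == nn_table.checksum()


class TestEnumeration:
    @pytest.mark.parametrize("length,expected", [(23, 1), (25, 3), (60, 38)])
    def test_candidate_count(self, length, expected):
        target = rna("ACGU" * 15)
        target = rna(target.residues[:length])
        cands = enumerate_candidates(target)
        assert len(cands) == expected
        assert [c.start for c in cands] == list(range(expected))

    def test_strand_geometry_against_slow_rederivation(self, fixture_300):
        """Strands match an independent window-by-window reconstruction."""
        t = fixture_300.residues
        for c in enumerate_candidates(fixture_300):
            window = t[c.start : c.start + FOOTPRINT_LEN]
            assert len(window) == FOOTPRINT_LEN
            assert c.sense_strand == window[2:]
            assert c.guide_strand == _revcomp_str(window[:21], Alphabet.RNA)
            assert len(c.sense_strand) == len(c.guide_strand) == STRAND_LEN
            # 19-bp core with 2-nt 3' overhangs on both strands
            assert c.sense_strand[:CORE_LEN] == _revcomp_str(
                c.guide_strand, Alphabet.RNA
            )[2:]
            assert c.guide_strand[:CORE_LEN] == _revcomp_str(
                c.sense_strand, Alphabet.RNA
            )[2:]

    def test_homopolymer_forces_both_strands(self):
        cands = enumerate_candidates(rna("A" * 23))
        assert cands[0].sense_strand == "A" * 21
        assert cands[0].guide_strand == "U" * 21

    def test_too_short_rejected(self):
        with pytest.raises(DesignError, match="too short"):
            enumerate_candidates(rna("A" * 22))

    def test_dna_rejected(self):
        dna = NucleotideSequence(id="d", residues="A" * 23, alphabet=Alphabet.DNA)
        with pytest.raises(DesignError, match="RNA"):
            enumerate_candidates(dna)


# hand-summed from the shipped Xia 1998 table, window 5 bp (4 stacks)
HAND_SUMMED = [
    ("GCGCAUAUGGCCAAUUGCA", -11.31, -8.57),
    ("AUAUAUAUAUAUAUAUAUA", -4.86, -4.86),
    ("GGGCCAUUAAGCUAGCGUA", -13.20, -9.35),
]


class TestEndFreeEnergy:
    @pytest.mark.parametrize("core,dg_sense,dg_guide", HAND_SUMMED)
    def test_hand_summed_windows(self, nn_table, core, dg_sense, dg_guide):
        assert end_free_energy(core, SENSE_5, 5, nn_table) == pytest.approx(
            dg_sense, abs=1e-9
        )
        assert end_free_energy(core, GUIDE_5, 5, nn_table) == pytest.approx(
            dg_guide, abs=1e-9
        )

    def test_window_two_is_one_stack(self, nn_table):
        assert end_free_energy("GCAUA", SENSE_5, 2, nn_table) == pytest.approx(
            nn_table.stacks["GC"]
        )
        assert end_free_energy("GCAUA", GUIDE_5, 2, nn_table) == pytest.approx(
            nn_table.stacks["UA"]
        )

    def test_self_reverse_complement_core_is_symmetric(self, nn_table):
        core = "GGAUCGAUCC"  # its own RNA reverse complement
        assert core == _revcomp_str(core, Alphabet.RNA)
        for w in range(2, len(core) + 1):
            assert end_free_energy(core, SENSE_5, w, nn_table) == pytest.approx(
                end_free_energy(core, GUIDE_5, w, nn_table), abs=1e-12
            )

    def test_window_bounds(self, nn_table):
        with pytest.raises(DesignError, match="window too small"):
            end_free_energy("GCGC", SENSE_5, 1, nn_table)
        with pytest.raises(DesignError, match="exceeds"):
            end_free_energy("GCGC", SENSE_5, 5, nn_table)


def _scored(target_residues, start=0, window=5, table=None):
    cand = enumerate_candidates(rna(target_residues))[start]
    return score_asymmetry(cand, window, table)


class TestAsymmetry:
    @given(core=rna_core)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_strand_swap(self, nn_table, core):
        """Swapping sense/guide labels negates the asymmetry exactly.

        Relabelling the strands turns the duplex core into its reverse
        complement and exchanges the two 5' ends.
        """
        swapped = _revcomp_str(core, Alphabet.RNA)
        asym = lambda c: end_free_energy(c, GUIDE_5, 5, nn_table) - end_free_energy(
            c, SENSE_5, 5, nn_table
        )
        assert asym(swapped) == pytest.approx(-asym(core), abs=1e-12)

    def test_au_guide_end_vs_gc_sense_end_is_positive(self, nn_table):
        # sense-5' end GC-rich (strong), guide-5' end AU-rich (weak)
        target = "GGCGC" + "ACGUACGUACGUA" + "AUAUA"
        cand = _scored(target, table=nn_table)
        assert cand.asymmetry > 0

    def test_terminal_gc_at_guide_end_decreases_asymmetry(self, nn_table):
        """Stabilizing the guide-5' end strictly lowers the score."""
        prefix = "ACGUACGUACGUACGUACG"  # target[0:19]; core = target[2:21]
        weak = _scored(prefix + "UAGU", table=nn_table)
        strong = _scored(prefix + "GCGU", table=nn_table)
        assert weak.core[-2:] == "UA" and strong.core[-2:] == "GC"
        assert strong.asymmetry < weak.asymmetry

    def test_scores_are_filled(self, fixture_300, nn_table):
        cand = score_asymmetry(
            enumerate_candidates(fixture_300)[0], 5, nn_table
        )
        assert cand.asymmetry == pytest.approx(
            cand.dg_guide_end - cand.dg_sense_end
        )


class TestFilters:
    def test_all_g_core_fires_every_rule(self, default_config):
        cand = enumerate_candidates(rna("G" * 23))[0]
        flagged = apply_filters(cand, default_config)
        assert {"gc_out_of_range", "homopolymer", "g_run"} <= flagged.filter_flags

    def test_balanced_core_passes(self, default_config):
        cand = enumerate_candidates(rna("ACGUACGUACGUACGUACGUACG"))[0]
        assert apply_filters(cand, default_config).filter_flags == frozenset()

    def test_five_base_run_is_homopolymer(self, default_config):
        target = "ACGUACG" + "AAAAA" + "CGUACGUACGC"
        cand = enumerate_candidates(rna(target))[0]
        assert "homopolymer" in apply_filters(cand, default_config).filter_flags

    def test_four_g_run_flagged_in_either_strand(self, default_config):
        target = "ACGUAC" + "GGGG" + "AUAUCGUACGUAC"
        cand = enumerate_candidates(rna(target))[0]
        assert "g_run" in apply_filters(cand, default_config).filter_flags


class TestSelectByPosition:
    def test_definition_and_boundary(self, fixture_300):
        cands = enumerate_candidates(fixture_300)
        L = len(fixture_300)
        assert select_by_position(cands, 0).sense_strand == fixture_300[2:23]
        assert select_by_position(cands, L - 23).start == L - 23

    def test_off_by_one_guard(self, fixture_300):
        cands = enumerate_candidates(fixture_300)
        with pytest.raises(DesignError, match="position out of range"):
            select_by_position(cands, len(fixture_300) - 22)


def _synthetic(start, asymmetry, target="t"):
    return SirnaCandidate(
        target_id=target,
        start=start,
        sense_strand="ACGUACGUACGUACGUACGUA",
        guide_strand="UACGUACGUACGUACGUACGU",
        dg_sense_end=-5.0,
        dg_guide_end=-5.0 + asymmetry,
        asymmetry=asymmetry,
    )


def _brute_force_best(cands, n):
    """Exhaustive search over disjoint subsets, maximizing sorted scores."""
    def disjoint(subset):
        ivs = sorted((c.start, c.start + FOOTPRINT_LEN) for c in subset)
        return all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    best = []
    key = lambda subset: sorted((c.asymmetry for c in subset), reverse=True)
    for size in range(min(n, len(cands)), 0, -1):
        feasible = [
            set(sub)
            for sub in itertools.combinations(cands, size)
            if disjoint(sub)
        ]
        if feasible:
            return max(feasible, key=lambda s: key(s))
    return set(best)


class TestSelection:
    def test_overlap_excludes_all_but_best(self):
        cands = [_synthetic(s, score) for s, score in [(0, 1.0), (5, 3.0), (10, 2.0)]]
        picked = select_top_nonoverlapping(cands, 3)
        assert [c.start for c in picked] == [5]

    def test_disjoint_pair_returned_regardless_of_order(self):
        cands = [_synthetic(23, 0.5), _synthetic(0, 2.0)]
        picked = select_top_nonoverlapping(cands, 2)
        assert sorted(c.start for c in picked) == [0, 23]

    def test_tie_break_prefers_smaller_start(self):
        cands = [_synthetic(40, 1.0), _synthetic(0, 1.0)]
        picked = select_top_nonoverlapping(cands, 1)
        assert picked[0].start == 0

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_greedy_matches_exhaustive_when_top_n_disjoint(self, data):
        m = data.draw(st.integers(3, 10))
        starts = data.draw(
            st.lists(st.integers(0, 200), min_size=m, max_size=m, unique=True)
        )
        scores = data.draw(
            st.lists(
                st.floats(-10, 10, allow_nan=False), min_size=m, max_size=m,
                unique=True,
            )
        )
        n = data.draw(st.integers(1, 3))
        cands = [_synthetic(s, a) for s, a in zip(starts, scores)]
        picked = select_top_nonoverlapping(cands, n)
        ivs = sorted((c.start, c.start + FOOTPRINT_LEN) for c in picked)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        top = sorted(cands, key=lambda c: (-c.asymmetry, c.start))[:n]
        top_ivs = sorted((c.start, c.start + FOOTPRINT_LEN) for c in top)
        if all(a[1] <= b[0] for a, b in zip(top_ivs, top_ivs[1:])):
            assert set(picked) == _brute_force_best(cands, n)

    def test_filtered_candidates_are_ignored(self, default_config):
        flagged = dataclasses.replace(
            _synthetic(0, 99.0), filter_flags=frozenset({"g_run"})
        )
        picked = select_top_nonoverlapping([flagged, _synthetic(30, 1.0)], 1)
        assert picked[0].start == 30

    def test_no_passing_candidates_is_an_error(self):
        flagged = dataclasses.replace(
            _synthetic(0, 1.0), filter_flags=frozenset({"gc_out_of_range"})
        )
        with pytest.raises(DesignError, match="no designable siRNA"):
            select_top_nonoverlapping([flagged], 1)

    def test_unsupported_n(self):
        with pytest.raises(DesignError, match="unsupported"):
            select_top_nonoverlapping([_synthetic(0, 1.0)], 4)
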