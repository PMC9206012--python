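"""Alignment filtering, pan/core composition, NG86 Ka/Ks, and dating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famscan import (
    AlignmentRecord,
    ParameterError,
    SaturationError,
    SelectionBand,
    SequenceRecord,
    ThresholdProfile,
    WITHIN_SPECIES,
    best_reciprocal_pairs,
    classify_selection,
    divergence_time,
    filter_alignments,
    ng86_kaks,
    pan_core,
    presence_matrix,
)
from famscan.synthetic import generate_alignment_table, generate_paralog_pair

from helpers_oracle import oracle_pair_counts


def rec(identity, length, evalue, q="g", s="a:ctg"):
    return AlignmentRecord(query_id=q, subject_id=s, identity=identity,
                           align_length=length, evalue=evalue)


class TestFilter:
    @pytest.mark.parametrize(
        "identity,length,evalue,kept",
        [
            (99.0, 200, 1.0e-100, True),   # every boundary inclusive
            (98.99, 500, 0.0, False),
            (99.5, 199, 0.0, False),
            (100.0, 1000, 1.1e-100, False),
        ],
    )
    def test_within_species_boundaries(self, identity, length, evalue, kept):
        out = filter_alignments([rec(identity, length, evalue)], WITHIN_SPECIES)
        assert (len(out) == 1) == kept

    def test_idempotent_and_subset(self):
        records = [rec(99.5, 300, 0.0), rec(80, 300, 0.0), rec(99.5, 100, 0.0)]
        once = filter_alignments(records, WITHIN_SPECIES)
        assert filter_alignments(once, WITHIN_SPECIES) == once
        assert set(id(r) for r in once) <= set(id(r) for r in records)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100), st.integers(1, 1000),
                st.floats(0, 1e-50),
            ),
            max_size=30,
        ),
        st.floats(0, 100), st.floats(0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_identity_threshold(self, rows, thr_a, thr_b):
        """Loosening a threshold never removes records."""
        records = [rec(i, l, e) for i, l, e in rows]
        lo, hi = sorted((thr_a, thr_b))
        loose = ThresholdProfile(lo, 1, 1.0)
        tight = ThresholdProfile(hi, 1, 1.0)
        assert set(map(id, filter_alignments(records, tight))) <= \
            set(map(id, filter_alignments(records, loose)))

    def test_synthetic_roundtrip_recovers_presence(self):
        genes = [f"g{i}" for i in range(12)]
        presence = {"A": {"g0", "g1", "g5"}, "B": {"g1", "g2"},
                    "C": {"g1", "g7", "g8", "g9"}}
        records, truth = generate_alignment_table(genes, presence, seed=42)
        kept = filter_alignments(records, WITHIN_SPECIES)
        mat = presence_matrix(kept, assemblies=["A", "B", "C"], genes=genes)
        recovered = {a: set(mat.index[mat[a]]) for a in mat.columns}
        assert recovered == truth.presence


class TestPanCore:
    def test_three_assembly_enumeration(self):
        mat = pd.DataFrame(
            {"A": [True, True, False], "B": [False, True, True],
             "C": [False, True, False]},
            index=["g1", "g2", "g3"],
        )
        pan, core, disp, regions = pan_core(mat)
        assert (pan, core, disp) == (3, 1, 2)
        assert regions["A&B&C"] == 1 and regions["A"] == 1 and regions["B"] == 1
        assert sum(regions.values()) == pan

    def test_identical_sets_pan_equals_core(self):
        mat = pd.DataFrame({"A": [True, True], "B": [True, True]},
                           index=["g1", "g2"])
        pan, core, disp, _ = pan_core(mat)
        assert pan == core == 2 and disp == 0

    def test_single_assembly(self):
        mat = pd.DataFrame({"A": [True, False, True]}, index=list("abc"))
        pan, core, disp, regions = pan_core(mat)
        assert pan == core == 2 and disp == 0 and regions == {"A": 2}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            pan_core(pd.DataFrame())

    def test_pan_core_ordering_invariant(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((20, 3)) < 0.6,
                           index=[f"g{i}" for i in range(20)],
                           columns=list("ABC"))
        pan, core, disp, regions = pan_core(mat)
        per_assembly = mat.sum(axis=0)
        assert pan >= per_assembly.max() >= core
        assert sum(regions.values()) == pan


def nt(seq, seq_id="s"):
    return SequenceRecord(seq_id, seq, "nucleotide")


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_kaks(nt("GGGGGG", "a"), nt("GGGGGG", "b"))
        assert r.ka == 0 and r.ks == 0 and r.ratio is None
        assert r.selection_mode == "undefined"
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(6.0)

    def test_hand_worked_two_glycine_codons(self):
        # GGG vs GGA: third position of Gly is fourfold degenerate
        r = ng86_kaks(nt("GGGGGG", "a"), nt("GGAGGG", "b"))
        assert r.syn_sites == pytest.approx(2.0)
        assert r.nonsyn_sites == pytest.approx(4.0)
        assert r.syn_diffs == pytest.approx(1.0)
        assert r.nonsyn_diffs == pytest.approx(0.0)
        assert r.ks == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-4)
        assert r.ka == 0.0

    def test_fourfold_codon_sequence_site_count(self):
        # all-Gly sequence: exactly one synonymous site per codon
        r = ng86_kaks(nt("GGG" * 30, "a"), nt("GGG" * 30, "b"))
        assert r.syn_sites == pytest.approx(30.0)

    def test_planted_counts_recovered_exactly(self):
        a, b, truth = generate_paralog_pair(300, n_syn=5, n_nonsyn=2, seed=8)
        r = ng86_kaks(a, b)
        assert r.syn_diffs == pytest.approx(truth.n_syn)
        assert r.nonsyn_diffs == pytest.approx(truth.n_nonsyn)

    def test_matches_bruteforce_oracle_on_random_codon_pairs(self, rng):
        from famscan.comparative import _codon_pair_diffs, _codon_site_counts
        from helpers_oracle import oracle_codon_diffs, oracle_codon_sites

        stops = {"TAA", "TAG", "TGA"}
        done = 0
        while done < 200:
            ca = "".join(rng.choice(list("ACGT"), 3))
            cb = "".join(rng.choice(list("ACGT"), 3))
            if ca in stops or cb in stops:
                continue
            assert _codon_site_counts(ca) == pytest.approx(oracle_codon_sites(ca))
            assert _codon_pair_diffs(ca, cb) == pytest.approx(
                oracle_codon_diffs(ca, cb)
            )
            done += 1

    def test_matches_oracle_on_generated_sequence_pair(self):
        a, b, _ = generate_paralog_pair(60, n_syn=6, n_nonsyn=4, seed=17)
        S, N, Sd, Nd = oracle_pair_counts(a.sequence, b.sequence)
        r = ng86_kaks(a, b)
        assert r.syn_sites == pytest.approx(S)
        assert r.nonsyn_sites == pytest.approx(N)
        assert r.syn_diffs == pytest.approx(Sd)
        assert r.nonsyn_diffs == pytest.approx(Nd)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ng86_kaks(nt("GGG", "a"), nt("GGGGGG", "b"))

    def test_internal_stop_rejected(self):
        with pytest.raises(ParameterError):
            ng86_kaks(nt("TAAGGG", "a"), nt("GGGGGG", "b"))

    def test_saturation_raises(self):
        # every codon differs at its fourfold third position -> ps = 1 > 3/4
        a = "GGG" * 10
        b = "GGA" * 10
        with pytest.raises(SaturationError):
            ng86_kaks(nt(a, "a"), nt(b, "b"))


class TestDating:
    def test_zero_ks(self):
        assert divergence_time(0.0) == 0.0

    @pytest.mark.parametrize("ks,expected", [(0.234, 18.0), (0.5291, 40.7)])
    def test_closed_form_values(self, ks, expected):
        assert divergence_time(ks) == pytest.approx(expected, abs=0.05)

    @given(st.floats(0, 2), st.floats(1e-10, 1e-7))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_ks_inverse_in_lambda(self, ks, lam):
        t = divergence_time(ks, lam)
        assert divergence_time(2 * ks, lam) == pytest.approx(2 * t, rel=1e-9)
        assert divergence_time(ks, 2 * lam) == pytest.approx(t / 2, rel=1e-9)

    def test_negative_ks_rejected(self):
        with pytest.raises(ParameterError):
            divergence_time(-0.1)


class TestSelection:
    @pytest.mark.parametrize(
        "ratio,mode",
        [
            (0.3, "purifying"), (0.89999, "purifying"),
            (0.9, "neutral"), (1.0, "neutral"), (1.05, "neutral"),
            (1.1, "neutral"), (1.1000001, "positive"), (5.0, "positive"),
            (None, "undefined"),
        ],
    )
    def test_band_boundaries(self, ratio, mode):
        assert classify_selection(ratio, SelectionBand()) == mode


class TestReciprocalPairs:
    def test_mutual_best_pairing(self):
        records = [
            AlignmentRecord("x", "y", 95.0, 100, evalue=1e-40),
            AlignmentRecord("x", "z", 90.0, 100, evalue=1e-40),
            AlignmentRecord("y", "x", 95.0, 100, evalue=1e-40),
            AlignmentRecord("z", "x", 99.0, 100, evalue=1e-40),
        ]
        # z's best is x, but x's best is y and y's best is x -> only (x, y)
        assert best_reciprocal_pairs(records) == [("x", "y")]
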