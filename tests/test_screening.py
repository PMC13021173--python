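import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from acpdiff import PeptideRecord
from acpdiff.screening import (
    _full_length_identity,
    blosum62,
    helical_wheel,
    motif_summary,
    novelty_scan,
    smith_waterman,
)


def brute_force_sw(a, b, matrix, gap_open, gap_extend):
    """Independent local-alignment oracle: recursive best-suffix formulation
    (memoized over position and gap state), affine gaps where a gap of
    length g costs open + g*extend, free stop anywhere (local)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        options = [0.0]  # stop here for free (local alignment)
        if i < len(a) and j < len(b):
            options.append(matrix[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "I" else gap_open + gap_extend
            options.append(rec(i + 1, j, "I") - cost)
        if j < len(b):
            cost = gap_extend if state == "D" else gap_open + gap_extend
            options.append(rec(i, j + 1, "D") - cost)
        return max(options)

    return max(
        rec(i, j, "M") for i in range(len(a) + 1) for j in range(len(b) + 1)
    )


class TestSmithWaterman:
    def test_identical_sequences_score(self):
        m = blosum62()
        seq = "KWKLFK"
        res = smith_waterman(seq, seq)
        assert res.score == sum(m[c, c] for c in seq)
        assert res.identity_pct == 100.0
        assert res.gap_pct == 0.0

    def test_brute_force_oracle_exhaustive_short(self):
        # all pairs of length <= 3 over a reduced alphabet
        m = blosum62()
        alphabet = "AKW"
        seqs = [
            "".join(p)
            for L in (1, 2, 3)
            for p in itertools.product(alphabet, repeat=L)
        ]
        for a in seqs[:: 3]:
            for b in seqs[:: 3]:
                expected = brute_force_sw(a, b, m, 11.0, 1.0)
                assert smith_waterman(a, b).score == pytest.approx(expected), (a, b)

    def test_brute_force_oracle_random_longer(self, rng):
        m = blosum62()
        alphabet = "AKWDE"
        for _ in range(40):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            assert smith_waterman(a, b).score == pytest.approx(
                brute_force_sw(a, b, m, 11.0, 1.0)
            ), (a, b)

    def test_pairwise_aligner_score_oracle(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "local"
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            a = "".join(rng.choice(alphabet, rng.integers(5, 30)))
            b = "".join(rng.choice(alphabet, rng.integers(5, 30)))
            ours = smith_waterman(a, b).score
            theirs = aligner.score(a, b)
            assert ours == pytest.approx(max(theirs, 0.0)), (a, b)

    def test_gap_alignment_reported(self):
        # bridging b's 6 extra residues (cost 11 + 6) beats aligning only one
        # block, and no ungapped overlay can align both blocks at once
        res = smith_waterman("WWWWKKKK", "WWWWAAAAAAKKKK")
        assert "-" in res.aligned_a
        assert res.gap_pct > 0
        m = blosum62()
        assert res.score == 4 * m["W", "W"] + 4 * m["K", "K"] - 17.0

    def test_empty_or_dissimilar(self):
        res = smith_waterman("WWWW", "DDDD")
        assert res.score == 0.0
        assert res.aligned_a == ""

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("AC", "AC", gap_open=0.0)

    def test_coordinates_one_based_consistent(self):
        res = smith_waterman("GGGKWKG", "KWK")
        assert res.aligned_a == "KWK"
        assert (res.a_start, res.a_end) == (4, 6)
        assert (res.b_start, res.b_end) == (1, 3)


class TestNovelty:
    def test_near_duplicate_boundary_inclusive(self):
        # 9 of 10 positions identical = 90% -> flagged
        ref = [PeptideRecord(id="r", sequence="KWKLFKKIEK")]
        cand = [PeptideRecord(id="c", sequence="KWKLFKKIEA")]
        hits = novelty_scan(cand, ref)
        assert hits[0].full_length_identity_pct == pytest.approx(90.0)
        assert hits[0].near_duplicate

    def test_distinct_not_flagged(self):
        ref = [PeptideRecord(id="r", sequence="DDDDDDDDDD")]
        cand = [PeptideRecord(id="c", sequence="KWKLFKKIEK")]
        hits = novelty_scan(cand, ref)
        assert not hits[0].near_duplicate

    def test_full_length_identity_offsets(self):
        assert _full_length_identity("AKWA", "AKWA") == 100.0
        # best gapless overlay of KW on AKWA matches 2 / longer length 4
        assert _full_length_identity("KW", "AKWA") == pytest.approx(50.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            novelty_scan([PeptideRecord(id="c", sequence="ACDE")], [])

    def test_best_reference_selected(self):
        refs = [
            PeptideRecord(id="far", sequence="DDDDDDD"),
            PeptideRecord(id="near", sequence="KWKLFKK"),
        ]
        cand = [PeptideRecord(id="c", sequence="KWKLFKK")]
        assert novelty_scan(cand, refs)[0].best_reference_id == "near"


class TestMotifs:
    def test_reference_peptide_counts(self):
        summary = motif_summary("INYQKARGVKSQNVINQNRVTIAG")
        assert summary.basic_count == 4
        assert summary.basic_breakdown == {"K": 2, "R": 2}
        assert summary.aromatic_count == 1
        assert summary.aromatic_breakdown == {"Y": 1}
        assert summary.aromatic_basic_proximity == "present"

    def test_proximity_grades(self):
        assert motif_summary("WAAAAAAK").aromatic_basic_proximity == "absent"
        assert motif_summary("WKAAAAAA").aromatic_basic_proximity == "present"
        assert motif_summary("WKWKAAAA").aromatic_basic_proximity == "strong"

    def test_moment_is_max_over_windows(self):
        seq = "AAAAAAAAAAAAIKIKIKIKIKI"
        from acpdiff.descriptors import hydrophobic_moment

        best = max(
            hydrophobic_moment(seq[i : i + 11]) for i in range(len(seq) - 10)
        )
        assert motif_summary(seq).amphipathic_moment == pytest.approx(best)

    def test_short_sequence_whole_window(self):
        from acpdiff.descriptors import hydrophobic_moment

        assert motif_summary("KWKLFKKI").amphipathic_moment == pytest.approx(
            hydrophobic_moment("KWKLFKKI")
        )


class TestHelicalWheel:
    def test_angles_and_classes(self):
        rows = helical_wheel("KAD")
        assert [r["angle_deg"] for r in rows] == [0.0, 100.0, 200.0]
        assert rows[0]["residue_class"] == "basic"
        assert rows[1]["residue_class"] == "hydrophobic"
        assert rows[2]["residue_class"] == "acidic"

    def test_wraps_past_360(self):
        rows = helical_wheel("A" * 5)
        assert rows[4]["angle_deg"] == pytest.approx(40.0)  # 400 mod 360

    def test_hydrophobicity_annotated(self):
        from acpdiff.descriptors import EISENBERG

        rows = helical_wheel("IW")
        assert rows[0]["hydrophobicity"] == EISENBERG["I"]
        assert rows[1]["hydrophobicity"] == EISENBERG["W"]
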