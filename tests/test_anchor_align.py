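"""Pairwise alignment, identity, anchor mapping and progressive MSA."""

import numpy as np
import pytest

from peroxscan.anchor_align import (
    ABSENT,
    GAP,
    AnchorSpec,
    assign_best_reference,
    global_align,
    map_anchors,
    percent_identity,
    progressive_msa,
)
from peroxscan.sequence_core import ProtRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


@pytest.fixture(scope="module")
def reference():
    """A 300-aa synthetic reference with W at 171 and D at 175."""
    rng = np.random.default_rng(77)
    seq = list(random_protein(rng, 300))
    seq[170] = "W"
    seq[174] = "D"
    return ProtRecord(id="ref", seq="".join(seq), partial=True)


@pytest.fixture(scope="module")
def spec():
    return AnchorSpec(
        ref_id="ref",
        family="CLASS_II",
        anchors={171: ("W", "catalytic Trp"), 175: ("D", "Mn-binding Asp")},
    )


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACD", "ACD")
        assert aln.aligned_a == aln.aligned_b == "ACD"

    def test_single_gap_column(self):
        aln = global_align("ACD", "AD")
        assert sorted([aln.aligned_a, aln.aligned_b]) == ["-AD", "ACD"]

    def test_score_symmetry(self):
        a, b = "WKDEACDYW", "WKEACDW"
        assert global_align(a, b).score == global_align(b, a).score

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")


class TestPercentIdentity:
    def test_identical_is_100(self):
        assert percent_identity(global_align("WKDEACD", "WKDEACD")) == 100.0

    def test_direct_count(self):
        assert percent_identity(global_align("AAAA", "AAAT")) == 75.0

    def test_overhang_counts_overlap_only(self, reference):
        # query = exact reference fragment: 100% on the overlap even
        # though the reference is 3x longer
        frag = ProtRecord(id="q", seq=reference.seq[100:180], partial=True)
        assert percent_identity(global_align(frag, reference)) == 100.0


class TestMapAnchors:
    def test_self_fragment_reports_reference_residues(self, reference, spec):
        query = ProtRecord(id="q", seq=reference.seq[159:260], partial=True)
        hits = {h.position: h for h in map_anchors(query, spec, reference)}
        assert hits[171].query_residue == "W" and hits[171].matches_expected
        assert hits[175].query_residue == "D" and hits[175].matches_expected
        # fragment starts at reference position 160 -> anchor 171 is query index 12
        assert hits[171].query_index == 12

    def test_deletion_spanning_anchor_gives_gap(self, reference, spec):
        seq = reference.seq[120:168] + reference.seq[178:240]  # removes 169..178
        query = ProtRecord(id="q", seq=seq, partial=True)
        hits = {h.position: h for h in map_anchors(query, spec, reference)}
        assert hits[171].query_residue == GAP and not hits[171].matches_expected

    def test_substitution_at_anchor_reported(self, reference, spec):
        seq = list(reference.seq[100:250])
        seq[70] = "F"  # reference position 171 within the fragment
        query = ProtRecord(id="q", seq="".join(seq), partial=True)
        hits = {h.position: h for h in map_anchors(query, spec, reference)}
        assert hits[171].query_residue == "F" and not hits[171].matches_expected
        assert hits[175].matches_expected

    def test_anchor_outside_partial_query_absent(self, reference, spec):
        query = ProtRecord(id="q", seq=reference.seq[200:300], partial=True)
        hits = {h.position: h for h in map_anchors(query, spec, reference)}
        assert hits[171].query_residue == ABSENT
        assert hits[175].query_residue == ABSENT

    def test_padding_invariance(self, reference, spec):
        rng = np.random.default_rng(5)
        core = reference.seq[150:250]
        plain = ProtRecord(id="q", seq=core, partial=True)
        padded = ProtRecord(id="q2", seq=random_protein(rng, 8) + core + random_protein(rng, 8),
                            partial=True)
        h1 = {h.position: h.query_residue for h in map_anchors(plain, spec, reference)}
        h2 = {h.position: h.query_residue for h in map_anchors(padded, spec, reference)}
        assert h1 == h2

    def test_anchor_out_of_range(self, reference):
        bad = AnchorSpec(ref_id="ref", family="CLASS_II", anchors={999: ("W", "")})
        with pytest.raises(ValueError):
            map_anchors(ProtRecord(id="q", seq="WWW", partial=True), bad, reference)

    def test_acidic_tolerance_accepts_glutamate(self, reference):
        tol = AnchorSpec(ref_id="ref", family="CLASS_II",
                         anchors={175: ("D", "Mn-binding Asp")}, tolerated={175: "E"})
        seq = list(reference.seq[100:250])
        seq[74] = "E"
        query = ProtRecord(id="q", seq="".join(seq), partial=True)
        (hit,) = map_anchors(query, tol, reference)
        assert hit.query_residue == "E" and hit.matches_expected


class TestProgressiveMSA:
    def test_two_records_reduce_to_pairwise(self):
        a = ProtRecord(id="a", seq="WKDEACDYW")
        b = ProtRecord(id="b", seq="WKEACDW")
        msa = progressive_msa([a, b])
        aln = global_align(a, b)
        assert msa.rows == (aln.aligned_a, aln.aligned_b)

    def test_identical_records_gap_free(self):
        recs = [ProtRecord(id=f"r{i}", seq="WKDEACDYWKDE") for i in range(4)]
        msa = progressive_msa(recs)
        assert all("-" not in row for row in msa.rows)

    def test_single_internal_deletion_one_gap_column(self):
        base = "WKDEACDYWKDEFG"
        recs = [
            ProtRecord(id="a", seq=base),
            ProtRecord(id="b", seq=base[:6] + base[7:]),  # one internal deletion
            ProtRecord(id="c", seq=base),
        ]
        msa = progressive_msa(recs)
        gap_cols = [c for c in range(msa.n_cols) if any(r[c] == "-" for r in msa.rows)]
        assert len(gap_cols) == 1
        row_b = dict(zip(msa.ids, msa.rows))["b"]
        assert row_b.count("-") == 1

    def test_rows_recover_inputs(self):
        recs = [
            ProtRecord(id="a", seq="WKDEACDYW"),
            ProtRecord(id="b", seq="WKDACDYW"),
            ProtRecord(id="c", seq="WKDEACYW"),
            ProtRecord(id="d", seq="KDEACDYW"),
        ]
        msa = progressive_msa(recs)
        by_id = dict(zip(msa.ids, msa.rows))
        for r in recs:
            assert by_id[r.id].replace("-", "") == r.seq

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([ProtRecord(id="a", seq="WKDE")])


class TestAssignBestReference:
    def test_identical_member_wins_at_100(self, small_sim):
        panel = list(small_sim.panels["CLASS_II"])
        query = ProtRecord(id="q", seq=panel[2].seq, partial=True)
        ref_id, pid = assign_best_reference(query, panel)
        assert ref_id == panel[2].id and pid == 100.0

    def test_panel_of_one(self):
        panel = [ProtRecord(id="only", seq="WKDEACDYW")]
        ref_id, pid = assign_best_reference(ProtRecord(id="q", seq="AAAA"), panel)
        assert ref_id == "only"

    def test_empty_panel(self):
        with pytest.raises(ValueError):
            assign_best_reference(ProtRecord(id="q", seq="AAAA"), [])

    def test_generator_source_recovered(self, small_sim):
        # records carry <=2% residue mutation off their source reference
        truth = small_sim.truth
        hits = total = 0
        for row in truth:
            if row.family != "CLASS_II" or row.duplicate_of:
                continue
            query = ProtRecord(id=row.record_id, seq=row.protein, partial=True)
            ref_id, _ = assign_best_reference(query, list(small_sim.panels["CLASS_II"]))
            total += 1
            hits += ref_id == row.source_ref
        assert total > 0
        assert hits / total >= 0.95
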