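import numpy as np
import pytest

from cladescan import paralog_scan as ps
from cladescan import synthetic_data as sd
from cladescan.io_core import GeneAnnotation, reverse_complement
from cladescan.motif_toolkit import MotifHit

from .oracles import naive_revcomp, naive_translate

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class TestSixFrameTranslate:
    def test_codon_table(self):
        assert ps.translate("ATGAAATAA") == "MK*"

    def test_n_codon_becomes_x(self):
        assert ps.translate("ATGANATAA") == "MX*"

    def test_reverse_strand_and_coordinate_map(self):
        tracks = ps.six_frame_translate("TTACATCAT", "t")
        rev0 = next(t for t in tracks if t.strand == "-" and t.frame == 0)
        assert rev0.protein == "MM*"
        # first residue of the reverse track comes from the 3' end:
        # revcomp is ATGATGTAA, codon 0 = ATG = forward positions [6, 9)
        assert rev0.residue_interval(0) == (6, 9)
        assert rev0.residue_interval(1) == (3, 6)
        assert rev0.residue_interval(2) == (0, 3)

    def test_all_six_tracks_match_naive_oracle(self):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        tracks = ps.six_frame_translate(seq, "t")
        rc = naive_revcomp(seq)
        for track in tracks:
            source = seq if track.strand == "+" else rc
            assert track.protein == naive_translate(source[track.frame :])

    def test_residue_intervals_reverse_map_in_frame(self):
        rng = np.random.default_rng(15)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        for track in ps.six_frame_translate(seq, "t"):
            for idx in range(len(track.protein)):
                start, end = track.residue_interval(idx)
                assert end - start == 3
                codon = seq[start:end]
                if track.strand == "-":
                    codon = naive_revcomp(codon)
                assert naive_translate(codon) == track.protein[idx]


class TestAnchors:
    def test_planted_members_have_anchor_pairs(self, family_genome, motif_models, anchor_motifs):
        genome, _, truth = family_genome
        first, last = anchor_motifs
        tracks = ps.six_frame_translate(genome["chr16"], "chr16")
        anchors = ps.find_anchors(tracks, first, last)
        n_first = sum(1 for a in anchors if a.kind == "first")
        n_last = sum(1 for a in anchors if a.kind == "last")
        # the two truncated members lack the first (N-terminal) anchor
        assert n_first >= 16
        assert n_last >= 18

    def test_anchor_free_genome_has_no_hits(self, anchor_motifs):
        first, last = anchor_motifs
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=6000))
        tracks = ps.six_frame_translate(seq, "rand")
        assert ps.find_anchors(tracks, first, last) == []

    def test_minus_strand_anchor_coordinates(self, anchor_motifs):
        """An anchor planted on the minus strand maps back to the forward
        interval covering its codons."""
        first, _ = anchor_motifs
        rng = np.random.default_rng(22)
        flank = "".join(rng.choice(list(RESIDUES), size=30))
        protein = flank + first.consensus + flank
        dna = sd._reverse_translate(protein, rng)
        seq = reverse_complement(dna)
        tracks = ps.six_frame_translate(seq, "t")
        anchors = ps.find_anchors(tracks, first, first)
        assert anchors
        hit = anchors[0]
        track = tracks[hit.track_index]
        assert track.strand == "-"
        g_start, g_end = hit.genomic
        sub = reverse_complement(seq[g_start:g_end])
        assert naive_translate(sub) == protein[hit.res_start : hit.res_end]


class TestBuildCandidates:
    def test_lone_first_anchor_gives_target_length(self, anchor_motifs):
        first, last = anchor_motifs
        rng = np.random.default_rng(5)
        protein = (
            "".join(rng.choice(list(RESIDUES), size=200))
            + first.consensus
            + "".join(rng.choice(list(RESIDUES), size=400))
        )
        dna = sd._reverse_translate(protein, rng)
        tracks = ps.six_frame_translate(dna, "t")
        anchors = ps.find_anchors(tracks, first, last)
        assert [a.kind for a in anchors] == ["first"]
        cands = ps.build_candidates(anchors, tracks, target_len=280, offsets=(6, 5))
        assert len(cands) == 1
        assert len(cands[0].protein) == 280
        assert cands[0].end - cands[0].start == 3 * 280

    def test_anchor_near_stop_truncates_then_discards(self, anchor_motifs):
        first, last = anchor_motifs
        rng = np.random.default_rng(6)
        # anchor 10 residues before a stop codon, short leader
        protein = "".join(rng.choice(list(RESIDUES), size=12)) + first.consensus
        tail = "".join(rng.choice(list(RESIDUES), size=10))
        dna = sd._reverse_translate(protein + tail, rng) + "TAA" + sd._reverse_translate(
            "".join(rng.choice(list(RESIDUES), size=200)), rng
        )
        tracks = ps.six_frame_translate(dna, "t")
        anchors = ps.find_anchors(tracks, first, last)
        assert anchors
        clipped = ps.build_candidates(
            anchors, tracks, target_len=280, offsets=(6, 5), min_length=1
        )
        # window opens 6 residues (offset) before the anchor at residue 12 and
        # is truncated at the stop: 6 leader + width + 10 tail residues
        expected_len = 6 + first.width + 10
        assert any(len(c.protein) == expected_len for c in clipped)
        # with the default min_length the truncated candidate is discarded
        assert ps.build_candidates(anchors, tracks, target_len=280, offsets=(6, 5)) == []

    def test_paired_anchors_recover_planted_protein(
        self, family_genome, motif_models, anchor_motifs
    ):
        genome, _, truth = family_genome
        first, last = anchor_motifs
        seeds = {k: v for k, v in truth.proteins.items() if len(v) == 280}
        offsets = ps.anchor_offsets_from_seeds(seeds, first, last)
        tracks = ps.six_frame_translate(genome["chr16"], "chr16")
        anchors = ps.find_anchors(tracks, first, last)
        cands = ps.build_candidates(anchors, tracks, offsets=offsets)
        proteins = {c.protein for c in cands}
        for member, protein in seeds.items():
            assert protein in proteins


def _mock_candidate(n_motifs, start=0, end=840, length=280, strand="+"):
    hits = [
        MotifHit("c", f"M{i+1}", 1 + 31 * i, 30 + 31 * i, 5.0, 0.9)
        for i in range(n_motifs)
    ]
    return ps.CandidateParalog(
        seq_id="chr16",
        strand=strand,
        frame=0,
        start=start,
        end=end,
        protein="A" * length,
        hits=hits,
    )


class TestFilterMembers:
    def test_membership_boundary_three_vs_two(self, motif_models):
        kept = ps.filter_members([_mock_candidate(3)], motif_models)
        assert len(kept) == 1
        assert ps.filter_members([_mock_candidate(2)], motif_models) == []

    def test_overlapping_candidates_collapse_to_one(self, motif_models):
        a = _mock_candidate(5, start=0, end=840)
        b = _mock_candidate(4, start=300, end=1140)
        kept = ps.filter_members([a, b], motif_models)
        assert kept == [a]

    def test_opposite_strand_overlaps_are_kept(self, motif_models):
        a = _mock_candidate(5, start=0, end=840, strand="+")
        b = _mock_candidate(4, start=300, end=1140, strand="-")
        assert len(ps.filter_members([a, b], motif_models)) == 2


class TestReconcile:
    def test_statuses_on_synthetic_run(self, motif_models):
        spec = sd.FamilySpec(n_members=5, n_annotated=3, truncation_flags={})
        genome, annotations, truth = sd.generate_family_genome(spec, seed=7)
        seeds = {g: truth.proteins[g] for g in truth.annotated_ids}
        members = ps.scan_genome(genome, motif_models, seeds, annotations)
        assert len(members) == 5
        confirmed = [m for m in members if m.status == "confirms-annotated"]
        novel = [m for m in members if m.status == "novel"]
        assert len(confirmed) == 3
        assert len(novel) == 2
        assert {m.matched_gene for m in confirmed} == truth.annotated_ids

    def test_empty_annotation_makes_all_novel(self):
        member = _mock_candidate(5)
        result = ps.reconcile_with_annotation([member], [])
        assert result[0].status == "novel"

    def test_reciprocal_overlap_required(self):
        member = _mock_candidate(5, start=0, end=840)
        tiny = GeneAnnotation("g", "chr16", 0, 60, "+")
        result = ps.reconcile_with_annotation([member], [tiny])
        assert result[0].status == "novel"
        matching = GeneAnnotation("g", "chr16", 0, 843, "+")
        result = ps.reconcile_with_annotation([member], [matching])
        assert result[0].status == "confirms-annotated"


class TestPipelineInvariants:
    @pytest.mark.parametrize("rate", [0.0, 0.10, 0.15])
    def test_seed_genes_rediscovered(self, rate):
        """Every annotated seed gene is found by a scan of its own genome."""
        spec = sd.FamilySpec(
            n_members=6, n_annotated=6, substitution_rate=rate, truncation_flags={}
        )
        genome, annotations, truth = sd.generate_family_genome(spec, seed=3)
        from cladescan import conservation as cv
        from cladescan import motif_toolkit as mt

        aln = cv.Alignment(list(truth.proteins), list(truth.proteins.values()))
        models = mt.discover_motifs(aln)
        members = ps.scan_genome(genome, models, truth.proteins, annotations)
        confirmed = {m.matched_gene for m in members if m.status == "confirms-annotated"}
        assert confirmed == truth.annotated_ids

    def test_intervals_within_chromosome_and_in_frame(self, family_genome, motif_models):
        genome, annotations, truth = family_genome
        seeds = {g: truth.proteins[g] for g in truth.annotated_ids if len(truth.proteins[g]) == 280}
        members = ps.scan_genome(genome, motif_models, seeds, annotations)
        length = len(genome["chr16"])
        for m in members:
            assert 0 <= m.start < m.end <= length
            assert (m.end - m.start) % 3 == 0
            assert m.end - m.start == 3 * len(m.protein)
            dna = genome["chr16"][m.start : m.end]
            if m.strand == "-":
                dna = naive_revcomp(dna)
            assert naive_translate(dna) == m.protein
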