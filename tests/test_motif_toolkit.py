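import numpy as np
import pytest

from cladescan import conservation as cv
from cladescan import motif_toolkit as mt
from cladescan import synthetic_data as sd

RESIDUES = mt.RESIDUES


def _column_ic_oracle(column, background):
    """Brute-force per-column information content with the same pseudocount."""
    freq = np.full(20, mt.PSEUDOCOUNT)
    for c in column:
        if c in RESIDUES:
            freq[RESIDUES.index(c)] += 1.0
    freq /= freq.sum()
    return float((freq * np.log2(freq / background)).sum())


class TestDiscovery:
    def test_planted_templates_recovered(self, seed_alignment, motif_models, family_genome):
        _, _, truth = family_genome
        spec = sd.FamilySpec()
        assert len(motif_models) == len(spec.motif_templates)
        # each recovered motif must overlap one planted template by >= 80%
        member = seed_alignment.ids[0]
        spans = {s[0]: (s[1], s[2]) for s in truth.motif_spans[member]}
        matched_templates = set()
        for model in motif_models:
            hit = mt.scan_protein(truth.proteins[member], model)
            best_overlap, best_tpl = 0, None
            for tpl, (s, e) in spans.items():
                overlap = min(hit.end, e) - max(hit.start - 1, s)
                if overlap > best_overlap:
                    best_overlap, best_tpl = overlap, tpl
            assert best_overlap >= 0.8 * model.width
            matched_templates.add(best_tpl)
        assert len(matched_templates) == len(spec.motif_templates)

    def test_identical_sequences_tile_all_columns(self):
        seq = "".join(
            np.random.default_rng(4).choice(list(RESIDUES), size=120)
        )
        aln = cv.Alignment(["a", "b", "c"], [seq] * 3)
        models = mt.discover_motifs(aln)
        assert sum(m.width for m in models) == 120
        assert all(7 <= m.width <= 50 for m in models)

    def test_random_unrelated_sequences_give_empty_list(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list(RESIDUES), size=100)) for _ in range(12)]
        aln = cv.Alignment([f"s{i}" for i in range(12)], rows)
        ic = mt.column_information(aln, mt.residue_frequencies(rows))
        # verified against the brute-force column-IC oracle: nothing conserved
        background = mt.residue_frequencies(rows)
        for j in (0, 50, 99):
            assert ic[j] == pytest.approx(
                _column_ic_oracle(aln.column(j), background), abs=1e-9
            )
        with pytest.warns(UserWarning):
            assert mt.discover_motifs(aln) == []

    def test_fewer_than_three_sequences_rejected(self):
        aln = cv.Alignment(["a", "b"], ["MKV", "MKV"])
        with pytest.raises(ValueError, match=">= 3"):
            mt.discover_motifs(aln)

    def test_determinism(self, seed_alignment):
        a = mt.discover_motifs(seed_alignment)
        b = mt.discover_motifs(seed_alignment)
        assert [m.consensus for m in a] == [m.consensus for m in b]
        assert [m.motif_id for m in a] == [f"M{i+1}" for i in range(len(a))]
        ics = [m.total_ic for m in a]
        assert ics == sorted(ics, reverse=True)


class TestScanning:
    def test_exact_consensus_hit(self, motif_models):
        model = motif_models[0]
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list(RESIDUES), size=40))
        protein = flank + model.consensus + flank
        hit = mt.scan_protein(protein, model, "p")
        assert hit.consensus_identity == 1.0
        assert hit.start == 41
        assert hit.end == 40 + model.width

    def test_score_matches_brute_force_windows(self, motif_models):
        model = motif_models[-1]
        rng = np.random.default_rng(1)
        protein = "".join(rng.choice(list(RESIDUES), size=60))
        hit = mt.scan_protein(protein, model)
        lo = model.logodds()
        best = -np.inf
        best_start = None
        for start in range(len(protein) - model.width + 1):
            s = sum(
                lo[i, RESIDUES.index(protein[start + i])] for i in range(model.width)
            )
            if s > best + 1e-12:
                best = s
                best_start = start
        assert hit.logodds == pytest.approx(best, abs=1e-9)
        assert hit.start == best_start + 1

    def test_single_window_protein(self, motif_models):
        model = motif_models[2]
        protein = model.consensus[::-1]
        hit = mt.scan_protein(protein, model)
        lo = model.logodds()
        expected = sum(lo[i, RESIDUES.index(protein[i])] for i in range(model.width))
        assert hit.logodds == pytest.approx(expected, abs=1e-9)

    def test_protein_shorter_than_width_gives_no_hit(self, motif_models):
        assert mt.scan_protein("MKV", motif_models[0]) is None
        assert mt.call_presence(None) is False

    def test_consensus_scores_maximum_attainable(self, motif_models):
        for model in motif_models:
            hit = mt.scan_protein(model.consensus, model)
            assert hit.logodds == pytest.approx(model.max_score(), abs=1e-9)

    def test_shuffled_member_fails_presence(self, motif_models, family_genome):
        """Permuting a member's residues destroys the motif calls (FP control)."""
        _, _, truth = family_genome
        protein = truth.proteins["member01"]
        model = motif_models[0]
        rng = np.random.default_rng(123)
        failures = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            shuffled = "".join(rng.permutation(list(protein)))
            hit = mt.scan_protein(shuffled, model)
            if not mt.call_presence(hit):
                failures += 1
        assert failures >= 0.95 * n_shuffles


class TestPresence:
    @pytest.mark.parametrize(
        "identity,logodds,expected",
        [
            (1.0, 5.0, True),
            (0.71, 3.0, True),  # ~71% motif identity is still the same motif
            (0.2, 3.0, False),
            (0.9, -1.0, False),
        ],
    )
    def test_presence_thresholds(self, identity, logodds, expected):
        hit = mt.MotifHit("p", "M1", 1, 10, logodds, identity)
        assert mt.call_presence(hit) is expected


class TestArchitecture:
    def test_full_member_has_all_motifs_in_order(self, motif_models, family_genome):
        _, _, truth = family_genome
        arch = mt.architecture(truth.proteins["member01"], motif_models, "member01")
        presence = arch.presence_vector([m.motif_id for m in motif_models])
        assert all(presence.values())
        starts = [h.start for h in arch.hits]
        assert starts == sorted(starts)
        # hits are non-overlapping after resolution
        for h1, h2 in zip(arch.hits, arch.hits[1:]):
            assert h1.end < h2.start

    def test_truncated_member_missing_leading_motifs(self, motif_models, family_genome):
        """A member lacking its first four templates loses exactly those calls."""
        _, _, truth = family_genome
        spec = sd.FamilySpec()
        # map models to template indices via the consensus templates
        arch = mt.architecture(truth.proteins["member12"], motif_models, "member12")
        present_templates = set()
        for hit in arch.hits:
            model = next(m for m in motif_models if m.motif_id == hit.motif_id)
            tpl_idx = max(
                range(len(spec.motif_templates)),
                key=lambda t: sum(
                    a == b for a, b in zip(model.consensus, spec.motif_templates[t])
                ),
            )
            present_templates.add(tpl_idx)
        assert present_templates == set(range(4, 9))

    def test_architecture_invariant_under_c_terminal_extension(self, motif_models, family_genome):
        _, _, truth = family_genome
        protein = truth.proteins["member02"]
        arch1 = mt.architecture(protein, motif_models)
        arch2 = mt.architecture(protein + "AAAAAAAAAA", motif_models)
        assert [(h.motif_id, h.start) for h in arch1.hits] == [
            (h.motif_id, h.start) for h in arch2.hits
        ]

    def test_empty_protein_set(self, motif_models):
        table = mt.architecture_table({}, motif_models)
        assert table.empty


class TestCompare:
    def test_self_identity_is_100(self, motif_models):
        for model in motif_models:
            assert mt.compare_motifs(model, model) == 100.0

    def test_known_divergence(self, motif_models):
        """A consensus with k substituted positions scores (w-k)/w identity."""
        model = motif_models[1]  # width 35
        cons = model.consensus
        mutated = list(cons)
        for pos in (3, 10, 20):
            mutated[pos] = "W" if cons[pos] != "W" else "Y"
        other = mt.build_motif_model(
            "mut", ["".join(mutated)], model.background
        )
        width = model.width
        expected = 100.0 * (width - 3) / width
        assert mt.compare_motifs(model, other) == pytest.approx(expected)

    def test_score_matches_independent_dp(self, motif_models):
        """Alignment score underlying the identity equals a brute-force Gotoh."""
        from .oracles import gotoh_score

        scoring = cv.protein_scoring()
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(list(RESIDUES), size=10))
            b = "".join(rng.choice(list(RESIDUES), size=10))
            res = cv.pairwise_align(a, b, scoring)
            assert res.score == pytest.approx(
                gotoh_score(a, b, scoring), abs=1e-9
            )


class TestSerialization:
    def test_round_trip(self, motif_models, tmp_path):
        prefix = tmp_path / "motifs"
        mt.write_motif_models(motif_models, prefix)
        back = mt.read_motif_models(prefix)
        assert [m.motif_id for m in back] == [m.motif_id for m in motif_models]
        assert [m.consensus for m in back] == [m.consensus for m in motif_models]
        for a, b in zip(back, motif_models):
            assert np.allclose(a.pfm, b.pfm)
            assert np.allclose(a.background, b.background)
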