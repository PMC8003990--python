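"""ORF discovery against a brute-force scanner, dynamic cutoff, scoring, homology."""

import numpy as np
import pandas as pd
import pytest

from lncpod.annotation_core import AnnotationSet, ExpressionTable, TranscriptModel
from lncpod.coding_potential import (
    OrfCall,
    UNIFORM_BASES,
    apply_homology_filter,
    classify_coding,
    dynamic_orf_cutoff,
    expected_orf_count,
    find_orfs,
    read_outfmt6,
    score_orf,
    select_candidates,
    train_hexamer_model,
    train_start_pssm,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq, min_aa=50):
    """Independent scanner: every ATG extended to its stop, nested in-frame
    calls removed afterwards."""
    seq = seq.upper()
    n = len(seq)
    raw = []
    for a in (i for i in range(n - 2) if seq[i : i + 3] == "ATG"):
        j = a + 3
        stop = None
        while j + 3 <= n:
            if seq[j : j + 3] in STOPS:
                stop = j
                break
            j += 3
        if stop is not None:
            aa, end, complete = (stop - a) // 3, stop + 3, True
        else:
            end = a + 3 * ((n - a) // 3)
            aa, complete = (end - a) // 3, False
        if aa >= min_aa:
            raw.append((a % 3, a, end, aa, complete))
    return sorted(
        o
        for o in raw
        if not any(
            o2 != o and o2[0] == o[0] and o2[1] < o[1] and o2[2] >= o[2] for o2 in raw
        )
    )


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindOrfs:
    def test_minimal_complete_orf(self):
        seq = "ATG" + "GCT" * 49 + "TAA"
        calls = find_orfs(seq, min_aa=50)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end, call.length_aa, call.complete) == (0, 153, 50, True)

    def test_nested_inner_orf_suppressed(self):
        # downstream in-frame ATG would start an ORF contained in the outer one
        seq = "ATG" + "GCT" * 10 + "ATG" + "GCT" * 49 + "TAA"
        calls = find_orfs(seq, min_aa=50)
        assert len(calls) == 1
        assert calls[0].start == 0 and calls[0].length_aa == 61

    def test_incomplete_orf_reported_without_stop(self):
        seq = "CC" + "ATG" + "GGA" * 60
        (call,) = find_orfs(seq, min_aa=50)
        assert not call.complete and call.length_aa == 61 and call.frame == 2

    def test_n_codons_never_start_or_stop(self):
        seq = "ANG" + "GCT" * 60  # no valid ATG
        assert find_orfs(seq, min_aa=1) == []
        seq2 = "ATG" + "TNA" * 60  # TNA is not a stop
        (call,) = find_orfs(seq2, min_aa=1)
        assert not call.complete

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            seq = _random_seq(rng, 1500)
            mine = sorted(
                (o.frame, o.start, o.end, o.length_aa, o.complete)
                for o in find_orfs(seq, min_aa=20)
            )
            assert mine == brute_force_orfs(seq, min_aa=20)


class TestDynamicCutoff:
    def test_matches_direct_formula_evaluation(self):
        # independent evaluation of the expected-count model at L=300
        L = 300
        p_start = 0.25**3
        p_stop = 3 * 0.25**3
        first_atg = p_stop / (p_stop + p_start)
        expected = next(
            n
            for n in range(50, 200)
            if max(0, L - 3 * n) * p_start * (1 - p_stop) ** (n - 1) * first_atg < 0.05
        )
        assert dynamic_orf_cutoff(300) == expected

    def test_monotone_in_transcript_length(self):
        cuts = [dynamic_orf_cutoff(L) for L in (300, 500, 1000, 2000, 5000, 20000)]
        assert cuts == sorted(cuts)
        assert cuts[0] >= 50

    def test_skewed_base_composition_changes_cutoff(self):
        gc_rich = {"A": 0.15, "C": 0.35, "G": 0.35, "T": 0.15}
        # fewer stops in GC-rich sequence -> longer chance ORFs -> higher cutoff
        assert dynamic_orf_cutoff(2000, base_freqs=gc_rich) > dynamic_orf_cutoff(2000)

    def test_degenerate_base_frequencies_rejected(self):
        with pytest.raises(ValueError):
            dynamic_orf_cutoff(500, base_freqs={"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0})

    def test_expected_count_nested_exceeds_non_nested(self):
        assert expected_orf_count(60, 2000, UNIFORM_BASES, nested=True) > expected_orf_count(
            60, 2000, UNIFORM_BASES
        )


class TestSelectCandidates:
    def _annot_expr(self, lengths, fpkms):
        txs = [
            TranscriptModel(f"t{i}", f"g{i}", "chr1", "+", ((0, L),), "noncoding")
            for i, L in enumerate(lengths)
        ]
        expr = ExpressionTable(
            pd.DataFrame({"s1": fpkms}, index=[f"t{i}" for i in range(len(lengths))]),
            {"s1": "podocyte"},
        )
        return AnnotationSet(txs), expr

    def test_length_cutoff_excludes_short_high_expression(self):
        annot, expr = self._annot_expr([150], [10.0])
        assert select_candidates(annot, expr) == set()

    def test_boundaries_inclusive(self):
        annot, expr = self._annot_expr([200], [1.0])
        assert select_candidates(annot, expr) == {"t0"}

    def test_all_zero_expression_empty(self):
        annot, expr = self._annot_expr([500, 900], [0.0, 0.0])
        assert select_candidates(annot, expr) == set()

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable(pd.DataFrame({"s1": [-1.0]}, index=["t0"]), {"s1": "podocyte"})


class TestScoring:
    def test_zero_model_gives_zero_score(self):
        seq = "ATG" + "GCT" * 10 + "TAA"
        (orf,) = find_orfs(seq, min_aa=5)
        ll, _ = score_orf(orf, seq, {}, {})
        assert ll == 0.0

    def test_single_hexamer_log_odds_summed(self):
        seq = "ATGGCT" + "TAA"
        orf = OrfCall("t", 0, 0, 9, 2, True)
        ll, _ = score_orf(orf, seq, {"ATGGCT": 1.5}, {})
        assert ll == pytest.approx(1.5)

    def test_trained_model_separates_coding_from_shuffled(self):
        rng = np.random.default_rng(3)
        from lncpod.synthetic_fixtures import _coding_seq

        coding = ["ATG" + _coding_seq(rng, 200) + "TAA" for _ in range(60)]
        shuffled = ["".join(rng.permutation(list(s))) for s in coding]
        model = train_hexamer_model(coding[:40], shuffled[:40])
        pssm = train_start_pssm(["GCCACCATGG"] * 10)

        def score(seq):
            orfs = [o for o in find_orfs(seq, min_aa=30) if o.complete]
            best = max(orfs, key=lambda o: o.length_aa)
            return score_orf(best, seq, model, pssm)[0]

        cod_scores = [score(s) for s in coding[40:]]
        shuf = []
        for s in shuffled[40:]:
            orfs = [o for o in find_orfs(s, min_aa=30) if o.complete]
            if orfs:
                best = max(orfs, key=lambda o: o.length_aa)
                shuf.append(score_orf(best, s, model, pssm)[0])
        assert np.mean(cod_scores) > (np.mean(shuf) if shuf else 0.0)

    def test_short_orf_rejected(self):
        orf = OrfCall("t", 0, 0, 3, 1, False)
        with pytest.raises(ValueError):
            score_orf(orf, "ATGTAA", {}, {})


class TestHomologyFilter:
    def test_bit_score_boundary_inclusive_at_50(self, tmp_path):
        rows = [
            "q1\ts1\t90\t100\t10\t0\t1\t100\t1\t100\t1e-10\t49.9",
            "q2\ts2\t90\t100\t10\t0\t1\t100\t1\t100\t1e-10\t50.0",
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        hits = read_outfmt6(str(path))
        assert apply_homology_filter({"q1", "q2"}, hits) == {"q2"}

    def test_empty_table_no_flags(self):
        assert apply_homology_filter({"a"}, pd.DataFrame(columns=["qseqid", "bitscore"])) == set()

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\tnotanumber\n")
        with pytest.raises(ValueError, match=":1:"):
            read_outfmt6(str(path))


class TestVerdict:
    def test_homology_hit_overrides_to_coding(self):
        seq = "".join(np.array(list("ACGT"))[np.random.default_rng(0).integers(0, 4, 400)])
        v = classify_coding({"t": seq}, {}, {}, homology_flagged={"t"})["t"]
        assert v.verdict == "coding" and v.homology_hit

    def test_anti_monotone_in_alpha(self, fixture_dir, manifest):
        """Raising alpha (laxer chance-ORF bound) never shrinks the coding set."""
        import os

        from lncpod.annotation_core import read_fasta

        seqs = dict(
            list(read_fasta(os.path.join(fixture_dir, manifest.files["transcripts_fasta"])).items())[:80]
        )
        pssm = {0: {b: 0.1 for b in "ACGT"}}  # always-positive start score
        coding_sets = []
        for alpha in (0.01, 0.05, 0.5):
            verdicts = classify_coding(seqs, {}, pssm, set(), alpha=alpha)
            coding_sets.append({t for t, v in verdicts.items() if v.verdict == "coding"})
        assert coding_sets[0] <= coding_sets[1] <= coding_sets[2]

    def test_planted_verdicts_recovered(self, pipeline_result, manifest):
        """Planted coding contaminants vs noncoding decoys: >= 95% accuracy."""
        correct = total = 0
        for tid, v in pipeline_result.verdicts.items():
            total += 1
            correct += (v.verdict == "coding") == manifest.transcripts[tid]["coding"]
        assert total > 200
        assert correct / total >= 0.95

    def test_planted_orf_recovered_exactly(self, fixture_dir, manifest):
        import os

        from lncpod.annotation_core import read_fasta

        seqs = read_fasta(os.path.join(fixture_dir, manifest.files["transcripts_fasta"]))
        for tid, rec in manifest.transcripts.items():
            if rec["planted_orf_aa"]:
                lengths = [o.length_aa for o in find_orfs(seqs[tid]) if o.complete]
                assert rec["planted_orf_aa"] in lengths
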