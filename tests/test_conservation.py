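"""Gene-order DP vs exhaustive enumeration, the internal aligner vs an
independent recursion, ortholog prediction and the conservation filters."""

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from lncpod.conservation import (
    GeneOrder,
    OrderedGene,
    OrthologPair,
    align_gene_orders,
    best_local_gene_order_score,
    human_expression_check,
    predict_synteny_orthologs,
    sequence_conservation_from_fasta,
    sequence_conservation_from_table,
    smith_waterman,
)

MATCH, MISMATCH, GAP = 1.0, -1.0, -0.5


def brute_force_gene_order(a, b, pairs):
    """Best local alignment score by enumerating every monotone anchor matching
    with inter-anchor gap penalties."""
    best = 0.0

    def extend(i, j, score):
        nonlocal best
        best = max(best, score)
        for i2 in range(i + 1, len(a)):
            for j2 in range(j + 1, len(b)):
                s = MATCH if (a[i2], b[j2]) in pairs else MISMATCH
                gap_cost = GAP * ((i2 - i - 1) + (j2 - j - 1))
                extend(i2, j2, score + s + gap_cost)

    for i in range(len(a)):
        for j in range(len(b)):
            s = MATCH if (a[i], b[j]) in pairs else MISMATCH
            extend(i, j, s)
    return best


def brute_force_affine(q, s, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5):
    """Independent affine-gap local alignment score via explicit-state recursion."""

    @lru_cache(maxsize=None)
    def end_at(i, j, state):
        # best score of an alignment ending exactly at (i, j) in the given state
        if state == "M":
            sub = match if q[i - 1] == s[j - 1] else mismatch
            prev = 0.0
            if i > 1 and j > 1:
                prev = max(
                    0.0,
                    end_at(i - 1, j - 1, "M"),
                    end_at(i - 1, j - 1, "X"),
                    end_at(i - 1, j - 1, "Y"),
                )
            return prev + sub
        if state == "X":
            opts = []
            if i > 1:
                opts.append(end_at(i - 1, j, "M") + gap_open)
                opts.append(end_at(i - 1, j, "X") + gap_extend)
            return max(opts) if opts else -1e30
        opts = []
        if j > 1:
            opts.append(end_at(i, j - 1, "M") + gap_open)
            opts.append(end_at(i, j - 1, "Y") + gap_extend)
        return max(opts) if opts else -1e30

    best = 0.0
    for i in range(1, len(q) + 1):
        for j in range(1, len(s) + 1):
            best = max(best, end_at(i, j, "M"))
    return best


def _order(species, chrom, genes):
    return GeneOrder(species, chrom, [OrderedGene(*g) for g in genes])


def _homology(pairs, bits=100.0):
    return pd.DataFrame(
        [
            {"qseqid": a, "sseqid": b, "pident": 90.0, "length": 200, "mismatch": 10,
             "gapopen": 0, "qstart": 1, "qend": 200, "sstart": 1, "send": 200,
             "evalue": 1e-40, "bitscore": bits}
            for a, b in pairs
        ]
    )


class TestGeneOrderAlignment:
    def test_perfect_colinearity_single_block(self):
        mouse = _order("m", "1", [(f"m{i}", 1000 * (i + 1), "+", "coding") for i in range(5)])
        human = _order("h", "1", [(f"h{i}", 1000 * (i + 1), "+", "coding") for i in range(5)])
        hom = _homology([(f"m{i}", f"h{i}") for i in range(5)])
        blocks = align_gene_orders(mouse, human, hom)
        assert len(blocks) == 1
        assert blocks[0].score == pytest.approx(5.0)
        assert blocks[0].anchor_pairs == tuple((f"m{i}", f"h{i}") for i in range(5))

    def test_missing_homolog_handled_by_dp(self):
        mouse = _order("m", "1", [(f"m{i}", 1000 * (i + 1), "+", "coding") for i in range(5)])
        human = _order("h", "1", [(f"h{i}", 1000 * (i + 1), "+", "coding") for i in range(5)])
        hom = _homology([(f"m{i}", f"h{i}") for i in range(5) if i != 2])
        blocks = align_gene_orders(mouse, human, hom)
        a = [g.gene_id for g in mouse.anchors]
        b = [g.gene_id for g in human.anchors]
        pairs = {(r.qseqid, r.sseqid) for r in hom.itertuples()}
        assert blocks[0].score == pytest.approx(brute_force_gene_order(a, b, pairs))

    def test_no_homology_no_blocks(self):
        mouse = _order("m", "1", [(f"m{i}", 1000 * (i + 1), "+", "coding") for i in range(6)])
        human = _order("h", "1", [(f"h{i}", 1000 * (i + 1), "+", "coding") for i in range(6)])
        assert align_gene_orders(mouse, human, _homology([])) == []

    def test_dp_equals_exhaustive_enumeration_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(120):
            na, nb = rng.integers(2, 7), rng.integers(2, 7)
            a = [f"a{i}" for i in range(na)]
            b = [f"b{j}" for j in range(nb)]
            pairs = {
                (a[i], b[j])
                for i in range(na)
                for j in range(nb)
                if rng.random() < 0.35
            }
            dp = best_local_gene_order_score(a, b, pairs, MATCH, MISMATCH, GAP)
            assert dp == pytest.approx(brute_force_gene_order(a, b, pairs))

    def test_inverted_chromosome_recovered(self):
        mouse = _order("m", "1", [(f"m{i}", 1000 * (i + 1), "+", "coding") for i in range(5)])
        rev = [(f"h{i}", 1000 * (5 - i), "+", "coding") for i in range(5)]
        human = _order("h", "1", rev)
        hom = _homology([(f"m{i}", f"h{i}") for i in range(5)])
        blocks = align_gene_orders(mouse, human, hom)
        assert blocks and blocks[0].score == pytest.approx(5.0)
        assert blocks[0].orientation == -1


class TestSyntenyOrthologs:
    def _setup(self):
        mouse_genes = [
            ("mA", 10_000, "+", "coding"),
            ("lnc1", 20_000, "+", "noncoding"),
            ("mB", 30_000, "+", "coding"),
            ("mC", 50_000, "+", "coding"),
        ]
        human_genes = [
            ("hA", 10_000, "+", "coding"),
            ("hnc1", 22_000, "+", "noncoding"),
            ("hB", 30_000, "+", "coding"),
            ("hC", 50_000, "+", "coding"),
        ]
        mouse = {"1": _order("m", "1", mouse_genes)}
        human = {"1": _order("h", "1", human_genes)}
        hom = _homology([("mA", "hA"), ("mB", "hB"), ("mC", "hC")])
        blocks = align_gene_orders(mouse["1"], human["1"], hom)
        return mouse, human, blocks

    def test_adjacent_ncrna_emitted(self):
        mouse, human, blocks = self._setup()
        pairs = predict_synteny_orthologs(
            {"lnc1": ("1", 20_000)}, blocks, mouse, human, max_anchor_distance=100_000
        )
        assert {(p.mouse_lnc_id, p.human_feature_id) for p in pairs} == {("lnc1", "hnc1")}
        assert pairs[0].evidence == "synteny"

    def test_unaligned_flanks_yield_nothing(self):
        mouse, human, _ = self._setup()
        pairs = predict_synteny_orthologs({"lnc1": ("1", 20_000)}, [], mouse, human, 100_000)
        assert pairs == []

    def test_distance_cap_excludes_far_ncrnas(self):
        mouse, human, blocks = self._setup()
        pairs = predict_synteny_orthologs(
            {"lnc1": ("1", 20_000)}, blocks, mouse, human, max_anchor_distance=5_000
        )
        assert pairs == []

    def test_translation_and_strand_flip_invariance(self):
        mouse, human, blocks = self._setup()
        base = predict_synteny_orthologs({"lnc1": ("1", 20_000)}, blocks, mouse, human, 100_000)
        # translate human coordinates and flip the chromosome orientation
        flipped = {"1": human["1"].reversed()}
        hom = _homology([("mA", "hA"), ("mB", "hB"), ("mC", "hC")])
        blocks2 = align_gene_orders(mouse["1"], flipped["1"], hom)
        flipped_pairs = predict_synteny_orthologs(
            {"lnc1": ("1", 20_000)}, blocks2, mouse, flipped, 100_000
        )
        assert {(p.mouse_lnc_id, p.human_feature_id) for p in flipped_pairs} == {
            (p.mouse_lnc_id, p.human_feature_id) for p in base
        }

    def test_planted_fixture_pairs_recovered(self, pipeline_result, manifest):
        found = {
            (p.mouse_lnc_id, p.human_feature_id)
            for p in pipeline_result.ortholog_pairs
            if p.evidence == "synteny"
        }
        planted = {tuple(p) for p in manifest.synteny_pairs}
        assert found == planted


class TestInternalAligner:
    def test_identical_sequences(self):
        aln = smith_waterman("ACGTACGT", "ACGTACGT")
        assert aln.score == 8.0 and aln.identity == 100.0 and aln.aln_length == 8

    def test_score_equals_independent_recursion(self):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        for _ in range(60):
            q = "".join(bases[rng.integers(0, 4, rng.integers(5, 31))])
            s = "".join(bases[rng.integers(0, 4, rng.integers(5, 31))])
            assert smith_waterman(q, s).score == pytest.approx(brute_force_affine(q, s))

    def test_gap_costs_affine(self):
        # a 3-base deletion costs one open (-2) plus two extensions (-0.5 each)
        q = "AAAATTTT" + "CCC" + "GGGGTTAA"
        s = "AAAATTTT" + "GGGGTTAA"
        aln = smith_waterman(q, s)
        assert aln.score == pytest.approx(16 - 3.0)
        assert aln.aln_length == 19  # 16 matched columns plus the 3-column gap


class TestSequenceConservation:
    def _row(self, pident, length):
        return pd.DataFrame(
            [{"qseqid": "m1", "sseqid": "h1", "pident": pident, "length": length,
              "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": length, "sstart": 1,
              "send": length, "evalue": 1e-30, "bitscore": 100.0}]
        )

    @pytest.mark.parametrize(
        "pident,length,kept",
        [(80.0, 150, False), (95.0, 100, False), (80.1, 101, True), (95.0, 150, True)],
    )
    def test_strict_identity_and_length_thresholds(self, pident, length, kept):
        pairs = sequence_conservation_from_table(self._row(pident, length))
        assert bool(pairs) == kept

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sequence_conservation_from_table(self._row(120.0, 200))

    def test_filter_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        rows = pd.concat(
            [self._row(float(rng.uniform(50, 100)), int(rng.integers(50, 400))) for _ in range(50)],
            ignore_index=True,
        )
        rows["qseqid"] = [f"m{i}" for i in range(50)]
        strict = {
            (p.mouse_lnc_id) for p in sequence_conservation_from_table(rows, 85.0, 150)
        }
        lax = {(p.mouse_lnc_id) for p in sequence_conservation_from_table(rows, 80.0, 100)}
        assert strict <= lax

    def test_internal_aligner_path_recovers_planted_pair(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        mouse = "".join(bases[rng.integers(0, 4, 300)])
        human = list(mouse)
        for i in rng.choice(300, 20, replace=False):
            human[i] = "ACGT"[(bases.tolist().index(human[i]) + 1) % 4]
        pairs = sequence_conservation_from_fasta({"m1": mouse}, {"h1": "".join(human)})
        assert [(p.mouse_lnc_id, p.human_feature_id) for p in pairs] == [("m1", "h1")]
        decoy = "".join(bases[rng.integers(0, 4, 300)])
        assert sequence_conservation_from_fasta({"m1": mouse}, {"d": decoy}) == []


class TestHumanExpression:
    def _pair(self, hid="h1"):
        return OrthologPair("m1", hid, "synteny")

    def test_all_zero_false_and_boundary_true(self):
        expr = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0]],
            index=["h0", "h1"],
            columns=[f"k{i}" for i in range(4)],
        )
        flagged = human_expression_check([self._pair("h0"), self._pair("h1")], expr)
        assert [p.human_expressed for p in flagged] == [False, True]

    def test_missing_feature_flagged_false(self):
        expr = pd.DataFrame([[5.0]], index=["other"], columns=["k1"])
        (p,) = human_expression_check([self._pair("absent")], expr)
        assert p.human_expressed is False

    def test_planted_expression_flags_recovered(self, pipeline_result, manifest):
        by_human = {}
        for p in pipeline_result.ortholog_pairs:
            by_human.setdefault(p.human_feature_id, False)
            by_human[p.human_feature_id] |= bool(p.human_expressed)
        for hid, rec in manifest.genes.items():
            if "human_expressed" in rec and hid in by_human:
                assert by_human[hid] == rec["human_expressed"]
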