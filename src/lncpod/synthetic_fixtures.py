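"""Seeded generator of a complete toy two-species dataset with known ground truth.

The generator emits every input the pipeline consumes — mouse reference and
assembled GTFs, transcript FASTA, coding-model training sets, BLAST-style
tabular homology/alignment tables, compartment FPKM tables, count matrices
for three disease models, a human kidney expression table and a 10x-style
single-cell triplet — together with a JSON manifest recording what was
planted where. Regeneration with the same seed is byte-identical.

The planted universe (default configuration):

* two mouse chromosomes; protein-coding anchor genes shared with a toy human
  genome. Human chr1 preserves the mouse anchor order (colinear synteny);
  human chr2 anchors are reordered and too diverged to align, so chr2 lncRNAs
  are synteny decoys.
* 400 lncRNA genes in disjoint classes: syntenic-conserved (each alone in a
  dedicated anchor gap, with a human ncRNA in the matching human gap),
  sequence-conserved (human partner copied with per-base substitutions),
  coding contaminants (planted ORFs with biased codon usage and protein
  homology hits), unexpressed, sub-200-bp, and plain noncoding filler.
* compartment profiles tilted so planted podocyte-specific features sit well
  above the TSI threshold and every other feature sits well below it.
* negative-binomial counts with planted log2 fold changes (0, +-1, +-2) per
  disease model, a 30-locus coherently up-regulated core shared by all three.
* single-cell counts in which generated podocytes express all four canonical
  markers and ten planted genes are podocyte-exclusive.

Strong, unambiguous effect sizes are planted on the focal (conserved and
specific) candidates so that the manifest is a usable ground truth; the
weaker +-1 fold changes exercise the statistics without entering the funnel.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation_core import (
    CODING,
    NONCODING,
    AnnotationSet,
    TranscriptModel,
    write_fasta,
    write_gtf,
)
from .coding_potential import OUTFMT6_COLUMNS

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# fixed codon-usage bias (GC-ending codons preferred) gives coding sequences a
# hexamer signature the trained log-odds model can learn
_CODON_WEIGHTS = np.array([3.0 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS])
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()

KOZAK = "GCCACCATGG"

MODELS = ("wt1", "podocin", "adriamycin")


@dataclass
class FixtureConfig:
    seed: int = 0
    n_lnc: int = 400
    n_anchors_chr1: int = 40
    n_anchors_chr2: int = 20
    n_synteny: int = 20
    n_seq_conserved: int = 60
    n_contaminants: int = 40
    n_unexpressed: int = 40
    n_short: int = 20
    frac_novel: float = 1.0 / 3.0
    substitution_rate: float = 0.12
    dispersion: float = 0.1
    n_replicates: int = 3
    n_podocyte_cells: int = 80
    n_other_cells: int = 220

    def __post_init__(self) -> None:
        structured = (
            self.n_synteny
            + self.n_seq_conserved
            + self.n_contaminants
            + self.n_unexpressed
            + self.n_short
        )
        if structured > self.n_lnc:
            raise ValueError("feature-class counts exceed n_lnc")
        if self.n_synteny > self.n_anchors_chr1 // 2:
            raise ValueError("need two anchors per syntenic lncRNA on chr1")


@dataclass
class FixtureManifest:
    """Ground truth for every planted feature; fully determines expected outputs."""

    seed: int
    config: Dict
    transcripts: Dict[str, Dict]
    genes: Dict[str, Dict]
    synteny_pairs: List[List[str]]
    sequence_pairs: List[List]
    podocyte_barcodes: List[str]
    files: Dict[str, str]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, float]:
    """Per-base substitution copy; returns (mutant, realized identity percent)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    subs = _BASES[rng.integers(0, 3, hit.sum())]
    # shift so the substitute always differs from the original base
    orig_idx = np.searchsorted(_BASES, arr[hit])
    sub_idx = (orig_idx + 1 + rng.integers(0, 3, hit.sum())) % 4
    arr[hit] = _BASES[sub_idx]
    identity = 100.0 * (len(arr) - hit.sum()) / len(arr)
    return "".join(arr), float(identity)


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons, p=_CODON_WEIGHTS)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _contaminant_seq(rng: np.random.Generator, orf_aa: int) -> Tuple[str, int]:
    """Transcript with one unambiguous planted ORF of exactly ``orf_aa`` codons.

    An in-frame stop immediately upstream of the ATG pins the ORF start; the
    codons carry the fixture's coding codon bias.
    """
    utr5 = _random_seq(rng, int(rng.integers(12, 45)) * 3) + "TAA"
    body = "ATG" + _coding_seq(rng, orf_aa - 1) + "TAA"
    utr3 = _random_seq(rng, int(rng.integers(30, 150)))
    return utr5 + body + utr3, len(utr5)


def _exon_chain(
    rng: np.random.Generator, gene_start: int, spliced_len: int, n_exons: int
) -> Tuple[Tuple[int, int], ...]:
    if n_exons == 1:
        return ((gene_start, gene_start + spliced_len),)
    cuts = np.sort(rng.choice(np.arange(1, spliced_len), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [spliced_len]]))
    introns = rng.integers(100, 300, n_exons - 1)
    exons = []
    pos = gene_start
    for k, size in enumerate(sizes):
        exons.append((pos, pos + int(size)))
        pos += int(size)
        if k < n_exons - 1:
            pos += int(introns[k])
    return tuple(exons)


def _kozak_context(rng: np.random.Generator) -> str:
    return "".join(
        b if rng.random() < 0.85 else str(_BASES[rng.integers(0, 4)]) for b in KOZAK
    )


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate(config: FixtureConfig, out_dir: str) -> FixtureManifest:
    """Write the full fixture bundle to ``out_dir`` and return its manifest."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = config
    rng_struct = _rng(cfg.seed, 0)
    rng_seq = _rng(cfg.seed, 1)
    rng_expr = _rng(cfg.seed, 2)
    rng_counts = _rng(cfg.seed, 3)
    rng_sc = _rng(cfg.seed, 4)
    rng_aln = _rng(cfg.seed, 5)
    rng_hom = _rng(cfg.seed, 6)
    rng_hexpr = _rng(cfg.seed, 7)

    n = cfg.n_lnc
    idx_synteny = list(range(cfg.n_synteny))
    base = cfg.n_synteny
    idx_seq = list(range(base, base + cfg.n_seq_conserved))
    base += cfg.n_seq_conserved
    idx_contaminant = list(range(base, base + cfg.n_contaminants))
    base += cfg.n_contaminants
    idx_unexpressed = list(range(base, base + cfg.n_unexpressed))
    base += cfg.n_unexpressed
    idx_short = list(range(base, base + cfg.n_short))
    base += cfg.n_short
    idx_plain = list(range(base, n))

    # podocyte-specific: split across syntenic, sequence-conserved and plain
    n_spec_syn = min(8, len(idx_synteny))
    n_spec_seq = min(12, len(idx_seq))
    idx_specific = (
        idx_synteny[:n_spec_syn] + idx_seq[:n_spec_seq] + idx_plain[: max(0, 40 - n_spec_syn - n_spec_seq)]
    )
    # single-cell classes
    idx_exclusive = idx_synteny[: min(5, n_spec_syn)] + idx_seq[: min(5, n_spec_seq)]
    idx_broad = [
        i for i in idx_synteny + idx_seq if i not in idx_exclusive
    ] + idx_plain[20:70]
    # differential expression: a coherent shared core (log2fc +2 in all three
    # models) covering the conserved+specific candidates, plus per-model
    # unique strong (+-2) and weak (+-1) effects on filler loci
    shared = idx_synteny[: min(6, n_spec_syn)] + idx_seq[: min(6, n_spec_seq)]
    shared += idx_plain[70 : 70 + (30 - len(shared))]
    pool = [i for i in idx_plain[100:] if i not in shared]
    lfc: Dict[str, Dict[int, float]] = {m: {} for m in MODELS}
    for i in shared:
        for m in MODELS:
            lfc[m][i] = 2.0
    for k, m in enumerate(MODELS):
        strong = pool[k * 20 : k * 20 + 10]
        weak = pool[60 + k * 10 : 60 + k * 10 + 10]
        for j, i in enumerate(strong):
            lfc[m][i] = 2.0 if j % 2 == 0 else -2.0
        for j, i in enumerate(weak):
            lfc[m][i] = 1.0 if j % 2 == 0 else -1.0

    gene_ids = [f"MLNC{i:04d}" for i in range(n)]
    tx_ids = [f"MLNC{i:04d}.1" for i in range(n)]
    known = [i % 3 >= round(3 * cfg.frac_novel) for i in range(n)]

    # ---- genome layout -----------------------------------------------------
    anchor_spacing = 20_000
    mouse_tx: List[TranscriptModel] = []
    human_tx: List[TranscriptModel] = []
    ref_tx: List[TranscriptModel] = []

    def _anchor(species: str, gid: str, chrom: str, pos: int) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=f"{gid}.t1",
            gene_id=gid,
            chrom=chrom,
            strand="+",
            exons=((pos, pos + 600), (pos + 800, pos + 1400)),
            biotype=CODING,
        )

    chr1_anchor_pos = [anchor_spacing * (k + 1) for k in range(cfg.n_anchors_chr1)]
    for k, pos in enumerate(chr1_anchor_pos):
        ref_tx.append(_anchor("mouse", f"MANC{k:03d}", "chr1", pos))
        human_tx.append(_anchor("human", f"HANC{k:03d}", "chr1", pos))

    # human chr2 anchors: same gene ids, reordered along the chromosome
    chr2_slot = 4_500
    chr2_anchor_slots = [j for j in range(0, cfg.n_lnc + cfg.n_anchors_chr2, 20)][
        : cfg.n_anchors_chr2
    ]
    chr2_anchor_pos = [5_000 + j * chr2_slot for j in chr2_anchor_slots]
    perm = rng_struct.permutation(cfg.n_anchors_chr2)
    for k, pos in enumerate(chr2_anchor_pos):
        ref_tx.append(_anchor("mouse", f"MANC{cfg.n_anchors_chr1 + k:03d}", "chr2", pos))
        human_tx.append(
            _anchor("human", f"HANC{cfg.n_anchors_chr1 + int(perm[k]):03d}", "chr2", pos)
        )

    # ---- lncRNA transcripts ------------------------------------------------
    lengths = np.zeros(n, dtype=int)
    seqs: Dict[str, str] = {}
    planted_orf_aa: Dict[int, int] = {}
    chr2_lnc = [i for i in range(n) if i not in idx_synteny]
    chr2_free_slots = [j for j in range(cfg.n_lnc + cfg.n_anchors_chr2) if j not in chr2_anchor_slots]

    for i in range(n):
        if i in idx_contaminant:
            orf_aa = int(rng_seq.integers(150, 250))
            seq, _utr = _contaminant_seq(rng_seq, orf_aa)
            planted_orf_aa[i] = orf_aa
            lengths[i] = len(seq)
        elif i in idx_short:
            lengths[i] = int(rng_seq.integers(120, 180))
            seq = _random_seq(rng_seq, lengths[i])
        else:
            lengths[i] = int(rng_seq.integers(300, 3000))
            seq = _random_seq(rng_seq, lengths[i])
        seqs[tx_ids[i]] = seq

    for rank, i in enumerate(idx_synteny):
        pos = chr1_anchor_pos[2 * rank] + 10_000
        n_exons = int(rng_struct.integers(1, 4))
        exons = _exon_chain(rng_struct, pos, int(lengths[i]), n_exons)
        mouse_tx.append(
            TranscriptModel(tx_ids[i], gene_ids[i], "chr1", "+", exons, NONCODING)
        )
    for rank, i in enumerate(chr2_lnc):
        pos = 5_000 + chr2_free_slots[rank] * chr2_slot
        n_exons = int(rng_struct.integers(1, 4))
        exons = _exon_chain(rng_struct, pos, int(lengths[i]), n_exons)
        mouse_tx.append(
            TranscriptModel(tx_ids[i], gene_ids[i], "chr2", "+", exons, NONCODING)
        )

    by_tid = {t.transcript_id: t for t in mouse_tx}
    for i in range(n):
        if known[i]:
            t = by_tid[tx_ids[i]]
            jit = int(rng_struct.integers(1, 11))
            exons = list(t.exons)
            s0, e0 = exons[0]
            exons[0] = (max(0, s0 - jit), e0 if len(exons) > 1 else e0 + jit)
            if len(exons) > 1:
                s1, e1 = exons[-1]
                exons[-1] = (s1, e1 + jit)
            ref_tx.append(
                TranscriptModel(
                    f"REF_{tx_ids[i]}", f"REF_{gene_ids[i]}", t.chrom, t.strand,
                    tuple(exons), NONCODING,
                )
            )

    # human ncRNAs: synteny partners in the matching chr1 gaps, sequence
    # partners as chr2 features
    human_seqs: Dict[str, str] = {}
    synteny_pairs: List[List[str]] = []
    for rank, i in enumerate(idx_synteny):
        hid = f"HLNC{i:04d}"
        pos = chr1_anchor_pos[2 * rank] + 10_000
        human_tx.append(
            TranscriptModel(f"{hid}.1", hid, "chr1", "+", ((pos, pos + 500),), NONCODING)
        )
        synteny_pairs.append([gene_ids[i], hid])

    sequence_pairs: List[List] = []
    aln_rows: List[List] = []
    for rank, i in enumerate(idx_seq):
        hid = f"HSEQ{i:04d}"
        mutant, identity = _mutate(rng_aln, seqs[tx_ids[i]], cfg.substitution_rate)
        human_seqs[hid] = mutant
        pos = 5_000 + (rank + 1) * 3_000
        human_tx.append(
            TranscriptModel(
                f"{hid}.1", hid, "chr2", "+", ((pos, pos + len(mutant)),), NONCODING
            )
        )
        length = len(mutant)
        matches = int(round(identity / 100.0 * length))
        aln_rows.append(
            [tx_ids[i], hid, round(identity, 2), length, length - matches, 0,
             1, length, 1, length, 1e-60, round(1.9 * matches, 1)]
        )
        sequence_pairs.append([tx_ids[i], hid, round(identity, 2)])
    # decoy alignments: below the identity or length thresholds
    decoy_targets = idx_plain[:40]
    for j, i in enumerate(decoy_targets):
        hid = f"HSEQ{idx_seq[j % len(idx_seq)]:04d}"
        if j % 2 == 0:
            ident, length = float(rng_aln.uniform(55, 78)), int(rng_aln.integers(120, 400))
        else:
            ident, length = float(rng_aln.uniform(82, 95)), int(rng_aln.integers(40, 95))
        matches = int(round(ident / 100.0 * length))
        aln_rows.append(
            [tx_ids[i], hid, round(ident, 2), length, length - matches, 0,
             1, length, 1, length, 1e-5, round(1.2 * matches, 1)]
        )

    # ---- anchor protein homology (BLASTP-like) -----------------------------
    hom_rows: List[List] = []
    for k in range(cfg.n_anchors_chr1):
        bits = float(rng_hom.uniform(120, 300))
        hom_rows.append(
            [f"MANC{k:03d}", f"HANC{k:03d}", round(float(rng_hom.uniform(70, 95)), 2),
             400, 40, 2, 1, 400, 1, 400, 1e-80, round(bits, 1)]
        )
    for k in range(cfg.n_anchors_chr2):
        gid = cfg.n_anchors_chr1 + k
        bits = float(rng_hom.uniform(22, 45))  # diverged: below the 50-bit anchor threshold
        hom_rows.append(
            [f"MANC{gid:03d}", f"HANC{gid:03d}", round(float(rng_hom.uniform(30, 50)), 2),
             150, 90, 5, 1, 150, 1, 150, 0.01, round(bits, 1)]
        )

    # ---- protein homology of transcripts (BLASTX-like, Swiss-Prot stand-in)
    prot_rows: List[List] = []
    for i in idx_contaminant:
        bits = float(rng_hom.uniform(60, 180))
        prot_rows.append(
            [tx_ids[i], f"SP{i:05d}", round(float(rng_hom.uniform(40, 90)), 2),
             planted_orf_aa[i], 30, 1, 1, 3 * planted_orf_aa[i], 1,
             planted_orf_aa[i], 1e-30, round(bits, 1)]
        )
    for i in idx_plain[40:70]:
        bits = float(rng_hom.uniform(20, 45))
        prot_rows.append(
            [tx_ids[i], f"SPX{i:05d}", round(float(rng_hom.uniform(25, 45)), 2),
             60, 35, 3, 1, 180, 1, 60, 0.5, round(bits, 1)]
        )

    # ---- compartment expression (FPKM) -------------------------------------
    compartments = ["podocyte", "glomerulus", "kidney"]
    samples = [f"{c}_{r + 1}" for c in compartments for r in range(cfg.n_replicates)]
    comp_of = {s: s.rsplit("_", 1)[0] for s in samples}
    profiles = np.zeros((n, 3))
    levels = np.zeros(n)
    specific_set = set(idx_specific)
    for i in range(n):
        if i in specific_set:
            f = rng_expr.uniform(0.88, 0.95)
            rest = rng_expr.dirichlet([2.0, 2.0]) * (1 - f)
            profiles[i] = [f, rest[0], rest[1]]
        else:
            prof = rng_expr.dirichlet([2.0, 2.0, 2.0])
            while prof.max() > 0.70:
                prof = rng_expr.dirichlet([2.0, 2.0, 2.0])
            profiles[i] = prof
        if i in idx_unexpressed:
            levels[i] = rng_expr.uniform(0.05, 0.5)
        else:
            levels[i] = np.exp(rng_expr.uniform(np.log(3.0), np.log(50.0)))
    noise = rng_expr.lognormal(0.0, 0.15, size=(n, len(samples)))
    comp_index = np.array([compartments.index(comp_of[s]) for s in samples])
    fpkm = levels[:, None] * profiles[:, comp_index] * noise
    expr_df = pd.DataFrame(np.round(fpkm, 4), index=tx_ids, columns=samples)

    # ---- NB counts per disease model ---------------------------------------
    phi = cfg.dispersion
    r_nb = 1.0 / phi
    count_tables: Dict[str, pd.DataFrame] = {}
    sheet_tables: Dict[str, pd.DataFrame] = {}
    mu = np.exp(rng_counts.uniform(np.log(30.0), np.log(300.0), size=n))
    for model in MODELS:
        two_factor = model != "adriamycin"
        if two_factor:
            cols, cond, age = [], [], []
            for a in ("4w", "12w"):
                for c in ("control", "disease"):
                    for rep in range(cfg.n_replicates):
                        cols.append(f"{model}_{c}_{a}_{rep + 1}")
                        cond.append(c)
                        age.append(a)
            beta_age = rng_counts.normal(0.0, 0.2, size=n)
        else:
            cols = [
                f"{model}_{c}_{rep + 1}"
                for c in ("control", "disease")
                for rep in range(cfg.n_replicates)
            ]
            cond = ["control"] * cfg.n_replicates + ["disease"] * cfg.n_replicates
            age = [""] * len(cols)
            beta_age = np.zeros(n)
        counts = np.zeros((n, len(cols)), dtype=int)
        for j, col in enumerate(cols):
            fold = np.array(
                [2.0 ** lfc[model].get(i, 0.0) if cond[j] == "disease" else 1.0 for i in range(n)]
            )
            age_fold = 2.0 ** (beta_age * (1.0 if age[j] == "12w" else 0.0))
            mean = mu * fold * age_fold
            counts[:, j] = rng_counts.negative_binomial(r_nb, r_nb / (r_nb + mean))
        count_tables[model] = pd.DataFrame(counts, index=gene_ids, columns=cols)
        sheet = pd.DataFrame({"sample": cols, "model": model, "condition": cond})
        if two_factor:
            sheet["age"] = age
        sheet_tables[model] = sheet

    # ---- human kidney expression (TPM, 4 samples) --------------------------
    human_features = [p[1] for p in synteny_pairs] + [p[1] for p in sequence_pairs]
    h_samples = [f"gtex_kidney_{k + 1}" for k in range(4)]
    h_expressed: Dict[str, bool] = {}
    h_rows = []
    for k, hid in enumerate(human_features):
        expressed = k % 5 < 3
        h_expressed[hid] = expressed
        if expressed:
            row = rng_hexpr.uniform(2.0, 20.0, 4)
        else:
            row = rng_hexpr.uniform(0.0, 0.5, 4)
        h_rows.append(np.round(row, 3))
    human_expr = pd.DataFrame(h_rows, index=human_features, columns=h_samples)

    # ---- single-cell matrix -------------------------------------------------
    markers = ["Wt1", "Nphs1", "Nphs2", "Mafb"]
    sc_genes = markers + gene_ids
    n_cells = cfg.n_podocyte_cells + cfg.n_other_cells
    cell_order = rng_sc.permutation(n_cells)
    is_pod = np.zeros(n_cells, dtype=bool)
    is_pod[cell_order[: cfg.n_podocyte_cells]] = True
    barcodes = [f"CELL{j:04d}" for j in range(n_cells)]
    dense = np.zeros((len(sc_genes), n_cells), dtype=int)
    for g in range(4):
        dense[g, is_pod] = rng_sc.poisson(5.0, is_pod.sum()) + 1
        dense[g, ~is_pod] = rng_sc.poisson(0.1, (~is_pod).sum())
    exclusive_set = set(idx_exclusive)
    broad_set = set(idx_broad)
    for i in range(n):
        row = 4 + i
        if i in exclusive_set:
            dense[row, is_pod] = rng_sc.poisson(3.0, is_pod.sum())
        elif i in broad_set:
            dense[row] = rng_sc.poisson(0.5, n_cells)
    detected_truth = {gene_ids[i]: bool((dense[4 + i] > 0).sum() >= 3) for i in range(n)}

    # ---- training sets for the coding models --------------------------------
    train_coding = {
        f"TRAINCDS{k:03d}": "ATG" + _coding_seq(rng_seq, 299) + "TAA" for k in range(120)
    }
    train_noncoding = {f"TRAINBG{k:03d}": _random_seq(rng_seq, 900) for k in range(120)}
    contexts = [_kozak_context(rng_seq) for _ in range(200)]

    # ---- write everything ----------------------------------------------------
    files = {
        "reference_gtf": "mouse_reference.gtf",
        "assembled_gtf": "mouse_assembled.gtf",
        "human_gtf": "human.gtf",
        "transcripts_fasta": "mouse_transcripts.fa",
        "human_ncrna_fasta": "human_ncrna.fa",
        "training_coding_fasta": "training_coding.fa",
        "training_noncoding_fasta": "training_noncoding.fa",
        "start_contexts": "start_contexts.txt",
        "expression_tsv": "expression_fpkm.tsv",
        "expression_samples_tsv": "expression_samples.tsv",
        "anchor_homology_tsv": "anchor_homology.tsv",
        "lnc_alignments_tsv": "lnc_alignments.tsv",
        "protein_hits_tsv": "protein_hits.tsv",
        "human_expression_tsv": "human_kidney_tpm.tsv",
        "scrna_matrix": "scrna_matrix.mtx",
        "scrna_features": "scrna_features.tsv",
        "scrna_barcodes": "scrna_barcodes.tsv",
        "manifest": "manifest.json",
    }
    for model in MODELS:
        files[f"counts_{model}_tsv"] = f"counts_{model}.tsv"
        files[f"samples_{model}_tsv"] = f"samples_{model}.tsv"

    def _path(key: str) -> str:
        return os.path.join(out_dir, files[key])

    write_gtf(AnnotationSet(ref_tx), _path("reference_gtf"))
    write_gtf(AnnotationSet(mouse_tx), _path("assembled_gtf"))
    write_gtf(AnnotationSet(human_tx), _path("human_gtf"))
    write_fasta(seqs, _path("transcripts_fasta"))
    write_fasta(human_seqs, _path("human_ncrna_fasta"))
    write_fasta(train_coding, _path("training_coding_fasta"))
    write_fasta(train_noncoding, _path("training_noncoding_fasta"))
    with open(_path("start_contexts"), "w") as fh:
        fh.write("\n".join(contexts) + "\n")
    expr_df.to_csv(_path("expression_tsv"), sep="\t")
    pd.DataFrame(
        {"sample": samples, "compartment": [comp_of[s] for s in samples]}
    ).to_csv(_path("expression_samples_tsv"), sep="\t", index=False)
    for name, rows in (
        ("anchor_homology_tsv", hom_rows),
        ("lnc_alignments_tsv", aln_rows),
        ("protein_hits_tsv", prot_rows),
    ):
        pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
            _path(name), sep="\t", header=False, index=False
        )
    human_expr.to_csv(_path("human_expression_tsv"), sep="\t")
    for model in MODELS:
        count_tables[model].to_csv(_path(f"counts_{model}_tsv"), sep="\t")
        sheet_tables[model].to_csv(_path(f"samples_{model}_tsv"), sep="\t", index=False)

    from scipy import sparse
    from scipy.io import mmwrite

    mmwrite(_path("scrna_matrix"), sparse.coo_matrix(dense))
    with open(_path("scrna_features"), "w") as fh:
        for g in sc_genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(_path("scrna_barcodes"), "w") as fh:
        fh.write("\n".join(barcodes) + "\n")

    # ---- manifest ------------------------------------------------------------
    pod_fpkm = expr_df[[s for s in samples if comp_of[s] == "podocyte"]]
    transcripts: Dict[str, Dict] = {}
    genes: Dict[str, Dict] = {}
    for i in range(n):
        tid, gid = tx_ids[i], gene_ids[i]
        expressed = bool(lengths[i] >= 200 and expr_df.loc[tid].max() >= 1.0)
        transcripts[tid] = {
            "gene_id": gid,
            "chrom": "chr1" if i in idx_synteny else "chr2",
            "length": int(lengths[i]),
            "known": bool(known[i]),
            "coding": i in idx_contaminant,
            "planted_orf_aa": planted_orf_aa.get(i),
            "expressed": expressed,
            "podocyte_expressed": bool(pod_fpkm.loc[tid].max() >= 1.0),
            "tsi_specific": i in specific_set,
            "seq_conserved": i in set(idx_seq),
            "synteny_conserved": i in set(idx_synteny),
            "homology_hit": i in set(idx_contaminant),
        }
        genes[gid] = {
            "log2fc": {m: lfc[m].get(i, 0.0) for m in MODELS},
            "scrna_detected": detected_truth[gid],
            "scrna_podocyte_exclusive": i in exclusive_set,
        }
    for hid, expressed in h_expressed.items():
        genes[hid] = {"human_expressed": expressed}

    manifest = FixtureManifest(
        seed=cfg.seed,
        config=asdict(cfg),
        transcripts=transcripts,
        genes=genes,
        synteny_pairs=synteny_pairs,
        sequence_pairs=sequence_pairs,
        podocyte_barcodes=[barcodes[j] for j in np.flatnonzero(is_pod)],
        files=files,
    )
    manifest.save(_path("manifest"))
    return manifest
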