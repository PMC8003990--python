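"""End-to-end candidate discovery: wires every stage into one run.

Inputs are the file bundle described by a configuration mapping (paths plus
thresholds); the output bundles per-transcript and per-locus candidate
records, funnel tiers, differential-expression tables and single-cell
validation results.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from . import annotation_core as ann
from . import candidate_integration as integ
from . import coding_potential as cp
from . import conservation as cons
from . import differential_expression as de
from . import scrna_validation as sc
from . import tissue_specificity as tsi

DEFAULT_THRESHOLDS = {
    "min_len": 200,
    "min_fpkm": 1.0,
    "min_aa": 50,
    "alpha": 0.05,
    "min_bits": 50.0,
    "min_identity": 80.0,
    "min_aln_length": 100,
    "tsi_threshold": 0.8,
    "fdr": 0.05,
    "max_anchor_distance": 100_000,
    "min_tpm": 1.0,
    "min_human_samples": 1,
}

MODEL_DESIGNS = {"wt1": "two_factor", "podocin": "two_factor", "adriamycin": "one_factor"}


@dataclass
class PipelineResult:
    transcript_records: List[integ.CandidateRecord]
    locus_records: List[integ.CandidateRecord]
    transcript_tiers: pd.DataFrame
    transcript_upset: pd.DataFrame
    locus_tiers: pd.DataFrame
    locus_upset: pd.DataFrame
    loci: List[ann.GeneLocus]
    known_novel: Dict[str, str]
    verdicts: Dict[str, cp.CodingVerdict]
    tsi_table: pd.DataFrame
    ortholog_pairs: List[cons.OrthologPair]
    de_results: Dict[str, Dict[str, pd.DataFrame]]
    de_calls: Dict[str, pd.DataFrame]
    coherence: pd.DataFrame
    scrna: pd.DataFrame

    def summary(self) -> Dict[str, object]:
        t_sizes = integ.tier_sizes(self.transcript_tiers)
        l_sizes = integ.tier_sizes(self.locus_tiers)
        n_novel = sum(1 for v in self.known_novel.values() if v == "novel")
        return {
            "n_transcripts": len(self.transcript_records),
            "n_novel": n_novel,
            "n_loci": len(self.loci),
            "transcript_tiers": t_sizes,
            "locus_tiers": l_sizes,
            "n_ortholog_pairs": len(self.ortholog_pairs),
            "de_significant": {
                m: int(calls["significant"].sum()) for m, calls in self.de_calls.items()
            },
            "scrna_detected": int(self.scrna["detected"].sum()),
        }


def _load_config(cfg: Mapping) -> Tuple[Dict[str, str], Dict[str, float]]:
    paths = dict(cfg["inputs"])
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    base = cfg.get("base_dir", "")
    if base:
        paths = {k: os.path.join(base, v) for k, v in paths.items()}
    return paths, thresholds


def run_pipeline(config: Mapping) -> PipelineResult:
    """Run every stage on the files named in ``config`` and integrate flags.

    ``config["inputs"]`` uses the same keys as the fixture generator's file
    manifest (reference_gtf, assembled_gtf, expression_tsv, ...).
    """
    paths, thr = _load_config(config)

    reference = ann.read_gtf(paths["reference_gtf"])
    assembled = ann.read_gtf(paths["assembled_gtf"])
    human_annot = ann.read_gtf(paths["human_gtf"])
    seqs = ann.read_fasta(paths["transcripts_fasta"])
    expr = ann.read_expression_table(
        paths["expression_tsv"], paths["expression_samples_tsv"]
    )

    known_novel = ann.classify_transcripts(assembled, reference)
    selected = cp.select_candidates(
        assembled, expr, min_len=int(thr["min_len"]), min_fpkm=thr["min_fpkm"]
    )

    # coding-potential models trained from the bundled training sets
    train_coding = ann.read_fasta(paths["training_coding_fasta"])
    train_bg = ann.read_fasta(paths["training_noncoding_fasta"])
    hexamer = cp.train_hexamer_model(train_coding.values(), train_bg.values())
    with open(paths["start_contexts"]) as fh:
        contexts = [line.strip() for line in fh if line.strip()]
    pssm = cp.train_start_pssm(contexts)

    prot_hits = cp.read_outfmt6(paths["protein_hits_tsv"])
    homology_flagged = cp.apply_homology_filter(
        seqs.keys(), prot_hits, min_bits=thr["min_bits"]
    )
    verdicts = cp.classify_coding(
        {tid: seqs[tid] for tid in sorted(selected) if tid in seqs},
        hexamer,
        pssm,
        homology_flagged,
        min_aa=int(thr["min_aa"]),
        alpha=thr["alpha"],
    )
    noncoding = {tid for tid, v in verdicts.items() if v.verdict == "noncoding"}

    # compartment specificity over expressed noncoding transcripts
    tsi_table = tsi.compute_tsi_table(expr, threshold=thr["tsi_threshold"])
    podocyte_specific = tsi.podocyte_specific_set(tsi_table, threshold=thr["tsi_threshold"])
    pod_samples = expr.samples_of("podocyte")
    pod_expressed = set(
        expr.values.index[(expr.values[pod_samples].max(axis=1) >= thr["min_fpkm"])]
    )

    # conservation: sequence route (alignment table) + synteny route
    aln = cp.read_outfmt6(paths["lnc_alignments_tsv"])
    seq_pairs = cons.sequence_conservation_from_table(
        aln, min_identity=thr["min_identity"], min_length=int(thr["min_aln_length"])
    )
    seq_pairs = [p for p in seq_pairs if p.mouse_lnc_id not in homology_flagged]

    anchor_hom = cp.read_outfmt6(paths["anchor_homology_tsv"])
    mouse_union = ann.AnnotationSet(
        [t for t in reference if t.biotype == ann.CODING] + list(assembled)
    )
    mouse_orders = cons.gene_order_from_annotation(mouse_union, "mouse")
    human_orders = cons.gene_order_from_annotation(human_annot, "human")
    blocks: List[cons.SyntenyBlock] = []
    for m_chrom, m_order in mouse_orders.items():
        for h_chrom, h_order in human_orders.items():
            blocks.extend(
                cons.align_gene_orders(m_order, h_order, anchor_hom, match_bits=thr["min_bits"])
            )
    clean_noncoding = {t for t in noncoding if t not in homology_flagged}
    mouse_lncs = {}
    for tid in sorted(clean_noncoding):
        t = assembled[tid]
        mouse_lncs.setdefault(t.gene_id, (t.chrom, (t.start + t.end) // 2))
    syn_pairs = cons.predict_synteny_orthologs(
        mouse_lncs, blocks, mouse_orders, human_orders,
        max_anchor_distance=int(thr["max_anchor_distance"]),
    )
    human_expr = pd.read_csv(paths["human_expression_tsv"], sep="\t", index_col=0)
    pairs = cons.human_expression_check(
        seq_pairs + syn_pairs, human_expr,
        min_tpm=thr["min_tpm"], min_samples=int(thr["min_human_samples"]),
    )

    seq_conserved_tids = {p.mouse_lnc_id for p in pairs if p.evidence == "sequence"}
    syn_conserved_genes = {p.mouse_lnc_id for p in pairs if p.evidence == "synteny"}
    human_expressed_features = {
        p.mouse_lnc_id for p in pairs if p.human_expressed
    }

    # gene loci and differential expression
    loci = ann.bundle_loci(assembled.subset(sorted(noncoding)))
    locus_of_gene: Dict[str, str] = {}
    for locus in loci:
        for tid in locus.transcript_ids:
            locus_of_gene.setdefault(assembled[tid].gene_id, locus.locus_id)

    de_results: Dict[str, Dict[str, pd.DataFrame]] = {}
    de_calls: Dict[str, pd.DataFrame] = {}
    for model, design in MODEL_DESIGNS.items():
        matrix = de.read_count_matrix(
            paths[f"counts_{model}_tsv"], paths[f"samples_{model}_tsv"]
        )
        de_results[model] = de.run_model(matrix, model, design, fdr=thr["fdr"])
        de_calls[model] = de.de_locus_calls(de_results[model])
    shared_index = de_calls["wt1"].index
    coherence = de.cross_model_summary(
        {m: calls.loc[shared_index] for m, calls in de_calls.items()}
    )

    # single-cell validation at the gene level
    matrix = sc.read_10x_mtx(
        paths["scrna_matrix"], paths["scrna_features"], paths["scrna_barcodes"]
    )
    labeled = sc.label_podocytes(matrix)
    gene_ids_sc = sorted({t.gene_id for t in assembled})
    scrna = sc.wilcoxon_specificity(labeled, gene_ids_sc)

    # integrate per-transcript flags
    def _de_flag(model: str, gene_id: str) -> bool:
        calls = de_calls[model]
        return bool(calls["significant"].get(gene_id, False))

    records: List[integ.CandidateRecord] = []
    for t in assembled:
        tid, gid = t.transcript_id, t.gene_id
        verdict = verdicts.get(tid)
        sc_row = scrna.loc[gid] if gid in scrna.index else None
        flags = {
            "expressed": tid in selected,
            "novel": known_novel[tid] == "novel",
            "noncoding": verdict is not None and verdict.verdict == "noncoding",
            "podocyte_expressed": tid in pod_expressed,
            "tsi_specific": tid in podocyte_specific,
            "seq_conserved": tid in seq_conserved_tids,
            "synteny_conserved": gid in syn_conserved_genes,
            "homology_clean": tid not in homology_flagged,
            "human_expressed": tid in human_expressed_features
            or gid in human_expressed_features,
            "de_wt1": _de_flag("wt1", gid),
            "de_podocin": _de_flag("podocin", gid),
            "de_adriamycin": _de_flag("adriamycin", gid),
            "scrna_detected": bool(sc_row["detected"]) if sc_row is not None else False,
            "scrna_podocyte_specific": bool(
                sc_row is not None
                and sc_row["detected"]
                and sc_row["podocyte_enriched"]
                and sc_row["q"] < thr["fdr"]
            ),
        }
        records.append(integ.CandidateRecord(tid, "transcript", flags))

    locus_de_flags = {}
    for locus in loci:
        member_genes = {assembled[tid].gene_id for tid in locus.transcript_ids}
        locus_de_flags[locus.locus_id] = {
            f"de_{m}": any(_de_flag(m, g) for g in member_genes) for m in MODEL_DESIGNS
        }
    bundled_tids = {tid for locus in loci for tid in locus.transcript_ids}
    locus_records = integ.transcript_to_locus_rollup(
        [r for r in records if r.feature_id in bundled_tids], loci, locus_de_flags
    )

    transcript_tiers, transcript_upset = integ.build_funnel(records)
    locus_tiers, locus_upset = integ.build_funnel(locus_records)

    return PipelineResult(
        transcript_records=records,
        locus_records=locus_records,
        transcript_tiers=transcript_tiers,
        transcript_upset=transcript_upset,
        locus_tiers=locus_tiers,
        locus_upset=locus_upset,
        loci=loci,
        known_novel=known_novel,
        verdicts=verdicts,
        tsi_table=tsi_table,
        ortholog_pairs=pairs,
        de_results=de_results,
        de_calls=de_calls,
        coherence=coherence,
        scrna=scrna,
    )


def fixture_config(fixture_dir: str, **thresholds) -> Dict:
    """Pipeline configuration pointing at a generated fixture bundle."""
    import json

    with open(os.path.join(fixture_dir, "manifest.json")) as fh:
        files = json.load(fh)["files"]
    inputs = {k: v for k, v in files.items() if k != "manifest"}
    return {"base_dir": fixture_dir, "inputs": inputs, "thresholds": thresholds}
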