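"""Human conservation of mouse lncRNAs by synteny and by sequence.

Two independent evidence routes assign human counterparts to mouse lncRNAs:

* **Gene-order synteny** — protein-coding genes serve as anchors; local
  gene-order alignments between mouse and human chromosomes are computed by a
  Smith-Waterman-style dynamic program whose pair score is +1 when the two
  anchors share protein homology (bit score above a threshold) and -1
  otherwise, with gaps at -0.5. lncRNAs immediately flanking an aligned mouse
  anchor inherit the human ncRNAs immediately flanking the matched human
  anchor as candidate orthologs.

* **Sequence identity** — nucleotide alignments (BLAST tabular, or the
  built-in affine-gap local aligner for small inputs) are retained when
  identity exceeds 80% and aligned length exceeds 100 bp (both strict).

Predicted human orthologs can additionally be checked for expression in human
kidney samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation_core import AnnotationSet, CODING, ExpressionTable


@dataclass(frozen=True)
class OrderedGene:
    gene_id: str
    position: int  # midpoint on the chromosome
    strand: str
    biotype: str


@dataclass
class GeneOrder:
    """Genes of one chromosome of one species, ordered by midpoint."""

    species: str
    chrom: str
    genes: List[OrderedGene]

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.position, g.gene_id))
        positions = [g.position for g in self.genes]
        if len(set(positions)) != len(positions):
            raise ValueError("gene midpoints must be distinct within a chromosome")

    @property
    def anchors(self) -> List[OrderedGene]:
        """Protein-coding genes only; the units of the gene-order alignment."""
        return [g for g in self.genes if g.biotype == CODING]

    def reversed(self) -> "GeneOrder":
        """The same chromosome traversed in the opposite orientation."""
        maxpos = max((g.position for g in self.genes), default=0)
        flipped = [
            OrderedGene(g.gene_id, maxpos - g.position, "-" if g.strand == "+" else "+", g.biotype)
            for g in self.genes
        ]
        return GeneOrder(self.species, self.chrom, flipped)


def gene_order_from_annotation(annot: AnnotationSet, species: str) -> Dict[str, GeneOrder]:
    """Per-chromosome gene orders with gene midpoints and majority biotype."""
    orders: Dict[str, GeneOrder] = {}
    for chrom in sorted(annot.chroms()):
        per_gene: Dict[str, List] = {}
        for t in annot.by_chrom(chrom):
            per_gene.setdefault(t.gene_id, []).append(t)
        genes = []
        for gid, members in per_gene.items():
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            biotype = CODING if any(m.biotype == CODING for m in members) else members[0].biotype
            genes.append(OrderedGene(gid, (start + end) // 2, members[0].strand, biotype))
        orders[chrom] = GeneOrder(species, chrom, genes)
    return orders


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    anchor_pairs: Tuple[Tuple[str, str], ...]  # (mouse_gene, human_gene)
    score: float
    chrom_pair: Tuple[str, str]
    orientation: int = 1  # -1 when the human order is inverted in this block


@dataclass(frozen=True)
class OrthologPair:
    mouse_lnc_id: str
    human_feature_id: str
    evidence: str  # "synteny" | "sequence"
    identity: Optional[float] = None
    aln_length: Optional[int] = None
    anchor: Optional[Tuple[str, str]] = None
    human_expressed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.evidence not in ("synteny", "sequence"):
            raise ValueError(f"bad evidence {self.evidence!r}")
        if self.evidence == "sequence":
            if self.identity is None or self.aln_length is None:
                raise ValueError("sequence evidence requires identity and aln_length")
            if not (self.identity > 80.0 and self.aln_length > 100):
                raise ValueError("sequence evidence requires identity>80 and length>100")


# ---------------------------------------------------------------------------
# Gene-order local alignment
# ---------------------------------------------------------------------------

def _homology_pairs(homology: pd.DataFrame, min_bits: float) -> Set[Tuple[str, str]]:
    if homology.empty:
        return set()
    strong = homology[homology["bitscore"] >= min_bits]
    return set(zip(strong["qseqid"], strong["sseqid"]))


def _gene_order_dp(
    a: Sequence[str],
    b: Sequence[str],
    pairs: Set[Tuple[str, str]],
    match: float,
    mismatch: float,
    gap: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Local-alignment score matrix H and a traceback pointer matrix.

    Pointer codes: 0 stop, 1 diagonal, 2 up (gap in b), 3 left (gap in a);
    ties resolve diagonal > up > left.
    """
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1))
    P = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (a[i - 1], b[j - 1]) in pairs else mismatch
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            best = max(0.0, diag, up, left)
            H[i, j] = best
            if best <= 0.0:
                P[i, j] = 0
            elif best == diag:
                P[i, j] = 1
            elif best == up:
                P[i, j] = 2
            else:
                P[i, j] = 3
    return H, P


def _traceback_block(
    H: np.ndarray,
    P: np.ndarray,
    i: int,
    j: int,
    a: Sequence[str],
    b: Sequence[str],
    pairs: Set[Tuple[str, str]],
) -> List[Tuple[str, str]]:
    matched: List[Tuple[str, str]] = []
    while H[i, j] > 0 and P[i, j] != 0:
        if P[i, j] == 1:
            if (a[i - 1], b[j - 1]) in pairs:
                matched.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif P[i, j] == 2:
            i -= 1
        else:
            j -= 1
    matched.reverse()
    return matched


def align_gene_orders(
    mouse: GeneOrder,
    human: GeneOrder,
    homology: pd.DataFrame,
    match_bits: float = 50.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -0.5,
    min_block_score: float = 3.0,
) -> List[SyntenyBlock]:
    """All local gene-order alignments (synteny blocks) between two chromosomes.

    Both orientations of the human chromosome are scanned, so whole-chromosome
    inversions are recovered. Blocks are extracted greedily by descending
    score; an anchor gene participates in at most one reported block.
    """
    a = [g.gene_id for g in mouse.anchors]
    pairs = _homology_pairs(homology, match_bits)
    candidates: List[Tuple[float, int, List[Tuple[str, str]]]] = []
    for orientation, horder in ((1, human), (-1, human.reversed())):
        b = [g.gene_id for g in horder.anchors]
        if not a or not b:
            continue
        H, P = _gene_order_dp(a, b, pairs, match, mismatch, gap)
        cells = [
            (float(H[i, j]), i, j)
            for i in range(1, len(a) + 1)
            for j in range(1, len(b) + 1)
            if H[i, j] >= min_block_score
        ]
        for score, i, j in sorted(cells, key=lambda c: (-c[0], c[1], c[2])):
            matched = _traceback_block(H, P, i, j, a, b, pairs)
            if matched:
                candidates.append((score, orientation, matched))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_mouse: Set[str] = set()
    used_human: Set[str] = set()
    blocks: List[SyntenyBlock] = []
    for score, orientation, matched in candidates:
        if any(mg in used_mouse or hg in used_human for mg, hg in matched):
            continue
        used_mouse.update(mg for mg, _ in matched)
        used_human.update(hg for _, hg in matched)
        blocks.append(
            SyntenyBlock(
                block_id=f"SYN{len(blocks) + 1:04d}",
                anchor_pairs=tuple(matched),
                score=score,
                chrom_pair=(mouse.chrom, human.chrom),
                orientation=orientation,
            )
        )
    return blocks


def best_local_gene_order_score(
    a: Sequence[str],
    b: Sequence[str],
    pairs: Set[Tuple[str, str]],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -0.5,
) -> float:
    """Maximum local gene-order alignment score (DP, single orientation)."""
    H, _ = _gene_order_dp(a, b, pairs, match, mismatch, gap)
    return float(H.max())


# ---------------------------------------------------------------------------
# Synteny-based ortholog prediction
# ---------------------------------------------------------------------------

def _flanking_anchors(order: GeneOrder, position: int) -> List[OrderedGene]:
    """Nearest protein-coding gene on each side of ``position``."""
    left = None
    right = None
    for g in order.anchors:
        if g.position <= position:
            left = g
        elif right is None:
            right = g
            break
    return [g for g in (left, right) if g is not None]


def _adjacent_ncrnas(
    order: GeneOrder, anchor: OrderedGene, max_distance: int
) -> List[OrderedGene]:
    """ncRNAs whose nearest coding neighbour is ``anchor``, within ``max_distance`` bp."""
    out = []
    for g in order.genes:
        if g.biotype == CODING:
            continue
        if abs(g.position - anchor.position) > max_distance:
            continue
        if any(f.gene_id == anchor.gene_id for f in _flanking_anchors(order, g.position)):
            out.append(g)
    return out


def predict_synteny_orthologs(
    mouse_lncs: Mapping[str, Tuple[str, int]],
    blocks: Sequence[SyntenyBlock],
    mouse_orders: Mapping[str, GeneOrder],
    human_orders: Mapping[str, GeneOrder],
    max_anchor_distance: int = 100_000,
) -> List[OrthologPair]:
    """Candidate human orthologs of mouse lncRNAs via aligned flanking anchors.

    ``mouse_lncs`` maps lncRNA gene/locus ids to (chrom, midpoint). For each
    lncRNA, each flanking coding anchor that participates in a synteny block
    yields every human ncRNA adjacent to the matched human anchor (within
    ``max_anchor_distance``) as an ortholog candidate.
    """
    anchor_map: Dict[str, List[Tuple[str, SyntenyBlock]]] = {}
    for block in blocks:
        for mg, hg in block.anchor_pairs:
            anchor_map.setdefault(mg, []).append((hg, block))

    human_gene_chrom = {
        g.gene_id: (chrom, g)
        for chrom, order in human_orders.items()
        for g in order.genes
    }

    pairs: List[OrthologPair] = []
    seen: Set[Tuple[str, str]] = set()
    for lnc_id in sorted(mouse_lncs):
        chrom, pos = mouse_lncs[lnc_id]
        order = mouse_orders.get(chrom)
        if order is None or not order.anchors:
            continue
        for anchor in _flanking_anchors(order, pos):
            if abs(anchor.position - pos) > max_anchor_distance:
                continue
            for human_gene_id, _block in anchor_map.get(anchor.gene_id, []):
                entry = human_gene_chrom.get(human_gene_id)
                if entry is None:
                    continue
                h_chrom, h_anchor = entry
                for nc in _adjacent_ncrnas(human_orders[h_chrom], h_anchor, max_anchor_distance):
                    key = (lnc_id, nc.gene_id)
                    if key in seen:
                        continue
                    seen.add(key)
                    pairs.append(
                        OrthologPair(
                            mouse_lnc_id=lnc_id,
                            human_feature_id=nc.gene_id,
                            evidence="synteny",
                            anchor=(anchor.gene_id, human_gene_id),
                        )
                    )
    return pairs


# ---------------------------------------------------------------------------
# Internal affine-gap local aligner (for fixtures and small inputs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    score: float
    identity: float  # percent of aligned columns that match
    aln_length: int  # aligned columns, gaps included
    query_range: Tuple[int, int]
    subject_range: Tuple[int, int]


def smith_waterman(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> LocalAlignment:
    """Affine-gap local alignment (Gotoh). First gap base costs ``gap_open``,
    each further base ``gap_extend``."""
    q, s = query.upper(), subject.upper()
    m, n = len(q), len(s)
    NEG = -1e30
    M = np.full((m + 1, n + 1), 0.0)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in subject (consume query)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in query (consume subject)
    # pointers: for M 0=stop,1=diag from M,2=diag from Ix,3=diag from Iy
    PM = np.zeros((m + 1, n + 1), dtype=np.int8)
    PX = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1=open from M, 2=extend
    PY = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = (0.0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            opts = (
                M[i - 1, j - 1],
                Ix[i - 1, j - 1],
                Iy[i - 1, j - 1],
            )
            k = int(np.argmax(opts))
            val = opts[k] + sub
            if val <= 0.0:
                M[i, j] = 0.0
                PM[i, j] = 0
            else:
                M[i, j] = val
                PM[i, j] = k + 1
            open_x = M[i - 1, j] + gap_open
            ext_x = Ix[i - 1, j] + gap_extend
            if open_x >= ext_x:
                Ix[i, j], PX[i, j] = open_x, 1
            else:
                Ix[i, j], PX[i, j] = ext_x, 2
            open_y = M[i, j - 1] + gap_open
            ext_y = Iy[i, j - 1] + gap_extend
            if open_y >= ext_y:
                Iy[i, j], PY[i, j] = open_y, 1
            else:
                Iy[i, j], PY[i, j] = ext_y, 2
            if M[i, j] > best[0]:
                best = (float(M[i, j]), i, j)

    score, i, j = best
    if score <= 0.0:
        return LocalAlignment(0.0, 0.0, 0, (0, 0), (0, 0))
    end_q, end_s = i, j
    matches = 0
    columns = 0
    state = "M"
    while True:
        if state == "M":
            if PM[i, j] == 0:
                break
            columns += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            prev = PM[i, j]
            i, j = i - 1, j - 1
            if M[i, j] <= 0.0 and prev == 1:
                break
            state = {1: "M", 2: "X", 3: "Y"}[prev]
        elif state == "X":
            columns += 1
            prev = PX[i, j]
            i -= 1
            state = "M" if prev == 1 else "X"
        else:
            columns += 1
            prev = PY[i, j]
            j -= 1
            state = "M" if prev == 1 else "Y"
    identity = 100.0 * matches / columns if columns else 0.0
    return LocalAlignment(score, identity, columns, (i, end_q), (j, end_s))


# ---------------------------------------------------------------------------
# Sequence-conservation filter
# ---------------------------------------------------------------------------

def sequence_conservation_from_table(
    alignments: pd.DataFrame,
    min_identity: float = 80.0,
    min_length: int = 100,
) -> List[OrthologPair]:
    """Ortholog pairs from a BLAST tabular alignment table.

    Retains alignments with identity strictly above ``min_identity`` percent
    and aligned length strictly above ``min_length`` bp.
    """
    if not alignments.empty:
        bad = alignments[(alignments["pident"] < 0) | (alignments["pident"] > 100)]
        if len(bad):
            raise ValueError("percent identity outside [0, 100]")
    pairs = []
    seen: Set[Tuple[str, str]] = set()
    for row in alignments.itertuples():
        if row.pident > min_identity and row.length > min_length:
            key = (row.qseqid, row.sseqid)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                OrthologPair(
                    mouse_lnc_id=row.qseqid,
                    human_feature_id=row.sseqid,
                    evidence="sequence",
                    identity=float(row.pident),
                    aln_length=int(row.length),
                )
            )
    return pairs


def sequence_conservation_from_fasta(
    mouse_seqs: Mapping[str, str],
    human_seqs: Mapping[str, str],
    min_identity: float = 80.0,
    min_length: int = 100,
) -> List[OrthologPair]:
    """All-vs-all local alignment with the internal aligner, then the identity
    and length filter. Intended for small (fixture-scale) inputs."""
    pairs = []
    for mid in sorted(mouse_seqs):
        for hid in sorted(human_seqs):
            aln = smith_waterman(mouse_seqs[mid], human_seqs[hid])
            if aln.identity > min_identity and aln.aln_length > min_length:
                pairs.append(
                    OrthologPair(
                        mouse_lnc_id=mid,
                        human_feature_id=hid,
                        evidence="sequence",
                        identity=aln.identity,
                        aln_length=aln.aln_length,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# Human expression check
# ---------------------------------------------------------------------------

def human_expression_check(
    pairs: Sequence[OrthologPair],
    human_expr: pd.DataFrame,
    min_tpm: float = 1.0,
    min_samples: int = 1,
) -> List[OrthologPair]:
    """Flag each pair by expression of its human feature in kidney samples.

    ``human_expr`` is features x samples (TPM). A pair is human-expressed when
    its human feature reaches ``min_tpm`` in at least ``min_samples`` samples;
    features absent from the table are flagged False.
    """
    flagged = []
    for pair in pairs:
        if pair.human_feature_id in human_expr.index:
            row = human_expr.loc[pair.human_feature_id]
            expressed = bool((row >= min_tpm).sum() >= min_samples)
        else:
            expressed = False
        flagged.append(replace(pair, human_expressed=expressed))
    return flagged


def pairs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_lnc_id": p.mouse_lnc_id,
                "human_feature_id": p.human_feature_id,
                "evidence": p.evidence,
                "identity": p.identity,
                "aln_length": p.aln_length,
                "anchor": "|".join(p.anchor) if p.anchor else "",
                "human_expressed": p.human_expressed,
            }
            for p in pairs
        ]
    )
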