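"""Single-cell validation of podocyte-specific expression.

Cells from droplet (10x-style) glomerular scRNA-seq are labelled podocytes
when they express all four canonical markers (Wt1, Nphs1, Nphs2, Mafb; raw
count > 0 for each). Per-gene specificity is then assessed by a two-sided
Wilcoxon rank-sum test of podocytes vs all other cells on log1p-CPM
expression — exact enumeration for small groups, tie-corrected normal
approximation otherwise — with BH correction across tested genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

from .differential_expression import bh_adjust

PODOCYTE_MARKERS = ("Wt1", "Nphs1", "Nphs2", "Mafb")
DETECTED_MIN_CELLS = 3
EXACT_MAX_GROUP = 8


@dataclass
class CellMatrix:
    """Sparse genes x cells counts with optional per-cell labels."""

    counts: sparse.csr_matrix
    gene_ids: List[str]
    barcodes: List[str]
    labels: Optional[np.ndarray] = None  # "podocyte" | "other" | "unassigned"

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode lists")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.labels is None:
            self.labels = np.full(len(self.barcodes), "unassigned", dtype=object)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None


def read_10x_mtx(matrix_path: str, features_path: str, barcodes_path: str) -> CellMatrix:
    """Read a 10x triplet (MTX + features TSV + barcodes TSV).

    Features files may carry one (id), two (id, symbol) or three (id, symbol,
    type) columns; the symbol is used as the gene id when present.
    """
    counts = sparse.csr_matrix(mmread(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_ids = list(features[1] if features.shape[1] >= 2 else features[0])
    barcodes = list(pd.read_csv(barcodes_path, sep="\t", header=None)[0])
    return CellMatrix(counts, gene_ids, barcodes)


def write_10x_mtx(
    matrix: CellMatrix, matrix_path: str, features_path: str, barcodes_path: str
) -> None:
    mmwrite(matrix_path, sparse.coo_matrix(matrix.counts))
    with open(features_path, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


# ---------------------------------------------------------------------------
# Marker-gated labelling
# ---------------------------------------------------------------------------

def label_podocytes(
    matrix: CellMatrix, markers: Sequence[str] = PODOCYTE_MARKERS
) -> CellMatrix:
    """Label cells podocyte iff every marker has raw count > 0; others 'other'.

    Raises KeyError naming the first marker absent from the matrix.
    """
    marker_rows = [matrix.gene_index(m) for m in markers]
    if matrix.n_cells == 0:
        labels = np.array([], dtype=object)
    else:
        expressed = np.ones(matrix.n_cells, dtype=bool)
        for row in marker_rows:
            expressed &= np.asarray((matrix.counts[row] > 0).todense()).ravel()
        labels = np.where(expressed, "podocyte", "other").astype(object)
    return CellMatrix(matrix.counts, list(matrix.gene_ids), list(matrix.barcodes), labels)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum specificity test
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Handles ties via midranks; feasible for group sizes up to ~10.
    """
    x = list(x)
    y = list(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    obs_dev = abs(observed - mean)
    total = 0
    extreme = 0
    for combo in combinations(range(len(pooled)), n1):
        stat = ranks[list(combo)].sum()
        total += 1
        if abs(stat - mean) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(rank-sum statistic of group x, two-sided p).

    Exact enumeration when both groups have <= 8 observations, tie-corrected
    normal approximation otherwise.
    """
    ranks = stats.rankdata(np.concatenate([x, y]))
    statistic = float(ranks[: len(x)].sum())
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        p = exact_rank_sum_p(x, y)
    else:
        if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
            return statistic, 1.0
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return statistic, min(p, 1.0)


def cpm_log1p(counts: sparse.spmatrix) -> np.ndarray:
    """Per-cell counts-per-million, then log1p. Dense output."""
    dense = np.asarray(counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals[None, :] * 1e6)


def wilcoxon_specificity(
    matrix: CellMatrix,
    gene_ids: Optional[Sequence[str]] = None,
    detected_min_cells: int = DETECTED_MIN_CELLS,
) -> pd.DataFrame:
    """Per-gene podocyte-vs-other rank-sum tests on log1p-CPM expression.

    Returns one row per requested gene: cell counts expressing it in each
    group, the rank-sum statistic, two-sided p, BH q across tested genes, the
    direction of podocyte enrichment, and a detected flag (nonzero in >=
    ``detected_min_cells`` cells). Genes absent from the matrix are reported
    not detected and untested.
    """
    labels = np.asarray(matrix.labels)
    is_pod = labels == "podocyte"
    is_other = labels == "other"
    if is_pod.sum() < 1 or is_other.sum() < 1:
        raise ValueError("need at least one podocyte and one other cell")
    if gene_ids is None:
        gene_ids = list(matrix.gene_ids)

    norm = cpm_log1p(matrix.counts)
    raw = np.asarray(matrix.counts.todense())
    rows = []
    for gene in gene_ids:
        try:
            idx = matrix.gene_index(gene)
        except KeyError:
            rows.append(
                {
                    "gene": gene, "n_podocyte_expr": 0, "n_other_expr": 0,
                    "statistic": float("nan"), "p": float("nan"),
                    "podocyte_enriched": False, "detected": False,
                }
            )
            continue
        x = norm[idx, is_pod]
        y = norm[idx, is_other]
        n_cells_expr = int((raw[idx] > 0).sum())
        statistic, p = rank_sum_test(x, y)
        rows.append(
            {
                "gene": gene,
                "n_podocyte_expr": int((raw[idx, is_pod] > 0).sum()),
                "n_other_expr": int((raw[idx, is_other] > 0).sum()),
                "statistic": statistic,
                "p": p,
                "podocyte_enriched": bool(x.mean() > y.mean()),
                "detected": n_cells_expr >= detected_min_cells,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_adjust(out["p"].values)
    return out[
        ["n_podocyte_expr", "n_other_expr", "statistic", "p", "q",
         "podocyte_enriched", "detected"]
    ]
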