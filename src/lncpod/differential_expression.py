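"""Negative-binomial differential expression of lncRNA loci across FSGS models.

Counts are normalized by median-of-ratios size factors. Per-locus dispersion
is estimated by the method of moments on normalized counts and shrunk toward
a trimmed-mean common dispersion. Each locus is then fitted with a
negative-binomial log-linear model (fixed dispersion) and the condition
effect is tested by a 1-df likelihood-ratio chi-square.

Two designs are supported, matching the study layout: a two-factor design
(age + condition) for the genetic models sampled at 4 and 12 weeks, and a
one-factor design (condition) for the pharmacological model. For two-factor
models, per-age one-factor contrasts are also computed, and a locus counts as
differentially expressed when significant at either time point or in the
two-factor model.

Significance is Benjamini-Hochberg FDR < 0.05 within one model/contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-6
DEFAULT_FDR = 0.05

TWO_FACTOR_CONTRASTS = ("two_factor", "4w", "12w")


@dataclass
class CountMatrix:
    """Integer locus x sample counts with a fully labelled sample sheet.

    ``samples`` has columns sample, model, condition (control/disease) and,
    for two-factor designs, age (4w/12w).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.counts.values
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        if "sample" not in self.samples.columns or "condition" not in self.samples.columns:
            raise ValueError("sample sheet needs 'sample' and 'condition' columns")
        missing = set(self.counts.columns) - set(self.samples["sample"])
        if missing:
            raise ValueError(f"samples without sheet entry: {sorted(missing)}")


def median_of_ratios(counts: pd.DataFrame) -> np.ndarray:
    """Size factors: per-sample median ratio to the geometric-mean reference."""
    values = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    finite = np.isfinite(log_values).all(axis=1)
    if not finite.any():
        return np.ones(values.shape[1])
    ref = log_values[finite].mean(axis=1)
    factors = np.exp(np.median(log_values[finite] - ref[:, None], axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Sequence,
    size_factors: Optional[np.ndarray] = None,
    n_loci_prior: float = 50.0,
) -> pd.Series:
    """Moment-based per-locus NB dispersion, shrunk toward the common value.

    Per locus, phi_raw = (s^2 - mu) / mu^2 on normalized counts with the
    within-group pooled variance. The common dispersion is the plain mean of
    the raw (untruncated) values: truncating at zero before averaging biases
    the estimate low at small replicate numbers, which makes downstream
    p-values anticonservative. Each per-locus estimate (truncated at zero) is
    shrunk toward the common value with weight
    w = n_loci_prior / (n_loci_prior + df), df the residual degrees of
    freedom. Estimates are floored at 1e-6.
    """
    if size_factors is None:
        size_factors = median_of_ratios(counts)
    norm = counts.values / size_factors[None, :]
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    n = norm.shape[1]
    df = n - len(labels)
    mu = norm.mean(axis=1)
    if df <= 0:
        warnings.warn("no replicated groups: using common dispersion only")
        pooled_var = norm.var(axis=1, ddof=1) if n > 1 else np.zeros_like(mu)
        df = max(n - 1, 1)
    else:
        ss = np.zeros(norm.shape[0])
        for lab in labels:
            cols = norm[:, groups == lab]
            if cols.shape[1] > 1:
                ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
        pooled_var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (pooled_var - mu) / np.square(mu)
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, 0.0)
    common = max(float(phi_raw.mean()), 0.0) if len(phi_raw) else 0.0
    phi_hat = np.maximum(phi_raw, 0.0)
    w = n_loci_prior / (n_loci_prior + df)
    phi = w * common + (1.0 - w) * phi_hat
    phi = np.maximum(phi, DISPERSION_FLOOR)
    return pd.Series(phi, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Per-locus NB GLM and likelihood-ratio test
# ---------------------------------------------------------------------------

def _design_matrices(samples: pd.DataFrame, design: str) -> Tuple[np.ndarray, np.ndarray]:
    condition = (samples["condition"].values == "disease").astype(float)
    intercept = np.ones(len(samples))
    if design == "one_factor":
        full = np.column_stack([intercept, condition])
        reduced = intercept[:, None]
    elif design == "two_factor":
        if "age" not in samples.columns:
            raise ValueError("two-factor design needs an 'age' column")
        age = pd.get_dummies(samples["age"], drop_first=True).values.astype(float)
        full = np.column_stack([intercept, age, condition])
        reduced = np.column_stack([intercept, age])
    else:
        raise ValueError(f"unknown design {design!r}")
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return full, reduced


def _fit_nb_lrt(
    y: np.ndarray,
    full: np.ndarray,
    reduced: np.ndarray,
    phi: float,
    offset: np.ndarray,
) -> Tuple[float, float]:
    """(log2 fold change of the last full-model column, LRT p-value)."""
    family = sm.families.NegativeBinomial(alpha=max(phi, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_full = sm.GLM(y, full, family=family, offset=offset).fit(maxiter=100, tol=1e-8)
        fit_red = sm.GLM(y, reduced, family=family, offset=offset).fit(maxiter=100, tol=1e-8)
    lrt = 2.0 * (fit_full.llf - fit_red.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    log2fc = float(fit_full.params[-1] / np.log(2.0))
    return log2fc, p


def test_de(
    matrix: CountMatrix,
    design: str,
    dispersion: Optional[pd.Series] = None,
    fdr: float = DEFAULT_FDR,
    model: str = "",
    contrast: str = "",
) -> pd.DataFrame:
    """Per-locus NB-GLM likelihood-ratio test of the condition effect.

    Returns a DataFrame indexed by locus with log2fc, p, q (BH within this
    contrast), significance at ``fdr`` and a testable flag. All-zero loci get
    p = 1 and log2fc = 0 and are marked untestable.
    """
    counts = matrix.counts
    samples = matrix.samples.set_index("sample").loc[list(counts.columns)].reset_index()
    full, reduced = _design_matrices(samples, design)
    size_factors = median_of_ratios(counts)
    offset = np.log(size_factors)
    if dispersion is None:
        group_key = samples["condition"].astype(str)
        if design == "two_factor":
            group_key = group_key + "/" + samples["age"].astype(str)
        dispersion = estimate_dispersion(counts, group_key.values, size_factors)

    log2fcs = np.zeros(len(counts))
    pvals = np.ones(len(counts))
    testable = np.zeros(len(counts), dtype=bool)
    values = counts.values.astype(float)
    for idx in range(len(counts)):
        y = values[idx]
        if y.sum() == 0:
            continue
        try:
            log2fc, p = _fit_nb_lrt(
                y, full, reduced, float(dispersion.iloc[idx]), offset
            )
        except Exception:  # non-convergent or degenerate locus
            continue
        if not np.isfinite(p):
            continue
        log2fcs[idx], pvals[idx], testable[idx] = log2fc, p, True

    q = bh_adjust(np.where(testable, pvals, np.nan))
    out = pd.DataFrame(
        {
            "model": model,
            "contrast": contrast or design,
            "log2fc": log2fcs,
            "p": np.where(testable, pvals, 1.0),
            "q": np.where(np.isnan(q), 1.0, q),
            "testable": testable,
        },
        index=counts.index,
    )
    out["significant"] = testable & (out["q"].values < fdr)
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values are excluded from the
    family and propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        _, q_masked, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = q_masked
    return q


# ---------------------------------------------------------------------------
# Model runners and cross-model coherence
# ---------------------------------------------------------------------------

def run_model(
    matrix: CountMatrix,
    model: str,
    design: str,
    fdr: float = DEFAULT_FDR,
) -> Dict[str, pd.DataFrame]:
    """All contrasts for one disease model.

    One-factor models yield a single ``condition`` contrast; two-factor models
    yield the two-factor contrast plus per-age one-factor contrasts.
    """
    if design == "one_factor":
        return {
            "condition": test_de(matrix, "one_factor", model=model, contrast="condition", fdr=fdr)
        }
    results = {
        "two_factor": test_de(matrix, "two_factor", model=model, contrast="two_factor", fdr=fdr)
    }
    for age in ("4w", "12w"):
        keep = matrix.samples["age"] == age
        sub_samples = matrix.samples[keep]
        sub_counts = matrix.counts[list(sub_samples["sample"])]
        sub = CountMatrix(sub_counts, sub_samples.reset_index(drop=True))
        results[age] = test_de(sub, "one_factor", model=model, contrast=age, fdr=fdr)
    return results


def de_locus_calls(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Collapse a model's contrasts to one row per locus.

    A locus is differentially expressed when significant in any contrast; the
    reported log2fc is the pooled (two-factor or single-factor) contrast's.
    """
    pooled_name = "two_factor" if "two_factor" in results else "condition"
    pooled = results[pooled_name]
    sig = np.zeros(len(pooled), dtype=bool)
    for table in results.values():
        sig |= table["significant"].values
    return pd.DataFrame(
        {"log2fc": pooled["log2fc"], "significant": sig}, index=pooled.index
    )


def cross_model_summary(per_model: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Joint-significance and sign-concordance counts for model pairs/triples.

    ``per_model`` maps model name to the per-locus collapse from
    :func:`de_locus_calls` (shared locus index).
    """
    names = sorted(per_model)
    rows = []
    for r in (2, 3):
        for combo in combinations(names, r):
            tables = [per_model[m] for m in combo]
            joint = np.ones(len(tables[0]), dtype=bool)
            for t in tables:
                joint &= t["significant"].values
            signs = np.column_stack([np.sign(t["log2fc"].values) for t in tables])
            concordant = joint & (np.abs(signs.sum(axis=1)) == len(combo))
            n_joint = int(joint.sum())
            rows.append(
                {
                    "models": "+".join(combo),
                    "n_models": r,
                    "jointly_significant": n_joint,
                    "concordant_sign": int(concordant.sum()),
                    "concordance_fraction": float(concordant.sum() / n_joint)
                    if n_joint
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def read_count_matrix(counts_path: str, sample_sheet_path: str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    return CountMatrix(counts, samples)
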