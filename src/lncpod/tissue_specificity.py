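"""Tissue specificity index (TSI) across renal compartments.

TSI is the max-fraction form: the largest compartment mean divided by the sum
of compartment means, bounded in [1/N, 1] for N compartments. A feature is
called compartment-specific when TSI >= 0.8, and podocyte-specific when in
addition the podocyte compartment carries the maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .annotation_core import ExpressionTable

# argmax ties resolve in this fixed biological order (most specific first)
COMPARTMENT_PRIORITY = ("podocyte", "glomerulus", "kidney")

DEFAULT_TSI_THRESHOLD = 0.8


@dataclass(frozen=True)
class SpecificityResult:
    feature_id: str
    compartment_means: Dict[str, float]
    tsi: float  # NaN when all compartment means are zero
    top_compartment: Optional[str]
    specific: bool


def _priority_key(compartment: str) -> tuple:
    try:
        return (0, COMPARTMENT_PRIORITY.index(compartment))
    except ValueError:
        return (1, compartment)


def compute_tsi(
    expr: ExpressionTable,
    feature_id: str,
    threshold: float = DEFAULT_TSI_THRESHOLD,
) -> SpecificityResult:
    """TSI for one feature from compartment means of its samples.

    All-zero features get ``tsi = NaN`` and ``specific = False``.
    """
    comps = expr.compartment_names()
    if len(comps) < 2:
        raise ValueError("TSI needs at least two compartments")
    means = expr.compartment_means(feature_id)
    total = sum(means.values())
    if total <= 0:
        return SpecificityResult(feature_id, means, float("nan"), None, False)
    top = min(
        (c for c in comps if means[c] == max(means.values())),
        key=_priority_key,
    )
    tsi = means[top] / total
    return SpecificityResult(feature_id, means, tsi, top, tsi >= threshold)


def compute_tsi_table(
    expr: ExpressionTable,
    threshold: float = DEFAULT_TSI_THRESHOLD,
) -> pd.DataFrame:
    """Vectorised TSI over all features; one row per feature."""
    comps = expr.compartment_names()
    if len(comps) < 2:
        raise ValueError("TSI needs at least two compartments")
    means = pd.DataFrame(
        {c: expr.values[expr.samples_of(c)].mean(axis=1) for c in comps}
    )
    total = means.sum(axis=1)
    # ties resolved by the fixed compartment priority: reorder columns so the
    # first maximal column wins idxmax
    ordered = sorted(comps, key=_priority_key)
    tsi = means[ordered].max(axis=1) / total
    top = means[ordered].idxmax(axis=1)
    out = means.copy()
    out["tsi"] = tsi
    out["top_compartment"] = top
    out.loc[total <= 0, "tsi"] = float("nan")
    out.loc[total <= 0, "top_compartment"] = None
    out["specific"] = out["tsi"] >= threshold
    return out


def podocyte_specific_set(
    results: pd.DataFrame,
    threshold: float = DEFAULT_TSI_THRESHOLD,
    compartment: str = "podocyte",
) -> Set[str]:
    """Features with TSI >= threshold whose top compartment is the podocyte."""
    mask = (results["tsi"] >= threshold) & (results["top_compartment"] == compartment)
    return set(results.index[mask])
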