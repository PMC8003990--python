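"""Multi-criteria integration of lncRNA candidate evidence.

Every upstream stage contributes a boolean flag per transcript or locus;
candidates descend a funnel of conjunctive tiers:

    T1  expressed lncRNA (length/expression/coding filters passed)
    T2  T1 and expressed in podocytes
    T3  T2 and compartment-specific to podocytes (TSI)
    T4  T3 and conserved in human (sequence or synteny) and free of protein
        homology
    T5  T4 and differentially expressed in at least one disease model

Set-intersection (upset-style) counts over all flag combinations are emitted
alongside the tier table. Transcript-level flags roll up to gene loci by OR
over member transcripts; differential-expression flags are natively
locus-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation_core import GeneLocus

FLAG_NAMES = (
    "expressed",
    "novel",
    "noncoding",
    "podocyte_expressed",
    "tsi_specific",
    "seq_conserved",
    "synteny_conserved",
    "homology_clean",
    "human_expressed",
    "de_wt1",
    "de_podocin",
    "de_adriamycin",
    "scrna_detected",
    "scrna_podocyte_specific",
)

# flags combined by OR when transcripts roll up to a locus; DE flags are
# locus-native and must not be present on transcript-level records
ROLLUP_FLAGS = tuple(f for f in FLAG_NAMES if not f.startswith("de_"))

TIER_NAMES = ("T1", "T2", "T3", "T4", "T5")


@dataclass(frozen=True)
class CandidateRecord:
    feature_id: str
    level: str  # "transcript" | "locus"
    flags: Dict[str, bool]

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "locus"):
            raise ValueError(f"bad level {self.level!r}")
        unknown = set(self.flags) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")

    def flag(self, name: str) -> bool:
        if name not in self.flags:
            raise KeyError(f"feature {self.feature_id!r} is missing flag {name!r}")
        return bool(self.flags[name])


def _tier_membership(rec: CandidateRecord) -> Dict[str, bool]:
    t1 = rec.flag("expressed") and rec.flag("noncoding")
    t2 = t1 and rec.flag("podocyte_expressed")
    t3 = t2 and rec.flag("tsi_specific")
    conserved = rec.flag("seq_conserved") or rec.flag("synteny_conserved")
    t4 = t3 and conserved and rec.flag("homology_clean")
    de_any = rec.flag("de_wt1") or rec.flag("de_podocin") or rec.flag("de_adriamycin")
    t5 = t4 and de_any
    return {"T1": t1, "T2": t2, "T3": t3, "T4": t4, "T5": t5}


def build_funnel(
    records: Sequence[CandidateRecord],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(tier table, upset-style intersection counts).

    The tier table has one row per feature (sorted by id) with its flags and
    tier memberships. The intersection table counts features per distinct
    combination of the funnel-relevant flags, restricted to T1 members, so the
    counts partition T1.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.feature_id):
        row = {"feature_id": rec.feature_id, "level": rec.level}
        for name in FLAG_NAMES:
            row[name] = rec.flag(name)
        row.update(_tier_membership(rec))
        rows.append(row)
    tiers = pd.DataFrame(rows).set_index("feature_id")

    funnel_flags = [
        "podocyte_expressed", "tsi_specific", "seq_conserved",
        "synteny_conserved", "homology_clean",
        "de_wt1", "de_podocin", "de_adriamycin",
    ]
    t1 = tiers[tiers["T1"]]
    if len(t1):
        upset = (
            t1.groupby(funnel_flags, sort=True)
            .size()
            .rename("count")
            .reset_index()
            .sort_values("count", ascending=False, kind="stable")
            .reset_index(drop=True)
        )
    else:
        upset = pd.DataFrame(columns=funnel_flags + ["count"])
    return tiers, upset


def tier_sizes(tiers: pd.DataFrame) -> Dict[str, int]:
    return {name: int(tiers[name].sum()) for name in TIER_NAMES}


def transcript_to_locus_rollup(
    records: Sequence[CandidateRecord],
    loci: Sequence[GeneLocus],
    locus_de_flags: Optional[Mapping[str, Mapping[str, bool]]] = None,
) -> List[CandidateRecord]:
    """Locus-level records: OR of member-transcript flags plus native DE flags.

    ``locus_de_flags`` maps locus_id -> {de_wt1, de_podocin, de_adriamycin};
    missing entries default to False. A transcript not assigned to any locus
    is an error.
    """
    by_transcript = {r.feature_id: r for r in records}
    assigned: Set[str] = set()
    out: List[CandidateRecord] = []
    for locus in loci:
        members = []
        for tid in locus.transcript_ids:
            rec = by_transcript.get(tid)
            if rec is not None:
                members.append(rec)
                assigned.add(tid)
        if not members:
            continue
        flags = {name: any(m.flag(name) for m in members) for name in ROLLUP_FLAGS}
        de = dict(locus_de_flags.get(locus.locus_id, {})) if locus_de_flags else {}
        for name in ("de_wt1", "de_podocin", "de_adriamycin"):
            flags[name] = bool(de.get(name, False))
        out.append(CandidateRecord(locus.locus_id, "locus", flags))
    orphans = set(by_transcript) - assigned
    if orphans:
        raise ValueError(f"transcripts not assigned to any locus: {sorted(orphans)[:5]}")
    return out
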