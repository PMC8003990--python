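"""Transcript models, annotation I/O, known/novel classification and locus bundling.

Coordinates are 0-based half-open internally; GTF I/O converts at the file
boundary (GTF 2.2 is 1-based inclusive). A transcript is *known* relative to a
reference annotation iff a same-strand reference transcript has an identical
intron chain (multi-exonic case) or, for mono-exonic transcripts, a same-strand
mono-exonic reference transcript reciprocally overlaps at least half of both
transcripts. lncRNA candidates are bundled into strand-aware gene loci by
single-linkage clustering on exonic overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

CODING = "coding"
NONCODING = "noncoding"
UNKNOWN = "unknown"


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on a genome strand.

    ``exons`` are 0-based half-open intervals, sorted by start and
    non-overlapping. ``biotype`` is one of {"coding", "noncoding", "unknown"}.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    biotype: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for start, end in exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: empty exon interval ({start}, {end})"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        if self.biotype not in (CODING, NONCODING, UNKNOWN):
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Ordered intron intervals between consecutive exons."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1


class AnnotationSet:
    """A collection of transcripts indexed by transcript id, gene id and chromosome."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._by_id: Dict[str, TranscriptModel] = {}
        self._by_gene: Dict[str, List[str]] = {}
        self._by_chrom: Dict[str, List[str]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_id:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._by_id[t.transcript_id] = t
        self._by_gene.setdefault(t.gene_id, []).append(t.transcript_id)
        self._by_chrom.setdefault(t.chrom, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> List[str]:
        return list(self._by_id)

    def gene_ids(self) -> List[str]:
        return list(self._by_gene)

    def by_gene(self, gene_id: str) -> List[TranscriptModel]:
        return [self._by_id[t] for t in self._by_gene.get(gene_id, [])]

    def by_chrom(self, chrom: str) -> List[TranscriptModel]:
        return [self._by_id[t] for t in self._by_chrom.get(chrom, [])]

    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self._by_id[t] for t in transcript_ids)


@dataclass(frozen=True)
class GeneLocus:
    """A strand-aware bundle of mutually overlapping transcripts."""

    locus_id: str
    chrom: str
    strand: str
    span: Interval
    transcript_ids: Tuple[str, ...]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _biotype_from_attrs(attrs: Mapping[str, str]) -> str:
    bt = attrs.get("gene_biotype", attrs.get("transcript_biotype"))
    if bt is None:
        return UNKNOWN
    return CODING if bt == "protein_coding" else NONCODING


def read_gtf(path: str, on_missing_id: str = "error") -> AnnotationSet:
    """Read exon features from a GTF 2.2 file into an :class:`AnnotationSet`.

    1-based inclusive file coordinates become 0-based half-open. Records
    without a ``transcript_id`` attribute are an error by default;
    ``on_missing_id="skip"`` logs and drops them instead.
    """
    if on_missing_id not in ("error", "skip"):
        raise ValueError("on_missing_id must be 'error' or 'skip'")
    exons: Dict[str, Dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if end1 < start1:
                raise GtfParseError(f"{path}:{lineno}: end < start")
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                if on_missing_id == "skip":
                    logger.warning("%s:%d: missing transcript_id, skipped", path, lineno)
                    continue
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": _biotype_from_attrs(attrs),
                },
            )
            rec["exons"].append((start1 - 1, end1))
    out = AnnotationSet()
    for tid, rec in exons.items():
        out.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                biotype=rec["biotype"],
            )
        )
    return out


_BIOTYPE_TO_GTF = {CODING: "protein_coding", NONCODING: "lncRNA"}


def write_gtf(annot: AnnotationSet, path: str, source: str = "lncpod") -> None:
    """Write transcripts as GTF 2.2 exon records (round-trips with :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for t in sorted(annot, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype != UNKNOWN:
                attrs += f' gene_biotype "{_BIOTYPE_TO_GTF[t.biotype]}";'
            for start, end in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA and expression tables
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    """Transcript sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


@dataclass
class ExpressionTable:
    """Per-sample expression values (FPKM or TPM) with compartment labels.

    ``values`` is a features x samples DataFrame; ``compartments`` maps every
    sample (column) to its compartment label.
    """

    values: pd.DataFrame
    compartments: Dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [c for c in self.values.columns if c not in self.compartments]
        if missing:
            raise ValueError(f"samples without compartment label: {missing}")

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    def compartment_names(self) -> List[str]:
        seen: List[str] = []
        for sample in self.values.columns:
            comp = self.compartments[sample]
            if comp not in seen:
                seen.append(comp)
        return seen

    def samples_of(self, compartment: str) -> List[str]:
        return [s for s in self.values.columns if self.compartments[s] == compartment]

    def compartment_means(self, feature_id: str) -> Dict[str, float]:
        row = self.values.loc[feature_id]
        return {
            comp: float(row[self.samples_of(comp)].mean())
            for comp in self.compartment_names()
        }


def read_expression_table(values_path: str, sample_sheet_path: str) -> ExpressionTable:
    """Read a TSV expression matrix plus a sidecar sample->compartment TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if not {"sample", "compartment"}.issubset(sheet.columns):
        raise ValueError("sample sheet needs 'sample' and 'compartment' columns")
    compartments = dict(zip(sheet["sample"].astype(str), sheet["compartment"].astype(str)))
    return ExpressionTable(values=values, compartments=compartments)


def write_expression_table(table: ExpressionTable, values_path: str, sample_sheet_path: str) -> None:
    table.values.to_csv(values_path, sep="\t")
    pd.DataFrame(
        {"sample": list(table.values.columns),
         "compartment": [table.compartments[s] for s in table.values.columns]}
    ).to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Known / novel classification
# ---------------------------------------------------------------------------

def _reciprocal_overlap_ge(a: Interval, b: Interval, frac: float) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def classify_transcripts(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    mono_overlap: float = 0.5,
) -> Dict[str, str]:
    """Label each assembled transcript ``known`` or ``novel`` against a reference.

    Multi-exonic transcripts match on an identical intron chain (terminal exon
    ends are free to differ); mono-exonic transcripts match a same-strand
    mono-exonic reference transcript with reciprocal overlap >= ``mono_overlap``
    of both lengths.
    """
    if len(reference) == 0:
        warnings.warn("empty reference annotation: all transcripts classified novel")
        return {t.transcript_id: "novel" for t in assembled}

    chains = set()
    mono: Dict[Tuple[str, str], List[Interval]] = {}
    for r in reference:
        if r.is_monoexonic:
            mono.setdefault((r.chrom, r.strand), []).append(r.span)
        else:
            chains.add((r.chrom, r.strand, r.introns))

    labels: Dict[str, str] = {}
    for t in assembled:
        if t.is_monoexonic:
            candidates = mono.get((t.chrom, t.strand), [])
            known = any(
                _reciprocal_overlap_ge(t.span, span, mono_overlap) for span in candidates
            )
        else:
            known = (t.chrom, t.strand, t.introns) in chains
        labels[t.transcript_id] = "known" if known else "novel"
    return labels


# ---------------------------------------------------------------------------
# Locus bundling
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def bundle_loci(candidates: AnnotationSet) -> List[GeneLocus]:
    """Single-linkage cluster noncoding transcripts into strand-aware gene loci.

    Two transcripts belong to the same locus iff they are connected by a chain
    of same-strand exonic overlaps (>= 1 bp). Locus ids are assigned in
    deterministic (chrom, span start, strand) order.
    """
    for t in candidates:
        if t.biotype == CODING:
            raise ValueError(
                f"coding transcript {t.transcript_id!r} passed to bundle_loci"
            )

    uf = _UnionFind()
    groups: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in candidates:
        groups.setdefault((t.chrom, t.strand), []).append(t)
        uf.find(t.transcript_id)

    for (chrom, strand), members in groups.items():
        # sweep over exons: overlapping exon intervals chain into one component
        exon_events = sorted(
            (start, end, t.transcript_id) for t in members for start, end in t.exons
        )
        cur_end = -1
        cur_root: Optional[str] = None
        for start, end, tid in exon_events:
            if cur_root is not None and start < cur_end:
                uf.union(cur_root, tid)
                cur_end = max(cur_end, end)
            else:
                cur_root = tid
                cur_end = end

    clusters: Dict[str, List[TranscriptModel]] = {}
    for t in candidates:
        clusters.setdefault(uf.find(t.transcript_id), []).append(t)

    raw = []
    for members in clusters.values():
        chrom = members[0].chrom
        strand = members[0].strand
        span = (min(m.start for m in members), max(m.end for m in members))
        tids = tuple(sorted(m.transcript_id for m in members))
        raw.append((chrom, span, strand, tids))
    raw.sort()
    return [
        GeneLocus(
            locus_id=f"LOCUS{idx + 1:06d}",
            chrom=chrom,
            strand=strand,
            span=span,
            transcript_ids=tids,
        )
        for idx, (chrom, span, strand, tids) in enumerate(raw)
    ]
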