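"""Coding-potential assessment for candidate lncRNAs.

Candidates must be >= 200 bp spliced and reach >= 1 FPKM in some sample. Each
retained sequence is scanned for sense-strand ATG-initiated open reading
frames of >= 50 codons; a transcript is called coding when its longest
complete ORF exceeds a *dynamic*, transcript-length-dependent cutoff and its
composition scores (in-frame hexamer log-likelihood, start-codon PSSM) favour
coding — or when it has a protein-database homology hit of >= 50 bits.

The dynamic cutoff is defined under an i.i.d. random-sequence null: the
smallest ORF length n >= 50 such that the expected number of (non-nested)
ORFs of >= n codons in a random sequence of the same length L falls below
``alpha``,

    E(n, L) = max(0, L - 3n) * p_start * (1 - p_stop)^(n-1)
                             * p_stop / (p_stop + p_start)

with p_start and p_stop the codon probabilities of ATG and {TAA, TAG, TGA}
under the supplied base composition; the trailing factor is the probability
that a qualifying ATG is the first of its stop-free stretch and hence the
one the scanner reports. Longer transcripts therefore need longer ORFs
before they are considered coding, reproducing the length dependence of
chance ORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation_core import AnnotationSet, ExpressionTable

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class OrfCall:
    """An ATG-initiated open reading frame on the sense strand of a transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates; for
    complete ORFs the stop codon is included in the span but not in
    ``length_aa``.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    length_aa: int
    complete: bool
    ll_score: float = 0.0
    start_pssm_score: float = 0.0

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        expected = (self.end - self.start) // 3 - (1 if self.complete else 0)
        if self.length_aa != expected:
            raise ValueError("length_aa inconsistent with span/completeness")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")


@dataclass(frozen=True)
class CodingVerdict:
    transcript_id: str
    longest_orf_aa: int
    dynamic_cutoff_aa: int
    ll_score: float
    start_pssm_score: float
    homology_hit: bool
    verdict: str  # "coding" | "noncoding"


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    annot: AnnotationSet,
    expr: ExpressionTable,
    min_len: int = 200,
    min_fpkm: float = 1.0,
) -> Set[str]:
    """Transcripts with spliced length >= min_len and max FPKM >= min_fpkm.

    Both cutoffs are inclusive. Transcripts absent from the expression table
    are treated as unexpressed.
    """
    max_expr = expr.values.max(axis=1)
    selected: Set[str] = set()
    for t in annot:
        if t.spliced_length < min_len:
            continue
        value = float(max_expr.get(t.transcript_id, 0.0))
        if value >= min_fpkm:
            selected.add(t.transcript_id)
    return selected


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------

def find_orfs(seq: str, min_aa: int = 50, transcript_id: str = "") -> List[OrfCall]:
    """All non-nested sense-strand ORFs of >= ``min_aa`` codons.

    Scans the three forward frames. Within a stop-delimited stretch of a
    frame, only the ORF from the first ATG is reported: any downstream
    in-frame ATG starts an ORF contained in it, and the longest is always
    preferred. ORFs that run off the 3' end without a stop are reported with
    ``complete=False``. Codons containing N never match start or stop.
    """
    seq = seq.upper()
    n = len(seq)
    calls: List[OrfCall] = []
    for frame in range(3):
        orf_start: Optional[int] = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if orf_start is None:
                if codon == START_CODON:
                    orf_start = pos
            elif codon in STOP_CODONS:
                aa = (pos - orf_start) // 3
                if aa >= min_aa:
                    calls.append(
                        OrfCall(
                            transcript_id=transcript_id,
                            frame=frame,
                            start=orf_start,
                            end=pos + 3,
                            length_aa=aa,
                            complete=True,
                        )
                    )
                orf_start = None
            pos += 3
        if orf_start is not None:
            # ran off the 3' end without a stop codon
            end = orf_start + 3 * ((n - orf_start) // 3)
            aa = (end - orf_start) // 3
            if aa >= min_aa:
                calls.append(
                    OrfCall(
                        transcript_id=transcript_id,
                        frame=frame,
                        start=orf_start,
                        end=end,
                        length_aa=aa,
                        complete=False,
                    )
                )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


# ---------------------------------------------------------------------------
# Dynamic ORF-length cutoff
# ---------------------------------------------------------------------------

def _codon_probs(base_freqs: Mapping[str, float]) -> Tuple[float, float]:
    for base in "ACGT":
        if base_freqs.get(base, 0.0) <= 0.0:
            raise ValueError(f"base_freqs must put positive mass on {base}")
    total = sum(base_freqs[b] for b in "ACGT")
    f = {b: base_freqs[b] / total for b in "ACGT"}
    p_start = f["A"] * f["T"] * f["G"]
    p_stop = f["T"] * f["A"] * f["A"] + f["T"] * f["A"] * f["G"] + f["T"] * f["G"] * f["A"]
    return p_start, p_stop


def expected_orf_count(
    n_aa: int,
    length_nt: int,
    base_freqs: Mapping[str, float],
    nested: bool = False,
) -> float:
    """Expected number of ORFs of >= n_aa codons in an i.i.d. sequence of length L.

    By default this counts ORFs as :func:`find_orfs` reports them — non-nested,
    i.e. anchored at the first ATG of a stop-free stretch. An ATG with n-1
    following non-stop codons is such an anchor when the nearest upstream
    in-frame blocker is a stop rather than another ATG, which under the i.i.d.
    null has probability p_stop / (p_stop + p_start). ``nested=True`` drops
    that factor and counts every qualifying ATG.
    """
    p_start, p_stop = _codon_probs(base_freqs)
    positions = max(0, length_nt - 3 * n_aa)
    expected = positions * p_start * (1.0 - p_stop) ** (n_aa - 1)
    if not nested:
        expected *= p_stop / (p_stop + p_start)
    return expected


UNIFORM_BASES = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def dynamic_orf_cutoff(
    length_nt: int,
    alpha: float = 0.05,
    base_freqs: Optional[Mapping[str, float]] = None,
) -> int:
    """Smallest n >= 50 with expected chance-ORF count E(n, L) below ``alpha``.

    The expected count is for non-nested ORFs (see
    :func:`expected_orf_count`), matching what the scanner reports; the
    cutoff tracks the Monte-Carlo longest-ORF quantile and is monotone
    non-decreasing in transcript length L.
    """
    if length_nt < 3:
        raise ValueError("transcript length must be >= 3 nt")
    freqs = UNIFORM_BASES if base_freqs is None else base_freqs
    n = 50
    while expected_orf_count(n, length_nt, freqs) >= alpha:
        n += 1
    return n


def simulate_longest_orf_lengths(
    length_nt: int,
    n_sims: int,
    rng: "np.random.Generator",
    base_freqs: Optional[Mapping[str, float]] = None,
) -> "np.ndarray":
    """Longest ORF length (codons, 3 forward frames, incomplete ORFs included)
    for ``n_sims`` i.i.d. random sequences — the Monte-Carlo reference the
    analytic cutoff is validated against."""
    import numpy as np

    freqs = UNIFORM_BASES if base_freqs is None else base_freqs
    p = np.array([freqs[b] for b in "ACGT"], dtype=float)
    p = p / p.sum()
    s = rng.choice(4, size=(n_sims, length_nt), p=p).astype(np.int8)
    best = np.zeros(n_sims, dtype=np.int32)
    weights = np.array([16, 4, 1])
    for frame in range(3):
        k = (length_nt - frame) // 3
        if k <= 0:
            continue
        codons = (s[:, frame : frame + 3 * k].reshape(n_sims, k, 3) * weights).sum(axis=2)
        is_stop = (codons == 48) | (codons == 50) | (codons == 56)  # TAA/TAG/TGA
        is_atg = codons == 14
        active = np.zeros(n_sims, dtype=bool)
        cur = np.zeros(n_sims, dtype=np.int32)
        for j in range(k):
            stop = is_stop[:, j]
            active &= ~stop
            cur[stop] = 0
            active |= is_atg[:, j] & ~stop
            cur[active] += 1
            np.maximum(best, cur, out=best)
    return best


# ---------------------------------------------------------------------------
# ORF scoring: in-frame hexamer log-likelihood and start-codon PSSM
# ---------------------------------------------------------------------------

# PSSM offsets are relative to the A of the ATG: 6 upstream positions, the
# start codon itself, and the first downstream base.
PSSM_OFFSETS = tuple(range(-6, 4))


def score_orf(
    orf: OrfCall,
    seq: str,
    hexamer_model: Mapping[str, float],
    start_pssm: Mapping[int, Mapping[str, float]],
) -> Tuple[float, float]:
    """(hexamer log-likelihood, start PSSM score) for one ORF.

    The hexamer score sums log-odds over in-frame hexamers (step 3) across the
    coding part of the ORF; the PSSM score sums positional log-odds in a
    window around the ATG. Hexamers or bases absent from the models (e.g.
    containing N) contribute zero.
    """
    if orf.length_aa < 2:
        raise ValueError("ORF must be at least 2 codons to score")
    seq = seq.upper()
    coding_end = orf.end - (3 if orf.complete else 0)
    ll = 0.0
    for pos in range(orf.start, coding_end - 5, 3):
        ll += hexamer_model.get(seq[pos : pos + 6], 0.0)
    pssm = 0.0
    for offset in PSSM_OFFSETS:
        pos = orf.start + offset
        if 0 <= pos < len(seq):
            table = start_pssm.get(offset)
            if table:
                pssm += table.get(seq[pos], 0.0)
    return ll, pssm


def train_hexamer_model(
    coding_seqs: Iterable[str],
    background_seqs: Iterable[str],
    pseudocount: float = 1.0,
) -> Dict[str, float]:
    """Log-odds of in-frame hexamer frequencies, coding vs background.

    Coding sequences are read in frame 0 with step 3; background sequences are
    read at every offset (frame-free null).
    """
    import itertools

    hexamers = ["".join(p) for p in itertools.product("ACGT", repeat=6)]

    def _freqs(seqs: Iterable[str], step: int) -> Dict[str, float]:
        counts = {h: pseudocount for h in hexamers}
        total = pseudocount * len(hexamers)
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - 5, step):
                h = s[i : i + 6]
                if h in counts:
                    counts[h] += 1.0
                    total += 1.0
        return {h: c / total for h, c in counts.items()}

    fg = _freqs(coding_seqs, step=3)
    bg = _freqs(background_seqs, step=1)
    return {h: math.log(fg[h] / bg[h]) for h in hexamers}


def train_start_pssm(
    contexts: Iterable[str],
    background_freqs: Optional[Mapping[str, float]] = None,
    pseudocount: float = 1.0,
) -> Dict[int, Dict[str, float]]:
    """Positional log-odds around true start codons.

    ``contexts`` are 10-mers covering PSSM offsets -6..+3 (the ATG occupies
    offsets 0..2).
    """
    bg = UNIFORM_BASES if background_freqs is None else background_freqs
    contexts = [c.upper() for c in contexts]
    pssm: Dict[int, Dict[str, float]] = {}
    for idx, offset in enumerate(PSSM_OFFSETS):
        counts = {b: pseudocount for b in "ACGT"}
        total = 4.0 * pseudocount
        for ctx in contexts:
            if idx < len(ctx) and ctx[idx] in counts:
                counts[ctx[idx]] += 1.0
                total += 1.0
        pssm[offset] = {b: math.log((counts[b] / total) / bg[b]) for b in "ACGT"}
    return pssm


# ---------------------------------------------------------------------------
# BLAST tabular I/O and the protein-homology filter
# ---------------------------------------------------------------------------

def read_outfmt6(path: str) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular (outfmt 6) file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                rows.append(
                    {
                        "qseqid": fields[0],
                        "sseqid": fields[1],
                        "pident": float(fields[2]),
                        "length": int(fields[3]),
                        "mismatch": int(fields[4]),
                        "gapopen": int(fields[5]),
                        "qstart": int(fields[6]),
                        "qend": int(fields[7]),
                        "sstart": int(fields[8]),
                        "send": int(fields[9]),
                        "evalue": float(fields[10]),
                        "bitscore": float(fields[11]),
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def write_outfmt6(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=OUTFMT6_COLUMNS)


def apply_homology_filter(
    ids: Iterable[str],
    hits: pd.DataFrame,
    min_bits: float = 50.0,
) -> Set[str]:
    """Ids with any protein-homology hit of bit score >= ``min_bits`` (inclusive)."""
    ids = set(ids)
    if hits.empty:
        return set()
    strong = hits[hits["bitscore"] >= min_bits]
    return set(strong["qseqid"]) & ids


# ---------------------------------------------------------------------------
# Composite verdict
# ---------------------------------------------------------------------------

def classify_coding(
    sequences: Mapping[str, str],
    hexamer_model: Mapping[str, float],
    start_pssm: Mapping[int, Mapping[str, float]],
    homology_flagged: Set[str],
    min_aa: int = 50,
    alpha: float = 0.05,
    base_freqs: Optional[Mapping[str, float]] = None,
) -> Dict[str, CodingVerdict]:
    """Per-transcript coding/noncoding verdicts.

    A transcript is coding iff its longest *complete* ORF reaches the dynamic
    length cutoff for its transcript length and either composition score is
    positive — or it carries a protein-homology hit, which overrides the
    sequence-composition evidence.
    """
    verdicts: Dict[str, CodingVerdict] = {}
    for tid, seq in sequences.items():
        orfs = find_orfs(seq, min_aa=min_aa, transcript_id=tid)
        complete = [o for o in orfs if o.complete]
        longest = max((o.length_aa for o in complete), default=0)
        cutoff = dynamic_orf_cutoff(len(seq), alpha=alpha, base_freqs=base_freqs)
        ll = pssm = 0.0
        if complete:
            best = max(complete, key=lambda o: o.length_aa)
            ll, pssm = score_orf(best, seq, hexamer_model, start_pssm)
        homology = tid in homology_flagged
        coding = homology or (longest >= cutoff and (ll > 0 or pssm > 0))
        verdicts[tid] = CodingVerdict(
            transcript_id=tid,
            longest_orf_aa=longest,
            dynamic_cutoff_aa=cutoff,
            ll_score=ll,
            start_pssm_score=pssm,
            homology_hit=homology,
            verdict="coding" if coding else "noncoding",
        )
    return verdicts


def verdicts_to_frame(verdicts: Mapping[str, CodingVerdict]) -> pd.DataFrame:
    """Tabular export: one row per transcript."""
    return pd.DataFrame(
        [
            {
                "transcript_id": v.transcript_id,
                "longest_orf_aa": v.longest_orf_aa,
                "dynamic_cutoff_aa": v.dynamic_cutoff_aa,
                "ll_score": v.ll_score,
                "start_pssm_score": v.start_pssm_score,
                "homology_hit": v.homology_hit,
                "verdict": v.verdict,
            }
            for v in verdicts.values()
        ]
    ).set_index("transcript_id")
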