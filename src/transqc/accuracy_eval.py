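"""Reference-based contig accuracy via reciprocal best hits.

Given the reference transcripts an assembly should reconstruct, each
contig is paired with a reference by mutual best local alignment, and
accuracy is summarized per contig as

    precision = identical bases / contig length
    recall    = identical bases / reference length
    F         = 2 P R / (P + R)

The built-in alignment backend runs Smith-Waterman (match +1, mismatch
-2, gap open -5, gap extend -2) on candidate pairs pre-filtered by
shared k-mer counts, which keeps all-vs-all search tractable at the
scale this package targets.  Tabular results from an external aligner
(outfmt-6 style TSV) are accepted as an alternative backend.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import spearmanr

try:
    from Bio import Align
except ImportError:  # pragma: no cover
    Align = None

from transqc.io_model import Contig
from transqc.scoring_filter import ContigScore

log = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -5.0, -2.0
#: Minimum local-alignment score for a hit to count (stands in for an
#: e-value threshold, which is database-size dependent).
DEFAULT_MIN_SCORE = 40.0
_KMER = 15
_MIN_SHARED_KMERS = 5


@dataclass(frozen=True)
class RbhPair:
    contig_id: str
    reference_id: str
    aligned_identical_bases: int
    contig_len: int
    reference_len: int


@dataclass(frozen=True)
class AccuracyResult:
    contig_id: str
    precision: float
    recall: float
    f_score: float


def _kmer_set(seq: str, k: int = _KMER) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def _make_aligner() -> "Align.PairwiseAligner":
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _best_local_hit(aligner, query: str, target: str) -> tuple[float, int]:
    """(score, identities) of the best local alignment, or (0, 0)."""
    try:
        alignments = aligner.align(query, target)
        if len(alignments) == 0:
            return 0.0, 0
        best = alignments[0]
    except (ValueError, OverflowError, MemoryError):
        return 0.0, 0
    identities = best.counts().identities
    return float(best.score), int(identities)


def reciprocal_best_hits(
    contigs: list[Contig],
    references: list[Contig],
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[RbhPair]:
    """Mutual best local-alignment pairs between contigs and references.

    Candidate pairs sharing at least a few k-mers are aligned; the best
    hit per contig and per reference are computed from the same score
    table (the alignment is symmetric, so one alignment serves both
    search directions); pairs that are each other's best are retained.
    Score ties break toward the lexicographically first partner id.
    """
    if not contigs or not references:
        raise ValueError("both contig and reference sets must be non-empty")
    if Align is None:  # pragma: no cover
        raise RuntimeError("Biopython is required for the built-in backend")
    aligner = _make_aligner()
    ref_kmers = {r.id: _kmer_set(r.sequence) for r in references}
    hits: dict[tuple[str, str], tuple[float, int]] = {}
    for c in contigs:
        ck = _kmer_set(c.sequence)
        for r in references:
            shared = len(ck & ref_kmers[r.id])
            if shared < _MIN_SHARED_KMERS:
                continue
            score, ident = _best_local_hit(aligner, c.sequence, r.sequence)
            if score >= min_score:
                hits[(c.id, r.id)] = (score, ident)

    def best_partner(fixed: str, axis: int) -> str | None:
        cands = [
            (pair[1 - axis], sc)
            for pair, (sc, _) in hits.items()
            if pair[axis] == fixed
        ]
        if not cands:
            return None
        best_score = max(sc for _, sc in cands)
        return sorted(p for p, sc in cands if sc == best_score)[0]

    ref_len = {r.id: r.length for r in references}
    contig_len = {c.id: c.length for c in contigs}
    out: list[RbhPair] = []
    for c in contigs:
        r = best_partner(c.id, 0)
        if r is None:
            continue
        if best_partner(r, 1) == c.id:
            _, ident = hits[(c.id, r)]
            out.append(RbhPair(c.id, r, ident, contig_len[c.id], ref_len[r]))
    return out


def read_tabular_hits(
    path: str | Path,
    contigs: list[Contig],
    references: list[Contig],
    max_evalue: float = 1e-5,
) -> list[RbhPair]:
    """Build RBH pairs from external outfmt-6 style alignment results.

    Expected columns: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore.  The best hit per query and
    per subject by bitscore are intersected to give reciprocal bests;
    identical bases are estimated as pident/100 * alignment length.
    """
    contig_len = {c.id: c.length for c in contigs}
    ref_len = {r.id: r.length for r in references}
    best_q: dict[str, tuple[float, str, int]] = {}
    best_s: dict[str, tuple[float, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            q, s = row[0], row[1]
            pident, length = float(row[2]), int(row[3])
            evalue, bits = float(row[10]), float(row[11])
            if evalue > max_evalue or q not in contig_len or s not in ref_len:
                continue
            ident = int(round(pident / 100.0 * length))
            if q not in best_q or bits > best_q[q][0]:
                best_q[q] = (bits, s, ident)
            if s not in best_s or bits > best_s[s][0]:
                best_s[s] = (bits, q)
    out = []
    for q, (_, s, ident) in sorted(best_q.items()):
        if best_s.get(s, (0.0, None))[1] == q:
            out.append(RbhPair(q, s, ident, contig_len[q], ref_len[s]))
    return out


def contig_f_score(p: RbhPair) -> AccuracyResult:
    """Precision/recall/F of one RBH pair."""
    precision = p.aligned_identical_bases / p.contig_len
    recall = p.aligned_identical_bases / p.reference_len
    if precision + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return AccuracyResult(p.contig_id, precision, recall, f)


def score_accuracy_correlation(
    scores: list[ContigScore],
    accuracies: list[AccuracyResult],
    drop_minimum: bool = False,
    floor: float = 0.01,
) -> float:
    """Spearman rank correlation between contig score and F-score.

    With ``drop_minimum``, contigs stuck at the floored minimum score
    (every component at or below the floor) are excluded first.
    """
    acc = {a.contig_id: a.f_score for a in accuracies}
    min_score = floor**4
    rows = []
    for cs in scores:
        if cs.contig_id not in acc:
            continue
        if drop_minimum and cs.s <= min_score:
            continue
        rows.append((cs.s, acc[cs.contig_id]))
    if len(rows) < 3:
        raise ValueError("need at least 3 joined (score, accuracy) rows")
    s_vals, f_vals = zip(*rows)
    rho = spearmanr(s_vals, f_vals).statistic
    return float(rho)
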