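"""Core domain types and I/O for assemblies and paired-end alignments.

Coordinates are 0-based, half-open everywhere inside the package; SAM's
1-based inclusive convention is converted on read (pysam already does
this).  A read pair may have several candidate placements (multi-mapping);
the evaluation stage later collapses each pair onto a single contig.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

FORWARD = "forward"
REVERSE = "reverse"

#: Maximum edit distance reported per mate alignment (the aligner's cap,
#: written e-hat in the score formulas).
DEFAULT_MAX_EDIT_DISTANCE = 30
#: Maximum number of candidate placements retained per pair.
DEFAULT_MAX_PLACEMENTS = 10
#: Placements more than this many edits worse than the best are dropped.
DEFAULT_PLACEMENT_EDIT_WINDOW = 5


@dataclass(frozen=True)
class Contig:
    """One assembled sequence (intended to represent one transcript)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MateAlignment:
    """Placement of a single mate on a contig.

    ``edit_distance`` is the NM value: the number of changes needed for
    the read to match the contig over the aligned span.
    """

    read_id: str
    contig_id: str | None
    start: int
    end: int
    strand: str
    edit_distance: int
    is_aligned: bool = True

    @staticmethod
    def unaligned(read_id: str) -> "MateAlignment":
        return MateAlignment(read_id, None, 0, 0, FORWARD, 0, is_aligned=False)


@dataclass(frozen=True)
class Placement:
    """One candidate placement of a pair: where each mate sits.

    ``contig_id`` is the contig of the first aligned mate; in a
    discordant placement the two mates may name different contigs.
    """

    contig_id: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def pair_edit_distance(self) -> int:
        """Summed mate NM values, used to rank candidate placements."""
        e = 0
        if self.mate1.is_aligned:
            e += self.mate1.edit_distance
        if self.mate2.is_aligned:
            e += self.mate2.edit_distance
        return e

    @property
    def both_aligned(self) -> bool:
        return self.mate1.is_aligned and self.mate2.is_aligned

    @property
    def same_contig(self) -> bool:
        return (
            self.both_aligned
            and self.mate1.contig_id == self.mate2.contig_id
        )


@dataclass
class PairAlignment:
    """All alignment evidence for one read pair, before and after assignment."""

    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    candidate_placements: list[Placement] = field(default_factory=list)
    assigned_contig: str | None = None

    @property
    def is_mapped(self) -> bool:
        return bool(self.candidate_placements)

    @property
    def both_mates_mapped(self) -> bool:
        return any(p.both_aligned for p in self.candidate_placements)

    def best_placement_on(self, contig_id: str) -> Placement | None:
        """Lowest-edit-distance candidate placement touching ``contig_id``."""
        best = None
        for p in self.candidate_placements:
            touches = (
                (p.mate1.is_aligned and p.mate1.contig_id == contig_id)
                or (p.mate2.is_aligned and p.mate2.contig_id == contig_id)
            )
            if touches and (best is None or p.pair_edit_distance < best.pair_edit_distance):
                best = p
        return best


@dataclass(frozen=True)
class AlignmentConfig:
    """Alignment-reporting contract mirrored from the external mapper."""

    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE
    max_placements: int = DEFAULT_MAX_PLACEMENTS
    placement_edit_window: int = DEFAULT_PLACEMENT_EDIT_WINDOW

    def __post_init__(self) -> None:
        if self.max_edit_distance < 1:
            raise ValueError("max_edit_distance must be positive")
        if self.placement_edit_window > self.max_edit_distance:
            raise ValueError("placement_edit_window must be <= max_edit_distance")


@dataclass
class ContigEvidence:
    """Per-base evidence accumulated from the pairs assigned to one contig.

    ``depth[k]`` counts mates covering base k; ``support_sum[k]`` sums
    1 - e/e-hat over those mates, so support_sum <= depth everywhere.
    """

    contig_id: str
    depth: np.ndarray
    support_sum: np.ndarray
    assigned_pairs: int = 0
    order_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Contig]:
    """Read an assembly (or reference transcript set) from FASTA.

    Sequences are uppercased and multi-line records joined.  Duplicate
    ids and empty files are errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_seq: list[str] = []

    def flush() -> None:
        nonlocal cur_id, cur_seq
        if cur_id is not None:
            contigs.append(Contig(cur_id, "".join(cur_seq).upper()))
        cur_id, cur_seq = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                if cur_id in seen:
                    raise ValueError(f"duplicate contig id {cur_id!r}")
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise ValueError("sequence line before any FASTA header")
                cur_seq.append(line)
    flush()
    if not contigs:
        raise ValueError("no contigs in FASTA file")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM

def _truncate_placements(placements: list[Placement], cfg: AlignmentConfig) -> list[Placement]:
    """Keep the best placements within the edit window, up to the cap."""
    if not placements:
        return placements
    placements = sorted(placements, key=lambda p: p.pair_edit_distance)
    best = placements[0].pair_edit_distance
    kept = [p for p in placements if p.pair_edit_distance <= best + cfg.placement_edit_window]
    return kept[: cfg.max_placements]


def read_alignments(
    path: str | Path,
    contigs: list[Contig],
    cfg: AlignmentConfig = AlignmentConfig(),
    missing_nm: str = "error",
) -> list[PairAlignment]:
    """Read paired-end alignments from SAM/BAM into PairAlignment records.

    Records are grouped by query name; every (primary or secondary)
    placement of the pair becomes a candidate placement, then the list is
    truncated to ``cfg.max_placements`` best placements within
    ``cfg.placement_edit_window`` edits of the best.  Mates without an
    alignment are represented with ``is_aligned=False``.

    ``missing_nm`` controls what happens when an aligned record lacks an
    NM tag: ``"error"`` raises, ``"zero"`` treats the edit distance as 0.
    """
    if missing_nm not in ("error", "zero"):
        raise ValueError("missing_nm must be 'error' or 'zero'")
    known = {c.id for c in contigs}
    # query name -> (mate1 placements, mate2 placements, saw-pair flag)
    by_name: dict[str, tuple[list[MateAlignment], list[MateAlignment]]] = {}
    order: list[str] = []

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_supplementary:
                continue
            name = rec.query_name
            if name not in by_name:
                by_name[name] = ([], [])
                order.append(name)
            slot = 1 if rec.is_read2 else 0
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in known:
                raise ValueError(f"alignment target {ref!r} is not in the assembly")
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif missing_nm == "zero":
                nm = 0
            else:
                raise ValueError(f"record {name!r} has no NM tag")
            if nm > cfg.max_edit_distance:
                continue
            mate = MateAlignment(
                read_id=f"{name}/{slot + 1}",
                contig_id=ref,
                start=rec.reference_start,
                end=rec.reference_end,
                strand=REVERSE if rec.is_reverse else FORWARD,
                edit_distance=nm,
            )
            by_name[name][slot].append(mate)

    pairs: list[PairAlignment] = []
    for name in order:
        m1s, m2s = by_name[name]
        placements = _pair_up_mates(name, m1s, m2s)
        placements = _truncate_placements(placements, cfg)
        if placements:
            best = placements[0]
            mate1, mate2 = best.mate1, best.mate2
        else:
            mate1 = MateAlignment.unaligned(f"{name}/1")
            mate2 = MateAlignment.unaligned(f"{name}/2")
        pairs.append(PairAlignment(name, mate1, mate2, placements))
    return pairs


def _pair_up_mates(
    name: str, m1s: list[MateAlignment], m2s: list[MateAlignment]
) -> list[Placement]:
    """Combine per-mate placements into pair placements.

    Mates on the same contig are joined (best mate2 per mate1 by edit
    distance); leftovers become one-sided placements.  This recovers the
    pair structure from SAM files that report each mate's alignments as
    independent records.
    """
    placements: list[Placement] = []
    used2: set[int] = set()
    for m1 in m1s:
        partner_idx = None
        for j, m2 in enumerate(m2s):
            if j in used2 or m2.contig_id != m1.contig_id:
                continue
            if partner_idx is None or m2.edit_distance < m2s[partner_idx].edit_distance:
                partner_idx = j
        if partner_idx is not None:
            used2.add(partner_idx)
            placements.append(Placement(m1.contig_id, m1, m2s[partner_idx]))
        else:
            placements.append(
                Placement(m1.contig_id, m1, MateAlignment.unaligned(f"{name}/2"))
            )
    for j, m2 in enumerate(m2s):
        if j not in used2:
            placements.append(
                Placement(m2.contig_id, MateAlignment.unaligned(f"{name}/1"), m2)
            )
    return placements


# ---------------------------------------------------------------------------
# Internal alignment interchange TSV (written by the simulator)

TSV_COLUMNS = [
    "pair_id", "contig_id",
    "m1_start", "m1_end", "m1_strand", "m1_nm",
    "m2_start", "m2_end", "m2_strand", "m2_nm",
]
_NA = "."


def write_alignments_tsv(pairs: Iterable[PairAlignment], path: str | Path) -> None:
    """Write pairs (one row per candidate placement) to the interchange TSV.

    An unmapped pair is written as a single row with both mates blank so
    the total read-pair count survives a round trip.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for pair in pairs:
            if not pair.candidate_placements:
                w.writerow([pair.pair_id, _NA] + [_NA] * 8)
                continue
            for p in pair.candidate_placements:
                row = [pair.pair_id, p.contig_id]
                for mate in (p.mate1, p.mate2):
                    if mate.is_aligned:
                        row += [mate.start, mate.end, mate.strand, mate.edit_distance]
                    else:
                        row += [_NA, _NA, _NA, _NA]
                w.writerow(row)


def read_alignments_tsv(
    path: str | Path,
    contigs: list[Contig],
    cfg: AlignmentConfig = AlignmentConfig(),
) -> list[PairAlignment]:
    """Read the internal interchange TSV back into PairAlignment records."""
    known = {c.id for c in contigs}
    by_id: dict[str, PairAlignment] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != TSV_COLUMNS:
            raise ValueError("unexpected alignment TSV header")
        for row in r:
            pid = row[0]
            if pid not in by_id:
                by_id[pid] = PairAlignment(
                    pid,
                    MateAlignment.unaligned(f"{pid}/1"),
                    MateAlignment.unaligned(f"{pid}/2"),
                )
                order.append(pid)
            if row[1] == _NA:
                continue
            mates = []
            for slot, base in ((1, 2), (2, 6)):
                if row[base] == _NA:
                    mates.append(MateAlignment.unaligned(f"{pid}/{slot}"))
                    continue
                mates.append(
                    MateAlignment(
                        read_id=f"{pid}/{slot}",
                        contig_id=row[1],
                        start=int(row[base]),
                        end=int(row[base + 1]),
                        strand=row[base + 2],
                        edit_distance=int(row[base + 3]),
                    )
                )
            if row[1] not in known:
                raise ValueError(f"alignment target {row[1]!r} is not in the assembly")
            by_id[pid].candidate_placements.append(Placement(row[1], mates[0], mates[1]))

    pairs = []
    for pid in order:
        pair = by_id[pid]
        pair.candidate_placements = _truncate_placements(pair.candidate_placements, cfg)
        if pair.candidate_placements:
            best = pair.candidate_placements[0]
            pair.mate1, pair.mate2 = best.mate1, best.mate2
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# Evidence

def build_evidence(
    contigs: list[Contig],
    assigned: list[PairAlignment],
    cfg: AlignmentConfig = AlignmentConfig(),
) -> dict[str, ContigEvidence]:
    """Accumulate per-base depth and support from assigned pairs.

    For every mate of a pair's placement on its assigned contig, depth is
    incremented over the aligned span [start, end) and 1 - e/e-hat is
    added to the support sum over the same span.
    """
    lengths: Mapping[str, int] = {c.id: c.length for c in contigs}
    ev = {
        c.id: ContigEvidence(
            c.id,
            depth=np.zeros(c.length, dtype=np.int64),
            support_sum=np.zeros(c.length, dtype=np.float64),
        )
        for c in contigs
    }
    ehat = float(cfg.max_edit_distance)
    for pair in assigned:
        cid = pair.assigned_contig
        if cid is None:
            continue
        if cid not in ev:
            raise ValueError(f"assigned contig {cid!r} is not in the assembly")
        placement = pair.best_placement_on(cid)
        if placement is None:
            raise ValueError(
                f"pair {pair.pair_id!r} assigned to {cid!r} without a placement there"
            )
        e = ev[cid]
        e.assigned_pairs += 1
        for mate in (placement.mate1, placement.mate2):
            if not mate.is_aligned or mate.contig_id != cid:
                continue
            n = lengths[cid]
            s, t = max(0, mate.start), min(n, mate.end)
            if s >= t:
                continue
            e.depth[s:t] += 1
            e.support_sum[s:t] += 1.0 - mate.edit_distance / ehat
    return ev
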