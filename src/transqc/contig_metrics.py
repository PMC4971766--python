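"""Per-contig score components from assigned-pair evidence.

s_nuc: mean per-read-per-nucleotide support 1 - e/e-hat (coverage
weighted).  s_cov: fraction of bases with at least one mapped read.
s_ord: fraction of the contig's pairs that are proper given the inferred
library model.  The segmentation component s_seg lives in
:mod:`transqc.segmentation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from transqc.assignment import (
    LibraryModel,
    placement_fragment_size,
    placement_orientation,
)
from transqc.io_model import ContigEvidence, PairAlignment

STATUS_GOOD = "good"
STATUS_DIFFERENT_CONTIGS = "different-contigs"
STATUS_BAD_ORIENTATION = "bad-orientation"
STATUS_BAD_DISTANCE = "bad-distance"
STATUS_HALF_MAPPED = "half-mapped-at-edge"
STATUS_UNMAPPED = "unmapped"

ALL_STATUSES = (
    STATUS_GOOD,
    STATUS_DIFFERENT_CONTIGS,
    STATUS_BAD_ORIENTATION,
    STATUS_BAD_DISTANCE,
    STATUS_HALF_MAPPED,
    STATUS_UNMAPPED,
)

#: Half-width of the acceptable fragment-size window, in standard deviations.
DEFAULT_K_SD = 3.0


@dataclass(frozen=True)
class OrderClassification:
    pair_id: str
    status: str


@dataclass
class ComponentScores:
    contig_id: str
    s_nuc: float = 0.0
    s_cov: float = 0.0
    s_ord: float = 0.0
    s_seg: float = 0.0


def score_nuc(ev: ContigEvidence) -> float:
    """Mean read support per covered (read, nucleotide) pair; 0 if uncovered."""
    total_depth = int(ev.depth.sum())
    if total_depth == 0:
        return 0.0
    return float(ev.support_sum.sum() / total_depth)


def score_cov(ev: ContigEvidence) -> float:
    """Fraction of bases receiving at least one mapped read."""
    n = ev.depth.size
    if n == 0:
        return 0.0
    return float(np.count_nonzero(ev.depth >= 1) / n)


def classify_pair(
    pair: PairAlignment,
    lib: LibraryModel,
    k_sd: float = DEFAULT_K_SD,
    contig_lengths: Mapping[str, int] | None = None,
) -> OrderClassification:
    """Classify one pair's placement on its assigned contig.

    A pair is ``good`` when both mates align to the assigned contig, the
    orientation matches the library model, and the implied fragment size
    falls within mean +/- k_sd * sd.  Failing pairs take the first
    matching category: different-contigs, bad-orientation, bad-distance.
    A pair with one mate unmapped is ``half-mapped-at-edge`` when the
    mapped mate sits within one fragment window of a contig terminus
    (the contig could have been extended); otherwise it is treated as
    ``unmapped`` evidence.
    """
    if pair.assigned_contig is None or not pair.candidate_placements:
        return OrderClassification(pair.pair_id, STATUS_UNMAPPED)
    placement = pair.best_placement_on(pair.assigned_contig)
    if placement is None:
        return OrderClassification(pair.pair_id, STATUS_UNMAPPED)
    m1, m2 = placement.mate1, placement.mate2
    if m1.is_aligned and m2.is_aligned:
        if m1.contig_id != m2.contig_id:
            return OrderClassification(pair.pair_id, STATUS_DIFFERENT_CONTIGS)
        if placement_orientation(placement) != lib.orientation:
            return OrderClassification(pair.pair_id, STATUS_BAD_ORIENTATION)
        frag = placement_fragment_size(placement)
        lo = lib.fragment_mean - k_sd * lib.fragment_sd
        hi = lib.fragment_mean + k_sd * lib.fragment_sd
        if not (lo <= frag <= hi):
            return OrderClassification(pair.pair_id, STATUS_BAD_DISTANCE)
        return OrderClassification(pair.pair_id, STATUS_GOOD)
    # exactly one mate aligned
    mate = m1 if m1.is_aligned else m2
    window = lib.fragment_mean + k_sd * lib.fragment_sd
    near_edge = True
    if contig_lengths is not None and mate.contig_id in contig_lengths:
        n = contig_lengths[mate.contig_id]
        near_edge = mate.start < window or (n - mate.end) < window
    if near_edge:
        return OrderClassification(pair.pair_id, STATUS_HALF_MAPPED)
    return OrderClassification(pair.pair_id, STATUS_UNMAPPED)


def score_ord(classifications: list[OrderClassification]) -> float:
    """Proportion of a contig's pairs classified good; 0 for no pairs."""
    if not classifications:
        return 0.0
    good = sum(1 for c in classifications if c.status == STATUS_GOOD)
    return good / len(classifications)


def order_count_table(classifications: list[OrderClassification]) -> dict[str, int]:
    counts = {s: 0 for s in ALL_STATUSES}
    for c in classifications:
        counts[c.status] += 1
    return counts
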