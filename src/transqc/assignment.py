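"""Library-model inference, EM abundance estimation, and read-pair assignment.

Multi-mapping read pairs are resolved in two stages, mirroring how
quantification-style fractional assignment is combined with an
all-or-nothing evaluation assignment: first an EM over pair-to-contig
responsibilities estimates relative contig abundances, then each pair is
assigned entirely to a single contig by sampling from its final
responsibilities.  Uniquely mapping pairs are assigned deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from transqc.io_model import Contig, PairAlignment, Placement, FORWARD, REVERSE

log = logging.getLogger(__name__)

ORIENT_FR = "forward-reverse"   # inward-pointing mates (standard paired-end)
ORIENT_RF = "reverse-forward"   # outward-pointing mates
ORIENT_SAME = "same-strand"

DEFAULT_SUBSAMPLE_FRACTION = 0.01
DEFAULT_EM_TOL = 1e-6
DEFAULT_EM_MAX_ITER = 1000


@dataclass(frozen=True)
class LibraryModel:
    """Inferred read-pair orientation and fragment-size distribution."""

    orientation: str
    fragment_mean: float
    fragment_sd: float
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_mean <= 0 or self.fragment_sd < 0:
            raise ValueError("fragment_mean must be > 0 and fragment_sd >= 0")


@dataclass(frozen=True)
class AbundanceEstimate:
    contig_id: str
    est_fragments: float
    tpm: float


def placement_orientation(p: Placement) -> str:
    """Relative orientation of a same-contig placement.

    The leftmost mate (smaller start) pointing forward with the rightmost
    pointing reverse is inward (``forward-reverse``); the converse is
    outward; equal strands are ``same-strand``.
    """
    m1, m2 = p.mate1, p.mate2
    if m1.strand == m2.strand:
        return ORIENT_SAME
    left, right = (m1, m2) if (m1.start, m1.end) <= (m2.start, m2.end) else (m2, m1)
    return ORIENT_FR if left.strand == FORWARD else ORIENT_RF


def placement_fragment_size(p: Placement) -> int:
    """Outer distance: rightmost mate end minus leftmost mate start."""
    return max(p.mate1.end, p.mate2.end) - min(p.mate1.start, p.mate2.start)


def _best_same_contig_placement(pair: PairAlignment) -> Placement | None:
    best = None
    for p in pair.candidate_placements:
        if p.same_contig and (
            best is None or p.pair_edit_distance < best.pair_edit_distance
        ):
            best = p
    return best


def infer_library(
    pairs: list[PairAlignment],
    fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
) -> LibraryModel:
    """Infer orientation and fragment-size mean/sd from a subsample.

    A seeded uniform subsample of the pairs with both mates on one contig
    is analyzed; the subsample size is max(fraction*N, 1000) capped at N.
    Orientation is the modal orientation (lexicographic tie-break, with a
    warning); fragment sizes are outer distances of the sampled placements.
    """
    candidates = []
    for pair in pairs:
        p = _best_same_contig_placement(pair)
        if p is not None:
            candidates.append(p)
    if not candidates:
        raise ValueError("cannot infer library model: no same-contig pairs")
    n = len(candidates)
    k = min(n, max(int(np.ceil(fraction * n)), 1000))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
    sample = [candidates[i] for i in idx]

    counts: dict[str, int] = {}
    sizes = np.empty(len(sample), dtype=np.float64)
    for i, p in enumerate(sample):
        o = placement_orientation(p)
        counts[o] = counts.get(o, 0) + 1
        sizes[i] = placement_fragment_size(p)
    top = max(counts.values())
    modal = sorted(o for o, c in counts.items() if c == top)
    if len(modal) > 1:
        warnings.warn(
            f"orientation tie {modal}; using {modal[0]!r}", stacklevel=2
        )
    mean = float(np.mean(sizes))
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0
    return LibraryModel(
        orientation=modal[0],
        fragment_mean=mean,
        fragment_sd=sd,
        subsample_fraction=fraction,
        subsample_seed=seed,
    )


def effective_length(contig_length: int, fragment_mean: float) -> float:
    """Number of valid fragment start positions, floored at 1."""
    return max(contig_length - fragment_mean + 1.0, 1.0)


def _placement_arrays(
    contigs: list[Contig], pairs: list[PairAlignment]
) -> tuple[np.ndarray, np.ndarray, list[int], dict[str, int]]:
    """Flatten candidate placements into (pair index, contig index) arrays.

    Placements of one pair on the same contig each contribute a slot, so
    a contig hosting two candidate placements receives twice the weight.
    """
    cidx = {c.id: i for i, c in enumerate(contigs)}
    pair_idx: list[int] = []
    contig_idx: list[int] = []
    mapped: list[int] = []
    for j, pair in enumerate(pairs):
        if not pair.candidate_placements:
            continue
        mapped.append(j)
        for p in pair.candidate_placements:
            for cid in {
                m.contig_id for m in (p.mate1, p.mate2) if m.is_aligned
            }:
                pair_idx.append(j)
                contig_idx.append(cidx[cid])
    return (
        np.asarray(pair_idx, dtype=np.int64),
        np.asarray(contig_idx, dtype=np.int64),
        mapped,
        cidx,
    )


def estimate_abundances(
    contigs: list[Contig],
    pairs: list[PairAlignment],
    lib: LibraryModel,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
) -> list[AbundanceEstimate]:
    """EM estimate of expected fragments per contig and TPM.

    E-step: responsibility(pair -> contig) is proportional to
    theta_c / efflen_c summed over the pair's candidate placements on c.
    M-step: theta_c proportional to summed responsibilities.  Iterates
    until the largest absolute change in theta drops below ``tol``.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    n_c = len(contigs)
    pair_idx, contig_idx, mapped, _ = _placement_arrays(contigs, pairs)
    n_mapped = len(mapped)
    eff = np.array(
        [effective_length(c.length, lib.fragment_mean) for c in contigs]
    )
    theta = np.full(n_c, 1.0 / n_c)
    est = np.zeros(n_c)
    if n_mapped:
        for _ in range(max_iter):
            w = theta[contig_idx] / eff[contig_idx]
            denom = np.zeros(len(pairs))
            np.add.at(denom, pair_idx, w)
            d = denom[pair_idx]
            # pairs whose candidates all collapsed to theta 0: uniform share
            zero = d <= 0.0
            if np.any(zero):
                cnt = np.zeros(len(pairs))
                np.add.at(cnt, pair_idx, 1.0)
                w = np.where(zero, 1.0 / cnt[pair_idx], w / np.where(zero, 1.0, d))
            else:
                w = w / d
            est = np.zeros(n_c)
            np.add.at(est, contig_idx, w)
            new_theta = est / n_mapped
            delta = float(np.max(np.abs(new_theta - theta)))
            theta = new_theta
            if delta < tol:
                break
    rate = est / eff
    total_rate = rate.sum()
    tpm = 1e6 * rate / total_rate if total_rate > 0 else np.zeros(n_c)
    return [
        AbundanceEstimate(c.id, float(est[i]), float(tpm[i]))
        for i, c in enumerate(contigs)
    ]


def final_responsibilities(
    contigs: list[Contig],
    pairs: list[PairAlignment],
    abundances: list[AbundanceEstimate],
    lib: LibraryModel,
) -> dict[str, dict[str, float]]:
    """Per-pair contig responsibilities under the final abundance estimates."""
    est = {a.contig_id: a.est_fragments for a in abundances}
    eff = {c.id: effective_length(c.length, lib.fragment_mean) for c in contigs}
    out: dict[str, dict[str, float]] = {}
    for pair in pairs:
        if not pair.candidate_placements:
            continue
        w: dict[str, float] = {}
        for p in pair.candidate_placements:
            for cid in {m.contig_id for m in (p.mate1, p.mate2) if m.is_aligned}:
                w[cid] = w.get(cid, 0.0) + est[cid] / eff[cid]
        total = sum(w.values())
        if total <= 0.0:
            # collapsed abundances: fall back to a uniform draw
            w = {cid: 1.0 for cid in w}
            total = float(len(w))
        out[pair.pair_id] = {cid: v / total for cid, v in w.items()}
    return out


def assign_pairs(
    pairs: list[PairAlignment],
    abundances: list[AbundanceEstimate],
    seed: int = 0,
    *,
    contigs: list[Contig] | None = None,
    lib: LibraryModel | None = None,
) -> list[PairAlignment]:
    """Draw one all-or-nothing contig assignment per mapped pair.

    Multi-mapping pairs sample their contig with probability proportional
    to the final EM responsibilities; uniquely mapping pairs are assigned
    deterministically; unmapped pairs stay unassigned.  With a fixed seed
    the assignment is reproducible bit for bit.
    """
    if contigs is None or lib is None:
        raise ValueError("assign_pairs requires contigs and lib keywords")
    resp = final_responsibilities(contigs, pairs, abundances, lib)
    rng = np.random.default_rng(seed)
    for pair in pairs:
        if not pair.candidate_placements:
            pair.assigned_contig = None
            continue
        r = resp[pair.pair_id]
        cids = sorted(r)
        if len(cids) == 1:
            pair.assigned_contig = cids[0]
            continue
        probs = np.array([r[c] for c in cids])
        probs = probs / probs.sum()
        pair.assigned_contig = cids[int(rng.choice(len(cids), p=probs))]
    return pairs


def write_abundance_tsv(abundances: list[AbundanceEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\test_fragments\ttpm\n")
        for a in abundances:
            fh.write(f"{a.contig_id}\t{a.est_fragments:.6g}\t{a.tpm:.6g}\n")
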