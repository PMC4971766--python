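"""Synthetic transcriptomes, paired reads with ground truth, and corruptions.

The generator emulates a bulk RNA-seq experiment at desk scale:
transcripts with log-normal lengths and exponentially distributed
abundances, uniform random fragmentation size-selected to a normal
fragment-length distribution, inward-oriented paired-end reads with
i.i.d. substitution errors, and ground-truth alignments (with exact
per-mate edit distances) that feed the evaluation pipeline directly, so
no external read aligner is needed.  In-silico chimeras (head-to-tail
fusions) and assembly corruptions (insertions, truncations, fusions,
duplications) come with manifests and truth-alignment projection, giving
every contig a known error status for validation experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from transqc.io_model import (
    Contig,
    MateAlignment,
    PairAlignment,
    Placement,
    FORWARD,
    REVERSE,
    DEFAULT_MAX_EDIT_DISTANCE,
)

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults follow a typical size-selected Illumina paired-end library:
    100-bp mates from fragments of mean 400 nt and sd 50 nt, transcript
    lengths log-normal around ~1.3 kb, exponentially distributed
    abundances, and a 1% per-base substitution error rate.
    """

    n_transcripts: int = 50
    length_log_mean: float = 7.2
    length_log_sd: float = 0.4
    abundance_rate: float = 1.0
    n_pairs: int = 20_000
    read_length: int = 100
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if min(self.n_transcripts, self.n_pairs, self.read_length) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class ChimeraSpec:
    n_fusions: int
    abundance_ratio: float = 1.0
    pairing: str = "random"  # "random" or "ratio"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Transcriptome

def simulate_transcriptome(cfg: SimConfig) -> tuple[list[Contig], dict[str, float]]:
    """Random transcripts with log-normal lengths and exponential abundances.

    Lengths are floored at the shortest fragment the library can
    produce; abundances are normalized to sum to 1.
    """
    rng = np.random.default_rng(cfg.seed)
    min_len = int(max(2 * cfg.read_length, cfg.fragment_mean - 3 * cfg.fragment_sd))
    lengths = np.maximum(
        rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, cfg.n_transcripts)
        .round()
        .astype(int),
        min_len,
    )
    transcripts = [
        Contig(f"t{i:04d}", "".join(rng.choice(_BASES, size=n)))
        for i, n in enumerate(lengths)
    ]
    ab = rng.exponential(1.0 / cfg.abundance_rate, cfg.n_transcripts)
    ab = ab / ab.sum()
    abundances = {t.id: float(a) for t, a in zip(transcripts, ab)}
    return transcripts, abundances


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(
    transcripts: list[Contig],
    abundances: dict[str, float],
    cfg: SimConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[PairAlignment]]:
    """Simulate read pairs and their ground-truth alignments.

    Per pair: a transcript is chosen with probability proportional to
    abundance * length (molecule mass under uniform fragmentation), a
    fragment length is drawn Normal(mean, sd) truncated to
    [2 * read_length, transcript length], the fragment start is uniform,
    and the two mates read inward from the fragment ends.  Substitution
    errors are injected i.i.d. at ``error_rate``; the truth edit
    distance of each mate counts its injected substitutions.
    """
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    usable = [t for t in transcripts if t.length >= 2 * rl]
    skipped = len(transcripts) - len(usable)
    if skipped:
        warnings.warn(f"excluded {skipped} transcripts shorter than 2*read_length")
    if not usable:
        raise ValueError("no transcripts long enough to carry a read pair")
    weights = np.array([abundances[t.id] * t.length for t in usable])
    weights = weights / weights.sum()
    choices = rng.choice(len(usable), size=cfg.n_pairs, p=weights)
    flens = rng.normal(cfg.fragment_mean, cfg.fragment_sd, cfg.n_pairs)

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    truth: list[PairAlignment] = []
    for i in range(cfg.n_pairs):
        t = usable[choices[i]]
        flen = int(round(flens[i]))
        flen = max(2 * rl, min(flen, t.length))
        start = int(rng.integers(0, t.length - flen + 1))
        m1_span = (start, start + rl)
        m2_span = (start + flen - rl, start + flen)
        pid = f"p{i:07d}"
        seq1 = t.sequence[m1_span[0] : m1_span[1]]
        seq2 = revcomp(t.sequence[m2_span[0] : m2_span[1]])
        nm1 = nm2 = 0
        if cfg.error_rate > 0:
            seq1, nm1 = _mutate(seq1, cfg.error_rate, rng)
            seq2, nm2 = _mutate(seq2, cfg.error_rate, rng)
        reads1.append((pid, seq1))
        reads2.append((pid, seq2))
        m1 = MateAlignment(f"{pid}/1", t.id, m1_span[0], m1_span[1], FORWARD, nm1)
        m2 = MateAlignment(f"{pid}/2", t.id, m2_span[0], m2_span[1], REVERSE, nm2)
        truth.append(PairAlignment(pid, m1, m2, [Placement(t.id, m1, m2)]))
    return reads1, reads2, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    n_err = int(rng.binomial(len(seq), rate))
    if n_err == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        alt = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alt[int(rng.integers(0, 3))]
    return "".join(chars), n_err


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, mate: int) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Chimeras

def make_chimeras(
    transcripts: list[Contig],
    abundances: dict[str, float],
    spec: ChimeraSpec,
    seed: int = 0,
) -> tuple[list[Contig], list[dict]]:
    """Fuse transcript pairs head-to-tail, replacing both constituents.

    With ``pairing="random"`` partners are drawn uniformly (the realized
    abundance ratio is recorded in the manifest); with
    ``pairing="ratio"`` partners are greedily matched so their abundance
    ratios approximate ``spec.abundance_ratio``.  Manifest rows carry the
    fusion id, both parts, the junction coordinate, and the true ratio.
    """
    if 2 * spec.n_fusions > len(transcripts):
        raise ValueError("not enough transcripts for the requested fusions")
    if spec.n_fusions == 0:
        return list(transcripts), []
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in transcripts}
    chosen = list(
        rng.choice([t.id for t in transcripts], size=2 * spec.n_fusions, replace=False)
    )
    if spec.pairing == "random":
        pairs = [(chosen[2 * i], chosen[2 * i + 1]) for i in range(spec.n_fusions)]
    elif spec.pairing == "ratio":
        pairs = _ratio_pairs(chosen, abundances, spec.abundance_ratio)
    else:
        raise ValueError("pairing must be 'random' or 'ratio'")

    manifest: list[dict] = []
    fused_ids = set()
    out: list[Contig] = []
    new: list[Contig] = []
    for i, (a, b) in enumerate(pairs):
        fused_ids.update((a, b))
        fid = f"fusion{i:04d}"
        seq = by_id[a].sequence + by_id[b].sequence
        new.append(Contig(fid, seq))
        ab_a, ab_b = abundances[a], abundances[b]
        lo, hi = min(ab_a, ab_b), max(ab_a, ab_b)
        realized = hi / lo if lo > 0 else math.inf
        rec = dict(
            fusion_id=fid, part1=a, part2=b,
            junction=by_id[a].length, realized_ratio=realized,
        )
        if spec.pairing == "ratio" and not (
            spec.abundance_ratio * 0.75 <= realized <= spec.abundance_ratio * 1.25
        ):
            rec["ratio_off_target"] = True
        manifest.append(rec)
    out = [t for t in transcripts if t.id not in fused_ids] + new
    return out, manifest


def _ratio_pairs(
    ids: list[str], abundances: dict[str, float], target: float
) -> list[tuple[str, str]]:
    """Greedy matching: pair each remaining id with the partner whose
    abundance ratio is closest to the target."""
    remaining = sorted(ids, key=lambda i: abundances[i], reverse=True)
    pairs = []
    while remaining:
        a = remaining.pop(0)
        best_j, best_err = 0, math.inf
        for j, b in enumerate(remaining):
            lo, hi = sorted((abundances[a], abundances[b]))
            ratio = hi / lo if lo > 0 else math.inf
            err = abs(math.log(ratio / target)) if math.isfinite(ratio) else math.inf
            if err < best_err:
                best_j, best_err = j, err
        pairs.append((a, remaining.pop(best_j)))
    return pairs


def lift_truth_to_chimeras(
    pairs: list[PairAlignment], manifest: list[dict]
) -> list[PairAlignment]:
    """Re-express truth alignments in the fused assembly's coordinates.

    Reads from part1 keep their coordinates under the fusion id; reads
    from part2 are shifted by the junction offset.
    """
    offset: dict[str, tuple[str, int]] = {}
    for rec in manifest:
        offset[rec["part1"]] = (rec["fusion_id"], 0)
        offset[rec["part2"]] = (rec["fusion_id"], rec["junction"])
    out = []
    for pair in pairs:
        if not pair.candidate_placements:
            out.append(
                PairAlignment(pair.pair_id,
                              MateAlignment.unaligned(f"{pair.pair_id}/1"),
                              MateAlignment.unaligned(f"{pair.pair_id}/2"), [])
            )
            continue
        new_placements = []
        for p in pair.candidate_placements:
            mates = []
            cid = None
            for m in (p.mate1, p.mate2):
                if m.is_aligned and m.contig_id in offset:
                    fid, off = offset[m.contig_id]
                    m = replace(m, contig_id=fid, start=m.start + off, end=m.end + off)
                if m.is_aligned and cid is None:
                    cid = m.contig_id
                mates.append(m)
            new_placements.append(Placement(cid or p.contig_id, mates[0], mates[1]))
        out.append(
            PairAlignment(pair.pair_id, new_placements[0].mate1,
                          new_placements[0].mate2, new_placements)
        )
    return out


# ---------------------------------------------------------------------------
# Assembly corruption

def corrupt_assembly(
    contigs: list[Contig],
    operations: Sequence[dict],
    seed: int = 0,
) -> tuple[list[Contig], list[dict]]:
    """Apply named corruptions to randomly chosen contigs.

    Each operation dict names a ``type`` (insertion | truncation |
    fusion | duplication), how many contigs to hit (``n``), and its
    parameters (insertion: ``length``; truncation and duplication:
    ``fraction``).  Targets are drawn without replacement across all
    operations, so each contig carries at most one corruption; the
    manifest records the ground truth per affected contig.
    """
    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in contigs}
    available = [c.id for c in contigs]
    rng.shuffle(available)
    manifest: list[dict] = []
    removed: set[str] = set()
    replaced: dict[str, Contig] = {}
    added: list[Contig] = []

    def take(n: int) -> list[str]:
        if n > len(available):
            raise ValueError("not enough uncorrupted contigs left")
        return [available.pop() for _ in range(n)]

    for op in operations:
        kind = op["type"]
        n = int(op.get("n", 1))
        if kind == "insertion":
            ilen = int(op.get("length", 50))
            for cid in take(n):
                c = by_id[cid]
                pos = int(rng.integers(1, c.length))
                ins = "".join(rng.choice(_BASES, size=ilen))
                replaced[cid] = Contig(cid, c.sequence[:pos] + ins + c.sequence[pos:])
                manifest.append(dict(type=kind, contig_id=cid, position=pos, length=ilen))
        elif kind == "truncation":
            frac = float(op.get("fraction", 0.3))
            for cid in take(n):
                c = by_id[cid]
                keep = max(1, int(round(c.length * (1 - frac))))
                replaced[cid] = Contig(cid, c.sequence[:keep])
                manifest.append(dict(type=kind, contig_id=cid, new_length=keep))
        elif kind == "fusion":
            for _ in range(n):
                a, b = take(2)
                fid = f"{a}--{b}"
                removed.update((a, b))
                added.append(Contig(fid, by_id[a].sequence + by_id[b].sequence))
                manifest.append(
                    dict(type=kind, contig_id=fid, part1=a, part2=b,
                         junction=by_id[a].length)
                )
        elif kind == "duplication":
            frac = float(op.get("fraction", 0.6))
            for cid in take(n):
                c = by_id[cid]
                dlen = max(1, int(round(c.length * frac)))
                start = int(rng.integers(0, c.length - dlen + 1))
                did = f"{cid}__dup"
                added.append(Contig(did, c.sequence[start : start + dlen]))
                manifest.append(
                    dict(type=kind, contig_id=did, source=cid,
                         source_start=start, source_end=start + dlen)
                )
        else:
            raise ValueError(f"unknown corruption type {kind!r}")

    out = []
    for c in contigs:
        if c.id in removed:
            continue
        out.append(replaced.get(c.id, c))
    out.extend(added)
    return out, manifest


def project_truth_to_corrupted(
    pairs: list[PairAlignment],
    manifest: list[dict],
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> list[PairAlignment]:
    """Model how truth alignments look against the corrupted assembly.

    insertion: mates downstream shift; mates spanning an insertion no
    longer than the reporting cap keep their placement with the span
    stretched over the inserted bases and the edit distance raised by
    the insertion length (a conservative model of an aligner forcing
    the read across unsupported sequence), while longer insertions
    break the alignment and the mate is dropped.  truncation: mates
    beyond or
    crossing the new end are dropped (unaligned).  fusion: coordinates
    lift as for chimeras.  duplication: placements falling inside the
    copied window gain a second candidate placement on the duplicate.
    """
    insertions = {m["contig_id"]: m for m in manifest if m["type"] == "insertion"}
    truncations = {m["contig_id"]: m for m in manifest if m["type"] == "truncation"}
    fusion_manifest = [
        dict(fusion_id=m["contig_id"], part1=m["part1"], part2=m["part2"],
             junction=m["junction"])
        for m in manifest if m["type"] == "fusion"
    ]
    duplications = {m["source"]: m for m in manifest if m["type"] == "duplication"}

    out = []
    for pair in pairs:
        placements: list[Placement] = []
        for p in pair.candidate_placements:
            mates = []
            for m in (p.mate1, p.mate2):
                mates.append(_transform_mate(m, insertions, truncations, max_edit_distance))
            cid = next((m.contig_id for m in mates if m.is_aligned), None)
            if cid is not None:
                placements.append(Placement(cid, mates[0], mates[1]))
            # duplicate placements
            dup = duplications.get(p.contig_id)
            if dup is not None and cid is not None:
                a, b = dup["source_start"], dup["source_end"]
                dm = []
                ok = True
                for m in mates:
                    if not m.is_aligned:
                        dm.append(m)
                        continue
                    if m.start >= a and m.end <= b:
                        dm.append(
                            replace(m, contig_id=dup["contig_id"],
                                    start=m.start - a, end=m.end - a)
                        )
                    else:
                        ok = False
                        break
                if ok and any(m.is_aligned for m in dm):
                    placements.append(Placement(dup["contig_id"], dm[0], dm[1]))
        new_pair = PairAlignment(
            pair.pair_id,
            placements[0].mate1 if placements else MateAlignment.unaligned(f"{pair.pair_id}/1"),
            placements[0].mate2 if placements else MateAlignment.unaligned(f"{pair.pair_id}/2"),
            placements,
        )
        out.append(new_pair)
    if fusion_manifest:
        out = lift_truth_to_chimeras(out, fusion_manifest)
    return out


def _transform_mate(
    m: MateAlignment,
    insertions: dict[str, dict],
    truncations: dict[str, dict],
    ehat: int,
) -> MateAlignment:
    if not m.is_aligned:
        return m
    ins = insertions.get(m.contig_id)
    if ins is not None:
        pos, ilen = ins["position"], ins["length"]
        if m.end <= pos:
            pass
        elif m.start >= pos:
            m = replace(m, start=m.start + ilen, end=m.end + ilen)
        elif ilen <= ehat:
            # an aligner can force the read across a short insertion,
            # reporting it with a raised edit distance
            m = replace(m, end=m.end + ilen,
                        edit_distance=min(m.edit_distance + ilen, ehat))
        else:
            # insertions beyond the reporting cap break the alignment
            return MateAlignment.unaligned(m.read_id)
    trunc = truncations.get(m.contig_id)
    if trunc is not None and m.end > trunc["new_length"]:
        return MateAlignment.unaligned(m.read_id)
    return m


def shuffle_mate_strands(
    pairs: list[PairAlignment], fraction: float, seed: int = 0
) -> list[PairAlignment]:
    """Flip the second mate's strand for a seeded fraction of mapped pairs.

    Used to emulate orientation-scrambled pairs for monotonicity checks
    on the order component.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        if pair.candidate_placements and rng.random() < fraction:
            placements = []
            for p in pair.candidate_placements:
                m2 = p.mate2
                if m2.is_aligned:
                    m2 = replace(
                        m2, strand=FORWARD if m2.strand == REVERSE else REVERSE
                    )
                placements.append(Placement(p.contig_id, p.mate1, m2))
            pair = PairAlignment(
                pair.pair_id, placements[0].mate1, placements[0].mate2, placements
            )
        else:
            pair = PairAlignment(
                pair.pair_id, pair.mate1, pair.mate2,
                list(pair.candidate_placements),
            )
        out.append(pair)
    return out


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    keys: list[str] = []
    for rec in manifest:
        for k in rec:
            if k not in keys:
                keys.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for rec in manifest:
            fh.write("\t".join(str(rec.get(k, ".")) for k in keys) + "\n")
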