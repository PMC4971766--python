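"""Contig and assembly scores, cutoff learning, and assembly filtering.

The contig score s(C) is the product of the four components (each
floored at a small value so that a single failed component cannot
annihilate the assembly-level geometric mean).  The assembly score is
the geometric mean of contig scores times the fraction of read pairs
mapped (R_valid).  An optimal score cutoff is learned by exhaustively
sweeping the distinct contig scores: the objective is piecewise constant
in the cutoff, so the sweep solves the global optimization exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from transqc.assignment import (
    AbundanceEstimate,
    LibraryModel,
    assign_pairs,
    estimate_abundances,
    infer_library,
)
from transqc.contig_metrics import (
    ComponentScores,
    DEFAULT_K_SD,
    STATUS_DIFFERENT_CONTIGS,
    classify_pair,
    order_count_table,
    score_cov,
    score_nuc,
    score_ord,
)
from transqc.io_model import (
    AlignmentConfig,
    Contig,
    PairAlignment,
    build_evidence,
    write_fasta,
)
from transqc.segmentation import (
    DEFAULT_ALPHA,
    DEFAULT_BIN_WIDTH,
    DEFAULT_K_MAX,
    encode_profile,
    p_single_segment,
    trim_edges,
)

#: Component floor applied before taking the product.
DEFAULT_FLOOR = 0.01


@dataclass
class ContigScore:
    contig_id: str
    components: ComponentScores
    s: float
    s_w: float
    tpm: float


@dataclass
class AssemblyReport:
    n_contigs: int
    r_valid: float
    geomean_contig_score: float
    score: float
    weighted_score: float
    optimal_cutoff: float
    optimized_score: float
    contig_scores: list[ContigScore] = field(default_factory=list)
    library: LibraryModel | None = None

    def contig_table(self) -> pd.DataFrame:
        rows = []
        for cs in self.contig_scores:
            c = cs.components
            rows.append(
                dict(
                    contig_id=cs.contig_id,
                    s_nuc=c.s_nuc,
                    s_cov=c.s_cov,
                    s_ord=c.s_ord,
                    s_seg=c.s_seg,
                    score=cs.s,
                    weighted_score=cs.s_w,
                    tpm=cs.tpm,
                )
            )
        return pd.DataFrame(rows)


def contig_score(components: ComponentScores, floor: float = DEFAULT_FLOOR) -> float:
    """Product of the four components, each floored at ``floor``."""
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must be in (0, 1)")
    vals = (components.s_nuc, components.s_cov, components.s_ord, components.s_seg)
    out = 1.0
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"component out of [0,1]: {v}")
        out *= max(v, floor)
    return out


def weighted_contig_score(s: float, tpm: float, n_contigs: int) -> float:
    """Abundance-weighted contig score s ** (1 + log_n(TPM + 1)).

    The log base is the number of contigs, so the exponent grows from 1
    (TPM = 0) and a highly abundant but erroneous contig is penalized
    more heavily than a rare contig with the same errors.
    """
    if n_contigs < 2:
        raise ValueError("weighted score undefined for fewer than 2 contigs")
    if tpm < 0:
        raise ValueError("tpm must be >= 0")
    exponent = 1.0 + math.log(tpm + 1.0) / math.log(n_contigs)
    return s**exponent


def assembly_score(scores: list[ContigScore], r_valid: float, weighted: bool = False) -> float:
    """Geometric mean of contig scores times the mapped-pair fraction."""
    if not scores:
        raise ValueError("cannot score an empty assembly")
    if not 0.0 <= r_valid <= 1.0:
        raise ValueError("r_valid must be in [0, 1]")
    logs = [math.log(cs.s_w if weighted else cs.s) for cs in scores]
    return math.exp(sum(logs) / len(logs)) * r_valid


def compute_r_valid(pairs: list[PairAlignment]) -> float:
    """Fraction of input read pairs with both mates aligned somewhere."""
    if not pairs:
        raise ValueError("no input read pairs")
    mapped = sum(1 for p in pairs if p.both_mates_mapped)
    return mapped / len(pairs)


def _retained_objective(
    sorted_scores: np.ndarray,
    sorted_pair_counts: np.ndarray,
    n_total_pairs: int,
    cutoff: float,
) -> float:
    keep = sorted_scores >= cutoff
    if not np.any(keep) or n_total_pairs == 0:
        return 0.0
    logs = np.log(sorted_scores[keep])
    r = sorted_pair_counts[keep].sum() / n_total_pairs
    return float(np.exp(logs.mean()) * r)


def learn_cutoff(
    scores: list[ContigScore], pairs: list[PairAlignment]
) -> tuple[float, float]:
    """Find the contig-score cutoff maximizing the assembly score.

    Every candidate cutoff in {0} plus the distinct contig scores is
    evaluated on the retained subset, with R_valid recomputed from the
    pairs whose assigned contig survives (both mates mapped); pairs are
    not re-assigned.  Ties prefer the smaller cutoff (retain more).
    """
    if not scores:
        raise ValueError("cannot learn a cutoff for an empty assembly")
    per_contig_pairs: dict[str, int] = {cs.contig_id: 0 for cs in scores}
    n_total = len(pairs)
    for p in pairs:
        if p.both_mates_mapped and p.assigned_contig in per_contig_pairs:
            per_contig_pairs[p.assigned_contig] += 1
    svals = np.array([cs.s for cs in scores])
    counts = np.array([per_contig_pairs[cs.contig_id] for cs in scores], dtype=float)
    candidates = sorted({0.0} | set(svals.tolist()))
    best_cut, best_obj = 0.0, -np.inf
    for cut in candidates:
        obj = _retained_objective(svals, counts, n_total, cut)
        if obj > best_obj:
            best_cut, best_obj = cut, obj
    if best_obj <= 0.0:
        return 0.0, _retained_objective(svals, counts, n_total, 0.0)
    return best_cut, best_obj


def filter_assembly(
    contigs: list[Contig],
    scores: list[ContigScore],
    cutoff: float,
    kept_path: str | Path | None = None,
    discarded_path: str | Path | None = None,
) -> tuple[list[Contig], list[Contig]]:
    """Partition contigs by score >= cutoff; optionally write both FASTAs."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    by_id = {cs.contig_id: cs.s for cs in scores}
    kept = [c for c in contigs if by_id.get(c.id, 0.0) >= cutoff]
    discarded = [c for c in contigs if by_id.get(c.id, 0.0) < cutoff]
    if kept_path is not None:
        write_fasta(kept, kept_path)
    if discarded_path is not None:
        write_fasta(discarded, discarded_path)
    return kept, discarded


# ---------------------------------------------------------------------------
# End-to-end pipeline

def score_assembly(
    contigs: list[Contig],
    pairs: list[PairAlignment],
    cfg: AlignmentConfig = AlignmentConfig(),
    seed: int = 0,
    k_sd: float = DEFAULT_K_SD,
    k_max: int = DEFAULT_K_MAX,
    alpha: float = DEFAULT_ALPHA,
    bin_width: int | None = DEFAULT_BIN_WIDTH,
    floor: float = DEFAULT_FLOOR,
    subsample_fraction: float = 0.01,
    lib: LibraryModel | None = None,
) -> AssemblyReport:
    """Run the full evaluation: library model, EM assignment, components,
    contig and assembly scores, and cutoff learning.

    ``bin_width`` controls the coverage binning for the segmentation
    component (``None`` or 1 forces per-nucleotide symbols).  Passing
    ``lib`` skips library inference (useful for controlled experiments).
    """
    if lib is None:
        lib = infer_library(pairs, fraction=subsample_fraction, seed=seed)
    abundances = estimate_abundances(contigs, pairs, lib)
    tpm = {a.contig_id: a.tpm for a in abundances}
    pairs = assign_pairs(pairs, abundances, seed=seed + 1, contigs=contigs, lib=lib)
    evidence = build_evidence(contigs, pairs, cfg)
    lengths = {c.id: c.length for c in contigs}

    # order classification: each pair counts toward its assigned contig,
    # and a different-contigs pair also toward the partner contig
    per_contig_cls: dict[str, list] = {c.id: [] for c in contigs}
    for pair in pairs:
        if pair.assigned_contig is None:
            continue
        cls = classify_pair(pair, lib, k_sd=k_sd, contig_lengths=lengths)
        per_contig_cls[pair.assigned_contig].append(cls)
        if cls.status == STATUS_DIFFERENT_CONTIGS:
            placement = pair.best_placement_on(pair.assigned_contig)
            for mate in (placement.mate1, placement.mate2):
                if mate.is_aligned and mate.contig_id != pair.assigned_contig:
                    per_contig_cls[mate.contig_id].append(cls)

    # segmentation: terminal depth within one fragment length of each end
    # is geometrically depressed, so it is trimmed before encoding;
    # alphabet shared across the assembly for comparability
    bw = bin_width if bin_width is not None else 1
    trim = int(round(lib.fragment_mean))
    profiles = {
        c.id: encode_profile(
            trim_edges(evidence[c.id].depth, trim), max(1, bw), contig_id=c.id
        )
        for c in contigs
    }
    shared_alphabet = max(max(p.alphabet_size for p in profiles.values()), 2)

    contig_scores: list[ContigScore] = []
    n_contigs = len(contigs)
    for c in contigs:
        ev = evidence[c.id]
        comp = ComponentScores(c.id)
        comp.s_nuc = score_nuc(ev)
        comp.s_cov = score_cov(ev)
        comp.s_ord = score_ord(per_contig_cls[c.id])
        if ev.assigned_pairs == 0:
            comp.s_seg = 0.0
        else:
            comp.s_seg = p_single_segment(
                profiles[c.id], k_max=k_max, alpha=alpha,
                alphabet_size=shared_alphabet,
            ).p_single
        ev.order_counts = order_count_table(per_contig_cls[c.id])
        s = contig_score(comp, floor=floor)
        s_w = (
            weighted_contig_score(s, tpm[c.id], n_contigs)
            if n_contigs >= 2
            else s
        )
        contig_scores.append(ContigScore(c.id, comp, s, s_w, tpm[c.id]))

    r_valid = compute_r_valid(pairs)
    raw = assembly_score(contig_scores, r_valid)
    weighted = assembly_score(contig_scores, r_valid, weighted=True)
    geomean = raw / r_valid if r_valid > 0 else 0.0
    cutoff, optimized = learn_cutoff(contig_scores, pairs)
    return AssemblyReport(
        n_contigs=n_contigs,
        r_valid=r_valid,
        geomean_contig_score=geomean,
        score=raw,
        weighted_score=weighted,
        optimal_cutoff=cutoff,
        optimized_score=optimized,
        contig_scores=contig_scores,
        library=lib,
    )


def write_report(report: AssemblyReport, out_dir: str | Path) -> None:
    """Write assembly_report.tsv and contig_scores.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "assembly_report.tsv", "w") as fh:
        cols = [
            "n_contigs", "r_valid", "geomean", "score",
            "weighted_score", "optimal_cutoff", "optimized_score",
        ]
        fh.write("\t".join(cols) + "\n")
        vals = [
            report.n_contigs, report.r_valid, report.geomean_contig_score,
            report.score, report.weighted_score, report.optimal_cutoff,
            report.optimized_score,
        ]
        fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for v in vals) + "\n")
    table = report.contig_table()
    table.to_csv(out / "contig_scores.tsv", sep="\t", index=False, float_format="%.6g")
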