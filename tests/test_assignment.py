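"""Library inference, EM abundance estimation, and pair assignment."""

import numpy as np
import pytest

from transqc.assignment import (
    LibraryModel,
    assign_pairs,
    estimate_abundances,
    infer_library,
)
from transqc.io_model import Contig, MateAlignment, PairAlignment, Placement
from transqc.simulate import SimConfig, simulate_reads, simulate_transcriptome


def _inward_pair(pid, contig_id, start, frag, nm=0, contig_ids=None):
    """A pair mapping inward on one contig (optionally multi-mapped)."""
    placements = []
    for cid in contig_ids or [contig_id]:
        m1 = MateAlignment(f"{pid}/1", cid, start, start + 100, "forward", nm)
        m2 = MateAlignment(
            f"{pid}/2", cid, start + frag - 100, start + frag, "reverse", nm
        )
        placements.append(Placement(cid, m1, m2))
    return PairAlignment(pid, placements[0].mate1, placements[0].mate2, placements)


# ---------------------------------------------------------------------------
# infer_library


def test_infer_library_constant_fragments():
    pairs = [_inward_pair(f"p{i}", "c", 0, 400) for i in range(1000)]
    lib = infer_library(pairs, seed=0)
    assert lib.orientation == "forward-reverse"
    assert lib.fragment_mean == 400.0
    assert lib.fragment_sd == 0.0


def test_infer_library_orientation_tie_warns():
    inward = [_inward_pair(f"p{i}", "c", 0, 400) for i in range(10)]
    outward = []
    for i in range(10):
        m1 = MateAlignment(f"q{i}/1", "c", 0, 100, "reverse", 0)
        m2 = MateAlignment(f"q{i}/2", "c", 300, 400, "forward", 0)
        outward.append(PairAlignment(f"q{i}", m1, m2, [Placement("c", m1, m2)]))
    with pytest.warns(UserWarning, match="tie"):
        lib = infer_library(inward + outward, seed=0)
    assert lib.orientation == "forward-reverse"  # lexicographically first


def test_infer_library_no_candidates_error():
    m1 = MateAlignment("p/1", "a", 0, 100, "forward", 0)
    m2 = MateAlignment("p/2", "b", 0, 100, "reverse", 0)
    pair = PairAlignment("p", m1, m2, [Placement("a", m1, m2)])
    with pytest.raises(ValueError, match="cannot infer"):
        infer_library([pair])


def test_infer_library_recovers_simulated_fragment_model():
    cfg = SimConfig(seed=3, n_transcripts=20, n_pairs=20000, error_rate=0.0)
    transcripts, abundances = simulate_transcriptome(cfg)
    _, _, truth = simulate_reads(transcripts, abundances, cfg)
    lib = infer_library(truth, seed=5)
    assert abs(lib.fragment_mean - 400) <= 3
    assert abs(lib.fragment_sd - 50) <= 3


# ---------------------------------------------------------------------------
# estimate_abundances

LIB = LibraryModel("forward-reverse", 400.0, 50.0)


def test_em_identical_contigs_split_half():
    contigs = [Contig("a", "A" * 1000), Contig("b", "A" * 1000)]
    pairs = [
        _inward_pair(f"p{i}", "a", 0, 400, contig_ids=["a", "b"]) for i in range(50)
    ]
    est = estimate_abundances(contigs, pairs, LIB)
    by_id = {a.contig_id: a for a in est}
    assert by_id["a"].est_fragments == pytest.approx(25.0, abs=1e-6)
    assert by_id["b"].est_fragments == pytest.approx(25.0, abs=1e-6)
    assert by_id["a"].tpm == pytest.approx(500000.0, rel=1e-6)


def test_em_unique_mapping_counts_exact():
    contigs = [Contig("a", "A" * 1000), Contig("b", "A" * 2000)]
    pairs = [_inward_pair(f"p{i}", "a", 0, 400) for i in range(30)]
    pairs += [_inward_pair(f"q{i}", "b", 0, 400) for i in range(70)]
    for max_iter in (1, 5, 100):
        est = {
            a.contig_id: a.est_fragments
            for a in estimate_abundances(contigs, pairs, LIB, max_iter=max_iter)
        }
        assert est["a"] == pytest.approx(30.0, abs=1e-9)
        assert est["b"] == pytest.approx(70.0, abs=1e-9)


def _reference_em(contigs, pairs, lib, iters=2000):
    """Independent plain-dict EM run to convergence (test oracle)."""
    eff = {c.id: max(c.length - lib.fragment_mean + 1, 1.0) for c in contigs}
    cand = []
    for p in pairs:
        cids = []
        for pl in p.candidate_placements:
            for cid in {m.contig_id for m in (pl.mate1, pl.mate2) if m.is_aligned}:
                cids.append(cid)
        if cids:
            cand.append(cids)
    theta = {c.id: 1.0 / len(contigs) for c in contigs}
    for _ in range(iters):
        est = {c.id: 0.0 for c in contigs}
        for cids in cand:
            # per-placement weights, repeated contigs count per placement
            weights = [theta[cid] / eff[cid] for cid in cids]
            total = sum(weights)
            for cid, w in zip(cids, weights):
                est[cid] += w / total if total > 0 else 1.0 / len(cids)
        theta = {cid: est[cid] / len(cand) for cid in est}
    return est


def test_em_matches_independent_reference_on_toy():
    contigs = [
        Contig("a", "A" * 600),
        Contig("b", "A" * 900),
        Contig("c", "A" * 1500),
    ]
    pairs = []
    pairs += [_inward_pair(f"u{i}", "a", 0, 400) for i in range(12)]
    pairs += [_inward_pair(f"v{i}", "b", 0, 400) for i in range(4)]
    pairs += [
        _inward_pair(f"m{i}", "a", 0, 400, contig_ids=["a", "b"]) for i in range(9)
    ]
    pairs += [
        _inward_pair(f"n{i}", "c", 0, 400, contig_ids=["b", "c"]) for i in range(5)
    ]
    est = {
        a.contig_id: a.est_fragments
        for a in estimate_abundances(contigs, pairs, LIB, tol=1e-12, max_iter=5000)
    }
    ref = _reference_em(contigs, pairs, LIB)
    for cid in est:
        assert est[cid] == pytest.approx(ref[cid], abs=1e-6)


def test_em_loglik_nondecreasing():
    contigs = [Contig("a", "A" * 600), Contig("b", "A" * 900)]
    pairs = [_inward_pair(f"u{i}", "a", 0, 400) for i in range(5)]
    pairs += [
        _inward_pair(f"m{i}", "a", 0, 400, contig_ids=["a", "b"]) for i in range(15)
    ]
    eff = {c.id: max(c.length - 400 + 1, 1.0) for c in contigs}

    def loglik(est):
        theta = {cid: v / 20 for cid, v in est.items()}
        ll = 0.0
        for p in pairs:
            contrib = sum(
                theta[pl.contig_id] / eff[pl.contig_id]
                for pl in p.candidate_placements
            )
            ll += np.log(contrib)
        return ll

    lls = []
    for it in range(1, 12):
        est = {
            a.contig_id: a.est_fragments
            for a in estimate_abundances(contigs, pairs, LIB, tol=1e-15, max_iter=it)
        }
        lls.append(loglik(est))
    assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))


def test_em_conservation_on_simulation(noisy_sim):
    cfg, transcripts, _, truth = noisy_sim
    lib = infer_library(truth, seed=0)
    est = estimate_abundances(transcripts, truth, lib)
    n_mapped = sum(1 for p in truth if p.is_mapped)
    total = sum(a.est_fragments for a in est)
    assert total == pytest.approx(n_mapped, rel=1e-6)
    assert sum(a.tpm for a in est) == pytest.approx(1e6, rel=1e-6)


def test_em_recovers_true_fragment_counts(small_sim):
    """Without multi-mapping, est_fragments ranks with true pair counts."""
    from scipy.stats import spearmanr

    cfg, transcripts, _, truth = small_sim
    lib = infer_library(truth, seed=0)
    est = {a.contig_id: a.est_fragments
           for a in estimate_abundances(transcripts, truth, lib)}
    true_counts = {c.id: 0 for c in transcripts}
    for p in truth:
        true_counts[p.candidate_placements[0].contig_id] += 1
    ids = [c.id for c in transcripts]
    rho = spearmanr([est[i] for i in ids], [true_counts[i] for i in ids]).statistic
    assert rho > 0.95


# ---------------------------------------------------------------------------
# assign_pairs


def test_assign_unique_is_deterministic():
    contigs = [Contig("a", "A" * 1000)]
    pairs = [_inward_pair("p0", "a", 0, 400)]
    est = estimate_abundances(contigs, pairs, LIB)
    out = assign_pairs(pairs, est, seed=0, contigs=contigs, lib=LIB)
    assert out[0].assigned_contig == "a"


def test_assign_sampling_follows_responsibilities():
    contigs = [Contig("a", "A" * 1000), Contig("b", "A" * 1000)]
    # abundance heavily skewed toward a
    pairs = [_inward_pair(f"u{i}", "a", 0, 400) for i in range(999)]
    pairs += [_inward_pair("v0", "b", 0, 400)]
    multi = [
        _inward_pair(f"m{i}", "a", 0, 400, contig_ids=["a", "b"])
        for i in range(10000)
    ]
    est = estimate_abundances(contigs, pairs + multi, LIB)
    out = assign_pairs(multi, est, seed=1, contigs=contigs, lib=LIB)
    frac_a = np.mean([p.assigned_contig == "a" for p in out])
    assert frac_a >= 0.95


def test_assign_zero_responsibility_uniform_fallback():
    contigs = [Contig("a", "A" * 1000), Contig("b", "A" * 1000)]
    pairs = [
        _inward_pair(f"m{i}", "a", 0, 400, contig_ids=["a", "b"])
        for i in range(2000)
    ]
    from transqc.assignment import AbundanceEstimate

    est = [AbundanceEstimate("a", 0.0, 0.0), AbundanceEstimate("b", 0.0, 0.0)]
    out = assign_pairs(pairs, est, seed=3, contigs=contigs, lib=LIB)
    frac_a = np.mean([p.assigned_contig == "a" for p in out])
    assert 0.4 < frac_a < 0.6
    assert all(p.assigned_contig in ("a", "b") for p in out)


def test_assignment_reproducible_and_conserving(noisy_sim):
    cfg, transcripts, _, truth = noisy_sim
    lib = infer_library(truth, seed=0)
    est = estimate_abundances(transcripts, truth, lib)
    a1 = [
        p.assigned_contig
        for p in assign_pairs(truth, est, seed=9, contigs=transcripts, lib=lib)
    ]
    a2 = [
        p.assigned_contig
        for p in assign_pairs(truth, est, seed=9, contigs=transcripts, lib=lib)
    ]
    assert a1 == a2
    assert all(a is not None for a in a1)  # every mapped pair assigned
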