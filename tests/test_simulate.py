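"""Determinism, distributional checks, and corruption bookkeeping."""

import numpy as np
import pytest

from transqc.io_model import build_evidence
from transqc.simulate import (
    ChimeraSpec,
    SimConfig,
    corrupt_assembly,
    lift_truth_to_chimeras,
    make_chimeras,
    project_truth_to_corrupted,
    simulate_reads,
    simulate_transcriptome,
)


def test_transcriptome_deterministic_under_seed():
    cfg = SimConfig(seed=13, n_transcripts=20)
    t1, a1 = simulate_transcriptome(cfg)
    t2, a2 = simulate_transcriptome(cfg)
    assert [(c.id, c.sequence) for c in t1] == [(c.id, c.sequence) for c in t2]
    assert a1 == a2


def test_transcriptome_abundances_normalized():
    transcripts, ab = simulate_transcriptome(SimConfig(seed=2, n_transcripts=100))
    assert len(transcripts) == 100
    assert sum(ab.values()) == pytest.approx(1.0, abs=1e-9)


def test_transcriptome_degenerate_length_sd():
    transcripts, _ = simulate_transcriptome(
        SimConfig(seed=2, n_transcripts=10, length_log_sd=0.0)
    )
    lengths = {c.length for c in transcripts}
    assert len(lengths) == 1


def test_reads_error_free_have_zero_edit_distance(small_sim):
    _, _, _, truth = small_sim
    for p in truth[:500]:
        pl = p.candidate_placements[0]
        assert pl.mate1.edit_distance == 0
        assert pl.mate2.edit_distance == 0


def test_reads_deterministic_under_seed():
    cfg = SimConfig(seed=17, n_transcripts=5, n_pairs=200, error_rate=0.02)
    ts, ab = simulate_transcriptome(cfg)
    r1a, r2a, ta = simulate_reads(ts, ab, cfg)
    r1b, r2b, tb = simulate_reads(ts, ab, cfg)
    assert r1a == r1b and r2a == r2b
    assert [p.candidate_placements[0].mate1.start for p in ta] == [
        p.candidate_placements[0].mate1.start for p in tb
    ]


def test_reads_match_transcript_sequence_when_error_free(small_sim):
    from transqc.simulate import revcomp

    _, transcripts, ab, truth = small_sim
    cfg = SimConfig(seed=7, n_transcripts=12, n_pairs=4000, error_rate=0.0)
    r1, r2, truth2 = simulate_reads(transcripts, ab, cfg)
    by_id = {c.id: c.sequence for c in transcripts}
    for (rid, seq), pair in list(zip(r1, truth2))[:200]:
        m1 = pair.candidate_placements[0].mate1
        assert seq == by_id[m1.contig_id][m1.start : m1.end]
    for (rid, seq), pair in list(zip(r2, truth2))[:200]:
        m2 = pair.candidate_placements[0].mate2
        assert seq == revcomp(by_id[m2.contig_id][m2.start : m2.end])


def test_reads_fragment_sd_zero():
    cfg = SimConfig(
        seed=4, n_transcripts=5, n_pairs=500, fragment_sd=0.0, error_rate=0.0,
        length_log_mean=7.6, length_log_sd=0.0,
    )
    ts, ab = simulate_transcriptome(cfg)
    _, _, truth = simulate_reads(ts, ab, cfg)
    sizes = {
        p.candidate_placements[0].mate2.end - p.candidate_placements[0].mate1.start
        for p in truth
    }
    assert sizes == {400}


def test_read_counts_proportional_to_abundance_times_length():
    cfg = SimConfig(seed=9, n_transcripts=50, n_pairs=20000, error_rate=0.0)
    ts, ab = simulate_transcriptome(cfg)
    _, _, truth = simulate_reads(ts, ab, cfg)
    counts = {c.id: 0 for c in ts}
    for p in truth:
        counts[p.candidate_placements[0].contig_id] += 1
    w = np.array([ab[c.id] * c.length for c in ts])
    expected = w / w.sum() * len(truth)
    observed = np.array([counts[c.id] for c in ts])
    sigma = np.sqrt(expected * (1 - expected / len(truth)))
    assert np.all(np.abs(observed - expected) <= 3 * sigma + 3)


# ---------------------------------------------------------------------------
# chimeras


def test_make_chimeras_zero_is_identity(small_sim):
    _, transcripts, ab, _ = small_sim
    out, manifest = make_chimeras(transcripts, ab, ChimeraSpec(0))
    assert [c.id for c in out] == [c.id for c in transcripts]
    assert manifest == []


def test_make_chimeras_record_arithmetic():
    cfg = SimConfig(seed=3, n_transcripts=60)
    ts, ab = simulate_transcriptome(cfg)
    out, manifest = make_chimeras(ts, ab, ChimeraSpec(10), seed=1)
    # 60 - 2*10 constituents removed + 10 fusions = 50
    assert len(out) == 50
    assert len(manifest) == 10
    ids = {c.id for c in out}
    for rec in manifest:
        assert rec["fusion_id"] in ids
        assert rec["part1"] not in ids and rec["part2"] not in ids


def test_make_chimeras_ratio_pairing_targets_ratio():
    cfg = SimConfig(seed=5, n_transcripts=40)
    ts, ab = simulate_transcriptome(cfg)
    out, manifest = make_chimeras(
        ts, ab, ChimeraSpec(5, abundance_ratio=1.0, pairing="ratio"), seed=2
    )
    random_out, random_manifest = make_chimeras(
        ts, ab, ChimeraSpec(5, pairing="random"), seed=2
    )
    med_ratio = np.median([m["realized_ratio"] for m in manifest])
    med_random = np.median([m["realized_ratio"] for m in random_manifest])
    assert med_ratio <= med_random  # targeting ratio 1 compresses ratios


def test_chimera_junction_and_lifting(small_sim):
    _, transcripts, ab, truth = small_sim
    fused, manifest = make_chimeras(transcripts, ab, ChimeraSpec(3), seed=6)
    lifted = lift_truth_to_chimeras(truth, manifest)
    assert len(lifted) == len(truth)
    by_id = {c.id: c for c in fused}
    seqs = {c.id: c.sequence for c in transcripts}
    for rec in manifest:
        fid = rec["fusion_id"]
        assert by_id[fid].sequence == seqs[rec["part1"]] + seqs[rec["part2"]]
    # lifted placements stay within bounds and are consistent
    part2 = {rec["part2"]: rec for rec in manifest}
    for orig, new in zip(truth, lifted):
        m1o = orig.candidate_placements[0].mate1
        m1n = new.candidate_placements[0].mate1
        if m1o.contig_id in part2:
            rec = part2[m1o.contig_id]
            assert m1n.contig_id == rec["fusion_id"]
            assert m1n.start == m1o.start + rec["junction"]
        assert m1n.end <= by_id[m1n.contig_id].length


# ---------------------------------------------------------------------------
# corruption


def test_corrupt_insertion_and_manifest(small_sim):
    _, transcripts, _, _ = small_sim
    corrupted, manifest = corrupt_assembly(
        transcripts, [dict(type="insertion", n=3, length=50)], seed=1
    )
    assert len(corrupted) == len(transcripts)
    by_id = {c.id: c for c in corrupted}
    orig = {c.id: c for c in transcripts}
    for rec in manifest:
        assert rec["type"] == "insertion"
        c = by_id[rec["contig_id"]]
        o = orig[rec["contig_id"]]
        assert c.length == o.length + 50
        p = rec["position"]
        assert c.sequence[:p] == o.sequence[:p]
        assert c.sequence[p + 50 :] == o.sequence[p:]


def test_corrupt_truncation_projection_drops_tail_reads(small_sim):
    _, transcripts, _, truth = small_sim
    corrupted, manifest = corrupt_assembly(
        transcripts, [dict(type="truncation", n=3, fraction=0.4)], seed=2
    )
    proj = project_truth_to_corrupted(truth, manifest)
    new_len = {m["contig_id"]: m["new_length"] for m in manifest}
    for orig, new in zip(truth, proj):
        mo = orig.candidate_placements[0].mate2
        if mo.contig_id in new_len and mo.end > new_len[mo.contig_id]:
            if new.candidate_placements:
                assert not new.candidate_placements[0].mate2.is_aligned
    # some pairs became half-mapped
    half = sum(
        1
        for p in proj
        if p.candidate_placements
        and not p.candidate_placements[0].both_aligned
    )
    assert half > 0


def test_corrupt_long_insertion_leaves_uncovered_gap(small_sim):
    _, transcripts, _, truth = small_sim
    corrupted, manifest = corrupt_assembly(
        transcripts, [dict(type="insertion", n=2, length=250)], seed=3
    )
    proj = project_truth_to_corrupted(truth, manifest)
    for p in proj:
        if p.candidate_placements:
            p.assigned_contig = p.candidate_placements[0].contig_id
    ev = build_evidence(corrupted, proj)
    for rec in manifest:
        cid, pos = rec["contig_id"], rec["position"]
        gap = ev[cid].depth[pos : pos + 250]
        assert np.all(gap == 0)


def test_corrupt_duplication_creates_multimapping(small_sim):
    _, transcripts, _, truth = small_sim
    corrupted, manifest = corrupt_assembly(
        transcripts, [dict(type="duplication", n=2, fraction=0.6)], seed=4
    )
    assert len(corrupted) == len(transcripts) + 2
    proj = project_truth_to_corrupted(truth, manifest)
    dup_ids = {m["contig_id"] for m in manifest}
    multi = [
        p for p in proj
        if {pl.contig_id for pl in p.candidate_placements} & dup_ids
    ]
    assert multi, "reads inside the copied window should multi-map"
    for p in multi:
        assert len(p.candidate_placements) == 2


def test_corrupt_unknown_type_error(small_sim):
    _, transcripts, _, _ = small_sim
    with pytest.raises(ValueError, match="unknown"):
        corrupt_assembly(transcripts, [dict(type="inversion")], seed=0)
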