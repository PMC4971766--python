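"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest

from transqc.simulate import SimConfig, simulate_reads, simulate_transcriptome


@pytest.fixture(scope="session")
def small_sim():
    """A small error-free experiment: 12 transcripts, 4000 pairs."""
    cfg = SimConfig(seed=7, n_transcripts=12, n_pairs=4000, error_rate=0.0)
    transcripts, abundances = simulate_transcriptome(cfg)
    reads1, reads2, truth = simulate_reads(transcripts, abundances, cfg)
    return cfg, transcripts, abundances, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Same scale with 1% substitution errors."""
    cfg = SimConfig(seed=8, n_transcripts=12, n_pairs=4000, error_rate=0.01)
    transcripts, abundances = simulate_transcriptome(cfg)
    reads1, reads2, truth = simulate_reads(transcripts, abundances, cfg)
    return cfg, transcripts, abundances, truth
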