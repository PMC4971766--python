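"""Bayesian coverage segmentation: the chimera component s_seg.

A contig assembled from a single transcript should show one coverage
regime along its length; a chimera fusing transcripts expressed at
different levels shows a step.  The per-base depth profile is encoded as
a sequence of symbols over an unordered alphabet (rounded log2 of depth)
and scored with a Bayesian change-point model: each segment's symbol
counts are modeled by a Dirichlet-multinomial marginal likelihood, the
evidence for k segments averages over all contiguous k-part partitions
(uniform prior over change-point placements), and s_seg is the posterior
probability of k = 1 under a uniform prior over k in 1..k_max.

Dynamic programming makes the k-segment evidence exact in
O(k_max * L^2) for a profile of L symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

#: Default bin width in nucleotides.  Read-length-scale bins decorrelate
#: adjacent symbols (per-base depth is smoothed over a mate span, so
#: finer bins turn sampling noise into spurious runs) while an abundance
#: step between fused transcripts still spans many symbols.
DEFAULT_BIN_WIDTH = 100
DEFAULT_K_MAX = 2
DEFAULT_ALPHA = 1.0


@dataclass(frozen=True)
class SymbolProfile:
    contig_id: str
    symbols: np.ndarray
    bin_width: int
    alphabet_size: int


@dataclass(frozen=True)
class SegmentationResult:
    contig_id: str
    p_single: float
    per_k_log_evidence: np.ndarray
    k_max: int
    alpha: float


def encode_profile(
    depth: np.ndarray,
    bin_width: int = DEFAULT_BIN_WIDTH,
    contig_id: str = "",
) -> SymbolProfile:
    """Encode a per-base depth vector as log2 symbols over windows.

    Depth is averaged over consecutive windows of ``bin_width`` bases
    (the last window may be short); each window's symbol is
    round(log2(mean_depth + 1)), so zero depth maps to symbol 0.  The
    alphabet size is max symbol + 1, padded to at least 2 so that
    segmentation is meaningful.
    """
    depth = np.asarray(depth, dtype=np.float64)
    if depth.size < 1:
        raise ValueError("depth must have length >= 1")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n = depth.size
    edges = np.arange(0, n, bin_width)
    sums = np.add.reduceat(depth, edges)
    widths = np.minimum(edges + bin_width, n) - edges
    means = sums / widths
    # round half up for determinism across platforms
    symbols = np.floor(np.log2(means + 1.0) + 0.5).astype(np.int64)
    alphabet = max(int(symbols.max()) + 1, 2)
    return SymbolProfile(contig_id, symbols, bin_width, alphabet)


def trim_edges(depth: np.ndarray, trim: int) -> np.ndarray:
    """Drop terminal depth that is depressed by fragment-placement geometry.

    Within roughly one fragment length of each contig terminus the read
    depth necessarily ramps down (a fragment must fit inside the
    contig), which a change-point model would otherwise read as evidence
    of a second coverage regime.  At most one third of the profile is
    trimmed from each end so short contigs keep a usable interior.
    """
    depth = np.asarray(depth)
    t = int(min(trim, depth.size // 3))
    if t <= 0:
        return depth
    return depth[t : depth.size - t]


def segment_log_ml(counts: np.ndarray, alpha: float) -> float:
    """Log Dirichlet-multinomial marginal likelihood of one segment.

    For symbol counts c over an alphabet of size A with symmetric
    concentration alpha:

        log Gamma(A a) - log Gamma(m + A a)
        + sum_a [log Gamma(c_a + a) - log Gamma(a)]
    """
    counts = np.asarray(counts, dtype=np.float64)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    m = counts.sum()
    if m < 1:
        raise ValueError("counts must total at least 1")
    a = counts.size
    return float(
        gammaln(a * alpha)
        - gammaln(m + a * alpha)
        + np.sum(gammaln(counts + alpha) - gammaln(alpha))
    )


def _segment_lml_matrix(symbols: np.ndarray, alphabet_size: int, alpha: float) -> np.ndarray:
    """lml[i, j] = segment marginal of symbols[i:j] for i < j."""
    L = symbols.size
    A = alphabet_size
    onehot = np.zeros((L + 1, A))
    for i, s in enumerate(symbols):
        onehot[i + 1, s] = 1.0
    prefix = np.cumsum(onehot, axis=0)  # prefix[i] = counts of symbols[:i]
    lml = np.full((L + 1, L + 1), -np.inf)
    const = gammaln(A * alpha) - A * gammaln(alpha)
    for i in range(L):
        counts = prefix[i + 1 :] - prefix[i]  # segments starting at i
        m = counts.sum(axis=1)
        lml[i, i + 1 :] = (
            const - gammaln(m + A * alpha) + gammaln(counts + alpha).sum(axis=1)
        )
    return lml


def p_single_segment(
    profile: SymbolProfile,
    k_max: int = DEFAULT_K_MAX,
    alpha: float = DEFAULT_ALPHA,
    alphabet_size: int | None = None,
) -> SegmentationResult:
    """Posterior probability that one segment explains the profile.

    For each k, the evidence averages the product of segment marginals
    over all ordered partitions into k non-empty contiguous segments
    (the 1/C(L-1, k-1) prior over change points); p_single is the
    normalized mass on k = 1 under a uniform prior over k.  Values of k
    exceeding the profile length contribute zero probability.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    A = alphabet_size if alphabet_size is not None else profile.alphabet_size
    symbols = profile.symbols
    if symbols.max(initial=0) >= A:
        raise ValueError("alphabet_size too small for the profile's symbols")
    L = symbols.size
    lml = _segment_lml_matrix(symbols, A, alpha)

    # f[k][j] = logsumexp over partitions of symbols[:j] into k segments
    f = lml[0, :].copy()  # k = 1
    log_evidence = np.full(k_max, -np.inf)
    log_evidence[0] = f[L]
    for k in range(2, k_max + 1):
        g = np.full(L + 1, -np.inf)
        for j in range(k, L + 1):
            g[j] = logsumexp(f[k - 1 : j] + lml[k - 1 : j, j])
        f = g
        if L >= k:
            n_partitions = (
                gammaln(L) - gammaln(k) - gammaln(L - k + 1)
            )  # log C(L-1, k-1)
            log_evidence[k - 1] = f[L] - n_partitions
    p = np.exp(log_evidence - logsumexp(log_evidence))
    return SegmentationResult(
        contig_id=profile.contig_id,
        p_single=float(p[0]),
        per_k_log_evidence=log_evidence,
        k_max=k_max,
        alpha=alpha,
    )
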