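# Methods

`transqc` scores a de novo transcriptome assembly from the reads it was
built from. This note records the model behind each stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the bundled simulator does and does not
emulate.

## Pipeline

1. Parse the assembly (FASTA) and paired-end alignments (SAM/BAM with
   NM tags, or the simulator's ground-truth TSV).
2. Infer the library model (orientation, fragment-size mean/sd) from a
   subsample of concordant pairs.
3. Estimate contig abundances by EM over multi-mapping pairs, then draw
   one all-or-nothing contig assignment per pair.
4. Accumulate per-base depth and support evidence per contig.
5. Compute the four components, combine them into contig scores,
   compute raw/weighted assembly scores, and learn the optimal
   score cutoff.

## Alignment contract

Alignments are expected from a mapper that reports up to
`max_placements = 10` placements per pair within
`placement_edit_window = 5` edits of the best, with per-mate edit
distances capped at `ê = max_edit_distance = 30`. These caps are
re-applied on read, so over-reporting mappers are truncated to the same
contract. A pair-level placement is ranked by the sum of its mates' NM
values; the mapper's own pair-ranking convention is unknowable from the
BAM, and the summed-NM convention is the natural additive extension.
Coordinates are 0-based half-open internally; SAM's 1-based inclusive
convention is converted on input. Mate coverage uses the aligned span
including mismatch positions; clipped bases do not contribute. `N`
bases in contigs are not special-cased — mismatch accounting is
delegated entirely to NM.

## Library model

A seeded uniform subsample of pairs with both mates on one contig —
`max(0.01·N, 1000)` pairs, capped at N — determines the modal relative
orientation (`forward-reverse` inward, `reverse-forward` outward, or
`same-strand`; ties break lexicographically with a warning) and the
fragment-size mean and standard deviation, where a pair's fragment size
is the outer distance (rightmost mate end minus leftmost mate start).
Proper pairs must fall within `mean ± k_sd·sd` with `k_sd = 3`
(≈ 99.7% of a normal fragment distribution kept).

## EM assignment

Responsibilities use abundance and effective length only:
`r(pair→c) ∝ θ_c / ℓ̃_c` summed over the pair's candidate placements on
`c`, with effective length `ℓ̃_c = max(length_c − fragment_mean + 1, 1)`.
θ is initialized uniform; the M-step sets `θ_c ∝ Σ responsibilities`;
iteration stops when `max|Δθ| < 10⁻⁶` or after 1000 iterations. TPM is
`10⁶ · (est_c/ℓ̃_c) / Σ_d (est_d/ℓ̃_d)`. Alignment edit distances are
deliberately not part of the responsibility model — assignment samples
from relative abundances, and folding error terms in would be an
undocumented extension.

For evaluation, each mapped pair is assigned entirely to a single
contig, sampled once from its final responsibilities with a seeded
generator (uniquely mapping pairs deterministically; a degenerate
all-zero responsibility set falls back to a uniform draw, since every
mapped pair must land somewhere for evidence building). With a fixed
seed the full assignment is reproducible bit for bit.

A consequence worth knowing: a contig that duplicates a *substring* of
another is shorter and therefore has a smaller effective length, so the
EM fixed point legitimately keeps abundance mass on the duplicate
(reads inside the window have a higher per-base rate there). Redundant
contigs are thus *not* starved of reads; they are penalized instead
through the bridging/order signals of the contigs around them.

## Score components

- `s_nuc = Σ_k support_sum[k] / Σ_k depth[k]` — the mean of `1 − e/ê`
  over all (read, nucleotide) incidences. This coverage-weighted global
  mean (rather than a mean of per-base means) weights every aligned
  read base equally.
- `s_cov = |{k : depth[k] ≥ 1}| / n`.
- `s_ord`: every assigned pair is classified as `good`,
  `different-contigs`, `bad-orientation`, `bad-distance`,
  `half-mapped-at-edge`, or `unmapped` — the first failing criterion in
  that order wins. A pair with exactly one mapped mate is
  `half-mapped-at-edge` when the mate lies within one fragment window
  (`mean + k_sd·sd`) of a contig terminus, implementing the
  "contig could have been extended" penalty; a lone mate far from both
  termini is treated as unmapped evidence (read error, not assembly
  error) but still counts against the contig. `s_ord` is the fraction
  of the contig's pairs classified good; a `different-contigs` pair
  counts in the denominator of both contigs it touches, so the
  fragmentation penalty is visible to both fragments.
- `s_seg`: below.
- Contigs with no assigned reads get all components 0.

## Coverage segmentation (`s_seg`)

The chimera component asks whether one coverage regime explains the
contig. Per-base depth is encoded as symbols `round(log2(mean_depth + 1))`
over windows of `bin_width` nucleotides (the `+1` makes zero depth
well-defined as symbol 0; rounding is half-up for determinism). Each
segment's symbol counts get a Dirichlet-multinomial marginal likelihood
with symmetric concentration `α = 1`:

```
log ML(c) = log Γ(Aα) − log Γ(m + Aα) + Σ_a [log Γ(c_a + α) − log Γ(α)]
```

The evidence for `k` segments averages the product of segment marginals
over all contiguous `k`-part partitions (uniform prior over change-point
placements, the `1/C(L−1, k−1)` factor), computed exactly by dynamic
programming in `O(k_max · L²)`; `s_seg` is the posterior mass on `k = 1`
under a uniform prior over `k ∈ {1..k_max}`. `k_max = 2` by default
(single transcript vs. one fusion junction); the DP supports any
`k_max`. The alphabet size is shared across the whole assembly
(max observed symbol + 1, at least 2) so posteriors are comparable
between contigs.

Two preprocessing choices matter and were validated on simulations:

- **Edge trimming.** Within roughly one fragment length of each contig
  terminus, depth is geometrically depressed — a fragment must fit
  inside the contig, so only one mate's starts can fall there. A
  change-point model reads that ramp as a spurious segment on *every*
  contig. The profile is therefore trimmed by `fragment_mean`
  nucleotides per end before encoding, capped at one third of the
  contig so short contigs keep a usable interior. Fusion junctions sit
  in the contig interior and survive trimming.
- **Bin width.** Per-base depth is smoothed over a mate span, so
  per-base symbols carry strongly autocorrelated noise that produces
  spurious runs; very coarse bins leave too few symbols for the
  exchangeable Dirichlet-multinomial to resolve a step (its evidence
  comes from within-segment purity, not spatial coherence, and is
  exponential in segment length). `bin_width = 100` nt (one read
  length) decorrelates adjacent symbols while a junction between two
  transcripts still spans many symbols. With these defaults the
  simulated fusion experiment reproduces the expected detectability
  limit: fusions whose constituents differ at least two-fold in
  abundance separate from clean contigs, fusions below two-fold do not.

## Contig and assembly scores, cutoff learning

`s(C)` is the product of the four components, each floored at
`floor = 0.01` so one failed component cannot annihilate the assembly
geometric mean; `T = exp(mean log s(C)) · R_valid`, computed in log
space, where `R_valid` is the fraction of *all* input pairs with both
mates aligned. The abundance-weighted variant uses
`s_w(C) = s(C)^(1 + log(TPM+1)/log(n_contigs))`; the log base
`n_contigs` is the only reading of the weighting under which abundant
erroneous contigs are penalized more heavily for scores in (0, 1), and
it makes the exponent scale-free in assembly size.

The score cutoff is learned by evaluating every candidate in
{0} ∪ {distinct contig scores}: the objective — assembly score of the
retained subset with `R_valid` recomputed from pairs assigned to
retained contigs (both mates mapped) — is piecewise constant in the
cutoff, so the exhaustive sweep *is* the global optimizer. Pairs are
not re-assigned during the sweep; re-running EM inside the optimizer
would change the objective mid-search. Ties prefer the smaller cutoff
(retain more contigs), and the cutoff-0 objective equals the raw score,
so the optimized score never falls below it.

## Reference-based accuracy

When reference transcripts are available, contigs are paired to
references by reciprocal best local alignment (Smith-Waterman, match
+1, mismatch −2, gap open −5, gap extend −2, minimum score 40 standing
in for a database-size-dependent e-value cutoff; candidate pairs are
prefiltered by shared 15-mers so all-vs-all stays tractable at the
scale this package targets). External outfmt-6 tables are accepted as
an alternative backend. Per contig: `precision = identities /
contig_len`, `recall = identities / reference_len`, `F = 2PR/(P+R)`,
with identities counted in the single best local alignment (not summed
over multiple HSPs). Score validity is summarized as the Spearman rank
correlation between `s(C)` and F, optionally excluding contigs stuck at
the floored minimum score.

## Simulator

The generator emulates a size-selected Illumina paired-end bulk RNA-seq
experiment: random transcripts with log-normal lengths (defaults
`log_mean = 7.2`, `log_sd = 0.4`, i.e. ~1.3 kb median, floored at the
shortest library-compatible fragment), exponential abundances
normalized to 1, transcripts chosen per fragment with probability
proportional to abundance × length (molecule mass under uniform
fragmentation), fragment lengths Normal(400, 50) truncated to
[2·read_length, transcript length], uniform fragment starts, inward
100-bp mates, and i.i.d. substitutions at `error_rate` (default 1%).
Ground-truth alignments record exact placements, with the per-mate edit
distance equal to the number of injected substitutions, and feed the
pipeline directly through the interchange TSV.

Chimeras are head-to-tail concatenations of transcript pairs drawn
without replacement, replacing both constituents; partners are paired
uniformly at random (with the realized abundance ratio recorded) or
greedily matched to a target ratio. Assembly corruptions — insertions,
truncations, fusions, substring duplications — come with manifests and
a truth-projection that models how an aligner would see the corrupted
contig: downstream mates shift across insertions; mates spanning an
insertion no longer than `ê` are kept with the edit distance raised by
the insertion length (worst-case support), while longer insertions
break the alignment and leave the inserted bases uncovered; mates
beyond or crossing a truncation are dropped, making their pairs
half-mapped; reads inside a duplicated window gain a second candidate
placement.

What the simulator does *not* emulate: indels and quality-dependent
error profiles, GC/positional coverage bias, isoforms and shared exons
(transcripts are independent random sequences, so multi-mapping arises
only from simulated duplications), strand-specific protocols, and
adapter/quality artifacts. Passing tests therefore demonstrate the
scoring machinery's behavior under controlled error modes, not
robustness to every artifact of real libraries; on real data the
homology-driven multi-mapping load is far higher and the EM matters
correspondingly more.

## Validation experiments and problem sizes

The test suite runs the full pipeline on simulations sized for seconds
per case: the ideal-assembly identity (50 transcripts, 20k error-free
pairs), the chimera detectability experiment (200 transcripts, 40
random fusions, 100k pairs), the segmentation DP against exhaustive
enumeration (500 random short profiles), the cutoff optimizer against
an independent sweep (200 random instances), component monotonicity
under targeted corruptions (20 replicates of 24 transcripts / 10k
pairs), score-accuracy correlation on a heavily corrupted 120-contig
assembly (Spearman ρ ≈ 0.6–0.7 against RBH F-scores), library-model
recovery (±3 nt), and EM conservation/symmetry.

Monotonicity legs are mapped to the corruption that structurally
targets each component: short insertions (≤ ê) depress `s_nuc`; long
insertions leave uncovered bases and depress `s_cov` (contig
*truncation*, by contrast, does not reduce the covered fraction of what
remains — its real signals are half-mapped pairs in `s_ord` and lost
reads in `R_valid`, and it is checked there); strand scrambling
depresses `s_ord`; fusions depress `s_seg`, checked for fusions whose
constituents both carry read support and differ at least two-fold in
abundance, the component's documented applicability domain.

## Known limitations

- **The ideal assembly does not reach T = 1 exactly.** `s_seg` is a
  posterior probability with strictly positive mass on k ≥ 2 for every
  finite profile, and uniform random fragmentation leaves occasional
  terminal bases uncovered, so even a perfect assembly of error-free
  reads scores T ≈ 0.74 at the default experiment size rather than
  1.0. The score is therefore a *relative* instrument — consistent
  with the published score ranges of real assemblies, which top out
  far below 1 — and comparisons should be made between assemblies
  scored under the same configuration.
- Fusions of similar-abundance transcripts (< 2-fold) are invisible to
  `s_seg` by construction, as are fusions of barely expressed
  transcripts.
- The segmentation DP is exact but `O(k_max·L²)` in the number of
  symbols; profiles are binned, not subsampled, so extremely long
  contigs (≫ 100 kb) would need a larger `bin_width`.
- `R_valid` during cutoff learning attributes each pair to its sampled
  contig; a filtered assembly would in reality re-capture some reads on
  retained paralogs, so optimized scores are slightly conservative.
- Per-mate evidence ignores indel structure beyond NM and soft-clips.
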