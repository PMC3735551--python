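# Methods

This note documents the statistical model behind `pwmrefine`, the default
parameters and why they hold their values, what the synthetic generator
does and does not emulate, and the numerical conventions a user relying on
exact reproducibility should know.

## Scope and data model

The package operates on two kinds of sequence sets:

* **Promoters** — equal-length, gap-free, TSS-aligned DNA sequences.
  The default convention emulates proximal-promoter collections: 600-nt
  sequences spanning −499..+100 around the TSS (`tss_offset = 499`).
  Records containing unknown nucleotides (`N`) are excluded at load time
  and the exclusion count is logged.
* **Sites** — an aligned, equal-length, gap-free set of binding-site
  sequences (at least two for matrix building). Alignment is an input
  contract: the package performs no multiple sequence alignment.

All coordinates are 0-based and half-open; TSS-relative positions are
`index − tss_offset`. Bases are ordered (A, T, G, C) and dinucleotides
(AA, AT, AG, AC, TA, …, CC) throughout; file dialects with other layouts
(e.g. JASPAR's A,C,G,T rows) are re-mapped on read. Only the forward
strand is scanned — promoter sets aligned on the TSS carry their functional
sites in a defined orientation, and a reverse-strand scan would double the
multiple-testing burden without a corresponding truth set; users who need
both strands can scan the reverse complement explicitly.

## Matrix construction

For base (or dinucleotide) `b` at motif column `i`:

    p_bi = (n_bi + s_i) / (n_m + A·s_i)
    w_bi = ln( p_bi / e_b ) − c_i

* `n_bi` — observed count among the `n_m` training sites.
* `A` — alphabet size: 4 (mononucleotide) or 16 (dinucleotide).
* `s_i` — pseudocount: 1 in columns containing at least one zero count,
  else 0. This keeps the logarithm finite and assigns rare letters a
  finite, strongly negative weight, while leaving fully observed columns
  untouched. It is a per-column Laplace rule; no dependence on `n_m` is
  assumed.
* `e_b` — background fraction of `b`, pooled over a promoter region
  (default: the whole promoter span) and over all promoters;
  position-independent by design. Dinucleotide backgrounds are pooled
  *empirical* dinucleotide fractions, not products of base fractions, so
  the dinucleotide model can absorb neighbor dependence present in the
  background itself. Zero background fractions (degenerate inputs) are
  floored at `1/(total+A)` and renormalized, with a warning.
* `c_i` — the per-column maximum of the raw log-odds, subtracted so that
  every column's best letter weighs exactly 0. Consequently all matching
  scores are ≤ 0, the consensus scores 0, and cut-offs live on a
  non-positive scale.

A sequence window scores the plain sum of its per-column weights (the
dinucleotide model scores the overlapping-pair sequence, one column
shorter). A scoring model is the suite ⟨W, c⟩; the hit rule is `S ≥ c`
(closed, so the consensus qualifies at `c = 0`).

Information content per column is `IC_i = 2 + Σ_b f_bi log2 f_bi` bits with
`0·log 0 = 0`, clipped to [0, 2]; no small-sample correction is applied
(the export feeds logo rendering, where the uncorrected form is the common
default). The per-base letter heights are `f_bi · IC_i`.

## Signal detection

For a suite ⟨W, c⟩ the positional hit count `O(p)` is the number of
promoters with a hit starting at `p` (capped at one per promoter and
position). The z-profile standardizes `O` against its own positional
distribution: `z = (O − E)/σ` with `E` the mean and `σ` the *population*
standard deviation over start positions (at ~590 positions the sample/
population distinction is negligible; the population form matches the
estimator as stated). A constant profile (σ = 0) yields z ≡ 0.

Because the right cut-off is unknown a priori, the z-profile is computed on
a descending grid of cut-offs (default: 0 down to the matrix's minimum
achievable score in steps of 0.5) — a cut-off × position matrix that is the
numeric form of the signal-detection heat map. Functional windows are
derived from it as follows:

1. **Anchor.** The start position with the largest *sustained* signal:
   the above-threshold excess `max(z − 3, 0)` summed over grid rows,
   counting only positions that qualify at two or more cut-offs. The
   persistence requirement is essential: at very stringent cut-offs the
   positional counts are tiny and two or three chance hits produce one-row
   z spikes of 8–10 that say nothing about over-representation, whereas a
   genuine signal stays above threshold across a contiguous band of
   cut-offs. (On single-row grids, where persistence cannot be demanded,
   the plain excess is used.)
2. **Collection and fusion.** Qualifying positions (z ≥ 3) are collected
   at the anchor's strongest row; runs of positions closer than the motif
   length L are fused into one window spanning from the first peak to the
   last peak + L. A single peak yields a window of span exactly L.
3. **Cut-off band.** Each window records the contiguous band of grid rows,
   around its peak row, over which it stays above threshold. The
   permissive end of this band becomes the initial matching cut-off c₀ for
   refinement. A permissive c₀ is what makes the first cycle collect
   degenerate site variants rather than only exact consensus copies — with
   c₀ = 0 the rebuilt matrix reproduces the handful of consensus hits
   exactly, Cor = 1 trivially, and the loop terminates having learned
   nothing.
4. **Ranking.** Windows are ranked by their summed sustained mass. When
   several windows are detected, only those within 80% of the strongest
   (`window_strength = 0.8`, configurable) are considered comparably
   strong; each is refined independently and the one with the maximal
   optimized Cor is returned (sustained mass breaks ties).

## The refinement loop

Starting from ⟨W⁰, c₀⟩ and a functional window, each cycle:

1. collects the hits of the current suite inside the window;
2. unions the hit sites with the initial training sites (while the motif
   length still matches them) and rebuilds the matrix;
3. grid-searches the cut-off `c ∈ [c₁, c₂]` (defaults: minimum achievable
   score to 0, step 0.5) maximizing the Matthews correlation `Cor` between
   the new suite's hits and the current hits, with the current hits taken
   as true: TP = |new ∩ old| by exact (promoter, start) identity,
   FP = |new| − TP, FN = |old| − TP, and TN the complement to
   `N_total = n_promoters · max(1, span − L + 1)`;
4. builds the four one-nucleotide length variants from the current hit
   sites — clipped left (`cl`) or right (`cr`, length L−1, not below
   `min_length = 5`), extended left (`el`) or right (`er`, length L+1,
   hits at promoter boundaries dropped) — rebuilds a matrix from each and
   grid-searches it the same way. Variant hit starts are mapped back to
   the unmodified coordinate frame (cl: −1, el: +1) before intersecting,
   so a site and its one-nucleotide re-definition count as the same hit;
5. accepts the best candidate by (Cor, unmodified length, shorter length,
   more stringent cut-off) in lexicographic order and repeats, stopping at
   Cor = 1, at the first non-improving cycle, or at `max_cycles = 20`
   (convergence is typically reached in well under ten cycles).

When a length variant is accepted the working window shifts with the motif
footprint (cl: start+1; cr: end−1; el: start−1, clamped at 0; er: end+1,
clamped at the promoter end), keeping the number of admissible start
positions constant. With `rewindow = true` the window is instead
re-detected each cycle with the current matrix and the detected window
overlapping the working one is adopted; the default keeps the stage-2
window, treating the window as a parameter fixed by signal detection.

Two conventions in the cycle-level Cor deserve note. Exact agreement
(TP > 0, FP = FN = 0) counts as Cor = 1 even when the window is saturated
and TN = 0 — the classification is perfect and the stopping rule demands a
defined value there. Conversely `evaluation.mcc`, the user-facing metric,
stays strictly undefined (reported "n/a") whenever a marginal is zero.
Within the optimizer an undefined Cor simply disqualifies that cut-off.

Accepted-trajectory Cor is non-decreasing by construction, the final
cut-off is always on the grid, and every reported site re-scores at or
above it under the final matrix; the test suite asserts all three on every
run it makes. Given identical inputs and configuration the procedure is
fully deterministic.

## Synthetic data

The generator produces three fixture families, all reproducible from a
single integer seed (per-replicate streams are spawned deterministically):

* **Background promoters** — i.i.d. sequences from a base-fraction model
  (default uniform; skewed fractions available). They emulate the scale
  and TSS alignment of curated proximal-promoter sets, not their sequence
  structure: no CpG islands, no Inr/TATA elements, no positional
  composition gradients. Passing tests on them demonstrates correct
  algorithmic behavior under a known truth, not performance on genomic
  promoters.
* **Planted-motif fixtures** — sites sampled column-wise from a given
  frequency matrix overwrite a chosen fraction of promoters at uniform
  offsets within a window; a truth table records every insertion. The
  standard recovery benchmark (`planted_benchmark`) plants an 8-nt,
  70%-consensus motif in 10% of 2000 promoters at offsets 500–510 (just
  downstream of the TSS) and samples 10 initial training sites from the
  same matrix — small enough to be realistically noisy, large enough to
  seed detection.
* **Embedded-site tests** — possibly flanked site sequences whose local
  alignment block is placed at a fixed position (default 27) in every
  test sequence, padded to a common length (default 300 nt) with equally
  distributed random nucleotides. Replicates (default 10) permute only the
  padding (30 successive permutations), preserving each site and its
  unaligned flanks verbatim, so padding composition is conserved exactly
  and the truth table is shared. Flank permutation is available as an
  option but off by default.

## Evaluation

On embedded-site tests a predicted hit is credited to a truth motif when
its start lies within `⌊L/2⌋+1` nt of the nearer motif edge — the looser
reading of "half the motif length ± 1", resolving the odd-L ambiguity
generously toward the compared method. Each truth motif yields at most one
true positive (the closest qualifying hit); all surplus hits are false
positives; FN = test size − TP; TN completes to
`N_total = test_size · (seq_len − L + 1)`. A second tolerance mode
(`tolerance=L`) accepts any hit within one motif length, for comparisons
against tools that report a systematically shifted anchor position.
Precision, recall and MCC follow the standard definitions and are reported
"n/a" when undefined; replicate evaluations report per-replicate values and
the mean over replicates where defined.

`frequency_recovery` compares a recovered 4 × L column-frequency matrix
with the generating one by the mean per-column Pearson correlation,
maximized over column offsets (refinement may legitimately return a motif
one or two columns longer, shorter, or shifted).

## Known limitations

* **Matrix dilution at permissive initial cut-offs.** Because the
  objective is self-consistency between successive hit sets, a first cycle
  that admits substantially more background than signal can drift: the
  matrix flattens, score ranges compress, and the discovered set grows far
  beyond the planted population while Cor keeps rising. On the standard
  benchmark this occurs at a minority of seeds (window localization still
  succeeds; recovered-frequency correlation drops to ≈ 0.7–0.8). Real
  promoter sets with stronger positional signal are less exposed, but
  users should inspect the discovered-site count and the information
  content of the final matrix.
* The z-score treats positional counts as approximately normal; at very
  stringent cut-offs (counts of 0–3 per position) this fails, which is
  precisely why window detection demands persistence across cut-offs.
* Background models above first order (dinucleotide) are not implemented;
  the background is position-independent by design.
* Scores are uncalibrated log-odds: no p-values, no FDR control across
  positions, no energy interpretation.
* Synthetic tests share one insertion position per test set; methods that
  exploit positional regularity would be flattered by them. Replicate
  reshuffling varies only the background, not the site composition.
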