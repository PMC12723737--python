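# Methods

## The regression model

`phopt` regresses an enzyme's optimal pH on its amino-acid sequence. The
input is a per-residue embedding matrix *r* ∈ ℝ^(dim×L). Two backends
produce it:

* **fixture** (default, used by all tests): a dictionary embedder in which
  each residue letter maps to a fixed vector drawn once from a seeded
  standard normal. Column *i* of the matrix depends only on `sequence[i]`
  and the seed, so embeddings are bit-reproducible and alphabet-closed. The
  five ambiguity codes (X, B, Z, U, O) share a single "unknown" vector.
* **plm_adapter**: the small ESM-2 protein language model
  (esm2_t6_8M_UR50D, dim = 320), final hidden layer, begin/end special
  tokens stripped so the output length is exactly L. The upstream
  publication of this architecture does not state which layer was used or
  whether specials were excluded; the adapter documents this choice without
  claiming fidelity on that point. It requires `torch` and `fair-esm` and
  raises a capability error when they are absent; nothing else in the
  package depends on them.

The network stages and the reasoning behind each numerical choice:

1. **Multi-scale CNN.** One 1-D convolution per window size (1, 2, 3, 4, 5),
   all length-preserving, outputs summed element-wise. Length preservation
   forces a padding convention: symmetric zero padding for odd windows; for
   even windows the extra zero goes on the **left**. Any fixed convention
   works — the network learns around it — but it must be fixed for the
   element-wise sum across scales to align.
2. **Linear featuremap.** Position-wise dim → 2·dim → dim. No activation
   between the two layers is stated in the source description; one LeakyReLU
   is inserted (matching the network's nonlinearity family). This choice is
   not externally verified.
3. **Multiplicative self-attention.** Per head: values *v* (dim×L), keys *k*
   (1×L) and queries *q* (1×L) from *pointwise* (window-1) convolutions —
   the minimal reading consistent with the stated output shapes. Attention
   logits are the element-wise product *q* ⊙ *k* with **no √dim scaling**
   (the defining equation shows none); softmax is over the L positions.
   Padded positions receive −∞ logits before the softmax, which makes
   padding provably inert (weight exactly 0).
4. **Residual dense blocks.** *x* ⊕ LeakyReLU(*Wx* + *b*) at constant width
   n_head·dim. Width-preserving blocks are the natural reading of "a dense
   layer with residual connection".
5. **Linear head**, no output nonlinearity. Training targets are pH/14, so
   raw outputs may stray slightly outside [0, 1]; predictions are clamped to
   [0, 14] only at reporting time (flag, default on).

LeakyReLU negative slope is 0.01 (the activation's common default; none is
stated upstream). Parameters are initialized from a seeded uniform fan-in
scheme (±1/√fan_in); the seed is part of `ModelConfig`, so every model is
reproducible.

### Why NumPy

The execution environment provides no deep-learning framework, so every
stage has a hand-derived backward pass and the optimizer is a NumPy Adam.
The gradients are verified against central finite differences over *every*
parameter of a small configuration (relative error < 10⁻⁴ at ε = 10⁻⁶), and
a separate test asserts every parameter group receives a nonzero gradient
(guarding against silently detached attention weights). At the scales the
package targets (dim ≤ 320, L ≤ a few hundred) the einsum-based batched
forward/backward is fast enough to train thousands of sequences per minute
on one CPU core.

## Training protocol

* targets scaled to pH/14; inverse applied at inference;
* 10% of the training set split off (seeded uniform random, unstratified)
  as the dev set;
* mini-batch Adam (batch 32, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on MSE;
* learning rate 5·10⁻⁴ halved every 10 epochs:
  lr(e) = 5·10⁻⁴ · 0.5^⌊e/10⌋, asserted exactly in tests;
* default 50 epochs. No stopping rule is stated upstream; the returned state
  is the snapshot with the best dev RMSE, which is the faithful reading of
  dev-tracking curves;
* batches are composed by bucketing sequences by length to limit padding
  waste. This is output-neutral: padding inertness is an asserted property
  (batched vs single predictions agree to 10⁻⁵), so batch composition cannot
  change results beyond float summation order.

A non-finite training loss aborts with an error naming the epoch and batch.

## Evaluation

RMSE, MAE and R² use their closed forms; R² is the **coefficient of
determination** 1 − SS_res/SS_tot (the alternative reading, squared Pearson
correlation, is not implemented; the choice is flagged here because the
source's formula sheet is not public). Zero-variance labels make R²
undefined — the function returns `None`, never a number.

Stratified slices are defined on experimental labels only: pH_opt < 6,
pH_opt > 8; EC classes 1–6 (EC 7 excluded by default because it is rare in
curated sets; a flag re-enables it); identity-score bins [0, 0.30),
[0.30, 0.60), [0.60, 1.0] — the verbal labels "<30%, 30–60%, >60%" leave the
boundaries ambiguous, so this half-open convention is fixed and asserted in
tests.

pH-preference classification calls a prediction below the cutoff (default
7.0) acidophilic, at or above it alkaliphilic; the boundary tie rule is
arbitrary but fixed. Distribution comparisons use the two-sided
Mann–Whitney U test (the upstream work reports p-values without naming a
test; rank tests avoid normality assumptions about predicted pH). Fully
tied inputs are flagged as degenerate rather than tested.

## Attention interpretation

w_avg (the per-position mean over heads) inherits the simplex property.
Because a uniform head puts 1/L on each residue, raw weights from sequences
of different lengths are not comparable; all cross-sequence statistics use
**length-normalized** weights L·w_avg, whose null expectation is 1 per
residue regardless of length. Min-max "normalized weights" exist only for
display profiles. The residue-class partition (acidic D/E; basic K/R/H;
polar uncharged S/T/N/Q/C/Y; nonpolar G/A/V/L/I/P/F/M/W) is a standard
chemistry grouping — glycine in nonpolar and histidine in basic are
conventions, not upstream facts. Enzyme strata reuse the evaluation ranges
(acidophilic < 6, alkaliphilic > 8, neutrophilic between).

Site enrichment pools length-normalized weights at annotated active/binding
positions against all other positions (two-sided Mann–Whitney U, effect size
= ratio of medians). Peaks in a profile are local maxima at or above a
configurable quantile (default 0.90) of the profile's weights.

## Mutational screen

`enumerate_mutants` takes the union of clipped windows
[center − radius, center + radius] (overlaps deduplicated — the reference
windows do not overlap, but the behavior must be defined), then emits all 19
non-wild-type substitutions per position in canonical order (position, then
mutant letter). The reference configuration — three centers, radius 10, on a
sequence of length ≥ 162 — yields 63 × 19 = 1197 mutants. Candidates with
predicted pH_opt below the threshold (default 7.0) are selected. An external
activity scorer (any callable sequence → score, or a mutation-name → score
table; stands in for a turnover-number predictor, which is not reimplemented
here) optionally re-ranks threshold-passers by ascending predicted pH and
descending activity, keeping `top_k` — an explicit operationalization of
"lowest predicted optimum with acceptable activity"; the upstream selection
of wet-lab candidates was partly manual. Scorer failures flag the row and
the screen continues.

## Synthetic data: what it does and does not establish

`generate_dataset` draws, per sequence, an acidic fraction f_a and a basic
fraction f_b (each Uniform(0.05, 0.35) — a realistic span for ionizable
content in globular proteins), samples residues i.i.d. under those
fractions, and labels the sequence

    pH_opt = 7 + effect_size · (frac_basic − frac_acidic) + N(0, noise_sd)

using the *realized* fractions, clipped to [2, 12]. Defaults
(effect_size = 4, noise_sd = 0.3, lengths 40–160) give labels ~7 ± 0.6 with
roughly 70% of variance explainable — a learnable but non-trivial task. All
randomness flows from one seed through named substreams, so datasets are
bit-reproducible. EC classes and identity scores are filled with seeded
draws purely so the stratified-evaluation plumbing can be exercised.

What a green test on this fixture establishes: that the architecture,
gradients, training loop, evaluation and screening machinery work end to
end, and that the model recovers a planted composition → pH signal
(held-out R² ≈ 0.7 at the default world). What it does **not** establish:
real-data accuracy (the fixture has no domain structure, no phylogeny, no
real embedding geometry), and — importantly — attention *localization*.
Because the planted label is a function of global composition, uniform
attention pooling is the optimum (the pooled feature under uniform weights
is exactly a linear image of the composition vector), so a well-trained
model's attention converges toward uniform (all length-normalized weights
≈ 1.00) and its residual deviations have seed-random sign. Claims that
attention concentrates on ionizable residues or annotated sites therefore
cannot be validated end-to-end on this fixture; they are validated at the
component level instead, on profiles with *planted* enrichment
(`generate_annotated_profiles`), where the rank tests recover spiked signal
(p < 0.01 at spike factor 10, n = 50) and lose it under within-sequence
label permutation.

## Known limitations

* The protein-language-model backend is an adapter only; without `torch` +
  `fair-esm` the package runs exclusively on fixture embeddings.
* No multi-property heads, transfer-learning export, oversampling or loss
  reweighting; no combinatorial (multi-point) mutagenesis; no structural
  mapping of attention weights.
* R² is undefined for zero-variance label sets and returned as `None`;
  downstream tables display it as NaN.
* Checkpoints are NumPy `.npz` archives with a format-version field; loading
  rejects unknown versions rather than guessing.
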