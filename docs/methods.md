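# Methods

## Model

A compound set is represented as a binary matrix of molecules × fingerprint
bits. Condensing the set into one fingerprint is a per-bit decision rule:

* **DFP (threshold rule).** Bit *j* is set iff `count_j / n ≥ t` with
  threshold `t = 0.5` by default. The comparison is `≥`, so an exact tie sets
  the bit ("at least half").
* **SB-DFP (statistical rule).** Bit *j* is set iff a pooled one-sided
  two-proportion Z-test rejects equality in favour of "target proportion
  larger" at level `α`:

  ```
  z = (p_t - p_r) / sqrt( P (1 - P) (1/n_t + 1/n_r) ),
  P = (n_t p_t + n_r p_r) / (n_t + n_r),   p-value = 1 - Φ(z) < α.
  ```

  The comparison with `α` is strict. The pooled-variance form is used
  (it is also what `statsmodels.proportions_ztest` computes by default; the
  test suite cross-checks against it). Rejection entails `p_t > p_r`, so a
  set's SB-DFP against its own profile is always all-zero.

Modelling assumptions worth stating plainly: bits are treated independently
(no multiple-testing correction across bits — `α` is an operating point
chosen by downstream performance, not a family-wise error rate), and the
normal approximation to the binomial is used on both sides. With reference
collections of 10⁵–10⁷ molecules the reference side is effectively exact;
the target side is adequate for the set sizes this tool targets (tens to
thousands of molecules), with the usual discreteness at very small `n_t`.

### Degenerate cases

When the pooled proportion is 0 or 1, both sample proportions are equal and
the variance term vanishes. We define `z = 0`, `p = 0.5` (the continuous
limit of the equal-proportion case); the bit is never set. Similarly,
`min_significant_count` returns an "unattainable" sentinel (`None`) when no
count in `[0, n_t]` reaches significance — e.g. against a saturated
reference bit. `min_significant_count` binary-searches the decision
boundary, which is valid because the p-value is non-increasing in the target
count (property-tested exhaustively on small grids); the result is verified
against the definitional boundary and falls back to a linear scan if the
check ever fails numerically.

## Similarity, distance, clustering

Similarity between binary fingerprints is the Tanimoto coefficient
`|a∧b| / |a∨b|`. The undefined 0/0 case is defined as **0**: an empty
fingerprint shares no features with anything, and this prevents an all-zero
condensed fingerprint from appearing maximally similar to every other. Users
matching toolkits with the other convention can pass `zero_zero=1`. One
consequence: two identical datasets whose DFPs are all-zero (every bit under
threshold) compare at 0, not 1, off the diagonal.

Inter-dataset matrices come in three methodologies: **ACC** (median Tanimoto
over all cross-set compound pairs; the diagonal is the intra-set median over
distinct pairs, which need not be 1 — self-comparisons are excluded so the
diagonal is a diversity statistic, not a fixed point), and **DFP** /
**SB-DFP** (one condensed fingerprint per set, one Tanimoto per pair; the
diagonal is exactly 1 by construction). Medians over an even number of pairs
are the midpoint of the central values. The off-diagonal value range
(`max − min`) is reported as a resolution measure.

Distance is `1 − similarity`. Clustering is agglomerative complete linkage
(SciPy backend) cut into exactly `k` flat clusters (default `k = 10`); when
two merges tie at the minimal distance SciPy's deterministic ordering
applies — merge *heights* are tie-invariant and are what the oracle tests
assert. Trees export to Newick with branch length = parent height − child
height. Agreement with a ground-truth partition (typically the clustering of
a sequence-identity-derived distance matrix, auto-converted from percent or
unit scale) is the permutation-model Adjusted Rand Index
(scikit-learn backend, cross-checked in tests against explicit
pair counting).

## Screening benchmark

Per replicate: draw `query_size = 10` actives without replacement; the
remaining actives (ADCs) are hidden in the decoy library; score the library
under 1-NN (max Tanimoto over the 10 queries), DFP and SB-DFP (both
condensed from the 10 queries alone; SB-DFP against the reference profile).
Metrics:

* **Recovery rate** — fraction of ADCs inside the top-`|ADC|` selection.
  Ranking sorts by descending score with ties broken by ascending compound
  identifier, making RR invariant to library order. The selection-size
  denominator is the per-replicate ADC count (actives minus queries); a
  `selection_size` override exists.
* **ROC AUC** — rank-based Mann–Whitney form with ties credited 0.5.
  Single-fingerprint searches produce heavily tied score distributions, and
  0.5 credit is the unbiased convention; on tie-free scores it equals
  trapezoidal integration of the ROC curve to 10 decimals (tested).

Replicate *r* draws from substream *r* of a single seeded generator
(`SeedSequence.spawn`), so results are bit-reproducible and any prefix of
replicates is independent of `n_reps`. Summaries report per-strategy
mean ± sd; "best strategy" calls use a two-sided Welch t-test across
replicate values at 0.05, counting statistically indistinguishable
strategies as tied. A sweep utility repeats the benchmark over a list of
significance levels, default {0.10, 0.05, 0.01, 0.005, 0.001}
(confidence 90–99.9%).

## Synthetic data

The generator draws each bit of each molecule independently from a per-bit
Bernoulli probability — the null model implied by summarising a collection
as per-bit frequencies.

* **Background frequencies**: drawn once (seeded) from Beta(1.6, 3.0), mean
  ≈ 0.35 with roughly a fifth of bits above 0.5. This mimics the skewed
  frequency spectrum of dictionary fingerprints over large collections,
  where a minority of generic bits dominate — the bias the SB-DFP is
  designed to remove.
* **Enriched bits**: a designated subset pinned to background frequency 0.2
  and elevated to 0.6 in "active" sets — a strong but not degenerate
  per-bit signal.
* **Defaults**: 166 bits, reference of 10⁶ observations, target sets of 350
  molecules — echoing realistic study scales.
* **Reference profiles** come in `exact` mode (`round(p·n_obs)`, the
  idealised infinitely-mixed reference used for calibration tests) and
  `sampled` mode (binomial counts).
* **Block-correlation stress mode**: within a declared block, each bit
  copies a shared latent Bernoulli draw with probability `block_weight`,
  preserving marginals (exactly for equal within-block probabilities) while
  inducing positive correlation. Off by default.

Calibration behaviour under this generator (asserted in the test suite): on
null targets of 200 molecules drawn from the exact reference frequencies,
the mean fraction of bits the SB-DFP sets at `α = 0.01` lies in
[0.004, 0.025] — close to nominal, with the spread reflecting per-bit
discreteness; and 20 planted 0.2→0.6 enrichments are all recovered in ≥ 99%
of replicates at `n_t = 200`.

## Limitations

* **Independent bits are not real fingerprints.** Real molecular
  fingerprints have strongly correlated bits, and actives for one target
  form structurally related series. The generator reproduces *marginal*
  frequency structure only. Consequences: (1) passing calibration/power
  tests here says the per-bit test behaves as designed under its own
  assumptions, not that `α` transfers untouched to correlated bits;
  (2) the 1-NN strategy, whose real-data strength is that a hidden active
  usually has a near-identical neighbour among the queries, loses that
  advantage under per-bit independence — in the synthetic benchmark the
  condensed DFP, which averages query noise, scores above 1-NN, whereas on
  real compound sets 1-NN typically outperforms DFP. The SB-DFP's dominance
  is robust in both regimes. The block-correlation mode softens but does not
  remove this gap.
* The normal approximation is optimistic for very small target sets
  (`n_t` below ~30 with rare bits); an exact test is deliberately not the
  shipped rule (the Z-test is the method's definition), but small-`n_t`
  users should read `min_significant_count` output with that in mind.
* MACCS bit numbering follows the installed toolkit (RDKit keys 1–166
  re-based to 0–165, placeholder key 0 dropped); bit-level agreement across
  different chemistry toolkits is not promised, only internal consistency.
* No molecule standardisation beyond toolkit sanitisation is applied before
  fingerprinting; unparseable inputs are dropped and reported, never
  silently.

## Problem sizes used in the shipped tests

Worked-example checks run on the published reference-bit counts directly.
Calibration uses 2000 null targets × 166 bits (binomial count sampling);
power uses 200 replicates of 200-molecule targets; the screening benchmark
fixture uses 200 actives, 5000 decoys and 25 replicates. These sizes give
stable Monte-Carlo estimates (binomial sampling error well inside the
asserted bands) while keeping the whole suite fast.
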