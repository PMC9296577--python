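# Methods

## Model and assumptions

`hkrank` treats reference-gene discovery as a rank-aggregation problem over
a compendium of independent expression studies. The working assumptions:

1. A usable reference gene is *quiet* (low coefficient of variation across
   all samples of a study) and *unresponsive* (group-mean fold change near 1
   between condition and control). Both criteria are computed on linear-scale
   values; deposited log2 matrices are exponentiated (base 2) first.
2. Absolute expression values are not comparable across platforms, but
   within-study *ranks* are. All cross-study aggregation therefore happens
   on the per-study rank scale (the ascending rank of the CV-rank × FC-rank
   product), which removes the need for cross-platform normalization or
   batch correction entirely.
3. Study selection is itself a noise source. Resampling whole studies with
   replacement (the bootstrap unit is the data set, not the sample) measures
   how much a gene's aggregate rank depends on which studies happened to be
   included. Genes whose rank distribution is tight across resamplings are
   robust candidates.
4. Genes are not measured by every platform. Rather than intersecting gene
   sets (which discards most of the genome once platforms are heterogeneous),
   each study keeps its own genes, the union forms the universe, and the
   final score carries a multiplicative absence penalty
   `mean_bootstrap_rank × D / presence_count`. Within a bootstrap
   repetition, a gene absent from every drawn study scores the universe size
   (the worst plausible mean rank), keeping every repetition's ranking a
   valid permutation with average ties.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `repetitions` | 10,000 | bootstrap resamplings; 1,000 is enough for stable top-50 lists and is used in the test suite for speed |
| `top_n` | 25 | candidates reported by `summary()`/sessions |
| `cutoff` | 0.15 | stability call threshold on ρ (dimensionless, log2 scale) |
| `seed` | — | drives every random draw; identical seeds reproduce results bit-for-bit |
| log-scale detection | 99th percentile ≤ 30 | a deposited matrix whose 99th-percentile value is ≤ 30 is taken as log2; the percentile (not the max) makes the call robust to single corrupt outliers |

Numerical conventions, chosen where the problem leaves them open and then
fixed: CV uses the sample (n−1) standard deviation; ranks use average ties
everywhere; residual ties in the final ordering break lexicographically by
gene id so runs are reproducible; probe-to-gene collapse keeps the probe
with the highest mean intensity (averaging would blend cross-hybridizing
probes of very different signal); gene rows with missing or nonpositive
linear values are dropped from that study and handled as "absent" — no
imputation, since the absence penalty already prices missingness.

## Stability score

The cross-validation score works on log2 group means z_ig (gene i, group
g): α_i is the gene's mean level over groups, θ_g the group's global mRNA
shift *centered on the grand mean*, and f_ig = z_ig − θ_g − α_i the
residual; ρ_i = |mean_g(f) + sd_g(f)| (sample sd over groups). The centering
of θ_g is deliberate: without it an all-constant data set would receive
nonzero ρ, contradicting the score's own reading ("smaller = more stable"),
while with it relative comparisons between genes are unchanged. ρ is
reported per gene; this is the lightweight screening rendition, not the
original NormFinder variance-decomposition estimator, which is kept as a
conceptual reference only.

The overlap significance test is a one-sided hypergeometric tail on the
intersection of two fixed-size lists drawn from a shared universe — the
standard choice for gene-list overlaps. It is exact, and is verified in the
tests against rational-arithmetic enumeration on universes ≤ 100.

## What the simulator emulates — and what it does not

`simulate_collection` generates D studies over a shared gene universe with
three planted roles: *stable* genes (high log2 baselines, drawn from the top
quarter of the baseline range, multiplicative noise at CV 0.10, fold change
exactly 1), *responsive* decoys (|FC| drawn from [2, 8], direction random,
applied to the condition group), and *background* genes (CV 0.50, FC 1).
Noise is log-normal: a target linear-scale CV c maps exactly to a log2-sd of
sqrt(ln(1+c²))/ln 2, so empirical moments converge to the configured values
(verified at n = 5,000 samples/group in the tests). Each study independently
drops 10% of genes (platform coverage differences; never all planted genes),
and half the studies are emitted log2-transformed to exercise scale
detection. Defaults — 4 studies × 2,000 genes, 50 planted stable, 200
responsive, 10 samples/group — are large enough to exercise ties, dropout
and the absence penalty, small enough for seconds-scale runs.

The simulator does **not** model probe-level artifacts, batch structure,
correlated genes, count noise, or real platform designs. Passing the
recovery tests therefore shows the pipeline correctly identifies genes that
are stable *under the generative model's assumptions*; it does not certify
performance on any particular real compendium, where unmodelled correlation
between genes and between studies can only loosen the separation.

## Validation design

* **Oracle equivalence.** For two studies and a small universe, the
  bootstrap expectation is enumerable exactly (all D^D ordered draws,
  equally likely); Monte-Carlo mean ranks at 10,000 repetitions are required
  to match within 3 standard errors.
* **Seed robustness.** Ten rankings of one simulated compendium differing
  only in bootstrap seed must agree with mean pairwise top-50 overlap
  (reproducibility R) ≥ 0.99 at 1,000 repetitions.
* **Independent confirmation.** Top-10 candidates are re-scored with the
  stability score on a *held-out* validation study generated from the same
  ground truth with fresh noise and no dropout (a validation assay measures
  every candidate); ≥ 80% must score ρ < 0.15.
* **Negative control.** Two compendia with disjoint planted gene sets must
  produce top-20 lists with overlap coefficient ≤ 0.05.

## qPCR normalization

The 2^−ΔΔCt calculator combines a multi-gene reference panel as the
arithmetic mean of the member Cts — the geometric mean of their linear
expression, the standard multi-reference practice. Amplification efficiency
is fixed at 2 per cycle (no efficiency correction). Group results are
summarized as mean ± SEM of per-sample fold changes. The panel algebra makes
the case for multi-gene normalization directly: a reference gene shifted by
+1 Ct in the condition group alone inflates an unchanged target's apparent
fold change 2-fold, but only 2^(1/k)-fold inside a k-gene panel.

## Known limitations

* The absence penalty's multiplicative form is a design choice (monotone and
  rank-scale preserving); other monotone penalties would reorder genes with
  very low presence counts.
* Per-study scoring uses raw group-mean fold changes, not a moderated
  differential-expression model; with very few samples per group the FC rank
  is noisy, which the bootstrap absorbs only partially.
* Log-scale detection is a heuristic; matrices of genuinely small linear
  values would be misread as log2. The `scale` field can be set explicitly
  when the provenance is known.
* The hypergeometric overlap test treats lists as unordered sets; it carries
  no credit for agreement in rank order.
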