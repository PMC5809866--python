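# Methods

## Model

### Rank-frequency and Pareto views

A sample's positive scaled counts are reduced to their unique values,
sorted descending and ranked 1..U (`pareto_tail`). Rank r counts the
unique values ≥ x_r, so rank 1 is the maximum and the logarithm of the
rank is defined everywhere; a strict ">" convention would give rank 0 at
the maximum. Ranks run over *unique values*, not transcripts: many tied
low counts occupy a single curve point. All fits regress log10 rank on
log10 amplitude; the slope m relates to the Pareto tail exponent by
s = −m and to the rank-frequency exponent by b = 1/s. Base 10 is used
throughout (segments are decades); slopes are base-invariant.

For the Type I Pareto distribution with exponent s and minimum x_min the
moments are μ = s·x_min/(s−1) for s > 1 (infinite otherwise) and
σ² = s·x_min²/((s−1)²(s−2)) for s > 2 (infinite for 0 < s ≤ 2). Divergent
moments are why shallow-sloped count segments reproduce poorly across
replicates: `expected_sigma` extrapolates a reference segment's residual
spread by the exponent ratio s_ref/s_i to quantify exactly that excess.

### Aliasing

Sequencing is modelled as sampling an analogue abundance signal. An
undersampled power-law signal carries an additive alias term,
Y(f) = S_o f^(−α) + S_o (f_s − f)^(−α). The observable is the distortion
of a replicate against the *surrogate original signal* — the replicate
with the largest total read count. The distortion ratio
ΔY(f) = 1 + (f/(f_s−f))^α is inverted for f_s at a single evaluation
rank (`solve_fs`); the verdict is undersampled ⇔ f_s < 2·f_max with
f_max the surrogate's maximum rank.

Two empirical conventions matter:

* **Evaluation rank.** When the replicate has fewer unique values than
  the surrogate, ΔY is evaluated at the replicate's own terminal rank —
  the largest rank where both curves exist — while the Nyquist
  comparison still uses the surrogate's f_max as the bandwidth.
* **Magnitude of the distortion.** For the analytic aliased
  construction the sampled curve sits *above* the original, and the
  signed log-ratio is the distortion. For finite-depth multinomial
  replicates the signed ratio at matched rank is provably ≤ 1 near the
  terminal rank (a sample's unique-value count never exceeds its
  maximum count, so its terminal amplitude 1/max_count is at most the
  surrogate's amplitude there): tie-compression pushes the tail *below*
  the surrogate by the same distortion factor. `fit_alias` therefore
  fits |log10 ΔY|, which coincides with the signed series on analytic
  constructions and captures the empirical distortion on sampled data.
  `observed_alias` itself returns the signed series.

A terminal distortion of exactly 1 (e.g. the surrogate against itself)
yields f_s = ∞ and a clean verdict rather than an error; `solve_fs`
still rejects ΔY < 1, which the alias model cannot represent. The
default estimator uses the single terminal-rank value, reproducible and
faithful to the solving procedure; `fs_mode="lsq"` minimizes the model
MSE over the whole shared rank grid instead. The verdict uses a 1e−9
relative tolerance so the exact Nyquist boundary counts as adequately
sampled. Multi-alias terms (k ≥ 2 folds) are out of scope: for a
band-limited signal only the k = 1 term survives.

### Segmented power-law correction

Per sample, the Pareto curve is partitioned into consecutive segments of
PPS points starting at the highest count (a terminal remainder of < 3
points merges into the previous segment). Each segment's OLS fit
(m, log10 k) maps its counts onto the reference power law,

    log10 x' = (log10 k − log10 k_ref)/m_ref + (m/m_ref)·log10 x,

an exact algebraic identity: the segment's fitted rank of x equals the
reference law evaluated at x'. The reference intercept k_ref is always
the sample's own first segment (anchoring its amplitude); the reference
slope m_ref is, by default, the *series* median first-segment slope at
the selected PPS, which guarantees a common exponent across samples
(`ref_slope="per-sample"` restores the strictly per-sample reading).
Correction operates on unique values: all transcripts sharing a count
receive the same corrected value; zeros pass through; cross-segment
monotonicity is not enforced (violations are logged at debug level).
Corrected counts are real-valued; `round_counts=True` rounds to the
nearest integer with a floor of 1 for positive inputs.

### PPS selection

The grid 5..100 in steps of 5 is searched. Per candidate: (a) the median
of the per-sample first-segment slopes, and (b) after correcting every
sample at that PPS, the median R² of the log-log regressions of the N−1
non-reference samples against the reference sample over shared positive
transcripts. The acceptance margin for (a) is the mean ± 1 SD of the
decade-based highest-count-segment slopes across samples — the decade
fits are the stable, segment-size-free estimate of the top exponent.
Within the margin the largest median R² wins; ties go to the smallest
PPS (finer segmentation corrects more locally). If no candidate lands in
the margin the one nearest the margin midpoint is used and a warning is
emitted.

## Synthetic data

The generator emulates the statistical structure the method assumes and
nothing else: a Zipf library (p_r ∝ r^(−b), default n = 1000 species,
b = 1) sampled by one multinomial draw per replicate at the requested
depth. Defaults mirror a dilution design at desk scale: depths
(1e6, 5e5, 2.5e5, 1.25e5) spanning 8×, two technical replicates per
depth. A second condition applies planted log2 fold changes to the
abundances before renormalization, so library-composition effects exist,
as in real data. `alias_signal` produces the deterministic aliased
construction used as the exact test bench for the aliasing module.

What the generator does **not** emulate: PCR/GC/length bias,
overdispersion beyond multinomial sampling, biological variation between
replicates, and the very wide (5+ decade) abundance range of real miRNA
libraries. Consequently a green test establishes that the machinery
behaves as the theory predicts under clean finite sampling — not that
any particular biological dataset will show effects of a given size.
Two regime notes:

* With 1000 Zipf species, counts reach the tied 1..10 region only below
  ~1e5 reads; the comparative benchmark therefore runs at depths
  8e4..1e4 (10–80 reads per species), the regime that reproduces the
  count-1 tails and undersampling verdicts of real shallow libraries.
* In the benchmark, planted fold changes are placed over abundance
  ranks 10–500 (the detectable range), mirroring spike-in designs.
  Fold changes planted in the deep tail are *structurally compressed*
  by the correction itself — the method attributes tail fold gaps to
  aliasing — which is a real limitation of the approach, not of the
  implementation.

## Numerical choices

* OLS via `scipy.stats.linregress`; a segment needs ≥ 3 points and
  nonzero amplitude spread.
* Decade boundaries are half-open [10^(−d−1), 10^(−d)) with the top
  decade closed at 1; short decades merge into the adjacent
  higher-count segment (the leading decade merges downward).
* Intra-sample scaling divides each sample by its own maximum count
  (the only reading consistent with every sample sharing the (0, 1]
  amplitude convention); ties at the maximum all map to 1.
* Scaled values reproduce counts to relative 1e−12; exact-match lookup
  in the correction uses the same tolerance, and novel values fall back
  to the segment of the nearest unique value.
* The evaluation harness's p-values are a labelled stand-in: a
  two-sample t-test on log2 normalized values whose per-transcript
  pooled variance is smoothed by the median pooled variance across
  transcripts. Without the floor, technical replicates with underflowing
  within-group variance produce p = 0 and break the min-noise-p cutoff
  rule. The stand-in exercises the cutoff/concordance machinery and does
  not claim to reproduce count-GLM inference; externally computed
  p-values can be supplied instead.
* Normalizers are formula-level: CPM; upper-quartile (per-sample 75th
  percentile of nonzero counts, rescaled to the mean library size);
  quantile (cross-sample rank means, ties averaged); median-of-ratios
  (size factor = median count/geometric-mean over all-positive rows).

## Segment variability reports

Two Table-style reports quantify heteroskedasticity. `segment_report`
works on one curve: per decade segment the fit-residual spread σ_obs and
the extrapolated σ_exp = σ_ref·(s_ref/s_i); the reference (highest-count)
segment has σ_exp = σ_obs by construction. `replicate_report` works on
the replicate scatter: σ_obs is the SD of log10(replicate) −
log10(reference) over shared transcripts, binned by the reference's
decades, with slopes from pooled decade fits. On pure multinomial data
the *fit-residual* worst ratio drops markedly after correction (≈3 →
≈1.2 at shallow depths), while the *scatter* ratio can rise: the
corrected tail of a bounded-range multinomial library is dominated by
rank noise of the dense low-count cluster, and σ_exp loses its slope
inflation once slopes are restored. Real libraries, with sparser tails
and larger top-segment scatter, sit between the two pictures.

## Known limitations

* The correction compresses genuine fold changes in the tied low-count
  tail along with the alias distortion (see above).
* The surrogate is assumed alias-free; if even the deepest replicate is
  strongly undersampled, f_s estimates are biased upward.
* α is fixed (default 1) rather than fitted; the estimator at the
  terminal rank uses one point by design and inherits its noise
  (`fs_mode="lsq"` trades faithfulness for robustness).
* Pure multinomial technical noise understates real replicate scatter;
  absolute SNR and concordance numbers on synthetic data are not
  comparable to real-data values, only their direction of change.
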