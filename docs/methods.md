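# Methods

## Signal model

At heterozygous locus *i* the observed allele-specific signals are

    X_A,i = α·1 + (1−α)·C_A,i + ε_A,i
    X_B,i = α·1 + (1−α)·C_B,i + ε_B,i

where α ∈ [0, 1) is the normal-cell fraction, (C_A, C_B) the tumor
allele-specific copy numbers (integers per clone; fractional after mixing
over subclones), and (ε_A, ε_B) zero-mean Gaussian noise with per-allele
variance σ² and inter-allele correlation ρ. Totals X = X_A + X_B. All
downstream statistics are derived from this model; its parameters and their
defaults are listed below.

The model is deliberately simple: noise is homoscedastic across copy
states (a variance–mean relationship is not modeled), loci are independent
given the segment, and only heterozygous (AB) loci carry allele-specific
information. Genotypes are required as input (matched-normal calls or
simulator truth); no genotype calling is performed.

## Pipeline stages and the reasoning behind them

**Moving-average smoothing** (default window 51 loci, odd, truncated at
chromosome edges) reduces noise before histogram modeling. The mixture is
fitted on smoothed totals; smoothing a 0.25-sd signal with a 51-locus
window leaves component peaks ~0.04 wide, which is what makes BIC model
selection of the copy-state peaks reliable.

**Balance filtering.** The windowed Pearson correlation r_i of (X_A, X_B)
over 200 heterozygous loci detects allelic imbalance: within an imbalanced
segment the deviating allele alternates randomly between A and B across
SNPs, so A and B move in opposition and r_i drops far below the genuine
noise correlation ρ. Expected centers, with per-allele offset
δ = (1−α)·|C_A−C_B|/2:  r ≈ (ρσ² − δ²)/(σ² + δ²). At α = 0.4 a
hemi-deletion sits near −0.6 and copy-neutral LOH near −0.85; at α = 0.7
they rise to about −0.3 — which is why the threshold cannot be a fixed
value.

The automatic threshold works on the distribution of defined r values:
1-D 2-means splits are applied recursively, peeling imbalanced clusters
off from below, until the remainder is unimodal (center separation
< 0.2). Two guards make this robust: a candidate lower cluster must be
materially negative (imbalance is a negative-correlation phenomenon; a
near-zero or positive "cluster" is boundary-window artifact), and must
carry at least 5% of loci (a genuine imbalanced population is a genomic
segment, not a thin tail from windows straddling borders). The final
threshold is the last split midpoint or, if higher, the balanced cluster's
median minus 3 robust standard deviations. With fewer than 100 values or
no detectable imbalance the floor −0.5 is used, which retains all
plausible loci. Window sizes were chosen so the null sd of r (≈1/√window ≈
0.07 at 200) is small against the weakest imbalance to be detected; when
simulating smaller tracks the windows should be scaled with the segment
lengths.

**Absolute normalization.** A univariate Gaussian mixture is fitted by EM
to the smoothed totals of masked-in loci (K = 1..6, BIC selection, three
starts per K: deterministic quantile seeding plus k-means++-style random
restarts; convergence at per-observation log-likelihood gain < 1e-5, max
200 iterations; components with variance below 1e-6 of the data variance
are pruned and the fit continues). Fits are capped at 5,000 evenly-strided
values — the baseline mean gains nothing from more. The per-iteration
log-likelihood trace is recorded and asserted non-decreasing in tests.

Baseline selection operates on *peaks*: EM routinely splits a heavy copy
state into near-identical components, so components whose means lie within
10% of a peak's weight-averaged mean are coalesced first (10% because
adjacent copy states are at least (1−α)/2 ≈ 11% apart in relative mean for
α ≤ 0.75; anchoring on the peak mean prevents chaining through thin
boundary-blend components). Policies: `dominant` (largest total weight —
the Gaussian mode equals the mean), `lowest_mean` (smallest mean among
peaks with weight ≥ 0.05, for samples where everything above copy 2
dominates), and `auto` (dominant, unless the dominant mean exceeds 1.5×
the lowest admissible mean — the signature of copy-4 dominance). The scale
2/baseline is applied to the allele signals, not just the totals, so the
Y statistic operates on absolutely normalized alleles. With `scope=auto`,
genome-wide and per-chromosome baselines are compared; a chromosome
deviating more than 15% (configurable) is rescaled on its own baseline and
the result flagged. Normalization is exactly scale-equivariant and fails
with an explicit error when fewer than 50 balanced loci are available —
the honest failure mode for extreme aneuploidy.

**Segmentation** is recursive binary splitting of the *unsmoothed*
normalized totals: at each node the split maximizing the two-sample z
statistic of means is accepted if |z| > 5 and both children have ≥ 50
loci. The noise scale comes from 1.4826·MAD of first differences divided
by √2, which is consistent only on serially uncorrelated signals — on a
moving-averaged profile this estimate shrinks by roughly the window factor
while segment-mean variance does not, inflating z and causing gross
over-segmentation; hence the raw profile is segmented. Boundaries with no
total-copy change (e.g. diploid next to copy-neutral LOH) are invisible to
a total-signal segmenter; such merged segments still carry correct means
and balanced fractions, and the mask handles their LOH content. External
SEG files can replace this stage.

**Noise model.** ρ and σ² are estimated from loci that are heterozygous,
masked-in, and inside segments with normalized mean in [1.8, 2.2] —
balanced normal-copy loci. Estimating over all loci instead mixes
between-state mean differences into σ² and the anticorrelated imbalanced
loci into ρ, inflating σ_d² = 2σ²(1−ρ) several-fold. The regression tests
document the consequence precisely: with the contaminated noise model every
simulated hemi-deletion is misclassified as homo (Y and λ both shrink, and
the inflated σ collapses the signal-to-noise ratio); substituting the
corrupted ρ alone while keeping the true σ does *not* flip the calls —
both distortions act together.

**Deletion typing.** Candidates are segments with normalized mean < 1.8
(configurable). Y = √(Σ d_i²/σ_d²) over the segment's het loci; homo model
= central chi(L); hemi model = noncentral chi(L, λ), λ = √L(1−α_seg)/σ_d
with α_seg the segment's own hemi-candidate estimate (mean − 1, clamped),
since the global α is unknown at this stage. The noncentral density is
evaluated as f_Y(y) = 2y·f_Q(y²) with Q noncentral chi-square(L, λ²), in
log space. Priors default to (0.5, 0.5).

**Purity.** homo: E[X] = 2α; hemi: E[X] = 1 + α. Because signals are
measured with a floor at zero, a deleted allele's observed mean is the
censored-Gaussian mean g(α) = α·Φ(α/σ) + σ·φ(α/σ) rather than α; at
α = 0.1, σ = 0.25 the naive estimate would be inflated by ≈ 0.06. The
per-segment estimate therefore inverts g (homo: 2g(α) = mean; hemi:
g(α) = mean − g(1)), which reduces to the linear map whenever the mean is
a few σ above zero. The genome-wide α̂ is the 9th percentile (linear
interpolation between order statistics, segments weighted equally) of the
per-segment values: a deletion carried by only a subclone leaves part of
the tumor diploid, raising the segment mean, so heterogeneity can only
inflate per-segment estimates and a low percentile tracks the homogeneous
segments. Equal weighting keeps one long deletion from dominating the
percentile.

**Tumor profile and ploidy.** X_tumor = (X − 2α̂)/(1 − α̂), clipped at 0,
applied to segment means; average ploidy is the locus-weighted mean,
deliberately not rounded to integers (under subclonality the restored
values are not integers).

**Legacy mode** (`run_legacy`) reproduces the classic procedure this
package replaces: scale = 2/median of all totals, no balance mask, noise
parameters over all loci, and *mean* aggregation of per-segment α (the
low-percentile aggregation is part of the revised method, so the contrast
keeps the original mean). On the bundled validation design the median
locus is amplified, balanced diploid segments are dragged below the
deletion threshold, called homo (they are balanced, so Y is small), and α
is overestimated by ≈ 0.2.

## The simulator

`simulate_sample` draws exactly from the signal model: per-segment integer
allele copy states, optional subclone fraction f (aberration carried by a
fraction f of tumor cells, remainder diploid), linear mixing with α,
bivariate Gaussian noise (marginal sd σ, correlation ρ), clipping at zero.
Within imbalanced segments the aberrant allele is assigned per locus by a
fair coin — the mechanism that produces the negative windowed correlation
on real arrays. Optional distortions: linear crosstalk a' = a + c·b and
saturation s(x) = M(1 − e^(−x/M)); both have exact inverses used by
`correct_crosstalk` (the coefficients are inputs, not estimated).

The default validation design is one chromosome of 40,000 heterozygous
loci in eight variable-length segments with allele states
(0,0), (1,0), (1,1), (2,0), (2,1), (1,1), (2,2), (3,0) at fractions
1.25/7.5/11.25/12.5/22.5/10/11.25/23.75 %, α = 0.40, ρ = −0.042,
σ = 0.25. The lengths are deliberately uneven, with the majority of loci
amplified or imbalanced, so the median locus is not diploid — the
challenging regime the method exists for. A variant
(`heterogeneous_validation_config`) makes two of four deletion segments
subclonal (f = 0.6) to exercise the percentile aggregation.

What the simulator does **not** emulate: probe-level intensity effects
(GC/wave artifacts, fragment-length bias), locus-specific noise,
genotyping error, and spatial noise correlation along the genome. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to array-specific artifacts — on real
arrays the preprocessing upstream of this package must deal with those.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `ma_window` | 51 | loci | smoothing for histogram modeling only |
| `rho_window` | 200 | het loci | null sd of r ≈ 1/√window |
| `balance_threshold` | auto | r | override for the automatic rule |
| `k_max` | 6 | — | copy states 0..5 plausible |
| `min_seg_len` | 50 | loci | conservative against micro-segments |
| `z_threshold` | 5 | — | split acceptance |
| `deletion_threshold` | 1.8 | copies | candidate gate |
| `cn_window` | [1.8, 2.2] | copies | noise-model loci |
| `alpha_percentile` | 9 | % | heterogeneity-robust aggregation |
| `priors` | (0.5, 0.5) | — | homo/hemi |

## Numerical choices and degenerate inputs

- Mixture fits are capped at 5,000 evenly-strided values; EM stops on
  per-observation log-likelihood gain < 1e-5; the BIC sweep over K stops
  after two consecutive non-improving values.
- Segmentation with a zero MAD (noiseless input) floors σ at 1e-12, so any
  exact mean change still splits and constant signals do not.
- Ties in baseline selection resolve to the lower-index (lower-mean) peak.
- `aggregate_alpha` uses numpy's default linear-interpolation quantile on
  raw order statistics (not a smoothed density).
- A hemi call at mean ≥ 2 clamps to α = 1 and is excluded from aggregation
  as non-informative; means below the censoring floor clamp to α = 0.
- Y calibration: the central-chi null is exact while the zero floor is
  inactive. In deep homo-deletions at low purity the floor truncates the
  noise and deflates Y slightly — a conservative distortion (it favors the
  homo call, which is already the truth there); the calibration tests pin
  the null at signal levels where censoring is negligible.

## Validation study sizes

The bundled tests run the full pipeline on the 40,000-locus design for the
headline estimates; the purity grid runs α ∈ {0.1, …, 0.7} × 50 replicates
at 20,000 loci per sample (same design proportions); typing calibration
uses 2,000 homo-deletion segments of L = 100 and 100 replicates per
deletion type. The problem sizes keep the whole suite fast while leaving
every acceptance margin comfortably wide of its tolerance.

## Known limitations

- No joint purity–ploidy grid search: normalization, purity and ploidy are
  estimated sequentially (divide and conquer), which is transparent but
  cannot rescue samples with no balanced diploid loci.
- Purity requires at least one informative deletion segment.
- Subclone deconvolution and localized (per-chromosome) ploidy are out of
  scope; the per-segment α distribution is reported in the QC block as a
  heterogeneity diagnostic.
- B-allele-frequency-based imbalance detection is a known alternative to
  the correlation criterion and is not implemented.
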