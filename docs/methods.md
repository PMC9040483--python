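# Methods

## Detection model

The detector treats stoma finding as dense binary classification of circular
image neighborhoods. A candidate location is described by a disk of diameter
*d* = 80 px centered on it. Inside the disk, *R* = 40 concentric rings at
radii r_k = k·r_max/R (r_max = (d−1)/2, so the outermost ring remains
bilinearly interpolable inside the patch) are sampled at *N* = 64 equally
spaced angles, and each ring's angular profile is passed through a 1-D DFT.
For ring r and harmonic k ≤ H (H = 8 kept, plus the DC term):

* amplitude A_{r,k} = |X_k|/N — invariant to in-plane rotation of the disk
  up to interpolation error;
* relative phase φ_{r,k} = arg X_k − k·arg X_1, wrapped to (−π, π] — the
  harmonic-1 reference cancels the rotation offset, leaving a (approximately
  rotation-invariant) shape descriptor.

Because only H+1 harmonics are needed, the DFT is evaluated as a dense
matrix product against a truncated cosine/sine basis rather than a full FFT;
on regular prediction grids the ring samples are assembled from strided
slices of the image (one slice per ring/angle offset), which keeps dense
512×512 prediction at stride 2 to a few seconds per image on one CPU.

**Feature encoding.** Raw relative phases of near-zero harmonics are
circular-uniform noise. With 320 phase dimensions against 360 amplitude
dimensions, that noise dominates the feature covariance: a 95%-variance PCA
basis consists almost entirely of phase-noise directions and the classifiers
barely separate the classes (cross-validated AUC ≈ 0.62), while amplitudes
alone separate them perfectly (AUC 1.0 in 18 components). The classifier
path therefore uses the amplitude-weighted encoding
[A_{r,k}, A_{r,k}·cos φ_{r,k}, A_{r,k}·sin φ_{r,k}] — equivalently the
harmonic-1-derotated complex coefficients — which preserves phase
information, is continuous across the ±π wrap, and suppresses the noise of
weak harmonics. The raw amplitude+phase encoding remains available
(`encoding="raw"`).

Flattening is ring-major; the encoding and flattening order are recorded in
the PCA basis metadata. The PCA keeps the smallest number of components
reaching 95% explained variance (typically 200–300 on the weighted
encoding); the sign convention makes the largest-magnitude loading of each
component positive so bases are reproducible.

## Training set and learners

One positive disk per annotation whose disk fits in the image; 3 background
disks per positive, sampled uniformly among valid centers at least one disk
radius (40 px) from every annotation. Neither the class ratio nor the
exclusion radius is critical; both are parameters.

Nine learner kinds share the PCA scores: a single-hidden-layer perceptron
(32 units), LDA, a small 1-D convolutional net over the score sequence
(8 filters, kernel 5, ReLU, global average pooling, logistic readout, Adam,
written in numpy), logistic regression with no penalty, with ridge and with
lasso penalty (penalty strength by 3-fold internal CV, fixed seed), PLS
regression on the 0/1 label (5 components, clipped to [0,1]),
forward-stepwise linear regression selected by BIC (candidate pool capped at
the first 40 components for tractability, output clipped), and a decision
tree (min 5 samples per leaf). Probabilistic learners emit class
posteriors; regression learners are clipped to [0,1].

Probability maps are evaluated on a stride-2 grid of valid centers (one
shared feature pass for all nine learners), bilinearly upsampled, and the
border band where no disk fits is identically 0.

## Fusion and tuning

The fused map is the pixel-wise weighted mean of the nine maps (uniform
weights by default; weights renormalize with a warning if they do not sum
to 1), Gaussian-filtered with reflective boundaries, then local maxima at or
above a height threshold are accepted greedily in decreasing height with an
exclusion radius (ties by row then column; a hash grid keeps suppression
linear-time). Maps are combined before filtering; the reverse order is a
one-line change and was not found to matter on synthetic data.

Detections are matched to annotations greedily by increasing pair distance
within a match radius (default 20 px ≈ one stoma length). Matched pairs are
TP, leftover detections FP, leftover annotations FN. Point detection has no
natural TN; here TN = sub-threshold candidate peaks not within the match
radius of any annotation. This makes the MCC computable and rewards
thresholds that convert spurious maxima into rejections; it also means the
tuned optimum depends on how many weak local maxima the smoothed map
carries.

Tuning maximizes the mean MCC over the training images with a Nelder–Mead
simplex over (σ, τ), box-constrained through softplus/logit transforms
(standard coefficients 1, 2, 0.5, 0.5; convergence when the objective
spread < 1e−4 or 200 iterations). Two robustness details: the initial
simplex steps are ±1 in transformed space (scipy's default 5% perturbation
is smaller than one step of the MCC staircase, which makes the objective
look locally flat), and the best parameter set ever evaluated — including
the initial one — is returned, so tuning can never worsen the initial MCC.
`max_iter=0` returns the initial parameters unchanged. Weight optimization
is available behind a flag but off by default. The end-to-end fit computes
tuning maps for 6 of the training images (the disk training set still uses
all images); this keeps the fit inside a few minutes without affecting the
tuned optimum noticeably.

## Density and plasticity

SD = count / 0.64 mm⁻² for the default 800 × 800 µm field of view; the
sample value is the median of its 4–6 FOV densities (a warning is logged
outside that range; mean-of-middle-two for even n). Count validation fits
OLS of automatic on manual counts by default; the direction is configurable
and R² is direction-invariant in simple regression. Plasticity formulas use
the wetter-season value as the denominator, oriented so that the typical
between-season response (SLA up, SD down) is positive:
%ΔSLA = (SLA₂₀₁₇ − SLA₂₀₁₆)/SLA₂₀₁₇ × 100,
%ΔSD = (SD₂₀₁₆ − SD₂₀₁₇)/SD₂₀₁₆ × 100.

## Candidate-gene ensemble

Coordinates are 1-based inclusive internally (GFF3 convention); BED inputs
are converted on read. Percentile selection takes the ceil(f·n) smallest
p-values with ties at the cutoff broken by identifier so the selection size
is exact. Nearest-gene assignment restricts to the top 10% of SNPs; distance
is zero inside the gene body, else base pairs to the nearer boundary;
equidistant ties go to the smaller start then the smaller gene id; a gene
hit by several SNPs keeps the minimum p (conventional and monotone — the
choice is recorded in the output metadata). Fisher's combination of the
gene-level GWAS p with each tissue's TWAS p uses χ² = −2(ln p₁ + ln p₂) on
4 df, equal to the closed form p₁p₂(1 − ln p₁p₂). GWAS nomination takes the
top 0.1% of SNPs, finds their LD blocks (a SNP inside no block contributes
a degenerate single-position block), and extracts every gene overlapping a
hit block by ≥ 1 bp, border-spanning genes included. No multiple-testing
correction is applied anywhere: the method ranks by percentile, not by
adjusted significance.

Confidence tiers are evaluated in priority order: GWAS plus TWAS-or-Fisher
in at least one tissue; else TWAS-or-Fisher evidence in both tissues
(labeled as the TWAS-only sub-case when no Fisher or GWAS nomination is
involved); else none. A gene with TWAS hits in both tissues satisfies both
of the two-tissue phrasings; the priority order here is a package decision.
"High confidence" means any non-none tier.

## Synthetic data

**Images** emulate the reflective-intensity layer of an optical-topometry
scan of a grass leaf: a striated pavement-cell background (stripe period
from the file spacing, plus band-limited mottle), dumbbell-like stoma motifs
(bright guard-cell rim, darker pore, bright polar caps; ~35 × 12 µm) laid in
vertical files (65 µm spacing) on a jittered lattice with rejection sampling
enforcing a minimum center spacing (40 µm ≥ stoma length), and additive
Gaussian sensor noise (sd 0.03 on a [0,1] intensity scale; pavement
amplitude 0.08; stoma contrast ~0.38). The default raster is 512 × 512 px at
800/512 µm/px, i.e. one 0.64 mm² field of view. The stoma count equals
round(density × area); infeasible density/spacing combinations raise an
error rather than silently under-filling. Stoma centers keep a 62.5 µm
margin from the border: the detector's border band (no full disk fits) is
structurally zero, so the generator emulates the analyzable interior of a
field of view. What this generator does *not* emulate: real topography
artifacts, uneven illumination, non-stomatal structures (veins, trichomes,
dust), partially visible border stomata, and annotation error — so passing
benchmarks here demonstrate the machinery works as designed, not field
accuracy on real micrographs.

**Association tables** (`synth_assoc`): genes tile two chromosomes (3 kb
bodies every 10 kb); LD blocks tile with gaps (20 kb blocks, 5 kb gaps) so
some genes sit outside every block; SNP positions and all background
p-values are Uniform(0, 1]. Each planted causal gene receives one SNP moved
to its midpoint with p = 10^(−s(1+2u)) and TWAS p-values 10^(−s(1+u)) in
both tissues (s = signal strength, default 8; u uniform). The GWAS exponent
spans twice the TWAS range, reflecting the much wider dynamic range of GWAS
p-values in real studies; this also keeps the Fisher rankings from
collapsing onto the TWAS rankings, so the evidence channels stay
quasi-independent — the premise of combining them. Between-tissue
correlation of causal signals runs through a Gaussian copula (default 0.3).
With 10 causal genes and top-1% lists of 5, each list can hold at most half
the causal set; recovery relies on the union across tests and settles
around 80–90%, which is the structural ceiling of these list sizes rather
than a power limit.

## Problem sizes and numerical choices

The acceptance benchmark uses 30 training + 20 held-out 512 × 512 images at
densities 30–120 mm⁻², stride 2, tuning maps from 6 images — about ten
minutes on one CPU, dominated by the dense feature pass. Grid feature
extraction runs in float32 (agreement with the float64 per-patch path to
~1e−4, dominated by phase terms near the wrap); all oracle comparisons of
the transform itself use the float64 path. Degenerate inputs are errors,
not warnings: single-class training sets, images smaller than the disk,
empty tables, non-positive denominators. MCC is defined as 0 when any
denominator factor vanishes and raises on an all-zero table.

## Known limitations

Stoma *sizes* are not measured (detection only). The greedy point matching
is not optimal assignment; on small instances the difference is bounded by
the oracle tests. The 1-D conv net is a minimal classifier over score
sequences, not an image CNN. Real-data performance claims cannot be made
from the synthetic benchmark (see the generator's non-goals above).
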