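# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the beadscreen toolkit: what the simulator emulates, how the
analysis stages work, and which numerical decisions were made where the
design was genuinely open.

## 1. The simulated assay

The simulator emulates one well of a multiplex microbead binding assay at
the point of imaging: a settled monolayer of dye/size-encoded microbeads,
photographed in two encoding channels (internal dyes) and one measurement
channel (surface-bound fluorescent label). Beads belonging to one
population share a nominal diameter and a nominal pair of encoding
intensities; the measurement channel shows a ring ("halo") at each bead's
rim because surface-bound label on a sphere projects to an annulus in a
2-D image.

**Bead layout.** Centers are placed by rejection sampling, uniform over the
image minus a margin that keeps bead and halo fully inside, with a hard
minimum center distance enforced through a grid-based neighbour lookup
(O(1) per attempt). The attempt budget is 200 attempts per bead on average;
exhausting it raises a capacity error rather than silently under-filling
the chip. An optional `doublet_fraction` attaches that fraction of beads to
a random earlier bead at ~1 bead-diameter spacing to emulate clumps;
it defaults to 0 (doublets are a QC scenario, not the baseline).

**Rendering.** Encoding channels: per bead, a filled disk with a soft edge
(erf profile, i.e. an ideal disk convolved with a Gaussian of width
`edge_sigma` = 0.7 px), scaled by the bead's true encoding intensities.
Measurement channel: per bead, a ring with Gaussian radial profile
`A·exp(−(ρ−r)²/2σ²)` centred on the bead radius, with σ = `halo_width`
(default 1.5 µm) and amplitude A the bead's programmed halo level. All
channels sit on a common `background_level` (default 200 a.u.). Noise is
applied per channel: optional shot noise (Poisson at unit photon gain, so
pixel variance equals the mean in these units) followed by additive
Gaussian read noise (default SD 20 a.u.), then rounding and clipping to
the 16-bit range. A single integer seed makes images bit-reproducible.

**Default study conditions.** The default panel has 16 populations — two
diameters (10 and 15 µm at 1 µm/pixel) crossed with eight enc1/enc2 dye
ratios stepping by factors of 2 (enc2 fixed at 2000 a.u.) — mirroring how
commercial bead sets encode by size plus two dye intensities; the first
four populations carry the screen's targets, the rest act as specificity
controls. The default bead count is 500 per population, at the lower end
of the 500–1000 beads/population typical for one well of such an assay;
per-bead encoding intensities vary with a 5% coefficient of variation and
radii with 2%. The diameters and intensity levels themselves are
simulator conventions (real panels do not publish them), so they are
configurable and everything downstream reads them from the panel, not
from constants.

**What the simulator does not emulate.** No optical PSF or focus
variation, no spectral bleed-through between channels, no spatial
illumination gradients, no bead auto-fluorescence variation beyond the
encoding CV, no Brownian motion between frames. Passing tests therefore
demonstrate correctness of the analysis chain under a well-behaved imaging
model, not robustness to every instrument artefact; the gating and
background machinery (circularity filter, doublet gate, occlusion-aware
local background, edge flags) is exercised by construction, but its
real-data effectiveness is untested here.

## 2. Detection and decoding

Detection runs on the *sum* of the two encoding channels (every bead is
bright there regardless of its ratio): median background subtraction,
max-normalization, then multi-scale Laplacian-of-Gaussian blob detection
(scikit-image `blob_log`, 8 scales spanning radii 3.5–10 px, relative
threshold 0.05, overlap pruning 0.3). Each blob is refined to an
intensity-weighted sub-pixel centroid; the radius is re-estimated as the
half-maximum crossing of the azimuthally averaged radial profile
(interpolated between 24 radial bins), which is insensitive to the LoG
scale quantization. Circularity is the square root of the minor/major
eigenvalue ratio of the blob's intensity covariance (1 for a circular
footprint); candidates below 0.7 are dropped. Detections touching the
border are edge-flagged, and beads whose neighbour sits closer than
1.2×(r₁+r₂) are flagged as doublets and excluded from statistics.

Encoding features are means over the inner disk eroded by 30% of the
radius (staying clear of the soft edge), corrected by a far-field
background (median over pixels ≥ 2 radii away from every detection).
Decoding operates in (log enc1/enc2 ratio, diameter) space — ratio and
size are what the encoding scheme actually varies — with a per-dimension
standardized Euclidean distance (default dispersions: 0.1 in log-ratio,
5% of diameter) and a 3-SD gate; beads beyond the gate are "unclassified".
Exact distance ties resolve by panel order and are flagged ambiguous.
Every detection ends in exactly one bucket (population / unclassified /
QC-failed), so counts always partition the detection total.

## 3. Halo quantification and rMFI

For a bead of radius r, the ring statistic is the mean of
measurement-channel pixels in the annulus [r(1−w_in), r(1+w_out)]
(defaults w_in = 0.1, w_out = 0.3, bracketing the ring crest). The local
background is the median of an outer annulus [r·2.0, r·2.6] — far enough
out that the Gaussian ring tail (≤ 3σ) contributes negligibly — after
excluding pixels inside any neighbouring detection inflated by 1.3×; if
more than 80% of that annulus is occluded the global image median is used
and the bead flagged. Because the halo has a radial profile, the raw
annulus mean understates the crest amplitude by a purely geometric factor;
the statistic is divided by κ, the mean of the expected profile
`exp(−(ρ−r)²/2σ²)` over the same pixels, so a noise-free halo of
amplitude A measures exactly A. κ uses the configured `halo_width`; an
analysis run with a wrong width mis-scales all populations by a common
factor, which cancels in percent-change screening statistics.

Numerical choices worth recording:

* **Plain mean, not trimmed (default `trim = 0`).** A trimmed mean
  interacts with the asymmetric distribution of profile values over the
  annulus and with signal-dependent shot noise to give a ≈ −0.5%
  multiplicative bias; the plain mean is linear in the pixel values and
  measured unbiased to < 0.1% at n = 500 beads. The trim fraction remains
  configurable for contaminated data.
* **Negative `halo_surface` values are kept**, so population means stay
  unbiased around zero binding.
* An optional measurement-channel crest re-estimation
  (`refine_ring_radius`) exists for data where the halo sits off the
  detected bead radius; it is off by default because with the plain mean
  it is unnecessary and its residual noise costs ~0.3% of amplitude.
* Background-offset invariance is exact by construction: adding a
  constant to the measurement channel shifts ring mean and background
  median equally.

rMFI is the arithmetic mean of `halo_surface` over QC-passing beads of a
population, divided by a configurable `reference_scale` (default 1.0).
The "reference" of the rMFI convention is not pinned to a numeric recipe
by the assay's public descriptions — the encoding dyes are a stable
reference *system* for identifying populations — so the normalization is
surfaced as one parameter rather than hard-coded. Summaries with fewer
than `min_beads` (default 10) usable beads are marked invalid, never
silently reported. Kinetic mode re-runs the full pipeline per frame and
aggregates per population; beads are not tracked across frames.

## 4. Dose-response fitting, AIC selection, ED50

Candidate families (the default set has exactly eleven):

| family | f(x) | free parameters |
|---|---|---|
| LL.2 | 1/(1+(x/e)^b), c=0, d=1 | b, e |
| LL.3 | d/(1+(x/e)^b) | b, d, e |
| LL.4 | c+(d−c)/(1+(x/e)^b) | b, c, d, e |
| LL.5 | c+(d−c)/(1+(x/e)^b)^f | b, c, d, e, f |
| EXD.2 | d·exp(−x/e) | d, e |
| EXD.3 | c+(d−c)·exp(−x/e) | c, d, e |
| W1.2 | exp(−(x/e)^b), c=0, d=1 | b, e |
| W1.3 | d·exp(−(x/e)^b) | b, d, e |
| W1.4 | c+(d−c)·exp(−(x/e)^b) | b, c, d, e |
| W2.3 | d(1−exp(−(x/e)^b)) | b, d, e |
| W2.4 | c+(d−c)(1−exp(−(x/e)^b)) | b, c, d, e |

The (x/e)^b parameterization is defined at x = 0 (no log of zero). Fixed
asymptote families (LL.2, W1.2) are fitted to max-normalized responses;
the normalization factor is recorded, predictions and RSS are mapped back
to the original scale so all candidates compete on one likelihood, and
the normalizer counts as one effective AIC parameter because it is a
data-derived scale.

Fitting is deterministic multi-start non-linear least squares
(`scipy.optimize.least_squares`, ftol 1e-10): starts take d ≈ max
response, c ≈ min response, e ≈ the dose nearest the half-range crossing
and b ∈ {±0.5, ±1, ±2}; bounds keep e > 0 and |b| ≤ 50. LL.4 solutions
are canonicalized through the exact symmetry (b,c,d) → (−b,d,c) so d is
always the zero-dose asymptote. Degenerate inputs (all responses equal)
raise a distinct error; non-convergence is reported, never silent.

`AIC = n·ln(RSS/n) + 2(p+1)` with p the free parameters (+1 for the error
variance); additive constants are dropped, which cannot change the
ranking. For the AIC only, RSS is floored at 1e-10·Σy², so interpolating
fits of nested families tie on the likelihood term and the parameter
penalty decides — e.g. noise-free EXD.2 data selects EXD.2, not EXD.3 or
LL.4. Exponential-decay families precede the Weibulls in the default
order so that exact ties between observationally identical curves (W1
with unit slope *is* exponential decay) resolve to the more parsimonious
parameterization. A caveat documented on purpose: AIC is not consistent —
a family nesting the truth with k extra parameters wins with probability
≈ P(χ²ₖ > 2k) (~13.5% for k = 2) at *any* noise level, so "selects the
generating family" can never be guaranteed at the ~90% level; what the
toolkit validates is that the selected curve reproduces the generating
curve (RMSE < 5% of the upper asymptote in ≥ 90/100 low-noise runs).

ED50 is the dose where the fitted response is halfway between the
asymptotes. Closed forms: e for LL.2/LL.3/LL.4, e·(2^(1/f)−1)^(1/b) for
LL.5, e·(ln 2)^(1/b) for both Weibull types, e·ln 2 for EXD.2/EXD.3. A
bisection fallback brackets the midpoint on a geometric grid spanning six
decades around e, reports the smallest crossing and flags non-monotone
curves as ambiguous; closed form and bisection agree to better than 1e-6
relative for all converged fits.

## 5. Screening statistics

Percent change is 100·(test−reference)/reference on QC'd rMFI values,
signed; a non-positive reference makes the quantity undefined and the
cell is masked (NaN), never zeroed. The specificity matrix is conditions
× non-target populations of percent changes against the aptamer's
reference condition, with the target population reported separately —
the tabular form of the screening heat maps. Inference across conditions
uses classical one-way ANOVA plus many-to-one two-sided pooled-variance
t-tests against the control with Bonferroni adjustment — a deliberately
conservative stand-in for Dunnett's procedure, chosen for transparency
and kept behind a config switch so an exact Dunnett implementation can be
slotted in. Effect sizes (mean difference, percent change, Cohen's d)
accompany every p-value; groups need ≥ 2 replicates, and all-zero
within-group variance is flagged degenerate rather than producing
spurious infinities.

## 6. Protein charge properties

Net charge at a given pH is the Henderson–Hasselbalch sum over the
N-terminus, C-terminus and the ionizable side chains: positive groups
contribute +1/(1+10^(pH−pKa)), negative groups −1/(1+10^(pKa−pH)). The
pKa table is the Bjellqvist set, shipped as a versioned YAML data file
(N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0,
R 12.0); alternative tables can be supplied. The charge is strictly
decreasing in pH, so the isoelectric point is the unique root in [0, 14],
found by bisection to |charge| < 1e-4. Molecular weight comes from
Biopython's `molecular_weight`. Sequences are restricted to the 20
standard residues and rejected with the offending position otherwise. The
bundled FASTA (`examples/synthetic_panel_proteins.fasta`) contains
*synthetic* sequences constructed to span low/neutral/high pI — stand-ins
for panel proteins, not real database entries — and is labelled as such.

## 7. Problem sizes used by tests and the acceptance script

Chosen as the smallest sizes at which the statistical assertions are
well-powered: detection/decoding on one 2048² chip with 16 populations ×
200 beads; quantification on one 2200² chip with 2 × 500 beads at
amplitude 800 a.u.; dose-response studies with 8 doses (0–1000 mM) × 3
replicates and 100 Monte-Carlo runs at CV 5% (ED50 recovery) and CV 2%
(model selection); ANOVA null calibration with 1000 simulations of 3
groups × 6 replicates; a 10-sequence random panel for pI consistency; and
an end-to-end screen of 8 doses × 16 populations × 100 beads with four
LL.3 target responses and constant controls.

## 8. Known limitations

* The decoder's dispersion estimates are panel-level defaults, not fitted
  per run; heavily drifted optics would need recalibrated dispersions.
* The halo calibration κ assumes the configured Gaussian ring width;
  real point-spread functions are only approximately Gaussian.
* Bonferroni is conservative relative to Dunnett for many comparisons.
* LL.2/W1.2 inherit their scale from the observed maximum response; with
  very noisy data this plug-in normalization understates uncertainty.
* Bead tracking across kinetic frames (per-bead kinetics) is out of
  scope; only population-level traces are produced.
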