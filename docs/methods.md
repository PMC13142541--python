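# Methods

This note documents the models behind each module, the numerical choices
made where the methodology is genuinely open, the defaults and their
units, and what the synthetic data do and do not emulate.

## Cross-channel FRC (`poca.frc`)

**Statistic.** Both stacks are reduced to 2D by a maximum-intensity
projection along z, center-cropped to the largest common square, apodized
with a separable 2D Tukey window (10% cosine taper by default), and
Fourier transformed. Each Fourier pixel is assigned to the annulus whose
integer radius (in frequency pixels) is nearest; ring *r* of an N×N image
sits at frequency r/(N·pixel_size) cycles/nm, and rings beyond Nyquist
(r > N/2) are discarded. The per-ring statistic is the *real part* of the
complex cross-sum normalized by the geometric mean of the ring powers, so
Cauchy–Schwarz bounds it in [−1, 1]; the real-part convention is standard
FRC practice and keeps anticorrelated structure visible as negative
values. The reported curve is additionally smoothed with a centered
uniform filter of five frequency bins (reflected at the ends so the curve
keeps its length).

**Crossing.** The smoothed curve is scanned from the coarsest non-DC ring
toward Nyquist; the crossing is the first frequency at which it falls
below the threshold (1/7 by default), linearly interpolated *in
frequency* between the bracketing rings, and reported as a feature size
in nm (1/frequency). A curve that never falls below the threshold is
flagged uncrossed — fidelity holds to the Nyquist limit — and a curve
already below threshold at the first ring reports that ring's feature
size. Per-condition results aggregate fields of view as mean ± sample sd
(ddof = 1), excluding (and counting) uncrossed FOVs.

**Choices at open points.** Cropping precedes windowing so the taper acts
on the analyzed square (windowing a rectangle and then cropping would
reintroduce hard edges). No background subtraction or intensity
normalization is applied beyond the window: the statistic is
scale-invariant per ring. Line scans use bilinear interpolation at evenly
spaced points, which is exact on locally linear intensity fields.

## Image simulator (`poca.simulate.simulate_image_pair`)

The generator emulates punctate nuclear FISH/IF fields. Nuclei are
non-overlapping disks placed by rejection sampling (deterministic error
after a bounded number of attempts, naming the offending parameter);
puncta counts per nucleus are Poisson and positions uniform within the
disk. The target channel sees the puncta through an isotropic lateral
Gaussian PSF; the deposition channel sees the *same* puncta through
σ_eff = √(σ_PSF² + σ_diffusion²) — the minimal model of reagent diffusion
— optionally mixed with `halo_fraction` of an annular kernel, a Gaussian
shell of PSF width centered at `halo_radius`. The shell models *displaced
label*: reactive intermediates that travel before depositing. Its Fourier
transform oscillates like J₀(2πqR), so a dominant halo drives the
fine-scale cross-spectrum — and therefore the FRC — negative, the
mechanism proposed for peroxidase/tyramide chemistry. Axial blur is not
modelled because the analysis max-projects; each punctum contributes to a
single z slice.

Noise follows the standard camera model: Poisson shot noise on signal
plus constant background, then additive Gaussian read noise, clipped at
zero to keep intensities physical. A `shot_noise` flag disables the
Poisson stage for exact-identity tests.

Defaults (chosen once as a realistic confocal regime): 8×512×512 voxels
at 110 nm/pixel, 10 nuclei of 4 µm radius with 30 expected puncta each
(~300 per field, within the per-FOV punctum range the assay operates at),
PSF σ = 150 nm for both channels, 2000 photons/punctum, 20
photons/pixel background, read noise σ = 3. Bead slides share identical
point sources between channels (each blurred by its own PSF) and default
to the same source density as the labeled simulation so crossings are
compared at matched signal-to-noise; bead count is exposed as a
parameter.

## Interactome simulator and randomization null (`poca.network`)

**Generator.** Prey sampling weights are drawn from a discrete power law
(pmf ∝ k^−γ, k = 1..n_baits, inverse-CDF sampling), giving hub-heavy prey
degrees; edges are sampled without replacement with pair weight
w(prey) · boost^[both endpoints in module], so `module_edge_boost = 1`
reduces exactly to the unplanted model and the emitted edge count equals
`n_edges` exactly. The planted module is split between bait and prey
sides roughly proportionally.

**Null.** Randomization uses attempt-and-reject double-edge swaps on the
bait→prey edge set (b₁–p₁, b₂–p₂ → b₁–p₂, b₂–p₁), rejecting swaps that
would create a self-loop or a duplicate unordered pair. The proposal is
symmetric, so the chain's stationary distribution is uniform over simple
role-respecting graphs with the observed degree sequence; an exhaustive
enumeration oracle on a 6-node toy confirms the sampled null mean. The
default burn-in is 10 attempted swaps per edge, each randomization an
independent fresh chain from the observed graph. Interactions are counted
as unordered protein pairs; orientation matters only as the swap
constraint. Query proteins absent from the network are dropped and
reported, not errors. z-scores use the null sd with ddof = 1 over the 200
null counts, and the primary p-value is the two-sided normal tail;
an empirical permutation p is reported alongside. Because the randomized
networks do not depend on the query, `null_counts_for_queries` generates
them once and scores many queries against the same ensemble — this is
what makes 500-query calibration runs take seconds. The inner swap loop
is JIT-compiled with numba.

## LFQ simulator and enrichment chain (`poca.enrichment`)

**Generator.** Per-protein baseline log₂ abundance is normal
(mean 25, sd 2 — a typical LFQ intensity scale); a designated proximal
subset carries a mean log₂ difference `effect_log2` (default 2) between
the target and reference groups; replicate noise is normal with σ = 0.25
log₂ units (~19% CV, mid-range for LFQ replicates). Entries are censored
missing-not-at-random with logistic probability in log₂ abundance
(midpoint 21 = two baseline sd below the mean, slope 1), i.e. ~50%
missing at two sd below the mean and a few percent overall — low-abundance
proteins are preferentially unobserved, which is exactly the regime the
downshifted-normal imputation assumes.

**Chain.** Zeros are missing by LFQ convention. Normalization centers
each sample's median log₂ intensity on the global median. Imputation
draws each missing value from N(μₛ − 1.8σₛ, (0.3σₛ)²) with per-sample
statistics — the canonical downshift parameters. Testing is a per-protein
two-sided Welch *t*; proteins with zero variance in both groups get p = 1
when the means agree and are flagged (not fatal) otherwise.
Benjamini–Hochberg adjustment excludes flagged proteins from the family.
Hit calling is strict in both inequalities (log₂FC > 1 AND adjusted
p < 0.05), directional by default with a symmetric |log₂FC| mode for
bait-vs-bait volcanoes. The annotation ROC treats log₂FC as the
classifier score with tie-aware thresholds; AUC equals the tie-corrected
Mann–Whitney statistic, and the Youden-optimal threshold maximizes
TPR − FPR.

The test whose p-values feed BH is a design choice: upstream LFQ
pipelines vary between plain and moderated *t*-statistics, and Welch on
log₂ intensities is the most defensible default without that detail. The
recovery results do not hinge on it at the simulated effect size.

## Pipelines and seeds

Every simulator is a pure function of its config; all pipeline randomness
derives from one global seed via SHA-256 hashing of (seed, stage name),
so stages are independently rerunnable and the composed pipeline equals
its parts. The acceptance script and the analysis drivers use the
following problem sizes, chosen to keep each design statistically
informative at interactive runtimes: 3 FOVs per imaging condition at
512×512×8; 500 nodes / 1000 edges and 500 calibration queries at 200
randomizations for the network null; 3000 proteins × (4+4) replicates and
10 simulation seeds for the enrichment recovery.

## What the synthetic data do not emulate

- Optics: no chromatic aberration, 3D PSF anisotropy, photobleaching, or
  drift; bead noise levels are a stated default, not a measurement.
- Interactomes: degree tails are power-law-like but not fit to any real
  bait–prey survey; no weighted or directed interaction semantics beyond
  the bait/prey roles.
- Proteomics: no peptide-level structure, shared peptides, or
  batch/run-order effects; missingness is purely abundance-driven.

Passing tests therefore demonstrate correctness of the statistics and
their calibration under these generative assumptions — not performance on
any particular instrument or cell system.

## Known limitations

- FRC operates on whole fields; per-nucleus cropping is not implemented.
- The normal-approximation p-value of the network test inherits the
  skewness of small interaction counts; the reported empirical p is the
  safer quantity when counts are low.
- `simulate_interactome` rejects configurations whose planted module
  saturates the feasible edge set rather than renormalizing weights.
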