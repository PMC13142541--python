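# poca

Quantitative validation statistics for **targeted proximity labeling** —
experiments that deliver a photosensitizer (or peroxidase) to a DNA locus,
RNA, or protein and deposit biotin on its spatial neighbours for
streptavidin enrichment and mass spectrometry. The package answers three
questions such experiments raise, each with a tested, reusable
implementation and a synthetic-data module that makes every stage
verifiable against known ground truth:

1. **How finely does biotin deposition track the targeting signal?**
   Cross-channel Fourier ring correlation (FRC) between the target channel
   (FISH/IF) and the streptavidin channel. Per spatial-frequency ring *r*:

   FRC(*r*) = Re Σᵣ F₁·F̄₂ / √(Σᵣ |F₁|² · Σᵣ |F₂|²)

   computed on max-projected, Tukey-apodized (10% taper) images, smoothed
   with a 5-bin uniform filter. The finest reliable scale is the feature
   size (1/frequency) at which the smoothed curve first drops below the
   conventional **1/7 threshold**, averaged over fields of view and
   compared against a bead-slide optical floor.

2. **Which proteins are enriched near the target?** Label-free
   differential enrichment: log₂ transform and per-sample median
   centering, Perseus-style downshifted-normal imputation
   (N(μₛ − 1.8σₛ, (0.3σₛ)²)), per-protein Welch *t*-tests,
   Benjamini–Hochberg FDR, and hit calling at a strict >2-fold change with
   adjusted *p* < 0.05. Hit lists are benchmarked against compartment
   annotations via ROC on the log₂FC score (trapezoid AUC, Youden-optimal
   threshold J = TPR − FPR).

3. **Do the hits interact more than chance predicts?** The number of
   known bait–prey interactions among the hits is compared with its
   distribution over networks randomized by role-respecting double-edge
   swaps, which exactly preserve the vertex set, edge count, per-node
   degree, and bait/prey identity. z = (obs − μ₀)/σ₀ with a two-sided
   normal *p*-value (200 randomizations by default).

## Layout

- `src/poca/` — the library: `frc`, `enrichment`, `network`, `simulate`,
  `pipeline`, `io`, `cli`.
- `analysis/` — numbered narrative drivers that run each study design and
  write tables under `results/` (regenerated on each run; not committed).
- `docs/methods.md` — models, assumptions, parameter choices, limitations.

## Worked example

```python
import dataclasses, poca

base = poca.ImageSimConfig()            # 110 nm pixels, ~300 puncta/field
report = poca.run_frc_comparison(
    {"poca_like": base,
     "hrp_like": dataclasses.replace(base, diffusion_sigma=800.0,
                                     halo_fraction=0.8, halo_radius=700.0)},
    n_fov=3, bead_config=base, seed=1)
print(round(report["bead_floor_nm"]),
      round(report["conditions"]["poca_like"]["mean_nm"]),
      round(report["conditions"]["hrp_like"]["mean_nm"]))
```

prints `344 331 1906`: the bead pair (shared point sources, independent
noise) crosses 1/7 at 344 nm — the optical ceiling of the simulated
microscope. A labeling chemistry with no diffusion beyond the PSF crosses
at 331 nm, statistically at that floor, while a peroxidase-like chemistry
(800 nm reagent diffusion plus a displaced-label halo at 700 nm) crosses
at ~1.9 µm, a ~6-fold loss of spatial fidelity, and its FRC turns
*negative* below 1 µm — fine-scale deposition anticorrelated with the
target. Running `python analysis/01_imaging_fidelity.py` reproduces the
full sweep; `02`–`04` run the enrichment, network-null, and
cross-modality-intersection designs and print what they find.

A shell workflow is available through the `poca` command
(`poca sim | frc | enrich | net | intersect | run`); run any subcommand
with `--help` for its flags.

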