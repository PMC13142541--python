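"""Synthetic data generators with ground truth.

Every generator is a pure function of its config: the same seed yields
bitwise-identical output.  Each returns a :class:`SimTruth` record naming
the planted structure (punctum coordinates, module members, true-proximal
proteins) so downstream recovery can be scored exactly.

The image simulator emulates punctate nuclear FISH/IF fields: the target
channel is the ground-truth puncta blurred by the microscope PSF; the
deposition (streptavidin) channel is the *same* puncta blurred by the PSF
widened by a labeling-diffusion kernel, optionally mixed with an annular
"displaced label" component that reproduces the fine-scale anticorrelation
characteristic of peroxidase/tyramide chemistry.  Both channels receive
constant background, Poisson shot noise, and Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from poca.frc import ImagePair
from poca.network import InteractionNetwork

__all__ = [
    "ImageSimConfig", "NetSimConfig", "LfqSimConfig", "SimTruth",
    "simulate_image_pair", "simulate_bead_pair",
    "simulate_interactome", "simulate_lfq",
]


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset.

    Only the fields relevant to the emitting simulator are populated.
    ``puncta_coords`` is a list (one entry per nucleus) of ``(n, 3)``
    arrays of ``(z, y, x)`` positions in nanometres.
    """

    puncta_coords: list = field(default_factory=list)
    module_members: set = field(default_factory=set)
    proximal_ids: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# imaging


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of the two-channel punctate image simulator.

    All lengths are nanometres.  ``field_shape`` is ``(z, y, x)`` in
    voxels; the analysis max-projects along z, so axial blur is not
    modelled and each punctum contributes to a single z slice.
    """

    field_shape: tuple = (8, 512, 512)
    pixel_size: float = 110.0
    n_nuclei: int = 10
    nucleus_radius: float = 4000.0
    puncta_per_nucleus: float = 30.0   # Poisson mean
    psf_sigma_target: float = 150.0
    psf_sigma_deposit: float = 150.0
    diffusion_sigma: float = 0.0       # labeling spread beyond the PSF
    halo_fraction: float = 0.0         # weight of the displaced-label ring
    halo_radius: float = 700.0
    amplitude_target: float = 2000.0   # photons per punctum
    amplitude_deposit: float = 2000.0
    background: float = 20.0           # photons per pixel
    read_noise_sd: float = 3.0         # photons
    shot_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.field_shape
        if nz < 1 or ny < 2 or nx < 2:
            raise ValueError(f"field_shape must be positive, got {self.field_shape}")
        for name in ("pixel_size", "nucleus_radius", "psf_sigma_target",
                     "psf_sigma_deposit", "halo_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("diffusion_sigma", "amplitude_target", "amplitude_deposit",
                     "background", "read_noise_sd", "puncta_per_nucleus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.halo_fraction <= 1.0:
            raise ValueError(f"halo_fraction must be in [0, 1], got {self.halo_fraction}")
        if self.n_nuclei < 0:
            raise ValueError(f"n_nuclei must be >= 0, got {self.n_nuclei}")
        r_px = self.nucleus_radius / self.pixel_size
        if 2 * r_px > min(ny, nx):
            raise ValueError(
                f"nucleus_radius={self.nucleus_radius} nm does not fit in a "
                f"{ny}x{nx} field at pixel_size={self.pixel_size} nm"
            )


def _place_nuclei(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping nucleus centres (y, x) in pixels, by rejection."""
    _, ny, nx = cfg.field_shape
    r = cfg.nucleus_radius / cfg.pixel_size
    centers: list = []
    attempts = 0
    while len(centers) < cfg.n_nuclei:
        attempts += 1
        if attempts > 1000 * max(cfg.n_nuclei, 1):
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei of "
                f"nucleus_radius={cfg.nucleus_radius} nm after {attempts} attempts"
            )
        y = rng.uniform(r, ny - r)
        x = rng.uniform(r, nx - r)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= (2 * r) ** 2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _render_deltas(coords_px: np.ndarray, shape: tuple) -> np.ndarray:
    """Accumulate unit point sources at (z, y, x) pixel coords into a stack."""
    stack = np.zeros(shape, dtype=float)
    if coords_px.size == 0:
        return stack
    zi = np.clip(np.floor(coords_px[:, 0]).astype(int), 0, shape[0] - 1)
    yi = np.clip(np.round(coords_px[:, 1]).astype(int), 0, shape[1] - 1)
    xi = np.clip(np.round(coords_px[:, 2]).astype(int), 0, shape[2] - 1)
    np.add.at(stack, (zi, yi, xi), 1.0)
    return stack


def _ring_kernel(shape_yx: tuple, radius_px: float, width_px: float) -> np.ndarray:
    """Annular kernel: Gaussian shell at ``radius_px``, normalized to unit sum."""
    ny, nx = shape_yx
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    rr = np.hypot(*np.meshgrid(y, x, indexing="ij"))
    k = np.exp(-0.5 * ((rr - radius_px) / width_px) ** 2)
    return k / k.sum()


def _apply_noise(signal_stack: np.ndarray, cfg: ImageSimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    img = signal_stack + cfg.background
    if cfg.shot_noise:
        img = rng.poisson(img).astype(float)
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _blur_deposit(deltas: np.ndarray, cfg: ImageSimConfig) -> np.ndarray:
    """Deposition-channel kernel: widened Gaussian + optional annular halo."""
    px = cfg.pixel_size
    sigma_eff = math.hypot(cfg.psf_sigma_deposit, cfg.diffusion_sigma) / px
    direct = ndimage.gaussian_filter(deltas, sigma=(0.0, sigma_eff, sigma_eff))
    if cfg.halo_fraction == 0.0:
        return direct
    ring = _ring_kernel(deltas.shape[1:], cfg.halo_radius / px,
                        cfg.psf_sigma_deposit / px)
    halo = np.empty_like(deltas)
    for z in range(deltas.shape[0]):
        halo[z] = signal.fftconvolve(deltas[z], ring, mode="same")
    return (1.0 - cfg.halo_fraction) * direct + cfg.halo_fraction * halo


def simulate_image_pair(config: ImageSimConfig,
                        fov_id: str = "fov") -> tuple[ImagePair, SimTruth]:
    """Simulate a matched target/deposition stack with known puncta.

    Puncta are Poisson-distributed within non-overlapping nuclear disks.
    The target channel sees them through a Gaussian PSF of
    ``psf_sigma_target``; the deposition channel through
    ``sqrt(psf_sigma_deposit**2 + diffusion_sigma**2)`` mixed with
    ``halo_fraction`` of an annular kernel at ``halo_radius``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.field_shape
    px = config.pixel_size

    centers = _place_nuclei(config, rng)
    r_px = config.nucleus_radius / px
    truth = SimTruth()
    all_coords = []
    for cy, cx in centers:
        n_p = rng.poisson(config.puncta_per_nucleus)
        # uniform in the nuclear disk, uniform in z
        rho = r_px * np.sqrt(rng.uniform(0, 1, n_p))
        theta = rng.uniform(0, 2 * np.pi, n_p)
        zz = rng.uniform(0, nz, n_p)
        coords = np.column_stack([zz, cy + rho * np.sin(theta),
                                  cx + rho * np.cos(theta)])
        all_coords.append(coords)
        truth.puncta_coords.append(coords * px)
    coords_px = (np.concatenate(all_coords, axis=0)
                 if all_coords else np.empty((0, 3)))

    deltas = _render_deltas(coords_px, config.field_shape)
    s_t = config.psf_sigma_target / px
    target = config.amplitude_target * ndimage.gaussian_filter(
        deltas, sigma=(0.0, s_t, s_t))
    deposit = config.amplitude_deposit * _blur_deposit(deltas, config)

    target = _apply_noise(target, config, rng)
    deposit = _apply_noise(deposit, config, rng)
    pair = ImagePair(target=target, deposition=deposit,
                     pixel_size=px, fov_id=fov_id)
    return pair, truth


def simulate_bead_pair(config: ImageSimConfig, n_beads: int | None = None,
                       fov_id: str = "beads") -> ImagePair:
    """Simulate a calibration bead slide: both channels share point sources.

    Each channel is blurred only by its own PSF (no diffusion, no halo),
    so the pair measures the optical ceiling of the imaging system.  The
    default bead count matches the expected punctum count of the labeled
    simulation so that crossings are compared at matched source density.
    """
    config.validate()
    if n_beads is None:
        n_beads = int(round(config.n_nuclei * config.puncta_per_nucleus))
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.field_shape
    px = config.pixel_size
    margin = 3.0 * max(config.psf_sigma_target, config.psf_sigma_deposit) / px
    coords_px = np.column_stack([
        rng.uniform(0, nz, n_beads),
        rng.uniform(margin, ny - margin, n_beads),
        rng.uniform(margin, nx - margin, n_beads),
    ])
    deltas = _render_deltas(coords_px, config.field_shape)
    s_t = config.psf_sigma_target / px
    s_d = config.psf_sigma_deposit / px
    target = config.amplitude_target * ndimage.gaussian_filter(
        deltas, sigma=(0.0, s_t, s_t))
    deposit = config.amplitude_deposit * ndimage.gaussian_filter(
        deltas, sigma=(0.0, s_d, s_d))
    target = _apply_noise(target, config, rng)
    deposit = _apply_noise(deposit, config, rng)
    return ImagePair(target=target, deposition=deposit,
                     pixel_size=px, fov_id=fov_id)


# ---------------------------------------------------------------------------
# interactome


@dataclass(frozen=True)
class NetSimConfig:
    """Parameters of the bait–prey interactome simulator.

    Prey degrees are heavy-tailed: each prey draws a sampling weight from
    a discrete power law with tail exponent ``degree_exponent`` truncated
    at ``n_baits``.  A planted module of ``module_size`` nodes has its
    within-module edge probability multiplied by ``module_edge_boost``.
    """

    n_baits: int = 100
    n_preys: int = 400
    degree_exponent: float = 2.0
    n_edges: int = 1000
    module_size: int = 0
    module_edge_boost: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_baits < 1 or self.n_preys < 1:
            raise ValueError("n_baits and n_preys must be >= 1")
        if self.n_edges < 0 or self.n_edges > self.n_baits * self.n_preys:
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for "
                f"{self.n_baits} baits x {self.n_preys} preys")
        if self.module_size < 0 or self.module_size > self.n_baits + self.n_preys:
            raise ValueError(f"module_size={self.module_size} out of range")
        if self.module_edge_boost <= 0:
            raise ValueError("module_edge_boost must be > 0")
        if self.degree_exponent <= 1.0:
            raise ValueError("degree_exponent must be > 1")


def _powerlaw_weights(n: int, exponent: float, kmax: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from pmf(k) ∝ k^-exponent, k = 1..kmax."""
    k = np.arange(1, kmax + 1, dtype=float)
    pmf = k ** (-exponent)
    cdf = np.cumsum(pmf / pmf.sum())
    return 1.0 + np.searchsorted(cdf, rng.uniform(0, 1, n))


def simulate_interactome(config: NetSimConfig) -> tuple[InteractionNetwork, SimTruth]:
    """Simulate a bait→prey edge list with heavy-tailed prey degrees.

    Edges are sampled without replacement with pair weight
    ``w(prey) * boost**[both endpoints in module]``, so
    ``module_edge_boost=1`` reduces exactly to the unplanted model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    baits = np.array([f"B{i:04d}" for i in range(config.n_baits)])
    preys = np.array([f"P{i:04d}" for i in range(config.n_preys)])
    w = _powerlaw_weights(config.n_preys, config.degree_exponent,
                          config.n_baits, rng)

    # split the module between sides roughly proportionally
    module_b = np.array([], dtype=int)
    module_p = np.array([], dtype=int)
    if config.module_size > 0:
        frac_b = config.n_baits / (config.n_baits + config.n_preys)
        n_mb = int(round(config.module_size * frac_b))
        n_mb = min(max(n_mb, 1 if config.module_size >= 2 else 0), config.n_baits)
        n_mp = min(config.module_size - n_mb, config.n_preys)
        module_b = rng.choice(config.n_baits, size=n_mb, replace=False)
        module_p = rng.choice(config.n_preys, size=n_mp, replace=False)

    # mass of the base component (all pairs, weight w_p) and of the extra
    # module component (module pairs, weight (boost-1)*w_p)
    base_mass = config.n_baits * w.sum()
    extra_mass = (config.module_edge_boost - 1.0) * len(module_b) * w[module_p].sum()
    p_extra = extra_mass / (base_mass + extra_mass) if extra_mass > 0 else 0.0
    w_all = w / w.sum()
    w_mod = (w[module_p] / w[module_p].sum()) if len(module_p) else None

    chosen: set = set()
    edges_b: list = []
    edges_p: list = []
    max_rounds = 200
    rounds = 0
    while len(chosen) < config.n_edges:
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                f"could not draw n_edges={config.n_edges} distinct edges; "
                "edge count too close to saturation for the planted module")
        m = config.n_edges - len(chosen)
        batch = max(2 * m, 64)
        in_extra = rng.uniform(0, 1, batch) < p_extra
        b = np.where(in_extra,
                     module_b[rng.integers(0, max(len(module_b), 1), batch)]
                     if len(module_b) else 0,
                     rng.integers(0, config.n_baits, batch))
        p = np.where(in_extra,
                     module_p[rng.choice(len(module_p), size=batch, p=w_mod)]
                     if len(module_p) else 0,
                     rng.choice(config.n_preys, size=batch, p=w_all))
        for bi, pi in zip(b, p):
            key = (int(bi), int(pi))
            if key not in chosen:
                chosen.add(key)
                edges_b.append(key[0])
                edges_p.append(key[1])
                if len(chosen) == config.n_edges:
                    break

    edge_list = [(baits[bi], preys[pi]) for bi, pi in zip(edges_b, edges_p)]
    roles = {b: "bait" for b in baits}
    roles.update({p: "prey" for p in preys})
    net = InteractionNetwork.from_edges(edge_list, roles=roles)
    members = {baits[i] for i in module_b} | {preys[i] for i in module_p}
    return net, SimTruth(module_members=members)


# ---------------------------------------------------------------------------
# LFQ


@dataclass(frozen=True)
class LfqSimConfig:
    """Parameters of the two-condition label-free quantification simulator.

    Log2 abundances are normal; a designated proximal subset carries a mean
    log2 difference of ``effect_log2`` between the target and reference
    groups.  Entries go missing with probability given by a logistic curve
    of their log2 abundance (lower abundance → more missing), the standard
    missing-not-at-random mechanism of LFQ proteomics.
    """

    n_proteins: int = 3000
    n_replicates_per_group: int = 4
    n_true_proximal: int = 150
    effect_log2: float = 2.0
    intensity_mean_log2: float = 25.0
    intensity_sd_log2: float = 2.0
    noise_sd_log2: float = 0.25
    missing_logistic_midpoint: float = 21.0
    missing_logistic_slope: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_replicates_per_group < 1:
            raise ValueError("n_proteins and n_replicates_per_group must be >= 1")
        if not 0 <= self.n_true_proximal <= self.n_proteins:
            raise ValueError(
                f"n_true_proximal={self.n_true_proximal} exceeds "
                f"n_proteins={self.n_proteins}")
        if self.intensity_sd_log2 < 0 or self.noise_sd_log2 < 0:
            raise ValueError("sd parameters must be >= 0")
        if self.missing_logistic_slope < 0:
            raise ValueError("missing_logistic_slope must be >= 0")


def missingness_probability(log2_abundance: np.ndarray,
                            midpoint: float, slope: float) -> np.ndarray:
    """Probability of censoring as a function of log2 abundance (MNAR)."""
    return 1.0 / (1.0 + np.exp(slope * (np.asarray(log2_abundance) - midpoint)))


def simulate_lfq(config: LfqSimConfig,
                 proximal_idx: np.ndarray | None = None
                 ) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Simulate a raw-scale protein x sample intensity matrix.

    Returns the raw matrix (missing entries are NaN), a sample→group label
    Series (groups ``target`` and ``reference``), and the truth record
    naming the proximal proteins (enriched in ``target``).  Passing
    ``proximal_idx`` fixes the proximal subset explicitly, so two
    experiments targeting the same compartment through different
    modalities can share their ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_proteins, config.n_replicates_per_group
    ids = np.array([f"PROT{i:05d}" for i in range(n)])
    if proximal_idx is None:
        proximal_idx = rng.choice(n, size=config.n_true_proximal, replace=False)
    else:
        proximal_idx = np.asarray(proximal_idx)
        if proximal_idx.max(initial=-1) >= n or len(proximal_idx) > n:
            raise ValueError("proximal_idx out of range")

    base = rng.normal(config.intensity_mean_log2, config.intensity_sd_log2, n)
    effect = np.zeros(n)
    effect[proximal_idx] = config.effect_log2

    samples = [f"target_{i + 1}" for i in range(k)] + \
              [f"reference_{i + 1}" for i in range(k)]
    groups = pd.Series(["target"] * k + ["reference"] * k, index=samples)

    means = np.column_stack([base + effect] * k + [base] * k)
    log2 = means + rng.normal(0.0, config.noise_sd_log2, means.shape)
    p_miss = missingness_probability(log2, config.missing_logistic_midpoint,
                                     config.missing_logistic_slope)
    missing = rng.uniform(0, 1, log2.shape) < p_miss
    raw = np.power(2.0, log2)
    raw[missing] = np.nan

    matrix = pd.DataFrame(raw, index=ids, columns=samples)
    truth = SimTruth(proximal_ids=set(ids[proximal_idx]))
    return matrix, groups, truth
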