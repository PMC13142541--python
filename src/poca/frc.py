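"""Cross-channel Fourier ring correlation (FRC) and line-scan profiles.

FRC is the classical split-half resolution statistic of cryo-EM and
super-resolution imaging.  Here it is applied *across channels*: the
target channel (FISH/IF signal) and the deposition channel (fluorescent
streptavidin bound to deposited biotin) are treated as two independent
measurements of the same underlying structure.  Per spatial-frequency
ring ``r``::

    FRC(r) = Re sum_r F1 . conj(F2) / sqrt(sum_r |F1|^2 . sum_r |F2|^2)

computed on max-projected, Tukey-apodized images.  The finest reliable
scale is the feature size (1/frequency) at which the smoothed curve first
drops below the conventional 1/7 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import windows

__all__ = [
    "ImagePair", "FrcCurve", "CrossingResult",
    "max_intensity_projection", "tukey_window_2d", "frc_curve",
    "threshold_crossing", "aggregate_fovs", "line_scan",
]

DEFAULT_THRESHOLD = 1.0 / 7.0


@dataclass
class ImagePair:
    """Matched target/deposition stacks sharing geometry.

    ``target`` and ``deposition`` are ``(z, y, x)`` intensity arrays (2D
    arrays are accepted and treated as single-slice stacks);
    ``pixel_size`` is the lateral pixel pitch in nm.
    """

    target: np.ndarray
    deposition: np.ndarray
    pixel_size: float
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        self.target = _as_stack(self.target)
        self.deposition = _as_stack(self.deposition)
        if self.target.shape != self.deposition.shape:
            raise ValueError(
                f"channel shapes differ: {self.target.shape} vs "
                f"{self.deposition.shape}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (np.all(np.isfinite(self.target)) and
                np.all(np.isfinite(self.deposition))):
            raise ValueError("intensities must be finite")


def _as_stack(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[None, :, :]
    if a.ndim != 3:
        raise ValueError(f"expected a 2D image or 3D stack, got ndim={a.ndim}")
    return a


@dataclass
class FrcCurve:
    """Per-ring cross-correlation vs spatial frequency for one FOV."""

    frequencies: np.ndarray       # cycles/nm at ring centers
    raw_frc: np.ndarray
    smoothed_frc: np.ndarray
    n_pixels_per_ring: np.ndarray
    feature_sizes: np.ndarray     # nm, = 1/frequency (inf at DC)
    pixel_size: float = 1.0
    fov_id: str = "fov"


@dataclass
class CrossingResult:
    """Threshold-crossing feature size, single-FOV or aggregated."""

    crossed: bool
    feature_size_nm: float | None
    threshold: float = DEFAULT_THRESHOLD
    per_fov: list = field(default_factory=list)
    mean_nm: float | None = None
    sd_nm: float | None = None
    n_uncrossed: int = 0


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Reduce a (z, y, x) stack to 2D by per-pixel maximum along z."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1 or stack.size == 0:
        raise ValueError(f"expected a non-empty 3D stack, got shape {stack.shape}")
    return stack.max(axis=0)


def tukey_window_2d(shape: tuple, taper_fraction: float = 0.1) -> np.ndarray:
    """Separable 2D Tukey (tapered-cosine) apodization window.

    ``taper_fraction=0`` is the rectangular window; ``1`` the Hann window.
    """
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError(f"taper_fraction must be in [0, 1], got {taper_fraction}")
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise ValueError(f"window shape must be at least 2x2, got {shape}")
    wy = windows.tukey(ny, alpha=taper_fraction, sym=True)
    wx = windows.tukey(nx, alpha=taper_fraction, sym=True)
    return np.outer(wy, wx)


def _center_crop_square(img: np.ndarray) -> np.ndarray:
    ny, nx = img.shape
    n = min(ny, nx)
    y0 = (ny - n) // 2
    x0 = (nx - n) // 2
    return img[y0:y0 + n, x0:x0 + n]


def _ring_indices(n: int) -> np.ndarray:
    """Integer-radius ring label of each Fourier pixel of an n x n FFT."""
    k = np.fft.fftfreq(n) * n
    ky, kx = np.meshgrid(k, k, indexing="ij")
    return np.round(np.hypot(ky, kx)).astype(int)


def frc_curve(pair: ImagePair, taper_fraction: float = 0.1,
              smooth_width: int = 5) -> FrcCurve:
    """Compute the cross-channel FRC curve for one field of view.

    The stacks are max-projected, center-cropped to the largest common
    square, apodized with a Tukey window, and Fourier transformed; the
    real part of the ring cross-sum is normalized by the ring power of
    each channel.  The smoothed curve is a centered moving average of
    width ``smooth_width`` rings (reflected at the ends).
    """
    p1 = _center_crop_square(max_intensity_projection(pair.target))
    p2 = _center_crop_square(max_intensity_projection(pair.deposition))
    for name, img in (("target", p1), ("deposition", p2)):
        if not np.any(img):
            raise ValueError(f"degenerate channel: {name} is all zeros")

    win = tukey_window_2d(p1.shape, taper_fraction)
    f1 = np.fft.fft2(p1 * win)
    f2 = np.fft.fft2(p2 * win)

    n = p1.shape[0]
    ring = _ring_indices(n)
    n_rings = n // 2 + 1
    mask = ring < n_rings
    r = ring[mask]
    num = np.bincount(r, weights=(f1 * np.conj(f2)).real[mask], minlength=n_rings)
    d1 = np.bincount(r, weights=np.abs(f1[mask]) ** 2, minlength=n_rings)
    d2 = np.bincount(r, weights=np.abs(f2[mask]) ** 2, minlength=n_rings)
    counts = np.bincount(r, minlength=n_rings)

    denom = np.sqrt(d1 * d2)
    raw = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    smoothed = ndimage.uniform_filter1d(raw, size=smooth_width, mode="reflect")
    freqs = np.arange(n_rings) / (n * pair.pixel_size)
    with np.errstate(divide="ignore"):
        feat = np.divide(1.0, freqs)
    return FrcCurve(frequencies=freqs, raw_frc=raw, smoothed_frc=smoothed,
                    n_pixels_per_ring=counts, feature_sizes=feat,
                    pixel_size=pair.pixel_size, fov_id=pair.fov_id)


def threshold_crossing(curve: FrcCurve,
                       threshold: float = DEFAULT_THRESHOLD) -> CrossingResult:
    """Feature size at which the smoothed curve first drops below threshold.

    The curve is scanned from the coarsest (lowest) non-DC frequency
    upward; the crossing frequency is linearly interpolated between the
    bracketing rings.  If the smoothed curve never falls below the
    threshold the result is flagged uncrossed — fidelity holds to the
    Nyquist limit.
    """
    s = np.asarray(curve.smoothed_frc)
    q = np.asarray(curve.frequencies)
    if s.size < 2:
        raise ValueError("curve has no non-DC rings")
    below = np.nonzero(s[1:] < threshold)[0]
    if below.size == 0:
        return CrossingResult(crossed=False, feature_size_nm=None,
                              threshold=threshold)
    i = below[0] + 1
    if i == 1:
        qc = q[1]  # below threshold from the very first ring
    else:
        s0, s1 = s[i - 1], s[i]
        qc = q[i - 1] + (s0 - threshold) / (s0 - s1) * (q[i] - q[i - 1])
    feat = 1.0 / qc
    return CrossingResult(crossed=True, feature_size_nm=feat,
                          threshold=threshold, per_fov=[feat],
                          mean_nm=feat, sd_nm=None)


def aggregate_fovs(crossings: list[CrossingResult]) -> CrossingResult:
    """Mean ± sample sd (ddof=1) of feature size across fields of view.

    FOVs whose curve never crossed are excluded from the mean and counted
    in ``n_uncrossed``.  At least one crossed FOV is required.
    """
    if not crossings:
        raise ValueError("no crossings supplied")
    sizes = [c.feature_size_nm for c in crossings if c.crossed]
    n_uncrossed = sum(1 for c in crossings if not c.crossed)
    if not sizes:
        raise ValueError("no FOV crossed the threshold")
    mean = float(np.mean(sizes))
    sd = float(np.std(sizes, ddof=1)) if len(sizes) >= 2 else None
    return CrossingResult(crossed=True, feature_size_nm=mean,
                          threshold=crossings[0].threshold, per_fov=sizes,
                          mean_nm=mean, sd_nm=sd, n_uncrossed=n_uncrossed)


def line_scan(image: np.ndarray, p0: tuple, p1: tuple, n_samples: int,
              pixel_size: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity profile along the segment p0→p1 (pixel coords).

    Returns ``(distances_nm, values)`` at ``n_samples`` evenly spaced
    points, distances measured from ``p0`` using ``pixel_size`` nm/pixel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("line_scan expects a 2D image")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("line scan endpoints are identical")
    ny, nx = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image of shape {image.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    ys = p0[0] + t * (p1[0] - p0[0])
    xs = p0[1] + t * (p1[1] - p0[1])
    values = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    length = float(np.hypot(*(p1 - p0))) * pixel_size
    return t * length, values
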