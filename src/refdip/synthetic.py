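"""Synthetic phantom pairs and simulated k-space acquisition.

The generator emulates the reference-driven setting: two images of the
same anatomy that are similar but not identical. The reference is a
superposition of random ellipses inside a skull-like ring; the target is
the same scene with small geometric and intensity perturbations plus one
structure (a lesion analogue) present in only one of the pair. Acquisition
is simulated by masking the centered orthonormal 2-D DFT of the target,
optionally with additive circularly symmetric complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import ComplexImage, KSpaceMeasurement, forward_fft, undersample
from .masks import SamplingMask
from .metrics import ssim

__all__ = [
    "PhantomPair",
    "NoiseModel",
    "make_phantom_pair",
    "simulate_acquisition",
    "shepp_logan",
]

#: windowed-SSIM band that certifies "similar but not identical" pairs
SIMILARITY_BAND = (0.55, 0.98)

_SUPERSAMPLE = 4


@dataclass(frozen=True)
class PhantomPair:
    """A (reference, target) image pair with its generation parameters."""

    reference: ComplexImage
    target: ComplexImage
    similarity_params: tuple[float, float, int]  # (jitter_px, jitter_intensity, n_structures)
    seed: int

    @property
    def n(self) -> int:
        return self.reference.n


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian measurement noise.

    ``sigma`` is interpreted relative to a named statistic of the noiseless
    k-space magnitude (``kspace_std`` or ``kspace_max``), making the noise
    level meaningful across phantoms of arbitrary intensity scale.
    """

    sigma: float = 0.0
    mean: complex = 0.0
    relative_to: str = "kspace_std"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.relative_to not in ("kspace_std", "kspace_max"):
            raise ValueError(
                f"relative_to must be 'kspace_std' or 'kspace_max', got {self.relative_to!r}"
            )


def _render_ellipses(n: int, ellipses: list[dict]) -> np.ndarray:
    """Render additive ellipses at 4× supersampling, then box-downsample.

    Supersampling anti-aliases the edges, which keeps the phantom
    band-limited enough that undersampling artifacts, not pixelation,
    dominate the reconstruction error.
    """
    s = _SUPERSAMPLE
    m = n * s
    coords = (np.arange(m) + 0.5) / s  # pixel units of the target grid
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    img = np.zeros((m, m))
    for e in ellipses:
        cy, cx, ay, ax_, ang, amp = (
            e["cy"], e["cx"], e["ay"], e["ax"], e["angle"], e["amp"],
        )
        ca, sa = np.cos(ang), np.sin(ang)
        u = (yy - cy) * ca + (xx - cx) * sa
        v = -(yy - cy) * sa + (xx - cx) * ca
        img += amp * (((u / ay) ** 2 + (v / ax_) ** 2) <= 1.0)
    return img.reshape(n, s, n, s).mean(axis=(1, 3))


def _draw_scene(n: int, n_structures: int, rng: np.random.Generator) -> list[dict]:
    c = n / 2.0
    scene = [
        # skull-like ring: bright outer ellipse minus interior
        dict(cy=c, cx=c, ay=0.46 * n, ax=0.44 * n, angle=0.0, amp=0.9),
        dict(cy=c, cx=c, ay=0.42 * n, ax=0.40 * n, angle=0.0, amp=-0.7),
    ]
    for _ in range(n_structures):
        scene.append(
            dict(
                cy=c + rng.uniform(-0.25, 0.25) * n,
                cx=c + rng.uniform(-0.25, 0.25) * n,
                ay=rng.uniform(0.04, 0.16) * n,
                ax=rng.uniform(0.04, 0.16) * n,
                angle=rng.uniform(0.0, np.pi),
                amp=rng.uniform(-0.4, 0.6),
            )
        )
    return scene


def _smooth_phase(n: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    c = rng.uniform(-0.5, 0.5, size=5)
    return np.pi / 4 * (
        c[0] + c[1] * yy + c[2] * xx + c[3] * yy * xx
        + c[4] * np.cos(np.pi * np.hypot(yy, xx))
    )


def make_phantom_pair(
    n: int,
    n_structures: int = 8,
    jitter_px: float = 1.5,
    jitter_intensity: float = 0.1,
    phase: str = "none",
    seed: int = 0,
    lesion: bool = True,
) -> PhantomPair:
    """Generate a (reference, target) ellipse-phantom pair.

    The target repeats the reference's structures with centers/axes
    perturbed by at most ``jitter_px`` pixels and intensities by at most
    ``jitter_intensity`` (fractional), plus one small lesion-analogue
    ellipse present in the target only. ``phase='smooth'`` multiplies each
    image by a low-order smooth phase map, making it genuinely complex.
    Pairs failing the similarity band are regenerated (up to 10 attempts).
    """
    if n_structures < 1:
        raise ValueError("n_structures must be ≥ 1")
    if phase not in ("none", "smooth"):
        raise ValueError(f"phase must be 'none' or 'smooth', got {phase!r}")

    for attempt in range(10):
        rng = np.random.default_rng((seed + attempt * 1_000_003) % 2**31)
        scene = _draw_scene(n, n_structures, rng)
        target_scene = []
        for e in scene:
            p = dict(e)
            if jitter_px > 0:
                p["cy"] += rng.uniform(-jitter_px, jitter_px)
                p["cx"] += rng.uniform(-jitter_px, jitter_px)
                p["ay"] = max(1.0, p["ay"] + rng.uniform(-jitter_px, jitter_px))
                p["ax"] = max(1.0, p["ax"] + rng.uniform(-jitter_px, jitter_px))
            if jitter_intensity > 0:
                p["amp"] *= 1.0 + rng.uniform(-jitter_intensity, jitter_intensity)
            target_scene.append(p)
        if lesion:
            c = n / 2.0
            target_scene.append(
                dict(
                    cy=c + rng.uniform(-0.2, 0.2) * n,
                    cx=c + rng.uniform(-0.2, 0.2) * n,
                    ay=rng.uniform(0.03, 0.06) * n,
                    ax=rng.uniform(0.03, 0.06) * n,
                    angle=rng.uniform(0.0, np.pi),
                    amp=0.5,
                )
            )

        ref = _render_ellipses(n, scene)
        tgt = _render_ellipses(n, target_scene)
        scale = max(ref.max(), tgt.max())
        if scale <= 0:
            continue
        ref, tgt = np.clip(ref / scale, 0, None), np.clip(tgt / scale, 0, None)

        ref_c, tgt_c = ref.astype(complex), tgt.astype(complex)
        if phase == "smooth":
            ref_c = ref_c * np.exp(1j * _smooth_phase(n, rng))
            tgt_c = tgt_c * np.exp(1j * _smooth_phase(n, rng))

        identical = jitter_px == 0 and jitter_intensity == 0 and not lesion
        if identical:
            tgt_c = ref_c.copy()
            return PhantomPair(
                ComplexImage(ref_c), ComplexImage(tgt_c),
                (jitter_px, jitter_intensity, n_structures), seed,
            )
        s = ssim(np.abs(ref_c), np.abs(tgt_c), mode="windowed")
        if SIMILARITY_BAND[0] <= s <= SIMILARITY_BAND[1]:
            return PhantomPair(
                ComplexImage(ref_c), ComplexImage(tgt_c),
                (jitter_px, jitter_intensity, n_structures), seed,
            )
    raise RuntimeError(
        f"could not generate a pair in the SSIM similarity band {SIMILARITY_BAND} "
        f"after 10 attempts (n={n}, jitter_px={jitter_px})"
    )


def shepp_logan(n: int) -> ComplexImage:
    """Classic Shepp–Logan head phantom resized to N×N (regression fixture)."""
    from skimage.data import shepp_logan_phantom
    from skimage.transform import resize

    img = resize(shepp_logan_phantom(), (n, n), anti_aliasing=True)
    return ComplexImage(img.astype(complex))


def simulate_acquisition(
    target: ComplexImage,
    mask: SamplingMask,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> KSpaceMeasurement:
    """Masked DFT of the target with optional complex Gaussian k-space noise.

    The noise is circularly symmetric: independent real and imaginary
    parts, each with standard deviation ``sigma·scale/√2`` so that the
    complex noise magnitude has std ``sigma·scale``, where ``scale`` is
    the k-space statistic named by the noise model. ``sigma = 0`` (or no
    noise model) reproduces the exact undersampled transform.
    """
    grid = forward_fft(target)
    if noise is not None and noise.sigma > 0:
        k = grid.data
        scale = float(np.std(k)) if noise.relative_to == "kspace_std" else float(
            np.abs(k).max()
        )
        rng = np.random.default_rng(seed)
        s = noise.sigma * scale / np.sqrt(2.0)
        eps = rng.normal(0, s, k.shape) + 1j * rng.normal(0, s, k.shape)
        from .fourier import KSpaceGrid

        grid = KSpaceGrid(k + noise.mean + eps)
    return undersample(grid, mask)
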