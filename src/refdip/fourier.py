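"""Centered, orthonormal 2-D Fourier encoding and undersampled variants.

The forward operator F maps an N×N complex image to its k-space grid with
the DC component at the array center; the orthonormal ("ortho") scaling
makes F unitary, so Parseval holds exactly and data-consistency residuals
are scale-comparable across image sizes. The undersampled operator F_u is
the composition of F with restriction to a :class:`~refdip.masks.SamplingMask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import SamplingMask

__all__ = [
    "ComplexImage",
    "KSpaceGrid",
    "KSpaceMeasurement",
    "forward_fft",
    "inverse_fft",
    "undersample",
    "zero_fill",
]

MIN_SIZE = 8


def _validate_square(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=np.complex128)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{what} must be a square 2-D array, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIZE:
        raise ValueError(f"{what} side must be ≥ {MIN_SIZE}, got {arr.shape[0]}")
    if not (np.all(np.isfinite(arr.real)) and np.all(np.isfinite(arr.imag))):
        raise ValueError(f"{what} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class ComplexImage:
    """N×N complex-valued image (dimensionless intensity).

    ``pixel_spacing`` (mm per pixel) is carried as metadata only and plays
    no role in any computation.
    """

    data: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate_square(self.data, "image"))

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def norm(self) -> float:
        return float(np.linalg.norm(self.data))


@dataclass(frozen=True)
class KSpaceGrid:
    """Fully gridded k-space samples, DC at the array center."""

    data: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate_square(self.data, "k-space grid"))

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class KSpaceMeasurement:
    """Undersampled k-space data: a mask and a dense grid, zero where unmeasured.

    Storing the dense grid (rather than a packed vector) makes the
    data-correction substitution an exact elementwise ``where``. A
    measurement with an empty mask is representable — reconstruction entry
    points reject it via :attr:`is_valid`.
    """

    mask: SamplingMask
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = _validate_square(self.data, "measurement grid")
        if arr.shape != self.mask.data.shape:
            raise ValueError(
                f"measurement shape {arr.shape} does not match mask shape "
                f"{self.mask.data.shape}"
            )
        if np.any(arr[~self.mask.data] != 0):
            arr = np.where(self.mask.data, arr, 0.0)
        object.__setattr__(self, "data", arr)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mask.n_sampled

    @property
    def is_valid(self) -> bool:
        """False for the degenerate empty-mask measurement."""
        return not self.mask.is_empty

    def values(self) -> np.ndarray:
        """The measured values as a flat vector, row-major over mask-true sites."""
        return self.data[self.mask.data]


def forward_fft(image: ComplexImage | np.ndarray) -> KSpaceGrid:
    """Unitary centered 2-D DFT (image → k-space); energy preserving."""
    x = image.data if isinstance(image, ComplexImage) else _validate_square(image, "image")
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))
    return KSpaceGrid(k)


def inverse_fft(grid: KSpaceGrid | np.ndarray) -> ComplexImage:
    """Exact inverse of :func:`forward_fft` up to floating-point roundoff."""
    k = grid.data if isinstance(grid, KSpaceGrid) else _validate_square(grid, "k-space grid")
    x = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))
    return ComplexImage(x)


def undersample(grid: KSpaceGrid, mask: SamplingMask) -> KSpaceMeasurement:
    """Restrict a k-space grid to the sampled locations of ``mask``."""
    if grid.shape != mask.data.shape:
        raise ValueError(
            f"grid shape {grid.shape} does not match mask shape {mask.data.shape}"
        )
    return KSpaceMeasurement(mask, np.where(mask.data, grid.data, 0.0))


def zero_fill(measurement: KSpaceMeasurement) -> ComplexImage:
    """Baseline reconstruction: inverse transform with missing k-space zeroed."""
    return inverse_fft(KSpaceGrid(measurement.data))
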