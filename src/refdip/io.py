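"""File I/O: NIfTI and HDF5 images, HDF5 k-space measurements, PNG masks.

Complex images are written to NIfTI as complex64 volumes (nibabel handles
the complex NIfTI datatypes natively); on read, a trailing length-2 axis
is also accepted as a real/imaginary pair. HDF5 layouts:

* image files — datasets ``/image/real`` and ``/image/imag``;
* k-space files — ``/kspace/real``, ``/kspace/imag`` and ``/mask`` with
  mask metadata (family, target rate, seed) as attributes on ``/mask``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .fourier import ComplexImage, KSpaceMeasurement
from .masks import SamplingMask

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_measurement",
    "load_measurement",
    "save_mask_png",
    "load_mask_png",
]

_IDENTITY_AFFINE = np.eye(4)


def save_image(image: ComplexImage, path: str | Path) -> None:
    """Write a complex image to NIfTI (.nii/.nii.gz) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("image/real", data=image.data.real)
            f.create_dataset("image/imag", data=image.data.imag)
            if image.pixel_spacing is not None:
                f["image"].attrs["pixel_spacing_mm"] = image.pixel_spacing
        return
    affine = _IDENTITY_AFFINE.copy()
    if image.pixel_spacing is not None:
        affine[0, 0] = affine[1, 1] = image.pixel_spacing
    nib.save(nib.Nifti1Image(image.data.astype(np.complex64), affine), str(path))


def load_image(path: str | Path) -> ComplexImage:
    """Read a complex image from NIfTI or HDF5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["image/real"][()] + 1j * f["image/imag"][()]
            spacing = f["image"].attrs.get("pixel_spacing_mm")
        return ComplexImage(data, pixel_spacing=spacing)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim == 3 and data.shape[-1] == 2:  # real/imag pair volume
        data = data[..., 0] + 1j * data[..., 1]
    spacing = float(img.affine[0, 0])
    return ComplexImage(data.astype(np.complex128), pixel_spacing=spacing or None)


def save_mask(mask: SamplingMask, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("mask", data=mask.data.astype(np.uint8))
        ds.attrs["family"] = mask.family
        ds.attrs["target_rate"] = mask.target_rate
        ds.attrs["seed"] = mask.seed


def load_mask(path: str | Path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        ds = f["mask"]
        return SamplingMask(
            ds[()].astype(bool),
            family=str(ds.attrs.get("family", "unknown")),
            target_rate=float(ds.attrs.get("target_rate", float(ds[()].mean()))),
            seed=int(ds.attrs.get("seed", 0)),
        )


def save_measurement(measurement: KSpaceMeasurement, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace/real", data=measurement.data.real)
        f.create_dataset("kspace/imag", data=measurement.data.imag)
        ds = f.create_dataset("mask", data=measurement.mask.data.astype(np.uint8))
        ds.attrs["family"] = measurement.mask.family
        ds.attrs["target_rate"] = measurement.mask.target_rate
        ds.attrs["seed"] = measurement.mask.seed


def load_measurement(path: str | Path) -> KSpaceMeasurement:
    with h5py.File(path, "r") as f:
        data = f["kspace/real"][()] + 1j * f["kspace/imag"][()]
        ds = f["mask"]
        mask = SamplingMask(
            ds[()].astype(bool),
            family=str(ds.attrs.get("family", "unknown")),
            target_rate=float(ds.attrs.get("target_rate", float(ds[()].mean()))),
            seed=int(ds.attrs.get("seed", 0)),
        )
    return KSpaceMeasurement(mask, data)


def save_mask_png(mask: SamplingMask, path: str | Path) -> None:
    """Write the mask as an 8-bit PNG (sampled = 255)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.data.astype(np.uint8) * 255))


def load_mask_png(
    path: str | Path, family: str = "unknown", target_rate: float | None = None, seed: int = 0
) -> SamplingMask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    data = arr > 127
    return SamplingMask(
        data,
        family=family,
        target_rate=float(data.mean()) if target_rate is None else target_rate,
        seed=seed,
    )
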