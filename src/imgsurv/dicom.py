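"""Thin DICOM adapter: a CT series + mask images -> the standard manifest.

Reads a directory of single-frame DICOM files with pydicom, sorts slices by
``InstanceNumber`` (falling back to filename), applies rescale slope and
intercept to get Hounsfield units, windows intensities to [0, 255], pairs
each slice with a same-index binary mask PNG, and writes the
``subject_id,slice_path,mask_path,slice_index`` manifest consumed by the
rest of the pipeline. Slices whose mask is empty are skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .imaging import ImageSample, write_manifest

logger = logging.getLogger(__name__)

#: Default soft-tissue window (center 40 HU, width 400 HU).
DEFAULT_WINDOW = (40.0, 400.0)


def _window_to_uint8(hu: np.ndarray, center: float, width: float) -> np.ndarray:
    lo = center - width / 2.0
    scaled = np.clip((hu - lo) / width, 0.0, 1.0) * 255.0
    return np.round(scaled).astype(np.float32)


def read_dicom_series(series_dir) -> list[np.ndarray]:
    """Sorted raw-HU slices of a single-frame DICOM series."""
    import pydicom

    paths = sorted(Path(series_dir).glob("*.dcm"))
    if not paths:
        raise ValueError(f"no .dcm files in {series_dir}")

    def sort_key(p: Path):
        ds = pydicom.dcmread(p, stop_before_pixels=True)
        return (int(getattr(ds, "InstanceNumber", 0)), p.name)

    slices = []
    for p in sorted(paths, key=sort_key):
        ds = pydicom.dcmread(p)
        hu = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(hu * slope + intercept)
    return slices


def dicom_to_manifest(
    series_dir,
    mask_dir,
    out_dir,
    subject_id: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> Path:
    """Convert one subject's DICOM series + mask PNGs into a cohort manifest.

    ``mask_dir`` must hold one PNG per slice, named so lexicographic order
    matches the series order ({0,1} or {0,255} values). Returns the manifest
    path; slices without any ROI pixel are dropped with a log message.
    """
    from PIL import Image

    hu_slices = read_dicom_series(series_dir)
    mask_paths = sorted(Path(mask_dir).glob("*.png"))
    if len(mask_paths) != len(hu_slices):
        raise ValueError(
            f"{len(hu_slices)} DICOM slices but {len(mask_paths)} masks"
        )
    center, width = window
    samples = []
    for i, (hu, mp) in enumerate(zip(hu_slices, mask_paths)):
        with Image.open(mp) as im:
            mask = (np.asarray(im.convert("L")) > 0).astype(np.uint8)
        if mask.shape != hu.shape:
            raise ValueError(
                f"slice {i}: mask shape {mask.shape} != image shape {hu.shape}"
            )
        if mask.sum() == 0:
            logger.info("skipping slice %d of %s: empty mask", i, subject_id)
            continue
        pixels = _window_to_uint8(hu, center, width) * mask
        samples.append(ImageSample(pixels, mask, subject_id, i))
    if not samples:
        raise ValueError(f"subject {subject_id!r}: no contoured slices")
    return write_manifest(samples, out_dir)
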