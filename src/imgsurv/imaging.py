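"""Tumor-slice preprocessing: masking, ROI filtering, selection, standardization.

The pipeline mirrors how contoured CT slices are prepared for a fixed-size
grayscale network input: zero out everything outside the radiologist's
contour, drop slices whose region of interest (ROI) is too small to carry
texture (fewer than 250 pixels by default), rank the remainder by ROI size
with mean ROI intensity as tiebreak, and crop a fixed window centered on the
ROI centroid with intensities min-max rescaled to [0, 255] over ROI pixels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSample",
    "MIN_ROI_PIXELS",
    "MODEL_INPUT_SIDE",
    "apply_mask",
    "roi_size",
    "rank_and_select",
    "standardize",
    "aggregate_patient",
    "load_manifest",
    "write_manifest",
]

#: Slices with fewer ROI pixels than this are excluded from training.
MIN_ROI_PIXELS = 250
#: Side length of the network's square grayscale input.
MODEL_INPUT_SIDE = 140


@dataclass(frozen=True)
class ImageSample:
    """A 2-D grayscale slice with a binary ROI mask (1 = tumor)."""

    pixels: np.ndarray
    mask: np.ndarray
    subject_id: str
    slice_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        mk = np.asarray(self.mask)
        if mk.dtype != np.uint8:
            mk = (mk > 0).astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mask", mk)
        if px.ndim != 2 or px.shape != mk.shape:
            raise ValueError(
                f"pixels {px.shape} and mask {mk.shape} must be 2-D and shape-matched"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")

    @property
    def mean_roi_intensity(self) -> float:
        if self.mask.sum() == 0:
            return 0.0
        return float(self.pixels[self.mask == 1].mean())


def apply_mask(sample: ImageSample) -> ImageSample:
    """Zero every pixel outside the contoured region. Idempotent."""
    return replace(sample, pixels=sample.pixels * sample.mask)


def roi_size(sample: ImageSample) -> int:
    """Number of pixels inside the contour."""
    return int(sample.mask.sum())


def rank_and_select(
    slices: Iterable[ImageSample],
    k: int,
    min_roi: int = MIN_ROI_PIXELS,
) -> list[ImageSample]:
    """Keep slices with at least ``min_roi`` ROI pixels; return the top ``k``.

    Ranking is by ROI pixel count descending, with mean ROI intensity
    descending as the tiebreak, so the selection is deterministic and any
    nonempty result automatically honors the minimum ROI size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [s for s in slices if roi_size(s) >= min_roi]
    if not eligible:
        warnings.warn("no slices meet the minimum ROI size", stacklevel=2)
        return []
    ranked = sorted(
        eligible, key=lambda s: (-roi_size(s), -s.mean_roi_intensity)
    )
    return ranked[:k]


def standardize(sample: ImageSample, side: int = MODEL_INPUT_SIDE) -> ImageSample:
    """Crop/pad to a ``side x side`` window on the ROI centroid and rescale.

    The window start is ``floor(centroid) - side // 2`` in each axis (so a
    second pass reproduces the same window exactly); regions outside the
    original image are zero-padded. Intensities are min-max rescaled to
    [0, 255] using ROI pixels only; background stays 0; a constant-intensity
    ROI maps to 255 everywhere inside the contour.

    When the ROI fits inside the window the operation is exactly idempotent;
    an ROI wider than ``side`` is truncated at the window edge (with a
    warning), and repeated application may then shift the window.
    """
    masked = apply_mask(sample)
    rows, cols = np.nonzero(masked.mask)
    if rows.size == 0:
        raise ValueError(f"subject {sample.subject_id!r}: empty ROI")
    cr = int(np.floor(rows.mean()))
    cc = int(np.floor(cols.mean()))
    r0 = cr - side // 2
    c0 = cc - side // 2
    out_px = np.zeros((side, side), dtype=np.float32)
    out_mk = np.zeros((side, side), dtype=np.uint8)
    h, w = masked.pixels.shape
    src_r = slice(max(r0, 0), min(r0 + side, h))
    src_c = slice(max(c0, 0), min(c0 + side, w))
    dst_r = slice(src_r.start - r0, src_r.stop - r0)
    dst_c = slice(src_c.start - c0, src_c.stop - c0)
    out_px[dst_r, dst_c] = masked.pixels[src_r, src_c]
    out_mk[dst_r, dst_c] = masked.mask[src_r, src_c]
    if int(out_mk.sum()) < rows.size:
        warnings.warn(
            f"subject {sample.subject_id!r}: ROI larger than the "
            f"{side}x{side} window was truncated", stacklevel=2,
        )

    roi = out_mk == 1
    vals = out_px[roi]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        out_px[roi] = (out_px[roi] - lo) / (hi - lo) * 255.0
    else:
        out_px[roi] = 255.0
    out_px[~roi] = 0.0
    return ImageSample(out_px, out_mk, sample.subject_id, sample.slice_index)


def aggregate_patient(
    slices: Sequence[ImageSample],
    per_slice_hazards: np.ndarray,
    mode: Literal["largest_slice", "mean"] = "largest_slice",
) -> tuple[list[str], np.ndarray]:
    """Reduce per-slice hazard rows to one row per patient.

    ``mean`` averages hazards across each patient's slices per interval;
    ``largest_slice`` keeps only the row of the slice with the largest ROI
    (mean ROI intensity as tiebreak). Patients appear in first-seen order.
    """
    slices = list(slices)
    h = np.atleast_2d(np.asarray(per_slice_hazards, dtype=float))
    if len(slices) == 0:
        raise ValueError("no slices to aggregate")
    if h.shape[0] != len(slices):
        raise ValueError("need one hazard row per slice")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(slices):
        if s.subject_id not in groups:
            groups[s.subject_id] = []
            order.append(s.subject_id)
        groups[s.subject_id].append(i)
    rows = np.empty((len(order), h.shape[1]))
    for gi, sid in enumerate(order):
        idx = groups[sid]
        if mode == "mean":
            rows[gi] = h[idx].mean(axis=0)
        elif mode == "largest_slice":
            best = max(
                idx,
                key=lambda i: (roi_size(slices[i]), slices[i].mean_roi_intensity),
            )
            rows[gi] = h[best]
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
    return order, rows


# ---------------------------------------------------------------------------
# Manifest I/O: CSV `subject_id,slice_path,mask_path,slice_index` with 8-bit
# grayscale PNGs for slices and {0,1} or {0,255} PNGs for masks.


def _read_png(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float32)


def load_manifest(manifest_csv) -> list[ImageSample]:
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    required = {"subject_id", "slice_path", "mask_path", "slice_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    base = manifest_csv.parent
    samples = []
    for row in df.itertuples(index=False):
        px = _read_png(base / str(row.slice_path))
        mk = _read_png(base / str(row.mask_path))
        samples.append(
            ImageSample(px, (mk > 0).astype(np.uint8), str(row.subject_id),
                        int(row.slice_index))
        )
    logger.info("loaded %d slices from %s", len(samples), manifest_csv)
    return samples


def write_manifest(samples: Sequence[ImageSample], out_dir) -> Path:
    """Write PNG slices + masks and the manifest CSV; return the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        stem = f"{s.subject_id}_s{s.slice_index:03d}"
        slice_rel = f"images/{stem}.png"
        mask_rel = f"images/{stem}_mask.png"
        Image.fromarray(np.round(s.pixels).astype(np.uint8)).save(out_dir / slice_rel)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / mask_rel)
        rows.append((s.subject_id, slice_rel, mask_rel, s.slice_index))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(
        rows, columns=["subject_id", "slice_path", "mask_path", "slice_index"]
    ).to_csv(manifest, index=False)
    return manifest
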