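"""Synthetic cohorts: masked tumor-like slices with a known hazard signal.

Each subject gets a latent prognostic score ``z ~ N(0, 1)``. The image is an
elliptical ROI on a black background filled with smoothed random texture,
soft-thresholded so that the *fraction of bright blob area* increases
monotonically with ``z``; the mean ROI intensity therefore rises with ``z``
as well. Because the link changes the bright-area fraction rather than a
global intensity offset, the signal is invariant to the per-slice min-max
rescaling applied at preprocessing.
Event times are exponential with rate ``baseline_rate * exp(beta_signal * z)``
and censoring is an independent uniform draw on ``[0, censor_horizon]``.

The generator emulates what a radiomics premise needs — an ROI-confined
texture/intensity cue that carries prognosis — not anatomically realistic
CT: there is no anatomy outside the contour, no scanner noise model, and no
3-D structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import ImageSample, write_manifest
from .survival import SurvivalRecord, write_survival_csv

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_feature_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for an image cohort.

    Defaults model a poor-prognosis cancer cohort: exponential event times
    with ~1-year median under ``z = 0`` (``baseline_rate`` = ln 2 / 365 per
    day), uniform administrative censoring over a 5-year accrual window, one
    contoured slice per subject, and an ROI radius of 15–30% of the image
    side.
    """

    n_subjects: int
    seed: int
    image_side: int = 140
    slices_per_subject: int = 1
    beta_signal: float = 1.0
    baseline_rate: float = float(np.log(2) / 365.0)
    censor_horizon: float = 1825.0
    blob_scale: float = 0.025
    intensity_range: tuple[float, float] = (30.0, 225.0)
    roi_radius_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.slices_per_subject < 1:
            raise ValueError("n_subjects and slices_per_subject must be >= 1")
        if self.image_side < 16:
            raise ValueError("image_side too small for a meaningful ROI")
        if self.baseline_rate <= 0 or self.censor_horizon <= 0:
            raise ValueError("baseline_rate and censor_horizon must be positive")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("degenerate ROI radius range")
        if hi * 2 >= self.image_side:
            raise ValueError("ROI radius too large for the image side")

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.roi_radius_range is not None:
            return self.roi_radius_range
        return (0.15 * self.image_side, 0.30 * self.image_side)


@dataclass
class SyntheticCohort:
    samples: list[ImageSample]
    records: list[SurvivalRecord]
    truth: pd.DataFrame = field(repr=False)  # subject_id, z, event_time, censor_time


def _render_slice(rng: np.random.Generator, cfg: SyntheticConfig,
                  z: float) -> tuple[np.ndarray, np.ndarray]:
    side = cfg.image_side
    lo_r, hi_r = cfg.radius_range
    a = rng.uniform(lo_r, hi_r)
    b = rng.uniform(lo_r, hi_r)
    theta = rng.uniform(0, np.pi)
    cy = side / 2 + rng.uniform(-0.1, 0.1) * side
    cx = side / 2 + rng.uniform(-0.1, 0.1) * side
    yy, xx = np.mgrid[0:side, 0:side]
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    mask = ((yr / a) ** 2 + (xr / b) ** 2 <= 1.0).astype(np.uint8)

    field_ = gaussian_filter(rng.standard_normal((side, side)),
                             sigma=cfg.blob_scale * side)
    f01 = field_ - field_.min()
    if f01.max() > 0:
        f01 = f01 / f01.max()
    # soft threshold: higher z lowers the cut, growing the bright-blob area
    tau = float(np.clip(0.5 - 0.18 * z, 0.08, 0.92))
    w = 1.0 / (1.0 + np.exp(-(f01 - tau) / 0.07))
    lo_i, hi_i = cfg.intensity_range
    pixels = np.round((lo_i + (hi_i - lo_i) * w) * mask).astype(np.float32)
    return np.clip(pixels, 0, 255), mask


def simulate_cohort(cfg: SyntheticConfig, out_dir=None) -> SyntheticCohort:
    """Draw a full image cohort; optionally write PNGs + CSVs to ``out_dir``.

    Deterministic for a given config (same seed twice gives bit-identical
    images and tables). When ``out_dir`` is given, writes the manifest CSV,
    the survival table, the latent-truth table and one PNG pair per slice —
    exactly the on-disk formats the training CLI consumes.
    """
    rng = np.random.default_rng(cfg.seed)
    z = rng.standard_normal(cfg.n_subjects)
    rate = cfg.baseline_rate * np.exp(cfg.beta_signal * z)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0, cfg.censor_horizon, cfg.n_subjects)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    samples: list[ImageSample] = []
    records: list[SurvivalRecord] = []
    width = len(str(cfg.n_subjects))
    for i in range(cfg.n_subjects):
        sid = f"S{i:0{width}d}"
        records.append(SurvivalRecord(sid, float(max(observed[i], 1e-3)),
                                      int(event[i])))
        for s in range(cfg.slices_per_subject):
            px, mk = _render_slice(rng, cfg, float(z[i]))
            samples.append(ImageSample(px, mk, sid, s))
    truth = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "z": z,
            "event_time": event_time,
            "censor_time": censor_time,
        }
    )
    cohort = SyntheticCohort(samples, records, truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_manifest(samples, out_dir)
        write_survival_csv(records, out_dir / "survival.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return cohort


def simulate_feature_cohort(
    n: int,
    p: int,
    beta: Sequence[float] | np.ndarray,
    baseline_rate: float = float(np.log(2) / 365.0),
    censor_horizon: float = 1825.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SurvivalRecord]]:
    """Tabular analogue: standard-normal features, exponential event times
    with rate ``baseline_rate * exp(x' beta)``, uniform censoring.

    Pass ``censor_horizon=np.inf`` for a censoring-free cohort.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ValueError(f"beta must have shape ({p},)")
    if n < 1 or baseline_rate <= 0 or censor_horizon <= 0:
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    rate = baseline_rate * np.exp(x @ beta)
    event_time = rng.exponential(1.0 / rate)
    if np.isinf(censor_horizon):
        censor_time = np.full(n, np.inf)
    else:
        censor_time = rng.uniform(0, censor_horizon, n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    width = len(str(n))
    ids = [f"S{i:0{width}d}" for i in range(n)]
    features = pd.DataFrame(x, columns=[f"f{j+1}" for j in range(p)])
    features.insert(0, "subject_id", ids)
    records = [
        SurvivalRecord(ids[i], float(max(observed[i], 1e-3)), int(event[i]))
        for i in range(n)
    ]
    return features, records
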