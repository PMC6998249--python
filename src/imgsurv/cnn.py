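"""The survival CNN: architecture, two-stage training, prediction, features.

The network maps a masked 140x140 grayscale tumor slice to one conditional
failure probability per follow-up interval. Three blocks of two 3x3
convolutions (32 filters each, batch-normalized, ReLU) are followed by max
pooling (2x2, then 3x3, 3x3) and dropout 0.5; global average pooling over
the 32 channels feeds a 19-unit dense feature layer (627 parameters) and a
sigmoid hazard head with one unit per interval. Training minimizes the
discrete-time hazard likelihood loss.

Transfer learning is freeze-and-finetune: pretrain everything on a large
source cohort, then freeze the convolutional backbone (batch-norm layers run
on their frozen inference statistics) and update only the dense feature
layer — plus, by default, the hazard head, since the head must adapt to the
target disease's survival pattern.

Two entry points: the functional operations (`build_model`, `pretrain`,
`finetune`, `predict_hazards`, `extract_features`) and the
:class:`CNNSurvival` / :class:`CNNSurvivalResults` model-object pair that
wraps them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .imaging import ImageSample, aggregate_patient
from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2D,
    ReLU,
    Sequential,
)
from .survival import (
    DiscreteTargets,
    IntervalGrid,
    SurvivalCurve,
    SurvivalRecord,
    discrete_survival_loss,
    encode_targets,
    hazards_to_survival,
    make_interval_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "build_model",
    "pretrain",
    "finetune",
    "predict_hazards",
    "extract_features",
    "CNNSurvival",
    "CNNSurvivalResults",
]

_BACKBONE_LAYERS = frozenset(
    {f"conv{i}" for i in range(1, 7)} | {f"bn{i}" for i in range(1, 7)}
)
_FEATURE_LAYER = "feature_dense"
_HEAD_LAYER = "hazard_head"


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters. Defaults pin the reference design:
    six 3x3 convolutions with 32 filters, pools [2, 3, 3], dropout 0.5,
    19 dense features."""

    n_intervals: int
    input_side: int = 140
    n_filters: int = 32
    kernel: int = 3
    pool_sizes: tuple[int, int, int] = (2, 3, 3)
    dropout_rate: float = 0.5
    feature_dim: int = 19

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        side = self.input_side
        for p in self.pool_sizes:
            side //= p
        if side < 1:
            raise ValueError(
                f"input side {self.input_side} too small for pool chain "
                f"{self.pool_sizes}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. The reference schedule: Adam at learning rate
    1e-4, 50 pretraining epochs, 20 finetuning epochs, no augmentation."""

    learning_rate: float = 1e-4
    pretrain_epochs: int = 50
    finetune_epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    augmentation: bool = False
    freeze_policy: Literal["head_and_features", "features_only"] = (
        "head_and_features"
    )

    def __post_init__(self) -> None:
        if self.augmentation:
            raise NotImplementedError("training is defined without augmentation")


def build_model(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> Sequential:
    """Instantiate the network with He-initialized weights."""
    rng = np.random.default_rng(seed)
    f = spec.n_filters
    layers: list[tuple[str, object]] = []
    in_ch = 1
    conv_i = 0
    for b, pool in enumerate(spec.pool_sizes, start=1):
        for _ in range(2):
            conv_i += 1
            layers.append(
                (f"conv{conv_i}",
                 Conv2D(in_ch, f, spec.kernel, rng=rng, dtype=dtype,
                        is_first=conv_i == 1))
            )
            layers.append((f"bn{conv_i}", BatchNorm2D(f, dtype=dtype)))
            layers.append((f"relu{conv_i}", ReLU()))
            in_ch = f
        layers.append((f"pool{b}", MaxPool2D(pool)))
        layers.append((f"drop{b}", Dropout(spec.dropout_rate, rng=rng)))
    layers.append(("gap", GlobalAvgPool()))
    layers.append(
        (_FEATURE_LAYER, Dense(f, spec.feature_dim, rng=rng, dtype=dtype))
    )
    layers.append(("feature_relu", ReLU()))
    layers.append(
        (_HEAD_LAYER,
         Dense(spec.feature_dim, spec.n_intervals, rng=rng, dtype=dtype,
               zero_init=True))
    )
    return Sequential(layers)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def samples_to_batch(samples: Sequence[ImageSample], side: int,
                     dtype=np.float32) -> np.ndarray:
    """Stack standardized slices into an (n, side, side, 1) tensor in [0, 1]."""
    arrs = []
    for s in samples:
        if s.pixels.shape != (side, side):
            raise ValueError(
                f"subject {s.subject_id!r}: slice shape {s.pixels.shape} != "
                f"({side}, {side}); run imaging.standardize first"
            )
        arrs.append(s.pixels)
    return (np.stack(arrs)[:, :, :, None] / 255.0).astype(dtype)


def batch_loss(net: Sequential, x: np.ndarray, targets: DiscreteTargets) -> float:
    """Hazard-likelihood loss of the network on a prepared batch (train-mode
    forward, so the value matches what the optimizer sees)."""
    h = _sigmoid(net.forward(x, train=True))
    return discrete_survival_loss(h, targets)


def _run_training(
    net: Sequential,
    x: np.ndarray,
    targets: DiscreteTargets,
    epochs: int,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam on the hazard likelihood; returns per-epoch total loss.

    The optimizer descends the per-batch mean subject loss (the likelihood
    sum divided by batch size) so the learning rate is batch-size independent;
    the recorded history is the summed loss over the epoch's batches.
    """
    n = x.shape[0]
    opt = Adam(net, lr=cfg.learning_rate)
    d_all = targets.event_flags.astype(x.dtype)
    r_all = targets.atrisk_flags.astype(x.dtype)
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n) if cfg.batch_size < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = net.forward(x[idx], train=True)
            h = _sigmoid(z)
            d, r = d_all[idx], r_all[idx]
            hc = np.clip(h, 1e-7, 1 - 1e-7)
            loss = float(-(d * r * np.log(hc)).sum() - ((1 - d) * r * np.log1p(-hc)).sum())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"hazard range [{h.min()}, {h.max()}]"
                )
            epoch_loss += loss
            # d(loss)/d(logit) for the masked Bernoulli likelihood
            dz = (r * (h - d) / idx.size).astype(x.dtype)
            net.backward(dz)
            opt.step()
        history.append(epoch_loss)
        logger.info("epoch %d/%d: loss %.4f", epoch + 1, epochs, epoch_loss)
    return history


def _init_head_bias(net: Sequential, targets: DiscreteTargets) -> None:
    """Start a fresh hazard head at the marginal interval event rates.

    With the head weights at zero, initializing each output bias to
    ``logit(events_j / at_risk_j)`` makes the initial hazards match the
    cohort's marginal discrete hazard, so early gradients carry
    discriminative signal instead of a global level correction (which the
    non-negative features would otherwise absorb with an arbitrary
    feature-to-hazard coupling). Applied only to an untrained head.
    """
    head = net[_HEAD_LAYER]
    if np.any(head.params["weight"] != 0) or np.any(head.params["bias"] != 0):
        return
    d = targets.event_flags.sum(axis=0).astype(float)
    r = np.maximum(targets.atrisk_flags.sum(axis=0).astype(float), 1.0)
    rate = np.clip(d / r, 1e-3, 1 - 1e-3)
    head.params["bias"] = np.log(rate / (1 - rate)).astype(
        head.params["bias"].dtype
    )


def pretrain(
    net: Sequential,
    samples: Sequence[ImageSample],
    targets: DiscreteTargets,
    cfg: TrainConfig,
    spec: ModelSpec,
    epochs: int | None = None,
) -> list[float]:
    """Stage 1: train every layer. Returns the per-epoch loss history."""
    net.set_trainable(None)
    x = samples_to_batch(samples, spec.input_side)
    rng = np.random.default_rng(cfg.seed)
    n_epochs = cfg.pretrain_epochs if epochs is None else epochs
    if n_epochs > 0:
        _init_head_bias(net, targets)
    logger.info(
        "pretraining: %d samples, %d epochs, %d trainable parameters",
        len(samples), n_epochs, net.n_parameters(trainable_only=True),
    )
    return _run_training(net, x, targets, n_epochs, cfg, rng)


def finetune(
    net: Sequential,
    samples: Sequence[ImageSample],
    targets: DiscreteTargets,
    cfg: TrainConfig,
    spec: ModelSpec,
    epochs: int | None = None,
) -> list[float]:
    """Stage 2: freeze the convolutional backbone and adapt the dense layers.

    Under the default ``head_and_features`` policy the 19-unit feature layer
    and the hazard head are updated; under ``features_only`` just the feature
    layer (the strict reading of "all weights frozen except the final dense
    layer"). Frozen batch-norm layers run on their pretrained inference
    statistics, so every backbone parameter and buffer stays bit-identical.
    """
    if cfg.freeze_policy == "head_and_features":
        unfrozen = {_FEATURE_LAYER, _HEAD_LAYER}
    elif cfg.freeze_policy == "features_only":
        unfrozen = {_FEATURE_LAYER}
    else:
        raise ValueError(f"unknown freeze policy {cfg.freeze_policy!r}")
    net.set_trainable(unfrozen)
    if net.n_parameters(trainable_only=True) == 0:
        raise ValueError("freeze policy leaves no trainable parameters")
    for name, layer in net.layers:
        if isinstance(layer, BatchNorm2D):
            layer.frozen = True
    x = samples_to_batch(samples, spec.input_side)
    rng = np.random.default_rng(cfg.seed)
    n_epochs = cfg.finetune_epochs if epochs is None else epochs
    logger.info(
        "finetuning: %d samples, %d epochs, unfrozen layers %s (%d parameters)",
        len(samples), n_epochs, sorted(unfrozen),
        net.n_parameters(trainable_only=True),
    )
    return _run_training(net, x, targets, n_epochs, cfg, rng)


def predict_hazards(
    net: Sequential,
    samples: Sequence[ImageSample],
    spec: ModelSpec,
    batch_size: int = 64,
) -> np.ndarray:
    """Per-slice hazard rows in (0, 1); inference mode (dropout off, BN on
    running statistics)."""
    x = samples_to_batch(samples, spec.input_side)
    rows = []
    for start in range(0, x.shape[0], batch_size):
        z = net.forward(x[start : start + batch_size], train=False)
        rows.append(_sigmoid(z.astype(np.float64)))
    h = np.vstack(rows)
    return np.clip(h, 1e-7, 1 - 1e-7)


def extract_features(
    net: Sequential,
    samples: Sequence[ImageSample],
    spec: ModelSpec,
    batch_size: int = 64,
) -> pd.DataFrame:
    """Activations of the 19-unit dense feature layer, one row per slice."""
    x = samples_to_batch(samples, spec.input_side)
    rows = []
    for start in range(0, x.shape[0], batch_size):
        rows.append(net.forward(x[start : start + batch_size], train=False,
                                upto="feature_relu"))
    feats = np.vstack(rows).astype(np.float64)
    df = pd.DataFrame(feats, columns=[f"f{i+1}" for i in range(feats.shape[1])])
    df.insert(0, "subject_id", [s.subject_id for s in samples])
    df.insert(1, "slice_index", [s.slice_index for s in samples])
    return df


# ---------------------------------------------------------------------------
# Model / Results objects


class CNNSurvival:
    """Survival CNN bound to a training cohort of slices and follow-up records.

    Parameters
    ----------
    samples
        Standardized slices (see :func:`imgsurv.imaging.standardize`); several
        slices per subject are allowed and share that subject's targets.
    records
        One follow-up record per subject appearing in ``samples``.
    n_intervals
        Number of follow-up intervals when ``grid`` is not given; the grid is
        placed at quantiles of the observed event times.
    """

    def __init__(
        self,
        samples: Sequence[ImageSample],
        records: Sequence[SurvivalRecord],
        n_intervals: int = 12,
        grid: IntervalGrid | None = None,
        spec: ModelSpec | None = None,
        config: TrainConfig | None = None,
    ) -> None:
        self.samples = list(samples)
        self.records = list(records)
        if not self.samples:
            raise ValueError("no training slices")
        self.grid = grid if grid is not None else make_interval_grid(
            self.records, n_intervals
        )
        side = self.samples[0].pixels.shape[0]
        if spec is None:
            spec = ModelSpec(n_intervals=self.grid.n_intervals, input_side=side)
        elif spec.n_intervals != self.grid.n_intervals:
            raise ValueError("spec.n_intervals must match the grid")
        self.spec = spec
        self.config = config if config is not None else TrainConfig()
        by_id = {r.subject_id: r for r in self.records}
        missing = {s.subject_id for s in self.samples} - set(by_id)
        if missing:
            raise ValueError(f"no survival record for subjects {sorted(missing)[:5]}")
        self._slice_records = [by_id[s.subject_id] for s in self.samples]

    def slice_targets(self, samples: Sequence[ImageSample],
                      records: Sequence[SurvivalRecord]) -> DiscreteTargets:
        by_id = {r.subject_id: r for r in records}
        return encode_targets([by_id[s.subject_id] for s in samples], self.grid)

    def fit(self, epochs: int | None = None,
            seed: int | None = None) -> "CNNSurvivalResults":
        """Pretrain all layers on the bound cohort."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        net = build_model(self.spec, seed=cfg.seed)
        targets = self.slice_targets(self.samples, self.records)
        history = pretrain(net, self.samples, targets, cfg, self.spec, epochs)
        return CNNSurvivalResults(self, net, history, stage="pretrained", config=cfg)


class CNNSurvivalResults:
    """A trained survival CNN: prediction, features, finetuning, persistence."""

    def __init__(self, model: CNNSurvival, net: Sequential,
                 loss_history: list[float], stage: str,
                 config: TrainConfig) -> None:
        self.model = model
        self.net = net
        self.loss_history = list(loss_history)
        self.stage = stage
        self.config = config

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def grid(self) -> IntervalGrid:
        return self.model.grid

    # -- transfer learning ----------------------------------------------------

    def finetune(
        self,
        samples: Sequence[ImageSample],
        records: Sequence[SurvivalRecord],
        epochs: int | None = None,
        config: TrainConfig | None = None,
    ) -> "CNNSurvivalResults":
        """Adapt the dense layers to a new cohort; backbone stays frozen.

        Returns a new results object; this one is unchanged."""
        cfg = config if config is not None else self.config
        net = build_model(self.spec, seed=cfg.seed)
        net.load_state_dict(self.net.state_dict())
        by_id = {r.subject_id: r for r in records}
        targets = encode_targets(
            [by_id[s.subject_id] for s in samples], self.grid
        )
        history = finetune(net, samples, targets, cfg, self.spec, epochs)
        return CNNSurvivalResults(self.model, net, history, "finetuned", cfg)

    # -- inference ------------------------------------------------------------

    def predict_hazards(self, samples: Sequence[ImageSample]) -> np.ndarray:
        """One hazard row per slice."""
        return predict_hazards(self.net, samples, self.spec)

    def predict_patient_hazards(
        self,
        samples: Sequence[ImageSample],
        mode: Literal["largest_slice", "mean"] = "largest_slice",
    ) -> tuple[list[str], np.ndarray]:
        """Aggregate slice hazards to one row per patient."""
        h = self.predict_hazards(samples)
        return aggregate_patient(samples, h, mode=mode)

    def predict_survival(
        self,
        samples: Sequence[ImageSample],
        mode: Literal["largest_slice", "mean"] = "largest_slice",
    ) -> list[SurvivalCurve]:
        """Per-patient survival curves from aggregated hazards."""
        ids, h = self.predict_patient_hazards(samples, mode=mode)
        return hazards_to_survival(h, self.grid, ids)

    def extract_features(self, samples: Sequence[ImageSample]) -> pd.DataFrame:
        """19-dimensional dense-layer features, one row per slice."""
        return extract_features(self.net, samples, self.spec)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "CNN survival model",
            "=" * 50,
            f"stage:                {self.stage}",
            f"input:                {self.spec.input_side}x{self.spec.input_side}x1",
            f"intervals (J):        {self.spec.n_intervals}",
            f"grid boundaries:      {np.array2string(self.grid.boundaries, precision=1)}",
            f"feature dimension:    {self.spec.feature_dim}",
            f"total parameters:     {self.net.n_parameters()}",
            "feature-layer params:  "
            f"{self.net[_FEATURE_LAYER].n_parameters}",
            f"trainable parameters: {self.net.n_parameters(trainable_only=True)}",
            f"epochs trained:       {len(self.loss_history)}",
        ]
        if self.loss_history:
            lines.append(f"final epoch loss:     {self.loss_history[-1]:.4f}")
        return "\n".join(lines)

    def plot_survival(self, samples: Sequence[ImageSample], ax=None,
                      mode: Literal["largest_slice", "mean"] = "largest_slice"):
        """Step plot of predicted per-patient survival curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve in self.predict_survival(samples, mode=mode):
            b = curve.grid.boundaries
            ax.step(b, np.concatenate([[1.0], curve.probabilities]),
                    where="post", label=curve.subject_id)
        ax.set_xlabel("days")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax

    # -- persistence ----------------------------------------------------------

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "grid": self.grid.to_json_list(),
            "stage": self.stage,
        }
        (out_dir / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(out_dir / "params.npz", **self.net.state_dict())
        pd.DataFrame(
            {"epoch": range(1, len(self.loss_history) + 1),
             "loss": self.loss_history}
        ).to_csv(out_dir / "loss_history.csv", index=False)

    @classmethod
    def load(cls, model_dir) -> "CNNSurvivalResults":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        spec = ModelSpec(**{**meta["spec"],
                            "pool_sizes": tuple(meta["spec"]["pool_sizes"])})
        cfg = TrainConfig(**meta["config"])
        grid = IntervalGrid(np.array(meta["grid"]))
        net = build_model(spec, seed=cfg.seed)
        with np.load(model_dir / "params.npz") as state:
            net.load_state_dict(dict(state))
        history = []
        hist_path = model_dir / "loss_history.csv"
        if hist_path.exists():
            history = pd.read_csv(hist_path)["loss"].tolist()
        model = object.__new__(CNNSurvival)
        model.samples = []
        model.records = []
        model.grid = grid
        model.spec = spec
        model.config = cfg
        model._slice_records = []
        return cls(model, net, history, meta["stage"], cfg)
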