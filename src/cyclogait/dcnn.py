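"""Residual 1-D convolutional classifier for multi-plane cyclogram cycles.

The network stacks residual blocks (two convolutions each) over the
256-point x 6-channel cycle matrix, global-average-pools the final
feature maps, optionally concatenates four standardized clinical scalars,
and ends in a single fully connected softmax layer. Training uses Adam
with a reduce-on-plateau learning-rate schedule (factor 0.9, patience 5
epochs on training loss).

Inputs are Z-score normalized per channel with statistics computed from
the training fold only; the same applies to the clinical scalars.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .evaluation import NEGATIVE, POSITIVE, FoldPlan
from .events import N_CHANNELS, N_POINTS, GaitCycle
from .synthetic import CLINICAL_FIELDS, ValidationError


@dataclass(frozen=True)
class DCNNConfig:
    n_residual_blocks: int = 16
    convs_per_block: int = 2  # architectural constant, audited
    kernel_size: int = 3
    base_filters: int = 32
    growth_every: int = 4  # double filters (and stride 2) every this many blocks
    dropout: float = 0.3
    use_clinical: bool = True
    n_classes: int = 2
    input_length: int = N_POINTS
    input_channels: int = N_CHANNELS
    lr0: float = 1e-3
    lr_decay_factor: float = 0.9
    lr_patience: int = 5
    batch_size: int = 8
    epochs: int = 100
    #: SD (deg) of per-channel constant-offset jitter added to training
    #: batches; teaches invariance to subject-level baseline shifts, which
    #: carry no group information in this task.
    augment_offset_sd: float = 2.0
    seed: int = 0
    block_plan: tuple[tuple[int, int], ...] | None = None  # (filters, stride) overrides

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        for name in ("n_residual_blocks", "kernel_size", "base_filters",
                     "batch_size", "epochs", "n_classes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.input_length != N_POINTS or self.input_channels != N_CHANNELS:
            raise ValidationError(
                f"input shape fixed to ({N_POINTS}, {N_CHANNELS})"
            )
        if self.block_plan is not None and len(self.block_plan) != self.n_residual_blocks:
            raise ValidationError("block_plan length must equal n_residual_blocks")

    def resolved_block_plan(self) -> tuple[tuple[int, int], ...]:
        if self.block_plan is not None:
            return tuple((int(f), int(s)) for f, s in self.block_plan)
        plan = []
        for i in range(self.n_residual_blocks):
            filters = self.base_filters * 2 ** (i // self.growth_every)
            stride = 2 if (i > 0 and i % self.growth_every == 0) else 1
            plan.append((filters, stride))
        return tuple(plan)

    @classmethod
    def reduced(cls, **overrides) -> "DCNNConfig":
        """Small preset (4 blocks, 30 epochs) that trains in seconds on one CPU."""
        base = dict(
            n_residual_blocks=4,
            base_filters=16,
            epochs=30,
            batch_size=32,
            dropout=0.1,
            block_plan=((16, 2), (32, 2), (32, 2), (32, 1)),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class NormalizationStats:
    """Training-fold Z-score statistics for channels and clinical scalars."""

    channel_mean: np.ndarray  # (6,)
    channel_sd: np.ndarray  # (6,)
    clinical_mean: np.ndarray  # (4,)
    clinical_sd: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        if np.any(self.channel_sd <= 0):
            raise ValidationError("channel SD must be > 0")
        if np.any(self.clinical_sd <= 0):
            raise ValidationError("clinical SD must be > 0")

    @classmethod
    def from_training(cls, X: np.ndarray, clinical: np.ndarray) -> "NormalizationStats":
        return cls(
            channel_mean=X.mean(axis=(0, 1)),
            channel_sd=X.std(axis=(0, 1)),
            clinical_mean=clinical.mean(axis=0),
            clinical_sd=np.maximum(clinical.std(axis=0), 1e-8),
        )

    def normalize(self, X: np.ndarray, clinical: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xn = (X - self.channel_mean) / self.channel_sd
        cn = (clinical - self.clinical_mean) / self.clinical_sd
        return Xn.astype(np.float32), cn.astype(np.float32)


class PlateauSchedule:
    """Reduce-on-plateau learning rate: multiply by ``factor`` whenever the
    monitored loss fails to improve for ``patience`` consecutive epochs."""

    def __init__(self, lr0: float, factor: float = 0.9, patience: int = 5,
                 min_delta: float = 1e-6):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self._best = np.inf
        self._stale = 0

    def update(self, loss: float) -> float:
        """Record an epoch loss; returns the learning rate for the next epoch."""
        if loss < self._best - self.min_delta:
            self._best = loss
            self._stale = 0
        else:
            self._stale += 1
            if self._stale >= self.patience:
                self.lr *= self.factor
                self._stale = 0
        return self.lr


class ResNet1D:
    """The classifier network; see module docstring for the architecture."""

    def __init__(self, config: DCNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        self.blocks: list[nn.ResidualBlock] = []
        c_in = config.input_channels
        for filters, stride in config.resolved_block_plan():
            self.blocks.append(
                nn.ResidualBlock(c_in, filters, stride, config.kernel_size,
                                 config.dropout, rng)
            )
            c_in = filters
        self.feature_dim = c_in
        head_in = c_in + (len(CLINICAL_FIELDS) if config.use_clinical else 0)
        self.head = nn.Dense(head_in, config.n_classes, rng)
        # populated on forward/backward, consumed by grad-CAM
        self.last_feature: np.ndarray | None = None
        self.last_feature_grad: np.ndarray | None = None
        self._cache = None

    # -- architecture audit -------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_convs_main(self) -> int:
        """Convolutions on the main path (excludes projection shortcuts)."""
        return self.config.convs_per_block * len(self.blocks)

    @property
    def n_params(self) -> int:
        return sum(p.v.size for p in self.params())

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, clinical: np.ndarray | None,
                training: bool) -> np.ndarray:
        if X.ndim != 3 or X.shape[1:] != (self.config.input_length, self.config.input_channels):
            raise ValidationError(
                f"expected input (batch, {self.config.input_length}, "
                f"{self.config.input_channels}), got {X.shape}"
            )
        h = X.astype(np.float32)
        for b in self.blocks:
            h = b.forward(h, training, self._dropout_rng)
        self.last_feature = h
        pooled = h.mean(axis=1)  # global average pooling over time
        if self.config.use_clinical:
            if clinical is None:
                raise ValidationError("model expects clinical inputs")
            feats = np.concatenate([pooled, clinical.astype(np.float32)], axis=1)
        else:
            feats = pooled
        self._cache = (h.shape[1], feats.shape)
        return self.head.forward(feats)

    def backward(self, dlogits: np.ndarray) -> None:
        t_feat, _ = self._cache
        dfeats = self.head.backward(dlogits)
        dpooled = dfeats[:, : self.feature_dim]
        dh = np.repeat(dpooled[:, None, :], t_feat, axis=1) / t_feat
        self.last_feature_grad = dh.copy()
        for b in reversed(self.blocks):
            dh = b.backward(dh)

    def predict_proba(self, X: np.ndarray, clinical: np.ndarray | None,
                      batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            c = clinical[i:i + batch_size] if clinical is not None else None
            out.append(nn.softmax(self.forward(X[i:i + batch_size], c, training=False)))
        return np.concatenate(out, axis=0)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ResNet1D":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_model(config: DCNNConfig) -> ResNet1D:
    return ResNet1D(config)


def fit_fold(
    X: np.ndarray,
    clinical: np.ndarray,
    labels: np.ndarray,
    config: DCNNConfig,
    model: ResNet1D | None = None,
) -> tuple[ResNet1D, NormalizationStats, list[dict]]:
    """Train one fold; returns (model, normalization stats, per-epoch log).

    Z-score statistics are computed from the provided (training) samples
    only. The learning rate is multiplied by ``lr_decay_factor`` whenever
    the epoch training loss fails to improve for ``lr_patience``
    consecutive epochs.
    """
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if y.min() == y.max():
        raise ValidationError("training fold contains a single class")
    stats = NormalizationStats.from_training(X, clinical)
    Xn, cn = stats.normalize(X, clinical)
    aug_scale = (config.augment_offset_sd / stats.channel_sd).astype(np.float32)
    model = model or build_model(config)
    opt = nn.Adam(model.params(), lr=config.lr0)
    rng = np.random.default_rng(config.seed + 2)
    sched = PlateauSchedule(config.lr0, config.lr_decay_factor, config.lr_patience)
    log = []
    n = len(Xn)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = Xn[idx]
            if config.augment_offset_sd > 0:
                jitter = rng.normal(0.0, 1.0, (len(idx), 1, xb.shape[2]))
                xb = xb + (jitter * aug_scale).astype(np.float32)
            opt.zero_grad()
            logits = model.forward(xb, cn[idx] if config.use_clinical else None,
                                   training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        opt.lr = sched.update(epoch_loss)
        log.append({"epoch": epoch + 1, "loss": epoch_loss, "lr": opt.lr})
    return model, stats, log


def predict_cycles(
    model: ResNet1D,
    X: np.ndarray,
    clinical: np.ndarray | None,
    stats: NormalizationStats,
) -> np.ndarray:
    """Per-cycle class probabilities (columns: NP, P) for held-out cycles."""
    if X.shape[2] != len(stats.channel_mean):
        raise ValidationError("channel count mismatch with normalization stats")
    Xn, cn = stats.normalize(X, clinical if clinical is not None else
                             np.zeros((len(X), len(CLINICAL_FIELDS))))
    return model.predict_proba(Xn, cn if model.config.use_clinical else None)


@dataclass
class CycleDataset:
    """Cycle tensors plus per-cycle metadata for model training."""

    X: np.ndarray  # (n, 256, 6)
    clinical: np.ndarray  # (n, 4) in CLINICAL_FIELDS order
    labels: np.ndarray  # (n,) of "P"/"NP"
    subject_ids: np.ndarray  # (n,)
    cycle_ids: np.ndarray  # (n,)
    stance_boundaries: np.ndarray = field(default=None)  # (n,) int

    @classmethod
    def from_cycles(
        cls,
        cycles: list[GaitCycle],
        clinical_by_subject: dict[str, dict[str, float]],
        label_by_subject: dict[str, str],
    ) -> "CycleDataset":
        if not cycles:
            raise ValidationError("no cycles supplied")
        X = np.stack([c.angles for c in cycles])
        clin = np.array(
            [[clinical_by_subject[c.subject_id][f] for f in CLINICAL_FIELDS]
             for c in cycles]
        )
        return cls(
            X=X,
            clinical=clin,
            labels=np.array([label_by_subject[c.subject_id] for c in cycles]),
            subject_ids=np.array([c.subject_id for c in cycles]),
            cycle_ids=np.array([f"{c.side}{c.cycle_index:03d}" for c in cycles]),
            stance_boundaries=np.array([c.stance_boundary for c in cycles]),
        )

    def subset(self, mask: np.ndarray) -> "CycleDataset":
        return CycleDataset(
            X=self.X[mask], clinical=self.clinical[mask], labels=self.labels[mask],
            subject_ids=self.subject_ids[mask], cycle_ids=self.cycle_ids[mask],
            stance_boundaries=self.stance_boundaries[mask],
        )


def cross_validate_dcnn(
    data: CycleDataset, plan: FoldPlan, config: DCNNConfig
) -> tuple[pd.DataFrame, dict[int, tuple[ResNet1D, NormalizationStats]]]:
    """Subject-wise CV of the network; per-cycle predictions plus fold models."""
    frames = []
    fold_models: dict[int, tuple[ResNet1D, NormalizationStats]] = {}
    for fold in range(plan.k):
        test_ids = set(plan.test_subjects(fold))
        is_test = np.isin(data.subject_ids, sorted(test_ids))
        train, test = data.subset(~is_test), data.subset(is_test)
        if len(test.X) == 0:
            raise ValidationError(f"fold {fold}: no test cycles")
        cfg = replace(config, seed=config.seed + 1000 * fold)
        model, stats, _ = fit_fold(train.X, train.clinical, train.labels, cfg)
        probs = predict_cycles(model, test.X, test.clinical, stats)
        score = probs[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": test.subject_ids,
                    "cycle_id": test.cycle_ids,
                    "fold": fold,
                    "score": score,
                    "pred": np.where(score > 0.5, POSITIVE, NEGATIVE),
                    "label": test.labels,
                }
            )
        )
        fold_models[fold] = (model, stats)
    return pd.concat(frames, ignore_index=True), fold_models
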