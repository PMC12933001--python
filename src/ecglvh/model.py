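"""Fully convolutional network for iLVM regression and LVH classification.

Architecture: three 1-D convolutional blocks (128x8, 256x5, 128x3 filters x
kernel) each with batch normalization, ReLU and max-pooling; dropout 0.4 after
the convolutional stack; global average pooling; concatenation with the
15-entry clinical metadata vector; a 128-unit fully connected layer; dropout
0.6; and a single-output head (linear for regression over indexed LV mass,
sigmoid for direct LVH classification). Roughly 2.9e5 trainable parameters.

Training uses Adam (lr 5e-4, batch 64), log-cosh loss for regression (robust
to the long-tailed mass distribution) or binary cross-entropy for
classification, early stopping after 20 non-improving epochs and learning-rate
reduction x0.1 after 10, restoring the best-validation weights at the end.
Fine-tuning for an external cohort unfreezes the output head first (lr 5e-5,
weight decay 1e-4) and then each convolutional block deepest-first (lr 1e-4,
weight decay 1e-5), with morphology-preserving augmentation of training beats.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DivergenceError, InvalidArgumentError
from .nn import (
    DTYPE,
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    GlobalAveragePool,
    MaxPool1d,
    ReLU,
)

LOG2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ModelConfig:
    conv_blocks: tuple = ((128, 8), (256, 5), (128, 3))
    dropout_after_conv: float = 0.4
    dropout_between_fc: float = 0.6
    fc_hidden: int = 128
    metadata_dim: int = 15  # 0 = metadata-excluded variant
    n_leads: int = 8
    beat_length: int = 120
    target: str = "LVM_regression"  # or "LVH_classification"
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_blocks) != 3:
            raise ConfigurationError("the network uses exactly three conv blocks")
        if self.metadata_dim < 0:
            raise ConfigurationError("metadata_dim must be >= 0")
        for p in (self.dropout_after_conv, self.dropout_between_fc):
            if not 0.0 <= p < 1.0:
                raise ConfigurationError("dropout probabilities must be in [0, 1)")
        if self.target not in ("LVM_regression", "LVH_classification"):
            raise ConfigurationError(f"unknown target {self.target!r}")
        # each block halves the length; the final map must be non-empty
        length = self.beat_length
        for _, kernel in self.conv_blocks:
            if length < kernel:
                raise ConfigurationError(
                    f"beat_length {self.beat_length} too short for kernel {kernel}"
                )
            length //= 2
        if length < 1:
            raise ConfigurationError("beat_length too short after pooling")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 20
    lr_reduce_patience: int = 10
    lr_reduce_factor: float = 0.1
    weight_decay: float = 0.0
    min_improvement: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience <= 0 or self.lr_reduce_patience <= 0:
            raise ConfigurationError("patiences must be positive")
        if not 0.0 < self.lr_reduce_factor < 1.0:
            raise ConfigurationError("lr_reduce_factor must be in (0, 1)")


@dataclass(frozen=True)
class FineTuneConfig:
    head_learning_rate: float = 5e-5
    head_weight_decay: float = 1e-4
    block_learning_rate: float = 1e-4
    block_weight_decay: float = 1e-5
    crop_max: int = 25  # samples cropped from each end, uniform 0..crop_max
    noise_sd: float = 0.005  # mV, per lead
    amplitude_scale: tuple = (0.9, 1.1)
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.crop_max < 0 or self.noise_sd < 0:
            raise ConfigurationError("crop_max and noise_sd must be >= 0")
        if self.amplitude_scale[0] > self.amplitude_scale[1]:
            raise ConfigurationError("amplitude_scale bounds must be ordered")


@dataclass
class TrainingHistory:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    learning_rates: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def best_val_loss(self) -> float:
        return min(self.val_losses) if self.val_losses else float("nan")


@dataclass
class PredictionSet:
    participant_ids: tuple
    model_variant: str  # FCN_LVM or FCN_LVH
    predicted_ilvm: np.ndarray | None = None
    lvh_probability: np.ndarray | None = None


# ---------------------------------------------------------------------------
# losses

def log_cosh_loss(predicted, observed, return_grad: bool = False):
    """Mean log(cosh(pred - obs)), in the overflow-safe form
    |x| + log1p(exp(-2|x|)) - log 2."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise InvalidArgumentError("prediction/target length mismatch")
    x = predicted - observed
    ax = np.abs(x)
    loss = float(np.mean(ax + np.log1p(np.exp(-2.0 * ax)) - LOG2))
    if not return_grad:
        return loss
    grad = np.tanh(x) / x.size
    return loss, grad


def bce_with_logits_loss(logits, labels, return_grad: bool = False):
    """Binary cross-entropy on raw logits (numerically stable)."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if logits.shape != labels.shape:
        raise InvalidArgumentError("logit/label length mismatch")
    loss = float(np.mean(np.maximum(logits, 0) + np.log1p(np.exp(-np.abs(logits)))
                         - labels * logits))
    if not return_grad:
        return loss
    grad = (_sigmoid(logits) - labels) / logits.size
    return loss, grad


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# the network

class FCN:
    """The network handle: layers, forward/backward, weight (de)serialization."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        in_ch = config.n_leads
        for filters, kernel in config.conv_blocks:
            self.blocks.append({
                "conv": Conv1d(in_ch, filters, kernel, rng),
                "bn": BatchNorm1d(filters),
                "relu": ReLU(),
                "pool": MaxPool1d(),
            })
            in_ch = filters
        self.dropout_conv = Dropout(config.dropout_after_conv)
        self.gap = GlobalAveragePool()
        fc_in = config.conv_blocks[-1][0] + config.metadata_dim
        self.fc1 = Dense(fc_in, config.fc_hidden, rng)
        self.fc_relu = ReLU()
        self.dropout_fc = Dropout(config.dropout_between_fc)
        self.fc2 = Dense(config.fc_hidden, 1, rng)
        self._meta_dim = config.metadata_dim

    # -- parameter bookkeeping ------------------------------------------------

    def param_refs(self, trainable: set | None = None):
        """(name, layer, key) triples; filter by top-level group names."""
        refs = []
        for bi, block in enumerate(self.blocks):
            group = f"block{bi + 1}"
            for lname in ("conv", "bn"):
                for key in block[lname].params:
                    refs.append((f"{group}.{lname}.{key}", block[lname], key))
        for lname, layer in (("fc1", self.fc1), ("fc2", self.fc2)):
            for key in layer.params:
                refs.append((f"head.{lname}.{key}", layer, key))
        if trainable is not None:
            refs = [r for r in refs if r[0].split(".")[0] in trainable]
        return refs

    def get_weights(self) -> dict:
        state = {name: layer.params[key].copy()
                 for name, layer, key in self.param_refs()}
        for bi, block in enumerate(self.blocks):
            state[f"block{bi + 1}.bn.running_mean"] = block["bn"].running_mean.copy()
            state[f"block{bi + 1}.bn.running_var"] = block["bn"].running_var.copy()
        return state

    def set_weights(self, state: dict) -> None:
        for name, layer, key in self.param_refs():
            layer.params[key] = state[name].copy()
        for bi, block in enumerate(self.blocks):
            block["bn"].running_mean = state[f"block{bi + 1}.bn.running_mean"].copy()
            block["bn"].running_var = state[f"block{bi + 1}.bn.running_var"].copy()

    def set_bn_updates(self, groups: set) -> None:
        """Enable running-statistics updates only for the named blocks."""
        for bi, block in enumerate(self.blocks):
            block["bn"].update_stats = f"block{bi + 1}" in groups

    # -- forward / backward ---------------------------------------------------

    def forward(self, ecg, meta, training: bool = False, rng=None):
        """Raw head output (N,): predicted iLVM or LVH logit."""
        h = np.ascontiguousarray(ecg, dtype=DTYPE)
        if h.ndim != 3 or h.shape[1] != self.config.n_leads:
            raise InvalidArgumentError("ecg must be (N, n_leads, L)")
        for block in self.blocks:
            for lname in ("conv", "bn", "relu", "pool"):
                h = block[lname].forward(h, training=training, rng=rng)
        h = self.dropout_conv.forward(h, training=training, rng=rng)
        pooled = self.gap.forward(h, training=training, rng=rng)
        if self._meta_dim:
            meta = np.asarray(meta, dtype=DTYPE)
            if meta.shape != (pooled.shape[0], self._meta_dim):
                raise InvalidArgumentError(
                    f"metadata must be (N, {self._meta_dim}), got {meta.shape}"
                )
            z = np.concatenate([pooled, meta], axis=1)
        else:
            z = pooled
        z = self.fc1.forward(z, training=training, rng=rng)
        z = self.fc_relu.forward(z, training=training, rng=rng)
        z = self.dropout_fc.forward(z, training=training, rng=rng)
        out = self.fc2.forward(z, training=training, rng=rng)
        return out[:, 0]

    def backward(self, dout):
        """Backpropagate d(loss)/d(output); returns (d_ecg, d_meta)."""
        dz = self.fc2.backward(np.asarray(dout, dtype=DTYPE)[:, None])
        dz = self.dropout_fc.backward(dz)
        dz = self.fc_relu.backward(dz)
        dz = self.fc1.backward(dz)
        if self._meta_dim:
            dpooled, dmeta = dz[:, : -self._meta_dim], dz[:, -self._meta_dim:]
        else:
            dpooled, dmeta = dz, None
        dh = self.gap.backward(dpooled)
        dh = self.dropout_conv.backward(dh)
        for block in reversed(self.blocks):
            for lname in ("pool", "relu", "bn", "conv"):
                dh = block[lname].backward(dh)
        return dh, dmeta

    def zero_grad(self):
        for _, layer, _ in self.param_refs():
            layer.zero_grad()

    # -- inference ------------------------------------------------------------

    def predict_raw(self, ecg, meta, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference (dropout off, frozen BN statistics)."""
        outputs = []
        for start in range(0, len(ecg), batch_size):
            sl = slice(start, start + batch_size)
            outputs.append(self.forward(ecg[sl],
                                        None if not self._meta_dim else meta[sl],
                                        training=False))
        return np.concatenate(outputs).astype(float)

    def input_gradients(self, ecg, meta):
        """d(output)/d(inputs) in inference mode, one row per sample."""
        out = self.forward(ecg, meta, training=False)
        d_ecg, d_meta = self.backward(np.ones_like(out))
        return np.asarray(d_ecg, dtype=float), (
            None if d_meta is None else np.asarray(d_meta, dtype=float)
        ), out


def build_fcn(config: ModelConfig) -> FCN:
    return FCN(config)


def count_parameters(model: FCN) -> int:
    """Number of trainable parameter elements (conv/dense weights and biases,
    batch-norm scales and shifts; running statistics excluded)."""
    return int(sum(layer.params[key].size for _, layer, key in model.param_refs()))


# ---------------------------------------------------------------------------
# augmentation

def augment_waveform(ecg: np.ndarray, cfg: FineTuneConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Morphology-preserving augmentation of one (n_leads, L) beat.

    Random crops of up to ``crop_max`` samples at each end with linear
    re-interpolation back to L; per-lead Gaussian noise; a single amplitude
    scale drawn uniformly from ``amplitude_scale`` applied to all leads.
    """
    ecg = np.asarray(ecg, dtype=float)
    L = ecg.shape[-1]
    if L <= 2 * cfg.crop_max:
        raise InvalidArgumentError(f"beat length {L} too short for crop_max {cfg.crop_max}")
    c0 = int(rng.integers(0, cfg.crop_max + 1))
    c1 = int(rng.integers(0, cfg.crop_max + 1))
    out = ecg
    if c0 or c1:
        seg = ecg[..., c0 : L - c1]
        x_new = np.linspace(0.0, seg.shape[-1] - 1.0, L)
        x_old = np.arange(seg.shape[-1], dtype=float)
        out = np.stack([np.interp(x_new, x_old, lead) for lead in seg])
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    lo, hi = cfg.amplitude_scale
    scale = rng.uniform(lo, hi) if hi > lo else lo
    return out * scale


# ---------------------------------------------------------------------------
# training

def _loss_fn(target: str):
    return log_cosh_loss if target == "LVM_regression" else bce_with_logits_loss


def _validation_loss(model, val, loss, batch_size=512):
    ecg, meta, y = val
    preds = model.predict_raw(ecg, meta, batch_size=batch_size)
    return loss(preds, y)


def train_model(
    model: FCN,
    train: tuple,
    validation: tuple,
    cfg: TrainConfig,
    augment_cfg: FineTuneConfig | None = None,
    trainable: set | None = None,
) -> tuple[FCN, TrainingHistory]:
    """Mini-batch Adam training with early stopping and LR reduction.

    ``train``/``validation`` are (ecg (N,8,L), metadata (N,m), target (N,))
    triples. ``trainable`` optionally restricts updates to named parameter
    groups ("head", "block1"..."block3"); frozen blocks also keep their
    batch-norm running statistics. Best-validation weights are restored on
    return. Fully reproducible under ``cfg.seed``.
    """
    ecg_tr, meta_tr, y_tr = train
    if len(ecg_tr) == 0 or len(validation[0]) == 0:
        raise InvalidArgumentError("training and validation sets must be non-empty")
    loss = _loss_fn(model.config.target)
    rng = np.random.default_rng(cfg.seed)

    if model.config.target == "LVM_regression" and model.fc2.params["b"][0] == 0.0:
        # Start the head at the training-target mean so the (locally linear)
        # log-cosh gradient does not have to walk the bias tens of g/m^2.
        model.fc2.params["b"] = np.array([np.mean(y_tr)], dtype=DTYPE)

    refs = model.param_refs(trainable)
    if trainable is not None:
        model.set_bn_updates(trainable)
    optimizer = Adam(refs, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainingHistory()
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), -1
    epochs_since_best, epochs_since_reduce = 0, 0

    n = len(ecg_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = ecg_tr[idx]
            if augment_cfg is not None:
                xb = np.stack([augment_waveform(x, augment_cfg, rng) for x in xb])
            mb = meta_tr[idx] if model._meta_dim else None
            preds = model.forward(xb, mb, training=True, rng=rng)
            batch_loss, dpred = loss(preds, y_tr[idx], return_grad=True)
            if not np.isfinite(batch_loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            model.zero_grad()
            model.backward(dpred)
            optimizer.step()
            epoch_loss += batch_loss
            n_batches += 1

        val_loss = _validation_loss(model, validation, loss)
        history.train_losses.append(epoch_loss / max(n_batches, 1))
        history.val_losses.append(val_loss)
        history.learning_rates.append(optimizer.lr)

        if val_loss < best_loss - cfg.min_improvement:
            best_loss, best_epoch = val_loss, epoch
            best_weights = model.get_weights()
            epochs_since_best = epochs_since_reduce = 0
        else:
            epochs_since_best += 1
            epochs_since_reduce += 1
        if epochs_since_best >= cfg.early_stop_patience:
            history.stop_reason = "early_stopping"
            break
        if epochs_since_reduce >= cfg.lr_reduce_patience:
            optimizer.lr *= cfg.lr_reduce_factor
            epochs_since_reduce = 0
    else:
        history.stop_reason = "max_epochs"

    history.best_epoch = best_epoch
    model.set_weights(best_weights)
    model.set_bn_updates({f"block{i + 1}" for i in range(len(model.blocks))})
    return model, history


def fine_tune(
    model: FCN,
    train: tuple,
    validation: tuple,
    ft_cfg: FineTuneConfig,
    train_cfg: TrainConfig | None = None,
) -> tuple[FCN, list[TrainingHistory]]:
    """Staged unfreezing for external-cohort adaptation.

    Stage 1 trains only the post-GAP head; subsequent stages unfreeze the
    convolutional blocks one at a time, deepest first, keeping earlier stages'
    groups trainable. Augmentation is applied to training batches only.
    """
    base = train_cfg or TrainConfig(seed=ft_cfg.seed)
    n_blocks = len(model.blocks)
    stages = [("head", ft_cfg.head_learning_rate, ft_cfg.head_weight_decay)]
    for bi in range(n_blocks, 0, -1):
        stages.append((f"block{bi}", ft_cfg.block_learning_rate,
                       ft_cfg.block_weight_decay))
    histories = []
    trainable: set = set()
    aug = ft_cfg if ft_cfg.augment else None
    for si, (group, lr, wd) in enumerate(stages):
        trainable = trainable | {group}
        stage_cfg = TrainConfig(
            learning_rate=lr,
            batch_size=base.batch_size,
            max_epochs=base.max_epochs,
            early_stop_patience=base.early_stop_patience,
            lr_reduce_patience=base.lr_reduce_patience,
            lr_reduce_factor=base.lr_reduce_factor,
            weight_decay=wd,
            seed=base.seed + si,
        )
        model, history = train_model(model, train, validation, stage_cfg,
                                     augment_cfg=aug, trainable=set(trainable))
        histories.append(history)
    return model, histories


def predict(model: FCN, ecg, meta, participant_ids=None) -> PredictionSet:
    """Deterministic inference producing a PredictionSet."""
    ids = tuple(participant_ids) if participant_ids is not None else tuple(
        str(i) for i in range(len(ecg))
    )
    if len(ids) != len(ecg):
        raise InvalidArgumentError("one id per sample required")
    raw = model.predict_raw(np.asarray(ecg), None if not model._meta_dim
                            else np.asarray(meta))
    if model.config.target == "LVM_regression":
        return PredictionSet(ids, "FCN_LVM", predicted_ilvm=raw)
    return PredictionSet(ids, "FCN_LVH", lvh_probability=_sigmoid(raw))
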