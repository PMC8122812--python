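"""Sequence-to-sequence LSTM autoencoder with two-stage transfer learning.

Stage 1 trains the full encoder–decoder to reconstruct the PPG channel
from the 3-channel input (PPG, velocity, acceleration).  The encoder is
then frozen and the decoder retrained to emit the arterial-pressure
waveform (stage 2): the encoder's per-timestep hidden-state sequence is
the learned pulse-morphology representation, and only the decoding side
adapts to the pressure target.

Architecture: two stacked LSTM layers per phase (encoder and decoder),
a dropout layer at the end of the decoding phase, and a per-timestep
linear projection to one output channel.  Because the latent is the
full hidden-state sequence (not a single bottleneck vector), input
sequences of any length map to outputs of the same length.

Defaults follow the reference operating point: 128 hidden units per
layer, dropout 0.2, Adam with learning rate 0.0025, at most 50 epochs.
All fields are overridable for desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from pulse2abp import nn
from pulse2abp.preprocess import GlobalNormParams, NormParams, fit_global_norm, invert_norm, zscore

RECONSTRUCTION = "reconstruction"
TRANSLATION = "translation"


class ContractError(RuntimeError):
    """A stage/freeze contract of the two-stage procedure was violated."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class ModelConfig:
    encoder_layers: int = 2
    decoder_layers: int = 2
    hidden_units: int = 128
    dropout_rate: float = 0.2
    learning_rate: float = 0.0025
    max_epochs: int = 50
    batch_size: int = 128
    patience: int = 5
    grad_clip: float = 5.0
    input_channels: int = 3
    output_channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.encoder_layers, self.decoder_layers, self.hidden_units,
               self.batch_size, self.input_channels, self.output_channels) < 1:
            raise ValueError("layer counts, sizes and batch size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainReport:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_early: bool
    param_digest: str


@dataclass
class TranslatorModel:
    """Encoder/decoder recurrent network with a stage flag.

    ``stage`` is ``"reconstruction"`` until `freeze_encoder` promotes the
    model to ``"translation"``; once frozen, encoder parameters are
    bit-identical across any further training.
    """

    config: ModelConfig
    encoder: nn.Sequential
    decoder: nn.Sequential
    stage: str = RECONSTRUCTION
    encoder_frozen: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        latent = self.encoder.forward(x, train=train and not self.encoder_frozen)
        return self.decoder.forward(latent, train=train)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """(n, T, C) -> (n, T) prediction in normalized target units."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.config.input_channels:
            raise ValueError(
                f"expected (n, T, {self.config.input_channels}) input, got {x.shape}"
            )
        if x.shape[1] < 3:
            raise ValueError("sequence length must be >= 3")
        return self.forward(x, train=False)[..., 0]

    def encoder_digest(self) -> str:
        return nn.parameter_digest([self.encoder])

    def decoder_digest(self) -> str:
        return nn.parameter_digest([self.decoder])

    def digest(self) -> str:
        return nn.parameter_digest([self.encoder, self.decoder])

    def trainable_params(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        nets = [self.decoder] if self.encoder_frozen else [self.encoder, self.decoder]
        params = [p for net in nets for _, _, p in net.param_items()]
        grads = [
            layer.grads()[name]
            for net in nets
            for layer, name, _ in net.param_items()
        ]
        return params, grads

    # -- persistence -----------------------------------------------------
    def save(self, path: Path) -> None:
        path = Path(path)
        arrays = {}
        for prefix, net in (("enc", self.encoder), ("dec", self.decoder)):
            for li, layer in enumerate(net.layers):
                for name, arr in layer.params().items():
                    arrays[f"{prefix}.{li}.{name}"] = arr
        header = {
            "config": asdict(self.config),
            "stage": self.stage,
            "encoder_frozen": self.encoder_frozen,
        }
        np.savez(path, __header__=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: Path) -> "TranslatorModel":
        with np.load(Path(path), allow_pickle=False) as data:
            header = json.loads(str(data["__header__"]))
            model = build_model(ModelConfig(**header["config"]))
            model.stage = header["stage"]
            model.encoder_frozen = header["encoder_frozen"]
            for prefix, net in (("enc", model.encoder), ("dec", model.decoder)):
                for li, layer in enumerate(net.layers):
                    for name, arr in layer.params().items():
                        arr[:] = data[f"{prefix}.{li}.{name}"]
        return model


def build_model(config: ModelConfig) -> TranslatorModel:
    """Build a seeded, reproducible translator in the reconstruction stage."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    H = config.hidden_units
    enc_layers: list[nn.Layer] = []
    in_dim = config.input_channels
    for _ in range(config.encoder_layers):
        enc_layers.append(nn.LSTM(in_dim, H, rng))
        in_dim = H
    dec_layers: list[nn.Layer] = []
    for _ in range(config.decoder_layers):
        dec_layers.append(nn.LSTM(in_dim, H, rng))
        in_dim = H
    dec_layers.append(nn.Dropout(config.dropout_rate, rng))
    dec_layers.append(nn.Dense(H, config.output_channels, rng))
    return TranslatorModel(
        config=config,
        encoder=nn.Sequential(enc_layers),
        decoder=nn.Sequential(dec_layers),
        rng=rng,
    )


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected (n, T, C) array of feature stacks, got {x.shape}")
    return x


def _encode_batched(model: "TranslatorModel", X: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [
        model.encoder.forward(X[i : i + batch_size], train=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _train_loop(
    model: TranslatorModel,
    X: np.ndarray,
    Y: np.ndarray,
    X_val: np.ndarray | None,
    Y_val: np.ndarray | None,
    config: ModelConfig,
) -> TrainReport:
    params, grads = model.trainable_params()
    opt = nn.Adam(params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    if model.encoder_frozen:
        # the encoder is deterministic and fixed: encode the corpus once
        # and train the decoder on cached latent sequences
        X = _encode_batched(model, X, config.batch_size)
        if X_val is not None:
            X_val = _encode_batched(model, X_val, config.batch_size)
        forward = lambda xb, train: model.decoder.forward(xb, train=train)
    else:
        forward = lambda xb, train: model.forward(xb, train=train)
    n = X.shape[0]
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    stopped_early = False
    monitor_val = X_val is not None and len(X_val) > 0

    def snapshot():
        return [p.copy() for p in params]

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            for net in (model.encoder, model.decoder):
                net.zero_grad()
            pred = forward(xb, train=True)
            loss, dloss = nn.mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch start {start} "
                    f"(lr={config.learning_rate}, batch_size={config.batch_size})"
                )
            dlatent = model.decoder.backward(
                dloss.astype(np.float32),
                need_input_grad=not model.encoder_frozen,
            )
            if not model.encoder_frozen:
                model.encoder.backward(dlatent, need_input_grad=False)
            nn.clip_global_norm(grads, config.grad_clip)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        train_losses.append(epoch_loss / n)

        if monitor_val:
            val_pred = forward(X_val, train=False)
            val_loss, _ = nn.mse_loss(val_pred, Y_val)
        else:
            val_loss = train_losses[-1]
        val_losses.append(val_loss)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(
                f"non-finite validation loss at epoch {epoch} "
                f"(lr={config.learning_rate}, batch_size={config.batch_size})"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = snapshot()
        elif config.patience > 0 and epoch - best_epoch >= config.patience:
            stopped_early = True
            break

    if best_state is not None:
        for p, b in zip(params, best_state):
            p[:] = b
    return TrainReport(
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=max(best_epoch, 0),
        stopped_early=stopped_early,
        param_digest=model.digest(),
    )


def train_reconstruction(
    model: TranslatorModel,
    stacks: np.ndarray,
    val_stacks: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> TrainReport:
    """Stage 1: train the autoencoder to reproduce the PPG channel.

    The target is channel 0 of each feature stack, so the decoder head
    has the same one-channel shape it will keep in the translation
    stage.
    """
    if model.stage != RECONSTRUCTION:
        raise ContractError(
            f"reconstruction training requires stage={RECONSTRUCTION!r}, "
            f"model is in stage {model.stage!r}"
        )
    config = config or model.config
    X = _as_batch(stacks)
    Y = X[..., :1].copy()
    Xv = _as_batch(val_stacks) if val_stacks is not None else None
    Yv = Xv[..., :1].copy() if Xv is not None else None
    return _train_loop(model, X, Y, Xv, Yv, config)


def freeze_encoder(model: TranslatorModel) -> TranslatorModel:
    """Freeze the encoder and promote the model to the translation stage.

    Decoder parameters are carried over (transferred, not re-initialized)
    and remain trainable.  Idempotent.
    """
    model.encoder_frozen = True
    model.stage = TRANSLATION
    return model


def train_translation(
    model: TranslatorModel,
    stacks: np.ndarray,
    abp_targets: np.ndarray,
    val_stacks: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    config: ModelConfig | None = None,
) -> TrainReport:
    """Stage 2: decoder-only training against normalized ABP targets.

    Refuses to run on an unfrozen encoder — silent full fine-tuning
    would defeat the transfer-learning contract.
    """
    if model.stage != TRANSLATION or not model.encoder_frozen:
        raise ContractError(
            "translation training requires a frozen encoder; call "
            "freeze_encoder(model) after reconstruction training"
        )
    config = config or model.config
    X = _as_batch(stacks)
    Y = np.asarray(abp_targets, dtype=np.float32)
    if Y.ndim == 2:
        Y = Y[..., None]
    Xv = _as_batch(val_stacks) if val_stacks is not None else None
    Yv = None
    if val_targets is not None:
        Yv = np.asarray(val_targets, dtype=np.float32)
        if Yv.ndim == 2:
            Yv = Yv[..., None]
    return _train_loop(model, X, Y, Xv, Yv, config)


def translate(
    model: TranslatorModel,
    stacks: np.ndarray,
    abp_norm: GlobalNormParams | None,
) -> np.ndarray:
    """Map PPG feature stacks to predicted ABP waveforms in mmHg.

    ``stacks`` may be a single (T, 3) stack or a batch (n, T, 3); any
    sequence length T >= 3 is accepted.  The network's normalized output
    is inverted to mmHg with the global ABP normalization parameters.
    """
    if model.stage != TRANSLATION:
        raise ContractError("translate requires a translation-stage model")
    if abp_norm is None:
        raise ValueError(
            "global ABP normalization parameters are required to invert "
            "predictions to mmHg; pass the sidecar saved at training time"
        )
    x = np.asarray(stacks, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    z = model.predict(x)
    out = invert_norm(z, abp_norm)
    return out[0] if single else out


class PpgToAbpTranslator(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the two-stage translator.

    ``fit(X, y)`` takes normalized PPG feature stacks ``X`` of shape
    (n, T, 3) and raw ABP waveforms ``y`` of shape (n, T) in mmHg; it
    fits the global ABP normalization, runs reconstruction training,
    freezes the encoder, and runs translation training.  ``predict(X)``
    returns ABP waveforms in mmHg.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        encoder_layers: int = 2,
        decoder_layers: int = 2,
        dropout_rate: float = 0.2,
        learning_rate: float = 0.0025,
        max_epochs: int = 50,
        batch_size: int = 128,
        patience: int = 5,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _config(self) -> ModelConfig:
        return ModelConfig(
            encoder_layers=self.encoder_layers,
            decoder_layers=self.decoder_layers,
            hidden_units=self.hidden_units,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = _as_batch(X).astype(np.float64)
        y = np.asarray(y, dtype=np.float64)
        if y.shape != X.shape[:2]:
            raise ValueError(
                f"y must be (n, T) ABP waveforms matching X, got {y.shape}"
            )
        per_signal = []
        y_z = np.empty_like(y)
        for i in range(len(y)):
            _, p = zscore(y[i])
            per_signal.append(p)
        self.abp_norm_ = fit_global_norm(per_signal)
        for i in range(len(y)):
            y_z[i] = (y[i] - self.abp_norm_.mu_bar) / self.abp_norm_.sigma_bar

        rng = np.random.default_rng(self.seed + 17)
        n = len(X)
        n_val = int(round(self.validation_fraction * n))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        Xt, Xv = X[train_idx], X[val_idx] if n_val else None
        yt = y_z[train_idx]
        yv = y_z[val_idx] if n_val else None

        cfg = self._config()
        self.model_ = build_model(cfg)
        self.recon_report_ = train_reconstruction(self.model_, Xt, Xv, cfg)
        freeze_encoder(self.model_)
        self.encoder_digest_ = self.model_.encoder_digest()
        self.trans_report_ = train_translation(self.model_, Xt, yt, Xv, yv, cfg)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return translate(self.model_, np.asarray(X, dtype=np.float64), self.abp_norm_)
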