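"""Recurrent sequence-to-vector regressors for the CV-distribution inverse
problem.

A model consumes one CMAP waveform — a length-251 univariate sequence — and
regresses the 28-bin axon-count histogram.  Architectures follow the study
grid: simple RNN (one layer only), LSTM and GRU with 1-3 layers, each
optionally bidirectional, with dropout after every recurrent layer and a
dense projection to the 28 outputs.  Training uses MSE loss, Adam, and
early stopping on the *training* loss with a small patience.

The reported "accuracy" is dominant-bin accuracy: the fraction of cases in
which the predicted histogram's largest bin coincides with the true one.
Predicted counts are rounded half-away-from-zero and clipped at zero when a
discrete histogram is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .cv import CVHistogram, N_BINS
from .simulate import DatasetSplit, WAVEFORM_SAMPLES, corpus_arrays

CELLS = ("simple_rnn", "lstm", "gru")
_CELL_CLS = {"simple_rnn": nn.SimpleRNN, "lstm": nn.LSTM, "gru": nn.GRU}


@dataclass(frozen=True)
class ModelSpec:
    """One architecture from the comparison grid."""

    cell: str = "lstm"
    bidirectional: bool = True
    n_layers: int = 2
    hidden_units: int = 1000
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.cell not in CELLS:
            raise ValueError(f"cell must be one of {CELLS}, got {self.cell!r}")
        if not (1 <= self.n_layers <= 3):
            raise ValueError("n_layers must be 1, 2 or 3")
        if self.cell == "simple_rnn" and (self.n_layers != 1 or self.bidirectional):
            raise ValueError(
                "simple_rnn is only supported unidirectional with a single "
                "layer (the grid does not stack or mirror it)"
            )
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")

    @property
    def name(self) -> str:
        prefix = "bi_" if self.bidirectional else ""
        return f"{prefix}{self.cell}_{self.n_layers}l_{self.hidden_units}u"


def grid_specs(hidden_units: int = 1000, dropout_rate: float = 0.5) -> list[ModelSpec]:
    """The 13-network comparison grid: simple RNN (1 layer) plus LSTM/GRU x
    uni/bidirectional x 1-3 layers."""
    specs = [ModelSpec("simple_rnn", False, 1, hidden_units, dropout_rate)]
    for cell in ("lstm", "gru"):
        for bidir in (False, True):
            for n_layers in (1, 2, 3):
                specs.append(ModelSpec(cell, bidir, n_layers, hidden_units, dropout_rate))
    return specs


@dataclass(frozen=True)
class TrainConfig:
    """Fixed training hyperparameters (MSE + Adam + early stop on loss)."""

    max_epochs: int = 1000
    batch_size: int = 2048
    learning_rate: float = 1e-3
    early_stop_patience: int = 2
    seed: int = 0
    standardize: bool = False    # optional input z-scoring; off by default
    #: Optimize on per-bin z-scored targets (inverted at prediction time).
    #: Purely a numerical-conditioning device: reported losses and metrics
    #: are always on the raw axon-count scale.
    scale_targets: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 0:
            raise ValueError("patience must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    """Per-epoch curves plus final metrics; one row per completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    @property
    def final_training_loss(self) -> float:
        return self.train_loss[-1]

    @property
    def final_training_accuracy(self) -> float:
        return self.train_accuracy[-1]

    @property
    def final_validation_loss(self) -> float:
        return self.val_loss[-1]

    @property
    def final_validation_accuracy(self) -> float:
        return self.val_accuracy[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_acc": self.val_accuracy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class SequenceRegressor:
    """A built architecture: (251, 1) sequence in, 28 real outputs out."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        input_dim = 1
        cls = _CELL_CLS[spec.cell]
        for i in range(spec.n_layers):
            return_seq = i < spec.n_layers - 1
            if spec.bidirectional:
                layer = nn.Bidirectional(
                    cls(input_dim, spec.hidden_units, rng, return_seq),
                    cls(input_dim, spec.hidden_units, rng, return_seq),
                )
                input_dim = 2 * spec.hidden_units
            else:
                layer = cls(input_dim, spec.hidden_units, rng, return_seq)
                input_dim = spec.hidden_units
            layers.append(layer)
            layers.append(nn.Dropout(spec.dropout_rate))
        layers.append(nn.Dense(input_dim, N_BINS, rng))
        self.net = nn.Sequential(layers)
        self.input_mean = 0.0
        self.input_scale = 1.0
        # affine output transform (identity unless the trainer standardized
        # the targets); predictions are always returned on the count scale
        self.output_mean = np.zeros(N_BINS, dtype=nn.F32)
        self.output_scale = np.ones(N_BINS, dtype=nn.F32)
        self.trained = False

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def _prep(self, waveforms: np.ndarray) -> np.ndarray:
        x = np.asarray(waveforms, dtype=nn.F32)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != WAVEFORM_SAMPLES:
            raise ValueError(f"waveforms must have {WAVEFORM_SAMPLES} samples")
        x = (x - nn.F32(self.input_mean)) / nn.F32(self.input_scale)
        return x[:, :, None]

    def predict(self, waveforms: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Raw (unrounded) 28-vector predictions, inference mode."""
        x = self._prep(waveforms)
        outs = [
            self.net.forward(x[i: i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        raw = np.concatenate(outs, axis=0)
        return raw * self.output_scale + self.output_mean


def build_model(spec: ModelSpec, seed: int = 0) -> SequenceRegressor:
    """Instantiate a regressor for an architecture spec (seeded init)."""
    return SequenceRegressor(spec, seed=seed)


def dominant_bin_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of rows whose predicted argmax bin equals the true argmax
    bin (ties broken toward the first index)."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape or p.ndim != 2:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(np.mean(np.argmax(p, axis=1) == np.argmax(y, axis=1)))


def round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def predict_histogram(model: SequenceRegressor, waveform: np.ndarray) -> CVHistogram:
    """Round one waveform's raw prediction to integer counts (half away
    from zero, clipped at 0).  The rounded counts are reported as-is: the
    network is not constrained to conserve the 200-axon total."""
    if not model.trained:
        raise ValueError("model has not been trained")
    raw = model.predict(np.asarray(waveform))[0]
    counts = np.clip(round_half_away_from_zero(raw), 0, None).astype(int)
    return CVHistogram(counts)


def train(
    model: SequenceRegressor,
    split: DatasetSplit,
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Fit with MSE + Adam; early-stops when the training loss fails to
    improve for ``early_stop_patience`` consecutive epochs (patience 0
    stops at the first non-improving epoch).  The held-out partition of
    the split provides the per-epoch validation metrics."""
    if not split.train:
        raise ValueError("training partition is empty")
    Xtr, Ytr, _ = corpus_arrays(split.train)
    if split.test:
        Xte, Yte, _ = corpus_arrays(split.test)
    else:
        Xte = Yte = None
    if cfg.standardize:
        model.input_mean = float(Xtr.mean())
        model.input_scale = float(Xtr.std()) or 1.0
    if cfg.scale_targets:
        model.output_mean = Ytr.mean(axis=0).astype(nn.F32)
        model.output_scale = np.maximum(Ytr.std(axis=0), 1e-6).astype(nn.F32)

    x = model._prep(Xtr)
    y_raw = Ytr.astype(nn.F32)
    y = (y_raw - model.output_mean) / model.output_scale
    scale_sq = (model.output_scale.astype(np.float64)) ** 2
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    result = TrainResult()
    best = np.inf
    wait = 0
    stop_after = max(cfg.early_stop_patience, 1)
    n = len(x)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            model.net.zero_grad()
            pred = model.net.forward(xb, training=True, rng=rng)
            _, dpred = nn.mse_loss(pred, yb)
            model.net.backward(dpred)
            opt.step()
            # report on the raw count scale regardless of target scaling
            diff_sq = (pred.astype(np.float64) - yb) ** 2 * scale_sq
            losses.append(float(diff_sq.mean()) * len(idx))
            pred_raw = pred * model.output_scale + model.output_mean
            hits += int(np.sum(np.argmax(pred_raw, 1) == np.argmax(y_raw[idx], 1)))
        epoch_loss = float(np.sum(losses) / n)
        result.train_loss.append(epoch_loss)
        result.train_accuracy.append(hits / n)
        if Xte is not None:
            vp = model.predict(Xte)
            vl, _ = nn.mse_loss(vp.astype(nn.F32), Yte.astype(nn.F32))
            result.val_loss.append(vl)
            result.val_accuracy.append(dominant_bin_accuracy(vp, Yte))
        else:
            result.val_loss.append(float("nan"))
            result.val_accuracy.append(float("nan"))
        result.stopped_epoch = epoch
        if epoch_loss < best:
            best = epoch_loss
            wait = 0
        else:
            wait += 1
            if wait >= stop_after:
                break
    model.trained = True
    return result


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: SequenceRegressor, directory) -> None:
    """Write spec.json + weights.npz into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = asdict(model.spec)
    meta["input_mean"] = model.input_mean
    meta["input_scale"] = model.input_scale
    meta["trained"] = model.trained
    (d / "spec.json").write_text(json.dumps(meta, indent=2))
    weights = model.net.get_weights()
    np.savez(
        d / "weights.npz",
        output_mean=model.output_mean,
        output_scale=model.output_scale,
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_model(directory) -> SequenceRegressor:
    d = Path(directory)
    meta = json.loads((d / "spec.json").read_text())
    trained = meta.pop("trained", True)
    mean = meta.pop("input_mean", 0.0)
    scale = meta.pop("input_scale", 1.0)
    model = SequenceRegressor(ModelSpec(**meta))
    with np.load(d / "weights.npz") as data:
        n_w = sum(1 for k in data.files if k.startswith("w"))
        weights = [data[f"w{i}"] for i in range(n_w)]
        model.output_mean = data["output_mean"]
        model.output_scale = data["output_scale"]
    model.net.set_weights(weights)
    model.input_mean = mean
    model.input_scale = scale
    model.trained = trained
    return model
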