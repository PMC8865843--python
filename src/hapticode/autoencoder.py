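"""Convolutional autoencoder for 80 ms vibrotactile segments.

The model compresses a 256-sample acceleration segment (80 ms at 3200 Hz)
through four same-padding 1-D convolutional layers (kernel size 5) with
max-pooling by 4 after each, so the temporal axis shrinks 256 -> 64 -> 16 ->
4 -> 1 and the bottleneck is a single time step of ``latent_dim`` features
(the *code*). The decoder mirrors the encoder with step-repetition
upsampling and ends in a sigmoid layer so reconstructions live in (0, 1).
Training minimizes mean absolute error with Adam.

The bottleneck is parameterizable: for a latent dimensionality ``d`` every
intermediate layer's feature count is clamped to at least ``d`` so that no
layer is narrower than the code itself, which is what makes the compression
sweep (6.25% ... 100% compression rate) well defined.
"""

from __future__ import annotations

import ast
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, Conv1D, MaxPool1D, Sequential, UpSample1D, mae_loss

__all__ = [
    "AutoencoderSpec",
    "build",
    "ConvAutoencoder",
    "train",
    "encode",
    "reconstruction_r2",
    "compression_rate",
    "save_model",
    "load_model",
]

INPUT_LENGTH = 256
KERNEL_SIZE = 5
POOL = 4
# feature counts of the reference 16-dim architecture; clamped to >= latent_dim
_ENCODER_BASE = (64, 32, 16)
_DECODER_BASE = (16, 32, 64)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture contract of the autoencoder for one bottleneck size."""

    latent_dim: int
    input_length: int = INPUT_LENGTH
    kernel_size: int = KERNEL_SIZE
    pool: int = POOL
    encoder_channels: tuple = field(default=())
    decoder_channels: tuple = field(default=())

    def layer_schedule(self):
        """(name, in_len, in_ch, out_len, out_ch) for every conv layer.

        Convolutions preserve time length (same padding); each encoder conv
        is followed by pooling, each decoder conv but the last by upsampling.
        """
        rows = []
        L = self.input_length
        ch = 1
        for i, c in enumerate(self.encoder_channels):
            rows.append((f"enc_conv{i + 1}", L, ch, L, c))
            L //= self.pool
            ch = c
        for i, c in enumerate(self.decoder_channels[:-1]):
            rows.append((f"dec_conv{i + 1}", L, ch, L, c))
            L *= self.pool
            ch = c
        rows.append((f"dec_conv{len(self.decoder_channels)}", L, ch, L, self.decoder_channels[-1]))
        return rows


def build(latent_dim: int) -> AutoencoderSpec:
    """Architecture spec for a given bottleneck dimensionality.

    Encoder feature counts are (64, 32, 16, latent_dim) and decoder counts
    (latent_dim, 16, 32, 64, 1), with every intermediate count clamped to at
    least ``latent_dim``.
    """
    if not isinstance(latent_dim, (int, np.integer)) or isinstance(latent_dim, bool):
        raise ValueError("latent_dim must be an integer")
    if not 1 <= latent_dim <= INPUT_LENGTH:
        raise ValueError(f"latent_dim must be in [1, {INPUT_LENGTH}], got {latent_dim}")
    d = int(latent_dim)
    enc = tuple(max(c, d) for c in _ENCODER_BASE) + (d,)
    dec = (d,) + tuple(max(c, d) for c in _DECODER_BASE) + (1,)
    return AutoencoderSpec(latent_dim=d, encoder_channels=enc, decoder_channels=dec)


def compression_rate(latent_dim: int, input_dim: int = INPUT_LENGTH) -> float:
    """Latent over input dimensionality, in percent (16/256 -> 6.25)."""
    if latent_dim <= 0 or input_dim <= 0:
        raise ValueError("dimensionalities must be positive")
    return 100.0 * latent_dim / input_dim


def _check_segments(X, input_length: int) -> np.ndarray:
    X = np.asarray(getattr(X, "data", X), dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != input_length:
        raise ValueError(f"expected segments of shape (N, {input_length}), got {X.shape}")
    if X.min() < -1e-6 or X.max() > 1.0 + 1e-6:
        raise ValueError("segments must be normalized to [0, 1] before the autoencoder")
    return X


class ConvAutoencoder(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator around the convolutional autoencoder.

    Parameters
    ----------
    latent_dim : int, default 16
        Bottleneck width; 16 gives a 6.25% compression rate on 256-sample
        input.
    epochs : int, default 50
        Training epochs of the MAE objective.
    batch_size, learning_rate :
        Adam minibatch settings.
    random_state : int or None
        Seeds weight initialization and minibatch shuffling; a fixed seed
        makes training bit-reproducible on one CPU.

    Attributes
    ----------
    spec_ : AutoencoderSpec
    encoder_, decoder_ : Sequential
    training_report_ : pandas.DataFrame with per-epoch train (and, when a
        validation set was supplied, validation) mean absolute error.
    """

    def __init__(self, latent_dim: int = 16, epochs: int = 50, batch_size: int = 128,
                 learning_rate: float = 1e-3, random_state: int | None = None):
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- construction -----------------------------------------------------
    def _build_net(self, rng: np.random.Generator) -> None:
        spec = build(self.latent_dim)
        enc_layers = []
        ch = 1
        for c in spec.encoder_channels:
            enc_layers.append(Conv1D(ch, c, spec.kernel_size, "relu", rng))
            enc_layers.append(MaxPool1D(spec.pool))
            ch = c
        dec_layers = []
        for c in spec.decoder_channels[:-1]:
            dec_layers.append(Conv1D(ch, c, spec.kernel_size, "relu", rng))
            dec_layers.append(UpSample1D(spec.pool))
            ch = c
        dec_layers.append(Conv1D(ch, 1, spec.kernel_size, "sigmoid", rng))
        self.spec_ = spec
        self.encoder_ = Sequential(enc_layers)
        self.decoder_ = Sequential(dec_layers)

    def _calibrate_init(self, X: np.ndarray) -> None:
        """LSUV-style variance calibration of the initial weights.

        Wide bottlenecks compound the max-pool amplification until the
        output sigmoid saturates at initialization and training stalls;
        rescaling each convolution so its initial activations have unit RMS
        (and the pre-sigmoid output roughly unit scale) makes every
        bottleneck size start in the responsive range.
        """
        x = X[: min(256, X.shape[0])].astype(np.float32)[None, :, :]
        for layer in self.encoder_.layers + self.decoder_.layers:
            if isinstance(layer, Conv1D) and layer.activation == "relu":
                pre = layer.forward(x)
                rms = float(np.sqrt(np.mean(pre**2)))
                if rms > 0:
                    layer.W /= rms
                    layer.b /= rms
            x = layer.forward(x)

    # -- training ----------------------------------------------------------
    def fit(self, X, y=None, validation=None):
        X = _check_segments(X, INPUT_LENGTH)
        rng = np.random.default_rng(self.random_state)
        self._build_net(rng)
        self._calibrate_init(X)
        net = Sequential(self.encoder_.layers + self.decoder_.layers)
        # width-compensated steps: per-unit drift per Adam step scales with
        # fan-in, so wide bottleneck variants need proportionally smaller
        # steps or their sigmoid output saturates within a few batches
        scales = []
        for layer in net.layers:
            if isinstance(layer, Conv1D):
                mult = min(1.0, 160.0 / (layer.in_channels * layer.kernel_size))
                scales.extend([mult, mult])  # W and b
        opt = Adam(net.params, lr=self.learning_rate, lr_scales=scales)
        n = X.shape[0]
        report = []
        X_val = None if validation is None else _check_segments(validation, INPUT_LENGTH)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                batch = X[order[start : start + self.batch_size]][None, :, :]
                out = net.forward(batch, training=True)
                loss, grad = mae_loss(out, batch)
                net.backward(grad)
                opt.step()
                losses.append(loss)
            row = {"epoch": epoch + 1, "train_mae": float(np.mean(losses))}
            if X_val is not None:
                row["val_mae"] = float(np.abs(self._reconstruct_array(X_val) - X_val).mean())
            report.append(row)
        self.training_report_ = pd.DataFrame(report)
        self.n_features_in_ = INPUT_LENGTH
        return self

    def _forward_batched(self, net: Sequential, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        # X is channels-first (C, N, L); chunk over the batch axis
        outs = [net.forward(X[:, i : i + chunk]) for i in range(0, X.shape[1], chunk)]
        return np.concatenate(outs, axis=1)

    # -- inference ---------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Encode segments into the (N, latent_dim) code matrix."""
        self._check_is_fitted()
        X = _check_segments(X, INPUT_LENGTH)
        codes = self._forward_batched(self.encoder_, X[None, :, :])
        return codes[:, :, 0].T.astype(np.float64)

    def inverse_transform(self, codes: np.ndarray) -> np.ndarray:
        """Decode (N, latent_dim) codes back into 256-sample segments."""
        self._check_is_fitted()
        codes = np.asarray(codes, dtype=np.float32)
        if codes.ndim != 2 or codes.shape[1] != self.spec_.latent_dim:
            raise ValueError(f"expected codes of shape (N, {self.spec_.latent_dim})")
        out = self._forward_batched(self.decoder_, codes.T[:, :, None])
        return out[0].astype(np.float64)

    def _reconstruct_array(self, X: np.ndarray) -> np.ndarray:
        net = Sequential(self.encoder_.layers + self.decoder_.layers)
        return self._forward_batched(net, X[None, :, :])[0]

    def reconstruct(self, X) -> np.ndarray:
        """decode(encode(X)); values lie strictly in (0, 1)."""
        self._check_is_fitted()
        X = _check_segments(X, INPUT_LENGTH)
        return self._reconstruct_array(X).astype(np.float64)

    def score(self, X, y=None) -> float:
        return reconstruction_r2(self, X)

    def _check_is_fitted(self):
        if not hasattr(self, "encoder_"):
            raise RuntimeError("ConvAutoencoder is not fitted; call fit() first")


def save_model(model: ConvAutoencoder, path) -> None:
    """Save weights + hyperparameters to an .npz checkpoint."""
    model._check_is_fitted()
    arrays = {}
    convs = [l for l in model.encoder_.layers + model.decoder_.layers if isinstance(l, Conv1D)]
    for i, layer in enumerate(convs):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    params = model.get_params()
    arrays["param_names"] = np.array(sorted(params), dtype=object)
    arrays["param_values"] = np.array([repr(params[k]) for k in sorted(params)], dtype=object)
    report = getattr(model, "training_report_", pd.DataFrame())
    arrays["report_json"] = np.array(report.to_json(orient="split"), dtype=object)
    np.savez(path, **arrays)


def load_model(path) -> ConvAutoencoder:
    """Rebuild a ConvAutoencoder from an .npz checkpoint."""
    with np.load(path, allow_pickle=True) as data:
        params = {
            str(k): ast.literal_eval(str(v))
            for k, v in zip(data["param_names"], data["param_values"])
        }
        model = ConvAutoencoder(**params)
        model._build_net(np.random.default_rng(0))
        convs = [l for l in model.encoder_.layers + model.decoder_.layers if isinstance(l, Conv1D)]
        for i, layer in enumerate(convs):
            layer.W = data[f"W{i}"].astype(np.float32)
            layer.b = data[f"b{i}"].astype(np.float32)
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)
        model.training_report_ = pd.read_json(io.StringIO(str(data["report_json"])), orient="split")
    model.n_features_in_ = INPUT_LENGTH
    return model


def train(spec_or_dim, train_set, validation=None, epochs: int = 50, seed: int | None = None,
          batch_size: int = 128, learning_rate: float = 1e-3) -> ConvAutoencoder:
    """Fit a ConvAutoencoder; thin functional wrapper over the estimator."""
    latent_dim = spec_or_dim.latent_dim if isinstance(spec_or_dim, AutoencoderSpec) else int(spec_or_dim)
    model = ConvAutoencoder(latent_dim=latent_dim, epochs=epochs, batch_size=batch_size,
                            learning_rate=learning_rate, random_state=seed)
    return model.fit(train_set, validation=validation)


def encode(model: ConvAutoencoder, segments) -> np.ndarray:
    return model.transform(segments)


def reconstruction_r2(model: ConvAutoencoder, segments) -> float:
    """Mean squared Pearson correlation between segments and reconstructions.

    Each segment is correlated with its own reconstruction; r**2 is averaged
    over segments. Constant segments carry no correlation and are excluded
    with a warning.
    """
    X = _check_segments(segments, INPUT_LENGTH)
    recon = model.reconstruct(X)
    X = X.astype(np.float64)
    xs = X - X.mean(axis=1, keepdims=True)
    rs = recon - recon.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xs**2).sum(axis=1))
    r_norm = np.sqrt((rs**2).sum(axis=1))
    ok = x_norm > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} constant segment(s) from R^2")
    if not ok.any():
        raise ValueError("no non-constant segments to score")
    # a constant reconstruction of a varying segment explains no variance
    denom = np.where(r_norm[ok] > 0, x_norm[ok] * r_norm[ok], 1.0)
    r = np.where(r_norm[ok] > 0, (xs[ok] * rs[ok]).sum(axis=1) / denom, 0.0)
    return float(np.mean(r**2))
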