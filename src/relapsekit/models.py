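"""Autoencoder architectures for physiological day tensors, log-mel
spectrogram slices, and hourly HRV tensors.

Physiological sequence models consume (N, T, 10) sub-sequences of the
288x10 day tensor:

* ``fnn`` - 2 fully connected encoder and 2 decoder layers with ReLU and a
  dropout layer before the output.
* ``cnn`` - 4 downsampling blocks (1D convolution, batch norm, LeakyReLU)
  mirrored by 4 upsampling blocks and a final linear map.
* ``gru`` - sequence-to-sequence GRU (hidden size 100) with attention over
  the encoder outputs feeding the decoder.
* ``transformer`` - positional encoding, 4 stacked transformer encoder
  layers, the encoded sequence reversed into a 4-layer decoder of the same
  structure, and a final linear map.

Audio/HRV models:

* ``cae`` - 4 blocks of (2D convolution, ReLU, 2x2 max-pool) on 1x128x64
  spectrogram slices, decoded by alternating upsampling and convolutions.
* ``cvae`` - the CAE with the last encoder block replaced by parallel
  convolutional blocks estimating (mu, log sigma^2) of a latent Gaussian,
  trained with MSE + W_KL * KL to the isotropic unit Gaussian.
* ``cvae1d`` - the 1-D variational adaptation operating on 5x30 hourly HRV
  tensors.

Hidden widths, filter counts and kernel sizes are unexported defaults of
``ModelConfig``; the reference training hyper-parameters live in
:class:`relapsekit.detection.TrainSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm1d,
    Conv1d,
    Conv2d,
    Dropout,
    GRU,
    LayerNorm,
    Linear,
    MaxPool2d,
    Module,
    MultiheadSelfAttention,
    Tensor,
    positional_encoding,
)

__all__ = ["ModelConfig", "build_model", "ARCHITECTURES"]

ARCHITECTURES = ("fnn", "cnn", "gru", "transformer", "cae", "cvae", "cvae1d")


@dataclass(frozen=True)
class ModelConfig:
    fnn_hidden: int = 64
    fnn_latent: int = 32
    fnn_dropout: float = 0.2
    cnn_filters: tuple = (32, 64, 128, 256)
    cnn_kernel: int = 5
    gru_hidden: int = 100
    tr_d_model: int = 32
    tr_heads: int = 2
    tr_ff: int = 64
    tr_layers: int = 4
    cae_filters: tuple = (16, 32, 64, 128)
    cae_kernel: int = 3
    cvae1d_filters: tuple = (16, 32)
    cvae1d_latent: int = 64


class FNNAutoencoder(Module):
    def __init__(self, seq_len: int, n_features: int, cfg: ModelConfig, rng):
        super().__init__()
        n = seq_len * n_features
        self.seq_len, self.n_features = seq_len, n_features
        self.enc1 = Linear(n, cfg.fnn_hidden, rng)
        self.enc2 = Linear(cfg.fnn_hidden, cfg.fnn_latent, rng)
        self.dec1 = Linear(cfg.fnn_latent, cfg.fnn_hidden, rng)
        self.dec2 = Linear(cfg.fnn_hidden, n, rng)
        self.dropout = Dropout(cfg.fnn_dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        z = self.enc2(self.enc1(x.reshape(n, -1)).relu()).relu()
        y = self.dropout(self.dec1(z).relu())
        return self.dec2(y).reshape(n, self.seq_len, self.n_features)


class CNNAutoencoder(Module):
    """1-D convolutional AE over the temporal axis (stride-2 downsampling)."""

    def __init__(self, seq_len: int, n_features: int, cfg: ModelConfig, rng):
        super().__init__()
        if seq_len % 16:
            raise ValueError("cnn autoencoder needs a sequence length divisible by 16")
        self.seq_len, self.n_features = seq_len, n_features
        filters = cfg.cnn_filters
        chans = [n_features, *filters]
        self.enc_convs = [Conv1d(chans[i], chans[i + 1], cfg.cnn_kernel, rng, stride=2)
                          for i in range(4)]
        self.enc_bns = [BatchNorm1d(c) for c in filters]
        rev = [*filters[::-1], filters[0]]
        self.dec_convs = [Conv1d(rev[i], rev[i + 1], cfg.cnn_kernel, rng)
                          for i in range(4)]
        self.dec_bns = [BatchNorm1d(c) for c in rev[1:]]
        self.head = Linear(filters[0], n_features, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x.transpose(0, 2, 1)                     # (N, F, T)
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = bn(conv(h)).leaky_relu(0.01)
        for conv, bn in zip(self.dec_convs, self.dec_bns):
            h = bn(conv(h.upsample_nearest(2, 2))).leaky_relu(0.01)
        return self.head(h.transpose(0, 2, 1))


class GRUAutoencoder(Module):
    """Seq2seq GRU with attention from decoder state over encoder outputs."""

    def __init__(self, seq_len: int, n_features: int, cfg: ModelConfig, rng):
        super().__init__()
        h = cfg.gru_hidden
        self.encoder = GRU(n_features, h, rng)
        self.decoder_cell = GRU(h, h, rng).cell
        self.attn = Linear(h, h, rng)
        self.head = Linear(h, n_features, rng)
        self.hidden = h
        self.seq_len = seq_len

    def __call__(self, x: Tensor) -> Tensor:
        from .nn import stack

        enc_out, h = self.encoder(x)                 # (N, T, H)
        outputs = []
        state = h
        keys = enc_out.transpose(0, 2, 1)            # (N, H, T)
        for _ in range(self.seq_len):
            # attention weights from the current decoder state
            query = self.attn(state).reshape(state.shape[0], 1, self.hidden)
            scores = (query @ keys) * (1.0 / np.sqrt(self.hidden))
            weights = scores.softmax(axis=-1)        # (N, 1, T)
            context = (weights @ enc_out).reshape(state.shape[0], self.hidden)
            state = self.decoder_cell(context, state)
            outputs.append(self.head(state))
        return stack(outputs, axis=1)


class TransformerLayer(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.attn = MultiheadSelfAttention(cfg.tr_d_model, cfg.tr_heads, rng)
        self.norm1 = LayerNorm(cfg.tr_d_model)
        self.ff1 = Linear(cfg.tr_d_model, cfg.tr_ff, rng)
        self.ff2 = Linear(cfg.tr_ff, cfg.tr_d_model, rng)
        self.norm2 = LayerNorm(cfg.tr_d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff2(self.ff1(x).relu()))


class TransformerAutoencoder(Module):
    def __init__(self, seq_len: int, n_features: int, cfg: ModelConfig, rng):
        super().__init__()
        self.embed = Linear(n_features, cfg.tr_d_model, rng)
        self.pos = Tensor(positional_encoding(seq_len, cfg.tr_d_model))
        self.encoder = [TransformerLayer(cfg, rng) for _ in range(cfg.tr_layers)]
        self.decoder = [TransformerLayer(cfg, rng) for _ in range(cfg.tr_layers)]
        self.head = Linear(cfg.tr_d_model, n_features, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.embed(x) + self.pos
        for layer in self.encoder:
            h = layer(h)
        h = h.flip(1)                                # reversed into the decoder
        for layer in self.decoder:
            h = layer(h)
        return self.head(h)


class ConvAutoencoder2d(Module):
    """CAE for (N, 1, 128, 64) spectrogram slices."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        f = cfg.cae_filters
        chans = [1, *f]
        self.enc = [Conv2d(chans[i], chans[i + 1], cfg.cae_kernel, rng) for i in range(4)]
        self.pool = MaxPool2d(2)
        rev = [*f[::-1], f[0]]
        self.dec = [Conv2d(rev[i], rev[i + 1], cfg.cae_kernel, rng) for i in range(4)]
        self.out = Conv2d(f[0], 1, cfg.cae_kernel, rng)

    def encode(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.enc:
            h = self.pool(conv(h).relu())
        return h

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for conv in self.dec:
            h = conv(h.upsample_nearest(2, 2).upsample_nearest(3, 2)).relu()
        return self.out(h)

    def __call__(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


class ConvVAE2d(Module):
    """CVAE: parallel convolutional (mu, log sigma^2) blocks in the bottleneck."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        f = cfg.cae_filters
        chans = [1, *f[:-1]]
        self.enc = [Conv2d(chans[i], chans[i + 1], cfg.cae_kernel, rng) for i in range(3)]
        self.pool = MaxPool2d(2)
        self.conv_mu = Conv2d(f[-2], f[-1], cfg.cae_kernel, rng)
        self.conv_logvar = Conv2d(f[-2], f[-1], cfg.cae_kernel, rng)
        rev = [*f[::-1], f[0]]
        self.dec = [Conv2d(rev[i], rev[i + 1], cfg.cae_kernel, rng) for i in range(4)]
        self.out = Conv2d(f[0], 1, cfg.cae_kernel, rng)
        self.rng = rng

    def encode(self, x: Tensor):
        h = x
        for conv in self.enc:
            h = self.pool(conv(h).relu())
        mu = self.pool(self.conv_mu(h))
        logvar = self.pool(self.conv_logvar(h))
        return mu, logvar

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for conv in self.dec:
            h = conv(h.upsample_nearest(2, 2).upsample_nearest(3, 2)).relu()
        return self.out(h)

    def reparameterize(self, mu: Tensor, logvar: Tensor, sample: bool = True):
        if not sample:
            return mu
        eps = Tensor(self.rng.standard_normal(mu.shape))
        return mu + (logvar * 0.5).exp() * eps

    def kl(self, mu: Tensor, logvar: Tensor) -> Tensor:
        """KL(N(mu, sigma^2) || N(0, I)) summed over latent units, per sample."""
        term = (mu * mu + logvar.exp() - logvar - 1.0) * 0.5
        return term.reshape(mu.shape[0], -1).sum(axis=1)

    def __call__(self, x: Tensor):
        mu, logvar = self.encode(x)
        z = self.reparameterize(mu, logvar, sample=self.training)
        return self.decode(z), mu, logvar


class ConvVAE1d(Module):
    """1-D CVAE for (N, 5, 30) hourly HRV tensors."""

    def __init__(self, n_features: int, seq_len: int, cfg: ModelConfig, rng):
        super().__init__()
        f = cfg.cvae1d_filters
        self.seq_len = seq_len
        self.c1 = Conv1d(n_features, f[0], 3, rng, stride=2)
        self.c2 = Conv1d(f[0], f[1], 3, rng, stride=2)
        self.conv_mu = Conv1d(f[1], cfg.cvae1d_latent, 3, rng)
        self.conv_logvar = Conv1d(f[1], cfg.cvae1d_latent, 3, rng)
        self.d1 = Conv1d(cfg.cvae1d_latent, f[1], 3, rng)
        self.d2 = Conv1d(f[1], f[0], 3, rng)
        self.head = Conv1d(f[0], n_features, 3, rng)
        self.rng = rng

    def encode(self, x: Tensor):
        h = self.c2(self.c1(x.transpose(0, 2, 1)).relu()).relu()
        return self.conv_mu(h), self.conv_logvar(h)

    def decode(self, z: Tensor) -> Tensor:
        h = self.d1(z.upsample_nearest(2, 2)).relu()
        h = self.d2(h.upsample_nearest(2, 2)).relu()
        out = self.head(h)[:, :, : self.seq_len]
        return out.transpose(0, 2, 1)

    reparameterize = ConvVAE2d.reparameterize
    kl = ConvVAE2d.kl

    def __call__(self, x: Tensor):
        mu, logvar = self.encode(x)
        z = self.reparameterize(mu, logvar, sample=self.training)
        return self.decode(z), mu, logvar


def build_model(architecture: str, input_shape: tuple,
                config: ModelConfig = ModelConfig(), seed: int = 0) -> Module:
    """Instantiate an untrained model for the given input shape.

    ``input_shape`` excludes the batch dimension: (T, F) for sequence
    models, (128, 64) for the spectrogram models, (30, 5) for the hourly
    HRV variational model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    if architecture == "fnn":
        return FNNAutoencoder(input_shape[0], input_shape[1], config, rng)
    if architecture == "cnn":
        return CNNAutoencoder(input_shape[0], input_shape[1], config, rng)
    if architecture == "gru":
        return GRUAutoencoder(input_shape[0], input_shape[1], config, rng)
    if architecture == "transformer":
        return TransformerAutoencoder(input_shape[0], input_shape[1], config, rng)
    if architecture in ("cae", "cvae"):
        if tuple(input_shape) != (128, 64):
            raise ValueError("spectrogram models expect 128x64 slices")
        return ConvAutoencoder2d(config, rng) if architecture == "cae" \
            else ConvVAE2d(config, rng)
    if architecture == "cvae1d":
        return ConvVAE1d(input_shape[1], input_shape[0], config, rng)
    raise ValueError(f"unknown architecture {architecture!r}")
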