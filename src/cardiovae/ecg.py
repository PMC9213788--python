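"""Time-series branch: convolutional ECG encoder and transposed-conv decoder.

The encoder runs the 400-sample standardized beat through two convolutional
blocks (convolution, ELU, batch normalization), an average-pooling layer and
two fully connected layers; the decoder mirrors it with a dense block and
two transposed convolutions whose padding is chosen by the config validator
so that the output length equals the input length exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (
    BatchNorm1d, Conv1d, ConvTranspose1d, ELU, Linear, MLP, Module, Sequential,
    Tensor,
)

__all__ = ["ECGBranchConfig", "ECGEncoder", "ECGDecoder"]


@dataclasses.dataclass
class ECGBranchConfig:
    length: int = 400
    conv_channels: tuple = (16, 32)
    kernel: int = 7
    stride: int = 2
    pool_window: int = 2
    fc_widths: tuple = (128, 64)
    decoder_dense_width: int = 64

    def __post_init__(self):
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd so 'same' padding is defined")
        if self.length % (self.stride ** 2) != 0:
            raise ValueError(
                f"ECG length {self.length} must be divisible by stride^2 = "
                f"{self.stride ** 2} for the decoder to reproduce it exactly")

    @property
    def padding(self) -> int:
        return (self.kernel - 1) // 2

    @property
    def enc_len_after_convs(self) -> int:
        l = self.length
        for _ in self.conv_channels:
            l = Conv1d.out_len(l, self.kernel, self.stride, self.padding)
        return l

    @property
    def enc_len_after_pool(self) -> int:
        return self.enc_len_after_convs // self.pool_window

    @property
    def dec_start_len(self) -> int:
        return self.length // (self.stride ** 2)

    @property
    def feature_width(self) -> int:
        return self.fc_widths[-1]

    def transposed_output_padding(self, in_len: int, target_len: int) -> int:
        base = ConvTranspose1d.out_len(in_len, self.kernel, self.stride,
                                       self.padding, 0)
        op = target_len - base
        if not (0 <= op < self.stride):
            raise ValueError(
                f"cannot reach length {target_len} from {in_len} with "
                f"kernel {self.kernel}, stride {self.stride}")
        return op


class ECGEncoder(Module):
    def __init__(self, config: ECGBranchConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        chans = (1, *config.conv_channels)
        blocks: list[Module] = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            blocks.extend([
                Conv1d(cin, cout, config.kernel, config.stride,
                       config.padding, rng),
                ELU(),
                BatchNorm1d(cout),
            ])
        self.conv = Sequential(*blocks)
        flat = config.conv_channels[-1] * config.enc_len_after_pool
        self.fc = MLP([flat, *config.fc_widths], rng)

    def forward(self, samples: np.ndarray | Tensor) -> Tensor:
        """(B, L) standardized samples -> (B, feature_width) branch feature."""
        if isinstance(samples, Tensor):
            samples = samples.data
        samples = np.atleast_2d(np.asarray(samples, dtype=np.float32))
        if samples.shape[1] != self.config.length:
            raise ValueError(
                f"ECG length {samples.shape[1]} != configured {self.config.length}")
        b = samples.shape[0]
        x = Tensor(samples.reshape(b, 1, self.config.length))
        h = self.conv(x)                                  # (B, C, L')
        w = self.config.pool_window
        lp = h.shape[2] // w
        h = h[:, :, :lp * w].reshape(b, h.shape[1], lp, w).mean(axis=3)
        return self.fc(h.reshape(b, -1))


class ECGDecoder(Module):
    def __init__(self, config: ECGBranchConfig, latent_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.latent_dim = latent_dim
        c = config.conv_channels
        l0 = config.dec_start_len
        self.dense = MLP([latent_dim, config.decoder_dense_width, c[-1] * l0],
                         rng, final_activation=True)
        l1 = l0 * config.stride
        self.deconv1 = ConvTranspose1d(
            c[-1], c[0], config.kernel, config.stride, config.padding,
            config.transposed_output_padding(l0, l1), rng)
        self.act = ELU()
        self.deconv2 = ConvTranspose1d(
            c[0], 1, config.kernel, config.stride, config.padding,
            config.transposed_output_padding(l1, config.length), rng)

    def forward(self, z: Tensor) -> Tensor:
        """(B, latent) -> (B, L) reconstructed standardized-scale samples."""
        if z.shape[-1] != self.latent_dim:
            raise ValueError(
                f"latent dimension mismatch: got {z.shape[-1]}, expected {self.latent_dim}")
        b = z.shape[0]
        cfg = self.config
        h = self.dense(z).reshape(b, cfg.conv_channels[-1], cfg.dec_start_len)
        h = self.act(self.deconv1(h))
        out = self.deconv2(h)                             # (B, 1, L)
        return out.reshape(b, cfg.length)
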