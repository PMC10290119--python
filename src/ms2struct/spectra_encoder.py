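"""Four-channel spectra encoder trained into the autoencoder's latent space.

Two strided 1-D convolutions followed by two fully connected layers map the
4 x L binned-intensity tensor to a vector the size of the SMILES embedding.
Training minimizes the RMSE between the spectra embedding and the frozen
autoencoder's embedding of the true molecule, so at inference the SMILES
decoder can read spectra embeddings as if they were molecule embeddings.
Missing spectra are all-zero channels — the encoder trains and predicts on
every availability pattern.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .autoencoder import SmilesAutoencoder
from .simulate import DatasetInstance
from .spectra import ChannelTensor, assemble_channels

logger = logging.getLogger(__name__)

__all__ = ["SpecEncoderConfig", "SpectraEncoder", "train_spectra_encoder", "encode_spectra"]


@dataclass(frozen=True)
class SpecEncoderConfig:
    """Exactly two convolutional and two fully connected stages.

    ``fc_sizes[-1]`` must equal the companion autoencoder's ``d_embed``.
    Wide kernels with stride pooling shrink the m/z axis; ReLU sits between
    all stages.
    """

    conv_channels: tuple[int, int] = (16, 32)
    kernel_sizes: tuple[int, int] = (9, 7)
    strides: tuple[int, int] = (3, 3)
    fc_sizes: tuple[int, int] = (256, 96)
    input_len: int = 500
    lr: float = 1.5e-3
    lr_final: float = 3e-4
    batch_size: int = 64
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 2 or len(self.fc_sizes) != 2:
            raise ValueError("exactly two conv and two fully connected stages")


class SpectraEncoder:
    """CNN mapping a ChannelTensor to the shared embedding space."""

    def __init__(self, config: SpecEncoderConfig, ae_hash: str = "") -> None:
        self.config = config
        self.ae_hash = ae_hash  # weights hash of the companion AE
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.conv_channels
        k1, k2 = config.kernel_sizes
        s1, s2 = config.strides
        self.conv1 = nn.Conv1d(4, c1, k1, s1, rng)
        self.conv2 = nn.Conv1d(c1, c2, k2, s2, rng)
        l1 = self.conv1.out_len(config.input_len)
        l2 = self.conv2.out_len(l1)
        self._flat = c2 * l2
        self.fc1 = nn.Dense(self._flat, config.fc_sizes[0], rng)
        self.fc2 = nn.Dense(config.fc_sizes[0], config.fc_sizes[1], rng)

    @property
    def modules(self) -> list[nn.Module]:
        return [self.conv1, self.conv2, self.fc1, self.fc2]

    _prefixes = ["conv1", "conv2", "fc1", "fc2"]

    @property
    def d_out(self) -> int:
        return self.config.fc_sizes[1]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 4, L) -> (B, d_embed)."""
        if x.shape[1:] != (4, self.config.input_len):
            raise ValueError(
                f"expected input shape (B, 4, {self.config.input_len}), got {x.shape}"
            )
        a1 = self.conv1.forward(x.astype(nn.DTYPE))
        r1 = np.maximum(a1, 0.0)
        a2 = self.conv2.forward(r1)
        r2 = np.maximum(a2, 0.0)
        flat = r2.reshape(x.shape[0], -1)
        a3 = self.fc1.forward(flat)
        r3 = np.maximum(a3, 0.0)
        out = self.fc2.forward(r3)
        if train:
            self._cache = (a1, a2, r2.shape, a3)
        return out

    def backward(self, dout: np.ndarray) -> None:
        a1, a2, r2_shape, a3 = self._cache
        d3 = self.fc2.backward(dout)
        d3 *= a3 > 0
        dflat = self.fc1.backward(d3.astype(nn.DTYPE))
        d2 = dflat.reshape(r2_shape)
        d2 = d2 * (a2 > 0)
        d1 = self.conv2.backward(d2.astype(nn.DTYPE))
        d1 *= a1 > 0
        self.conv1.backward(d1.astype(nn.DTYPE))

    def encode_tensor(self, tensor: ChannelTensor) -> np.ndarray:
        """Deterministic embedding of one assembled channel tensor."""
        if tensor.values.shape[1] != self.config.input_len:
            raise ValueError(
                f"tensor length {tensor.values.shape[1]} != configured input_len "
                f"{self.config.input_len}"
            )
        return self.forward(tensor.values[None, :, :])[0]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        header = json.dumps({"config": asdict(self.config), "ae_hash": self.ae_hash})
        state = nn.collect_params(self.modules, self._prefixes)
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "SpectraEncoder":
        archive = np.load(path)
        header = json.loads(archive["__header__"].tobytes().decode())
        cfg = header["config"]
        for key in ("conv_channels", "kernel_sizes", "strides", "fc_sizes"):
            cfg[key] = tuple(cfg[key])
        model = cls(SpecEncoderConfig(**cfg), ae_hash=header["ae_hash"])
        nn.load_params(model.modules, model._prefixes, archive)
        return model


def encode_spectra(encoder: SpectraEncoder, tensor: ChannelTensor) -> np.ndarray:
    return encoder.encode_tensor(tensor)


def _tensor_for(inst: DatasetInstance, input_len: int, bin_width: float) -> np.ndarray:
    return assemble_channels(
        inst.spectra, bin_width=bin_width, max_mz=input_len * bin_width
    ).values


def train_spectra_encoder(
    ae: SmilesAutoencoder,
    dataset: list[DatasetInstance],
    config: SpecEncoderConfig,
    val_dataset: list[DatasetInstance] | None = None,
    bin_width: float = 1.0,
) -> tuple[SpectraEncoder, list[dict]]:
    """Regress spectra embeddings onto frozen SMILES embeddings.

    The loss is the root of the mean squared componentwise error between the
    encoder output and the AE embedding of each instance's molecule, over
    the batch. The AE receives no gradient. The returned log has one row per
    epoch with training (and optionally validation) RMSE.
    """
    if config.fc_sizes[1] != ae.config.d_embed:
        raise ValueError(
            f"encoder output size {config.fc_sizes[1]} != AE d_embed {ae.config.d_embed}"
        )
    if any(not inst.spectra for inst in dataset):
        raise ValueError("every training instance needs at least one spectrum")

    encoder = SpectraEncoder(config, ae_hash=ae.weights_hash())
    optimizer = nn.Adam(encoder.modules, lr=config.lr)
    rng = np.random.default_rng(config.seed + 29)

    def targets_for(instances: list[DatasetInstance]) -> np.ndarray:
        smiles = [inst.molecule.canonical_smiles for inst in instances]
        chunks = [
            ae.encode_batch(smiles[i : i + 256]) for i in range(0, len(smiles), 256)
        ]
        return np.concatenate(chunks, axis=0).astype(nn.DTYPE)

    inputs = np.stack(
        [_tensor_for(inst, config.input_len, bin_width) for inst in dataset]
    ).astype(nn.DTYPE)
    targets = targets_for(dataset)
    val_inputs = val_targets = None
    if val_dataset:
        val_inputs = np.stack(
            [_tensor_for(inst, config.input_len, bin_width) for inst in val_dataset]
        ).astype(nn.DTYPE)
        val_targets = targets_for(val_dataset)

    n = len(dataset)
    log: list[dict] = []
    for epoch in range(config.epochs):
        if config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            optimizer.lr = config.lr * (config.lr_final / config.lr) ** frac
        order = rng.permutation(n)
        sq_sum, n_seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            x, y = inputs[batch], targets[batch]
            optimizer.zero_grad()
            pred = encoder.forward(x, train=True)
            err = pred - y
            mse = float((err * err).mean())
            rmse = np.sqrt(mse)
            # d rmse / d pred = err / (rmse * N_elements)
            dpred = err / max(rmse, 1e-12) / err.size
            encoder.backward(dpred.astype(nn.DTYPE))
            optimizer.step()
            sq_sum += mse * len(batch)
            n_seen += len(batch)
        row = {"epoch": epoch, "rmse": float(np.sqrt(sq_sum / n_seen))}
        if val_inputs is not None:
            val_err = encoder.forward(val_inputs) - val_targets
            row["val_rmse"] = float(np.sqrt((val_err * val_err).mean()))
        log.append(row)
        if epoch % 10 == 0:
            logger.info("epoch %d rmse %.4f", epoch, row["rmse"])
    return encoder, log
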