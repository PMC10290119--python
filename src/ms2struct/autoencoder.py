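"""SMILES translation autoencoder: randomized SMILES in, canonical SMILES out.

A GRU encoder maps a tokenized SMILES to a fixed-length embedding; a GRU
decoder reconstructs the canonical SMILES from that embedding. Training is
a translation task — every epoch each molecule is presented as a freshly
randomized SMILES with its canonical form as the target — so the embedding
must capture the molecule, not the surface string. The embedding space this
model learns is later the regression target for the spectra encoder, which
is why ``encode_smiles`` canonicalizes internally: equivalent SMILES must
map to one embedding.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .chem import (
    Molecule,
    TokenVocabulary,
    canonicalize,
    detokenize,
    randomize_smiles,
    tokenize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AEConfig",
    "SmilesAutoencoder",
    "train_autoencoder",
    "char_accuracy",
    "exact_reconstruction_rate",
]


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder hyperparameters (desk-scale defaults).

    ``d_embed`` is the shared latent dimension; the spectra encoder must
    produce vectors of the same size. ``max_seq_len`` bounds tokenized
    sequences (including the start/end frame); longer molecules are skipped
    during training with a warning.
    """

    d_embed: int = 96
    hidden_size: int = 256
    n_gru_layers: int = 1
    token_embed_dim: int = 64
    dropout: float = 0.0
    max_seq_len: int = 64
    teacher_forcing: bool = True
    lr: float = 2.5e-3
    lr_final: float = 3e-4
    batch_size: int = 64
    epochs: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_embed, self.hidden_size, self.n_gru_layers) <= 0:
            raise ValueError("model sizes must be positive")


class SmilesAutoencoder:
    """GRU seq2seq model over a frozen token vocabulary."""

    def __init__(self, vocab: TokenVocabulary, config: AEConfig) -> None:
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        V, E, H, D = len(vocab), config.token_embed_dim, config.hidden_size, config.d_embed
        L = config.n_gru_layers
        self.enc_embed = nn.Embedding(V, E, rng)
        self.enc_grus = [nn.GRU(E if i == 0 else H, H, rng) for i in range(L)]
        self.enc_proj = nn.Dense(H, D, rng)
        self.dec_init = nn.Dense(D, L * H, rng)
        self.dec_embed = nn.Embedding(V, E, rng)
        self.dec_grus = [nn.GRU(E if i == 0 else H, H, rng) for i in range(L)]
        self.out_proj = nn.Dense(H, V, rng)

    @property
    def modules(self) -> list[nn.Module]:
        return [
            self.enc_embed,
            *self.enc_grus,
            self.enc_proj,
            self.dec_init,
            self.dec_embed,
            *self.dec_grus,
            self.out_proj,
        ]

    @property
    def _prefixes(self) -> list[str]:
        L = self.config.n_gru_layers
        return (
            ["enc_embed"]
            + [f"enc_gru{i}" for i in range(L)]
            + ["enc_proj", "dec_init", "dec_embed"]
            + [f"dec_gru{i}" for i in range(L)]
            + ["out_proj"]
        )

    # -- encoding -----------------------------------------------------------

    def _encode_ids(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        xs = self.enc_embed.forward(ids)
        h = xs
        h_last = None
        for gru in self.enc_grus:
            h, h_last = gru.forward(h, mask)
        self._enc_tanh_in = self.enc_proj.forward(h_last)
        return np.tanh(self._enc_tanh_in)

    def encode_batch(self, smiles_list: list[str]) -> np.ndarray:
        """Embeddings for a list of SMILES (canonicalized internally)."""
        canon = [canonicalize(s) for s in smiles_list]
        ids_list = [tokenize(c, self.vocab, allow_unknown=True) for c in canon]
        T = max(len(i) for i in ids_list)
        B = len(ids_list)
        ids = np.full((B, T), self.vocab.pad_id, dtype=np.int64)
        mask = np.zeros((B, T), dtype=nn.DTYPE)
        for r, seq in enumerate(ids_list):
            ids[r, : len(seq)] = seq
            mask[r, : len(seq)] = 1.0
        return self._encode_ids(ids, mask)

    def encode_smiles(self, smiles: str) -> np.ndarray:
        """Deterministic embedding of one molecule; pure in canonical SMILES."""
        canon = canonicalize(smiles)
        if len(tokenize(canon, self.vocab, allow_unknown=True)) > self.config.max_seq_len:
            raise ValueError(f"SMILES exceeds max_seq_len: {smiles!r}")
        return self.encode_batch([canon])[0]

    # -- decoding -----------------------------------------------------------

    def decode_embedding(
        self,
        emb: np.ndarray,
        mode: str = "greedy",
        seed: int = 0,
        max_len: int | None = None,
    ) -> str:
        """Decode one embedding to a SMILES string.

        ``greedy`` takes the argmax token at each step (deterministic);
        ``sample`` draws from the full, untruncated output distribution
        (pure sampling — no temperature, no top-k). The output may be an
        invalid SMILES; callers filter.
        """
        return self.decode_embeddings(np.asarray(emb)[None, :], mode, seed, max_len)[0]

    def decode_embeddings(
        self,
        embs: np.ndarray,
        mode: str = "greedy",
        seed: int = 0,
        max_len: int | None = None,
    ) -> list[str]:
        if embs.shape[1] != self.config.d_embed:
            raise ValueError(
                f"embedding dimension {embs.shape[1]} != d_embed {self.config.d_embed}"
            )
        if mode not in ("greedy", "sample"):
            raise ValueError("mode must be 'greedy' or 'sample'")
        max_len = max_len or self.config.max_seq_len
        rng = np.random.default_rng(seed)
        B = embs.shape[0]
        H, L = self.config.hidden_size, self.config.n_gru_layers
        hs = list(
            np.tanh(self.dec_init.forward(embs.astype(nn.DTYPE))).reshape(B, L, H).transpose(1, 0, 2)
        )
        token = np.full(B, self.vocab.start_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        outputs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(max_len):
            x = self.dec_embed.forward(token)
            for i, gru in enumerate(self.dec_grus):
                hs[i], _ = gru.step(x, hs[i])
                x = hs[i]
            logits = self.out_proj.forward(x)
            if mode == "greedy":
                token = logits.argmax(axis=1)
            else:
                shifted = logits - logits.max(axis=1, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=1, keepdims=True)
                cum = probs.cumsum(axis=1)
                u = rng.random((B, 1))
                token = (cum < u).sum(axis=1).clip(max=len(self.vocab) - 1)
            for b in range(B):
                if not done[b]:
                    if token[b] == self.vocab.end_id:
                        done[b] = True
                    else:
                        outputs[b].append(int(token[b]))
            if done.all():
                break
        return [detokenize(seq, self.vocab) for seq in outputs]

    # -- training forward/backward -----------------------------------------

    def _run_batch(
        self,
        enc_ids: np.ndarray,
        enc_mask: np.ndarray,
        dec_target: np.ndarray,
        dec_mask: np.ndarray,
        train: bool = True,
    ) -> tuple[float, int, int]:
        """One teacher-forced pass; backpropagates when ``train``.

        Returns (loss, n_correct_tokens, n_tokens).
        """
        z = self._encode_ids(enc_ids, enc_mask)
        B, T = dec_target.shape
        H, L = self.config.hidden_size, self.config.n_gru_layers
        h0_flat = self.dec_init.forward(z)
        h0 = np.tanh(h0_flat)
        dec_in = np.concatenate(
            [np.full((B, 1), self.vocab.start_id, dtype=np.int64), dec_target[:, :-1]],
            axis=1,
        )
        # teacher forcing off: free-run with argmax feedback (no grad through feedback)
        if train and not self.config.teacher_forcing:
            dec_in = self._free_run_inputs(z, dec_target)
        xs = self.dec_embed.forward(dec_in)
        layer_h0 = h0.reshape(B, L, H)
        hs = xs
        for i, gru in enumerate(self.dec_grus):
            hs, _ = gru.forward(hs, None, h0=np.ascontiguousarray(layer_h0[:, i]))
        logits = self.out_proj.forward(hs)
        loss, dlogits, correct = nn.softmax_cross_entropy(logits, dec_target, dec_mask)
        if train:
            dhs = self.out_proj.backward(dlogits)
            dh0_parts = []
            for i in range(L - 1, -1, -1):
                dhs, dh0_i = self.dec_grus[i].backward(dhs)
                dh0_parts.append(dh0_i)
            dh0 = np.stack(dh0_parts[::-1], axis=1).reshape(B, L * H)
            self.dec_embed.backward(dhs)
            dz = self.dec_init.backward((dh0 * (1.0 - h0 * h0)).astype(nn.DTYPE))
            dz = dz * (1.0 - z * z)
            denc_last = self.enc_proj.backward(dz.astype(nn.DTYPE))
            d_in = None
            for gru in reversed(self.enc_grus):
                d_in, _ = gru.backward(d_in, dh_last=denc_last)
                denc_last = None
            self.enc_embed.backward(d_in)
        return loss, int(correct.sum()), int(dec_mask.sum())

    def _free_run_inputs(self, z: np.ndarray, dec_target: np.ndarray) -> np.ndarray:
        B, T = dec_target.shape
        H, L = self.config.hidden_size, self.config.n_gru_layers
        hs = list(np.tanh(self.dec_init.forward(z)).reshape(B, L, H).transpose(1, 0, 2))
        token = np.full(B, self.vocab.start_id, dtype=np.int64)
        dec_in = np.empty((B, T), dtype=np.int64)
        for t in range(T):
            dec_in[:, t] = token
            x = self.dec_embed.forward(token)
            for i, gru in enumerate(self.dec_grus):
                hs[i], _ = gru.step(x, hs[i])
                x = hs[i]
            token = self.out_proj.forward(x).argmax(axis=1)
        return dec_in

    # -- persistence --------------------------------------------------------

    def weights_hash(self) -> str:
        digest = hashlib.sha256()
        for prefix, mod in zip(self._prefixes, self.modules):
            for k in sorted(mod.params):
                digest.update(np.ascontiguousarray(mod.params[k]).tobytes())
        return digest.hexdigest()[:16]

    def save(self, path) -> None:
        header = json.dumps(
            {"config": asdict(self.config), "tokens": self.vocab.tokens,
             "weights_hash": self.weights_hash()}
        )
        state = nn.collect_params(self.modules, self._prefixes)
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "SmilesAutoencoder":
        archive = np.load(path)
        header = json.loads(archive["__header__"].tobytes().decode())
        model = cls(TokenVocabulary(header["tokens"]), AEConfig(**header["config"]))
        nn.load_params(model.modules, model._prefixes, archive)
        return model


# ---------------------------------------------------------------------------


def _pad_batch(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=nn.DTYPE)
    for r, s in enumerate(seqs):
        ids[r, : len(s)] = s
        mask[r, : len(s)] = 1.0
    return ids, mask


def build_vocabulary(corpus: list[Molecule], seed: int, n_variants: int = 12) -> TokenVocabulary:
    """Vocabulary over canonical plus randomized surface forms of the corpus."""
    forms = []
    for i, mol in enumerate(corpus):
        forms.append(mol.canonical_smiles)
        for v in range(n_variants):
            forms.append(randomize_smiles(mol.canonical_smiles, seed * 7919 + i * n_variants + v))
    return TokenVocabulary.from_corpus(forms)


def train_autoencoder(
    corpus: list[Molecule],
    config: AEConfig,
    log_every: int = 1,
) -> tuple[SmilesAutoencoder, list[dict]]:
    """Train the randomized-to-canonical translation AE.

    Each epoch draws one fresh randomized SMILES per molecule (seeded by
    epoch and molecule index), so the model sees many surface forms of each
    target. Loss is the per-token cross-entropy against the canonical
    target; the returned log has one row per epoch with loss and
    teacher-forced token accuracy.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    vocab = build_vocabulary(corpus, config.seed)
    model = SmilesAutoencoder(vocab, config)
    optimizer = nn.Adam(model.modules, lr=config.lr)
    rng = np.random.default_rng(config.seed + 17)

    targets = []
    kept: list[Molecule] = []
    for mol in corpus:
        ids = tokenize(mol.canonical_smiles, vocab)
        if len(ids) > config.max_seq_len:
            logger.warning(
                "skipping molecule longer than max_seq_len: %s", mol.canonical_smiles
            )
            continue
        targets.append(ids[1:])  # decoder target: tokens... <end>
        kept.append(mol)

    n = len(kept)
    log: list[dict] = []
    for epoch in range(config.epochs):
        # geometric lr decay from lr to lr_final across the run
        if config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            optimizer.lr = config.lr * (config.lr_final / config.lr) ** frac
        order = rng.permutation(n)
        # length-bucketed batches cut padding waste; batch order reshuffled
        order = sorted(order, key=lambda i: len(targets[i]))
        batches = [
            order[i : i + config.batch_size] for i in range(0, n, config.batch_size)
        ]
        rng.shuffle(batches)
        total_loss, total_correct, total_tokens = 0.0, 0, 0
        for batch in batches:
            enc_seqs = []
            for i in batch:
                rand = randomize_smiles(
                    kept[i].canonical_smiles,
                    (config.seed * 1_000_003 + epoch * n + int(i)) % (2**31),
                )
                ids = tokenize(rand, vocab, allow_unknown=True)[: config.max_seq_len]
                enc_seqs.append(ids)
            enc_ids, enc_mask = _pad_batch(enc_seqs, vocab.pad_id)
            dec_target, dec_mask = _pad_batch([targets[i] for i in batch], vocab.pad_id)
            optimizer.zero_grad()
            loss, n_correct, n_tokens = model._run_batch(
                enc_ids, enc_mask, dec_target, dec_mask, train=True
            )
            optimizer.step()
            total_loss += loss * n_tokens
            total_correct += n_correct
            total_tokens += n_tokens
        row = {
            "epoch": epoch,
            "loss": total_loss / max(total_tokens, 1),
            "char_acc": total_correct / max(total_tokens, 1),
        }
        log.append(row)
        if log_every and epoch % log_every == 0:
            logger.info(
                "epoch %d loss %.4f char_acc %.4f", epoch, row["loss"], row["char_acc"]
            )
    return model, log


def char_accuracy(model: SmilesAutoencoder, eval_set: list[Molecule]) -> float:
    """Teacher-forced per-token accuracy on canonical reconstruction.

    At each position the decoder's most probable token is compared with the
    target token; padding is excluded from the denominator.
    """
    if not eval_set:
        raise ValueError("empty evaluation set")
    vocab = model.vocab
    total_correct, total_tokens = 0, 0
    batchsize = model.config.batch_size
    for i in range(0, len(eval_set), batchsize):
        chunk = eval_set[i : i + batchsize]
        enc, targets = [], []
        for mol in chunk:
            ids = tokenize(mol.canonical_smiles, vocab, allow_unknown=True)
            enc.append(ids[: model.config.max_seq_len])
            targets.append(ids[1:][: model.config.max_seq_len - 1])
        enc_ids, enc_mask = _pad_batch(enc, vocab.pad_id)
        dec_target, dec_mask = _pad_batch(targets, vocab.pad_id)
        _, n_correct, n_tokens = model._run_batch(
            enc_ids, enc_mask, dec_target, dec_mask, train=False
        )
        total_correct += n_correct
        total_tokens += n_tokens
    return total_correct / max(total_tokens, 1)


def exact_reconstruction_rate(model: SmilesAutoencoder, eval_set: list[Molecule]) -> float:
    """Fraction of molecules whose greedy decode canonicalizes to the input.

    Invalid decoded strings count as misses, never as errors.
    """
    if not eval_set:
        raise ValueError("empty evaluation set")
    hits = 0
    batchsize = model.config.batch_size
    for i in range(0, len(eval_set), batchsize):
        chunk = eval_set[i : i + batchsize]
        embs = model.encode_batch([m.canonical_smiles for m in chunk])
        decoded = model.decode_embeddings(embs, mode="greedy")
        for mol, out in zip(chunk, decoded):
            try:
                hits += canonicalize(out) == mol.canonical_smiles
            except Exception:
                pass
    return hits / len(eval_set)
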