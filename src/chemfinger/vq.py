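"""Stage-1 tokenizer: dual-branch vector-quantized autoencoder on the STFT.

A fingerprint is transformed to a one-sided STFT, split into complementary
low-frequency (LF) and high-frequency (HF) zero-padded spectrograms, and
each branch is encoded by a 1-D convolutional stack over the frame axis.
Continuous latents are replaced by their nearest codebook vector in
Euclidean distance (straight-through gradients), decoded back to the
time-frequency domain, and mapped to the time domain by inverse STFT.

Training minimises the VQ loss

    L_VQ = L_codebook + L_recons

where the codebook loss carries, per branch, a codebook term
``||sg[E(u)] - z_q||^2`` and a beta-weighted commitment term
``beta * ||E(u) - sg[z_q]||^2`` (sg = stop-gradient), and the
reconstruction loss penalises squared error in both the time domain and
the time-frequency domain for each branch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .fingerprints import Fingerprint
from .nn import Adam, Conv1d, Module, Tensor
from .tfr import (DifferentiableISTFT, band_masks, complex_to_channels,
                  default_window_length, stft_batch)

#: loss-trace column order of the reference report shape
TRACE_COLUMNS = ["Loss", "Recons_loss", "Recons_loss.LF", "Recons_loss.HF"]


class TrainingError(RuntimeError):
    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class TokenGrid:
    """Integer codebook indices of one encoded branch."""

    branch: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)


class Codebook(Module):
    """Per-branch discrete latent vocabulary of K vectors of dimension d."""

    def __init__(self, branch: str, vectors: np.ndarray, trainable: bool = True):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] < 2:
            raise ValueError("codebook needs at least 2 vectors (K x d)")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("codebook vectors must be finite")
        self.branch = branch
        self.param = Tensor(vectors, requires_grad=trainable)

    @property
    def vectors(self) -> np.ndarray:
        return self.param.data

    @property
    def K(self) -> int:
        return self.param.data.shape[0]

    @property
    def d(self) -> int:
        return self.param.data.shape[1]


def quantize(latents: np.ndarray, codebook: Codebook) -> tuple[TokenGrid, np.ndarray]:
    """Replace each latent vector by its nearest codebook entry.

    Distances are Euclidean; ties resolve to the lowest codebook index.
    Returns the token grid and the quantized latents.  Inside training the
    quantized output takes part in a straight-through estimator, so
    gradients pass to the continuous input unchanged.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if latents.shape[-1] != codebook.d:
        raise ValueError(
            f"latent dimension {latents.shape[-1]} != codebook dimension {codebook.d}")
    flat = latents.reshape(-1, codebook.d)
    # ||z - c||^2 = ||z||^2 - 2 z.c + ||c||^2 ; argmin prefers lowest index on ties
    d2 = (np.sum(flat ** 2, axis=1, keepdims=True)
          - 2.0 * flat @ codebook.vectors.T
          + np.sum(codebook.vectors ** 2, axis=1))
    # guard against tiny negative/asymmetric float error breaking tie-lowest
    d2 = np.round(d2, 12)
    idx = np.argmin(d2, axis=1)
    grid = TokenGrid(branch=codebook.branch, indices=idx.reshape(latents.shape[:-1]))
    return grid, codebook.vectors[idx].reshape(latents.shape)


def codebook_loss(encoded_LF, encoded_HF, quantized_LF, quantized_HF,
                  beta: float = 0.25) -> float:
    """Value of the codebook + commitment loss (stop-gradients immaterial here)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    total = 0.0
    for e, q in ((encoded_LF, quantized_LF), (encoded_HF, quantized_HF)):
        e = np.asarray(e, dtype=np.float64)
        q = np.asarray(q, dtype=np.float64)
        if e.shape != q.shape:
            raise ValueError("encoded/quantized shapes differ")
        d2 = float(np.sum((e - q) ** 2))
        total += d2 + beta * d2
    return total


def reconstruction_loss(x_LF, xhat_LF, x_HF, xhat_HF,
                        u_LF, uhat_LF, u_HF, uhat_HF) -> float:
    """Squared-error reconstruction loss over time and time-frequency domains."""
    total = 0.0
    for a, b in ((x_LF, xhat_LF), (x_HF, xhat_HF), (u_LF, uhat_LF), (u_HF, uhat_HF)):
        diff = np.asarray(a) - np.asarray(b)
        total += float(np.sum(np.abs(diff) ** 2))
    return total


# ---------------------------------------------------------------------------
# networks


class _BranchEncoder(Module):
    """(B, 2F, T) channel-stacked spectrogram -> (B, d, ceil(T/4)) latents."""

    def __init__(self, c_in: int, hidden: int, d: int, rng: np.random.Generator):
        self.c1 = Conv1d(c_in, hidden, 3, rng, stride=2)
        self.c2 = Conv1d(hidden, hidden, 3, rng, stride=2)
        self.c3 = Conv1d(hidden, d, 3, rng, stride=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c3(self.c2(self.c1(x).relu()).relu())


class _BranchDecoder(Module):
    """(B, d, T') latents -> (B, 2F, >=4T') spectrogram channels."""

    def __init__(self, d: int, hidden: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv1d(d, hidden, 3, rng)
        self.c2 = Conv1d(hidden, hidden, 3, rng)
        self.c3 = Conv1d(hidden, c_out, 3, rng)

    def __call__(self, z: Tensor) -> Tensor:
        h = self.c1(z).relu().upsample_nearest(2)
        h = self.c2(h).relu().upsample_nearest(2)
        return self.c3(h)


@dataclass
class Stage1Config:
    """Tokenizer hyperparameters; defaults are the desk-scale regime."""

    window_length: int | None = None   # auto: 64 for signals >= 1024, else 16
    hop: int | None = None             # auto: window / 2
    cutoff_bin: int | None = None      # auto: ceil(F / 2)
    codebook_size: int = 64
    codebook_dim: int = 32
    hidden: int = 64
    beta: float = 0.25
    iterations: int = 1000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 16
    log_every: int = 10
    freeze_codebook: bool = False
    seed: int = 0

    def resolve(self, signal_length: int) -> "Stage1Config":
        win = self.window_length or default_window_length(signal_length)
        hop = self.hop or win // 2
        F = win // 2 + 1
        cut = self.cutoff_bin or -(-F // 2)
        out = Stage1Config(**{**asdict(self), "window_length": win,
                              "hop": hop, "cutoff_bin": cut})
        return out


class Stage1Tokenizer(Module):
    """Dual-branch VQ autoencoder over the STFT of fixed-length signals."""

    def __init__(self, signal_length: int, config: Stage1Config):
        self.config = cfg = config.resolve(signal_length)
        self.signal_length = signal_length
        self.F = cfg.window_length // 2 + 1
        lf, hf = band_masks(self.F, cfg.cutoff_bin)
        self.masks = {"LF": lf, "HF": hf}
        self.istft_op = DifferentiableISTFT(cfg.window_length, cfg.hop, signal_length)
        self.n_frames = self.istft_op.T
        rng = np.random.default_rng(cfg.seed)
        c = 2 * self.F
        self.encoders = {b: _BranchEncoder(c, cfg.hidden, cfg.codebook_dim, rng)
                         for b in ("LF", "HF")}
        self.decoders = {b: _BranchDecoder(cfg.codebook_dim, cfg.hidden, c, rng)
                         for b in ("LF", "HF")}
        self.codebooks = {b: Codebook(b, rng.normal(
            0.0, 0.1, size=(cfg.codebook_size, cfg.codebook_dim)),
            trainable=not cfg.freeze_codebook) for b in ("LF", "HF")}
        self.frozen = False

    # -- helpers -------------------------------------------------------------
    def band_channels(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """(B, L) signals -> per-branch (B, 2F, T) zero-padded channel stacks."""
        U = stft_batch(X, self.config.window_length, self.config.hop)
        out = {}
        for b, m in self.masks.items():
            out[b] = complex_to_channels(U * m[None, :, None])
        return out

    def encode_branch(self, c: np.ndarray, branch: str) -> Tensor:
        return self.encoders[branch](Tensor(c)).transpose(0, 2, 1)  # (B, T', d)

    def encode_tokens(self, X: np.ndarray) -> dict[str, TokenGrid]:
        """Signals (B, L) -> per-branch token grids (B, T')."""
        chans = self.band_channels(X)
        grids = {}
        for b in ("LF", "HF"):
            z = self.encode_branch(chans[b], b)
            grids[b], _ = quantize(z.data, self.codebooks[b])
        return grids

    def decode_branch_tokens(self, grid: TokenGrid) -> Tensor:
        """Token grid (B, T') -> branch time signal (B, L)."""
        b = grid.branch
        z = self.codebooks[b].param.gather_rows(grid.indices)  # (B, T', d)
        uhat = self.decoders[b](z.transpose(0, 2, 1))
        uhat = uhat[:, :, :self.n_frames]
        mask = np.concatenate([self.masks[b], self.masks[b]])
        uhat = uhat * Tensor(mask[None, :, None])
        return self.istft_op(uhat)

    def decode_tokens(self, grids: dict[str, TokenGrid]) -> np.ndarray:
        """Token grids -> reconstructed signals (sum of LF and HF components)."""
        x = self.decode_branch_tokens(grids["LF"]).data
        return x + self.decode_branch_tokens(grids["HF"]).data

    # -- training graph ------------------------------------------------------
    def _branch_losses(self, c: np.ndarray, branch: str
                       ) -> tuple[Tensor, Tensor, np.ndarray]:
        """Returns (codebook_term, recons_term, token indices) for one branch."""
        cfg = self.config
        B = c.shape[0]
        scale = 1.0 / c.size  # mean-reduction keeps magnitudes comparable
        z = self.encode_branch(c, branch)                     # (B, T', d)
        grid, q_val = quantize(z.data, self.codebooks[branch])
        q = self.codebooks[branch].param.gather_rows(grid.indices)
        commit = ((z - Tensor(q_val)) ** 2).sum() * scale
        book = ((z.detach() - q) ** 2).sum() * scale
        cb_term = book + cfg.beta * commit
        # straight-through: decoder sees quantized values, gradient flows to z
        z_q = z + Tensor(q_val - z.data)
        uhat = self.decoders[branch](z_q.transpose(0, 2, 1))[:, :, :self.n_frames]
        mask = np.concatenate([self.masks[branch], self.masks[branch]])
        uhat = uhat * Tensor(mask[None, :, None])
        u_loss = ((uhat - Tensor(c)) ** 2).sum() * scale
        xhat = self.istft_op(uhat)
        x_ref = self.istft_op(Tensor(c)).data
        t_scale = 1.0 / x_ref.size
        x_loss = ((xhat - Tensor(x_ref)) ** 2).sum() * t_scale
        return cb_term, u_loss + x_loss, grid.indices

    def loss(self, X: np.ndarray) -> dict[str, Tensor]:
        chans = self.band_channels(X)
        cb_lf, rec_lf, _ = self._branch_losses(chans["LF"], "LF")
        cb_hf, rec_hf, _ = self._branch_losses(chans["HF"], "HF")
        codebook = cb_lf + cb_hf
        recons = rec_lf + rec_hf
        return {"Loss": codebook + recons, "Codebook_loss": codebook,
                "Recons_loss": recons, "Recons_loss.LF": rec_lf,
                "Recons_loss.HF": rec_hf}


@dataclass
class Stage1Result:
    """Trained tokenizer plus its loss trace (report-table shape)."""

    model: Stage1Tokenizer
    loss_trace: pd.DataFrame

    def state_hash(self) -> str:
        return self.model.state_hash()


def train_stage1(data: list[Fingerprint] | np.ndarray,
                 config: Stage1Config | None = None) -> Stage1Result:
    """Fit the stage-1 tokenizer by Adam on the VQ loss; seeded and deterministic."""
    config = config or Stage1Config()
    X = data if isinstance(data, np.ndarray) else np.stack([f.values for f in data])
    if X.shape[0] < 2:
        raise TrainingError("need at least 2 training samples")
    model = Stage1Tokenizer(X.shape[1], config)
    cfg = model.config
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for it in range(cfg.iterations):
        batch = X[rng.choice(X.shape[0], size=min(cfg.batch_size, X.shape[0]),
                             replace=False)]
        losses = model.loss(batch)
        total = losses["Loss"]
        if not np.isfinite(total.data):
            raise TrainingError("non-finite training loss", iteration=it)
        opt.zero_grad()
        total.backward()
        opt.step()
        if it % cfg.log_every == 0 or it == cfg.iterations - 1:
            rows.append({"iteration": it,
                         **{k: float(v.data) for k, v in losses.items()}})
    trace = pd.DataFrame(rows)[["iteration", *TRACE_COLUMNS, "Codebook_loss"]]
    return Stage1Result(model=model, loss_trace=trace)


# ---------------------------------------------------------------------------
# serialization (runtime artifact: npz archive with a JSON manifest)


def save_stage1(result: Stage1Result, path: str):
    cfg = result.model.config
    manifest = {"signal_length": result.model.signal_length, **asdict(cfg)}
    arrays = {f"p{i}": a for i, a in enumerate(result.model.state_arrays())}
    np.savez(path, manifest=json.dumps(manifest),
             trace=result.loss_trace.to_records(index=False), **arrays)


def load_stage1(path: str) -> Stage1Result:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        length = manifest.pop("signal_length")
        model = Stage1Tokenizer(length, Stage1Config(**manifest))
        n = len(model.parameters())
        model.load_state_arrays([z[f"p{i}"] for i in range(n)])
        trace = pd.DataFrame(z["trace"])
    return Stage1Result(model=model, loss_trace=trace)
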