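"""Stage-2 prior: bidirectional transformer over frozen stage-1 tokens.

The LF and HF token grids of a sample are concatenated into one sequence
with branch and position embeddings, plus a learned grade embedding added
at every position so that sampling is class-conditional.  Training masks
a random fraction of tokens (cosine schedule by default) and minimises
cross-entropy of the true tokens at the masked positions; the stage-1
tokenizer stays frozen throughout.  Generation starts from a fully masked
sequence and iteratively commits the most confident predictions until all
positions hold real tokens, then decodes through the frozen stage-1
decoders and sums the LF and HF time-domain components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import GRADES, Fingerprint
from .nn import (Adam, Embedding, LayerNorm, Linear, Module, Tensor,
                 TransformerBlock, cross_entropy)
from .vq import Stage1Tokenizer, TokenGrid, TrainingError


class ScheduleError(ValueError):
    pass


def mask_fraction(r: np.ndarray | float, schedule: str = "cosine"):
    """Fraction of positions still masked at progress r in [0, 1]."""
    if schedule == "cosine":
        return np.cos(np.pi * np.asarray(r) / 2.0)
    if schedule in ("linear", "one_per_step"):
        return 1.0 - np.asarray(r)
    raise ScheduleError(f"unknown mask schedule {schedule!r}")


@dataclass
class GenerationRequest:
    grade: str
    n: int
    iterations: int = 10
    temperature: float = 1.0
    seed: int = 0
    anneal: bool = False

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.n < 1 or self.iterations < 1:
            raise ValueError("n and iterations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class PriorConfig:
    depth: int = 2
    width: int = 64
    heads: int = 4
    steps: int = 400
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 32
    mask_schedule: str = "cosine"
    log_every: int = 20
    seed: int = 0


class PriorModel(Module):
    """Bidirectional transformer over the joint (LF + HF) token sequence."""

    def __init__(self, K_LF: int, K_HF: int, T_LF: int, T_HF: int,
                 config: PriorConfig):
        self.config = config
        self.K = {"LF": K_LF, "HF": K_HF}
        self.T = {"LF": T_LF, "HF": T_HF}
        self.seq_len = T_LF + T_HF
        rng = np.random.default_rng(config.seed)
        w = config.width
        # mask token sits at index K, outside the codebook range
        self.tok_emb = {"LF": Embedding(K_LF + 1, w, rng),
                        "HF": Embedding(K_HF + 1, w, rng)}
        self.pos_emb = Embedding(self.seq_len, w, rng)
        self.branch_emb = Embedding(2, w, rng)
        self.grade_emb = Embedding(len(GRADES), w, rng)
        self.blocks = [TransformerBlock(w, config.heads, rng)
                       for _ in range(config.depth)]
        self.ln = LayerNorm(w)
        self.heads = {"LF": Linear(w, K_LF, rng), "HF": Linear(w, K_HF, rng)}

    @property
    def mask_token(self) -> dict[str, int]:
        return {b: self.K[b] for b in ("LF", "HF")}

    def forward(self, tokens: np.ndarray, grades: np.ndarray
                ) -> dict[str, Tensor]:
        """tokens (B, S) ints (mask = K), grades (B,) ints -> per-branch logits."""
        B = tokens.shape[0]
        t_lf = self.T["LF"]
        h_lf = self.tok_emb["LF"](tokens[:, :t_lf])
        h_hf = self.tok_emb["HF"](tokens[:, t_lf:])
        from .nn import concat
        h = concat([h_lf, h_hf], axis=1)
        pos = self.pos_emb(np.broadcast_to(np.arange(self.seq_len), (B, self.seq_len)))
        branch_ids = np.concatenate([np.zeros(t_lf, int), np.ones(self.T["HF"], int)])
        br = self.branch_emb(np.broadcast_to(branch_ids, (B, self.seq_len)))
        gr = self.grade_emb.weight.gather_rows(grades).reshape(B, 1, -1)
        h = h + pos + br + gr
        for blk in self.blocks:
            h = blk(h)
        h = self.ln(h)
        return {"LF": self.heads["LF"](h[:, :t_lf, :]),
                "HF": self.heads["HF"](h[:, t_lf:, :])}


def grade_indices(grades) -> np.ndarray:
    lut = {g: i for i, g in enumerate(GRADES)}
    try:
        return np.array([lut[g] for g in grades], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown grade label {e.args[0]!r}") from None


def build_token_corpus(stage1: Stage1Tokenizer, data: list[Fingerprint]
                       ) -> list[tuple[dict[str, TokenGrid], str]]:
    """Encode fingerprints to (token-grid pair, grade) training items."""
    X = np.stack([f.values for f in data])
    grids = stage1.encode_tokens(X)
    return [({"LF": TokenGrid("LF", grids["LF"].indices[i]),
              "HF": TokenGrid("HF", grids["HF"].indices[i])}, f.grade)
            for i, f in enumerate(data)]


def _corpus_arrays(corpus) -> tuple[np.ndarray, np.ndarray]:
    seqs = np.stack([np.concatenate([g["LF"].indices, g["HF"].indices])
                     for g, _ in corpus])
    grades = grade_indices([grade for _, grade in corpus])
    return seqs, grades


@dataclass
class PriorResult:
    model: PriorModel
    loss_trace: pd.DataFrame


def train_prior(token_corpus, stage1: Stage1Tokenizer,
                config: PriorConfig | None = None) -> PriorResult:
    """Masked-token training of the prior; stage-1 parameters are untouched."""
    if not token_corpus:
        raise ValueError("empty token corpus")
    config = config or PriorConfig()
    seqs, grades = _corpus_arrays(token_corpus)
    t_lf = token_corpus[0][0]["LF"].indices.size
    t_hf = token_corpus[0][0]["HF"].indices.size
    model = PriorModel(stage1.codebooks["LF"].K, stage1.codebooks["HF"].K,
                       t_lf, t_hf, config)
    stage1.frozen = True  # contract: stage 2 never updates stage-1 parameters
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 17)
    S = model.seq_len
    rows = []
    for step in range(config.steps):
        pick = rng.choice(seqs.shape[0], size=min(config.batch_size, seqs.shape[0]),
                          replace=False)
        toks = seqs[pick].copy()
        grd = grades[pick]
        B = toks.shape[0]
        r = rng.random(B)
        n_mask = np.maximum(1, np.ceil(mask_fraction(r, config.mask_schedule) * S)
                            .astype(int))
        mask = np.zeros((B, S), dtype=bool)
        for i in range(B):
            mask[i, rng.permutation(S)[:n_mask[i]]] = True
        masked = toks.copy()
        masked[:, :t_lf][mask[:, :t_lf]] = model.mask_token["LF"]
        masked[:, t_lf:][mask[:, t_lf:]] = model.mask_token["HF"]
        logits = model.forward(masked, grd)
        losses = []
        for b, sl in (("LF", slice(0, t_lf)), ("HF", slice(t_lf, S))):
            m = mask[:, sl]
            if m.any():
                lg = logits[b][m]
                losses.append(cross_entropy(lg, toks[:, sl][m]) * m.sum())
        loss = losses[0] if len(losses) == 1 else losses[0] + losses[1]
        loss = loss * (1.0 / mask.sum())
        if not np.isfinite(loss.data):
            raise TrainingError("non-finite prior loss", iteration=step)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % config.log_every == 0 or step == config.steps - 1:
            rows.append({"step": step, "masked_ce": float(loss.data)})
    return PriorResult(model=model, loss_trace=pd.DataFrame(rows))


def iterative_decode(model: PriorModel, request: GenerationRequest
                     ) -> list[dict[str, TokenGrid]]:
    """Confidence-ordered iterative decoding of `request.n` token-grid pairs.

    All positions start masked; at each of T iterations the masked
    positions are re-predicted, candidates are sampled at the requested
    temperature, and the most confident predictions are committed so that
    the schedule finishes with zero masked positions.
    """
    cfg = model.config
    S, T = model.seq_len, request.iterations
    if cfg.mask_schedule == "one_per_step" and T < S:
        raise ScheduleError(
            f"one_per_step schedule needs at least {S} iterations, got {T}")
    # committed-count targets per iteration (cumulative, reaching S at t=T)
    keep_t = [S - int(np.floor(mask_fraction(t / T, cfg.mask_schedule) * S))
              for t in range(1, T + 1)]
    keep_t[-1] = S
    rng = np.random.default_rng(request.seed)
    n = request.n
    t_lf = model.T["LF"]
    toks = np.empty((n, S), dtype=np.int64)
    toks[:, :t_lf] = model.mask_token["LF"]
    toks[:, t_lf:] = model.mask_token["HF"]
    committed = np.zeros((n, S), dtype=bool)
    grd = np.full(n, grade_indices([request.grade])[0])
    for t, target in enumerate(keep_t):
        temp = request.temperature
        if request.anneal:
            temp = max(temp * (1.0 - t / max(T - 1, 1)), 1e-4)
        logits = model.forward(toks, grd)
        for b, sl in (("LF", slice(0, t_lf)), ("HF", slice(t_lf, S))):
            lg = logits[b].data / temp
            lg = lg - lg.max(axis=-1, keepdims=True)
            p = np.exp(lg)
            p /= p.sum(axis=-1, keepdims=True)
            u = rng.random(p.shape[:2])
            cand = (p.cumsum(axis=-1) > u[..., None]).argmax(axis=-1)
            conf = np.take_along_axis(p, cand[..., None], axis=-1)[..., 0]
            if b == "LF":
                cand_all, conf_all = cand, conf
            else:
                cand_all = np.concatenate([cand_all, cand], axis=1)
                conf_all = np.concatenate([conf_all, conf], axis=1)
        conf_all = np.where(committed, np.inf, conf_all)  # keep committed fixed
        order = np.argsort(-conf_all, axis=1, kind="stable")
        for i in range(n):
            newly = order[i, :target]
            fresh = newly[~committed[i, newly]]
            toks[i, fresh] = cand_all[i, fresh]
            committed[i, fresh] = True
        # re-mask everything not yet committed
        toks[:, :t_lf][~committed[:, :t_lf]] = model.mask_token["LF"]
        toks[:, t_lf:][~committed[:, t_lf:]] = model.mask_token["HF"]
    assert committed.all()
    return [{"LF": TokenGrid("LF", toks[i, :t_lf]),
             "HF": TokenGrid("HF", toks[i, t_lf:])} for i in range(n)]


def generate_fingerprints(model: PriorModel, stage1: Stage1Tokenizer,
                          request: GenerationRequest,
                          axis: np.ndarray | None = None,
                          modality: str = "HPLC") -> list[Fingerprint]:
    """Sample new fingerprints of the requested grade through the frozen decoder."""
    grids = iterative_decode(model, request)
    batch = {"LF": TokenGrid("LF", np.stack([g["LF"].indices for g in grids])),
             "HF": TokenGrid("HF", np.stack([g["HF"].indices for g in grids]))}
    X = stage1.decode_tokens(batch)
    if not np.all(np.isfinite(X)):
        raise RuntimeError("non-finite decoded signal")
    if axis is None:
        axis = np.arange(stage1.signal_length, dtype=float)
    return [Fingerprint(
        sample_id=f"GEN-{request.grade}-{request.seed}-{i:04d}",
        grade=request.grade, modality=modality,
        values=X[i], axis=axis) for i in range(request.n)]
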