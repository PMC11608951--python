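"""Model-object facade over the two-stage generator and the PLS-DA grader.

`TimeVqvae` holds the data and configuration; `fit()` trains the stage-1
tokenizer and the stage-2 masked-token prior and returns a
`TimeVqvaeResults` carrying both fitted stages, their loss traces and a
`generate()` method.  `PLSDA` wraps the discriminant analysis the same
way.  The functional layer (`vq`, `prior`, `plsda`) remains available for
finer control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import GRADES, Fingerprint, frame_to_fingerprints, values_matrix
from .plsda import (MetricsTable, PlsdaModel, explained_variance, fit_plsda,
                    one_hot, score_classification, select_lv)
from .prior import (GenerationRequest, PriorConfig, PriorResult,
                    build_token_corpus, generate_fingerprints, train_prior)
from .vq import Stage1Config, Stage1Result, train_stage1


class TimeVqvae:
    """Two-stage vector-quantized generator for graded 1-D fingerprints."""

    def __init__(self, data: list[Fingerprint],
                 stage1_config: Stage1Config | None = None,
                 prior_config: PriorConfig | None = None):
        if not data:
            raise ValueError("no training data")
        self.data = data
        self.stage1_config = stage1_config or Stage1Config()
        self.prior_config = prior_config or PriorConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, axis: np.ndarray,
                       **kwargs) -> "TimeVqvae":
        return cls(frame_to_fingerprints(df, axis), **kwargs)

    def fit(self) -> "TimeVqvaeResults":
        stage1 = train_stage1(self.data, self.stage1_config)
        corpus = build_token_corpus(stage1.model, self.data)
        prior = train_prior(corpus, stage1.model, self.prior_config)
        return TimeVqvaeResults(self, stage1, prior)


@dataclass
class TimeVqvaeResults:
    model: TimeVqvae
    stage1: Stage1Result
    prior: PriorResult

    @property
    def loss_trace(self) -> pd.DataFrame:
        """Stage-1 VQ loss trace (report-table column names)."""
        return self.stage1.loss_trace

    def generate(self, grade: str, n: int, seed: int = 0,
                 iterations: int = 10, temperature: float = 1.0
                 ) -> list[Fingerprint]:
        req = GenerationRequest(grade=grade, n=n, iterations=iterations,
                                temperature=temperature, seed=seed)
        ref = self.model.data[0]
        return generate_fingerprints(self.prior.model, self.stage1.model, req,
                                     axis=ref.axis, modality=ref.modality)

    def generate_counts(self, counts: dict[str, int], seed: int = 0,
                        **kwargs) -> list[Fingerprint]:
        out: list[Fingerprint] = []
        for k, g in enumerate(GRADES):
            if counts.get(g, 0):
                out.extend(self.generate(g, counts[g], seed=seed * 131 + k,
                                         **kwargs))
        return out

    def summary(self) -> str:
        cfg = self.stage1.model.config
        tr = self.stage1.loss_trace
        lines = [
            "Two-stage VQ fingerprint generator",
            "=" * 42,
            f"samples: {len(self.model.data)}   signal length: "
            f"{self.stage1.model.signal_length}",
            f"STFT window/hop: {cfg.window_length}/{cfg.hop}   "
            f"LF/HF cutoff bin: {cfg.cutoff_bin}",
            f"codebooks: K={cfg.codebook_size}, d={cfg.codebook_dim} per branch"
            f"   beta={cfg.beta}",
            f"stage-1 iterations: {cfg.iterations}   "
            f"prior steps: {self.prior.model.config.steps}",
            "-" * 42,
            f"final VQ loss:        {tr['Loss'].iloc[-1]:.5f}",
            f"final recons loss:    {tr['Recons_loss'].iloc[-1]:.5f}",
            f"  LF branch:          {tr['Recons_loss.LF'].iloc[-1]:.5f}",
            f"  HF branch:          {tr['Recons_loss.HF'].iloc[-1]:.5f}",
            f"final prior masked CE: "
            f"{self.prior.loss_trace['masked_ce'].iloc[-1]:.5f}",
        ]
        return "\n".join(lines)


class PLSDA:
    """PLS-DA grade classifier built from fingerprints or a raw matrix."""

    def __init__(self, X: np.ndarray, labels, n_lv: int | None = None,
                 max_lv: int = 15, folds: int = 10, seed: int = 0):
        self.X = np.asarray(X, dtype=np.float64)
        self.labels = np.asarray(list(labels))
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.folds = folds
        self.seed = seed

    @classmethod
    def from_fingerprints(cls, fps: list[Fingerprint], **kwargs) -> "PLSDA":
        X, y = values_matrix(fps)
        return cls(X, y, **kwargs)

    def fit(self) -> "PLSDAResults":
        Y = one_hot(self.labels)
        curves = None
        n_lv = self.n_lv
        if n_lv is None:
            n_lv, curves = select_lv(self.X, Y, max_lv=self.max_lv,
                                     folds=self.folds, seed=self.seed)
        fitted = fit_plsda(self.X, Y, n_lv)
        train_metrics = score_classification(
            self.labels, fitted.predict(self.X), fitted.decision_scores(self.X))
        return PLSDAResults(self, fitted, train_metrics, curves)


@dataclass
class PLSDAResults:
    model: PLSDA
    fitted: PlsdaModel
    train_metrics: MetricsTable
    lv_curves: pd.DataFrame | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fitted.predict(X)

    def evaluate(self, X: np.ndarray, labels) -> MetricsTable:
        return score_classification(labels, self.fitted.predict(X),
                                    self.fitted.decision_scores(X))

    def explained_variance(self) -> pd.DataFrame:
        return explained_variance(self.fitted)

    def summary(self) -> str:
        ev = self.explained_variance()
        lines = [
            "PLS-DA grade classifier",
            "=" * 42,
            f"samples: {self.model.X.shape[0]}   features: {self.model.X.shape[1]}",
            f"latent variables: {self.fitted.n_lv}"
            + ("" if self.model.n_lv is not None
               else f"   (CV-selected, {self.model.folds}-fold)"),
            f"explained variance (cumulative): X {ev['X_cumulative'].iloc[-1]:.3f}"
            f"   Y {ev['Y_cumulative'].iloc[-1]:.3f}",
            "-" * 42,
            "training metrics (macro): "
            + "  ".join(f"{m}={v:.4f}" for m, v in self.train_metrics.macro.items()),
            f"overall training accuracy: {self.train_metrics.overall_accuracy:.4f}",
        ]
        return "\n".join(lines)
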