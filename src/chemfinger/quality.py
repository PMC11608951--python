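"""Scoring generated fingerprints against real ones.

A fully convolutional network (FCN) trained on the real cohort provides
both a feature space (global-average-pooled penultimate activations, used
by the Frechet distance) and per-sample class posteriors (used by the
inception-style score).  The Frechet distance between Gaussian fits is

    FID = ||mu_x - mu_g||^2 + Tr(S_x + S_g - 2 (S_x S_g)^{1/2})

and the inception score is the exponentiated mean Kullback-Leibler
divergence between per-sample posteriors and their marginal, computed per
split; with 3 grades it ranges from 1 (uninformative) to 3 (confident and
balanced).  PCA / t-SNE projections are offered in both the direct signal
space and the FCN latent space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .fingerprints import GRADES, Fingerprint, values_matrix
from .nn import Adam, Conv1d, Linear, Module, Tensor, cross_entropy
from .vq import TrainingError

#: column names of the generation-quality report
EVAL_COLUMNS = ["Data type", "FID", "IS mean", "IS std"]


@dataclass
class FeatureSet:
    """FCN features and class posteriors for a batch of samples."""

    features: np.ndarray
    class_probabilities: np.ndarray
    source: str = "real"

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        self.class_probabilities = np.atleast_2d(
            np.asarray(self.class_probabilities, dtype=np.float64))
        sums = self.class_probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


@dataclass
class EvalReport:
    data_type: str
    fid: float
    is_mean: float
    is_std: float

    def __post_init__(self):
        if self.fid < -1e-9:
            raise ValueError("FID must be non-negative")
        self.fid = max(self.fid, 0.0)


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([{"Data type": r.data_type, "FID": r.fid,
                          "IS mean": r.is_mean, "IS std": r.is_std}
                         for r in reports], columns=EVAL_COLUMNS)


# ---------------------------------------------------------------------------
# FCN feature extractor / classifier


@dataclass
class FcnConfig:
    """Desk-scale FCN: canonical (64, 128, 64) filters and (8, 5, 3) kernels,
    with strides (4, 2, 1) so the stack stays fast on a single CPU."""

    filters: tuple[int, int, int] = (64, 128, 64)
    kernels: tuple[int, int, int] = (8, 5, 3)
    strides: tuple[int, int, int] = (4, 2, 1)
    iterations: int = 250
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 16
    seed: int = 0


class FcnClassifier(Module):
    """1-D FCN: conv blocks + global average pooling + linear head."""

    def __init__(self, n_classes: int, config: FcnConfig | None = None):
        self.config = cfg = config or FcnConfig()
        rng = np.random.default_rng(cfg.seed)
        f1, f2, f3 = cfg.filters
        k1, k2, k3 = cfg.kernels
        s1, s2, s3 = cfg.strides
        self.c1 = Conv1d(1, f1, k1, rng, stride=s1)
        self.c2 = Conv1d(f1, f2, k2, rng, stride=s2)
        self.c3 = Conv1d(f2, f3, k3, rng, stride=s3)
        self.head = Linear(f3, n_classes, rng)
        self.feature_dim = f3

    def _trunk(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        return h.mean(axis=2)  # global average pool -> (B, f3)

    def logits(self, X: np.ndarray) -> Tensor:
        return self.head(self._trunk(Tensor(X[:, None, :])))

    def features(self, X: np.ndarray) -> np.ndarray:
        """Penultimate GAP features (deterministic after training)."""
        return self._trunk(Tensor(np.atleast_2d(X)[:, None, :])).data

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        return self.logits(np.atleast_2d(X)).softmax(axis=-1).data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(GRADES)[self.probabilities(X).argmax(axis=1)]

    def feature_set(self, X: np.ndarray, source: str = "real") -> FeatureSet:
        return FeatureSet(self.features(X), self.probabilities(X), source)


def train_fcn(real: list[Fingerprint] | np.ndarray, labels=None,
              config: FcnConfig | None = None) -> FcnClassifier:
    """Train the FCN grade classifier on real data (Adam, cross-entropy)."""
    if isinstance(real, np.ndarray):
        X, y = real, np.asarray(labels)
    else:
        X, y = values_matrix(real)
    classes = [g for g in GRADES if g in y]
    if len(classes) < 2:
        raise TrainingError("need at least two classes to train the extractor")
    y_idx = np.array([GRADES.index(g) for g in y])
    cfg = config or FcnConfig()
    model = FcnClassifier(len(GRADES), cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 23)
    for it in range(cfg.iterations):
        pick = rng.choice(X.shape[0], size=min(cfg.batch_size, X.shape[0]),
                          replace=False)
        loss = cross_entropy(model.logits(X[pick]), y_idx[pick])
        if not np.isfinite(loss.data):
            raise TrainingError("non-finite classifier loss", iteration=it)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return model


# ---------------------------------------------------------------------------
# metrics


def _sqrtm_product_trace(Sx: np.ndarray, Sg: np.ndarray) -> float:
    """Tr((Sx Sg)^{1/2}) via eigendecomposition of the symmetrised product."""
    w, V = np.linalg.eigh((Sx + Sx.T) / 2.0)
    w = np.clip(w, 0.0, None)
    root = (V * np.sqrt(w)) @ V.T                  # Sx^{1/2}, symmetric PSD
    M = root @ ((Sg + Sg.T) / 2.0) @ root
    ev = np.linalg.eigvalsh((M + M.T) / 2.0)
    return float(np.sqrt(np.clip(ev, 0.0, None)).sum())


def fid(real_features: FeatureSet | np.ndarray,
        gen_features: FeatureSet | np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two feature clouds."""
    A = real_features.features if isinstance(real_features, FeatureSet) else \
        np.atleast_2d(np.asarray(real_features, dtype=np.float64))
    B = gen_features.features if isinstance(gen_features, FeatureSet) else \
        np.atleast_2d(np.asarray(gen_features, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 samples per set for a covariance")
    mu_x, mu_g = A.mean(axis=0), B.mean(axis=0)
    Sx = np.cov(A, rowvar=False)
    Sg = np.cov(B, rowvar=False)
    Sx, Sg = np.atleast_2d(Sx), np.atleast_2d(Sg)
    tr_root = _sqrtm_product_trace(Sx, Sg)
    if not np.isfinite(tr_root):
        d = Sx.shape[0]
        tr_root = _sqrtm_product_trace(Sx + eps * np.eye(d), Sg + eps * np.eye(d))
    val = float(np.sum((mu_x - mu_g) ** 2) + np.trace(Sx) + np.trace(Sg)
                - 2.0 * tr_root)
    return max(val, 0.0)


def inception_score(probs: np.ndarray, n_splits: int = 10
                    ) -> tuple[float, float]:
    """Exponentiated mean KL between class posteriors and their marginal.

    Returns (mean, std) over `n_splits` contiguous splits of the rows.
    """
    P = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if np.any(P < 0):
        raise ValueError("negative probabilities")
    sums = P.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("zero probability row")
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    P = P / sums[:, None]
    n_splits = min(n_splits, P.shape[0])
    scores = []
    for chunk in np.array_split(P, n_splits):
        marginal = chunk.mean(axis=0)
        kl = rel_entr(chunk, marginal[None, :]).sum(axis=1)
        scores.append(float(np.exp(kl.mean())))
    return float(np.mean(scores)), float(np.std(scores))


def evaluate_generation(fcn: FcnClassifier, real: np.ndarray,
                        generated: np.ndarray, data_type: str,
                        n_splits: int = 10) -> EvalReport:
    """Score one data type: FID between real/generated feature clouds and
    the inception score of the generated samples under the real-trained FCN."""
    fs_real = fcn.feature_set(real, "real")
    fs_gen = fcn.feature_set(generated, "generated")
    is_mean, is_std = inception_score(fs_gen.class_probabilities, n_splits)
    return EvalReport(data_type=data_type, fid=fid(fs_real, fs_gen),
                      is_mean=is_mean, is_std=is_std)


# ---------------------------------------------------------------------------
# 2-D projections


def project(X: np.ndarray, method: str = "PCA", seed: int = 0,
            perplexity: float = 15.0) -> np.ndarray:
    """2-D embedding of rows of X (PCA deterministic, t-SNE seeded).

    PCA follows the sign convention that each component's largest-magnitude
    loading is positive; data are mean-centred but not scaled.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to project")
    if method.upper() == "PCA":
        if np.allclose(X.std(axis=0), 0.0):
            warnings.warn("constant data: degenerate variance, returning zeros")
            return np.zeros((X.shape[0], 2))
        n_comp = min(2, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        Z = pca.fit_transform(X)
        for j in range(Z.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                Z[:, j] = -Z[:, j]
        if Z.shape[1] < 2:
            warnings.warn("degenerate variance, second component set to zero")
            Z = np.column_stack([Z, np.zeros(X.shape[0])])
        return Z
    if method.upper() == "TSNE":
        pp = min(perplexity, (X.shape[0] - 1) / 3.0)
        ts = TSNE(n_components=2, perplexity=max(pp, 1.0), random_state=seed,
                  init="pca")
        return ts.fit_transform(X).astype(np.float64)
    raise ValueError(f"unknown projection method {method!r}")


def projection_panels(direct: np.ndarray, latent: np.ndarray,
                      sample_ids: list[str], sources: list[str],
                      seed: int = 0) -> pd.DataFrame:
    """Four projection panels (PCA/t-SNE x direct/latent) as tidy coordinates."""
    frames = []
    for space, X in (("direct", direct), ("latent", latent)):
        for method in ("PCA", "TSNE"):
            Z = project(X, method=method, seed=seed)
            frames.append(pd.DataFrame({
                "sample_id": sample_ids, "source": sources,
                "dim1": Z[:, 0], "dim2": Z[:, 1],
                "method": method, "space": space}))
    return pd.concat(frames, ignore_index=True)
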