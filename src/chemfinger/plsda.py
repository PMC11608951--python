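"""PLS-DA grading of fingerprints with one-hot targets.

Partial least squares regression (NIPALS PLS2, mean-centred, no scaling)
onto one-hot grade indicators, classified by arg-max of the predicted
indicator columns.  The latent-variable count is chosen by stratified
10-fold cross-validation (one-standard-error rule by default).  Per-grade
metrics follow the one-vs-rest counts:

    SEN = TP/(TP+FN)   SPE = TN/(TN+FP)   PRE = TP/(TP+FP)
    ACC = (TN+TP)/(TN+TP+FN+FP)           F1 = 2*PRE*SEN/(PRE+SEN)

with the macro average taken as the unweighted mean over grades.  Note
the per-grade ACC is one-vs-rest (it counts true negatives), which
differs from the overall multi-class accuracy (confusion-matrix trace
over total); both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from .fingerprints import GRADES, Fingerprint, SplitPlan, values_matrix

#: the six benchmark data types (base modalities and their augmented runs)
DATA_TYPES = ["HPLC", "FTIR", "HPLC-FTIR", "HPLC-TimeVQVAE",
              "FTIR-TimeVQVAE", "HPLC-FTIR-TimeVQVAE"]

METRIC_NAMES = ["SEN", "SPE", "PRE", "ACC", "F1"]


def one_hot(labels) -> np.ndarray:
    """Grade labels -> indicator matrix with column order H, M, L."""
    lut = {g: i for i, g in enumerate(GRADES)}
    labels = list(labels)
    out = np.zeros((len(labels), len(GRADES)))
    for i, g in enumerate(labels):
        if g not in lut:
            raise ValueError(f"unknown grade label {g!r}")
        out[i, lut[g]] = 1.0
    return out


@dataclass
class PlsdaModel:
    """Fitted PLS2 regression of one-hot grades on fingerprint matrices."""

    n_lv: int
    pls: PLSRegression
    x_total_var: float
    y_total_var: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(np.asarray(X, dtype=np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax returns the first maximum: ties go to the earlier class in (H, M, L)
        return np.asarray(GRADES)[self.decision_scores(X).argmax(axis=1)]


def fit_plsda(X: np.ndarray, Y: np.ndarray, n_lv: int) -> PlsdaModel:
    """Fit mean-centred PLS2 with `n_lv` components (no variance scaling)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    cap = min(X.shape[0] - 1, X.shape[1])
    if n_lv > cap:
        warnings.warn(f"n_lv={n_lv} exceeds rank bound {cap}; reduced")
        n_lv = cap
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, Y)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    return PlsdaModel(n_lv=n_lv, pls=pls,
                      x_total_var=float(np.sum(Xc ** 2)),
                      y_total_var=float(np.sum(Yc ** 2)))


def explained_variance(model: PlsdaModel) -> pd.DataFrame:
    """Per-LV and cumulative explained-variance fractions for X and Y blocks."""
    T = model.pls.x_scores_          # (n, k), orthogonal columns under NIPALS
    P = model.pls.x_loadings_        # (p, k)
    Q = model.pls.y_loadings_        # (m, k)
    t2 = np.sum(T ** 2, axis=0)
    x_frac = t2 * np.sum(P ** 2, axis=0) / model.x_total_var
    y_frac = t2 * np.sum(Q ** 2, axis=0) / model.y_total_var
    return pd.DataFrame({
        "LV": np.arange(1, model.n_lv + 1),
        "X_explained": x_frac, "Y_explained": y_frac,
        "X_cumulative": np.cumsum(x_frac), "Y_cumulative": np.cumsum(y_frac)})


def select_lv(X: np.ndarray, Y: np.ndarray, max_lv: int, folds: int = 10,
              seed: int = 0, rule: str = "1se") -> tuple[int, pd.DataFrame]:
    """Stratified k-fold CV accuracy per candidate LV count.

    Returns the chosen count (smallest within one standard error of the
    best mean CV accuracy, or the plain arg-max with ``rule='max'``) and
    the train/CV accuracy curves.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    labels = Y.argmax(axis=1)
    counts = np.bincount(labels, minlength=len(GRADES))
    present = counts[counts > 0]
    if folds > present.min():
        raise ValueError(f"{folds} folds exceed the smallest class count "
                         f"({present.min()})")
    max_lv = min(max_lv, X.shape[0] - 1 - (X.shape[0] // folds), X.shape[1])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, labels))
    cv_acc = np.zeros((max_lv, folds))
    train_acc = np.zeros(max_lv)
    for k in range(1, max_lv + 1):
        model = fit_plsda(X, Y, k)
        train_acc[k - 1] = np.mean(model.predict(X) == np.asarray(GRADES)[labels])
        for j, (tr, te) in enumerate(splits):
            m = fit_plsda(X[tr], Y[tr], k)
            cv_acc[k - 1, j] = np.mean(m.predict(X[te])
                                       == np.asarray(GRADES)[labels[te]])
    mean = cv_acc.mean(axis=1)
    se = cv_acc.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmax(mean))
    if rule == "1se":
        ok = np.flatnonzero(mean >= mean[best] - se[best])
        chosen = int(ok[0]) + 1
    elif rule == "max":
        chosen = best + 1
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    curves = pd.DataFrame({"LV": np.arange(1, max_lv + 1),
                           "train_accuracy": train_acc,
                           "cv_accuracy": mean, "cv_se": se})
    return chosen, curves


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsTable:
    """Per-grade one-vs-rest metrics, macro averages, confusion matrix, ROC."""

    per_grade: pd.DataFrame
    macro: dict[str, float]
    confusion: np.ndarray
    overall_accuracy: float
    roc: dict[str, dict] = field(default_factory=dict)

    @property
    def macro_f1(self) -> float:
        return self.macro["F1"]


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """3x3 counts; rows are true grades, columns predicted (order H, M, L)."""
    lut = {g: i for i, g in enumerate(GRADES)}
    cm = np.zeros((len(GRADES), len(GRADES)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[lut[t], lut[p]] += 1
    return cm


def score_classification(y_true, y_pred, scores: np.ndarray | None = None
                         ) -> MetricsTable:
    """One-vs-rest metric table from true and predicted grade labels.

    ``scores`` (n x 3 predicted-indicator values) enables per-grade ROC
    curves.  A grade absent from the truth yields missing (NaN) metrics
    and is excluded from the macro average with a warning.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    cm = confusion_matrix(y_true, y_pred)
    n = cm.sum()
    rows = []
    for i, g in enumerate(GRADES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"grade {g} absent from truth; metrics undefined")
            rows.append({"Grade": g, **{m: np.nan for m in METRIC_NAMES}})
            continue
        sen = tp / (tp + fn)
        spe = tn / (tn + fp) if tn + fp else np.nan
        if tp + fp == 0:
            warnings.warn(f"no predictions for grade {g}; precision set to 0")
            pre = 0.0
        else:
            pre = tp / (tp + fp)
        acc = (tn + tp) / n
        f1 = 0.0 if pre + sen == 0 else 2 * pre * sen / (pre + sen)
        rows.append({"Grade": g, "SEN": sen, "SPE": spe, "PRE": pre,
                     "ACC": acc, "F1": f1})
    per_grade = pd.DataFrame(rows)
    macro = {m: float(per_grade[m].mean(skipna=True)) for m in METRIC_NAMES}
    roc = {}
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        for i, g in enumerate(GRADES):
            truth = (y_true == g).astype(int)
            if truth.min() == truth.max():
                continue
            fpr, tpr, _ = roc_curve(truth, scores[:, i])
            roc[g] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return MetricsTable(per_grade=per_grade, macro=macro, confusion=cm,
                        overall_accuracy=float(np.trace(cm) / n), roc=roc)


# ---------------------------------------------------------------------------
# end-to-end benchmark runs


@dataclass
class ExperimentResult:
    data_type: str
    n_lv: int
    train_metrics: MetricsTable
    test_metrics: MetricsTable
    model: PlsdaModel
    lv_curves: pd.DataFrame | None = None

    def table_rows(self) -> pd.DataFrame:
        """Rows in the benchmark report shape (per grade + macro average)."""
        out = []
        for split, mt in (("Train", self.train_metrics), ("Test", self.test_metrics)):
            for _, r in mt.per_grade.iterrows():
                out.append({"Data type": self.data_type, "LVs": self.n_lv,
                            "Split": split, "Grade": r["Grade"],
                            **{m: r[m] for m in METRIC_NAMES}})
            out.append({"Data type": self.data_type, "LVs": self.n_lv,
                        "Split": split, "Grade": "Average",
                        **{m: mt.macro[m] for m in METRIC_NAMES}})
        return pd.DataFrame(out)


def _assemble(real: list[Fingerprint], generated: list[Fingerprint],
              split: SplitPlan, augmented: bool
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Xr, yr = values_matrix(real)
    X_train = Xr[split.train_real]
    y_train = yr[split.train_real]
    X_test = Xr[split.test_real]
    y_test = yr[split.test_real]
    if augmented:
        if not generated:
            raise ValueError("augmented run requested but no generated data")
        Xg, yg = values_matrix(generated)
        X_train = np.vstack([X_train, Xg[split.train_generated]])
        y_train = np.concatenate([y_train, yg[split.train_generated]])
        if split.mixed_test:
            X_test = np.vstack([X_test, Xg[split.test_generated]])
            y_test = np.concatenate([y_test, yg[split.test_generated]])
    return X_train, y_train, X_test, y_test


def run_experiment(data_type: str, real: list[Fingerprint],
                   generated: list[Fingerprint], split: SplitPlan,
                   n_lv: int | None = None, max_lv: int = 15,
                   folds: int = 10, seed: int = 0) -> ExperimentResult:
    """Fit and evaluate PLS-DA for one benchmark data type.

    ``real`` (and ``generated`` for augmented types) must carry the data
    type's base modality.  When ``n_lv`` is None the LV count is selected
    by stratified cross-validation on the training block.
    """
    if data_type not in DATA_TYPES:
        raise ValueError(f"unknown data type {data_type!r}; one of {DATA_TYPES}")
    augmented = data_type.endswith("-TimeVQVAE")
    X_train, y_train, X_test, y_test = _assemble(real, generated, split, augmented)
    Y_train = one_hot(y_train)
    curves = None
    if n_lv is None:
        n_lv, curves = select_lv(X_train, Y_train, max_lv=max_lv,
                                 folds=folds, seed=seed)
    model = fit_plsda(X_train, Y_train, n_lv)
    train_m = score_classification(y_train, model.predict(X_train),
                                   model.decision_scores(X_train))
    test_m = score_classification(y_test, model.predict(X_test),
                                  model.decision_scores(X_test))
    return ExperimentResult(data_type=data_type, n_lv=model.n_lv,
                            train_metrics=train_m, test_metrics=test_m,
                            model=model, lv_curves=curves)


def results_to_frame(results: list[ExperimentResult]) -> pd.DataFrame:
    return pd.concat([r.table_rows() for r in results], ignore_index=True)
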