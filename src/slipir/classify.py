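"""Repeated-partition classification, risk scores, and panel evaluation.

Models (ridge logistic regression with CV-chosen penalty, random forest,
linear SVM) are trained on stratified 80/20 partitions repeated
``n_repeats`` times.  AUC is computed per iteration on the held-out test
set; risk scores are *out-of-fold only* — a sample's score list comes
solely from iterations in which it was held out, and its median drives the
high-risk call at the 0.5 threshold.

Sensitivity and specificity follow the screening-oriented definitions used
with these panels: sensitivity = cases called high / all cases;
specificity = cases called high / all samples called high (a
precision-style quantity).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import LinearSVC

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    n_repeats: int = 100
    train_frac: float = 0.8
    seed: int = 0
    rf_trees: int = 500
    lr_cv: int = 10      # CV folds for the ridge penalty; 0 = plain ridge C=1
    svm_C: float = 1.0
    threshold: float = 0.5

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def make_estimator(algorithm: str, seed: int = 0, rf_trees: int = 500,
                   lr_cv: int = 10, svm_C: float = 1.0):
    if algorithm == "lr":
        if lr_cv and lr_cv >= 2:
            return LogisticRegressionCV(Cs=7, cv=lr_cv, l1_ratios=(0,),
                                        scoring="neg_log_loss", max_iter=500,
                                        use_legacy_attributes=False,
                                        random_state=seed)
        return LogisticRegression(C=1.0, max_iter=500)
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    if algorithm == "svm":
        return LinearSVC(C=svm_C, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _scores_of(estimator, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class, or decision values for SVMs."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


@dataclass
class ModelReport:
    algorithm: str
    panel: list[str]
    train_auc: np.ndarray
    test_auc: np.ndarray
    sample_scores: dict[str, list[float]]
    threshold: float = 0.5
    probabilistic: bool = True

    @property
    def median_scores(self) -> pd.Series:
        return pd.Series(
            {s: float(np.median(v)) for s, v in self.sample_scores.items() if v},
            name="median_risk_score",
        )

    def sens_spec(self, labels: Mapping[str, str] | pd.Series, case_label: str):
        labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        med = self.median_scores
        return sens_spec(med, labels[med.index], case_label, self.threshold)

    def summary(self) -> str:
        lines = [
            f"{self.algorithm.upper()} model, panel of {len(self.panel)} features, "
            f"{len(self.test_auc)} iterations",
            f"  median train AUC: {np.median(self.train_auc):.3f}",
            f"  median test AUC:  {np.median(self.test_auc):.3f}",
        ]
        return "\n".join(lines)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney concordance (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = scores[y == 1] if set(np.unique(y)) <= {0, 1} else None
    if pos is None:
        raise ValueError("labels must be 0/1")
    neg = scores[y == 0]
    pos = scores[y == 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # rank-based Mann-Whitney U, midranks for ties
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _binary_y(labels: pd.Series, case_label: str) -> np.ndarray:
    return (labels == case_label).to_numpy(dtype=int)


def repeat_harness(X: pd.DataFrame, labels: Mapping[str, str] | pd.Series,
                   panel: Sequence[str], algorithm: str, case_label: str,
                   config: ModelConfig = ModelConfig()) -> ModelReport:
    """Repeated stratified 80/20 train/test evaluation of one panel.

    ``X`` is samples x features (log2-RPM); features are z-scored using
    training-split statistics.  Out-of-fold scores are accumulated per
    sample.  If a partition drops a class (tiny cohorts), it is redrawn
    with the next seed and the event logged.
    """
    from slipir.select import _standardize  # shared z-scoring

    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = _binary_y(labels.reindex(X.index), case_label)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    panel = list(panel)
    missing = set(panel) - set(X.columns)
    if missing:
        raise ValueError(f"panel features missing from matrix: {sorted(missing)}")
    Xv = X[panel].to_numpy()

    train_auc, test_auc = [], []
    sample_scores: dict[str, list[float]] = {s: [] for s in X.index}
    probabilistic = algorithm != "svm"

    draws, done = 0, 0
    seed = config.seed
    while done < config.n_repeats:
        sss = StratifiedShuffleSplit(n_splits=1, train_size=config.train_frac,
                                     random_state=seed + draws)
        tr, te = next(sss.split(Xv, y))
        draws += 1
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            log.warning("iteration %d: class missing from partition, redrawing", done)
            continue
        Xtr, Xte = _standardize(Xv[tr], Xv[te])
        est = make_estimator(algorithm, seed=config.seed * 1000 + done,
                             rf_trees=config.rf_trees, lr_cv=config.lr_cv,
                             svm_C=config.svm_C)
        est.fit(Xtr, y[tr])
        s_tr = _scores_of(est, Xtr)
        s_te = _scores_of(est, Xte)
        train_auc.append(roc_auc(s_tr, y[tr]))
        test_auc.append(roc_auc(s_te, y[te]))
        if probabilistic:
            for idx, sc in zip(te, s_te):
                sample_scores[X.index[idx]].append(float(sc))
        done += 1
    return ModelReport(
        algorithm=algorithm,
        panel=panel,
        train_auc=np.asarray(train_auc),
        test_auc=np.asarray(test_auc),
        sample_scores=sample_scores,
        threshold=config.threshold,
        probabilistic=probabilistic,
    )


def sens_spec(median_scores: pd.Series, labels: pd.Series, case_label: str,
              threshold: float = 0.5) -> tuple[float, float]:
    """Screening sensitivity/specificity from median risk scores.

    sensitivity = cases with median >= threshold / all cases;
    specificity = cases with median >= threshold / all samples with
    median >= threshold (precision-style).  Returns NaN specificity when
    nobody scores high.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    labels = labels.reindex(median_scores.index)
    is_case = labels == case_label
    high = median_scores >= threshold
    n_cases = int(is_case.sum())
    n_high = int(high.sum())
    n_case_high = int((is_case & high).sum())
    sensitivity = n_case_high / n_cases if n_cases else float("nan")
    specificity = n_case_high / n_high if n_high else float("nan")
    return sensitivity, specificity


def enumerate_combos(types: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of RNA types, ordered by size then lexicographic."""
    types = list(types)
    if not types:
        raise ValueError("empty type list")
    if len(types) > 16:
        raise ValueError("too many types")
    combos = []
    for k in range(1, len(types) + 1):
        combos.extend(sorted(itertools.combinations(sorted(types), k)))
    return combos


def one_vs_rest(X: pd.DataFrame, labels: Mapping[str, str] | pd.Series,
                panels: Mapping[str, Sequence[str]], control_label: str,
                config: ModelConfig = ModelConfig(), algorithm: str = "lr",
                common_panel: Sequence[str] | None = None):
    """One-class-versus-others harness per class, plus a pooled "cancers"
    class when ``common_panel`` is given.

    Returns ``(reports, score_matrix)`` where ``score_matrix`` holds each
    sample's median out-of-fold risk score under every class panel.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(X.index)
    reports: dict[str, ModelReport] = {}
    scores: dict[str, pd.Series] = {}
    for cls, panel in panels.items():
        n_cls = int((labels == cls).sum())
        if n_cls < 5:
            log.warning("class %s has only %d samples", cls, n_cls)
        ovr = pd.Series(np.where(labels == cls, cls, "rest"), index=X.index)
        rep = repeat_harness(X, ovr, panel, algorithm, case_label=cls, config=config)
        reports[cls] = rep
        scores[cls] = rep.median_scores
    if common_panel is not None:
        pooled = pd.Series(
            np.where(labels == control_label, "control", "cancers"), index=X.index
        )
        rep = repeat_harness(X, pooled, common_panel, algorithm,
                             case_label="cancers", config=config)
        reports["cancers"] = rep
        scores["cancers"] = rep.median_scores
    score_matrix = pd.DataFrame(scores).reindex(X.index)
    return reports, score_matrix


def two_step_diagnosis(common_score: float, type_scores: Mapping[str, float],
                       threshold: float = 0.5):
    """Two-step verification call.

    Positive only when the common cancer score AND at least one cancer
    type-specific score reach the threshold; reports every type at or
    above it.  Returns ``("negative", [])`` or ``("positive", [types])``.
    """
    high_types = sorted(t for t, s in type_scores.items() if s >= threshold)
    if common_score >= threshold and high_types:
        return "positive", high_types
    return "negative", []
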