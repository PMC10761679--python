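"""Stability feature selection over repeated random partitions.

Three strategies, each run across stratified 80/20 train/test partitions
repeated ``n_repeats`` times:

* Top-N (filter): start from the two most significant features and add the
  next-ranked feature one at a time; a feature that lowers the mean
  held-out-test AUC (averaged over the LR/RF/SVM classifiers, paired
  across a fixed partition bank) is removed again.
* Boruta (wrapper): per repeat, random-forest importances are compared
  against shuffled "shadow" copies of every feature; features beating the
  maximum shadow importance in significantly many rounds (two-sided
  binomial test, alpha = 0.01) are confirmed.  A feature is selected when
  confirmed in at least ``frequency_floor`` of the repeats.
* LASSO (intrinsic): per repeat, an L1-penalized logistic regression on
  z-scored log2-RPM features with the penalty chosen by the 1-SE rule
  (largest penalty whose 10-fold CV deviance is within one standard error
  of the minimum); features with non-zero coefficients in at least
  ``frequency_floor`` repeats are selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from slipir.classify import roc_auc, make_estimator, _scores_of

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    n_repeats: int = 100
    train_frac: float = 0.8
    frequency_floor: int = 10
    topn_max: int = 20
    boruta_max_runs: int = 500
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    rf_trees: int = 100          # Top-N evaluation forest size
    lasso_cv_folds: int = 10
    lasso_n_lambdas: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0 < self.frequency_floor <= self.n_repeats:
            raise ValueError("frequency_floor must be in (0, n_repeats]")


@dataclass
class SelectionResult:
    strategy: str
    selected: list[str]
    frequency: pd.Series  # per-feature count out of n_repeats
    n_repeats: int

    def summary(self) -> str:
        top = self.frequency.sort_values(ascending=False).head(10)
        lines = [f"{self.strategy} selection: {len(self.selected)} features "
                 f"(floor {int(self.frequency.max()) and ''}{''})".replace(" ()", ""),
                 f"  repeats: {self.n_repeats}"]
        lines += [f"  {f}: {int(n)}/{self.n_repeats}" for f, n in top.items()]
        return "\n".join(lines)


def _as_xy(matrix, labels, features=None):
    """Accepts a CountMatrix or a samples x features DataFrame of
    log2-RPM values; returns (X DataFrame samples x features, y array)."""
    from slipir.quantify import CountMatrix

    if isinstance(matrix, CountMatrix):
        X = matrix.log2rpm().T
    else:
        X = matrix
    if features is not None:
        X = X[list(features)]
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = labels.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("binary labels required")
    return X, (y == classes[1]).to_numpy(dtype=int)


def _partition_bank(y: np.ndarray, config: SelectionConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    sss = StratifiedShuffleSplit(
        n_splits=config.n_repeats, train_size=config.train_frac, random_state=config.seed
    )
    return list(sss.split(np.zeros(len(y)), y))


def _standardize(train: np.ndarray, test: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    if test is None:
        return (train - mu) / sd
    return (train - mu) / sd, (test - mu) / sd


# --- Top-N ------------------------------------------------------------------

def _mean_test_auc(X: pd.DataFrame, y: np.ndarray, features: list[str],
                   bank, config: SelectionConfig) -> float:
    """Mean held-out AUC over the partition bank and the three classifiers."""
    sub = X[features].to_numpy()
    aucs = []
    for algo in ("lr", "rf", "svm"):
        for i, (tr, te) in enumerate(bank):
            Xtr, Xte = _standardize(sub[tr], sub[te])
            est = make_estimator(algo, seed=config.seed * 1000 + i,
                                 rf_trees=config.rf_trees, lr_cv=0)
            est.fit(Xtr, y[tr])
            aucs.append(roc_auc(_scores_of(est, Xte), y[te]))
    return float(np.mean(aucs))


def topn_select(matrix, labels, de_ranking: Sequence[str],
                config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Greedy Top-N filter over a significance ranking with AUC pruning.

    ``de_ranking`` must be sorted most-significant first.  The partition
    bank is fixed across N so successive AUC comparisons are paired.
    """
    ranking = list(de_ranking)[: config.topn_max]
    if len(ranking) < 2:
        raise ValueError("need at least 2 ranked features")
    X, y = _as_xy(matrix, labels)
    bank = _partition_bank(y, config)

    accepted = ranking[:2]
    best_auc = _mean_test_auc(X, y, accepted, bank, config)
    for feat in ranking[2:]:
        trial = accepted + [feat]
        auc = _mean_test_auc(X, y, trial, bank, config)
        if auc > best_auc:  # ties keep the smaller set (parsimony)
            accepted, best_auc = trial, auc
    freq = pd.Series(0, index=X.columns, dtype=int)
    freq[accepted] = config.n_repeats
    return SelectionResult("topn", accepted, freq, config.n_repeats)


# --- Boruta -----------------------------------------------------------------

def _boruta_one_repeat(Xtr: np.ndarray, ytr: np.ndarray, rng: np.random.Generator,
                       config: SelectionConfig) -> np.ndarray:
    """One Boruta run on a training split; returns a boolean confirmed mask."""
    n, m = Xtr.shape
    hits = np.zeros(m, dtype=int)
    confirmed = np.zeros(m, dtype=bool)
    rejected = np.zeros(m, dtype=bool)
    for run in range(1, config.boruta_max_runs + 1):
        shadow = Xtr.copy()
        for j in range(m):
            rng.shuffle(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=config.boruta_trees,
            random_state=int(rng.integers(2**31 - 1)),
        )
        rf.fit(np.hstack([Xtr, shadow]), ytr)
        imp = rf.feature_importances_
        max_shadow = imp[m:].max()
        hits += imp[:m] > max_shadow
        if run >= 5:
            undecided = ~(confirmed | rejected)
            if not undecided.any():
                break
            pv = np.array([
                stats.binomtest(int(h), run, 0.5).pvalue for h in hits
            ])
            newly_conf = undecided & (pv < config.boruta_alpha) & (hits > run / 2)
            newly_rej = undecided & (pv < config.boruta_alpha) & (hits < run / 2)
            confirmed |= newly_conf
            rejected |= newly_rej
            if not (~(confirmed | rejected)).any():
                break
    return confirmed


def boruta_select(matrix, labels, config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Shadow-feature random-forest wrapper selection over repeats."""
    X, y = _as_xy(matrix, labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    bank = _partition_bank(y, config)
    rng = np.random.default_rng(config.seed)
    freq = pd.Series(0, index=X.columns, dtype=int)
    Xv = X.to_numpy()
    for tr, _ in bank:
        confirmed = _boruta_one_repeat(Xv[tr].copy(), y[tr], rng, config)
        freq[confirmed] += 1
    selected = list(freq.index[freq >= config.frequency_floor])
    return SelectionResult("boruta", selected, freq, config.n_repeats)


# --- LASSO ------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _lambda_grid(X: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / len(y)
    lam_max = max(lam_max, 1e-3)
    # glmnet's convention: stop the path earlier when n_samples < n_features
    ratio = 1e-4 if len(y) > X.shape[1] else 1e-2
    return np.geomspace(lam_max, lam_max * ratio, n)


def _lasso_path_fit(Xtr: np.ndarray, ytr: np.ndarray, config: SelectionConfig,
                    seed: int) -> np.ndarray:
    """lambda.1se L1-logistic fit on one training split; non-zero mask."""
    # the grid must live on the same scale as the (z-scored) fits
    lambdas = _lambda_grid(_standardize(Xtr), ytr, config.lasso_n_lambdas)
    skf = StratifiedKFold(n_splits=config.lasso_cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xtr, ytr))
    dev = np.zeros((len(lambdas), len(folds)))
    for fi, (tr, te) in enumerate(folds):
        Xf, Xo = _standardize(Xtr[tr], Xtr[te])
        for li, lam in enumerate(lambdas):
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (lam * len(tr)),
                                     solver="liblinear", max_iter=200,
                                     random_state=0)
            clf.fit(Xf, ytr[tr])
            dev[li, fi] = _binomial_deviance(ytr[te], clf.predict_proba(Xo)[:, 1])
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(len(folds))
    best = int(np.argmin(mean_dev))
    # lambdas are sorted strongest-penalty first: pick the smallest index
    # (largest lambda) within one SE of the minimum
    ok = mean_dev <= mean_dev[best] + se_dev[best]
    lam_1se = lambdas[int(np.flatnonzero(ok)[0])]
    Xs = _standardize(Xtr)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (lam_1se * len(ytr)),
                             solver="liblinear", max_iter=200, random_state=0)
    clf.fit(Xs, ytr)
    return np.abs(clf.coef_.ravel()) > 1e-10


def lasso_select(matrix, labels, config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """lambda.1se LASSO-logistic stability selection over repeats."""
    X, y = _as_xy(matrix, labels)
    bank = _partition_bank(y, config)
    freq = pd.Series(0, index=X.columns, dtype=int)
    Xv = X.to_numpy()
    n_run = 0
    for i, (tr, _) in enumerate(bank):
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"repeat {i}: single-class training split skipped")
            log.warning("repeat %d: single-class training split skipped", i)
            continue
        nz = _lasso_path_fit(Xv[tr], y[tr], config, seed=config.seed * 100 + i)
        freq[nz] += 1
        n_run += 1
    selected = list(freq.index[freq >= config.frequency_floor])
    return SelectionResult("lasso", selected, freq, config.n_repeats)
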