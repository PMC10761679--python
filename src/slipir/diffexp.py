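"""Negative-binomial Wald differential expression.

The model follows the standard count-based DE formulation: raw counts
K_fs ~ NB(mu_fs, alpha_f) with mu_fs = s_s * q_fg, where s_s is a
median-of-ratios size factor, g the group of sample s, and alpha_f a
per-feature dispersion.  The group log-means are fitted by per-group
Fisher scoring on the NB log-likelihood; the Wald statistic is
log2FC / SE(log2FC) with SE from the observed Fisher information, and
two-sided normal p-values are BH-adjusted.

Deliberate simplifications relative to the full empirical-Bayes machinery:
dispersions are per-feature method-of-moments estimates on normalized
counts with a 1e-8 floor (no shrinkage across features, no independent
filtering); calibration is checked by simulation instead of by matching a
reference implementation feature-for-feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame, allow_fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over features (nonzero in every sample) of
    counts[f, s] / geometric_mean_f(counts[f, .]).  When no feature is
    nonzero in all samples, geometric means are taken over positive counts
    only (fallback), or an error is raised when ``allow_fallback=False``.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        geo = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    elif allow_fallback:
        with np.errstate(divide="ignore"):
            logm = np.where(mat > 0, np.log(mat), np.nan)
        log_geo = np.nanmean(logm, axis=1)
        usable = np.isfinite(log_geo)
        if not usable.any():
            raise ValueError("no usable features for size-factor estimation")
        ratios = np.exp(logm[usable] - log_geo[usable, None])
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError("no feature is nonzero in all samples and fallback is disabled")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray], sf: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments dispersion on normalized counts.

    Pools within-group mean/variance so planted group effects do not
    inflate the estimate: Var(K_s/s_s) ~ mu/s_s + alpha mu^2 gives
    alpha = (var - mu * E[1/s]) / mu^2, floored at 1e-8.
    """
    inv_sf_mean = float(np.mean(1.0 / sf))
    n_feat = norm.shape[0]
    ss = np.zeros(n_feat)
    dof = 0
    mu_w = np.zeros(n_feat)
    n_tot = 0
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        dof += len(idx) - 1
        mu_w += m * len(idx)
        n_tot += len(idx)
    var = ss / max(dof, 1)
    mu = mu_w / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu * inv_sf_mean) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _fit_group_logmeans(mat: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                        idx: np.ndarray, n_iter: int = 50):
    """Vectorized Fisher scoring for per-feature group log-mean beta.

    Model: K_s ~ NB(exp(beta) * s_s, alpha).  Returns (beta, info) where
    info is the Fisher information sum_s mu_s / (1 + alpha mu_s).
    Zero-count groups use a half-count initialisation, yielding a finite,
    conservative estimate.
    """
    k = mat[:, idx]
    s = sf[idx]
    mean_norm = (k / s).mean(axis=1)
    beta = np.log(np.where(mean_norm > 0, mean_norm, 0.5 / s.sum()))
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * s
        denom = 1.0 + a * mu
        score = ((k - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(beta)[:, None] * s
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return beta, info


@dataclass
class DEResults:
    """Per-feature DE table plus the fitted nuisance quantities."""

    table: pd.DataFrame          # baseMean, meanRawCount, log2FC, SE, stat, p, q, de_flag, candidate_flag
    size_factors: pd.Series
    dispersions: pd.Series
    case_label: str
    control_label: str
    fdr_level: float = 0.1

    @property
    def de_features(self) -> pd.Index:
        return self.table.index[self.table["de_flag"].fillna(False)]

    @property
    def candidates(self) -> pd.Index:
        return self.table.index[self.table["candidate_flag"].fillna(False)]

    def summary(self) -> str:
        t = self.table
        n_de = int(t["de_flag"].fillna(False).sum())
        n_up = int((t["de_flag"].fillna(False) & (t["log2FC"] > 0)).sum())
        lines = [
            "Negative-binomial Wald differential expression",
            f"  contrast: {self.case_label} vs {self.control_label}",
            f"  features tested: {int(t['p'].notna().sum())} of {len(t)}",
            f"  DE at BH-FDR < {self.fdr_level}: {n_de} ({n_up} up, {n_de - n_up} down)",
            f"  candidates (up, mean>10, log2FC>0.8): {int(t['candidate_flag'].fillna(False).sum())}",
        ]
        return "\n".join(lines)


def nb_wald_test(counts: pd.DataFrame, labels: Mapping[str, str] | pd.Series,
                 case_label: str, control_label: str,
                 factors: pd.Series | None = None,
                 fdr_level: float = 0.1) -> DEResults:
    """Two-group NB Wald test for every feature.

    ``labels`` maps sample -> group; only samples labelled ``case_label``
    or ``control_label`` are used (each group needs n >= 2).  All-zero
    features get p = NA and are excluded from the FDR correction.
    Positive log2FC means higher in the case group.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    case_samples = [s for s in counts.columns if labels.get(s) == case_label]
    ctrl_samples = [s for s in counts.columns if labels.get(s) == control_label]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    use = case_samples + ctrl_samples
    sub = counts[use]
    if factors is None:
        factors = size_factors(sub)
    sf = factors[use].to_numpy(dtype=float)
    mat = sub.to_numpy(dtype=float)
    norm = mat / sf
    idx_case = np.arange(len(case_samples))
    idx_ctrl = np.arange(len(case_samples), len(use))

    alpha = _mom_dispersion(norm, [idx_case, idx_ctrl], sf)
    beta_case, info_case = _fit_group_logmeans(mat, sf, alpha, idx_case)
    beta_ctrl, info_ctrl = _fit_group_logmeans(mat, sf, alpha, idx_ctrl)

    log2fc = (beta_case - beta_ctrl) / LN2
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / np.maximum(info_case, 1e-12) + 1.0 / np.maximum(info_ctrl, 1e-12)) / LN2
    stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    all_zero = mat.sum(axis=1) == 0
    p = np.where(all_zero, np.nan, p)
    log2fc = np.where(all_zero, np.nan, log2fc)

    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "meanRawCount": mat.mean(axis=1),
            "log2FC": log2fc,
            "SE": se,
            "stat": stat,
            "p": p,
            "q": q,
        },
        index=counts.index,
    )
    table["de_flag"] = pd.array(table["q"] < fdr_level, dtype="boolean")
    table.loc[table["p"].isna(), "de_flag"] = pd.NA
    res = DEResults(
        table=table,
        size_factors=factors,
        dispersions=pd.Series(alpha, index=counts.index, name="dispersion"),
        case_label=case_label,
        control_label=control_label,
        fdr_level=fdr_level,
    )
    res.table["candidate_flag"] = candidate_filter(res)
    return res


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NA passes through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        vals = p[mask]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def candidate_filter(de: DEResults, min_mean_count: float = 10.0,
                     min_log2fc: float = 0.8, fdr_level: float | None = None) -> pd.Series:
    """Initial-candidate rule: significant, upregulated in cases, mean raw
    counts > 10, log2FC > 0.8 (all strict inequalities)."""
    level = de.fdr_level if fdr_level is None else fdr_level
    t = de.table
    flag = (
        (t["q"] < level)
        & (t["log2FC"] > 0)
        & (t["meanRawCount"] > min_mean_count)
        & (t["log2FC"] > min_log2fc)
    )
    flag[t["p"].isna()] = False
    return flag


def cumulative_sum_compare(norm_matrix: pd.DataFrame, feature_ids: Sequence[str],
                           groups: Mapping[str, str] | pd.Series,
                           pairs: Sequence[tuple[str, str]] | None = None):
    """Per-sample cumulative sum of normalized reads over a DE set, with
    pairwise two-sided Welch t-tests between groups.

    Returns ``(sums, tests)``: a per-sample Series and a DataFrame with
    columns group_a, group_b, t, df, p.
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("empty feature set")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    sums = norm_matrix.loc[feature_ids].sum(axis=0)
    uniq = list(dict.fromkeys(groups[sums.index]))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    rows = []
    for a, b in pairs:
        xa = sums[groups[sums.index] == a].to_numpy()
        xb = sums[groups[sums.index] == b].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a if len(xa) < 2 else b!r} has < 2 samples")
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue)})
    return sums, pd.DataFrame(rows)
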