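"""Negative-binomial 13C-enrichment calling for genome bins and OTUs.

Replicated heavy-fraction read counts from 13C- and 12C-substrate microcosms
are compared feature by feature with a size-factor-normalized negative-binomial
Wald test: median-of-ratios normalization, method-of-moments dispersion
estimation moderated toward a parametric mean-dispersion trend, and a
two-coefficient NB GLM (intercept + condition) fitted by IRLS. A feature is
called 13C-enriched when its 13C-vs-12C log2 fold change is positive and the
(optionally BH-adjusted) p-value falls below alpha.

The design is deliberately minimal for the 2-vs-2 replication typical of SIP
experiments: no independent filtering, no fold-change shrinkage, no outlier
refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "rank_enriched",
]

CONDITIONS = ("12C", "13C")

#: Prior degrees of freedom pulling per-feature dispersions toward the trend.
#: With duplicate microcosms (2 residual df per feature) the trend dominates.
DISPERSION_PRIOR_DF = 8.0

_IRLS_MAX_ITER = 100
_IRLS_TOL = 1e-8
_MU_FLOOR = 1e-8


class InsufficientReplicationError(ValueError):
    """Fewer than two replicates in a condition."""


@dataclass
class CountMatrix:
    """Feature-by-sample integer read counts with condition labels.

    ``counts`` is a features x samples DataFrame; ``conditions`` maps each
    sample to '12C' or '13C'; ``replicates`` maps each sample to its
    replicate id.
    """

    counts: pd.DataFrame
    conditions: Mapping[str, str]
    replicates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        bad = set(self.conditions.values()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def condition_vector(self) -> pd.Series:
        return pd.Series({s: self.conditions[s] for s in self.counts.columns})

    def require_replication(self, min_per_condition: int = 2) -> None:
        cv = self.condition_vector()
        for cond in CONDITIONS:
            n = int((cv == cond).sum())
            if n < min_per_condition:
                raise InsufficientReplicationError(
                    f"condition {cond} has {n} sample(s); need >= {min_per_condition}"
                )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    The reference is the per-feature geometric mean over features positive in
    every sample; each sample's factor is the median of its count/reference
    ratios, rescaled so the factors have geometric mean 1. If no feature is
    positive everywhere, falls back to per-sample medians over that sample's
    positive features (with a warning).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.all(mat > 0, axis=1)
    if all_positive.any():
        log_ref = logs[all_positive].mean(axis=1)
        log_factors = np.median(logs[all_positive] - log_ref[:, None], axis=0)
    else:
        warnings.warn(
            "no feature has positive counts in all samples; "
            "falling back to positive-subset median-of-ratios",
            RuntimeWarning,
            stacklevel=2,
        )
        any_positive = mat > 0
        log_ref = np.where(
            any_positive.any(axis=1),
            np.nanmean(np.where(any_positive, logs, np.nan), axis=1),
            0.0,
        )
        log_factors = np.array(
            [
                np.median((logs[:, j] - log_ref)[any_positive[:, j]])
                for j in range(mat.shape[1])
            ]
        )
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def _normalized(counts: pd.DataFrame, sf: pd.Series) -> np.ndarray:
    return counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)[None, :]


def _group_masks(samples: Sequence[str], conditions: Mapping[str, str]) -> dict[str, np.ndarray]:
    labels = np.array([conditions[s] for s in samples])
    return {cond: labels == cond for cond in CONDITIONS}


def _raw_dispersion_mom(norm: np.ndarray, masks: Mapping[str, np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion on normalized counts, within-condition.

    alpha_hat = max(0, (s^2 - mu) / mu^2) with the residual variance pooled
    across conditions (df = n - 2) so the condition effect does not inflate it.
    """
    n = norm.shape[1]
    resid_ss = np.zeros(norm.shape[0])
    for mask in masks.values():
        grp = norm[:, mask]
        resid_ss += ((grp - grp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n - len(masks)
    s2 = resid_ss / max(df, 1)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, 0.0)


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of the parametric trend alpha(mu) = a0 + a1/mu."""
    use = (mu > 0) & (alpha > 0)
    if use.sum() < 2:
        a0 = float(np.median(alpha[mu > 0])) if (mu > 0).any() else 0.0
        return max(a0, 1e-6), 0.0
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
    a0 = max(float(coef[0]), 1e-6)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: Mapping[str, str],
    shrink: bool = True,
    prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.Series:
    """Per-feature NB dispersion alpha >= 0 on size-factor-normalized counts.

    Raw estimates are method-of-moments; with ``shrink`` they are moderated
    toward the fitted trend alpha(mu) = a0 + a1/mu with weight
    prior_df / (prior_df + residual_df), which at duplicate replication
    (2 residual df) leans strongly on the trend.
    """
    masks = _group_masks(list(counts.columns), conditions)
    for cond, mask in masks.items():
        if mask.sum() < 2:
            raise InsufficientReplicationError(
                f"condition {cond} has {int(mask.sum())} sample(s); need >= 2"
            )
    norm = _normalized(counts, sf)
    raw = _raw_dispersion_mom(norm, masks)
    if not shrink:
        return pd.Series(raw, index=counts.index, name="dispersion")
    mu = norm.mean(axis=1)
    a0, a1 = _fit_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)
    resid_df = norm.shape[1] - len(masks)
    w = prior_df / (prior_df + resid_df)
    alpha = w * trend + (1.0 - w) * raw
    return pd.Series(np.maximum(alpha, 0.0), index=counts.index, name="dispersion")


def _irls_nb_two_group(
    y: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    is13: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-feature NB GLMs with design [1, condition].

    Returns (beta0, beta1, se_beta1) in natural-log units; beta1 is the
    13C-vs-12C log fold change. Features are fitted in parallel.
    """
    n_feat, n_samp = y.shape
    X = np.column_stack([np.ones(n_samp), is13.astype(float)])
    log_sf = np.log(sf)

    # Start from group means of normalized counts.
    norm = y / sf[None, :]
    mu12 = np.maximum(norm[:, ~is13].mean(axis=1), _MU_FLOOR)
    mu13 = np.maximum(norm[:, is13].mean(axis=1), _MU_FLOOR)
    beta = np.column_stack([np.log(mu12), np.log(mu13) - np.log(mu12)])

    a = alpha[:, None]
    dev_prev = np.full(n_feat, np.inf)
    active = np.ones(n_feat, dtype=bool)
    xtwx = np.zeros((n_feat, 2, 2))
    for _ in range(_IRLS_MAX_ITER):
        eta = beta @ X.T + log_sf[None, :]
        mu = np.clip(np.exp(eta), _MU_FLOOR, 1e12)
        w = mu / (1.0 + a * mu)
        z = (eta - log_sf[None, :]) + (y - mu) / mu
        # Batched 2x2 normal equations.
        wx = w[:, :, None] * X[None, :, :]
        xtwx = np.einsum("sk,fsl->fkl", X, wx)
        xtwz = np.einsum("fsk,fs->fk", wx, z)
        xtwx += 1e-10 * np.eye(2)[None, :, :]
        beta_new = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        # NB deviance-like objective via log-likelihood change.
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                a > 0,
                y * np.log(mu) - (y + 1.0 / a) * np.log1p(a * mu),
                y * np.log(mu) - mu,
            ).sum(axis=1)
        dev = -2.0 * ll
        rel = np.abs(dev - dev_prev) / (np.abs(dev) + 0.1)
        beta[active] = beta_new[active]
        newly_done = rel < _IRLS_TOL
        active &= ~newly_done
        dev_prev = dev
        if not active.any():
            break

    # Standard errors from the final Fisher information.
    eta = beta @ X.T + log_sf[None, :]
    mu = np.clip(np.exp(eta), _MU_FLOOR, 1e12)
    w = mu / (1.0 + a * mu)
    wx = w[:, :, None] * X[None, :, :]
    xtwx = np.einsum("sk,fsl->fkl", X, wx) + 1e-10 * np.eye(2)[None, :, :]
    cov = np.linalg.inv(xtwx)
    se1 = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    return beta[:, 0], beta[:, 1], se1


def wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    dispersions: pd.Series,
    conditions: Mapping[str, str],
    alpha: float = 0.05,
    use_bh: bool = True,
) -> pd.DataFrame:
    """Per-feature NB Wald test of 13C vs 12C abundance.

    Fits an NB GLM with log link and design ~condition per feature, reports
    the log2 fold change (13C over 12C), its standard error, the Wald
    statistic against the standard normal, two-sided p-values and BH-adjusted
    p-values. ``enriched`` flags features with positive fold change whose
    (adjusted if ``use_bh``) p-value is below ``alpha``. All-zero features get
    NA statistics and are excluded from the BH denominator.
    """
    masks = _group_masks(list(counts.columns), conditions)
    for cond, mask in masks.items():
        if mask.sum() < 2:
            raise InsufficientReplicationError(
                f"condition {cond} has {int(mask.sum())} sample(s); need >= 2"
            )
    y = counts.to_numpy(dtype=float)
    sf_arr = sf.loc[counts.columns].to_numpy(dtype=float)
    alpha_arr = dispersions.loc[counts.index].to_numpy(dtype=float)
    is13 = masks["13C"]

    nonzero = y.sum(axis=1) > 0
    base_mean = (y / sf_arr[None, :]).mean(axis=1)

    lfc = np.full(y.shape[0], np.nan)
    se = np.full(y.shape[0], np.nan)
    if nonzero.any():
        _, b1, se1 = _irls_nb_two_group(
            y[nonzero], sf_arr, alpha_arr[nonzero], is13
        )
        ln2 = np.log(2.0)
        lfc[nonzero] = b1 / ln2
        se[nonzero] = se1 / ln2

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    pval = np.where(np.isfinite(stat), 2.0 * stats.norm.sf(np.abs(stat)), np.nan)

    padj = np.full_like(pval, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]

    crit = padj if use_bh else pval
    with np.errstate(invalid="ignore"):
        enriched = tested & (crit < alpha) & (lfc > 0)

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "enriched": enriched,
        },
        index=counts.index,
    )


def rank_enriched(
    result: pd.DataFrame,
    lfc_min: float = 0.0,
    use_bh: bool = True,
    alpha: float = 0.05,
) -> list[str]:
    """Enriched features sorted by log2 fold change (desc), id tie-break.

    Filters to positive-fold-change features significant at ``alpha`` on the
    BH-adjusted (or raw, if ``use_bh`` is False) p-value and with
    log2FoldChange >= ``lfc_min``.
    """
    if result.empty:
        return []
    crit = result["padj"] if use_bh else result["pvalue"]
    keep = (
        crit.notna()
        & (crit < alpha)
        & (result["log2FoldChange"] > 0)
        & (result["log2FoldChange"] >= lfc_min)
    )
    sub = result.loc[keep]
    order = sorted(
        sub.index, key=lambda fid: (-float(sub.at[fid, "log2FoldChange"]), str(fid))
    )
    return [str(f) for f in order]
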