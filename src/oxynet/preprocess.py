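"""Normalization and filtering cascade for expression matrices.

Mirrors a standard microarray / RNA-seq preprocessing chain: quantile
normalization, log2 transform, TPM conversion, a pooled-percentile signal
filter, a detection-rate filter, PCA-based outlier flagging, and
empirical-Bayes batch adjustment (location-scale ComBat model).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, FilterReport, OxynetError

logger = logging.getLogger("oxynet.preprocess")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the cross-column mean distribution.

    After normalization every sample has identical sorted values (the means
    of the column-sorted values). Within-column ties receive the mean of the
    rank-means their positions span, so the operation is idempotent and
    permutation-equivariant.
    """
    X = m.values.to_numpy(float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise OxynetError("quantile normalization needs >=2 samples")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # positions occupied by each run of tied values share the mean ref
        assigned = np.empty(n_feat)
        start = 0
        for i in range(1, n_feat + 1):
            if i == n_feat or sorted_col[i] != sorted_col[start]:
                assigned[start:i] = ref[start:i].mean()
                start = i
        out[order, j] = assigned
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); the scale tag becomes ``log2``."""
    X = m.values.to_numpy(float)
    shifted = X + offset
    if (shifted <= 0).any():
        bad = np.argwhere(shifted <= 0)
        offenders = [f"{m.values.index[r]}/{m.values.columns[c]}" for r, c in bad[:5]]
        raise OxynetError(
            f"log2: {len(bad)} nonpositive value(s) after offset {offset}; "
            f"first offenders: {', '.join(offenders)}")
    values = pd.DataFrame(np.log2(shifted), index=m.values.index, columns=m.values.columns)
    return m.with_values(values, scale="log2")


def counts_to_tpm(counts: ExpressionMatrix, lengths_kb: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per column: rate = count / length(kb); TPM = rate / sum(rate) * 1e6.
    Every output column sums to 1e6.
    """
    if counts.scale != "counts":
        raise OxynetError(f"counts_to_tpm expects counts scale, got {counts.scale}")
    missing = set(counts.feature_ids) - set(lengths_kb.index)
    if missing:
        raise OxynetError(f"lengths missing for features: {sorted(missing)[:5]}")
    L = lengths_kb.loc[counts.feature_ids].to_numpy(float)
    if (L <= 0).any():
        raise OxynetError("nonpositive feature lengths")
    rate = counts.values.to_numpy(float) / L[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(colsum == 0)]
        raise OxynetError(f"zero column sum for samples: {bad}")
    tpm = rate / colsum * 1e6
    values = pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values, layer=counts.layer, scale="TPM",
                            detection=counts.detection)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_by_signal_percentile(m: ExpressionMatrix, lower_pct: float = 20.0,
                                min_fraction: float = 0.5) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features whose signal rarely clears the pooled percentile floor.

    The threshold is the ``lower_pct`` percentile of the pooled value
    distribution; a feature is retained iff its value is >= threshold in at
    least ``min_fraction`` of samples.
    """
    X = m.values.to_numpy(float)
    threshold = np.percentile(X, lower_pct)
    frac_above = (X >= threshold).mean(axis=1)
    keep = frac_above >= min_fraction
    removed = tuple(m.values.index[~keep])
    if not keep.any():
        raise OxynetError(
            f"signal-percentile filter removed every feature; relax lower_pct={lower_pct} "
            f"or min_fraction={min_fraction}")
    out = m.subset_features(m.values.index[keep])
    report = FilterReport(
        stage=f"signal_percentile(lower_pct={lower_pct}, min_fraction={min_fraction})",
        features_before=m.n_features, features_after=out.n_features,
        samples_before=m.n_samples, samples_after=out.n_samples,
        removed_ids=removed)
    logger.info("%s: %d -> %d features", report.stage, report.features_before,
                report.features_after)
    return out, report


def filter_by_detection_rate(m: ExpressionMatrix,
                             min_rate: float = 0.25) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain features detected in at least ``min_rate`` of samples (inclusive)."""
    if m.detection is None:
        raise OxynetError("detection-rate filter requires detection flags")
    rate = m.detection.to_numpy(bool).mean(axis=1)
    keep = rate >= min_rate
    removed = tuple(m.values.index[~keep])
    out = m.subset_features(m.values.index[keep])
    report = FilterReport(
        stage=f"detection_rate(min_rate={min_rate})",
        features_before=m.n_features, features_after=out.n_features,
        samples_before=m.n_samples, samples_after=out.n_samples,
        removed_ids=removed)
    logger.info("%s: %d -> %d features", report.stage, report.features_before,
                report.features_after)
    return out, report


# ---------------------------------------------------------------------------
# PCA and outliers
# ---------------------------------------------------------------------------

def pca(m: ExpressionMatrix, n_components: int = 3):
    """Principal components of samples (column-centered SVD).

    Returns ``(scores, loadings, variance_fractions)``: scores are samples x
    components, loadings features x components. The sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    if m.n_samples < 2:
        raise OxynetError("PCA needs >=2 samples")
    X = m.values.to_numpy(float).T  # samples x features
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise OxynetError("PCA on a constant matrix is undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    total_var = (Xc ** 2).sum()
    var_frac = (s[:k] ** 2) / total_var
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    scores_df = pd.DataFrame(scores, index=m.sample_ids,
                             columns=[f"PC{i+1}" for i in range(k)])
    loadings_df = pd.DataFrame(loadings, index=m.feature_ids,
                               columns=[f"PC{i+1}" for i in range(k)])
    return scores_df, loadings_df, var_frac


def pca_outlier_flags(m: ExpressionMatrix, n_components: int = 3,
                      k_sd: float = 3.0) -> list[str]:
    """Flag samples far from the score centroid in the first PCs.

    A sample is flagged when its Euclidean distance from the centroid exceeds
    the median distance by more than ``k_sd`` robust standard deviations
    (1.4826 x MAD of the distances).
    """
    scores, _, _ = pca(m, n_components=n_components)
    S = scores.to_numpy()
    d = np.linalg.norm(S - S.mean(axis=0), axis=1)
    med = np.median(d)
    mad_sd = 1.4826 * np.median(np.abs(d - med))
    if mad_sd == 0:
        return []
    flagged = [sid for sid, di in zip(m.sample_ids, d) if di > med + k_sd * mad_sd]
    if flagged:
        logger.info("PCA outlier flags (%d PCs, k=%g): %s", n_components, k_sd,
                    ", ".join(flagged))
    return flagged


# ---------------------------------------------------------------------------
# ComBat batch adjustment
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted per-batch location (gamma) and scale (delta^2) effects."""

    batches: list
    gamma: pd.DataFrame       # batches x features, EB-shrunk location
    delta_sq: pd.DataFrame    # batches x features, EB-shrunk scale (>0)
    mode: str                 # parametric | nonparametric

    def __post_init__(self) -> None:
        if (self.delta_sq.to_numpy() <= 0).any():
            raise OxynetError("batch scale estimates must be positive")


def _parametric_priors(gamma_hat: np.ndarray, delta_hat_sq: np.ndarray):
    """Method-of-moments hyperparameters for the normal / inverse-gamma priors."""
    gamma_bar = gamma_hat.mean()
    tau_sq = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat_sq.mean()
    v = delta_hat_sq.var(ddof=1) if delta_hat_sq.size > 1 else 0.0
    if v == 0:
        lam, theta = np.inf, np.inf
    else:
        lam = (2 * v + m ** 2) / v
        theta = (m * v + m ** 3) / v
    return gamma_bar, tau_sq, lam, theta


def _parametric_shrink(z: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
                       n_b: int, tol: float = 1e-6, max_iter: int = 200):
    gamma_bar, tau_sq, lam, theta = _parametric_priors(gamma_hat, delta_hat_sq)
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat_sq.copy()
    if tau_sq == 0 or not np.isfinite(lam):
        # degenerate priors (e.g. 1 feature): fall back to raw estimates
        return gamma_star, np.maximum(delta_star, 1e-12)
    for _ in range(max_iter):
        g_new = (n_b * tau_sq * gamma_hat + delta_star * gamma_bar) / (n_b * tau_sq + delta_star)
        ss = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (theta + 0.5 * ss) / (n_b / 2 + lam - 1)
        if (np.max(np.abs(g_new - gamma_star)) < tol
                and np.max(np.abs(d_new - delta_star)) < tol):
            gamma_star, delta_star = g_new, d_new
            break
        gamma_star, delta_star = g_new, d_new
    return gamma_star, np.maximum(delta_star, 1e-12)


def _nonparametric_shrink(z: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray):
    """Empirical-prior posterior means: each feature's batch effect is a
    likelihood-weighted average over the other features' raw estimates."""
    G, n_b = z.shape
    gamma_star = np.empty(G)
    delta_star = np.empty(G)
    for g in range(G):
        mask = np.arange(G) != g
        gh, dh = gamma_hat[mask], delta_hat_sq[mask]
        resid_sq = (z[g][None, :] - gh[:, None]) ** 2  # (G-1) x n_b
        log_lik = -0.5 * n_b * np.log(2 * np.pi * dh) - resid_sq.sum(axis=1) / (2 * dh)
        w = np.exp(log_lik - log_lik.max())
        w_sum = w.sum()
        if w_sum == 0 or not np.isfinite(w_sum):
            gamma_star[g], delta_star[g] = gamma_hat[g], delta_hat_sq[g]
        else:
            gamma_star[g] = (w * gh).sum() / w_sum
            delta_star[g] = (w * dh).sum() / w_sum
    return gamma_star, np.maximum(delta_star, 1e-12)


def combat_adjust(m: ExpressionMatrix, batches: pd.Series,
                  covariates: Optional[pd.DataFrame] = None,
                  mode: str = "parametric") -> tuple[ExpressionMatrix, BatchModel]:
    """Remove batch effects with the empirical-Bayes location-scale model.

    Per feature the data are standardized against the batch-size-weighted
    grand mean and pooled variance, per-batch location/scale effects are
    estimated, shrunk toward a common prior (parametric normal /
    inverse-gamma, or a nonparametric empirical prior), removed, and the
    original scale restored. With a single batch the transform is the
    identity.
    """
    if mode not in ("parametric", "nonparametric"):
        raise OxynetError(f"unknown ComBat mode {mode!r}")
    sample_ids = m.sample_ids
    missing = set(sample_ids) - set(batches.index)
    if missing:
        raise OxynetError(f"no batch label for samples: {sorted(missing)[:5]}")
    b = batches.loc[sample_ids]
    levels = sorted(pd.unique(b))
    counts = b.value_counts()
    singles = [lv for lv in levels if counts[lv] < 2]
    if singles:
        raise OxynetError(f"batches with <2 samples: {singles}")

    X = m.values.to_numpy(float)
    var0 = X.var(axis=1)
    keep = var0 > 0
    if not keep.all():
        dropped = list(m.values.index[~keep])
        logger.warning("ComBat: excluding %d zero-variance features: %s",
                       len(dropped), ", ".join(dropped[:5]))
    idx = m.values.index[keep]
    X = X[keep]

    if len(levels) == 1:
        model = BatchModel(batches=levels,
                           gamma=pd.DataFrame(0.0, index=levels, columns=idx),
                           delta_sq=pd.DataFrame(1.0, index=levels, columns=idx),
                           mode=mode)
        return m.subset_features(idx), model

    N = X.shape[1]
    batch_idx = {lv: np.flatnonzero((b == lv).to_numpy()) for lv in levels}
    n_per = np.array([len(batch_idx[lv]) for lv in levels], float)

    # covariate-adjusted standardization
    design_cols = [np.isin(np.arange(N), batch_idx[lv]).astype(float) for lv in levels]
    D = np.column_stack(design_cols)
    if covariates is not None:
        C = covariates.loc[sample_ids].to_numpy(float)
        D = np.column_stack([D, C])
    # per-feature least squares for batch means (+ covariate effects)
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)  # (p, G)
    batch_means = beta[:len(levels)]                # per-batch intercepts
    alpha = (n_per / N) @ batch_means               # weighted grand mean per feature
    fitted = (D @ beta).T
    sigma_sq = ((X - fitted) ** 2).mean(axis=1)
    sigma_sq = np.maximum(sigma_sq, 1e-12)
    stand_mean = np.tile(alpha[:, None], (1, N))
    if covariates is not None:
        cov_effect = (D[:, len(levels):] @ beta[len(levels):]).T
        stand_mean = stand_mean + cov_effect
    Z = (X - stand_mean) / np.sqrt(sigma_sq)[:, None]

    gamma_rows, delta_rows = [], []
    Z_adj = Z.copy()
    for i, lv in enumerate(levels):
        cols = batch_idx[lv]
        z_b = Z[:, cols]
        gamma_hat = z_b.mean(axis=1)
        delta_hat_sq = z_b.var(axis=1, ddof=1)
        delta_hat_sq = np.maximum(delta_hat_sq, 1e-12)
        if mode == "parametric":
            g_star, d_star = _parametric_shrink(z_b, gamma_hat, delta_hat_sq, len(cols))
        else:
            g_star, d_star = _nonparametric_shrink(z_b, gamma_hat, delta_hat_sq)
        Z_adj[:, cols] = (z_b - g_star[:, None]) / np.sqrt(d_star)[:, None]
        gamma_rows.append(g_star)
        delta_rows.append(d_star)

    # shrinkage leaves a small residual row mean; re-center so the
    # per-feature grand mean is preserved exactly
    Z_adj = Z_adj - Z_adj.mean(axis=1, keepdims=True)
    X_adj = Z_adj * np.sqrt(sigma_sq)[:, None] + stand_mean
    values = pd.DataFrame(X_adj, index=idx, columns=sample_ids)
    det = m.detection.loc[idx] if m.detection is not None else None
    out = ExpressionMatrix(values, layer=m.layer, scale=m.scale, detection=det)
    model = BatchModel(batches=levels,
                       gamma=pd.DataFrame(np.array(gamma_rows), index=levels, columns=idx),
                       delta_sq=pd.DataFrame(np.array(delta_rows), index=levels, columns=idx),
                       mode=mode)
    logger.info("ComBat (%s): adjusted %d features across %d batches",
                mode, len(idx), len(levels))
    return out, model


# ---------------------------------------------------------------------------
# expression dichotomization (for survival / group comparisons)
# ---------------------------------------------------------------------------

def dichotomize_expression(values: pd.Series) -> tuple[pd.Series, str]:
    """Split samples into high/low expression groups.

    Median split when the median is nonzero (high = value >= median);
    any-vs-none when the median is zero (high = value > 0). Returns the
    labels and the grouping mode used.
    """
    v = values.astype(float)
    if len(v) < 2:
        raise OxynetError("dichotomization needs >=2 samples")
    if v.nunique() == 1:
        raise OxynetError("all values identical; no split possible")
    med = float(np.median(v))
    if med == 0:
        labels = pd.Series(np.where(v > 0, "high", "low"), index=v.index)
        mode = "any-vs-none"
    else:
        labels = pd.Series(np.where(v >= med, "high", "low"), index=v.index)
        mode = "median-split"
    if labels.nunique() < 2:
        raise OxynetError("degenerate split: one group is empty")
    return labels, mode
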