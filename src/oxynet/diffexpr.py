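"""Count-based differential expression between mutation or clinical groups.

A deliberately transparent variant of the standard count-model workflow:
trimmed-mean-of-M-values (TMM) normalization, a pooled method-of-moments
common dispersion, and a two-sided exact conditional test on group-sum
counts under a negative-binomial model with that shared dispersion
(reducing to the exact binomial test at dispersion 0). Fold changes are
reported as the group of interest over the reference with a 0.5 pseudocount.
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import ExpressionMatrix, GeneSet, OxynetError
from .corrnet import bh_adjust

logger = logging.getLogger("oxynet.diffexpr")


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------

def define_groups(sample_ids: Sequence[str],
                  variants: Optional[pd.DataFrame] = None,
                  genes: Union[str, GeneSet, None] = None,
                  clinical: Optional[pd.Series] = None,
                  positive_level: Optional[str] = None,
                  label: str = "group") -> pd.Series:
    """Assign each sample to ``"group"`` (of interest) or ``"reference"``.

    Mutation mode: a sample is in the group iff it carries >= 1 somatic
    variant of any class in any of the listed genes. Clinical mode: samples
    equal to ``positive_level`` of the given per-sample category form the
    group. Empty groups raise.
    """
    sample_ids = list(sample_ids)
    if variants is not None:
        if genes is None:
            raise OxynetError("mutation grouping needs a gene or gene set")
        gene_list = set(genes.members) if isinstance(genes, GeneSet) else {genes}
        hit = variants[variants["gene_symbol"].isin(gene_list)]
        mutated = set(hit["sample_id"])
        labels = pd.Series(["group" if s in mutated else "reference" for s in sample_ids],
                           index=sample_ids, name=label)
        spec_name = genes.name if isinstance(genes, GeneSet) else genes
    elif clinical is not None:
        if positive_level is None:
            raise OxynetError("clinical grouping needs positive_level")
        vals = clinical.loc[sample_ids]
        labels = pd.Series(np.where(vals == positive_level, "group", "reference"),
                           index=sample_ids, name=label)
        labels[vals.isna().to_numpy()] = np.nan
        spec_name = f"{clinical.name}={positive_level}"
    else:
        raise OxynetError("provide either a variant table or a clinical column")
    counts = labels.value_counts()
    for side in ("group", "reference"):
        if counts.get(side, 0) == 0:
            raise OxynetError(f"grouping {spec_name!r}: empty {side} group")
    n_g, n_r = counts["group"], counts["reference"]
    logger.info("grouping %s: %d vs %d reference", spec_name, n_g, n_r)
    if min(n_g, n_r) < 5:
        logger.warning("grouping %s: smallest group has %d samples; "
                       "results will be unstable", spec_name, min(n_g, n_r))
    return labels


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference column."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    o, r = obs[mask], ref[mask]
    p_o, p_r = o / lib_obs, r / lib_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix,
                reference_column: Optional[str] = None) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is, by default, the one whose 75th count percentile
    (as a fraction of library size) is closest to the mean across samples.
    """
    X = counts.values.to_numpy(float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(lib == 0)]
        raise OxynetError(f"all-zero count columns: {bad}")
    if reference_column is None:
        uq = np.array([np.percentile(X[:, j], 75) / lib[j] for j in range(X.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.sample_ids.index(reference_column)
    ref = X[:, ref_j]
    factors = np.array([
        _tmm_pair(X[:, j], ref, lib[j], lib[ref_j]) for j in range(X.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _normalized_counts(counts: ExpressionMatrix,
                       factors: Optional[pd.Series] = None) -> np.ndarray:
    """Counts rescaled to a common effective library size."""
    X = counts.values.to_numpy(float)
    lib = X.sum(axis=0)
    f = factors.loc[counts.sample_ids].to_numpy() if factors is not None else 1.0
    eff = lib * f
    target = np.exp(np.mean(np.log(eff)))
    return X * (target / eff)[None, :]


def estimate_common_dispersion(counts: ExpressionMatrix, groups: pd.Series,
                               factors: Optional[pd.Series] = None) -> float:
    """Pooled method-of-moments NB dispersion on normalized counts, floored at 0.

    Per gene and group, var = mu + phi * mu^2 gives phi = (s^2 - mu) / mu^2;
    estimates are pooled across genes and groups with weights mu^2.
    """
    labels = groups.loc[counts.sample_ids]
    levels = pd.unique(labels.dropna())
    Y = _normalized_counts(counts, factors)
    num = den = 0.0
    for lv in levels:
        cols = np.flatnonzero((labels == lv).to_numpy())
        if len(cols) < 2:
            raise OxynetError(f"group {lv!r} has a single sample; cannot estimate dispersion")
        sub = Y[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num += np.sum(s2[ok] - mu[ok])
        den += np.sum(mu[ok] ** 2)
    if den == 0:
        return 0.0
    return float(max(0.0, num / den))


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

def _exact_conditional_p(s1: int, total: int, n1: int, n2: int, phi: float,
                         mu: float, window_sds: float = 20.0) -> float:
    """Two-sided exact p for group-sum s1 given the total.

    Under H0 both groups share per-sample mean ``mu``; group sums are
    NB(n_k * mu, phi / n_k) (Poisson when phi = 0). The two-sided p sums the
    conditional probabilities of all outcomes no more likely than the one
    observed (the minimum-likelihood rule). For large totals the support is
    restricted to a +-``window_sds``-SD window around the conditional mean
    (always including the observed value); the excluded tail mass is far
    below double precision.
    """
    frac = n1 / (n1 + n2)
    if total > 2000:
        sd = math.sqrt(total * frac * (1 - frac) * (1 + phi * mu))
        lo = int(min(max(0, total * frac - window_sds * sd), max(0, s1 - 5 * sd)))
        hi = int(max(min(total, total * frac + window_sds * sd), min(total, s1 + 5 * sd)))
        t = np.arange(lo, hi + 1)
    else:
        t = np.arange(total + 1)
    if phi <= 0:
        # Poisson sums -> conditional is Binomial(total, n1/(n1+n2))
        logp = stats.binom.logpmf(t, total, frac)
    else:
        size1, size2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        logp = (stats.nbinom.logpmf(t, size1, size1 / (size1 + m1))
                + stats.nbinom.logpmf(total - t, size2, size2 / (size2 + m2)))
    logp = logp - logsumexp(logp)
    obs = logp[int(s1) - t[0]]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def exact_nb_test(counts: ExpressionMatrix, groups: pd.Series, phi: float,
                  factors: Optional[pd.Series] = None,
                  max_exact_total: int = 200_000) -> pd.DataFrame:
    """Per-gene two-sided exact conditional NB test between two groups.

    Counts are rescaled to a common effective library size, summed per
    group, and rounded; the observed group sum is tested against its
    conditional distribution given the total. Beyond ``max_exact_total`` a
    normal approximation to the conditional distribution is used. Fold
    changes are log2 of normalized group means with a 0.5 pseudocount,
    group over reference. q-values are BH across all genes.
    """
    labels = groups.loc[counts.sample_ids]
    levels = list(pd.unique(labels.dropna()))
    if set(levels) == {"group", "reference"}:
        levels = ["group", "reference"]
    if len(levels) != 2:
        raise OxynetError(f"exact test needs exactly 2 groups, got {levels}")
    if phi < 0:
        raise OxynetError("dispersion must be >= 0")
    g1 = np.flatnonzero((labels == levels[0]).to_numpy())
    g2 = np.flatnonzero((labels == levels[1]).to_numpy())
    n1, n2 = len(g1), len(g2)
    Y = _normalized_counts(counts, factors)
    s1 = np.rint(Y[:, g1].sum(axis=1)).astype(int)
    s2 = np.rint(Y[:, g2].sum(axis=1)).astype(int)
    total = s1 + s2
    mu0 = total / (n1 + n2)

    pvals = np.ones(len(total))
    for i in range(len(total)):
        if total[i] == 0:
            continue
        if total[i] <= max_exact_total:
            pvals[i] = _exact_conditional_p(int(s1[i]), int(total[i]), n1, n2,
                                            phi, float(mu0[i]))
        else:
            # normal approximation to the conditional distribution; the
            # (1 + phi*mu) term inflates the binomial variance for
            # overdispersed counts and vanishes at phi = 0
            frac = n1 / (n1 + n2)
            mean = total[i] * frac
            var = total[i] * frac * (1 - frac) * (1 + phi * mu0[i])
            z = (s1[i] - mean) / np.sqrt(max(var, 1e-12))
            pvals[i] = float(2 * stats.norm.sf(abs(z)))

    m1 = s1 / n1
    m2 = s2 / n2
    lfc = np.log2((m1 + 0.5) / (m2 + 0.5))
    out = pd.DataFrame({
        "gene": counts.feature_ids,
        "log2FC": lfc,
        "p": np.clip(pvals, 0, 1),
        "mean_expression": (s1 + s2) / (n1 + n2),
    })
    out["q"] = bh_adjust(out["p"].to_numpy(), family="exact_nb_test")
    return out[["gene", "log2FC", "p", "q", "mean_expression"]]


def volcano_table(results: pd.DataFrame, lfc_thresh: float = 2.0,
                  q_thresh: float = 0.05) -> pd.DataFrame:
    """Flag significant (q < q_thresh), high-FC (|log2FC| >= lfc_thresh), both."""
    if "q" not in results.columns:
        raise OxynetError("volcano_table requires adjusted q-values")
    out = results.copy()
    out["significant"] = out["q"] < q_thresh
    out["high_fc"] = out["log2FC"].abs() >= lfc_thresh
    out["hit"] = out["significant"] & out["high_fc"]
    return out
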