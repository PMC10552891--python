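"""Spearman correlation networks within and across omics layers.

All pairwise tests of one invocation form a single Benjamini-Hochberg
family, mirroring per-analysis FDR reporting. Edges are filtered on the
adjusted q-value and, for within-layer co-expression networks, on a strong
correlation threshold (|r| >= 0.8 by convention, inclusive).
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EDGE_COLUMNS, ExpressionMatrix, Network, OxynetError

logger = logging.getLogger("oxynet.corrnet")

VALIDATION_CLASSES = (
    "confirmed_both", "confirmed_one", "not_found", "disputed_one", "disputed_both",
)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 df; |r|=1 gives p=0."""
    r = np.asarray(r, float)
    p = np.ones_like(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    finite = np.isfinite(t)
    p[finite] = 2 * stats.t.sf(np.abs(t[finite]), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return np.clip(p, 0.0, 1.0)


def spearman(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    r is the Pearson correlation of average-ranked values (tie-aware).
    If ``exact_max_n`` >= n, the p-value is computed by exhaustive
    permutation instead (only sensible for n <= 9).

    A constant input has no defined rank correlation; an error is raised so
    the pair can be excluded from the test family rather than reported as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise OxynetError("spearman: length mismatch")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise OxynetError(f"spearman needs >=4 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise OxynetError("spearman undefined for a constant vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if exact_max_n >= n:
        from itertools import permutations
        obs = abs(r)
        count = total = 0
        for perm in permutations(ry):
            rp = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(rp) >= obs - 1e-12
            total += 1
        return r, count / total
    return r, float(_spearman_p_from_r(np.array([r]), n)[0])


def _rank_zscore(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, standardized; constant rows become NaN."""
    R = np.apply_along_axis(stats.rankdata, 1, X)
    R = R - R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = R / sd
    Z[np.repeat(sd == 0, X.shape[1], axis=1)] = np.nan
    return Z


def correlate_layers(a: ExpressionMatrix, b: Optional[ExpressionMatrix] = None,
                     family: str = "correlation") -> pd.DataFrame:
    """All pairwise Spearman correlations, within one layer or across two.

    Samples are joined by intersection (pairwise-complete by construction).
    With ``b`` omitted, all unordered within-layer pairs of ``a`` are tested;
    otherwise all cross-layer pairs. Constant features are excluded from the
    family with a warning. One BH family per invocation.
    """
    if b is None:
        shared = a.sample_ids
    else:
        shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    n = len(shared)
    if n < 4:
        raise OxynetError(f"correlate_layers: only {n} shared samples (need >=4)")

    Za = _rank_zscore(a.subset_samples(shared).values.to_numpy(float))
    ok_a = ~np.isnan(Za[:, 0])
    if b is None:
        C = np.einsum("ik,jk->ij", np.nan_to_num(Za), np.nan_to_num(Za)) / n
        iu, ju = np.triu_indices(a.n_features, k=1)
        rows = {
            "feature_a": np.asarray(a.feature_ids)[iu],
            "layer_a": a.layer,
            "feature_b": np.asarray(a.feature_ids)[ju],
            "layer_b": a.layer,
            "r": C[iu, ju],
            "valid": ok_a[iu] & ok_a[ju],
        }
    else:
        Zb = _rank_zscore(b.subset_samples(shared).values.to_numpy(float))
        ok_b = ~np.isnan(Zb[:, 0])
        C = np.einsum("ik,jk->ij", np.nan_to_num(Za), np.nan_to_num(Zb)) / n
        ii, jj = np.meshgrid(np.arange(a.n_features), np.arange(b.n_features),
                             indexing="ij")
        rows = {
            "feature_a": np.asarray(a.feature_ids)[ii.ravel()],
            "layer_a": a.layer,
            "feature_b": np.asarray(b.feature_ids)[jj.ravel()],
            "layer_b": b.layer,
            "r": C.ravel(),
            "valid": (ok_a[ii] & ok_b[jj]).ravel(),
        }
    df = pd.DataFrame(rows)
    n_const = int((~df["valid"]).sum())
    if n_const:
        logger.warning("family %s: excluding %d pairs with a constant feature",
                       family, n_const)
    df = df[df["valid"]].drop(columns="valid").reset_index(drop=True)
    df["r"] = np.clip(df["r"], -1.0, 1.0)
    df["p"] = _spearman_p_from_r(df["r"].to_numpy(), n)
    df["q"] = bh_adjust(df["p"].to_numpy(), family=family)
    df["n_pairs"] = n
    logger.info("family %s: %d pairs tested across %d samples", family, len(df), n)
    return df


def bh_adjust(p: Sequence[float], family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise OxynetError(f"BH family {family!r}: p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def build_network(results: pd.DataFrame, q_max: float = 0.05,
                  r_min: Optional[float] = None) -> Network:
    """Keep edges with q < q_max and (when set) |r| >= r_min (inclusive)."""
    if "q" not in results.columns:
        raise OxynetError("build_network requires adjusted q-values")
    keep = results["q"] < q_max
    if r_min is not None:
        keep &= results["r"].abs() >= r_min
    edges = results.loc[keep].copy()
    edges["validation_class"] = ""
    edges["predicted_dbs"] = ""
    edges["validated_dbs"] = ""
    net = Network(edges=edges)
    logger.info("network: %d / %d edges kept (q<%g%s)", net.n_edges, len(results),
                q_max, f", |r|>={r_min}" if r_min is not None else "")
    return net


def connected_components(network: Network) -> list[list[str]]:
    """Connected node groups, largest first; ties broken by smallest member."""
    g = nx.Graph()
    for _, row in network.edges.iterrows():
        g.add_edge(row["feature_a"], row["feature_b"])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# ---------------------------------------------------------------------------
# cross-cohort validation
# ---------------------------------------------------------------------------

def _cohort_status(discovery_r: float, val: Optional[tuple[float, float]],
                   q_max: float) -> str:
    """Status of a discovery edge in one validation cohort."""
    if val is None:
        return "absent"
    r, q = val
    if not np.isfinite(r) or not np.isfinite(q) or q >= q_max:
        return "absent"
    return "agree" if np.sign(r) == np.sign(discovery_r) else "dispute"


def classify_edge_validation(discovery_r: float,
                             val1: Optional[tuple[float, float]],
                             val2: Optional[tuple[float, float]],
                             q_max: float = 0.05) -> str:
    """Five-way replication class of a discovery edge in two validation cohorts.

    Per cohort the edge either agrees (significant, same sign), disputes
    (significant, opposite sign) or is absent (not significant / not
    tested). (agree, agree) -> confirmed_both; (agree, absent) ->
    confirmed_one; (absent, absent) -> not_found; (dispute, absent) ->
    disputed_one; (dispute, dispute) -> disputed_both. The mixed
    (agree, dispute) case maps to disputed_one with a logged conflict.
    """
    s1 = _cohort_status(discovery_r, val1, q_max)
    s2 = _cohort_status(discovery_r, val2, q_max)
    statuses = {s1, s2}
    if statuses == {"agree"}:
        return "confirmed_both"
    if statuses == {"agree", "absent"}:
        return "confirmed_one"
    if statuses == {"absent"}:
        return "not_found"
    if statuses == {"dispute", "absent"}:
        return "disputed_one"
    if statuses == {"dispute"}:
        return "disputed_both"
    # agree in one cohort, dispute in the other
    logger.warning("edge agrees in one validation cohort but disputes in the "
                   "other; classified disputed_one")
    return "disputed_one"


def validate_network(network: Network, val1: pd.DataFrame, val2: pd.DataFrame,
                     q_max: float = 0.05) -> Network:
    """Attach a validation class to every edge of a discovery network.

    ``val1``/``val2`` are correlation result tables (from
    :func:`correlate_layers`) for the two validation cohorts; edges missing
    from a table count as absent in that cohort.
    """
    def lookup(table: pd.DataFrame) -> dict:
        d = {}
        for row in table.itertuples(index=False):
            key = frozenset((row.feature_a, row.feature_b))
            d[key] = (row.r, row.q)
        return d

    lut1, lut2 = lookup(val1), lookup(val2)
    classes = []
    for row in network.edges.itertuples(index=False):
        key = frozenset((row.feature_a, row.feature_b))
        classes.append(classify_edge_validation(row.r, lut1.get(key), lut2.get(key),
                                                q_max=q_max))
    edges = network.edges.copy()
    edges["validation_class"] = classes
    counts = pd.Series(classes).value_counts()
    logger.info("validation classes: %s", counts.to_dict())
    return Network(edges=edges)


# ---------------------------------------------------------------------------
# subgroup differential correlation
# ---------------------------------------------------------------------------

def subgroup_delta_correlations(a: ExpressionMatrix, b: Optional[ExpressionMatrix],
                                groups: pd.Series, min_n: int = 10) -> pd.DataFrame:
    """Per-pair correlations within each of two subgroups, ranked by |delta r|.

    ``groups`` maps sample id to subgroup label (exactly two labels used).
    Each subgroup gets its own BH family. Subgroups below ``min_n`` are
    skipped with a warning; the result then carries NaN for that subgroup.
    """
    labels = [lv for lv in pd.unique(groups.dropna())]
    if len(labels) != 2:
        raise OxynetError(f"expected 2 subgroup labels, got {labels}")
    per_group = {}
    sizes = {}
    for lv in labels:
        ids = [s for s in groups.index[groups == lv] if s in set(a.sample_ids)]
        if b is not None:
            ids = [s for s in ids if s in set(b.sample_ids)]
        sizes[lv] = len(ids)
        if len(ids) < min_n:
            logger.warning("subgroup %r has %d samples (< %d); skipped",
                           lv, len(ids), min_n)
            per_group[lv] = None
            continue
        sub_a = a.subset_samples(ids)
        sub_b = b.subset_samples(ids) if b is not None else None
        per_group[lv] = correlate_layers(sub_a, sub_b, family=f"subgroup:{lv}")

    g1, g2 = labels
    base_cols = ["feature_a", "layer_a", "feature_b", "layer_b"]
    tables = [t for t in per_group.values() if t is not None]
    if not tables:
        raise OxynetError("both subgroups below min_n; nothing to compare")
    out = pd.concat([t[base_cols] for t in tables]).drop_duplicates().reset_index(drop=True)
    for lv, suffix in ((g1, "group1"), (g2, "group2")):
        t = per_group[lv]
        if t is None:
            out[f"r_{suffix}"] = np.nan
            out[f"q_{suffix}"] = np.nan
        else:
            sub = t[base_cols + ["r", "q"]].rename(
                columns={"r": f"r_{suffix}", "q": f"q_{suffix}"})
            out = out.merge(sub, on=base_cols, how="left")
    out["n_group1"] = sizes[g1]
    out["n_group2"] = sizes[g2]
    out["delta_r"] = out["r_group2"] - out["r_group1"]
    out = out.sort_values("delta_r", key=lambda s: s.abs(), ascending=False,
                          kind="mergesort").reset_index(drop=True)
    return out
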