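"""Concordance of network edges with miRNA-target interaction databases.

Predicted databases are first restricted to their strongest interactions
(top 20% by score, by default); validated databases are unscored row sets
and pass through unchanged. Cross-layer edges are then annotated with the
names of every supporting database.
"""
from __future__ import annotations

import logging
import math

import pandas as pd

from .containers import InteractionDB, Network, OxynetError

logger = logging.getLogger("oxynet.dbconcord")


def top_fraction_filter(db: InteractionDB, fraction: float = 0.2) -> InteractionDB:
    """Retain the ceil(fraction * n) highest-scoring rows of a predicted db.

    Ties at the cutoff are all retained (the result may exceed the nominal
    count; this is logged). Validated databases pass through with a warning.
    """
    if not 0 < fraction <= 1:
        raise OxynetError(f"fraction must be in (0, 1], got {fraction}")
    if db.kind == "validated":
        logger.warning("top_fraction_filter: db %r is validated (unscored); pass-through",
                       db.name)
        return db
    n = len(db.table)
    if n == 0 or fraction == 1.0:
        return db
    k = math.ceil(fraction * n)
    scores = db.table["score"].to_numpy()
    cutoff = sorted(scores, reverse=True)[k - 1]
    kept = db.table[db.table["score"] >= cutoff].reset_index(drop=True)
    if len(kept) > k:
        logger.info("db %s: %d rows retained (ties at score %g exceed nominal %d)",
                    db.name, len(kept), cutoff, k)
    return InteractionDB(name=db.name, kind=db.kind, table=kept)


def _normalize_id(s: str) -> str:
    return str(s).strip().casefold()


def annotate_edges(network: Network, dbs: list[InteractionDB],
                   mapping: dict[str, str] | None = None) -> tuple[Network, pd.DataFrame]:
    """Annotate cross-layer edges with supporting database names.

    Matching is exact string comparison after case-folding, with an optional
    identifier mapping applied first (e.g. a miRBase version map). Returns
    the annotated network and a one-row summary with counts and percentages
    of edges having predicted / validated / any support. Idempotent; edges
    and correlation values are unchanged.
    """
    mapping = {(_normalize_id(k)): _normalize_id(v) for k, v in (mapping or {}).items()}

    def canon(x: str) -> str:
        nx_ = _normalize_id(x)
        return mapping.get(nx_, nx_)

    support: dict[str, set[tuple[str, str]]] = {}
    kinds: dict[str, str] = {}
    for db in dbs:
        kinds[db.name] = db.kind
        pairs = {(canon(g), canon(m))
                 for g, m in zip(db.table["gene_symbol"], db.table["mirna_id"])}
        support[db.name] = pairs

    edges = network.edges.copy()
    pred_lists, val_lists = [], []
    for row in edges.itertuples(index=False):
        if row.layer_a == row.layer_b:
            pred_lists.append("")
            val_lists.append("")
            continue
        if row.layer_a == "mRNA":
            gene, mirna = canon(row.feature_a), canon(row.feature_b)
        else:
            gene, mirna = canon(row.feature_b), canon(row.feature_a)
        hits_p = sorted(n for n, pairs in support.items()
                        if kinds[n] == "predicted" and (gene, mirna) in pairs)
        hits_v = sorted(n for n, pairs in support.items()
                        if kinds[n] == "validated" and (gene, mirna) in pairs)
        pred_lists.append(",".join(hits_p))
        val_lists.append(",".join(hits_v))
    edges["predicted_dbs"] = pred_lists
    edges["validated_dbs"] = val_lists

    cross = edges["layer_a"] != edges["layer_b"]
    n_cross = int(cross.sum())
    has_p = (edges.loc[cross, "predicted_dbs"] != "").sum()
    has_v = (edges.loc[cross, "validated_dbs"] != "").sum()
    has_any = ((edges.loc[cross, "predicted_dbs"] != "")
               | (edges.loc[cross, "validated_dbs"] != "")).sum()
    summary = pd.DataFrame([{
        "n_cross_edges": n_cross,
        "n_predicted_support": int(has_p),
        "n_validated_support": int(has_v),
        "n_any_support": int(has_any),
        "pct_predicted": 100.0 * has_p / n_cross if n_cross else 0.0,
        "pct_validated": 100.0 * has_v / n_cross if n_cross else 0.0,
        "pct_any": 100.0 * has_any / n_cross if n_cross else 0.0,
    }])
    logger.info("db support: %d/%d edges predicted (%.1f%%), %d validated (%.1f%%)",
                has_p, n_cross, summary["pct_predicted"][0],
                has_v, summary["pct_validated"][0])
    return Network(edges=edges), summary
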