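"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are strict TSV: UTF-8, tab separated, '.' decimal, no
quoting. Floats are written with 15 significant digits so reader/writer
pairs round-trip losslessly at that precision. Parse errors name the file,
line and offending token.
"""
from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    EDGE_COLUMNS,
    ExpressionMatrix,
    GeneSet,
    InteractionDB,
    Network,
    OxynetError,
    validate_clinical,
    validate_variants,
)

FLOAT_FMT = "%.15g"

logger = logging.getLogger("oxynet")


def setup_logging(level: str = "INFO") -> None:
    """Timestamped, leveled logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s", "%Y-%m-%dT%H:%M:%S"))
    root = logging.getLogger("oxynet")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, layer: str, scale: str,
                    missing_policy: str = "error") -> ExpressionMatrix:
    """Read a feature x sample expression TSV.

    First column holds feature ids; the header row holds sample ids.
    ``missing_policy`` decides what to do with non-numeric/NA cells:
    ``error`` (default), ``drop-feature`` or ``drop-sample``.
    """
    path = Path(path)
    if missing_policy not in ("error", "drop-feature", "drop-sample"):
        raise OxynetError(f"unknown missing policy {missing_policy!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise OxynetError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})")
            ids.append(parts[0])
            rows.append(parts[1:])
    sample_ids = header[1:]
    seen: set[str] = set()
    for fid in ids:
        if fid in seen:
            raise OxynetError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
    raw = pd.DataFrame(rows, index=ids, columns=sample_ids)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        if missing_policy == "error":
            r, c = np.argwhere(bad.to_numpy())[0]
            raise OxynetError(
                f"{path}: non-numeric cell {raw.iat[r, c]!r} at feature "
                f"{values.index[r]!r}, sample {values.columns[c]!r}")
        if missing_policy == "drop-feature":
            dropped = values.index[bad.any(axis=1)].tolist()
            logger.warning("%s: dropping %d features with missing values: %s",
                           path, len(dropped), ", ".join(dropped[:5]))
            values = values.loc[~bad.any(axis=1)]
        else:
            dropped = values.columns[bad.any(axis=0)].tolist()
            logger.warning("%s: dropping %d samples with missing values: %s",
                           path, len(dropped), ", ".join(dropped[:5]))
            values = values.loc[:, ~bad.any(axis=0)]
    m = ExpressionMatrix(values, layer=layer, scale=scale)
    logger.info("read %s: %d features x %d samples (%s, %s)",
                path, m.n_features, m.n_samples, layer, scale)
    return m


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.insert(0, "feature_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_detection(path: str | Path) -> pd.DataFrame:
    """Read a boolean detection-flag matrix (0/1 TSV, same layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_detection(detection: pd.DataFrame, path: str | Path) -> None:
    out = detection.astype(int).copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical / variants / gene sets
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_clinical(table)


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_variants(path: str | Path, panel: Optional[Iterable[str]] = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_variants(table, panel=panel, logger=logger)


def write_variants(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then >= 1 member, tab separated."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OxynetError(
                    f"{path}:{lineno}: GMT line needs >=3 columns, got {len(parts)}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise OxynetError(f"{path}:{lineno}: gene set {parts[0]!r} has no members")
            sets.append(GeneSet(name=parts[0], description=parts[1], members=tuple(members)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network: Network, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Write a network as edge-TSV (full annotation) or SIF (pos/neg relations)."""
    path = Path(path)
    if fmt == "edge-tsv":
        network.edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in network.edges.iterrows():
                rel = "pos" if row["r"] >= 0 else "neg"
                fh.write(f"{row['feature_a']} {rel} {row['feature_b']}\n")
    else:
        raise OxynetError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> Network:
    edges = pd.read_csv(path, sep="\t", dtype={c: str for c in
                        ("feature_a", "layer_a", "feature_b", "layer_b",
                         "validation_class", "predicted_dbs", "validated_dbs")})
    for col in ("validation_class", "predicted_dbs", "validated_dbs"):
        if col in edges.columns:
            edges[col] = edges[col].fillna("")
    return Network(edges=edges)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# interaction databases
# ---------------------------------------------------------------------------

def read_interaction_db(path: str | Path, name: str, kind: str,
                        score_col: str = "score", ascending: bool = False) -> InteractionDB:
    """Read a predicted or validated interaction table.

    ``ascending=True`` flips score direction (some databases score low=strong);
    scores are negated internally so that higher always means stronger.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {"gene_symbol", "mirna_id"}
    if not cols.issubset(df.columns):
        raise OxynetError(f"{path}: interaction db missing columns {cols - set(df.columns)}")
    table = df[["gene_symbol", "mirna_id"]].copy()
    if kind == "predicted":
        if score_col not in df.columns:
            raise OxynetError(f"{path}: predicted db lacks score column {score_col!r}")
        score = pd.to_numeric(df[score_col])
        table["score"] = -score if ascending else score
    return InteractionDB(name=name, kind=kind, table=table)


def write_interaction_db(db: InteractionDB, path: str | Path) -> None:
    db.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# ground truth (simulator output)
# ---------------------------------------------------------------------------

def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
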