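"""Core in-memory containers shared across the pipeline.

Expression data travel as feature x sample matrices with an explicit layer
(mRNA or miRNA) and scale (counts, TPM or log2) tag, so each stage can refuse
inputs on the wrong scale instead of silently mis-normalizing. Clinical and
variant tables are plain pandas DataFrames validated on read.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "miRNA")
SCALES = ("counts", "TPM", "log2")

#: Columns of an edge table (the on-disk edge-TSV mirrors this order).
EDGE_COLUMNS = [
    "feature_a", "layer_a", "feature_b", "layer_b",
    "r", "p", "q", "n_pairs", "validation_class",
    "predicted_dbs", "validated_dbs",
]

CLINICAL_COLUMNS = [
    "sample_id", "pT", "pN", "stage", "subtype", "PR", "ER", "ERBB2",
    "Ki67", "menopause", "batch",
    "OS_time", "OS_event", "DFS_time", "DFS_event",
]


class OxynetError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    layer
        ``"mRNA"`` or ``"miRNA"``.
    scale
        ``"counts"``, ``"TPM"`` or ``"log2"``.
    detection
        Optional boolean DataFrame of identical shape marking whether a
        feature was detected (above the platform noise floor) in a sample.
    """

    values: pd.DataFrame
    layer: str
    scale: str
    detection: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise OxynetError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.scale not in SCALES:
            raise OxynetError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise OxynetError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise OxynetError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise OxynetError(f"{n_bad} non-finite values in {self.layer} matrix")
        if self.scale == "counts" and arr.size and (arr < 0).any():
            raise OxynetError("counts matrix contains negative values")
        if self.detection is not None and self.detection.shape != self.values.shape:
            raise OxynetError(
                f"detection shape {self.detection.shape} != values shape {self.values.shape}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        det = self.detection.loc[:, ids] if self.detection is not None else None
        return ExpressionMatrix(self.values.loc[:, ids], self.layer, self.scale, det)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        det = self.detection.loc[ids] if self.detection is not None else None
        return ExpressionMatrix(self.values.loc[ids], self.layer, self.scale, det)

    def with_values(self, values: pd.DataFrame, scale: Optional[str] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.layer, scale or self.scale, self.detection)


@dataclass
class GeneSet:
    """A named, nonempty set of gene symbols (one GMT line)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise OxynetError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise OxynetError(f"gene set {self.name!r} has duplicate members")
        self.members = tuple(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class InteractionDB:
    """One miRNA-target interaction database.

    Predicted databases carry an interaction score per (gene, miRNA) pair;
    experimentally validated databases are unscored row sets.
    """

    name: str
    kind: str  # "predicted" | "validated"
    table: pd.DataFrame  # columns: gene_symbol, mirna_id[, score]

    def __post_init__(self) -> None:
        if self.kind not in ("predicted", "validated"):
            raise OxynetError(f"db {self.name!r}: kind must be predicted|validated")
        required = {"gene_symbol", "mirna_id"}
        if not required.issubset(self.table.columns):
            raise OxynetError(f"db {self.name!r}: missing columns {required - set(self.table.columns)}")
        if self.kind == "predicted" and "score" not in self.table.columns:
            raise OxynetError(f"predicted db {self.name!r} has no score column")
        pairs = self.table[["gene_symbol", "mirna_id"]]
        if pairs.duplicated().any():
            raise OxynetError(f"db {self.name!r} has duplicate (gene, miRNA) pairs")


@dataclass
class FilterReport:
    """Attrition bookkeeping for one filtering stage."""

    stage: str
    features_before: int
    features_after: int
    samples_before: int
    samples_after: int
    removed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.features_after > self.features_before or self.samples_after > self.samples_before:
            raise OxynetError(f"filter report {self.stage!r}: 'after' exceeds 'before'")
        n_removed = (self.features_before - self.features_after) + (
            self.samples_before - self.samples_after
        )
        if len(self.removed_ids) != n_removed:
            raise OxynetError(
                f"filter report {self.stage!r}: {len(self.removed_ids)} removed ids "
                f"but attrition is {n_removed}"
            )

    def as_row(self) -> dict:
        d = dataclasses.asdict(self)
        d["removed_ids"] = ",".join(self.removed_ids)
        return d


@dataclass
class Network:
    """An undirected correlation network.

    ``edges`` is a DataFrame with :data:`EDGE_COLUMNS`; node identity is
    (feature id, layer). Self-edges and duplicate undirected edges are
    rejected.
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                self.edges[col] = "" if col in ("validation_class", "predicted_dbs", "validated_dbs") else np.nan
        self.edges = self.edges[EDGE_COLUMNS].reset_index(drop=True)
        a = self.edges["feature_a"].astype(str)
        b = self.edges["feature_b"].astype(str)
        if (a == b).any():
            bad = a[a == b].iloc[0]
            raise OxynetError(f"self-edge on {bad!r}")
        key = [tuple(sorted(t)) for t in zip(a, b)]
        if len(key) != len(set(key)):
            raise OxynetError("duplicate undirected edges in network")

    @property
    def nodes(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.edges.iterrows():
            seen.setdefault((row["feature_a"], row["layer_a"]), None)
            seen.setdefault((row["feature_b"], row["layer_b"]), None)
        return list(seen)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: times nonnegative, event flags boolean.

    Unknown values are kept as NA, never dropped.
    """
    missing = [c for c in ("sample_id", "OS_time", "OS_event", "DFS_time", "DFS_event")
               if c not in table.columns]
    if missing:
        raise OxynetError(f"clinical table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        raise OxynetError("clinical table has duplicate sample ids")
    for col in ("OS_time", "DFS_time"):
        t = pd.to_numeric(table[col], errors="coerce")
        if (t.dropna() < 0).any():
            raise OxynetError(f"negative values in {col}")
    for col in ("OS_event", "DFS_event"):
        ev = table[col].dropna()
        if not ev.isin([0, 1, True, False]).all():
            raise OxynetError(f"{col} must be boolean/0-1")
    return table


def validate_variants(table: pd.DataFrame, panel: Optional[Iterable[str]] = None,
                      logger=None) -> pd.DataFrame:
    """Validate a somatic-variant table against an optional gene panel.

    Unknown symbols are reported (logged), not silently dropped.
    """
    required = {"sample_id", "gene_symbol", "variant_class"}
    if not required.issubset(table.columns):
        raise OxynetError(f"variant table missing columns: {required - set(table.columns)}")
    if panel is not None:
        panel_set = set(panel)
        unknown = sorted(set(table["gene_symbol"]) - panel_set)
        if unknown and logger is not None:
            logger.warning("variant table: %d gene symbols outside the panel: %s",
                           len(unknown), ", ".join(unknown[:10]))
    return table
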