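"""Readers and writers for the pipeline's tabular and graph artifacts.

All tables are UTF-8, tab-separated, with a header row and a leading id
column.  Networks go out as edge-list TSV or GraphML (node attributes
preserved).  Run configuration is a flat YAML mapping.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import (
    CountTable,
    RelAbundanceTable,
    SampleMetadata,
    TraitTable,
    ValidationError,
)

logger = logging.getLogger("microkeystone")

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_traits",
    "write_traits",
    "write_network",
    "read_network_graphml",
    "load_config",
    "save_config",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"empty or missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return df


def read_count_table(
    path: str | Path,
    orientation: str = "features_as_rows",
    round_counts: bool = False,
) -> CountTable:
    """Read a tab-separated feature count table.

    Parameters
    ----------
    orientation:
        ``features_as_rows`` (default) or ``samples_as_rows``.
    round_counts:
        If True, numeric non-integer cells are rounded instead of rejected.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "samples_as_rows":
        df = df.T
    if round_counts:
        df = df.astype(float).round()
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path, group_column: str = "group") -> SampleMetadata:
    df = _read_tsv(path)
    if group_column not in df.columns:
        raise ValidationError(
            f"metadata lacks group column {group_column!r}; has {list(df.columns)}"
        )
    meta = SampleMetadata(df[group_column])
    logger.info("metadata: %s", meta.group_sizes())
    return meta


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame({"group": meta.groups}).to_csv(path, sep="\t", index_label="sample_id")


def read_traits(path: str | Path) -> TraitTable:
    return TraitTable(_read_tsv(path))


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, sep="\t", index_label="sample_id")


def write_rel_abundance(rel: RelAbundanceTable, path: str | Path) -> None:
    rel.data.to_csv(path, sep="\t", index_label="feature_id")


_EDGE_COLUMNS = ["source", "target", "rho", "p", "q"]


def write_network(network, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Export a co-occurrence network.

    ``edge_list_tsv`` writes one row per edge (source, target, rho, p, q);
    ``graphml`` writes the full graph with node attributes (centralities,
    module id, abundance class).
    """
    graph = network.graph if hasattr(network, "graph") else network
    if format == "edge_list_tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho", np.nan),
                "p": d.get("p", np.nan),
                "q": d.get("q", np.nan),
            }
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
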