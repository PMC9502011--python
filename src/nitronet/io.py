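"""TSV / GraphML / GEXF readers and writers for every pipeline artifact.

Count and taxonomy tables are TSV with taxa as rows and samples as
columns; lineages may alternatively be given as a single
semicolon-delimited ``lineage`` column (domain;phylum;class;order;
family;genus).  Networks export to GraphML and GEXF (Gephi-compatible)
plus a flat edge-list CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import RANKS


def read_count_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.astype(np.int64, errors="ignore")


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "lineage" in frame.columns:
        ranks = frame["lineage"].str.split(";", expand=True)
        ranks.columns = list(RANKS)[: ranks.shape[1]]
        frame = ranks
    return frame


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t")


read_env_matrix = read_metadata
write_env_matrix = write_metadata
read_agronomic_table = lambda path: pd.read_csv(path, sep="\t")  # noqa: E731


def write_agronomic_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_guild_map(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(frame.columns[0])[frame.columns[1]]


def write_guild_map(guilds: pd.Series, path) -> None:
    guilds.rename("guild").rename_axis("genus").to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(dtype=float), ids=list(frame.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def export_network(graph: nx.Graph, basepath) -> list[Path]:
    """Write GraphML + GEXF + edge-list CSV; returns the written paths."""
    base = Path(basepath)
    paths = [base.with_suffix(".graphml"), base.with_suffix(".gexf"), base.with_suffix(".edges.csv")]
    clean = nx.Graph(**{k: v for k, v in graph.graph.items()})
    for node, attrs in graph.nodes(data=True):
        clean.add_node(node, **{k: v for k, v in attrs.items() if v is not None and v == v})
    for u, v, attrs in graph.edges(data=True):
        clean.add_edge(u, v, **attrs)
    nx.write_graphml(clean, paths[0])
    nx.write_gexf(clean, paths[1])
    edges = pd.DataFrame(
        [(u, v, d["rho"], d["sign"], d["q"]) for u, v, d in graph.edges(data=True)],
        columns=["source", "target", "rho", "sign", "q"],
    )
    edges.to_csv(paths[2], index=False)
    return paths


def write_ground_truth(truth, path) -> None:
    payload = {
        "module_of": truth.module_of.astype(int).to_dict(),
        "differential_taxa": {
            str(day): truth.differential_taxa[day].to_dict()
            for day in truth.differential_taxa.columns
        },
        "env_loadings": {f: truth.env_loadings.loc[f].to_dict() for f in truth.env_loadings.index},
        "guild_of": truth.guild_of.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
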