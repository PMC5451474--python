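"""miRNA-gene interaction network assembly.

Joins predicted miRNA->target pairs with an offline gene-gene interaction
score table (STRING-export dialect: combined scores on either the 0-1000
integer or the 0-1 real scale, auto-detected and normalized to [0, 1]).
The resulting undirected graph carries node types (gene / miRNA), edge
scores for gene-gene edges, and an evidence label (validated / predicted)
per edge; regulatory directionality lives in the node types, not in edge
direction.
"""
from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["normalize_scores", "build_network", "node_stats", "top_hubs",
           "to_sif", "to_graphml", "from_graphml"]

DEFAULT_SCORE_MIN = 0.4  # conventional STRING medium confidence


def normalize_scores(interactions: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a gene-gene score table to [0, 1].

    Expects columns ``node_a``, ``node_b``, ``score`` and optional
    ``evidence``.  Self-pairs are rejected; duplicate unordered pairs must
    agree in score and are collapsed to one row.
    """
    required = {"node_a", "node_b", "score"}
    if not required <= set(interactions.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    df = interactions.copy()
    if len(df) == 0:
        df["evidence"] = df.get("evidence", pd.Series(dtype=str))
        return df
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if df["score"].isna().any() or (df["score"] < 0).any():
        raise ValueError("malformed score rows: scores must be non-negative numbers")
    if (df["node_a"] == df["node_b"]).any():
        bad = df.loc[df["node_a"] == df["node_b"], "node_a"].iloc[0]
        raise ValueError(f"self-pair in interaction table: {bad!r}")
    smax = df["score"].max()
    if smax > 1000:
        raise ValueError("scores exceed the 0-1000 STRING scale")
    if smax > 1:
        df["score"] = df["score"] / 1000.0
    if "evidence" not in df.columns:
        df["evidence"] = "predicted"
    key = df.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    df = df.assign(_key=key)
    for _, grp in df.groupby("_key"):
        if grp["score"].max() - grp["score"].min() > 1e-9:
            a, b = grp["_key"].iloc[0]
            raise ValueError(f"asymmetric scores for pair ({a}, {b})")
    df = df.drop_duplicates("_key").drop(columns="_key").reset_index(drop=True)
    return df


def build_network(
    targets: pd.DataFrame,
    interactions: pd.DataFrame,
    score_min: float = DEFAULT_SCORE_MIN,
    node_universe: set[str] | None = None,
    require_interaction: bool = False,
) -> nx.Graph:
    """Assemble the undirected miRNA-gene network.

    Gene-gene edges come from the score table and must pass ``score_min``;
    miRNA-gene edges come from the target table (evidence ``predicted``).
    With ``require_interaction`` genes must carry at least one passing
    gene-gene edge to be kept (the restriction used to trim a target list
    to its interacting core); by default all targeted genes are retained.
    ``node_universe`` optionally restricts every node.  Isolated nodes are
    dropped.
    """
    inter = normalize_scores(interactions)
    inter = inter[inter["score"] >= score_min]
    if node_universe is not None:
        inter = inter[inter["node_a"].isin(node_universe)
                      & inter["node_b"].isin(node_universe)]

    g = nx.Graph()
    for row in inter.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, score=float(row.score),
                   evidence=str(row.evidence), kind="gene-gene")
        g.nodes[row.node_a]["type"] = "gene"
        g.nodes[row.node_b]["type"] = "gene"

    interacting_genes = {n for n, d in g.nodes(data=True) if d.get("type") == "gene"}
    for row in targets.itertuples(index=False):
        gene, mirna = row.gene_id, row.mirna_id
        if node_universe is not None and (gene not in node_universe
                                          or mirna not in node_universe):
            continue
        if require_interaction and gene not in interacting_genes:
            continue
        g.add_edge(mirna, gene, evidence="predicted", kind="mirna-target")
        g.nodes[mirna]["type"] = "miRNA"
        g.nodes[gene]["type"] = "gene"

    g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0])
    return g


def node_stats(network: nx.Graph) -> pd.DataFrame:
    """Per-node degree table ranked descending (ties broken by node id)."""
    rows = [
        {"node": n, "type": network.nodes[n].get("type", "gene"),
         "degree": network.degree(n)}
        for n in network.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "type", "degree"])
    if len(df):
        df = df.sort_values(["degree", "node"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return df


def top_hubs(network: nx.Graph, k: int = 5) -> pd.DataFrame:
    """The k highest-degree nodes (the network's hubs)."""
    return node_stats(network).head(k)


def to_sif(network: nx.Graph, path: str | Path) -> None:
    """Write a Cytoscape-loadable SIF edge list (relation = edge kind)."""
    lines = []
    for a, b, data in sorted(network.edges(data=True)):
        lines.append(f"{a}\t{data.get('kind', 'interacts')}\t{b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def from_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
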