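"""Readers and writers for the on-disk formats the pipeline consumes.

Count/feature tables and distance matrices are plain delimited text; trees
are Newick (parsed with dendropy); networks are exported as GraphML so they
load directly into Gephi or igraph.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountTable, DistanceMatrix, FormatError, GeneTable

if TYPE_CHECKING:  # pragma: no cover
    from .network import NetworkModel


def read_count_table(path: str | os.PathLike, orientation: str = "taxa_as_rows",
                     sep: str = "\t") -> CountTable:
    """Read a delimited OTU/feature count table.

    Parameters
    ----------
    orientation
        ``"taxa_as_rows"`` (the common OTU-table export, default) or
        ``"samples_as_rows"``.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty count table file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"count table has no data rows/columns: {path}")
    if orientation == "taxa_as_rows":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path: str | os.PathLike,
                      orientation: str = "taxa_as_rows", sep: str = "\t") -> None:
    df = table.counts
    if orientation == "taxa_as_rows":
        df = df.T
        df.index.name = "taxon_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_metadata(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    """Read a sample metadata table (first column = sample id)."""
    meta = pd.read_csv(path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise FormatError(f"duplicate sample id(s) in metadata: {dupes}")
    return meta


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    """Read a rooted Newick tree, rejecting missing branch lengths.

    Null-model analyses turn branch lengths into distances; silently
    defaulting a missing length to zero would corrupt every βMNTD value, so
    an edge without a length is a hard error.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"unparseable Newick file {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(label is None for label in labels):
        raise FormatError("tree has unlabelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate tip label(s): {dupes}")
    if len(labels) < 2:
        raise FormatError("tree has fewer than 2 tips; pairwise distances undefined")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is irrelevant to tip-to-tip paths
        if edge.length is None:
            raise FormatError(
                "tree has edge(s) without branch lengths; lengths are required"
            )
        if edge.length < 0:
            raise FormatError("tree has negative branch length(s)")
    return tree


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distances(tree: dendropy.Tree,
                        taxa: Sequence[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix.

    Parameters
    ----------
    taxa
        Identifiers to include, in the order wanted; defaults to all tips.
    """
    labels = tip_labels(tree)
    if taxa is None:
        taxa = labels
    taxa = [str(t) for t in taxa]
    missing = sorted(set(taxa) - set(labels))
    if missing:
        raise KeyError(f"taxa missing from tree: {missing}")
    # d(i, j) = depth_i + depth_j − 2·depth(MRCA); filling per internal node
    # over its child-subtree tip blocks is O(n²) in vectorised chunks
    col = {label: k for k, label in enumerate(labels)}
    depth: dict = {tree.seed_node: 0.0}
    tips_below: dict = {}
    n_all = len(labels)
    depths = np.zeros(n_all)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    full = np.zeros((n_all, n_all))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = col[node.taxon.label]
            depths[k] = depth[node]
            tips_below[node] = np.array([k])
            continue
        blocks = [tips_below.pop(child) for child in node.child_nodes()]
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                ia, ib = blocks[a], blocks[b]
                d = depths[ia][:, None] + depths[ib][None, :] - 2.0 * depth[node]
                full[np.ix_(ia, ib)] = d
                full[np.ix_(ib, ia)] = d.T
        tips_below[node] = np.concatenate(blocks)
    idx = [col[t] for t in taxa]
    return DistanceMatrix(list(taxa), full[np.ix_(idx, idx)])


def write_distance_matrix(dm: DistanceMatrix, path: str | os.PathLike,
                          sep: str = "\t") -> None:
    df = dm.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def read_distance_matrix(path: str | os.PathLike, signed: bool = False,
                         sep: str = "\t") -> DistanceMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix rows and columns disagree")
    values = df.to_numpy(dtype=float)
    # text round-trips can leave asymmetry at the last printed digit
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(df.index), values, signed=signed)


def read_gene_table(path: str | os.PathLike, sep: str = "\t",
                    length_column: str = "length",
                    totals: pd.Series | None = None) -> GeneTable:
    """Read a gene-count table whose ``length`` column holds gene lengths (bp).

    If ``totals`` is not given, per-sample totals default to the column sums
    (i.e. every mapped read hit a catalogued gene).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if length_column not in df.columns:
        raise FormatError(f"gene table lacks a '{length_column}' column")
    lengths = df[length_column].astype(float)
    counts = df.drop(columns=[length_column])
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    return GeneTable(counts=counts, gene_lengths=lengths, total_mapped=totals)


def network_to_graph(network: "NetworkModel") -> nx.Graph:
    graph = nx.Graph()
    for node in network.nodes:
        graph.add_node(node, degree=int(network.degrees[node]),
                       taxonomy=str(network.taxonomy.get(node, "")))
    for i, j, r in network.edges:
        graph.add_edge(i, j, weight=float(r),
                       sign="positive" if r > 0 else "negative")
    return graph


def write_graphml(network: "NetworkModel", path: str | os.PathLike) -> None:
    """Export a co-occurrence network to GraphML (Gephi-loadable).

    Node attributes: taxon id (node key), ``degree``, ``taxonomy``.
    Edge attributes: ``weight`` (Pearson r) and ``sign``.
    """
    nx.write_graphml(network_to_graph(network), str(path))


def read_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(str(path))
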