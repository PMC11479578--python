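"""Build network edge lists from tabulated SBML data.

Two graph shapes are supported:

* the **bipartite species-reaction graph** — the structure a generic
  SBML import produces, with one node per species and per reaction and
  one edge per species appearance in a reaction;
* the **species-species projection** — a custom digraph with species as
  nodes and one arc from every reactant to every product of each
  reaction (optionally also modifier → product), which preserves the
  directional reading of a pathway.

Compartment handling in the projection follows the two renderings of a
cross-compartment transport reaction: with compartments preserved, a
chemical present in two compartments is two distinct nodes joined by an
edge; with compartments merged it is one node and the transport becomes
a self-loop.  Merging keys on the species' display name (any trailing
bracketed "[compartment]" suffix stripped, a common exporter
convention), falling back to the species id for unnamed species.

Edges carry the owning reaction id as provenance.  Parallel edges from
distinct reactions are kept; deduplication is a writer option.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Edge", "bipartite_edges", "species_projection", "relabel_nodes",
           "edges_to_graph", "write_edgelist", "write_graphml"]

_BIPARTITE_KIND = {
    "Reactant": "reactant_to_reaction",
    "Product": "reaction_to_product",
    "Modifier": "modifier_to_reaction",
}


@dataclass(frozen=True)
class Edge:
    """One directed link of an exported network.

    ``kind`` is one of ``reactant_to_reaction``, ``reaction_to_product``,
    ``modifier_to_reaction`` (bipartite graph) or ``species_to_species``
    (projection); ``reaction_id`` records which reaction produced the
    edge.
    """

    source: str
    target: str
    reaction_id: str
    kind: str


def _require_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(
            f"species-in-reactions table lacks required column(s) {missing}; "
            f"have {list(table.columns)}"
        )


def bipartite_edges(species_in_reactions: pd.DataFrame) -> list[Edge]:
    """One edge per species-in-reaction row, directed by role.

    Reactants and modifiers point into the reaction node; products point
    out of it.  An empty table (a model without reactions) yields no
    edges.
    """
    if species_in_reactions.empty and species_in_reactions.columns.empty:
        return []
    _require_columns(species_in_reactions, ("species", "reaction_id", "role"))
    edges: list[Edge] = []
    for row in species_in_reactions.itertuples(index=False):
        species, reaction, role = row.species, row.reaction_id, row.role
        kind = _BIPARTITE_KIND.get(role)
        if kind is None:
            raise ValueError(f"unknown role literal {role!r}")
        if role == "Product":
            edges.append(Edge(reaction, species, reaction, kind))
        else:
            edges.append(Edge(species, reaction, reaction, kind))
    return edges


def _merge_key(name: object, species_id: str) -> str:
    if name is None or pd.isna(name) or not str(name):
        return species_id
    name = str(name).strip()
    if name.endswith("]") and "[" in name:
        name = name[: name.rindex("[")].strip()
    return name or species_id


def species_projection(
    species_in_reactions: pd.DataFrame,
    species_table: pd.DataFrame | None = None,
    merge_compartments: bool = False,
    include_modifiers: bool = False,
) -> list[Edge]:
    """Species-as-nodes digraph: reactant → product arcs per reaction.

    For each reaction, emits one edge from every reactant to every
    product (and from every modifier to every product when
    ``include_modifiers``).  Nodes are species ids; since an SBML
    species element lives in exactly one compartment, distinct ids keep
    compartment information intact.  With ``merge_compartments``,
    species sharing a display name are collapsed onto one node (the
    first member's id), which turns a cross-compartment transport into
    a self-loop; this requires ``species_table`` with ``id`` and
    ``name`` columns.  Self-loops are emitted whenever source equals
    target.  An empty table yields no edges.
    """
    if species_in_reactions.empty and species_in_reactions.columns.empty:
        return []
    _require_columns(species_in_reactions, ("species", "reaction_id", "role"))
    canonical: dict[str, str] = {}
    if merge_compartments:
        if species_table is None:
            raise ValueError(
                "merge_compartments=True requires species_table to resolve "
                "species identity across compartments"
            )
        _require_columns(species_table, ("id",))
        names = (
            species_table["name"]
            if "name" in species_table.columns
            else [None] * len(species_table)
        )
        first_by_key: dict[str, str] = {}
        for species_id, name in zip(species_table["id"], names):
            key = _merge_key(name, str(species_id))
            canonical[str(species_id)] = first_by_key.setdefault(key, str(species_id))

    def node(species_id: str) -> str:
        return canonical.get(species_id, species_id)

    edges: list[Edge] = []
    by_reaction: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for row in species_in_reactions.itertuples(index=False):
        rid = row.reaction_id
        if rid not in by_reaction:
            by_reaction[rid] = {"Reactant": [], "Product": [], "Modifier": []}
            order.append(rid)
        by_reaction[rid][row.role].append(row.species)
    for rid in order:
        roles = by_reaction[rid]
        sources = roles["Reactant"] + (roles["Modifier"] if include_modifiers else [])
        for source in sources:
            for product in roles["Product"]:
                edges.append(
                    Edge(node(source), node(product), rid, "species_to_species")
                )
    return edges


def relabel_nodes(
    edges: Sequence[Edge], species_table: pd.DataFrame, label_column: str
) -> list[Edge]:
    """Replace species-id node labels by a species-table column value.

    Typical label columns are ``name`` (display names) or
    ``annotation_is`` (space-joined MIRIAM ids).  Species without a
    value in the column keep their id, with a warning; node labels not
    found in the table (e.g. reaction nodes of a bipartite graph) are
    left unchanged.  Relabeling never drops edges.
    """
    _require_columns(species_table, ("id",))
    if label_column not in species_table.columns:
        raise ValueError(
            f"unknown label column {label_column!r}; "
            f"species table has {list(species_table.columns)}"
        )
    labels: dict[str, str] = {}
    unlabeled: list[str] = []
    for species_id, value in zip(species_table["id"], species_table[label_column]):
        if value is None or pd.isna(value) or value == "":
            unlabeled.append(str(species_id))
        else:
            labels[str(species_id)] = str(value)
    if unlabeled:
        logger.warning(
            "%d species lack a %r value; their nodes keep the species id",
            len(unlabeled),
            label_column,
        )
    return [
        replace(
            edge,
            source=labels.get(edge.source, edge.source),
            target=labels.get(edge.target, edge.target),
        )
        for edge in edges
    ]


def edges_to_graph(edges: Sequence[Edge]) -> nx.MultiDiGraph:
    """Edge list → networkx multidigraph with provenance attributes."""
    graph = nx.MultiDiGraph()
    for edge in edges:
        graph.add_edge(
            edge.source, edge.target, reaction_id=edge.reaction_id, kind=edge.kind
        )
    return graph


def write_edgelist(
    edges: Sequence[Edge],
    path: Union[str, Path],
    fmt: str = "csv",
    deduplicate: bool = False,
) -> Path:
    """Write edges as a two-column (+ provenance) delimited table.

    With ``deduplicate``, parallel edges collapse to the first
    occurrence (provenance of the first reaction kept).
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    if deduplicate:
        kept: dict[tuple[str, str], Edge] = {}
        for edge in edges:
            kept.setdefault((edge.source, edge.target), edge)
        edges = list(kept.values())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="," if fmt == "csv" else "\t")
        writer.writerow(["source", "target", "reaction_id", "kind"])
        for edge in edges:
            writer.writerow([edge.source, edge.target, edge.reaction_id, edge.kind])
    return path


def write_graphml(edges: Sequence[Edge], path: Union[str, Path]) -> Path:
    """Write edges as GraphML with node labels and edge attributes."""
    graph = edges_to_graph(edges)
    for node in graph.nodes:
        graph.nodes[node]["label"] = str(node)
    path = Path(path)
    nx.write_graphml(graph, str(path))
    return path
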