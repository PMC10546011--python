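"""Word-trajectory graph construction and connectedness attributes.

The graph model: each unique word type is a node; each consecutive token
pair *within an utterance* contributes one directed edge.  Immediate
repetitions yield self-loops and repeated pairs yield parallel edges, so
the container is a directed multigraph.  No edge spans an utterance
boundary — an interruption breaks the word trajectory.

Two attributes quantify connectedness:

LCC
    node count of the largest connected component of the underlying
    undirected graph (all node pairs reachable ignoring direction) —
    a marker of the diversity of lexical items tied into one discourse.
LSC
    node count of the largest strongly connected component (all node
    pairs mutually reachable along directed paths) — a marker of
    long-range recurrence in word sequencing.  A single node is a
    strongly connected component of size 1, so LSC >= 1 on any
    non-empty graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import networkx as nx

from sgdem.errors import EmptyGraphError
from sgdem.transcript_io import Transcript

TokenSource = Union[Transcript, Sequence[Sequence[str]]]


@dataclass(frozen=True)
class ConnectednessResult:
    """The two component-size attributes of one speech graph."""

    lcc_nodes: int
    lsc_nodes: int

    def __post_init__(self):
        if not (0 <= self.lsc_nodes <= self.lcc_nodes):
            raise ValueError("lsc_nodes must satisfy 0 <= lsc <= lcc")


def _as_utterances(source: TokenSource) -> list[Sequence[str]]:
    if isinstance(source, Transcript):
        return list(source.utterances)
    return list(source)


def build_graph(source: TokenSource) -> nx.MultiDiGraph:
    """Build the word-trajectory multigraph from utterance-segmented tokens.

    Parameters
    ----------
    source
        A :class:`Transcript` or a list of utterances (lists of tokens).
        A single flat token window can be passed as ``[window_tokens]``.

    Raises
    ------
    EmptyGraphError
        If the source contains no tokens at all.
    """
    g = nx.MultiDiGraph()
    for utt in _as_utterances(source):
        for tok in utt:
            g.add_node(tok)
        for a, b in zip(utt, utt[1:]):
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("cannot build a graph from zero tokens")
    return g


def largest_connected_component(g: nx.MultiDiGraph) -> int:
    """Node count of the largest component of the undirected projection."""
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("empty graph has no components")
    return max(len(c) for c in nx.weakly_connected_components(g))


def largest_strongly_connected_component(g: nx.MultiDiGraph) -> int:
    """Node count of the largest strongly connected component.

    Singleton nodes count as components of size 1.
    """
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("empty graph has no components")
    return max(len(c) for c in nx.strongly_connected_components(g))


def connectedness(g: nx.MultiDiGraph) -> ConnectednessResult:
    """Both connectedness attributes of one graph; lsc <= lcc always."""
    return ConnectednessResult(
        lcc_nodes=largest_connected_component(g),
        lsc_nodes=largest_strongly_connected_component(g),
    )


# --- export ---------------------------------------------------------------


def graph_to_edgelist(g: nx.MultiDiGraph) -> str:
    """One tab-separated "from<TAB>to" line per edge (multiplicity kept)."""
    return "".join(f"{a}\t{b}\n" for a, b, _ in g.edges(keys=True))


def graph_to_json(g: nx.MultiDiGraph) -> str:
    """JSON ``{"nodes": [...], "edges": [[from, to], ...]}`` export."""
    return json.dumps(
        {
            "nodes": sorted(g.nodes()),
            "edges": [[a, b] for a, b, _ in g.edges(keys=True)],
        },
        indent=2,
    )


def write_graph(g: nx.MultiDiGraph, path: str | Path) -> None:
    """Write edge-list (`.tsv`/`.txt`) or JSON (`.json`) by extension."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(graph_to_json(g), encoding="utf-8")
    else:
        path.write_text(graph_to_edgelist(g), encoding="utf-8")
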