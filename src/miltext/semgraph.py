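"""Semantic dependency graphs and REAS-anchored factor extraction.

Each post is split into linguistic units at terminal punctuation; an
external semantic-role parser turns every unit into role triples
``<(wordA, wordB), Role>`` over nine roles: reason (REAS), agent (AGT),
experiencer (EXP), object (PAT), content (CONT), dative (DATV), link
(LINK), temporal (TIME), locative (LOC). This module consumes triples —
it never parses.

The lexical graph aggregates triples across units and posts: nodes are
normalized surface forms, edge weight is the corpus count of links
between the pair, self-links are dropped, stop nodes and punctuation are
excluded, and low-frequency edges are pruned. Factor extraction expands
breadth-first from the REAS anchors (Layer 0) through any of the nine
roles out to Layer 3; units with no REAS triple are flagged
unextractable, which is what caps the corpus-level extraction yield.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

ROLES = ("REAS", "AGT", "EXP", "PAT", "CONT", "DATV", "LINK", "TIME", "LOC")

_TERMINAL = re.compile(r"[.!?。！？]")
_PUNCT_ONLY = re.compile(r"^[\W_]+$", re.UNICODE)


def _norm(word: str) -> str:
    return unicodedata.normalize("NFKC", word).casefold()


@dataclass(frozen=True)
class RoleTriple:
    word_a: str
    word_b: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.word_a or not self.word_b:
            raise ValueError("triple words must be non-empty")


@dataclass
class SentenceParse:
    unit_id: str
    post_id: str
    triples: list[RoleTriple] = field(default_factory=list)


def split_units(text: str) -> list[str]:
    """Split text into units at terminal punctuation (. ! ? and CJK forms).

    Trailing text without terminal punctuation forms a final unit; empty
    fragments are dropped.
    """
    parts = _TERMINAL.split(text)
    return [p.strip() for p in parts if p.strip()]


def load_triples(path: str | Path) -> list[SentenceParse]:
    """Read a TSV with columns post_id, unit_id, word_a, word_b, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"post_id", "unit_id", "word_a", "word_b", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"triple table missing columns: {sorted(missing)}")
    parses: dict[tuple[str, str], SentenceParse] = {}
    for r in df.itertuples(index=False):
        key = (r.post_id, r.unit_id)
        if key not in parses:
            parses[key] = SentenceParse(unit_id=r.unit_id, post_id=r.post_id)
        parses[key].triples.append(RoleTriple(r.word_a, r.word_b, r.role))
    return list(parses.values())


def build_graph(
    parses: Iterable[SentenceParse],
    min_edge_weight: int = 2,
    stop_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Aggregate role triples into a weighted lexical graph.

    Edges are stored undirected with the original direction kept in the
    ``directions`` attribute and the set of linking roles in ``roles``;
    ``weight`` counts triples linking the pair across all units and posts.
    Self-links, stop-node endpoints, and punctuation-only tokens are
    excluded; edges with weight below ``min_edge_weight`` are pruned.
    """
    stop = {_norm(s) for s in stop_nodes}
    G = nx.Graph()
    freq: Counter[str] = Counter()
    for parse in parses:
        for t in parse.triples:
            a, b = _norm(t.word_a), _norm(t.word_b)
            if a == b:
                continue  # self-link
            if a in stop or b in stop:
                continue
            if _PUNCT_ONLY.match(a) or _PUNCT_ONLY.match(b):
                continue
            freq[a] += 1
            freq[b] += 1
            if G.has_edge(a, b):
                e = G[a][b]
                e["weight"] += 1
                e["roles"].add(t.role)
                e["directions"].append((a, b))
            else:
                G.add_edge(a, b, weight=1, roles={t.role}, directions=[(a, b)])
    nx.set_node_attributes(G, {n: freq[n] for n in G.nodes}, "freq")
    prune = [(u, v) for u, v, w in G.edges(data="weight") if w < min_edge_weight]
    G.remove_edges_from(prune)
    G.remove_nodes_from([n for n in list(G.nodes) if G.degree(n) == 0])
    return G


def reason_expansion(graph: nx.Graph, max_layers: int = 3) -> dict[str, int]:
    """Layer nodes breadth-first from the REAS anchors.

    Layer 0 = endpoints of REAS-labeled edges; Layer k = nodes linked (by
    any of the nine roles) to a Layer k-1 node and not yet assigned; nodes
    beyond ``max_layers`` are excluded. A node reachable at several depths
    keeps its first (smallest) layer. Empty result means no REAS anchor:
    the unit/graph is unextractable.
    """
    layer_of: dict[str, int] = {}
    frontier = set()
    for u, v, roles in graph.edges(data="roles"):
        if "REAS" in roles:
            frontier.update((u, v))
    for n in sorted(frontier):
        layer_of[n] = 0
    for k in range(1, max_layers + 1):
        nxt = set()
        for n in frontier:
            for nb in graph.neighbors(n):
                if nb not in layer_of:
                    nxt.add(nb)
        for n in sorted(nxt):
            layer_of[n] = k
        frontier = nxt
        if not frontier:
            break
    return layer_of


def extract_factor_terms(graph: nx.Graph, layer_of: dict[str, int]) -> list[tuple[str, int]]:
    """Candidate factor terms ordered by (layer asc, corpus frequency desc).

    Ties broken lexicographically for determinism. Returns (term, layer)
    pairs; an empty layering yields an empty list.
    """
    def key(item):
        node, layer = item
        return (layer, -graph.nodes[node].get("freq", 0), node)

    return sorted(layer_of.items(), key=key)


def export_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV: node_a, node_b, roles (comma-joined), weight."""
    rows = [
        {"node_a": u, "node_b": v,
         "roles": ",".join(sorted(d["roles"])), "weight": d["weight"]}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "roles", "weight"]).to_csv(
        path, sep="\t", index=False
    )
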