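"""Data model and I/O for directed consumer–resource networks.

A food web is a directed graph whose nodes are taxa and whose links are
trophic interactions oriented resource → consumer (the direction of energy
flow).  Webs are binary: a link is present or absent, never weighted.  The
module reads and writes the three plain-text formats ecological network
repositories typically use — two-column edge lists, 0/1 adjacency matrices
with taxon labels, and GraphML — and provides the label-cleaning step
(synonym resolution, typo merging) that any multi-site field dataset needs
before cross-site comparison.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FoodWeb",
    "CommunitySet",
    "SynonymTable",
    "ParseError",
    "canonicalize_label",
    "read_edgelist",
    "read_adjacency",
    "read_graphml",
    "write_web",
    "clean_taxa",
    "composition_counts",
]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def canonicalize_label(label: str) -> str:
    """Canonical taxon code: trimmed and case-folded.

    Field datasets routinely contain trailing blanks and inconsistent
    capitalisation of the same taxon; identity comparison is only meaningful
    after this normalisation.
    """
    code = label.strip().casefold()
    if not code:
        raise ValueError("taxon label is empty after trimming")
    return code


class FoodWeb:
    """An immutable directed food web: a named (V, E) pair.

    Parameters
    ----------
    name : str
        Community identifier (e.g. a site name).
    nodes : iterable of str
        Taxon codes (assumed already canonical).
    links : iterable of (str, str)
        Directed links ``(resource, consumer)``.  Every endpoint must be a
        node.  Self-loops (cannibalism) are permitted.  Duplicates collapse.
    """

    __slots__ = ("name", "nodes", "links")

    def __init__(self, name: str, nodes: Iterable[str] = (), links: Iterable[tuple[str, str]] = ()):
        node_set = frozenset(nodes)
        link_set = frozenset((str(u), str(v)) for u, v in links)
        for code in node_set:
            if not code:
                raise ValueError("empty taxon code")
        for u, v in link_set:
            if u not in node_set or v not in node_set:
                raise ValueError(f"link {u}->{v} has an endpoint outside the node set")
        self.name = name
        self.nodes = node_set
        self.links = link_set

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        for code in self.sorted_nodes():
            g.add_node(code, taxon=code)
        g.add_edges_from(sorted(self.links))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return self.nodes == other.nodes and self.links == other.links

    def __hash__(self) -> int:
        return hash((self.nodes, self.links))

    def __repr__(self) -> str:
        return f"FoodWeb({self.name!r}, |V|={self.n_nodes}, |E|={self.n_links})"


@dataclass
class CommunitySet:
    """An ordered collection of webs with distinct names sharing a species pool."""

    webs: list[FoodWeb] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [w.name for w in self.webs]
        if len(set(names)) != len(names):
            raise ValueError("web names must be unique within a CommunitySet")

    @property
    def pool(self) -> frozenset[str]:
        out: set[str] = set()
        for w in self.webs:
            out |= w.nodes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.webs)

    def __iter__(self):
        return iter(self.webs)

    def __getitem__(self, i):
        return self.webs[i]


class SynonymTable:
    """Raw label → canonical taxon code mapping.

    Chains (A→B, B→C) are resolved to their fixed point at construction so
    that applying the table is idempotent.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        raw = {canonicalize_label(k): canonicalize_label(v) for k, v in (mapping or {}).items()}
        resolved: dict[str, str] = {}
        for key, val in raw.items():
            seen = {key}
            while val in raw and raw[val] != val:
                if raw[val] in seen:
                    raise ValueError(f"synonym cycle involving {val!r}")
                seen.add(val)
                val = raw[val]
            resolved[key] = val
        self._map = resolved

    def resolve(self, label: str) -> str:
        code = canonicalize_label(label)
        return self._map.get(code, code)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def _rows_from_stream(source) -> Iterable[list[str]]:
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    first = text.splitlines()[0] if text.strip() else ""
    delimiter = "\t" if "\t" in first else ","
    return list(csv.reader(io.StringIO(text), delimiter=delimiter))


def read_edgelist(source, name: str) -> FoodWeb:
    """Read a web from a two-column ``source,target`` edge list.

    Accepts a text stream or a string.  A header row ``source,target`` (any
    case) is skipped.  One-column rows declare isolated taxa.  Duplicate
    link rows collapse silently (webs are binary); the collapsed count is
    logged.  Empty input yields an empty web.
    """
    rows = _rows_from_stream(source)
    nodes: set[str] = set()
    links: set[tuple[str, str]] = set()
    n_rows = 0
    for lineno, row in enumerate(rows, start=1):
        cells = [c for c in row if c.strip()]
        if not cells:
            continue
        if lineno == 1 and [c.strip().casefold() for c in cells] == ["source", "target"]:
            continue
        if len(cells) == 1:
            nodes.add(canonicalize_label(cells[0]))
        elif len(cells) == 2:
            u, v = canonicalize_label(cells[0]), canonicalize_label(cells[1])
            nodes.update((u, v))
            links.add((u, v))
            n_rows += 1
        else:
            raise ParseError(f"line {lineno}: expected 1 or 2 fields, got {len(cells)}")
    if n_rows > len(links):
        logger.info("%s: collapsed %d duplicate link rows", name, n_rows - len(links))
    return FoodWeb(name, nodes, links)


def read_adjacency(source, name: str, orientation: str) -> FoodWeb:
    """Read a web from a labelled 0/1 adjacency matrix (CSV).

    ``orientation`` is mandatory — a wrong default silently reverses every
    link.  ``"rows-eat-columns"``: cell (r, c) = 1 means the row taxon
    consumes the column taxon, i.e. a link c → r (resource → consumer).
    ``"columns-eat-rows"``: the transpose convention, link r → c.
    """
    if orientation not in ("rows-eat-columns", "columns-eat-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, index_col=0)
    row_labels = [canonicalize_label(str(r)) for r in df.index]
    col_labels = [canonicalize_label(str(c)) for c in df.columns]
    if len(set(row_labels)) != len(row_labels) or len(set(col_labels)) != len(col_labels):
        raise ParseError("duplicated taxon label in adjacency matrix")
    values = df.to_numpy()
    bad = ~((values == 0) | (values == 1))
    if bad.any():
        raise ParseError("adjacency matrix contains non-binary cells")
    nodes = set(row_labels) | set(col_labels)
    links: set[tuple[str, str]] = set()
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            if values[i, j] == 1:
                links.add((c, r) if orientation == "rows-eat-columns" else (r, c))
    return FoodWeb(name, nodes, links)


def read_graphml(source, name: str | None = None) -> FoodWeb:
    """Read a web from GraphML text (inverse of ``write_web(..., "graphml")``)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    g = nx.read_graphml(source)
    web_name = name if name is not None else g.graph.get("name", "web")
    return FoodWeb(web_name, (str(n) for n in g.nodes), ((str(u), str(v)) for u, v in g.edges))


def write_web(web: FoodWeb, format: str = "edgelist") -> str:
    """Serialise a web to text; ``read(write(w))`` round-trips exactly."""
    if format == "edgelist":
        lines = ["source,target"]
        linked = {u for u, _ in web.links} | {v for _, v in web.links}
        lines += [f"{u},{v}" for u, v in sorted(web.links)]
        lines += sorted(web.nodes - linked)  # isolated taxa as one-column rows
        return "\n".join(lines) + "\n"
    if format == "graphml":
        return "\n".join(nx.generate_graphml(web.to_networkx())) + "\n"
    raise ValueError(f"unknown format {format!r}")


def clean_taxa(cset: CommunitySet, synonyms: SynonymTable) -> tuple[CommunitySet, list[tuple[str, str, str]]]:
    """Apply a synonym table to every web; merged taxa union their links.

    Returns the cleaned set and a substitution report of
    ``(web_name, raw_code, canonical_code)`` triples.  Idempotent: the table
    resolves chains at construction, so a second pass is the identity.
    """
    report: list[tuple[str, str, str]] = []
    cleaned: list[FoodWeb] = []
    for web in cset:
        mapping = {}
        for code in web.nodes:
            try:
                new = synonyms.resolve(code)
            except ValueError:
                logger.warning("%s: cannot canonicalize %r; left untouched", web.name, code)
                new = code
            mapping[code] = new
            if new != code:
                report.append((web.name, code, new))
        links = {(mapping[u], mapping[v]) for u, v in web.links}
        if len(links) < web.n_links:
            logger.info("%s: %d links merged by synonym substitution", web.name, web.n_links - len(links))
        cleaned.append(FoodWeb(web.name, set(mapping.values()), links))
    return CommunitySet(cleaned), report


def composition_counts(w1: FoodWeb, w2: FoodWeb) -> tuple[int, int, int]:
    """Occurrence bookkeeping for similarity indices.

    Returns ``(a, b, c)``: taxa only in ``w1``, only in ``w2``, and shared.
    """
    c = len(w1.nodes & w2.nodes)
    return len(w1.nodes) - c, len(w2.nodes) - c, c
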