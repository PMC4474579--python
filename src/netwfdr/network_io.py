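"""Functional-network ingestion, query-seeded subnetworks and connectivity scores.

A functional relationship network is an undirected gene graph whose edge
scores are posterior probabilities (confidences in ``(0, 1]``) that the two
genes act in the same biological process.  Given a small list of seed
("query") genes, the subnetwork of genes reachable from the seeds supplies a
per-gene *total relationship confidence* (TRC): the sum of confidences of a
gene's incident edges.  The TRC is the raw material for the p-value weights
built in :mod:`netwfdr.weighting`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalNetwork",
    "QuerySet",
    "read_edge_list",
    "read_query_list",
    "subnetwork_from_queries",
    "total_relationship_confidence",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file contains a malformed row."""


@dataclass
class FunctionalNetwork:
    """Undirected gene graph with edge confidences in ``(0, 1]``.

    Thin wrapper over a :class:`networkx.Graph`; the ``confidence`` edge
    attribute holds the score.  Self-loops are forbidden and each unordered
    pair appears at most once.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], *, extra_nodes: Iterable[str] = ()
    ) -> "FunctionalNetwork":
        """Build a network from ``(gene_a, gene_b, confidence)`` triples.

        Duplicate unordered pairs are collapsed keeping the maximum
        confidence; self-loops are dropped with a warning (the node is kept).
        Confidences outside ``(0, 1]`` raise :class:`ValueError`.
        """
        g = nx.Graph()
        for a, b, conf in edges:
            conf = float(conf)
            if not (0.0 < conf <= 1.0):
                raise ValueError(
                    f"edge confidence must be in (0, 1], got {conf!r} for ({a}, {b})"
                )
            if a == b:
                logger.warning("dropping self-loop on gene %r", a)
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        g.add_nodes_from(extra_nodes)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, a: str, b: str) -> float:
        return float(self.graph[a][b]["confidence"])

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, data in self.graph.edges(data=True):
            yield a, b, float(data["confidence"])

    def total_confidence(self) -> float:
        """Sum of all edge confidences (each edge counted once)."""
        return float(sum(c for _, _, c in self.edges()))


@dataclass(frozen=True)
class QuerySet:
    """Ordered, duplicate-free list of seed gene identifiers."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("query set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("query set contains duplicate gene identifiers")

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "QuerySet":
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        return cls(tuple(seen))

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def _split_row(line: str, sep: str | None) -> list[str]:
    if sep is None:
        # auto: prefer tabs, fall back to commas, then whitespace
        if "\t" in line:
            return [f.strip() for f in line.split("\t")]
        if "," in line:
            return [f.strip() for f in line.split(",")]
        return line.split()
    return [f.strip() for f in line.split(sep)]


def read_edge_list(
    path: str | Path,
    *,
    sep: str | None = None,
    casefold: bool = False,
) -> FunctionalNetwork:
    """Read a functional-network edge list from a TSV/CSV file.

    Expected columns: ``gene_a``, ``gene_b``, ``confidence`` (extra columns
    ignored).  A header row is auto-detected by a non-numeric third field.
    Duplicate pairs keep the maximum confidence; self-loops are dropped with
    a logged warning.

    Parameters
    ----------
    path
        Edge-list file.
    sep
        Field separator; ``None`` auto-detects tab, then comma, then
        whitespace, per line.
    casefold
        If true, gene identifiers are lower-cased on ingestion.  Off by
        default: silent case-folding can hide data errors.
    """
    path = Path(path)
    triples: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line, sep)
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            a, b, raw_conf = fields[0], fields[1], fields[2]
            try:
                conf = float(raw_conf)
            except ValueError:
                if lineno == 1 and not triples:
                    continue  # header row
                raise EdgeListParseError(
                    f"{path}:{lineno}: non-numeric confidence {raw_conf!r}"
                ) from None
            if not (0.0 < conf <= 1.0):
                raise EdgeListParseError(
                    f"{path}:{lineno}: confidence {conf} outside (0, 1]"
                )
            if casefold:
                a, b = a.lower(), b.lower()
            triples.append((a, b, conf))
    if not triples:
        raise EdgeListParseError(f"{path}: no edges found")
    return FunctionalNetwork.from_edges(triples)


def read_query_list(path: str | Path, *, casefold: bool = False) -> QuerySet:
    """Read seed genes from a plain-text file, one identifier per line.

    Blank lines and ``#`` comments are skipped.
    """
    genes: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                genes.append(token.lower() if casefold else token)
    return QuerySet.from_iterable(genes)


def subnetwork_from_queries(
    net: FunctionalNetwork,
    queries: QuerySet,
    *,
    min_confidence: float = 0.0,
    expansion: float = 1,
) -> FunctionalNetwork:
    """Induced subnetwork of genes within ``expansion`` hops of any seed gene.

    Only edges with confidence strictly above ``min_confidence`` are
    traversed (and retained in the induced subnetwork).  Seed genes present
    in ``net`` are always included.  ``expansion=math.inf`` yields the union
    of connected components containing seed genes.

    Raises
    ------
    ValueError
        If none of the seed genes occur in the network (the missing
        identifiers are listed).
    """
    if not (0.0 <= min_confidence < 1.0):
        raise ValueError(f"min_confidence must be in [0, 1), got {min_confidence}")
    if expansion < 1:
        raise ValueError(f"expansion must be >= 1, got {expansion}")

    present = [q for q in queries if q in net.graph]
    missing = [q for q in queries if q not in net.graph]
    if not present:
        raise ValueError(f"no query gene found in the network; missing: {missing}")
    if missing:
        logger.warning("query genes absent from the network: %s", missing)

    # breadth-first search over the confidence-thresholded graph
    dist: dict[str, float] = {q: 0 for q in present}
    frontier = deque(present)
    while frontier:
        u = frontier.popleft()
        if dist[u] >= expansion:
            continue
        for v, data in net.graph[u].items():
            if data["confidence"] > min_confidence and v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)

    keep = set(dist)
    sub = nx.Graph()
    sub.add_nodes_from(keep)
    for a, b, data in net.graph.edges(keep, data=True):
        if a in keep and b in keep and data["confidence"] > min_confidence:
            sub.add_edge(a, b, confidence=data["confidence"])
    return FunctionalNetwork(sub)


def total_relationship_confidence(
    net: FunctionalNetwork, universe: Iterable[str]
) -> dict[str, float]:
    """Per-gene total relationship confidence over a gene universe.

    The TRC of a gene is the sum of the confidences of its incident edges in
    ``net``; genes absent from the network get 0.  Summed over all network
    nodes, the TRC equals twice the total edge confidence (each edge counts
    once per endpoint).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    trc: dict[str, float] = {}
    g = net.graph
    for gene in universe:
        if gene in g:
            trc[gene] = float(
                sum(data["confidence"] for _, data in g[gene].items())
            )
        else:
            trc[gene] = 0.0
    return trc
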