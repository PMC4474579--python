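"""Hypergeometric over-representation of a gene list against gene sets.

For a query list of size ``n`` drawn from a universe of ``N`` annotated
genes, the overlap ``k`` with a gene set of size ``K`` is tested against the
hypergeometric upper tail ``P(X >= k)`` — the classic one-sided
over-representation (Fisher exact) test.  Results mirror the usual
enrichment-table layout: network frequency ``k/n``, genome frequency
``K/N``, raw and multiplicity-adjusted p-values, and the overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .wfdr import bh_stepup, bonferroni

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "read_gmt", "hypergeom_upper_tail", "enrich"]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. one GMT row)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    from gseapy.parser import read_gmt as _read_gmt

    raw = _read_gmt(str(path))
    return [GeneSet(name, frozenset(genes)) for name, genes in raw.items()]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` genes in the universe, ``K`` of them in the annotated set, ``n``
    drawn (the query list), ``k`` observed in the overlap.  Computed through
    the survival function for numerical stability; ``k = 0`` returns exactly 1.
    """
    for name, val in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {val}")
    if k > min(n, K) or n > N or K > N:
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N} "
            "(need k <= min(n, K), n <= N, K <= N)"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    *,
    adjust: str = "bh",
    include_empty: bool = False,
) -> pd.DataFrame:
    """Over-representation test of ``query`` against each gene set.

    Genes outside the universe are dropped (with a warning for query genes);
    each set is intersected with the universe before testing.  All sets with
    at least one universe gene are tested and enter the multiplicity
    adjustment (``bh`` step-up by default, or ``bonferroni``); sets with zero
    query overlap are omitted from the output unless ``include_empty``.

    Returns a DataFrame sorted by adjusted p-value with columns: set_name,
    overlap_count (k), query_size (n), set_size (K), universe_size (N),
    network_freq (k/n), genome_freq (K/N), raw_p, adjusted_p, overlap_genes.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    dropped = query - universe
    if dropped:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(dropped),
            sorted(dropped)[:5],
        )
    query &= universe
    if not query:
        raise ValueError("no query genes remain after restricting to the universe")

    N, n = len(universe), len(query)
    rows = []
    for gs in sets:
        members = gs.genes & universe
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        rows.append(
            {
                "set_name": gs.name,
                "overlap_count": k,
                "query_size": n,
                "set_size": K,
                "universe_size": N,
                "network_freq": k / n,
                "genome_freq": K / N,
                "raw_p": hypergeom_upper_tail(k, n, K, N),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows)
    if adjust == "bh":
        _, adj = bh_stepup(df["raw_p"].to_numpy(), level=0.5)
    else:
        _, adj = bonferroni(df["raw_p"].to_numpy())
    df["adjusted_p"] = adj
    if not include_empty:
        df = df[df["overlap_count"] > 0]
    df = df.sort_values(
        ["adjusted_p", "raw_p", "set_name"], kind="stable", ignore_index=True
    )
    cols = [
        "set_name", "overlap_count", "query_size", "set_size", "universe_size",
        "network_freq", "genome_freq", "raw_p", "adjusted_p", "overlap_genes",
    ]
    return df[cols]
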