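"""P-value weights from network connectivity.

Weighted FDR (Genovese et al.) keeps its false-discovery-rate guarantee for
any nonnegative weights :math:`W_i` with :math:`\\sum_{i=1}^m W_i = m`, where
``m`` is the number of hypotheses.  This module turns per-gene total
relationship confidence (TRC) into such weights:

1. ``log1p_transform`` — variance-stabilising ``ln(1 + TRC)`` (hub genes can
   have TRCs two orders of magnitude above the median);
2. ``normalize_to_m`` — divide by the mean over the testing universe, so the
   weights have mean 1 and sum ``m``;
3. ``sensitivity_weights`` — a seed-bias guard that pins the seed genes'
   weights to 1 and redistributes the freed mass over the remaining genes.

``assign_weights`` composes the full pipeline from a network and a seed list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .network_io import FunctionalNetwork, QuerySet, subnetwork_from_queries, total_relationship_confidence

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "log1p_transform",
    "normalize_to_m",
    "sensitivity_weights",
    "assign_weights",
]

#: relative tolerance for the sum-to-m invariant (pure arithmetic, no fitting)
SUM_RTOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-gene weights constrained to sum to ``m``.

    ``m`` is the number of hypotheses (= number of genes in the testing
    universe).  The constraint holds to relative tolerance ``SUM_RTOL``.
    """

    weights: Mapping[str, float]
    m: int

    def __post_init__(self) -> None:
        if len(self.weights) != self.m:
            raise ValueError(
                f"weight vector has {len(self.weights)} genes but m={self.m}"
            )
        total = 0.0
        for g, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight {w} for gene {g!r}")
            total += w
        if not math.isclose(total, self.m, rel_tol=SUM_RTOL):
            raise ValueError(f"weights sum to {total}, expected m={self.m}")

    def __getitem__(self, gene: str) -> float:
        return self.weights[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.weights

    def genes(self) -> Iterable[str]:
        return self.weights.keys()


def log1p_transform(trc: Mapping[str, float]) -> dict[str, float]:
    """Apply ``v -> ln(1 + v)`` to every TRC value.

    Zero maps to zero and the gene ranking is preserved (the map is strictly
    increasing).  Negative inputs raise.
    """
    out: dict[str, float] = {}
    for g, v in trc.items():
        if v < 0:
            raise ValueError(f"TRC must be nonnegative, got {v} for gene {g!r}")
        out[g] = math.log1p(v)
    return out


def normalize_to_m(
    raw: Mapping[str, float], universe: Iterable[str]
) -> WeightVector:
    """Scale raw scores to mean 1 over the universe, hence sum ``m``.

    Genes in the universe missing from ``raw`` contribute a raw score of 0.
    If every raw score is zero the weights fall back to the uniform vector
    (all ones, also summing to ``m``) with a logged warning — with no network
    signal the procedure must reduce to the unweighted one.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if len(set(universe)) != len(universe):
        raise ValueError("universe contains duplicate gene identifiers")
    values = {g: float(raw.get(g, 0.0)) for g in universe}
    for g, v in values.items():
        if v < 0:
            raise ValueError(f"raw score must be nonnegative, got {v} for {g!r}")
    total = sum(values.values())
    m = len(universe)
    if total == 0.0:
        logger.warning("all raw scores are zero; falling back to uniform weights")
        return WeightVector({g: 1.0 for g in universe}, m)
    mean = total / m
    return WeightVector({g: v / mean for g, v in values.items()}, m)


def sensitivity_weights(w: WeightVector, queries: QuerySet) -> WeightVector:
    """Pin seed-gene weights to 1 and rescale the rest to restore sum ``m``.

    Seed (query) genes typically act as hubs of the extracted subnetwork and
    can receive extreme weights; this variant guards against that selection
    bias.  The mass freed by pinning is spread proportionally over non-seed
    genes (zero weights stay zero).  Applying the transform twice with the
    same seed set is a no-op.
    """
    missing = [q for q in queries if q not in w]
    if missing:
        raise ValueError(f"query genes missing from weight vector: {missing}")
    query_set = set(queries)
    m = w.m
    if len(query_set) == m:
        return WeightVector({g: 1.0 for g in w.genes()}, m)
    nonquery_sum = sum(v for g, v in w.weights.items() if g not in query_set)
    residual = m - len(query_set)
    out: dict[str, float] = {}
    if nonquery_sum == 0.0:
        logger.warning(
            "non-query weights are all zero; assigning uniform weight 1 to non-queries"
        )
        for g in w.genes():
            out[g] = 1.0
        return WeightVector(out, m)
    factor = residual / nonquery_sum
    for g, v in w.weights.items():
        out[g] = 1.0 if g in query_set else v * factor
    return WeightVector(out, m)


def assign_weights(
    net: FunctionalNetwork,
    queries: QuerySet,
    universe: Iterable[str],
    *,
    scheme: str = "log1p",
    min_confidence: float = 0.0,
    expansion: float = 1,
    min_weight: float = 0.0,
    sensitivity: bool = False,
) -> WeightVector:
    """Full weighting pipeline: subnetwork -> TRC -> transform -> normalise.

    Parameters
    ----------
    net, queries
        Functional network and seed genes defining the subnetwork.
    universe
        The testing universe (all genes with a p-value); ``m`` is its size.
        Genes outside the extracted subnetwork get TRC 0 and hence weight 0
        (unless ``min_weight`` raises the floor).
    scheme
        ``"log1p"`` (default) stabilises hub-dominated TRCs; ``"raw"`` uses
        TRC directly.  Both produce the same gene ranking.
    min_confidence, expansion
        Subnetwork extraction controls (edge threshold; hop count, default
        one hop from the seeds).
    min_weight
        Optional epsilon floor applied before a final rescale to sum ``m``;
        default 0 keeps the literal TRC-proportional scheme, under which
        zero-TRC genes can never be rejected.
    sensitivity
        If true, apply :func:`sensitivity_weights` to the result.
    """
    if scheme not in ("log1p", "raw"):
        raise ValueError(f"unknown scheme {scheme!r}")
    universe = list(universe)
    sub = subnetwork_from_queries(
        net, queries, min_confidence=min_confidence, expansion=expansion
    )
    trc = total_relationship_confidence(sub, universe)
    raw = log1p_transform(trc) if scheme == "log1p" else dict(trc)
    w = normalize_to_m(raw, universe)
    if min_weight > 0.0:
        floored = {g: max(v, min_weight) for g, v in w.weights.items()}
        total = sum(floored.values())
        w = WeightVector({g: v * w.m / total for g, v in floored.items()}, w.m)
    if sensitivity:
        w = sensitivity_weights(w, queries)
    return w
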