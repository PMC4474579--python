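"""Weighted and unweighted multiple-testing procedures.

The weighted false discovery rate procedure divides each p-value by its
weight, :math:`Q_i = P_i / W_i`, and runs the ordinary Benjamini–Hochberg
step-up on the :math:`Q_i`.  Provided the nonnegative weights sum to the
number of tests ``m``, the FDR stays controlled at the nominal level
(Genovese et al.).  With all weights equal to 1 the procedure is exactly
unweighted BH.

Conventions (all needed for the adjusted values to be valid probabilities):

* weighted p-values are capped at 1: ``Q_i = min(P_i / W_i, 1)``;
* a zero weight yields ``Q_i = 1`` — a hypothesis carrying no prior support
  can never be rejected — including the ``P_i = 0, W_i = 0`` corner;
* adjusted q-values come from the running-minimum (from the largest rank)
  construction, so tied inputs receive identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .weighting import WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "read_pvalues",
    "weighted_pvalues",
    "bh_stepup",
    "weighted_bh",
    "bonferroni",
    "WfdrResult",
]

#: default nominal FDR level (the cutoff used throughout the worked analyses)
DEFAULT_LEVEL = 0.2


def read_pvalues(path: str | Path, *, casefold: bool = False) -> pd.DataFrame:
    """Read a gene-level p-value table (TSV with columns gene_id, p_value).

    Gene identifiers must be unique and p-values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "p_value"}.issubset(df.columns):
        # headerless two-column fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "p_value"])
    df = df[["gene_id", "p_value"]].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    if casefold:
        df["gene_id"] = df["gene_id"].str.lower()
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene identifiers in p-value table: {dups[:5]}")
    p = df["p_value"].to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return df


def weighted_pvalues(
    p: Sequence[float] | np.ndarray, w: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Elementwise ``min(p / w, 1)`` with the zero-weight convention ``-> 1``."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p-values and weights must have the same length")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.ones_like(p)
    nz = w > 0
    np.divide(p, w, out=out, where=nz)
    return np.minimum(out, 1.0)


def bh_stepup(
    values: Sequence[float] | np.ndarray, level: float = DEFAULT_LEVEL
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up on a vector of (possibly weighted) p-values.

    Sorts ascending, finds the largest rank ``k`` with
    ``value_(k) <= k * level / m`` and rejects the ``k`` smallest values.
    Returns ``(rejected, q)`` in the input order, where the adjusted value
    ``q_i = min_{j >= rank(i)} m * value_(j) / j`` (capped at 1) satisfies
    ``rejected_i  <=>  q_i <= level`` for every level.  Exactly tied inputs
    get identical adjusted values and identical rejection status.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if (v < 0).any() or (v > 1).any():
        raise ValueError("inputs must lie in [0, 1]")
    m = v.size
    order = np.argsort(v, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    scaled = m * v[order] / ranks
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    rejected = q <= level
    return rejected, q


@dataclass(frozen=True)
class WfdrResult:
    """Per-gene outcome of a multiple-testing procedure.

    ``table`` has columns gene_id, p_value, weight, weighted_p, q_value,
    rejected, sorted by (weighted_p, gene_id) for deterministic output.
    """

    table: pd.DataFrame
    level: float
    m: int
    method: str

    @property
    def n_rejected(self) -> int:
        return int(self.table["rejected"].sum())

    def rejected_genes(self) -> list[str]:
        return self.table.loc[self.table["rejected"], "gene_id"].tolist()


def weighted_bh(
    p: pd.DataFrame, w: WeightVector, level: float = DEFAULT_LEVEL
) -> WfdrResult:
    """Weighted BH: divide p-values by their weights, then step up.

    ``p`` is a gene-level p-value table (columns gene_id, p_value); every
    gene must have a weight in ``w`` (no silent default).  With all weights
    equal to 1 the rejections and adjusted values are identical to plain BH.
    """
    genes = p["gene_id"].astype(str).tolist()
    missing = [g for g in genes if g not in w]
    if missing:
        raise KeyError(f"genes missing from weight vector: {missing[:5]}")
    pv = p["p_value"].to_numpy(dtype=float)
    wv = np.array([w[g] for g in genes], dtype=float)
    q_in = weighted_pvalues(pv, wv)
    rejected, qval = bh_stepup(q_in, level)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "p_value": pv,
            "weight": wv,
            "weighted_p": q_in,
            "q_value": qval,
            "rejected": rejected,
        }
    ).sort_values(["weighted_p", "gene_id"], kind="stable", ignore_index=True)
    return WfdrResult(table=table, level=level, m=len(genes), method="wfdr")


def bonferroni(
    p: Sequence[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: reject iff ``p <= alpha / m``.

    Returns ``(rejected, adjusted)`` with ``adjusted = min(m * p, 1)``.
    """
    pv = np.asarray(p, dtype=float)
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    adjusted = np.minimum(m * pv, 1.0)
    rejected = pv <= alpha / m if m else np.zeros(0, dtype=bool)
    return rejected, adjusted
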