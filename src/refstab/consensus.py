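"""Consensus ranking by geometric mean of per-method ranks.

Each stability algorithm contributes its rank of every gene as a weight
(tied genes carry the average of the tied positions, e.g. a geNorm top pair
contributes 1.5 each); the comprehensive ranking orders genes by the
geometric mean of their weights, so every method counts equally and no
method's raw stability scale leaks into the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import gmean

from .ranking import StabilityRanking, average_ranks

__all__ = ["ConsensusRanking", "aggregate_rankings"]


@dataclass
class ConsensusRanking:
    """Weights per method, their geometric mean, and the final order."""

    weights: pd.DataFrame  # genes × methods, entries = per-method ranks
    geomean_weight: pd.Series
    final_rank: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def ordered_genes(self) -> list[str]:
        return list(self.final_rank.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        out = self.weights.copy()
        out["geomean_weight"] = self.geomean_weight
        out["final_rank"] = self.final_rank
        return out.rename_axis("gene").sort_values(
            ["final_rank", "geomean_weight"], kind="stable"
        )


def aggregate_rankings(rankings: list[StabilityRanking]) -> ConsensusRanking:
    """Geometric-mean aggregation of ≥2 rankings over one gene set.

    Final ranks ascend with the geometric mean; exact ties share an average
    rank. Gene order of the first ranking is preserved in the output.
    """
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to aggregate")
    genes = rankings[0].genes
    ref = set(genes)
    for r in rankings[1:]:
        if set(r.genes) != ref:
            extra = sorted(set(r.genes) - ref)
            missing = sorted(ref - set(r.genes))
            raise ValueError(
                f"gene sets differ between rankings ({r.method}): "
                f"extra={extra}, missing={missing}"
            )
    names = []
    for i, r in enumerate(rankings):
        names.append(r.method if r.method not in names else f"{r.method}_{i}")
    weights = pd.DataFrame(
        {name: r.ranks.reindex(genes) for name, r in zip(names, rankings)}
    )
    geo = pd.Series(gmean(weights, axis=1), index=weights.index)
    return ConsensusRanking(
        weights=weights, geomean_weight=geo, final_rank=average_ranks(geo)
    )
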