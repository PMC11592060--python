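"""Shared ranking container for the stability algorithms.

Every stability method (BestKeeper, NormFinder, geNorm, comparative ΔCt)
reports a per-gene scalar where *lower means more stable*, plus a rank.
Ties are reported as average ranks (a geNorm top pair gets 1.5/1.5) unless
a method defines its own deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import rankdata


def average_ranks(values: pd.Series) -> pd.Series:
    """Ascending ranks of ``values`` with ties as average ranks."""
    return pd.Series(rankdata(values.to_numpy(), method="average"), index=values.index)


@dataclass
class StabilityRanking:
    """Per-gene stability values and ranks for one method.

    Attributes
    ----------
    method:
        Method label, e.g. ``"BestKeeper"`` or ``"geNorm"``.
    values:
        Gene-indexed stability statistic (lower = more stable).
    ranks:
        Gene-indexed rank; a (possibly tied) permutation of 1..G.
    joint_top:
        Optional pair of genes reported jointly at the top (geNorm).
    """

    method: str
    values: pd.Series
    ranks: pd.Series
    joint_top: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.ranks.index):
            raise ValueError("values and ranks must share the same gene index")
        self.values = self.values.astype(float)
        self.ranks = self.ranks.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def ordered_genes(self) -> list[str]:
        """Genes from most to least stable (rank ascending, stable sort)."""
        return list(self.ranks.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"stability_value": self.values, "rank": self.ranks}
        ).rename_axis("gene")
        return frame.sort_values(["rank", "stability_value"], kind="stable")

    def display_labels(self) -> pd.Series:
        """Gene labels with a joint top pair formatted as ``"A/B"``."""
        labels = pd.Series(self.values.index, index=self.values.index, dtype=object)
        if self.joint_top is not None:
            joint = "/".join(self.joint_top)
            for g in self.joint_top:
                labels[g] = joint
        return labels
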