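"""Model-based stability estimation (NormFinder-style).

The model treats a log-scale expression value (Ct is already log2) of gene
g in sample j of group i as

    y_igj = mu_g + kappa_i + d_ig + b_ij + eps_igj

* ``b_ij`` — per-sample effect (loading), removed by centering each sample
  by its across-gene mean within its group;
* ``d_ig`` — systematic intergroup difference of the gene (bias): how much
  the gene's level in group i deviates from its own across-group average;
* ``eps_igj ~ N(0, sigma^2_ig)`` — intragroup noise.

A good reference gene has both small ``|d_ig|`` (no condition-specific
regulation) and small ``sigma^2_ig`` (low scatter). The stability value
combines the two:

    rho_g = mean over groups of ( |d~_ig| + sqrt(sigma^2_ig / n_i) )

where ``d~_ig`` is the raw intergroup difference shrunk toward zero by the
empirical-Bayes factor ``gamma^2 / (gamma^2 + sigma^2_ig / n_i)`` and
``gamma^2`` is the between-group variance of the d's net of their sampling
noise (floored at zero). Lower rho = more stable.

Intragroup variances use the small-sample corrections of the two-way
decomposition: with k genes, the naive residual variance s2 of a gene
underestimates its true variance because every sample mean contains the
gene itself, so

    sigma^2_ig = k/(k-2) * ( s2_ig - sum_l s2_lg / (k (k-1)) )

With a single group the intergroup part is undefined and rho reduces to
the intragroup residual SD, sqrt(sigma^2_g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import CtTable
from .ranking import StabilityRanking, average_ranks

__all__ = [
    "GroupingScheme",
    "NormFinderResult",
    "normfinder_stability",
    "normfinder_ungrouped",
    "fine_grouping",
    "coarse_grouping",
]


@dataclass
class GroupingScheme:
    """Named assignment of every sample to a subgroup."""

    name: str
    assignment: dict[str, str]

    def validate(self, table: CtTable, min_group_size: int = 2) -> None:
        missing = [s for s in table.samples if s not in self.assignment]
        if missing:
            raise ValueError(f"grouping {self.name!r}: samples not assigned: {missing}")
        counts = pd.Series([self.assignment[s] for s in table.samples]).value_counts()
        small = counts.index[counts < min_group_size].tolist()
        if small:
            raise ValueError(
                f"grouping {self.name!r}: subgroups with < {min_group_size} samples: {small}"
            )

    def labels(self, table: CtTable) -> pd.Series:
        return pd.Series([self.assignment[s] for s in table.samples], index=table.samples)


def fine_grouping(table: CtTable) -> GroupingScheme:
    """Each experimental group is its own subgroup (source × strain × tumor)."""
    return GroupingScheme(name="fine", assignment=dict(table.group_of))


def coarse_grouping(
    table: CtTable, tumor_markers: tuple[str, ...] = ("LLC", "RLS40")
) -> GroupingScheme:
    """Two subgroups only: healthy vs tumor-bearing.

    A sample is "tumor" when its group label contains any of
    ``tumor_markers`` (matches the default study design's labels).
    """
    assignment = {
        s: "tumor" if any(m in g for m in tumor_markers) else "healthy"
        for s, g in table.group_of.items()
    }
    return GroupingScheme(name="coarse", assignment=assignment)


@dataclass
class NormFinderResult:
    """Per-gene/per-group decomposition behind the stability values.

    ``d`` holds raw intergroup differences, ``d_shrunk`` their shrunken
    versions, ``sigma2`` the corrected intragroup variances (cycles²),
    ``gamma2`` the between-group variance of the d's, ``rho`` the combined
    stability value per gene (cycles).
    """

    d: pd.DataFrame
    d_shrunk: pd.DataFrame
    sigma2: pd.DataFrame
    gamma2: float
    rho: pd.Series
    grouping: str


def _group_decomposition(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within one group: gene profile means and residual variances.

    ``y`` is genes × samples. Returns (a, s2): per-gene means after
    sample-centering, and naive per-gene residual variances (ddof 1) of the
    two-way (gene + sample) decomposition.
    """
    centered = y - y.mean(axis=0, keepdims=True)
    a = centered.mean(axis=1)
    z = centered - a[:, None]
    n = y.shape[1]
    s2 = (z**2).sum(axis=1) / (n - 1)
    return a, s2


def _corrected_sigma2(s2: np.ndarray, k: int) -> np.ndarray:
    """Undo the bias of sample-centering on k genes; floor at zero."""
    return np.maximum(0.0, (k / (k - 2)) * (s2 - s2.sum() / (k * (k - 1))))


def normfinder_stability(
    table: CtTable, grouping: GroupingScheme | Mapping[str, str] | None = None
) -> tuple[NormFinderResult, StabilityRanking]:
    """Stability values combining intragroup variance and intergroup bias.

    Requires ≥3 genes and ≥2 samples per subgroup. With a single subgroup
    this reduces exactly to :func:`normfinder_ungrouped`.
    """
    if grouping is None:
        grouping = fine_grouping(table)
    elif not isinstance(grouping, GroupingScheme):
        grouping = GroupingScheme(name="custom", assignment=dict(grouping))
    grouping.validate(table)
    genes = table.genes
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    wide = table.matrix()
    labels = grouping.labels(table)
    group_names = list(pd.unique(labels))
    g = len(group_names)

    if g == 1:
        ranking = normfinder_ungrouped(table)
        zeros = pd.DataFrame(0.0, index=genes, columns=group_names)
        sigma2 = pd.DataFrame(
            (ranking.values**2).to_numpy()[:, None], index=genes, columns=group_names
        )
        result = NormFinderResult(
            d=zeros, d_shrunk=zeros.copy(), sigma2=sigma2, gamma2=0.0,
            rho=ranking.values.copy(), grouping=grouping.name,
        )
        return result, StabilityRanking(
            method="NormFinder", values=ranking.values, ranks=ranking.ranks
        )

    a = np.zeros((k, g))
    sigma2 = np.zeros((k, g))
    n_per = np.zeros(g, dtype=int)
    for gi, name in enumerate(group_names):
        cols = labels.index[labels == name]
        y = wide[cols].to_numpy()
        n_per[gi] = y.shape[1]
        a[:, gi], s2 = _group_decomposition(y)
        sigma2[:, gi] = _corrected_sigma2(s2, k)

    d = a - a.mean(axis=1, keepdims=True)  # double-centered: rows and columns sum to 0
    v = sigma2 / n_per[None, :]  # sampling variance of each d estimate
    gamma2 = max(0.0, float((d**2).sum() / ((k - 1) * (g - 1)) - v.mean()))
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + v)
    else:
        shrink = np.zeros_like(v)
    d_shrunk = d * shrink
    rho_arr = (np.abs(d_shrunk) + np.sqrt(v)).mean(axis=1)
    rho = pd.Series(rho_arr, index=genes)

    if np.allclose(rho_arr, 0.0):
        warnings.warn("degenerate table: all stability values are zero", stacklevel=2)

    result = NormFinderResult(
        d=pd.DataFrame(d, index=genes, columns=group_names),
        d_shrunk=pd.DataFrame(d_shrunk, index=genes, columns=group_names),
        sigma2=pd.DataFrame(sigma2, index=genes, columns=group_names),
        gamma2=gamma2,
        rho=rho,
        grouping=grouping.name,
    )
    ranking = StabilityRanking(method="NormFinder", values=rho, ranks=average_ranks(rho))
    return result, ranking


def normfinder_ungrouped(table: CtTable) -> StabilityRanking:
    """Single-group limit: rho = sqrt of the corrected residual variance.

    With no group structure there is no intergroup bias to estimate; a
    gene's stability is simply its residual SD after removing per-sample
    (loading) and per-gene (baseline) effects.
    """
    genes = table.genes
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    wide = table.matrix()
    if wide.shape[1] < 2:
        raise ValueError("NormFinder needs at least 2 samples")
    _, s2 = _group_decomposition(wide.to_numpy())
    sigma2 = _corrected_sigma2(s2, k)
    rho = pd.Series(np.sqrt(sigma2), index=genes)
    if np.allclose(rho.to_numpy(), 0.0):
        warnings.warn("degenerate table: all stability values are zero", stacklevel=2)
    return StabilityRanking(method="NormFinder", values=rho, ranks=average_ranks(rho))
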