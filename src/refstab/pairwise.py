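"""Pairwise stability algorithms: comparative ΔCt and geNorm, plus the
Pearson co-regulation diagnostic on linearized quantities.

Both methods score a gene by how constant its expression *ratio* to every
other candidate stays across samples. On the Ct (log2) scale a ratio is a
difference, so the pairwise variation V_jk is the standard deviation over
samples of Ct_k − Ct_j (equivalently, of the log-transformed expression
ratio of the linearized quantities). geNorm's stability measure M_j is the
mean of V_jk over all partners k ≠ j, recomputed while iteratively dropping
the worst gene until a final pair remains; the comparative ΔCt method stops
at the first pass and ranks by the same mean directly — the two are
algebraically identical at the first pass, a useful cross-check.

Both methods are blind to per-sample loading shifts and per-gene baselines
(they cancel in the ratio) — and therefore also blind to co-regulation:
two strongly correlated genes keep a low mutual variation no matter how
unstable they jointly are. The Pearson correlation matrix on linearized
quantities is the diagnostic for exactly that pitfall.
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
    "QuantityTable",
    "PairwiseVariation",
    "GenormResult",
    "linearize",
    "pairwise_variation",
    "delta_ct_stability",
    "genorm",
    "correlation_matrix",
]


@dataclass
class QuantityTable:
    """Relative quantities Q = base^(min Ct of gene − Ct), anchored per gene.

    0 < Q ≤ 1, with Q = 1 exactly at each gene's minimum-Ct sample. The
    anchor only affects readability: Pearson correlation and all ratio-based
    statistics are invariant to it.
    """

    q: pd.DataFrame  # genes × samples
    groups: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)


def _bases(table_genes: list[str], base: float | Mapping[str, float]) -> pd.Series:
    if isinstance(base, Mapping):
        missing = [g for g in table_genes if g not in base]
        if missing:
            raise ValueError(f"no base given for genes: {missing}")
        s = pd.Series({g: float(base[g]) for g in table_genes})
    else:
        s = pd.Series(float(base), index=table_genes)
    if (s <= 1).any():
        raise ValueError("log base must be > 1 (use 1 + efficiency, e.g. 2 for 100%)")
    return s


def linearize(table: CtTable, base: float | Mapping[str, float] = 2.0) -> QuantityTable:
    """Back-transform Ct to relative quantities.

    ``base`` is either a common amplification base (2 = perfect doubling) or
    a per-gene mapping gene → 1 + efficiency.
    """
    wide = table.matrix()
    b = _bases(list(wide.index), base)
    q = np.power(
        b.to_numpy()[:, None], (wide.min(axis=1).to_numpy()[:, None] - wide.to_numpy())
    )
    return QuantityTable(q=pd.DataFrame(q, index=wide.index, columns=wide.columns), groups=table.groups)


@dataclass
class PairwiseVariation:
    """Symmetric gene × gene matrix V and its row means M (excluding self)."""

    v: pd.DataFrame
    m: pd.Series


def _log_quantities(wide: pd.DataFrame, base: float | Mapping[str, float]) -> np.ndarray:
    """log2 of the linearized quantities; rows genes, columns samples."""
    b = _bases(list(wide.index), base).to_numpy()[:, None]
    anchored = wide.min(axis=1).to_numpy()[:, None] - wide.to_numpy()
    return anchored * np.log2(b)


def pairwise_variation(
    table: CtTable, base: float | Mapping[str, float] = 2.0
) -> PairwiseVariation:
    """V_jk = sample SD of the log2 expression ratio of genes j and k."""
    wide = table.matrix()
    if wide.shape[1] < 2:
        raise ValueError("pairwise variation needs at least 2 samples")
    logq = _log_quantities(wide, base)
    genes = list(wide.index)
    n = len(genes)
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            sd = float(np.std(logq[j] - logq[k], ddof=1))
            v[j, k] = v[k, j] = sd
    vf = pd.DataFrame(v, index=genes, columns=genes)
    m = vf.sum(axis=1) / (n - 1)
    return PairwiseVariation(v=vf, m=m)


def delta_ct_stability(table: CtTable) -> StabilityRanking:
    """Comparative ΔCt method: mean over partners of SD(Ct_j − Ct_k).

    For every gene pair the per-sample Ct difference is formed and its n−1
    SD taken over all samples pooled; a gene's stability value is the mean
    of those SDs over its partners. Lower = more stable.
    """
    wide = table.matrix()
    if len(wide) < 3:
        raise ValueError("comparative ΔCt needs at least 3 genes")
    if wide.shape[1] < 2:
        raise ValueError("comparative ΔCt needs at least 2 samples (SD undefined)")
    ct = wide.to_numpy()
    genes = list(wide.index)
    n = len(genes)
    pair_sd = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            sd = float(np.std(ct[j] - ct[k], ddof=1))
            pair_sd[j, k] = pair_sd[k, j] = sd
    values = pd.Series(pair_sd.sum(axis=1) / (n - 1), index=genes)
    return StabilityRanking(method="deltaCt", values=values, ranks=average_ranks(values))


@dataclass
class GenormResult:
    """Stepwise geNorm output.

    ``exclusion_order`` lists (gene, M at removal) from least to most stable
    among the removed; ``final_pair`` holds the two surviving genes with
    their common final M; ``initial_m`` is the first-pass M per gene;
    ``avg_m_trace`` records the mean M of the remaining genes at each step
    (non-increasing by construction).
    """

    exclusion_order: list[tuple[str, float]]
    final_pair: tuple[str, str]
    final_pair_m: float
    initial_m: pd.Series
    avg_m_trace: list[float]


def genorm(
    table: CtTable, base: float | Mapping[str, float] = 2.0
) -> tuple[GenormResult, StabilityRanking]:
    """geNorm: iterative exclusion of the gene with the highest M.

    The surviving pair is reported jointly at average rank 1.5; removed
    genes take ranks 3..G in reverse exclusion order, each with the M value
    it had when removed. A mid-iteration tie for the worst M removes the
    gene that appears later in input order (deterministic).
    """
    genes = table.genes
    if len(genes) < 3:
        raise ValueError("geNorm needs at least 3 genes")
    current = table
    exclusion: list[tuple[str, float]] = []
    initial_m: pd.Series | None = None
    trace: list[float] = []
    while True:
        pv = pairwise_variation(current, base=base)
        if initial_m is None:
            initial_m = pv.m.copy()
        trace.append(float(pv.m.mean()))
        remaining = list(pv.m.index)
        if len(remaining) == 2:
            final_pair = (remaining[0], remaining[1])
            final_m = float(pv.m.iloc[0])  # both rows equal by symmetry
            break
        worst_val = pv.m.max()
        # later-in-input-order member of any exact tie
        worst = [g for g in remaining if pv.m[g] == worst_val][-1]
        exclusion.append((worst, float(pv.m[worst])))
        current = current.subset_genes([g for g in remaining if g != worst])

    values = pd.Series(index=pd.Index(genes), dtype=float)
    ranks = pd.Series(index=pd.Index(genes), dtype=float)
    for g in final_pair:
        values[g] = final_m
        ranks[g] = 1.5
    for pos, (g, m_at_removal) in enumerate(reversed(exclusion), start=3):
        values[g] = m_at_removal
        ranks[g] = pos
    result = GenormResult(
        exclusion_order=exclusion,
        final_pair=final_pair,
        final_pair_m=final_m,
        initial_m=initial_m,
        avg_m_trace=trace,
    )
    ranking = StabilityRanking(method="geNorm", values=values, ranks=ranks, joint_top=final_pair)
    return result, ranking


def correlation_matrix(q: QuantityTable | CtTable) -> pd.DataFrame:
    """Gene × gene Pearson r across all samples pooled.

    Accepts a :class:`QuantityTable` (correlation on linearized quantities,
    the usual co-regulation diagnostic) or a raw :class:`CtTable`
    (correlation on Ct; unlike Pearson r on Q this is invariant to the
    linearization base). Zero-variance genes yield undefined correlations,
    reported as NaN with a warning.
    """
    values = q.q if isinstance(q, QuantityTable) else q.matrix()
    if values.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    constant = values.index[values.std(axis=1, ddof=1) == 0].tolist()
    if constant:
        warnings.warn(
            f"zero-variance genes have undefined correlations: {constant}", stacklevel=2
        )
    return values.T.corr(method="pearson")
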