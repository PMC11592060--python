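"""BestKeeper-style descriptive variation statistics on raw Ct.

BestKeeper judges each candidate reference gene by the dispersion of its
raw Ct values over *all* samples pooled (it is the only method here in which
genes do not influence each other's ranking). The classic tool reports, per
gene, the geometric and arithmetic mean Ct, the extreme values, a dispersion
"SD [± CP]" — a mean-absolute-deviation-type statistic — and the coefficient
of variation CV% = SD / arithmetic mean × 100. A gene with SD > 1 cycle is
considered inconsistent and unusable as a reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .core_io import CtTable
from .ranking import StabilityRanking

__all__ = [
    "BestKeeperStats",
    "descriptive_stats",
    "rank_by_variation",
    "flag_inconsistent",
    "bestkeeper_report",
]


@dataclass
class BestKeeperStats:
    """Per-gene frame with columns geo_mean, ar_mean, min_ct, max_ct, sd, cv_pct."""

    frame: pd.DataFrame
    sd_mode: str = "mad"

    def __post_init__(self) -> None:
        needed = {"geo_mean", "ar_mean", "min_ct", "max_ct", "sd", "cv_pct"}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"BestKeeperStats frame missing columns {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)


def descriptive_stats(table: CtTable, sd_mode: str = "mad") -> BestKeeperStats:
    """Pooled per-gene Ct statistics over all samples, ignoring groups.

    ``sd_mode`` selects the dispersion: ``"mad"`` is the mean absolute
    deviation from the arithmetic mean (the classic tool's "SD [± CP]");
    ``"sample_sd"`` is the n−1 standard deviation. CV% uses whichever mode
    is active.
    """
    if sd_mode not in {"mad", "sample_sd"}:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    wide = table.matrix()
    if (wide <= 0).any().any():
        raise ValueError("geometric mean undefined: non-positive Ct present")
    ar = wide.mean(axis=1)
    if sd_mode == "mad":
        sd = (wide.sub(ar, axis=0)).abs().mean(axis=1)
    else:
        sd = wide.std(axis=1, ddof=1)
    frame = pd.DataFrame(
        {
            "geo_mean": gmean(wide, axis=1),
            "ar_mean": ar,
            "min_ct": wide.min(axis=1),
            "max_ct": wide.max(axis=1),
            "sd": sd,
            "cv_pct": sd / ar * 100.0,
        },
        index=wide.index,
    )
    return BestKeeperStats(frame=frame, sd_mode=sd_mode)


def rank_by_variation(stats: BestKeeperStats) -> StabilityRanking:
    """Rank genes 1..G ascending by SD; ties by CV%, then input order."""
    frame = stats.frame
    if len(frame) < 2:
        raise ValueError("need stats for at least two genes to rank")
    order = sorted(
        range(len(frame)),
        key=lambda i: (frame["sd"].iloc[i], frame["cv_pct"].iloc[i], i),
    )
    ranks = pd.Series(0.0, index=frame.index)
    for pos, i in enumerate(order, start=1):
        ranks.iloc[i] = pos
    return StabilityRanking(method="BestKeeper", values=frame["sd"].copy(), ranks=ranks)


def flag_inconsistent(stats: BestKeeperStats, sd_limit: float = 1.0) -> set[str]:
    """Genes whose dispersion strictly exceeds ``sd_limit`` cycles."""
    frame = stats.frame
    return set(frame.index[frame["sd"] > sd_limit])


def bestkeeper_report(stats: BestKeeperStats, ranking: StabilityRanking) -> pd.DataFrame:
    """Classic report layout: statistics as rows, genes as columns, 2 d.p."""
    rows = {
        "Geo Mean [CP]": stats.frame["geo_mean"],
        "Ar Mean [CP]": stats.frame["ar_mean"],
        "min [CP]": stats.frame["min_ct"],
        "max [CP]": stats.frame["max_ct"],
        "SD [+/-CP]": stats.frame["sd"],
        "CV [% CP]": stats.frame["cv_pct"],
    }
    out = pd.DataFrame(rows).T.round(2)
    out.loc[f"Ranking [1->{len(stats.frame)}]"] = ranking.ranks.to_numpy()
    return out
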