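"""Amplification-efficiency standard curves from dilution-series Ct data.

A serial dilution of pooled cDNA gives one Ct per (dilution, replicate);
ordinary least squares of Ct on log10 relative concentration yields the
slope, from which the per-cycle amplification efficiency is

    E% = (10 ** (-1 / slope) - 1) * 100

A slope of -3.3219 (= -1/log10(2)) corresponds to perfect doubling, E = 100%.
Practically usable assays fall in the 90–110% window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyResult",
    "fit_standard_curve",
    "read_dilution_table",
    "efficiency_table",
    "PERFECT_SLOPE",
]

#: Slope of a perfectly doubling assay, -1/log10(2).
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass
class DilutionSeries:
    """Dilution points for one gene: (log10 relative concentration, Ct).

    Undiluted material is log10 concentration 0, a 10-fold dilution -1, and
    so on. Replicates are separate points and enter the regression
    individually.
    """

    gene: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        concs = {x for x, _ in self.points}
        if len(concs) < 3:
            raise ValueError(
                f"{self.gene}: need >= 3 distinct concentrations, got {len(concs)}"
            )
        if max(concs) - min(concs) < 2.0:
            warnings.warn(
                f"{self.gene}: dilution series spans < 2 log10 units; "
                "the efficiency estimate will be unreliable",
                stacklevel=2,
            )

    @classmethod
    def from_dilution_factors(
        cls, gene: str, dilution_factors: list[float], cts: list[float]
    ) -> "DilutionSeries":
        """Build from fold-dilutions (1, 10, 100, ...) instead of log10 units."""
        if len(dilution_factors) != len(cts):
            raise ValueError("dilution_factors and cts must have equal length")
        pts = [(-np.log10(f), ct) for f, ct in zip(dilution_factors, cts)]
        return cls(gene, pts)


@dataclass
class EfficiencyResult:
    gene: str
    slope: float
    intercept: float
    efficiency_pct: float
    r_squared: float
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def fit_standard_curve(
    series: DilutionSeries, efficiency_window: tuple[float, float] = (90.0, 110.0)
) -> EfficiencyResult:
    """OLS fit Ct = a + slope * log10(concentration) and derived efficiency.

    A positive slope is physically invalid (Ct must rise as template is
    diluted) and is returned flagged rather than raised, so a whole panel can
    be screened in one pass.
    """
    x = np.array([p[0] for p in series.points], dtype=float)
    y = np.array([p[1] for p in series.points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"{series.gene}: all concentrations identical; no slope")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope == 0:
        raise ValueError(f"{series.gene}: zero slope; efficiency undefined")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    r2 = float(fit.rvalue**2)
    flags = []
    if slope > 0:
        flags.append("invalid: positive slope")
    lo, hi = efficiency_window
    if not (lo <= eff <= hi):
        flags.append(f"efficiency outside [{lo:g}, {hi:g}]%")
    return EfficiencyResult(
        gene=series.gene,
        slope=slope,
        intercept=float(fit.intercept),
        efficiency_pct=float(eff),
        r_squared=r2,
        flags=flags,
    )


def read_dilution_table(path: str | Path, sep: str | None = None) -> list[DilutionSeries]:
    """Read ``gene, dilution_factor, ct`` rows into per-gene series."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"gene", "dilution_factor", "ct"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}")
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        out.append(
            DilutionSeries.from_dilution_factors(
                str(gene), sub["dilution_factor"].tolist(), sub["ct"].tolist()
            )
        )
    return out


def efficiency_table(series: list[DilutionSeries]) -> pd.DataFrame:
    """Fit every series and tabulate slope, E% and R² per gene."""
    rows = []
    for s in series:
        r = fit_standard_curve(s)
        rows.append(
            {
                "gene": r.gene,
                "slope": r.slope,
                "efficiency_pct": r.efficiency_pct,
                "r_squared": r.r_squared,
                "flags": "; ".join(r.flags),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
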