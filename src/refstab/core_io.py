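"""Ct-table data model, delimited-file I/O, replicate collapse and QC.

The universal pipeline input is a complete genes × samples matrix of
cycle-threshold (Ct) values, each sample carrying exactly one group label.
Tables are held tidy internally (one observation per row) so that technical
replicates can be kept distinct until they are explicitly collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "CtTableError",
    "QCReport",
    "read_ct_table",
    "write_ct_table",
    "read_group_map",
    "collapse_replicates",
    "validate_ct_table",
]

LONG_COLUMNS = ("sample", "group", "gene", "ct")


class CtTableError(ValueError):
    """Raised when a Ct table violates its contract."""


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass
class CtTable:
    """Tidy Ct table: columns ``gene, sample, group, ct`` (+ ``replicate``).

    Gene and sample order follow first appearance in the input and are
    preserved through every operation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in ("gene", "sample", "group", "ct") if c not in df.columns]
        if missing:
            raise CtTableError(f"missing required columns: {missing}")
        if "replicate" not in df.columns:
            df["replicate"] = 1
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = df.index[ct.isna()]
        if len(bad):
            row = df.loc[bad[0]]
            raise CtTableError(
                f"non-numeric Ct value {df.loc[bad[0], 'ct']!r} for "
                f"(gene={row['gene']}, sample={row['sample']})"
            )
        df["ct"] = ct.astype(float)
        if not np.isfinite(df["ct"]).all():
            raise CtTableError("Ct values must be finite")
        if (df["ct"] <= 0).any():
            offender = df.loc[df["ct"] <= 0].iloc[0]
            raise CtTableError(
                f"Ct values must be strictly positive; got {offender['ct']} for "
                f"(gene={offender['gene']}, sample={offender['sample']})"
            )
        dup = df.duplicated(subset=["gene", "sample", "replicate"], keep=False)
        if dup.any():
            g, s, r = df.loc[dup.idxmax(), ["gene", "sample", "replicate"]]
            raise CtTableError(f"duplicate observation (gene={g}, sample={s}, replicate={r})")
        n_groups = df.groupby("sample", sort=False)["group"].nunique()
        if (n_groups > 1).any():
            bad_sample = n_groups.index[(n_groups > 1).to_numpy().argmax()]
            raise CtTableError(f"sample {bad_sample!r} carries more than one group label")
        self.data = df.reset_index(drop=True)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame, groups: Mapping[str, str]) -> "CtTable":
        """Build from a genes × samples matrix and a sample → group map."""
        unknown = [s for s in matrix.columns if s not in groups]
        if unknown:
            raise CtTableError(f"samples missing from group map: {unknown}")
        long = matrix.rename_axis("gene").reset_index().melt(
            id_vars="gene", var_name="sample", value_name="ct"
        )
        long["group"] = long["sample"].map(dict(groups))
        return cls(long[["sample", "group", "gene", "ct"]])

    # -- basic accessors ----------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def group_of(self) -> dict[str, str]:
        return dict(self.data.drop_duplicates("sample")[["sample", "group"]].values)

    @property
    def groups(self) -> pd.Series:
        """Sample-indexed group labels, in sample order."""
        g = self.group_of
        return pd.Series([g[s] for s in self.samples], index=self.samples, name="group")

    @property
    def group_labels(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    @property
    def has_replicates(self) -> bool:
        return bool(self.data.duplicated(subset=["gene", "sample"]).any())

    def matrix(self) -> pd.DataFrame:
        """Complete genes × samples Ct matrix (requires collapsed replicates)."""
        if self.has_replicates:
            raise CtTableError(
                "table still has technical replicates; call collapse_replicates first"
            )
        wide = self.data.pivot(index="gene", columns="sample", values="ct")
        wide = wide.reindex(index=self.genes, columns=self.samples)
        if wide.isna().any().any():
            missing = [
                (g, s)
                for g in wide.index
                for s in wide.columns
                if pd.isna(wide.at[g, s])
            ]
            raise CtTableError(f"incomplete Ct matrix; missing (gene, sample) pairs: {missing}")
        wide.columns.name = None
        wide.index.name = "gene"
        return wide

    def subset_genes(self, genes: Iterable[str]) -> "CtTable":
        keep = list(genes)
        unknown = [g for g in keep if g not in self.genes]
        if unknown:
            raise CtTableError(f"unknown genes: {unknown}")
        df = self.data[self.data["gene"].isin(keep)]
        return CtTable(df.reset_index(drop=True))


@dataclass
class QCReport:
    """Applicability QC of a Ct table.

    ``flagged_cells`` lists exactly the cells at or above the Ct
    applicability threshold (the usable range is strictly below it).
    """

    flagged_cells: list[tuple[str, str, float, str]]
    n_groups: int
    n_samples_per_group: dict[str, int]
    ct_range: tuple[float, float]
    max_ct: float = 40.0

    @property
    def passed(self) -> bool:
        return not self.flagged_cells

    def to_dict(self) -> dict:
        return {
            "flagged_cells": [list(c) for c in self.flagged_cells],
            "n_groups": self.n_groups,
            "n_samples_per_group": self.n_samples_per_group,
            "ct_range": list(self.ct_range),
            "max_ct": self.max_ct,
            "passed": self.passed,
        }


# -- file I/O ---------------------------------------------------------


def read_group_map(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column ``sample,group`` file into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    cols = [c.lower() for c in df.columns]
    if "sample" in cols and "group" in cols:
        df.columns = cols
    elif df.shape[1] == 2:
        df.columns = ["sample", "group"]
    else:
        raise CtTableError(f"group map {path} needs columns sample,group")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    group_map: Mapping[str, str] | str | Path | None = None,
    sep: str | None = None,
) -> CtTable:
    """Read a Ct table from a delimited file.

    Long layout needs columns ``sample, group, gene, ct`` (``group`` may be
    supplied via ``group_map`` instead; an optional ``replicate`` column keeps
    technical replicates distinct). Wide layout has genes as rows and samples
    as columns, with groups from ``group_map`` (mapping or two-column file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path, sep)
    if isinstance(group_map, (str, Path)):
        group_map = read_group_map(group_map)

    if layout == "long":
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.strip().lower() for c in df.columns]
        if "group" not in df.columns:
            if group_map is None:
                raise CtTableError("long table without a group column needs group_map")
            df["group"] = df["sample"].map(dict(group_map))
            if df["group"].isna().any():
                unknown = df.loc[df["group"].isna(), "sample"].unique().tolist()
                raise CtTableError(f"samples missing from group_map: {unknown}")
        needed = [c for c in LONG_COLUMNS if c not in df.columns]
        if needed:
            raise CtTableError(f"long layout requires columns {LONG_COLUMNS}; missing {needed}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        if ct.isna().any():
            line = int(df.index[ct.isna()][0]) + 2  # 1-based + header
            raise CtTableError(f"non-numeric Ct at {path}:{line}")
        cols = [c for c in ("sample", "group", "gene", "ct", "replicate") if c in df.columns]
        return CtTable(df[cols])

    if layout == "wide":
        df = pd.read_csv(path, sep=sep)
        ct = df.set_index(df.columns[0])
        ct.index = ct.index.astype(str)
        ct.columns = ct.columns.astype(str)
        bad = ct.apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            gene = bad.index[bad.isna().any(axis=1)][0]
            raise CtTableError(f"non-numeric Ct in row for gene {gene!r} of {path}")
        if group_map is None:
            raise CtTableError("wide layout requires a group_map")
        return CtTable.from_matrix(bad, group_map)

    raise CtTableError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_ct_table(
    table: CtTable,
    path: str | Path,
    layout: str = "long",
    group_path: str | Path | None = None,
    sep: str | None = None,
    float_format: str = "%.4f",
) -> None:
    """Write a Ct table; wide layout stores groups in ``group_path``."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    if layout == "long":
        cols = ["sample", "group", "gene", "ct"]
        if table.has_replicates:
            cols.append("replicate")
        table.data[cols].to_csv(path, sep=sep, index=False, float_format=float_format)
    elif layout == "wide":
        table.matrix().to_csv(path, sep=sep, float_format=float_format)
        if group_path is not None:
            table.groups.rename_axis("sample").to_csv(Path(group_path), sep=sep)
    else:
        raise CtTableError(f"unknown layout {layout!r}")


# -- replicate handling ----------------------------------------------


def collapse_replicates(
    table: CtTable, spread_limit: float = 0.5
) -> tuple[CtTable, pd.DataFrame]:
    """Average technical replicates to one Ct per gene × sample.

    Returns the collapsed table and a side report with the within-cell
    replicate spread (max − min); cells whose spread exceeds
    ``spread_limit`` cycles are flagged for inspection, never dropped.
    """
    grouped = table.data.groupby(["gene", "sample"], sort=False)
    agg = grouped["ct"].agg(["mean", "min", "max", "count"]).reset_index()
    agg["spread"] = agg["max"] - agg["min"]
    agg["flagged"] = agg["spread"] > spread_limit
    report = agg.rename(columns={"count": "n_replicates", "mean": "ct"})[
        ["gene", "sample", "n_replicates", "ct", "spread", "flagged"]
    ]
    group_of = table.group_of
    collapsed = report[["gene", "sample", "ct"]].copy()
    collapsed["group"] = collapsed["sample"].map(group_of)
    return CtTable(collapsed[["sample", "group", "gene", "ct"]]), report


# -- QC ---------------------------------------------------------------


def validate_ct_table(table: CtTable, max_ct: float = 40.0) -> QCReport:
    """Applicability QC: flag cells outside the usable Ct range (< max_ct).

    A Ct at or beyond the threshold means the transcript was effectively
    not quantified; such cells are flagged, not removed. Incomplete
    matrices raise (the stability algorithms assume complete data).
    """
    wide = table.matrix()  # raises on incomplete matrices, naming the pairs
    flagged = [
        (g, s, float(wide.at[g, s]), f"Ct >= {max_ct:g} (outside applicable range)")
        for g in wide.index
        for s in wide.columns
        if wide.at[g, s] >= max_ct
    ]
    sizes = table.groups.value_counts(sort=False).to_dict()
    return QCReport(
        flagged_cells=flagged,
        n_groups=len(sizes),
        n_samples_per_group={str(k): int(v) for k, v in sizes.items()},
        ct_range=(float(wide.min().min()), float(wide.max().max())),
        max_ct=max_ct,
    )
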