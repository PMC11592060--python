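"""ΔΔCt relative quantification and reference-choice sensitivity.

For a target gene, a reference gene (or the mean of several), a control
group and a case group:

    dCt(group)  = mean Ct_target - mean Ct_reference      (within the group)
    ddCt        = dCt(case) - dCt(control)
    fold change = base ** (-ddCt)                          (base 2 by default)

A reference that itself moves between the groups by δ cycles multiplies the
apparent fold change by base**δ — which is exactly why reference-gene
stability matters. :func:`compare_references` quantifies that sensitivity
across candidate references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CtTable

__all__ = ["FoldChangeResult", "ddct_fold_change", "compare_references"]


@dataclass
class FoldChangeResult:
    """Group-mean ΔΔCt estimate plus per-sample fold values.

    ``fold_change`` is the headline group-mean estimate, expressed relative
    to the control group (control ≡ 1). ``per_sample_fold`` maps group →
    sample-resolved fold values (each sample's ΔCt against the control-group
    mean ΔCt), whose mean ± SD is what bar plots usually display.
    """

    target: str
    references: tuple[str, ...]
    control_group: str
    case_group: str
    delta_ct_control: float
    delta_ct_case: float
    ddct: float
    fold_change: float
    base: float = 2.0
    per_sample_fold: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def per_sample_mean_sd(self) -> dict[str, tuple[float, float]]:
        return {
            g: (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)
            for g, v in self.per_sample_fold.items()
        }


def _reference_ct(wide: pd.DataFrame, references: tuple[str, ...]) -> pd.Series:
    # arithmetic mean of Ct == geometric mean on the quantity scale
    return wide.loc[list(references)].mean(axis=0)


def ddct_fold_change(
    table: CtTable,
    target: str,
    reference: str | Sequence[str],
    control_group: str,
    case_group: str,
    base: float = 2.0,
) -> FoldChangeResult:
    """Fold change of ``target`` in ``case_group`` vs ``control_group``.

    ``reference`` may be one gene or several (normalization to their
    geometric-mean expression). Ct means are taken per group; per-sample
    fold values are reported alongside.
    """
    refs = (reference,) if isinstance(reference, str) else tuple(reference)
    if target in refs:
        raise ValueError(f"reference gene equals target gene {target!r}")
    for gene in (target, *refs):
        if gene not in table.genes:
            raise ValueError(f"gene {gene!r} not in table")
    groups = table.groups
    for grp in (control_group, case_group):
        if grp not in set(groups):
            raise ValueError(f"group {grp!r} not in table")
    wide = table.matrix()
    ref_ct = _reference_ct(wide, refs)
    dct_samples = wide.loc[target] - ref_ct  # per-sample ΔCt

    dct = {}
    per_fold = {}
    for grp in (control_group, case_group):
        cols = groups.index[groups == grp]
        dct[grp] = float(dct_samples[cols].mean())
    for grp in (control_group, case_group):
        cols = groups.index[groups == grp]
        per_fold[grp] = base ** -(dct_samples[cols] - dct[control_group])

    ddct = dct[case_group] - dct[control_group]
    return FoldChangeResult(
        target=target,
        references=refs,
        control_group=control_group,
        case_group=case_group,
        delta_ct_control=dct[control_group],
        delta_ct_case=dct[case_group],
        ddct=float(ddct),
        fold_change=float(base**-ddct),
        base=base,
        per_sample_fold=per_fold,
    )


@dataclass
class ReferenceComparison:
    """Fold changes per candidate reference plus a divergence summary."""

    results: list[FoldChangeResult]
    divergence_ratio: float  # max fold / min fold across candidates
    conclusion_flips: bool  # qualitative call (fold >= threshold) differs
    threshold: float
    outlier_reference: str  # candidate farthest (in log2) from the median fold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            mean_sd = r.per_sample_mean_sd[r.case_group]
            rows.append(
                {
                    "reference": "/".join(r.references),
                    "delta_ct_control": r.delta_ct_control,
                    "delta_ct_case": r.delta_ct_case,
                    "ddct": r.ddct,
                    "fold_change": r.fold_change,
                    "case_fold_mean": mean_sd[0],
                    "case_fold_sd": mean_sd[1],
                }
            )
        return pd.DataFrame(rows).set_index("reference")


def compare_references(
    table: CtTable,
    target: str,
    candidate_references: Sequence[str],
    control_group: str,
    case_group: str,
    base: float = 2.0,
    threshold: float = 2.0,
) -> ReferenceComparison:
    """How much does the fold-change estimate depend on the reference?

    Runs :func:`ddct_fold_change` per candidate and summarizes: the max/min
    fold ratio, whether the qualitative conclusion (fold ≷ ``threshold``)
    flips between candidates, and which candidate deviates most from the
    median fold (the likely unstable reference).
    """
    if len(candidate_references) < 2:
        raise ValueError("need at least 2 candidate references to compare")
    results = [
        ddct_fold_change(table, target, ref, control_group, case_group, base=base)
        for ref in candidate_references
    ]
    folds = np.array([r.fold_change for r in results])
    log_folds = np.log2(folds)
    median_log = np.median(log_folds)
    outlier_idx = int(np.argmax(np.abs(log_folds - median_log)))
    above = folds >= threshold
    return ReferenceComparison(
        results=results,
        divergence_ratio=float(folds.max() / folds.min()),
        conclusion_flips=bool(above.any() and not above.all()),
        threshold=threshold,
        outlier_reference="/".join(results[outlier_idx].references),
    )
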