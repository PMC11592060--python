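"""Synthetic Ct-table generator with known ground-truth stability.

Generative model for gene g, sample j of group i::

    Ct_igj = B_g + L_ij + Delta_ig + eps_igj + c_g * eps_partner

* ``B_g`` — per-gene baseline Ct (expression level; lower Ct = higher
  expression).
* ``L_ij ~ N(0, sigma_loading^2)`` — per-sample loading shift shared by all
  genes of the sample (input-RNA amount). This is exactly the nuisance that
  reference-gene normalization exists to remove, so the generator always
  includes it.
* ``Delta_ig`` — condition-specific regulation of an unstable gene.
* ``eps_igj ~ N(0, sigma_g^2)`` — per-observation noise, Gaussian on the Ct
  (log2) scale, the standard qPCR error model.
* Optional coupling adds a fraction ``c_g`` of a partner gene's noise to
  emulate co-regulated pairs (the classic pitfall of pairwise stability
  methods).

The ground-truth instability of a gene combines its own noise, any coupled
noise, and the spread its regulation shifts induce across the design; the
loading shift is excluded because it is common-mode and cancels in every
normalization-based analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import CtTable

__all__ = [
    "GeneSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_ct",
    "default_study_design",
    "parameter_recovery_design",
    "TUMOR_GROUPS",
]

#: Labels of the tumor-bearing groups in the default study design.
TUMOR_GROUPS = ("SP-LLC", "SP-RLS40High", "SP-RLS40Low")


@dataclass
class GeneSpec:
    """Simulation parameters of one gene.

    ``group_shift`` maps group label → additive Ct shift (cycles) applied to
    every sample of that group (negative shift = up-regulation).
    ``coupled_to`` is ``(partner_gene, coefficient)``: the gene additionally
    receives ``coefficient`` times the partner's own noise draw.
    """

    name: str
    baseline: float
    sigma_noise: float = 0.2
    group_shift: dict[str, float] = field(default_factory=dict)
    coupled_to: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError(f"sigma_noise must be >= 0 for gene {self.name}")


@dataclass
class SimConfig:
    """Study design for the generator: groups, genes, seed, loading noise."""

    seed: int
    groups: list[tuple[str, int]]
    genes: list[GeneSpec]
    sigma_loading: float = 0.5
    baseline_window: tuple[float, float] = (12.0, 35.0)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must not be empty")
        if not self.groups:
            raise ValueError("group list must not be empty")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs n_samples >= 1")
        if self.sigma_loading < 0:
            raise ValueError("sigma_loading must be >= 0")
        lo, hi = self.baseline_window
        for g in self.genes:
            if not (lo <= g.baseline <= hi):
                raise ValueError(
                    f"baseline {g.baseline} of gene {g.name} outside window [{lo}, {hi}]"
                )
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    # round-trip to a plain key/value tree so designs can live in config files
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "sigma_loading": self.sigma_loading,
            "baseline_window": list(self.baseline_window),
            "groups": [{"label": l, "n_samples": n} for l, n in self.groups],
            "genes": [
                {
                    "name": g.name,
                    "baseline": g.baseline,
                    "sigma_noise": g.sigma_noise,
                    "group_shift": dict(g.group_shift),
                    **(
                        {"coupled_to": {"gene": g.coupled_to[0], "coefficient": g.coupled_to[1]}}
                        if g.coupled_to
                        else {}
                    ),
                }
                for g in self.genes
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        genes = []
        for g in doc["genes"]:
            coupled = g.get("coupled_to")
            genes.append(
                GeneSpec(
                    name=g["name"],
                    baseline=float(g["baseline"]),
                    sigma_noise=float(g.get("sigma_noise", 0.2)),
                    group_shift={k: float(v) for k, v in (g.get("group_shift") or {}).items()},
                    coupled_to=(coupled["gene"], float(coupled["coefficient"])) if coupled else None,
                )
            )
        return cls(
            seed=int(doc["seed"]),
            groups=[(d["label"], int(d["n_samples"])) for d in doc["groups"]],
            genes=genes,
            sigma_loading=float(doc.get("sigma_loading", 0.5)),
            baseline_window=tuple(doc.get("baseline_window", (12.0, 35.0))),
        )


@dataclass
class GroundTruth:
    """Known stability ordering of a simulated design."""

    true_instability: dict[str, float]
    true_order: list[str]  # most stable first

    def top(self, k: int) -> list[str]:
        return self.true_order[:k]


def _true_instability(config: SimConfig) -> dict[str, float]:
    sigma = {g.name: g.sigma_noise for g in config.genes}
    out: dict[str, float] = {}
    for g in config.genes:
        var = g.sigma_noise**2
        if g.coupled_to is not None:
            partner, coeff = g.coupled_to
            var += (coeff * sigma[partner]) ** 2
        # population variance of the per-sample shift over the whole design
        shifts = np.repeat(
            [g.group_shift.get(label, 0.0) for label, _ in config.groups],
            [n for _, n in config.groups],
        )
        var += float(np.var(shifts))
        out[g.name] = float(np.sqrt(var))
    return out


def simulate_ct(config: SimConfig) -> tuple[CtTable, GroundTruth]:
    """Draw one Ct table from the generative model (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    names = [g.name for g in config.genes]
    for g in config.genes:
        if g.coupled_to is not None and g.coupled_to[0] not in names:
            raise ValueError(f"gene {g.name} coupled to unknown gene {g.coupled_to[0]}")

    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for label, n in config.groups:
        for j in range(1, n + 1):
            sid = f"{label}_{j}"
            sample_ids.append(sid)
            group_of[sid] = label
    n_samples = len(sample_ids)

    loading = rng.normal(0.0, config.sigma_loading, size=n_samples)
    noise = {
        g.name: rng.normal(0.0, 1.0, size=n_samples) * g.sigma_noise for g in config.genes
    }

    rows = np.empty((len(config.genes), n_samples))
    for gi, g in enumerate(config.genes):
        shift = np.array([g.group_shift.get(group_of[s], 0.0) for s in sample_ids])
        ct = g.baseline + loading + shift + noise[g.name]
        if g.coupled_to is not None:
            partner, coeff = g.coupled_to
            ct = ct + coeff * noise[partner]
        rows[gi] = ct

    matrix = pd.DataFrame(rows, index=names, columns=sample_ids)
    table = CtTable.from_matrix(matrix, group_of)
    instability = _true_instability(config)
    order = sorted(names, key=lambda n: (instability[n], names.index(n)))
    return table, GroundTruth(true_instability=instability, true_order=order)


def default_study_design(seed: int = 0) -> SimConfig:
    """Seven groups × 3 pooled samples × 10 candidate reference genes.

    Emulates a murine-neutrophil RT-qPCR panel: healthy bone-marrow and
    spleen neutrophils from two strains plus three tumor-bearing spleen
    groups. Baselines sit near the per-gene mean Ct of such panels
    (B2m most abundant, Sdha least). Hprt1 and Tbp are the designed stable
    genes; Ywhaz is co-regulated with Tbp (shared noise plus a common
    spleen/bone-marrow contrast); Rpl13a, Rack1 and B2m are regulated in the
    tumor groups; Gapdh, Sdha, Eef2 and Actb are simply noisy.
    """
    groups = [
        ("BM-C57Bl", 3),
        ("SP-C57Bl", 3),
        ("BM-CBA", 3),
        ("SP-CBA", 3),
        ("SP-LLC", 3),
        ("SP-RLS40High", 3),
        ("SP-RLS40Low", 3),
    ]
    bm_up = {"BM-C57Bl": 0.2, "BM-CBA": 0.2}  # higher Ct in bone marrow
    tumor = lambda delta: {g: delta for g in TUMOR_GROUPS}
    genes = [
        GeneSpec("Actb", 20.2, sigma_noise=0.50),
        GeneSpec("Hprt1", 24.5, sigma_noise=0.15),
        GeneSpec("Gapdh", 19.0, sigma_noise=0.55),
        GeneSpec("Sdha", 28.0, sigma_noise=0.90),
        GeneSpec("Ywhaz", 22.0, sigma_noise=0.35, group_shift=dict(bm_up), coupled_to=("Tbp", 0.6)),
        GeneSpec("Tbp", 26.2, sigma_noise=0.20, group_shift=dict(bm_up)),
        GeneSpec("B2m", 18.1, sigma_noise=0.25, group_shift=tumor(-1.0)),
        GeneSpec("Eef2", 24.4, sigma_noise=0.75),
        GeneSpec("Rpl13a", 25.3, sigma_noise=0.35, group_shift=tumor(-1.5)),
        GeneSpec("Rack1", 22.6, sigma_noise=0.45, group_shift=tumor(-1.2)),
    ]
    return SimConfig(seed=seed, groups=groups, genes=genes, sigma_loading=0.5)


def parameter_recovery_design(seed: int = 0) -> SimConfig:
    """Recovery benchmark: two clearly stable genes among eight unstable ones.

    Tbp and Hprt1 get sigma = 0.1 cycles and no regulation; the other eight
    genes span sigma 0.3–1.0 cycles, three of them additionally regulated in
    the tumor groups with shifts up to 2 cycles (Rpl13a carries the largest).
    """
    base = default_study_design(seed)
    tumor = lambda delta: {g: delta for g in TUMOR_GROUPS}
    genes = [
        GeneSpec("Actb", 20.2, sigma_noise=0.30),
        GeneSpec("Hprt1", 24.5, sigma_noise=0.10),
        GeneSpec("Gapdh", 19.0, sigma_noise=0.40),
        GeneSpec("Sdha", 28.0, sigma_noise=1.00),
        GeneSpec("Ywhaz", 22.0, sigma_noise=0.45),
        GeneSpec("Tbp", 26.2, sigma_noise=0.10),
        GeneSpec("B2m", 18.1, sigma_noise=0.50, group_shift=tumor(-1.0)),
        GeneSpec("Eef2", 24.4, sigma_noise=0.70),
        GeneSpec("Rpl13a", 25.3, sigma_noise=0.60, group_shift=tumor(-2.0)),
        GeneSpec("Rack1", 22.6, sigma_noise=0.80, group_shift=tumor(1.5)),
    ]
    return SimConfig(seed=seed, groups=base.groups, genes=genes, sigma_loading=0.5)
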