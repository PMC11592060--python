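import numpy as np
import pandas as pd
import pytest

from refstab import BestKeeperStats, CtTable, StabilityRanking

GENES = ["Actb", "Hprt1", "Gapdh", "Sdha", "Ywhaz", "Tbp", "B2m", "Eef2", "Rpl13a", "Rack1"]

# Published BestKeeper statistics block for the ten-gene murine-neutrophil
# panel (21 samples): genes × {geo mean, arithmetic mean, min, max, SD, CV%}
# plus the published 1..10 ranking. Used as *input* for re-ranking checks.
PANEL_STATS = pd.DataFrame(
    {
        "geo_mean": [20.21, 24.48, 19.03, 27.93, 21.94, 26.23, 18.07, 24.36, 25.26, 22.63],
        "ar_mean": [20.23, 24.48, 19.05, 27.96, 21.97, 26.24, 18.08, 24.39, 25.28, 22.65],
        "min_ct": [18.69, 23.68, 17.74, 25.26, 20.47, 25.10, 16.73, 22.15, 23.58, 20.82],
        "max_ct": [21.76, 25.94, 21.17, 30.83, 23.63, 28.14, 19.65, 27.64, 27.07, 24.13],
        "sd": [0.63, 0.35, 0.63, 1.02, 0.88, 0.57, 0.55, 0.94, 0.95, 0.81],
        "cv_pct": [3.13, 1.43, 3.33, 3.64, 3.98, 2.18, 3.07, 3.87, 3.74, 3.59],
    },
    index=GENES,
)

PANEL_BESTKEEPER_RANKING = pd.Series(
    [4, 1, 5, 10, 7, 3, 2, 8, 9, 6], index=GENES, dtype=float
)

# Published per-method rank columns for the same panel (geNorm top pair
# Ywhaz/Tbp reported jointly, carried as average rank 1.5 each).
PANEL_METHOD_RANKS = {
    "BestKeeper": {"Hprt1": 1, "B2m": 2, "Tbp": 3, "Actb": 4, "Gapdh": 5,
                   "Rack1": 6, "Ywhaz": 7, "Eef2": 8, "Rpl13a": 9, "Sdha": 10},
    "NormFinder": {"Tbp": 1, "Hprt1": 2, "Gapdh": 3, "Ywhaz": 4, "Actb": 5,
                   "Eef2": 6, "Sdha": 7, "B2m": 8, "Rpl13a": 9, "Rack1": 10},
    "deltaCt": {"Tbp": 1, "Hprt1": 2, "Ywhaz": 3, "Gapdh": 4, "B2m": 5,
                "Actb": 6, "Sdha": 7, "Eef2": 8, "Rpl13a": 9, "Rack1": 10},
    "geNorm": {"Ywhaz": 1.5, "Tbp": 1.5, "Actb": 3, "Gapdh": 4, "Hprt1": 5,
               "B2m": 6, "Sdha": 7, "Eef2": 8, "Rpl13a": 9, "Rack1": 10},
}


def make_table(matrix, genes, samples, groups):
    """CtTable from a plain nested list and a sample → group mapping."""
    wide = pd.DataFrame(matrix, index=genes, columns=samples, dtype=float)
    return CtTable.from_matrix(wide, groups)


def random_table(rng, n_genes=5, n_samples=8, n_groups=2, loc=24.0, scale=1.5):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    groups = {s: f"grp{j % n_groups}" for j, s in enumerate(samples)}
    matrix = loc + rng.normal(0.0, scale, size=(n_genes, n_samples))
    return make_table(matrix, genes, samples, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def panel_stats():
    return BestKeeperStats(frame=PANEL_STATS.copy(), sd_mode="mad")


@pytest.fixture
def panel_method_rankings():
    rankings = []
    for method, ranks in PANEL_METHOD_RANKS.items():
        r = pd.Series({g: float(ranks[g]) for g in GENES})
        rankings.append(
            StabilityRanking(
                method=method,
                values=r.copy(),  # ranks stand in for the unpublished raw values
                ranks=r,
                joint_top=("Ywhaz", "Tbp") if method == "geNorm" else None,
            )
        )
    return rankings


@pytest.fixture
def toy_abc():
    """Three genes over three samples with hand-computable pair SDs."""
    return make_table(
        [[20, 21, 22], [25, 26, 27], [20, 20, 20]],
        ["A", "B", "C"],
        ["s1", "s2", "s3"],
        {"s1": "g", "s2": "g", "s3": "g"},
    )
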