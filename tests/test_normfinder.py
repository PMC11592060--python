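import numpy as np
import pytest

from refstab import (
    GeneSpec,
    GroupingScheme,
    SimConfig,
    coarse_grouping,
    fine_grouping,
    normfinder_stability,
    normfinder_ungrouped,
    simulate_ct,
)

from conftest import make_table, random_table
from oracles import normfinder_oracle


def two_group_map(samples):
    half = len(samples) // 2
    return {s: ("g1" if i < half else "g2") for i, s in enumerate(samples)}


class TestDegenerateAndErrors:
    def test_identical_gene_rows_give_all_zero_rho(self):
        samples = [f"s{i}" for i in range(6)]
        row = [20.0, 21.0, 20.5, 22.0, 21.5, 20.8]
        t = make_table([row, row, row], ["A", "B", "C"], samples, two_group_map(samples))
        with pytest.warns(UserWarning, match="degenerate"):
            result, ranking = normfinder_stability(t, fine_grouping(t))
        assert np.allclose(result.rho, 0.0)
        assert np.allclose(result.d, 0.0)
        assert len(set(ranking.ranks)) == 1  # fully tied

    def test_subgroup_of_one_sample_rejected(self, rng):
        t = random_table(rng, n_genes=4, n_samples=5)
        lonely = {s: ("solo" if i == 0 else "rest") for i, s in enumerate(t.samples)}
        with pytest.raises(ValueError, match="solo"):
            normfinder_stability(t, GroupingScheme("bad", lonely))

    def test_unassigned_sample_rejected(self, rng):
        t = random_table(rng, n_genes=4, n_samples=4)
        partial = {s: "g" for s in t.samples[:-1]}
        with pytest.raises(ValueError, match="not assigned"):
            normfinder_stability(t, GroupingScheme("partial", partial))

    def test_needs_three_genes(self, rng):
        t = random_table(rng, n_genes=2, n_samples=6)
        with pytest.raises(ValueError, match="3 genes"):
            normfinder_ungrouped(t)


class TestOracleEquivalence:
    def test_matches_literal_formula_evaluation(self, rng):
        """Vectorized rho agrees with an independent loop-based evaluation
        of the variance-decomposition formulas on small instances."""
        for _ in range(15):
            n_genes = int(rng.integers(4, 7))
            n_samples = int(rng.integers(6, 10))
            n_groups = int(rng.integers(2, 4))
            t = random_table(rng, n_genes=n_genes, n_samples=n_samples, n_groups=1)
            labels = [f"G{j % n_groups}" for j in range(n_samples)]
            scheme = GroupingScheme("test", dict(zip(t.samples, labels)))
            result, _ = normfinder_stability(t, scheme)
            expected = normfinder_oracle(t.matrix().to_numpy().tolist(), labels)
            assert np.allclose(result.rho.to_numpy(), expected, atol=1e-6)

    def test_ungrouped_matches_oracle(self, rng):
        t = random_table(rng, n_genes=5, n_samples=8)
        got = normfinder_ungrouped(t).values.to_numpy()
        expected = normfinder_oracle(
            t.matrix().to_numpy().tolist(), ["g"] * len(t.samples)
        )
        assert np.allclose(got, expected, atol=1e-10)


class TestContracts:
    def test_single_group_equals_ungrouped_exactly(self, rng):
        t = random_table(rng, n_genes=5, n_samples=8)
        one = GroupingScheme("one", {s: "all" for s in t.samples})
        _, grouped = normfinder_stability(t, one)
        ungrouped = normfinder_ungrouped(t)
        assert np.allclose(grouped.values.to_numpy(), ungrouped.values.to_numpy())
        assert grouped.ranks.equals(ungrouped.ranks)

    def test_zero_residual_gene_ranks_first(self):
        samples = [f"s{i}" for i in range(6)]
        loading = np.array([0.0, 0.5, -0.3, 0.8, 0.2, -0.6])
        rng = np.random.default_rng(4)
        matrix = np.vstack(
            [
                20.0 + loading,  # follows loading exactly: zero residual
                24.0 + loading + rng.normal(0, 0.5, 6),
                28.0 + loading + rng.normal(0, 0.5, 6),
            ]
        )
        t = make_table(matrix, ["A", "B", "C"], samples, dict.fromkeys(samples, "g"))
        ranking = normfinder_ungrouped(t)
        assert ranking.values["A"] == pytest.approx(0.0, abs=1e-9)
        assert ranking.ranks["A"] == 1.0

    def test_sigma_separation_recovered(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=seed,
                groups=[("g", 50)],
                genes=[
                    GeneSpec("tight", 24.0, sigma_noise=0.2),
                    GeneSpec("loose", 26.0, sigma_noise=0.8),
                    GeneSpec("mid", 22.0, sigma_noise=0.5),
                ],
                sigma_loading=0.5,
            )
            t, _ = simulate_ct(cfg)
            ranking = normfinder_ungrouped(t)
            if ranking.ranks["tight"] < ranking.ranks["loose"]:
                hits += 1
        assert hits / n_seeds >= 0.99

    def test_loading_and_gene_shift_invariance(self, rng):
        t = random_table(rng, n_genes=5, n_samples=8)
        scheme = GroupingScheme("two", two_group_map(t.samples))
        base, _ = normfinder_stability(t, scheme)
        wide = t.matrix().copy()
        wide += rng.normal(0, 2.0, wide.shape[1])[None, :]
        wide += rng.normal(0, 2.0, wide.shape[0])[:, None]
        t2 = make_table(wide.to_numpy(), t.genes, t.samples, t.group_of)
        shifted, _ = normfinder_stability(t2, scheme)
        assert np.allclose(base.rho.to_numpy(), shifted.rho.to_numpy(), atol=1e-9)

    def test_rho_monotone_in_group_shift_noise_free(self):
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("a" if i < 4 else "b") for i, s in enumerate(samples)}
        rhos = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            shift = np.array([0.0] * 4 + [delta] * 4)
            matrix = np.vstack(
                [
                    20.0 + shift,
                    np.full(8, 24.0),
                    np.full(8, 28.0),
                    np.linspace(21, 22, 8),  # mild structure to avoid full degeneracy
                ]
            )
            t = make_table(matrix, ["shifted", "B", "C", "D"], samples, groups)
            result, _ = normfinder_stability(t, GroupingScheme("ab", groups))
            rhos.append(result.rho["shifted"])
        assert all(a <= b + 1e-12 for a, b in zip(rhos, rhos[1:]))


class TestGroupingPresets:
    def test_fine_preset_mirrors_experimental_groups(self, rng):
        from refstab import default_study_design

        t, _ = simulate_ct(default_study_design(seed=2))
        fine = fine_grouping(t)
        assert len(set(fine.assignment.values())) == 7

    def test_coarse_preset_splits_healthy_vs_tumor(self):
        from refstab import default_study_design

        t, _ = simulate_ct(default_study_design(seed=2))
        coarse = coarse_grouping(t)
        labels = set(coarse.assignment.values())
        assert labels == {"healthy", "tumor"}
        n_tumor = sum(v == "tumor" for v in coarse.assignment.values())
        assert n_tumor == 9  # three tumor groups × 3 samples

    def test_both_presets_favor_designed_stable_genes_on_average(self):
        """Under either grouping, the designed stable pair's mean rank over
        repeated draws beats every noisy or regulated gene's mean rank."""
        from collections import defaultdict

        from refstab import default_study_design

        n_seeds = 50
        mean_rank = {"fine": defaultdict(float), "coarse": defaultdict(float)}
        for seed in range(n_seeds):
            t, truth = simulate_ct(default_study_design(seed=seed))
            for scheme in (fine_grouping(t), coarse_grouping(t)):
                _, ranking = normfinder_stability(t, scheme)
                for g in ranking.genes:
                    mean_rank[scheme.name][g] += ranking.ranks[g] / n_seeds
        stable = {"Hprt1", "Tbp"}
        for scheme_name, ranks in mean_rank.items():
            worst_stable = max(ranks[g] for g in stable)
            best_other = min(v for g, v in ranks.items() if g not in stable)
            assert worst_stable < best_other, (scheme_name, dict(ranks))
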