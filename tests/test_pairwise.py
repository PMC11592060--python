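import numpy as np
import pytest

from refstab import (
    GeneSpec,
    SimConfig,
    correlation_matrix,
    delta_ct_stability,
    genorm,
    linearize,
    pairwise_variation,
    simulate_ct,
)

from conftest import make_table, random_table
from oracles import mean_pair_sd_oracle


class TestLinearize:
    def test_powers_of_two(self):
        t = make_table([[20, 21, 22]], ["A"], ["s1", "s2", "s3"], dict.fromkeys(["s1", "s2", "s3"], "g"))
        q = linearize(t, base=2.0).q
        assert list(q.loc["A"]) == [1.0, 0.5, 0.25]

    def test_100pct_efficiency_equals_base_2(self, rng):
        t = random_table(rng)
        common = linearize(t, base=2.0).q
        per_gene = linearize(t, base={g: 2.0 for g in t.genes}).q
        assert np.allclose(common, per_gene)

    def test_custom_base(self):
        t = make_table([[20, 21]], ["A"], ["s1", "s2"], {"s1": "g", "s2": "g"})
        q = linearize(t, base=1.93).q
        assert q.loc["A", "s2"] == pytest.approx(1 / 1.93, abs=1e-4)
        assert q.loc["A", "s2"] == pytest.approx(0.5181, abs=1e-4)

    def test_q_bounded_and_anchored(self, rng):
        q = linearize(random_table(rng)).q
        assert ((q > 0) & (q <= 1)).all().all()
        assert np.allclose(q.max(axis=1), 1.0)

    def test_base_at_most_one_rejected(self, rng):
        with pytest.raises(ValueError, match="base"):
            linearize(random_table(rng), base=1.0)


class TestDeltaCt:
    def test_hand_computed_toy(self, toy_abc):
        ranking = delta_ct_stability(toy_abc)
        assert ranking.values["A"] == pytest.approx(0.5)
        assert ranking.values["B"] == pytest.approx(0.5)
        assert ranking.values["C"] == pytest.approx(1.0)
        assert ranking.ranks["A"] == ranking.ranks["B"] == 1.5
        assert ranking.ranks["C"] == 3.0

    def test_constant_offset_pair_has_zero_pair_sd(self):
        t = make_table(
            [[20, 21, 22], [25, 26, 27], [23, 22, 24]],
            ["A", "B", "C"],
            ["s1", "s2", "s3"],
            dict.fromkeys(["s1", "s2", "s3"], "g"),
        )
        pv = pairwise_variation(t)
        assert pv.v.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_identity_with_first_pass_genorm_m(self, rng):
        """SD of the log2 expression ratio equals SD of ΔCt, gene by gene."""
        for _ in range(25):
            t = random_table(rng, n_genes=rng.integers(3, 7), n_samples=rng.integers(3, 10))
            dct = delta_ct_stability(t).values
            m = pairwise_variation(t, base=2.0).m
            assert np.max(np.abs(dct.to_numpy() - m.to_numpy())) < 1e-9

    def test_matches_brute_force_oracle(self, rng):
        t = random_table(rng, n_genes=5, n_samples=6)
        expected = mean_pair_sd_oracle(t.matrix().to_numpy().tolist())
        got = delta_ct_stability(t).values.to_numpy()
        assert np.allclose(got, expected, atol=1e-10)

    def test_needs_two_samples(self):
        t = make_table([[20], [21], [22]], ["A", "B", "C"], ["s1"], {"s1": "g"})
        with pytest.raises(ValueError, match="2 samples"):
            delta_ct_stability(t)


class TestGenorm:
    def test_toy_exclusion_and_final_pair(self, toy_abc):
        result, ranking = genorm(toy_abc)
        assert result.initial_m["A"] == pytest.approx(0.5)
        assert result.initial_m["B"] == pytest.approx(0.5)
        assert result.initial_m["C"] == pytest.approx(1.0)
        assert result.exclusion_order[0][0] == "C"
        assert set(result.final_pair) == {"A", "B"}
        assert ranking.ranks["A"] == ranking.ranks["B"] == 1.5
        assert ranking.ranks["C"] == 3.0

    def test_proportional_pair_survives_to_the_end(self, rng):
        n = 6
        samples = [f"s{i}" for i in range(n)]
        base = rng.normal(24, 1.0, n)
        matrix = np.vstack(
            [
                base,
                base + 3.0,  # exactly proportional partner
                rng.normal(20, 1.0, n),
                rng.normal(27, 1.0, n),
            ]
        )
        t = make_table(matrix, ["A", "B", "X", "Y"], samples, dict.fromkeys(samples, "g"))
        result, _ = genorm(t)
        assert set(result.final_pair) == {"A", "B"}
        pv = pairwise_variation(t)
        assert pv.m["A"] == pytest.approx(pv.m["B"], abs=1e-12)

    def test_joint_pair_display_label(self, toy_abc):
        _, ranking = genorm(toy_abc)
        labels = ranking.display_labels()
        assert labels["A"] == labels["B"] == "A/B"
        assert labels["C"] == "C"

    def test_average_m_trace_non_increasing(self, rng):
        for _ in range(10):
            t = random_table(rng, n_genes=6, n_samples=8)
            result, _ = genorm(t)
            trace = result.avg_m_trace
            assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_needs_three_genes(self):
        t = make_table([[20, 21], [22, 23]], ["A", "B"], ["s1", "s2"], {"s1": "g", "s2": "g"})
        with pytest.raises(ValueError, match="3 genes"):
            genorm(t)


class TestShiftInvariance:
    def test_loading_and_gene_shifts_cancel(self, rng):
        t = random_table(rng, n_genes=5, n_samples=7)
        wide = t.matrix().copy()
        wide += rng.normal(0, 2.0, wide.shape[1])[None, :]  # per-sample loading
        wide += rng.normal(0, 2.0, wide.shape[0])[:, None]  # per-gene constant
        t2 = make_table(wide.to_numpy(), t.genes, t.samples, t.group_of)
        assert np.allclose(
            pairwise_variation(t).m.to_numpy(), pairwise_variation(t2).m.to_numpy(), atol=1e-9
        )
        assert np.allclose(
            delta_ct_stability(t).values.to_numpy(),
            delta_ct_stability(t2).values.to_numpy(),
            atol=1e-9,
        )


class TestCorrelation:
    def test_unit_diagonal(self, rng):
        corr = correlation_matrix(linearize(random_table(rng)))
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_ct_offset_gives_identical_quantities(self):
        samples = [f"s{i}" for i in range(5)]
        ct = np.array([20.0, 21.0, 20.5, 22.0, 21.5])
        t = make_table(
            np.vstack([ct, ct + 4.0, np.linspace(25, 29, 5)]),
            ["A", "B", "C"],
            samples,
            dict.fromkeys(samples, "g"),
        )
        q = linearize(t)
        assert np.allclose(q.q.loc["A"], q.q.loc["B"])
        assert correlation_matrix(q).loc["A", "B"] == pytest.approx(1.0)

    def test_independent_genes_are_uncorrelated(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=seed,
                groups=[("g", 200)],
                genes=[GeneSpec("A", 22.0, 0.5), GeneSpec("B", 26.0, 0.5), GeneSpec("C", 24.0, 0.5)],
                sigma_loading=0.0,
            )
            t, _ = simulate_ct(cfg)
            r = correlation_matrix(linearize(t)).loc["A", "B"]
            if abs(r) < 0.3:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_zero_variance_gene_warns_and_reports_nan(self):
        samples = ["s1", "s2", "s3"]
        t = make_table(
            [[20, 21, 22], [25, 25, 25], [23, 24, 22]],
            ["A", "B", "C"],
            samples,
            dict.fromkeys(samples, "g"),
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(linearize(t))
        assert np.isnan(corr.loc["A", "B"])
        assert corr.loc["A", "C"] == corr.loc["C", "A"]


class TestCorrelatedPairPitfall:
    def test_coupled_unstable_pair_wins_genorm(self):
        """Two co-regulated genes with large shared variance look stable to
        geNorm (their mutual ratio is constant) even though each is noisy —
        and their linearized quantities are strongly correlated."""
        pair_wins = 0
        rs = []
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=seed,
                groups=[("g1", 6), ("g2", 6)],
                genes=[
                    GeneSpec("P1", 26.0, sigma_noise=0.8),
                    GeneSpec("P2", 22.0, sigma_noise=0.1, coupled_to=("P1", 1.0)),
                    GeneSpec("A", 24.0, sigma_noise=0.4),
                    GeneSpec("B", 20.0, sigma_noise=0.4),
                    GeneSpec("C", 28.0, sigma_noise=0.4),
                ],
                sigma_loading=0.3,
            )
            t, _ = simulate_ct(cfg)
            result, _ = genorm(t)
            if set(result.final_pair) == {"P1", "P2"}:
                pair_wins += 1
            rs.append(correlation_matrix(linearize(t)).loc["P1", "P2"])
        assert pair_wins / n_seeds >= 0.9
        assert np.median(rs) > 0.8
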