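import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from devcomp.expression import ExpressionMatrix
from devcomp.jsd import (
    GeneWiseJSD,
    bootstrap_jsd,
    gene_wise_jsd,
    jsd_raw,
    normalize_jsd,
    prepare_for_jsd,
    similarity_drivers,
    stage_distribution,
    stage_pair_matrix,
)
from devcomp.simulate import SimulationConfig, SpeciesSpec, simulate_dataset


def _qmatrix(values, species="x"):
    """quantile_uniform matrix from raw values (already in [0,1])."""
    values = np.asarray(values, dtype=float)
    cols = [f"S{j:02d}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=cols)
    return ExpressionMatrix(species, data, "quantile_uniform", cols)


def _dist(p, species="x", stage="S00"):
    p = np.asarray(p, dtype=float)
    from devcomp.jsd import StageDistribution

    return StageDistribution(species, stage, [f"g{i}" for i in range(p.size)], p)


class TestStageDistribution:
    def test_simplex_normalization(self):
        m = _qmatrix([[0.2], [0.2], [0.4]])
        d = stage_distribution(m, ["g0", "g1", "g2"], "S00")
        np.testing.assert_allclose(d.p, [0.25, 0.25, 0.5])

    def test_already_normalized_unchanged(self):
        m = _qmatrix([[0.25], [0.25], [0.5]])
        d = stage_distribution(m, ["g0", "g1", "g2"], "S00")
        np.testing.assert_allclose(d.p, [0.25, 0.25, 0.5])

    def test_all_zero_stage_errors(self):
        m = _qmatrix([[0.0], [0.0]])
        with pytest.raises(ValueError, match="S00"):
            stage_distribution(m, ["g0", "g1"], "S00")

    def test_sums_to_one(self, rng):
        m = _qmatrix(rng.random((20, 1)))
        d = stage_distribution(m, [f"g{i}" for i in range(20)], "S00")
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)


class TestJsdRaw:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd_raw(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one_bit(self):
        assert jsd_raw(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_worked_value(self):
        # independent term-by-term oracle, frozen:
        # 0.5*[0.5*log2(0.5/0.75) + 0.5*log2(0.5/0.25)] + 0.5*[1*log2(1/0.75)]
        expected = 0.5 * (0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)) + \
            0.5 * np.log2(1 / 0.75)
        assert expected == pytest.approx(0.3112781244591328, abs=1e-12)
        assert jsd_raw(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_scipy_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(2, 40)
            p = rng.random(n)
            q = rng.random(n)
            p, q = p / p.sum(), q / q.sum()
            assert jsd_raw(p, q) == pytest.approx(
                jensenshannon(p, q, base=2) ** 2, abs=1e-10
            )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            jsd_raw(np.array([1.0]), np.array([0.5, 0.5]))


class TestGeneWise:
    def test_equal_components_zero(self):
        g = gene_wise_jsd(_dist([0.5, 0.5]), _dist([0.5, 0.5], species="y"))
        np.testing.assert_allclose(g.values, 0.0)

    def test_decomposition_identity(self, rng):
        p, q = rng.random(100), rng.random(100)
        p, q = p / p.sum(), q / q.sum()
        g = gene_wise_jsd(_dist(p), _dist(q, species="y"))
        assert g.values.sum() == pytest.approx(jsd_raw(p, q), abs=1e-12)

    def test_term_by_term_oracle(self, rng):
        p, q = rng.random(10), rng.random(10)
        p, q = p / p.sum(), q / q.sum()
        g = gene_wise_jsd(_dist(p), _dist(q, species="y"))
        for i in range(10):
            m = 0.5 * (p[i] + q[i])
            term = 0.5 * p[i] * np.log2(p[i] / m) + 0.5 * q[i] * np.log2(q[i] / m)
            assert g.values[i] == pytest.approx(term, abs=1e-12)


class TestStagePairMatrix:
    def test_identical_pseudo_species_zero_diagonal(self, rng):
        vals = rng.random((50, 4))
        m_a, m_b = _qmatrix(vals, "A"), _qmatrix(vals, "B")
        pairs = [(g, g) for g in m_a.data.index]
        grid = stage_pair_matrix(m_a, m_b, pairs).raw.to_numpy()
        np.testing.assert_allclose(np.diag(grid), 0.0, atol=1e-12)

    def test_grid_matches_per_cell_oracle(self, rng):
        m_a = _qmatrix(rng.random((30, 3)), "A")
        m_b = _qmatrix(rng.random((30, 2)), "B")
        pairs = [(g, g) for g in m_a.data.index]
        result = stage_pair_matrix(m_a, m_b, pairs)
        for sa in m_a.stages:
            for sb in m_b.stages:
                p = stage_distribution(m_a, [a for a, _ in pairs], sa)
                q = stage_distribution(m_b, [b for _, b in pairs], sb)
                assert result.raw.loc[sa, sb] == pytest.approx(
                    jsd_raw(p, q), abs=1e-12
                )

    def test_species_swap_transposes(self, rng):
        m_a = _qmatrix(rng.random((20, 3)), "A")
        m_b = _qmatrix(rng.random((20, 4)), "B")
        pairs = [(g, g) for g in m_a.data.index]
        ab = stage_pair_matrix(m_a, m_b, pairs).raw.to_numpy()
        ba = stage_pair_matrix(m_b, m_a, [(b, a) for a, b in pairs]).raw.to_numpy()
        np.testing.assert_allclose(ab, ba.T, atol=1e-12)

    def test_empty_orthologues_errors(self, rng):
        m = _qmatrix(rng.random((5, 2)))
        with pytest.raises(ValueError, match="empty"):
            stage_pair_matrix(m, m, [])


class TestBootstrap:
    def test_reproducible_given_seed(self, rng):
        m_a = _qmatrix(rng.random((40, 3)), "A")
        m_b = _qmatrix(rng.random((40, 3)), "B")
        pairs = [(g, g) for g in m_a.data.index]
        r1 = bootstrap_jsd(m_a, m_b, pairs, n_boot=5, seed=7)
        r2 = bootstrap_jsd(m_a, m_b, pairs, n_boot=5, seed=7)
        assert (r1.boot_mean.to_numpy() == r2.boot_mean.to_numpy()).all()
        assert (r1.boot_sd.to_numpy() == r2.boot_sd.to_numpy()).all()

    def test_identical_species_zero_diagonal(self, rng):
        vals = rng.random((40, 3))
        pairs = [(f"g{i}", f"g{i}") for i in range(40)]
        r = bootstrap_jsd(_qmatrix(vals, "A"), _qmatrix(vals, "B"), pairs,
                          n_boot=20, seed=1)
        np.testing.assert_allclose(np.diag(r.boot_mean.to_numpy()), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(r.boot_sd.to_numpy()), 0.0, atol=1e-12)

    def test_monte_carlo_consistency(self, rng):
        m_a = _qmatrix(rng.random((60, 2)), "A")
        m_b = _qmatrix(rng.random((60, 2)), "B")
        pairs = [(g, g) for g in m_a.data.index]
        raw = stage_pair_matrix(m_a, m_b, pairs).raw.to_numpy()
        r = bootstrap_jsd(m_a, m_b, pairs, n_boot=1000, seed=3)
        se = r.boot_sd.to_numpy() / np.sqrt(1000)
        # bootstrap mean within 3 SE + small-sample bias allowance of raw value
        assert (np.abs(r.boot_mean.to_numpy() - raw) <= 3 * se + 0.01).all()

    def test_sd_shrinks_with_orthologue_count(self, rng):
        # SD should scale roughly as 1/sqrt(n): ratio within 30% of sqrt(4)=2
        sds = []
        for n in (100, 400):
            m_a = _qmatrix(rng.random((n, 2)), "A")
            m_b = _qmatrix(rng.random((n, 2)), "B")
            pairs = [(g, g) for g in m_a.data.index]
            r = bootstrap_jsd(m_a, m_b, pairs, n_boot=200, seed=5)
            sds.append(r.boot_sd.to_numpy().mean())
        ratio = sds[0] / sds[1]
        assert 2.0 * 0.7 <= ratio <= 2.0 * 1.3

    def test_too_few_replicates_errors(self, rng):
        m = _qmatrix(rng.random((5, 2)))
        with pytest.raises(ValueError, match="2 bootstrap"):
            bootstrap_jsd(m, m, [("g0", "g0")], n_boot=1)


class TestNormalize:
    def _matrices(self, rng, n_comparisons=3):
        out = []
        for i in range(n_comparisons):
            m_a = _qmatrix(rng.random((30, 3)), f"A{i}")
            m_b = _qmatrix(rng.random((30, 3)), f"B{i}")
            pairs = [(g, g) for g in m_a.data.index]
            out.append(stage_pair_matrix(m_a, m_b, pairs))
        return out

    def test_global_extremes_map_to_unit_interval(self, rng):
        normed = normalize_jsd(self._matrices(rng), scope="global")
        pooled = np.concatenate([m.normalized.to_numpy().ravel() for m in normed])
        assert pooled.min() == pytest.approx(0.0, abs=1e-12)
        assert pooled.max() == pytest.approx(1.0, abs=1e-12)
        assert ((pooled >= 0) & (pooled <= 1)).all()

    def test_single_comparison_scopes_agree(self, rng):
        (m,) = normalize_jsd(self._matrices(rng, 1), scope="global")
        np.testing.assert_allclose(
            m.normalized.to_numpy(), m.relative.to_numpy(), atol=1e-12
        )

    def test_matches_formula_oracle(self, rng):
        matrices = self._matrices(rng)
        normed = normalize_jsd(matrices, scope="global")
        adjusted = [m.raw.to_numpy() / m.n_orthologues for m in matrices]
        lo = min(a.min() for a in adjusted)
        hi = max(a.max() for a in adjusted)
        for m, adj in zip(normed, adjusted):
            np.testing.assert_allclose(
                m.normalized.to_numpy(), (adj - lo) / (hi - lo), atol=1e-12
            )
            np.testing.assert_allclose(
                m.relative.to_numpy(),
                (adj - adj.min()) / (adj.max() - adj.min()),
                atol=1e-12,
            )

    def test_degenerate_collection_errors(self):
        vals = np.full((10, 2), 0.5)
        m = _qmatrix(vals, "A")
        pairs = [(g, g) for g in m.data.index]
        grid = stage_pair_matrix(m, _qmatrix(vals, "B"), pairs)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_jsd([grid], scope="per_comparison")


class TestSimilarityDrivers:
    def test_threshold_is_quarter_of_mode(self, rng):
        vals = np.concatenate([rng.normal(0.02, 0.002, 500).clip(1e-6),
                               rng.uniform(0.05, 0.2, 50)])
        g = similarity_drivers(GeneWiseJSD("t", [f"g{i}" for i in range(550)], vals))
        assert g.threshold == pytest.approx(0.25 * g.mode)
        assert g.mode == pytest.approx(0.02, abs=0.004)
        assert set(g.drivers) == {gn for gn, v in zip(g.genes, vals) if v < g.threshold}

    def test_scale_equivariance(self, rng):
        vals = rng.gamma(3, 0.01, 300)
        genes = [f"g{i}" for i in range(300)]
        g1 = similarity_drivers(GeneWiseJSD("t", genes, vals))
        g2 = similarity_drivers(GeneWiseJSD("t", genes, vals * 10))
        assert g2.mode == pytest.approx(10 * g1.mode, rel=1e-9)
        assert g2.threshold == pytest.approx(10 * g1.threshold, rel=1e-9)
        assert g1.drivers == g2.drivers

    def test_mode_matches_grid_search_oracle(self, rng):
        from scipy.stats import gaussian_kde

        vals = np.concatenate([rng.uniform(0, 0.004, 60), rng.gamma(4, 0.0075, 540)])
        g = similarity_drivers(GeneWiseJSD("t", [f"g{i}" for i in range(600)], vals))
        kde = gaussian_kde(vals, bw_method="silverman")
        grid = np.linspace(0, vals.max(), 512)
        brute_mode = grid[np.argmax([kde(x)[0] for x in grid[::8]]) * 8]
        assert abs(g.mode - brute_mode) <= (grid[1] - grid[0]) * 8

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="30"):
            similarity_drivers(GeneWiseJSD("t", ["g"] * 10, np.linspace(0, 1, 10)))

    def test_degenerate_distribution_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            similarity_drivers(GeneWiseJSD("t", ["g"] * 40, np.full(40, 0.1)))


class TestStageMatchingRecovery:
    def test_matched_species_diagonal_argmin(self):
        cfg = SimulationConfig(
            species=[SpeciesSpec("A", n_stages=6), SpeciesSpec("B", n_stages=6)],
            n_orthologous=500, n_archetypes=6,
            archetype_peaks=list(np.linspace(0, 1, 6)), archetype_width=0.09,
            seed=77,
        )
        mats, omap, _, _ = simulate_dataset(cfg)
        pairs = omap.one_to_one("A", "B")
        qa = prepare_for_jsd(mats["A"]["tpm"], [a for a, _ in pairs])
        qb = prepare_for_jsd(mats["B"]["tpm"], [b for _, b in pairs])
        (m,) = normalize_jsd([stage_pair_matrix(qa, qb, pairs)], scope="global")
        argmin = m.normalized.to_numpy().argmin(axis=1)
        assert (argmin == np.arange(6)).mean() >= 0.9
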