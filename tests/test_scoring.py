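import numpy as np
import pytest

from mwimotif import (
    CostParams,
    FractionGrid,
    SequenceParams,
    build_single_t2_dictionary,
    compute_costs,
    enumerate_motifs,
    entropy_penalty,
    normalize_and_aggregate,
    select_basis,
    similarity_threshold,
)
from mwimotif.motifs import fill_equivalent_t2
from mwimotif.simulate import normalize_curves


class TestEntropyPenalty:
    def test_pure_motif_is_zero(self):
        assert entropy_penalty([1.0], 3.0) == 0.0

    def test_even_split_is_ln2(self):
        assert np.isclose(entropy_penalty([0.5, 0.5], 1.0), np.log(2), atol=1e-6)

    def test_weighted_split(self):
        expected = 2.0 * (-0.3 * np.log(0.3) - 0.7 * np.log(0.7))
        assert np.isclose(entropy_penalty([0.3, 0.7], 2.0), expected, atol=1e-9)
        assert np.isclose(expected, 1.221729, atol=1e-6)

    def test_rejects_nonpositive_fraction(self):
        with pytest.raises(ValueError):
            entropy_penalty([0.0, 1.0], 1.0)


class TestSimilarityThreshold:
    @pytest.mark.parametrize(
        "delta,etl,expected",
        [(0.01, 11, 0.0011), (0.008, 24, 0.001536), (1.0, 1, 1.0)],
    )
    def test_values(self, delta, etl, expected):
        assert np.isclose(similarity_threshold(delta, etl), expected, rtol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            similarity_threshold(0.0, 11)
        with pytest.raises(ValueError):
            similarity_threshold(0.01, 0)


@pytest.fixture(scope="module")
def toy_motifs():
    seq = SequenceParams(etl=11, echo_spacing=12.0)
    d = build_single_t2_dictionary((15, 200, 5), (1.0, 1.0, 1), seq, "epg")
    m = enumerate_motifs(d, 2, FractionGrid(0.25))
    return fill_equivalent_t2(m)


class TestComputeCosts:
    def test_zero_residual_and_similarity(self, toy_motifs):
        sig = toy_motifs.signals[4, 0, :][None, :]
        table = compute_costs(toy_motifs, sig, None, CostParams(lambda_ent=0.0))
        assert np.isclose(table.alpha[4, 0], 0.0, atol=1e-24)
        assert np.isclose(table.kappa[4, 0], 0.0, atol=1e-24)
        assert 0 in table.similar_set(4)

    def test_clipping_rule(self, toy_motifs):
        """Residuals are clipped at clip_factor * xi before entering kappa."""
        sig = np.ones((1, toy_motifs.etl)) / np.sqrt(toy_motifs.etl)  # flat, far from decays
        p = CostParams(lambda_ent=0.0, delta_mv=0.001)
        table = compute_costs(toy_motifs, sig, None, p)
        xi = similarity_threshold(0.001, toy_motifs.etl)
        assert np.all(table.alpha[:, 0] > 5 * xi)  # all residuals exceed the clip level
        assert np.allclose(table.kappa[:, 0], 5 * xi)

    def test_hand_computed_kappa_table(self, toy_motifs):
        """kappa = min(alpha, 5 xi) + beta reproduced by direct arithmetic."""
        sigs = normalize_curves(
            np.stack([toy_motifs.signals[1, 0, :], toy_motifs.signals[7, 0, :]]), "unit_l2"
        )
        p = CostParams(lambda_ent=0.002, delta_mv=0.05)
        table = compute_costs(toy_motifs, sigs, None, p)
        xi = similarity_threshold(p.delta_mv, toy_motifs.etl)
        d = toy_motifs.signals_at_b1(1.0)
        for i in range(toy_motifs.n_motifs):
            beta = entropy_penalty(toy_motifs.motif_fractions(i), p.lambda_ent)
            for j in range(2):
                alpha = float(np.sum((d[i] - sigs[j]) ** 2))
                assert np.isclose(table.alpha[i, j], alpha, atol=1e-12)
                assert np.isclose(table.kappa[i, j], min(alpha, 5 * xi) + beta, atol=1e-12)

    def test_deterministic_and_chunk_invariant(self, toy_motifs):
        rng = np.random.default_rng(3)
        sigs = normalize_curves(np.abs(rng.normal(0.5, 0.2, (7, toy_motifs.etl))), "unit_l2")
        a = compute_costs(toy_motifs, sigs, None, CostParams(), chunk_size=2)
        b = compute_costs(toy_motifs, sigs, None, CostParams(), chunk_size=4096)
        assert np.allclose(a.kappa_sum, b.kappa_sum)
        assert np.allclose(a.kappa_max, b.kappa_max)
        assert np.array_equal(a.similar.toarray() > 0, b.similar.toarray() > 0)


class TestNormalizeAndAggregate:
    def test_kappa_hat_range_and_endpoints(self, toy_motifs):
        rng = np.random.default_rng(5)
        sigs = normalize_curves(np.abs(rng.normal(0.5, 0.2, (6, toy_motifs.etl))), "unit_l2")
        table = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        assert np.all((table.kappa_hat >= -1e-12) & (table.kappa_hat <= 1 + 1e-12))
        # per motif, the max-cost voxel normalizes to zero
        for i in range(table.n_motifs):
            assert np.isclose(table.kappa_hat[i].min(), 0.0, atol=1e-12)
        assert np.all(table.global_score >= -1e-9)
        assert np.all(table.global_score <= table.n_voxels + 1e-9)

    def test_zero_cost_voxel_scores_one(self, toy_motifs):
        sigs = np.stack([toy_motifs.signals[2, 0, :], np.ones(toy_motifs.etl)])
        sigs = normalize_curves(sigs, "unit_l2")
        table = normalize_and_aggregate(
            compute_costs(toy_motifs, sigs, None, CostParams(lambda_ent=0.0))
        )
        assert np.isclose(table.kappa_hat[2, 0], 1.0, atol=1e-12)

    def test_hand_summed_global_score(self, toy_motifs):
        rng = np.random.default_rng(11)
        sigs = normalize_curves(np.abs(rng.normal(0.5, 0.2, (3, toy_motifs.etl))), "unit_l2")
        table = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        manual = (1.0 - table.kappa / table.kappa.max(axis=1, keepdims=True)).sum(axis=1)
        assert np.allclose(table.global_score, manual, atol=1e-9)

    def test_voxel_order_invariance(self, toy_motifs):
        rng = np.random.default_rng(7)
        sigs = normalize_curves(np.abs(rng.normal(0.5, 0.2, (8, toy_motifs.etl))), "unit_l2")
        t1 = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        t2 = normalize_and_aggregate(compute_costs(toy_motifs, sigs[::-1], None, CostParams()))
        assert np.allclose(t1.global_score, t2.global_score)


class TestSelectBasis:
    def _signals_from(self, motifs, idx, n_each):
        rows = np.repeat(idx, n_each)
        return normalize_curves(motifs.signals[rows, 0, :], "unit_l2"), rows

    def test_known_motifs_recovered(self, toy_motifs):
        """Tissue built from three known motifs, noiseless: exactly those
        motifs form the basis."""
        truth = [0, 9, 17]
        sigs, _ = self._signals_from(toy_motifs, truth, 30)
        table = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        sel = select_basis(toy_motifs, table, signals=sigs)
        assert set(truth) <= set(sel.motif_indices.tolist())

    def test_duplicate_signals_select_once(self, toy_motifs):
        sigs, _ = self._signals_from(toy_motifs, [5], 40)
        table = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        sel = select_basis(toy_motifs, table, signals=sigs)
        assert len(sel.motif_indices) == 1

    def test_max_motifs_cap(self, toy_motifs):
        truth = [0, 9, 17]
        sigs, _ = self._signals_from(toy_motifs, truth, 30)
        table = normalize_and_aggregate(compute_costs(toy_motifs, sigs, None, CostParams()))
        sel = select_basis(toy_motifs, table, signals=sigs, max_motifs=1)
        assert len(sel.motif_indices) == 1
        # the kept motif is the highest-scoring one in the basis ordering
        assert sel.global_scores[0] == sel.global_scores.max()

    def test_all_dissimilar_raises(self, toy_motifs):
        flat = np.ones((5, toy_motifs.etl)) / np.sqrt(toy_motifs.etl)
        table = normalize_and_aggregate(
            compute_costs(toy_motifs, flat, None, CostParams(delta_mv=0.0001))
        )
        with pytest.raises(RuntimeError, match="delta_mv"):
            select_basis(toy_motifs, table, signals=flat)

    def test_entropy_weight_monotone_ranking(self):
        """Raising lambda_ent never promotes a higher-entropy motif over a
        lower-entropy one with an identical residual profile."""
        seq = SequenceParams(etl=11, echo_spacing=12.0)
        d = build_single_t2_dictionary((15, 200, 4), (1.0, 1.0, 1), seq, "epg")
        m = fill_equivalent_t2(enumerate_motifs(d, 2, FractionGrid(0.5)))
        rng = np.random.default_rng(2)
        sigs = normalize_curves(np.abs(rng.normal(0.5, 0.2, (10, m.etl))), "unit_l2")
        ent = np.array([entropy_penalty(m.motif_fractions(i), 1.0) for i in range(m.n_motifs)])
        lo = normalize_and_aggregate(compute_costs(m, sigs, None, CostParams(lambda_ent=0.0)))
        hi = normalize_and_aggregate(compute_costs(m, sigs, None, CostParams(lambda_ent=0.5)))
        for i in range(m.n_motifs):
            for j in range(m.n_motifs):
                if ent[i] > ent[j] and np.allclose(lo.kappa[i] - lo.beta[i], lo.kappa[j] - lo.beta[j]):
                    # equal alpha profiles: the higher-entropy motif cannot overtake
                    assert hi.global_score[i] <= hi.global_score[j] + 1e-9
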