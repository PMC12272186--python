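import numpy as np
import pytest

from mwimotif import (
    B1Map,
    B1Params,
    FractionGrid,
    SequenceParams,
    build_single_t2_dictionary,
    correct_signals,
    enumerate_motifs,
    initial_b1_map,
    smooth_b1_map,
)


@pytest.fixture(scope="module")
def seq():
    return SequenceParams(etl=11, echo_spacing=12.0)


@pytest.fixture(scope="module")
def motifs_epg(seq):
    d = build_single_t2_dictionary((15, 200, 6), (0.8, 1.2, 9), seq, "epg")
    return enumerate_motifs(d, 2, FractionGrid(0.25))


@pytest.fixture(scope="module")
def motifs_exp(seq):
    # exponential curves carry no B1+ information: the data term ties
    d = build_single_t2_dictionary((15, 200, 4), (0.8, 1.2, 9), seq, "exponential")
    return enumerate_motifs(d, 2, FractionGrid(0.5))


def _volume_from_motifs(motifs, rows):
    """Image of shape (len(rows), 1, etl) built from (motif idx, plane idx)."""
    sig = np.stack([[motifs.signals[i, k, :]] for i, k in rows])
    mask = np.ones((len(rows), 1), dtype=bool)
    return sig, mask


class TestInitialMap:
    def test_on_grid_self_consistency(self, motifs_epg):
        """Noiseless voxels built at b1 = 0.90 are recovered exactly."""
        k = motifs_epg.source.b1_index(0.90)
        sig, mask = _volume_from_motifs(motifs_epg, [(3, k), (10, k), (20, k)])
        b1 = initial_b1_map(sig, motifs_epg, mask)
        assert np.allclose(b1.values[mask], 0.90)

    def test_identical_signals_identical_estimates(self, motifs_epg):
        k = motifs_epg.source.b1_index(0.85)
        sig, mask = _volume_from_motifs(motifs_epg, [(5, k), (5, k)])
        b1 = initial_b1_map(sig, motifs_epg, mask)
        assert b1.values[0, 0] == b1.values[1, 0]

    def test_off_grid_field_snaps_to_neighbor(self, seq, motifs_epg):
        """A voxel simulated at b1 = 0.93 lands on 0.90 or 0.95."""
        from mwimotif import simulate_epg_mese
        from mwimotif.simulate import normalize_curves

        t2s = motifs_epg.component_t2s(8)
        fr = motifs_epg.motif_fractions(8)
        raw = sum(f * normalize_curves(simulate_epg_mese(t, seq, 0.93), "unit_l2")
                  for t, f in zip(t2s, fr))
        sig = raw[None, None, :]
        mask = np.ones((1, 1), dtype=bool)
        b1 = initial_b1_map(sig, motifs_epg, mask)
        assert b1.values[0, 0] in (0.90, 0.95)

    def test_empty_mask_rejected(self, motifs_epg):
        with pytest.raises(ValueError):
            initial_b1_map(np.zeros((2, 2, 11)), motifs_epg, np.zeros((2, 2), dtype=bool))


class TestSmoothing:
    def test_mu_zero_returns_initial(self, motifs_epg):
        k = motifs_epg.source.b1_index(0.90)
        sig, mask = _volume_from_motifs(motifs_epg, [(3, k)] * 4)
        init = initial_b1_map(sig, motifs_epg, mask)
        out = smooth_b1_map(sig, motifs_epg, init, B1Params(mu=0.0), voxel_size_mm=5.0)
        assert np.array_equal(out.values[mask], init.values[mask])

    def test_uniform_field_is_fixed_point(self, motifs_epg):
        k = motifs_epg.source.b1_index(1.0)
        rows = [(i % motifs_epg.n_motifs, k) for i in range(9)]
        sig, _ = _volume_from_motifs(motifs_epg, rows)
        sig = sig.reshape(3, 3, -1)
        mask = np.ones((3, 3), dtype=bool)
        init = initial_b1_map(sig, motifs_epg, mask)
        out = smooth_b1_map(sig, motifs_epg, init, B1Params(mu=0.2), voxel_size_mm=5.0)
        assert np.allclose(out.values[mask], 1.0)
        assert out.converged and out.iterations_run == 1

    def test_salt_outlier_removed_under_ambiguous_data(self, motifs_exp):
        """With a B1-blind (exponential) data term, a lone 0.80 amid 1.00
        neighbors is replaced by the neighborhood value."""
        sig = np.tile(motifs_exp.signals[2, 0, :], (3, 3, 1))
        mask = np.ones((3, 3), dtype=bool)
        init = initial_b1_map(sig, motifs_exp, mask)
        vals = init.values.copy()
        vals[1, 1] = 0.80
        init_out = B1Map(values=vals, mask=mask, b1_grid=init.b1_grid)
        out = smooth_b1_map(sig, motifs_exp, init_out, B1Params(mu=5.0), voxel_size_mm=5.0)
        assert np.isclose(out.values[1, 1], 1.0)

    def test_fixed_point_idempotent(self, motifs_epg):
        rng = np.random.default_rng(0)
        rows = [(int(rng.integers(motifs_epg.n_motifs)), 2) for _ in range(16)]
        sig, _ = _volume_from_motifs(motifs_epg, rows)
        sig = sig.reshape(4, 4, -1)
        mask = np.ones((4, 4), dtype=bool)
        init = initial_b1_map(sig, motifs_epg, mask)
        once = smooth_b1_map(sig, motifs_epg, init, B1Params(mu=0.2), voxel_size_mm=5.0)
        again = smooth_b1_map(sig, motifs_epg, once, B1Params(mu=0.2), voxel_size_mm=5.0)
        assert np.array_equal(once.values[mask], again.values[mask])

    def test_values_stay_on_grid(self, motifs_epg):
        k = motifs_epg.source.b1_index(0.85)
        sig, _ = _volume_from_motifs(motifs_epg, [(1, k)] * 9)
        sig = sig.reshape(3, 3, -1)
        mask = np.ones((3, 3), dtype=bool)
        init = initial_b1_map(sig, motifs_epg, mask)
        out = smooth_b1_map(sig, motifs_epg, init, B1Params(mu=0.3), voxel_size_mm=5.0)
        for v in out.values[mask]:
            assert np.any(np.isclose(out.b1_grid, v))


class TestCorrection:
    def test_homogeneous_map_is_identity(self, motifs_epg):
        k = motifs_epg.source.b1_index(0.90)
        sig, mask = _volume_from_motifs(motifs_epg, [(3, k), (7, k)])
        vals = np.full(mask.shape, 1.0)
        b1 = B1Map(values=vals, mask=mask, b1_grid=motifs_epg.source.b1_grid)
        out = correct_signals(sig, b1, motifs_epg)
        assert np.array_equal(out, sig)

    def test_on_grid_motif_cancels_exactly(self, motifs_epg):
        """A noiseless voxel from motif m at b1 = 0.85 corrects to m's
        homogeneous-field signal."""
        k = motifs_epg.source.b1_index(0.85)
        i = 12
        sig, mask = _volume_from_motifs(motifs_epg, [(i, k)])
        vals = np.full(mask.shape, 0.85)
        b1 = B1Map(values=vals, mask=mask, b1_grid=motifs_epg.source.b1_grid)
        out = correct_signals(sig, b1, motifs_epg)
        home = motifs_epg.signals_at_b1(1.0)[i]
        out_n = out[mask][0] / np.linalg.norm(out[mask][0])
        assert np.allclose(out_n, home, atol=1e-9)

    def test_preserves_positivity(self, motifs_epg):
        k = motifs_epg.source.b1_index(0.80)
        sig, mask = _volume_from_motifs(motifs_epg, [(2, k), (9, k)])
        vals = np.full(mask.shape, 0.80)
        b1 = B1Map(values=vals, mask=mask, b1_grid=motifs_epg.source.b1_grid)
        out = correct_signals(sig, b1, motifs_epg)
        assert np.all(out[mask] > 0)


class TestB1Params:
    def test_kernel_voxel_conversion_is_odd(self):
        p = B1Params(kernel_extent_mm=15.0)
        assert p.kernel_half_width(1.0) == 7  # 15 voxels across
        assert p.kernel_half_width(2.5) == 3  # 7 voxels across
        assert p.kernel_half_width(5.0) == 1

    @pytest.mark.parametrize("kwargs", [{"mu": -1.0}, {"n_iter_max": 0}, {"kernel_extent_mm": 0.0}])
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            B1Params(**kwargs)
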