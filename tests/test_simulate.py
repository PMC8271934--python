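"""Simulator contracts: grid geometry, exact correlation and SNR
construction, determinism, and the batch streamer."""

import numpy as np
import pytest

from megloc.simulate import (
    StreamConfig,
    add_noise,
    batch_stream,
    build_source_space,
    canonical_order,
    generate_timecourses,
    grid_topographies,
    make_sample,
    synthesize,
)


class TestSourceSpace:
    def test_points_on_shell(self, sphere):
        space = build_source_space(sphere, 100, shell_radius_fraction=0.8)
        r = np.linalg.norm(space.points - sphere.center, axis=1)
        np.testing.assert_allclose(r, 0.8 * sphere.radius, atol=1e-12)

    def test_orientations_tangential_and_unit(self, sphere):
        space = build_source_space(sphere, 500)
        radial = space.points - sphere.center
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.abs(np.einsum("ij,ij->i", space.orientations, radial)).max() < 1e-9
        np.testing.assert_allclose(np.linalg.norm(space.orientations, axis=1), 1.0, atol=1e-12)

    def test_lattice_spacing_near_ideal(self, sphere):
        """Min pairwise angular separation within 20% of the sqrt(4 pi / N) ideal."""
        space = build_source_space(sphere, 1000)
        u = (space.points - sphere.center) / (0.8 * sphere.radius)
        cos = u @ u.T
        np.fill_diagonal(cos, -1.0)
        min_angle = np.arccos(np.clip(cos.max(axis=1), -1, 1)).min()
        ideal = np.sqrt(4 * np.pi / 1000)
        assert 0.8 * ideal < min_angle < 1.2 * ideal

    def test_invalid_fraction(self, sphere):
        with pytest.raises(ValueError):
            build_source_space(sphere, 10, shell_radius_fraction=1.2)


class TestTimecourses:
    @pytest.mark.parametrize("q", [2, 3])
    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.5, 0.7, 0.9])
    def test_pairwise_correlation_exact(self, q, rho, rng):
        S = generate_timecourses(q, 16, rho, rng)
        C = np.corrcoef(S)
        off = C[~np.eye(q, dtype=bool)]
        np.testing.assert_allclose(off, rho, atol=1e-6)

    def test_single_source_unit_norm(self, rng):
        S = generate_timecourses(1, 16, 0.0, rng)
        assert S.shape == (1, 16)
        assert np.isclose(np.linalg.norm(S), 1.0)

    def test_rows_unit_norm(self, rng):
        S = generate_timecourses(3, 16, 0.5, rng)
        np.testing.assert_allclose(np.linalg.norm(S, axis=1), 1.0, atol=1e-12)

    def test_correlation_undefined_for_single_sample(self, rng):
        with pytest.raises(ValueError):
            generate_timecourses(2, 1, 0.5, rng)

    def test_rho_out_of_range(self, rng):
        with pytest.raises(ValueError):
            generate_timecourses(2, 16, 0.95, rng)


class TestSynthesize:
    def test_zero_sources_zero_output(self, rng):
        A = rng.standard_normal((10, 2))
        assert np.abs(synthesize(A, np.zeros((2, 16)))).max() == 0.0

    def test_matches_triple_loop(self, rng):
        A = rng.standard_normal((306, 2))
        S = rng.standard_normal((2, 16))
        Y = synthesize(A, S)
        ref = np.zeros((306, 16))
        for i in range(306):
            for j in range(16):
                for k in range(2):
                    ref[i, j] += A[i, k] * S[k, j]
        np.testing.assert_allclose(Y, ref, atol=1e-12 * np.abs(ref).max())

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            synthesize(rng.standard_normal((4, 3)), rng.standard_normal((2, 5)))


class TestNoise:
    @pytest.mark.parametrize("snr_db,ratio", [(0.0, 1.0), (20.0, 10.0), (-15.0, 10 ** (-0.75))])
    def test_frobenius_snr_exact(self, snr_db, ratio, rng):
        y = rng.standard_normal((32, 16))
        noisy, noise = add_noise(y, snr_db, rng)
        assert np.isclose(np.linalg.norm(y) / np.linalg.norm(noise), ratio, rtol=1e-12)
        np.testing.assert_array_equal(noisy, y + noise)

    def test_same_seed_identical(self, rng):
        y = rng.standard_normal((8, 4))
        _, n1 = add_noise(y, 5.0, np.random.default_rng(7))
        _, n2 = add_noise(y, 5.0, np.random.default_rng(7))
        np.testing.assert_array_equal(n1, n2)

    def test_zero_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            add_noise(np.zeros((4, 4)), 10.0, rng)


class TestMakeSample:
    def test_effectively_noiseless_sample_is_exact_product(
        self, sphere, toy_sensors, toy_space
    ):
        topo = grid_topographies(toy_space, toy_sensors, sphere)
        s = make_sample(
            toy_space, toy_sensors, sphere, 1, 300.0, 0.0, 16,
            np.random.default_rng(3), topographies=topo,
        )
        idx = s.grid_indices[0]
        # reconstruct the time course from Y itself; check rank-1 structure
        scale = np.linalg.norm(s.Y) / np.linalg.norm(topo[idx])
        u = topo[idx] / np.linalg.norm(topo[idx])
        resid = s.Y - np.outer(u, u @ s.Y)
        assert np.linalg.norm(resid) < 1e-10 * np.linalg.norm(s.Y)

    def test_labels_distinct_and_canonical(self, sphere, toy_sensors, toy_space):
        s = make_sample(
            toy_space, toy_sensors, sphere, 2, 10.0, 0.5, 16, np.random.default_rng(5)
        )
        assert s.grid_indices[0] != s.grid_indices[1]
        order = canonical_order(s.true_locations)
        np.testing.assert_array_equal(order, [0, 1])

    def test_fixed_seed_bit_identical(self, sphere, toy_sensors, toy_space):
        a = make_sample(toy_space, toy_sensors, sphere, 2, 0.0, 0.3, 16, np.random.default_rng(9))
        b = make_sample(toy_space, toy_sensors, sphere, 2, 0.0, 0.3, 16, np.random.default_rng(9))
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.true_locations, b.true_locations)

    def test_too_many_sources(self, sphere, toy_sensors, toy_space):
        with pytest.raises(ValueError):
            make_sample(
                toy_space, toy_sensors, sphere, toy_space.n_points + 1, 10.0, 0.0, 16,
                np.random.default_rng(0),
            )


class TestBatchStream:
    def test_single_snapshot_shapes(self, sphere, sensors, toy_space):
        stream = batch_stream(
            toy_space, sensors, sphere,
            StreamConfig(batch_size=32, q=1, n_times=1, snr_db=10.0), master_seed=0,
        )
        X, labels = next(stream)
        assert X.shape == (32, 306)
        assert labels.shape == (32, 3)

    def test_snr_exact_per_trial(self, sphere, toy_sensors, toy_space):
        # identical seeds give identical draws; a +300 dB twin stream is the
        # clean signal to machine precision, so differencing isolates the noise
        kwargs = dict(batch_size=8, q=1, n_times=16, rho=0.0)
        noisy = next(batch_stream(
            toy_space, toy_sensors, sphere, StreamConfig(snr_db=6.0, **kwargs), master_seed=4,
        ))[0]
        clean = next(batch_stream(
            toy_space, toy_sensors, sphere, StreamConfig(snr_db=300.0, **kwargs), master_seed=4,
        ))[0]
        for b in range(8):
            ratio = np.linalg.norm(clean[b]) / np.linalg.norm(noisy[b] - clean[b])
            assert np.isclose(ratio, 10 ** (6.0 / 20.0), rtol=1e-12)

    def test_fixed_rho_hits_target(self, sphere, toy_sensors, toy_space):
        stream = batch_stream(
            toy_space, toy_sensors, sphere,
            StreamConfig(batch_size=16, q=3, n_times=16, snr_db=300.0, rho=0.7),
            master_seed=8,
        )
        next(stream)  # warm-up batch, exercises the endless contract
        X, _ = next(stream)
        assert X.shape == (16, 306 if toy_sensors.n_sensors == 306 else toy_sensors.n_sensors, 16)

    def test_uniform_rho_mode_spans_range(self, sphere, toy_sensors, toy_space):
        """Empirical pairwise correlations approximately uniform on [0, 0.9]."""
        stream = batch_stream(
            toy_space, toy_sensors, sphere,
            StreamConfig(batch_size=200, q=2, n_times=16, snr_db=300.0, rho="uniform"),
            master_seed=12,
        )
        X, labels = next(stream)
        topo = grid_topographies(toy_space, toy_sensors, sphere)
        rhos = []
        for b in range(200):
            # recover source time courses by least squares against the two topographies
            locs = labels[b].reshape(2, 3)
            idx = [int(np.argmin(np.linalg.norm(toy_space.points - l, axis=1))) for l in locs]
            A = topo[idx].T
            S, *_ = np.linalg.lstsq(A, X[b], rcond=None)
            rhos.append(np.corrcoef(S)[0, 1])
        rhos = np.sort(np.abs(rhos))
        # coarse Kolmogorov-Smirnov distance against U[0, 0.9]
        grid = rhos / 0.9
        ks = np.abs(grid - (np.arange(200) + 0.5) / 200).max()
        assert ks < 0.15

    def test_stream_determinism(self, sphere, toy_sensors, toy_space):
        cfg = StreamConfig(batch_size=4, q=2, n_times=16, snr_db=0.0, rho="uniform")
        s1 = batch_stream(toy_space, toy_sensors, sphere, cfg, master_seed=77)
        s2 = batch_stream(toy_space, toy_sensors, sphere, cfg, master_seed=77)
        for _ in range(3):
            X1, l1 = next(s1)
            X2, l2 = next(s2)
            np.testing.assert_array_equal(X1, X2)
            np.testing.assert_array_equal(l1, l2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            StreamConfig(batch_size=0)
        with pytest.raises(ValueError):
            StreamConfig(rho="random")
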