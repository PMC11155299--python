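"""Stage-1 orientation retrieval: dictionary and complex OMP."""

import numpy as np
import pytest

from sbsd.metrics import accuracy, angular_error, evaluate_stage1
from sbsd.phantom import make_scheme, sample_batch, sample_crossing
from sbsd.sphharm import legendre_correlation, rotation_filter
from sbsd.stage1_omp import (
    RotationDictionary,
    build_dictionary,
    fibonacci_hemisphere,
    fit_volume_directions,
    omp_directions,
)


class TestDictionary:
    def test_atoms_unit_norm(self, dict6):
        norms = np.linalg.norm(dict6.atoms, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_atom_correlation_is_legendre(self, dict6):
        rng = np.random.default_rng(1)
        idx = rng.integers(0, dict6.n_grid, size=(50, 2))
        for i, j in idx:
            corr = np.vdot(dict6.atoms[:, i], dict6.atoms[:, j])
            cosg = dict6.grid[i] @ dict6.grid[j]
            assert abs(corr - legendre_correlation(6, cosg)) < 1e-9

    def test_north_pole_column_is_identity_atom(self):
        grid = np.vstack([[0.0, 0.0, 1.0], fibonacci_hemisphere(50)])
        atoms = rotation_filter(grid, 4).T
        d = RotationDictionary(n0=4, grid=grid, atoms=atoms)
        e = np.zeros(9)
        e[4] = 1.0
        assert np.allclose(d.atoms[:, 0], e, atol=1e-12)

    def test_grid_resolution(self, dict6):
        # nearest-neighbor folded angle below the area heuristic
        g = np.abs(dict6.grid @ dict6.grid.T)
        np.fill_diagonal(g, 0.0)
        nn = np.degrees(np.arccos(np.clip(g.max(axis=1), -1, 1)))
        assert nn.max() <= 2.8

    def test_no_duplicate_grid_directions(self, dict6):
        g = np.abs(dict6.grid @ dict6.grid.T)
        np.fill_diagonal(g, 0.0)
        assert np.degrees(np.arccos(g.max())) > 0.1

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary(6, n_grid=10)


class TestOMP:
    def test_single_atom_identity(self, dict6):
        j = 1234
        C = -0.21
        res = omp_directions(C * dict6.atoms[:, j], dict6, K=1)
        assert np.array_equal(res.directions[0], dict6.grid[j])
        assert abs(res.coefficients[0] - C) < 1e-12
        assert res.residual_norm < 1e-12

    def test_residual_orthogonal_to_selected_atoms(self, dict6, bank, scheme130):
        s = sample_crossing(bank, scheme130, 20.0, seed=2)
        from sbsd.sphharm import fit_sh

        Sn0 = fit_sh(s.noisy, scheme130.directions, 8).degree_vector(6)
        res = omp_directions(Sn0, dict6, K=2)
        A = rotation_filter(res.directions, 6).T
        residual = Sn0 - A @ res.coefficients
        assert np.abs(A.conj().T @ residual).max() < 1e-8

    def test_exhaustive_pair_oracle_recovers_on_grid_mixture(self, dict6, bank):
        """The sparse mixture identity: the true snapped pair has residual 0."""
        C1 = bank[10].zonal_coefficients(3000.0, 6)[-1]
        C2 = bank[37].zonal_coefficients(3000.0, 6)[-1]
        u1 = dict6.grid[dict6.nearest(np.array([0.0, 0.0, 1.0]))]
        t = np.array([np.sin(np.radians(40.0)), 0.0, np.cos(np.radians(40.0))])
        u2 = dict6.grid[dict6.nearest(t)]
        S = 0.6 * C1 * rotation_filter(u1, 6) + 0.4 * C2 * rotation_filter(u2, 6)
        A = rotation_filter(np.stack([u1, u2]), 6).T
        x, *_ = np.linalg.lstsq(A, S, rcond=None)
        assert np.linalg.norm(S - A @ x) < 1e-12
        assert np.allclose(x.real, [0.6 * C1, 0.4 * C2], atol=1e-10)
        # greedy OMP on the coherent dictionary may tilt the first pick to a
        # neighboring atom; its error stays within a few grid spacings
        res = omp_directions(S, dict6, K=2)
        errs = angular_error(res.directions, np.stack([u1, u2])).errors
        assert errs.max() < 8.0

    def test_offgrid_single_fascicle_snaps_to_nearest_atom(self, dict6):
        rng = np.random.default_rng(7)
        for _ in range(20):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            res = omp_directions(-0.2 * rotation_filter(u, 6), dict6, K=1)
            nearest = dict6.grid[dict6.nearest(u)]
            got = angular_error(res.directions, u[None]).errors[0]
            best = angular_error(nearest[None], u[None]).errors[0]
            assert got <= best + 1e-6

    def test_zero_signal_rejected(self, dict6):
        with pytest.raises(ValueError):
            omp_directions(np.zeros(13), dict6, K=1)

    def test_all_atoms_masked_error(self):
        d = build_dictionary(2, n_grid=8)
        S = d.atoms[:, 0] * 0.5
        with pytest.raises(RuntimeError, match="masked"):
            omp_directions(S, d, K=4, exclusion_angle=89.0)

    def test_residual_norm_non_increasing(self, dict6, bank, scheme130):
        from sbsd.sphharm import fit_sh

        s = sample_crossing(bank, scheme130, 10.0, seed=14)
        Sn0 = fit_sh(s.noisy, scheme130.directions, 8).degree_vector(6)
        norms = [
            omp_directions(Sn0, dict6, K=k).residual_norm for k in (1, 2, 3)
        ]
        assert norms[0] >= norms[1] >= norms[2]


class TestStage1Statistical:
    def test_noiseless_recovery_is_nearly_perfect(self, bank, scheme150_b5000):
        """Noiseless two-fascicle recovery saturates near (not at) 100%.

        Dictionary coherence caps noiseless accuracy slightly below 1: the
        second fascicle tilts the greedy first pick, and near-equal-weight
        crossings can promote the atom at the Legendre-minimum angle.
        """
        samples = sample_batch(bank, scheme150_b5000, np.inf, 200, seed=7)
        for n0, floor in ((6, 0.92), (8, 0.94)):
            errs = evaluate_stage1(samples, n0)
            assert accuracy(errs.ravel()) >= floor

    def test_rotation_equivariance(self, bank, dict6):
        from scipy.spatial.transform import Rotation

        scheme = make_scheme(130, 3000.0, seed=1)
        rng = np.random.default_rng(0)
        mismatches = []
        for i in range(10):
            s = sample_crossing(bank, scheme, np.inf, seed=100 + i)
            R = Rotation.random(random_state=rng).as_matrix()
            k1, k2 = bank[s.kernel_ids[0]], bank[s.kernel_ids[1]]
            rot_dirs = s.gt_directions @ R.T
            z1, z2 = scheme.directions @ rot_dirs[0], scheme.directions @ rot_dirs[1]
            rot_signal = s.nu1 * k1.amplitude(3000.0, z1) + (1 - s.nu1) * k2.amplitude(
                3000.0, z2
            )
            from sbsd.sphharm import fit_sh

            e1 = omp_directions(
                fit_sh(s.noiseless, scheme.directions, 8).degree_vector(6), dict6, K=2
            )
            e2 = omp_directions(
                fit_sh(rot_signal, scheme.directions, 8).degree_vector(6), dict6, K=2
            )
            rotated_est = e1.directions @ R.T
            mismatches.append(
                angular_error(e2.directions, rotated_est).errors.max()
            )
        # estimates follow the rotation within grid resolution in the bulk
        assert np.median(mismatches) <= 2 * 2.8

    def test_noise_monotonicity(self, bank, scheme130):
        means = []
        for snr in (np.inf, 50.0, 20.0, 10.0):
            samples = sample_batch(bank, scheme130, snr, 300, seed=55)
            means.append(evaluate_stage1(samples, 6).mean())
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestVolumeWrapper:
    def test_single_voxel_consistency(self, bank, scheme130, dict6):
        from sbsd.sphharm import sh_design

        s = sample_crossing(bank, scheme130, 20.0, seed=9)
        vol = s.noisy.reshape(1, 1, 1, -1)
        peaks = fit_volume_directions(vol, scheme130, None, 6, K=2, dictionary=dict6)
        solver = sh_design(scheme130.directions, 8, 0.006)
        res = omp_directions(solver(s.noisy).degree_vector(6), dict6, K=2)
        expected = (res.directions * res.weights[:, None]).ravel()
        assert np.array_equal(peaks[0, 0, 0], expected)

    def test_background_voxels_zero(self, scheme130, dict6):
        vol = np.zeros((2, 2, 1, scheme130.n_dirs))
        peaks = fit_volume_directions(vol, scheme130, None, 6, K=2, dictionary=dict6)
        assert not np.any(peaks)

    def test_batch_matches_per_sample(self, bank, scheme130, dict6):
        samples = sample_batch(bank, scheme130, 30.0, 8, seed=77)
        vol = np.stack([s.noisy for s in samples]).reshape(8, 1, 1, -1)
        batch = fit_volume_directions(vol, scheme130, None, 6, K=2, dictionary=dict6)
        for i, s in enumerate(samples):
            single = fit_volume_directions(
                s.noisy.reshape(1, 1, 1, -1), scheme130, None, 6, K=2, dictionary=dict6
            )
            assert np.array_equal(batch[i, 0, 0], single[0, 0, 0])
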