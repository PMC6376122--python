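"""Solution grid, three-shell forward model, LAURA inverse, voxel statistics."""

import numpy as np
import pytest

from erpfield.containers import EvokedMap
from erpfield.montage import make_cap_montage
from erpfield.sources import (
    HeadModel,
    SourceEstimate,
    apply_inverse,
    build_laura_operator,
    build_solution_grid,
    compute_leadfield,
    dipole_potential_homogeneous,
    rms_normalize,
    voxelwise_ttest,
)


@pytest.fixture(scope="module")
def montage32():
    return make_cap_montage(32)


@pytest.fixture(scope="module")
def grid_mid():
    return build_solution_grid(0.2, 0.85)


@pytest.fixture(scope="module")
def leadfield_mid(grid_mid, montage32):
    return compute_leadfield(grid_mid, montage32, HeadModel())


class TestGrid:
    def test_degenerate_spacing_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            build_solution_grid(1.7, 0.85)

    def test_point_count_matches_sphere_volume(self):
        g = build_solution_grid(0.1, 0.85)
        expected = 4.0 / 3.0 * np.pi * (0.85 / 0.1) ** 3
        assert abs(g.n_points - expected) / expected < 0.05

    def test_points_strictly_inside(self, grid_mid):
        assert np.linalg.norm(grid_mid.points, axis=1).max() < 0.85

    def test_neighbors_symmetric_26(self, grid_mid):
        for i, nb in enumerate(grid_mid.neighbors):
            assert len(nb) <= 26
            for j in nb:
                assert i in grid_mid.neighbors[j]


class TestHeadModel:
    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            HeadModel(radii=(0.9, 0.8, 1.0))

    def test_invalid_conductivity_rejected(self):
        with pytest.raises(ValueError):
            HeadModel(conductivities=(0.33, 0.0, 0.33))


class TestLeadField:
    def test_columns_average_referenced(self, leadfield_mid):
        col_means = leadfield_mid.gain.mean(axis=2)
        assert np.abs(col_means).max() < 1e-9

    def test_linearity_in_moment(self, grid_mid, montage32, leadfield_mid):
        # doubling the moment doubles the potential: gains are the linear map
        g = leadfield_mid.gain[10]
        m = np.array([0.3, -1.2, 0.7])
        assert np.allclose(g.T @ (2 * m), 2 * (g.T @ m))

    def test_central_radial_dipole_axisymmetric(self, montage32):
        grid = build_solution_grid(0.2, 0.85)
        center = int(np.argmin(np.linalg.norm(grid.points, axis=1)))
        lf = compute_leadfield(grid, montage32, HeadModel())
        v = lf.gain[center, 2]  # z-oriented dipole at the center
        # potential must be a function of the electrode z coordinate only
        z = montage32.retained_positions()[:, 2]
        vs = v + v.mean() - v.mean()  # average-referenced already
        # electrodes at (nearly) equal z must give (nearly) equal potential
        order = np.argsort(z)
        for i, j in zip(order[:-1], order[1:]):
            if abs(z[i] - z[j]) < 1e-3:
                assert abs(vs[i] - vs[j]) < 1e-6 * np.abs(v).max()
        # and V should increase monotonically with z for a +z dipole
        assert np.corrcoef(v, z)[0, 1] > 0.99

    def test_homogeneous_limit_matches_single_sphere(self, grid_mid, montage32):
        head = HeadModel(conductivities=(0.33, 0.33, 0.33), n_terms=80)
        lf = compute_leadfield(grid_mid, montage32, head)
        E = montage32.retained_positions()
        rng = np.random.default_rng(7)
        for i in rng.choice(grid_mid.n_points, 5, replace=False):
            for comp, unit in enumerate(np.eye(3)):
                ref = dipole_potential_homogeneous(grid_mid.points[i], unit, E,
                                                   0.33, n_terms=400)
                ref = ref - ref.mean()
                err = np.abs(lf.gain[i, comp] - ref).max() / np.abs(ref).max()
                assert err < 0.005


class TestLauraInverse:
    def test_zero_map_gives_zero_estimate(self, grid_mid, leadfield_mid):
        op = build_laura_operator(leadfield_mid, grid_mid)
        est = op.apply(np.zeros(32))
        assert np.allclose(est, 0.0)

    def test_single_dipole_mean_error_within_two_spacings(self, grid_mid, leadfield_mid):
        op = build_laura_operator(leadfield_mid, grid_mid)
        rng = np.random.default_rng(11)
        errs = []
        for i in rng.choice(grid_mid.n_points, 10, replace=False):
            v = leadfield_mid.gain[i].T @ rng.standard_normal(3)
            mag = np.linalg.norm(op.apply(v), axis=1)
            j = int(np.argmax(mag))
            errs.append(np.linalg.norm(grid_mid.points[j] - grid_mid.points[i]))
        assert np.mean(errs) <= 2.0 * grid_mid.spacing

    def test_regularization_shrinks_estimates(self, grid_mid, leadfield_mid, rng):
        v = leadfield_mid.gain[40].T @ np.array([1.0, 0.5, -0.2])
        norms = []
        for lam in (1e-3, 1e-1, 1e1, 1e3):
            op = build_laura_operator(leadfield_mid, grid_mid, lambda_frac=lam)
            norms.append(np.linalg.norm(op.apply(v)))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_reconstruction_improves_with_less_regularization(self, grid_mid, leadfield_mid):
        # L G acts as a smoother on scalp maps: residual shrinks with lambda
        v = leadfield_mid.gain[25].T @ np.array([0.2, 1.0, 0.4])
        L = leadfield_mid.gain.reshape(-1, 32).T  # C x 3P
        res = []
        for lam in (1e1, 1e-1, 1e-3):
            op = build_laura_operator(leadfield_mid, grid_mid, lambda_frac=lam)
            j = op.apply(v).reshape(-1)
            res.append(np.linalg.norm(v - L @ j) / np.linalg.norm(v))
        assert res[0] > res[1] > res[2]

    def test_invalid_exponent(self, grid_mid, leadfield_mid):
        with pytest.raises(ValueError):
            build_laura_operator(leadfield_mid, grid_mid, exponent=0.0)


class TestApplyInverse:
    def _evoked(self, data):
        return EvokedMap("P01", "Fear", data, 500.0, 0.0,
                         [f"C{i+1}" for i in range(data.shape[0])])

    def test_single_sample_window(self, grid_mid, leadfield_mid, rng):
        op = build_laura_operator(leadfield_mid, grid_mid)
        data = rng.standard_normal((32, 50))
        ev = self._evoked(data)
        est = apply_inverse(ev, (20.0, 20.0), op)
        direct = op.apply(data[:, 10])
        assert np.allclose(est.values, direct)

    def test_zero_evoked(self, grid_mid, leadfield_mid):
        op = build_laura_operator(leadfield_mid, grid_mid)
        est = apply_inverse(self._evoked(np.zeros((32, 50))), (0.0, 50.0), op)
        assert np.allclose(est.magnitudes, 0.0)

    def test_empty_window_rejected(self, grid_mid, leadfield_mid, rng):
        op = build_laura_operator(leadfield_mid, grid_mid)
        with pytest.raises(ValueError):
            apply_inverse(self._evoked(rng.standard_normal((32, 50))),
                          (900.0, 950.0), op)


class TestRMSNormalize:
    def test_constant_magnitudes_become_one(self):
        values = np.tile([[2.0, 0.0, 0.0]], (30, 1))
        est = SourceEstimate(values, np.linalg.norm(values, axis=1))
        out = rms_normalize(est)
        assert np.allclose(out.magnitudes, 1.0)

    def test_scale_invariance(self, rng):
        values = rng.standard_normal((40, 3))
        est1 = SourceEstimate(values, np.linalg.norm(values, axis=1))
        est2 = SourceEstimate(10 * values, np.linalg.norm(10 * values, axis=1))
        assert np.allclose(rms_normalize(est1).magnitudes,
                           rms_normalize(est2).magnitudes)

    def test_unit_rms(self, rng):
        values = rng.standard_normal((40, 3))
        out = rms_normalize(SourceEstimate(values, np.linalg.norm(values, axis=1)))
        assert np.sqrt(np.mean(out.magnitudes**2)) == pytest.approx(1.0, abs=1e-9)

    def test_zero_estimate_rejected(self):
        with pytest.raises(ValueError):
            rms_normalize(SourceEstimate(np.zeros((5, 3)), np.zeros(5)))


def _estimates(grid, mags_list, cond):
    return [SourceEstimate(np.zeros((grid.n_points, 3)), m, f"P{i:02d}", cond)
            for i, m in enumerate(mags_list)]


class TestVoxelStats:
    def test_identical_conditions_empty(self, grid_mid, rng):
        mags = [rng.random(grid_mid.n_points) + 0.5 for _ in range(6)]
        rep = voxelwise_ttest(_estimates(grid_mid, mags, "A"),
                              _estimates(grid_mid, mags, "B"), grid_mid)
        assert rep.clusters == ()
        assert rep.subthreshold_clusters == ()

    def test_critical_t_for_19_participants(self, grid_mid, rng):
        mags_a = [rng.random(grid_mid.n_points) for _ in range(19)]
        mags_b = [rng.random(grid_mid.n_points) for _ in range(19)]
        rep = voxelwise_ttest(_estimates(grid_mid, mags_a, "A"),
                              _estimates(grid_mid, mags_b, "B"), grid_mid,
                              alpha=0.01)
        assert round(rep.critical_t, 2) == 2.88

    def test_nine_point_cluster_subthreshold(self):
        # toy lattice; 9 contiguous activated points with a cut-off of 10
        grid = build_solution_grid(0.28, 0.85)
        # pick a point with many neighbors and form a 9-point connected blob
        seed_pt = max(range(grid.n_points), key=lambda i: len(grid.neighbors[i]))
        blob = {seed_pt}
        frontier = [seed_pt]
        while len(blob) < 9:
            nxt = [j for j in grid.neighbors[frontier[0]] if j not in blob]
            for j in nxt:
                if len(blob) < 9:
                    blob.add(int(j))
            frontier = frontier[1:] + nxt
        blob = sorted(blob)
        rng = np.random.default_rng(3)
        base = [1.0 + 0.01 * rng.standard_normal(grid.n_points) for _ in range(12)]
        boosted = []
        for m in base:
            mm = m.copy()
            mm[blob] += 1.0
            boosted.append(mm)
        rep = voxelwise_ttest(_estimates(grid, boosted, "A"),
                              _estimates(grid, base, "B"), grid,
                              alpha=0.01, min_cluster=10)
        assert all(set(blob) - set(c.members) for c in rep.clusters) or rep.clusters == ()
        sub_sizes = [c.size for c in rep.subthreshold_clusters]
        assert 9 in sub_sizes
        # brute-force contiguity: the blob is one connected component
        comp = {blob[0]}
        stack = [blob[0]]
        while stack:
            u = stack.pop()
            for v_ in grid.neighbors[u]:
                if int(v_) in blob and int(v_) not in comp:
                    comp.add(int(v_))
                    stack.append(int(v_))
        assert comp == set(blob)

    def test_participant_mismatch_rejected(self, grid_mid, rng):
        a = _estimates(grid_mid, [rng.random(grid_mid.n_points)] * 3, "A")
        b = _estimates(grid_mid, [rng.random(grid_mid.n_points)] * 4, "B")
        with pytest.raises(ValueError):
            voxelwise_ttest(a, b, grid_mid)
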