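import numpy as np
import pytest

from ensemblefit.geometry import RigidTransform, kabsch_superpose
from ensemblefit.modes import (
    extreme_states,
    pca_modes,
    project_frames,
    projection_histogram,
)
from ensemblefit.models import TrajectoryEnsemble

from conftest import make_chain_model
from test_geometry import rotation_z


def _ensemble(coords, topo, conf="I", rep=0, timestep=1.0):
    return TrajectoryEnsemble(
        topology=topo,
        times=np.arange(coords.shape[0]) * timestep,
        coordinates=coords,
        origin_conformation=conf,
        replica_id=rep,
    )


@pytest.fixture
def base_topology():
    return make_chain_model(n_atoms=4, seed=5)


class TestPcaModes:
    def test_rank_one_ensemble(self, base_topology, rng):
        base = base_topology.coordinates
        direction = rng.normal(size=base.size)
        direction /= np.linalg.norm(direction)
        amplitudes = np.linspace(-2, 2, 9)
        frames = np.array([base + (a * direction).reshape(-1, 3) for a in amplitudes])
        basis = pca_modes(frames)
        assert basis.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        # mode 1 is +-direction; sign convention makes it deterministic
        assert abs(np.dot(basis.eigenvectors[:, 0], direction)) == pytest.approx(1.0, abs=1e-9)
        j = np.argmax(np.abs(basis.eigenvectors[:, 0]))
        assert basis.eigenvectors[j, 0] > 0

    def test_two_mode_variance_ratio(self, base_topology, rng):
        # two orthogonal directions with variances 4 and 1 -> fractions 0.8 / 0.2
        base = base_topology.coordinates
        n_dim = base.size
        e1 = np.zeros(n_dim); e1[0] = 1.0
        e2 = np.zeros(n_dim); e2[4] = 1.0
        n = 10_000
        a = rng.normal(scale=2.0, size=n)
        b = rng.normal(scale=1.0, size=n)
        frames = base[None] + (a[:, None] * e1 + b[:, None] * e2).reshape(n, -1, 3)
        basis = pca_modes(frames)
        assert basis.variance_fractions[0] == pytest.approx(0.8, abs=0.02)
        assert basis.variance_fractions[1] == pytest.approx(0.2, abs=0.02)

    def test_single_frame_raises(self, base_topology):
        frames = base_topology.coordinates[None]
        with pytest.raises(ValueError, match="2 sampled frames"):
            pca_modes(frames)

    def test_empty_selection_raises(self, base_topology, rng):
        frames = np.repeat(base_topology.coordinates[None], 3, axis=0)
        with pytest.raises(ValueError):
            pca_modes(frames, selection=np.array([], dtype=int))

    def test_total_variance_equals_covariance_trace(self, base_topology, rng):
        frames = base_topology.coordinates[None] + rng.normal(
            scale=0.5, size=(50, 4, 3)
        )
        basis = pca_modes(frames)
        flat = frames.reshape(50, -1)
        trace = np.trace(np.cov(flat, rowvar=False, ddof=1))
        assert basis.total_variance == pytest.approx(trace, abs=1e-8)

    def test_subsampling_by_time(self, base_topology, rng):
        coords = base_topology.coordinates[None] + rng.normal(size=(21, 4, 3))
        ens = _ensemble(coords, base_topology, timestep=0.5)  # times 0 .. 10 ns
        basis_all = pca_modes([ens], sample_interval_ns=0.5)
        basis_1ns = pca_modes([ens], sample_interval_ns=1.0)
        # 1 ns sampling uses 11 of 21 frames; bases differ but stay orthonormal
        assert basis_all.eigenvalues.size == basis_1ns.eigenvalues.size
        assert basis_1ns.variance_fractions.sum() == pytest.approx(1.0)


class TestProjections:
    @pytest.fixture
    def fitted_basis(self, base_topology, rng):
        coords = base_topology.coordinates[None] + rng.normal(scale=0.8, size=(40, 4, 3))
        ens = _ensemble(coords, base_topology)
        return ens, pca_modes([ens], sample_interval_ns=1.0)

    def test_mean_frame_projects_to_origin(self, fitted_basis, base_topology):
        ens, basis = fitted_basis
        mean_frames = basis.mean_coordinates[None]
        mean_ens = _ensemble(mean_frames, base_topology)
        proj = project_frames([mean_ens], basis)
        np.testing.assert_allclose(proj.projections, 0.0, atol=1e-9)

    def test_unit_displacement_along_mode(self, fitted_basis, base_topology):
        ens, basis = fitted_basis
        displaced = basis.mean_coordinates + 2.0 * basis.eigenvectors[:, 0].reshape(-1, 3)
        proj = project_frames([_ensemble(displaced[None], base_topology)], basis)
        np.testing.assert_allclose(proj.projections[0], [2.0, 0.0], atol=1e-9)

    def test_full_mode_reconstruction(self, fitted_basis, base_topology):
        ens, basis = fitted_basis
        frame = ens.coordinates[7]
        all_proj = project_frames([ens], basis, n_modes=basis.eigenvalues.size)
        coeffs = all_proj.projections[7]
        recon = basis.mean_coordinates.reshape(-1) + basis.eigenvectors @ coeffs
        np.testing.assert_allclose(recon.reshape(-1, 3), frame, atol=1e-8)

    def test_one_point_per_frame(self, fitted_basis):
        ens, basis = fitted_basis
        proj = project_frames([ens, ens], basis)
        assert len(proj) == 2 * ens.n_frames

    def test_projection_invariance_under_common_rigid_transform(
        self, base_topology, rng
    ):
        coords = base_topology.coordinates[None] + rng.normal(scale=0.6, size=(30, 4, 3))
        ens = _ensemble(coords, base_topology)
        basis = pca_modes([ens], sample_interval_ns=1.0)
        proj0 = project_frames([ens], basis).projections

        common = RigidTransform(rotation_z(33.0), np.array([1.0, -2.0, 0.5]))
        moved = np.array([common.apply(f) for f in coords])
        refitted = np.empty_like(moved)
        for i, frame in enumerate(moved):  # fit back onto the original reference
            t, _ = kabsch_superpose(frame, coords[i])
            refitted[i] = t.apply(frame)
        proj1 = project_frames([_ensemble(refitted, base_topology)], basis).projections
        np.testing.assert_allclose(proj1, proj0, atol=1e-6)


class TestExtremeStates:
    def test_linear_sweep_returns_endpoints(self, base_topology, rng):
        base = base_topology.coordinates
        direction = rng.normal(size=base.size)
        direction /= np.linalg.norm(direction)
        amplitudes = np.linspace(-3, 3, 7)
        coords = np.array([base + (a * direction).reshape(-1, 3) for a in amplitudes])
        ens = _ensemble(coords, base_topology)
        basis = pca_modes([ens], sample_interval_ns=1.0)
        proj = project_frames([ens], basis)
        lo, hi = extreme_states(proj, [ens], n_modes=1)[0]
        extremes = {
            tuple(np.round(lo.coordinates.ravel(), 6)),
            tuple(np.round(hi.coordinates.ravel(), 6)),
        }
        expected = {
            tuple(np.round(coords[0].ravel(), 6)),
            tuple(np.round(coords[-1].ravel(), 6)),
        }
        assert extremes == expected

    def test_single_frame_is_both_extremes(self, base_topology):
        coords = base_topology.coordinates[None] * np.ones((2, 1, 1))
        coords[1] += 1e-9  # two nearly identical frames so PCA is defined
        ens = _ensemble(coords, base_topology)
        basis = pca_modes([ens], sample_interval_ns=1.0)
        single = _ensemble(coords[:1], base_topology)
        proj = project_frames([single], basis)
        lo, hi = extreme_states(proj, [single], n_modes=1)[0]
        np.testing.assert_array_equal(lo.coordinates, hi.coordinates)

    def test_tie_broken_by_earliest_time(self, base_topology, rng):
        from ensemblefit.modes import ProjectionSet

        # hand-built projections: frames 0 and 2 tie at the minimum
        coords = base_topology.coordinates[None] + np.arange(3)[:, None, None]
        ens = _ensemble(coords, base_topology)
        proj = ProjectionSet(
            projections=np.array([[0.0], [5.0], [0.0]]),
            times=np.array([0.0, 1.0, 2.0]),
            origin_conformations=np.array(["I"] * 3, dtype=object),
            replica_ids=np.zeros(3, dtype=int),
            ensemble_indices=np.zeros(3, dtype=int),
            frame_indices=np.arange(3),
        )
        lo, _ = extreme_states(proj, [ens], n_modes=1)[0]
        # earliest tied frame (index 0), not frame 2
        np.testing.assert_allclose(lo.coordinates, coords[0])


class TestProjectionHistogram:
    def test_all_points_one_bin(self, base_topology):
        coords = np.repeat(base_topology.coordinates[None], 3, axis=0)
        ens = _ensemble(coords, base_topology)
        basis = pca_modes([ens], sample_interval_ns=1.0)
        proj = project_frames([ens], basis)
        hist = projection_histogram(proj, bins=5)
        assert hist.density.max() == pytest.approx(1.0)

    def test_density_sums_to_one(self, base_topology, rng):
        coords = base_topology.coordinates[None] + rng.normal(size=(50, 4, 3))
        ens = _ensemble(coords, base_topology)
        basis = pca_modes([ens], sample_interval_ns=1.0)
        proj = project_frames([ens], basis)
        hist = projection_histogram(proj, bins=8)
        assert hist.density.sum() == pytest.approx(1.0)

    def test_outline_of_block_is_its_boundary(self, base_topology):
        # hand-built projection set occupying a 3x3 block of bins
        from ensemblefit.modes import ProjectionSet

        pts = np.array([[x, y] for x in range(3) for y in range(3)], dtype=float)
        proj = ProjectionSet(
            projections=pts,
            times=np.arange(9, dtype=float),
            origin_conformations=np.array(["I"] * 9, dtype=object),
            replica_ids=np.zeros(9, dtype=int),
            ensemble_indices=np.zeros(9, dtype=int),
            frame_indices=np.arange(9),
        )
        hist = projection_histogram(proj, bins=[np.arange(-0.5, 3), np.arange(-0.5, 3)])
        outline = hist.outlines["I"]
        expected = np.ones((3, 3), dtype=bool)
        expected[1, 1] = False  # interior bin eroded away
        np.testing.assert_array_equal(outline, expected)

    def test_isolated_bins_outline_themselves(self, base_topology):
        from ensemblefit.modes import ProjectionSet

        pts = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
        proj = ProjectionSet(
            projections=pts,
            times=np.arange(3, dtype=float),
            origin_conformations=np.array(["A", "A", "A"], dtype=object),
            replica_ids=np.zeros(3, dtype=int),
            ensemble_indices=np.zeros(3, dtype=int),
            frame_indices=np.arange(3),
        )
        hist = projection_histogram(proj, bins=10)
        occupied = hist.density > 0
        np.testing.assert_array_equal(hist.outlines["A"], occupied)
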