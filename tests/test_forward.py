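"""SPFD assembly and solver: stencil, oracles, conservation, convergence."""

import numpy as np
import pytest
import scipy.sparse as sp

from cardioloc.forward import (CurrentSource, assemble_system,
                               edge_conductances, potentials_at_electrodes,
                               solve)
from cardioloc.voxelmodel import ElectrodeMontage

MM = 1e-3


def random_sigma(shape, seed, lo=0.02, hi=1.0):
    """Random heterogeneous conductivity with a 1-voxel air shell."""
    rng = np.random.default_rng(seed)
    sigma = np.zeros(shape)
    inner = tuple(slice(1, -1) for _ in shape)
    sigma[inner] = rng.uniform(lo, hi, tuple(s - 2 for s in shape))
    return sigma


def dense_laplacian_oracle(sigma, pitch_mm):
    """Independent brute-force edge enumeration of the nodal Laplacian."""
    dims = tuple(s + 1 for s in sigma.shape)
    n = int(np.prod(dims))
    A = np.zeros((n, n))

    def sig(i, j, k):
        if (0 <= i < sigma.shape[0] and 0 <= j < sigma.shape[1]
                and 0 <= k < sigma.shape[2]):
            return sigma[i, j, k]
        return 0.0

    def ravel(i, j, k):
        return (i * dims[1] + j) * dims[2] + k

    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                a = ravel(i, j, k)
                for axis in range(3):
                    nb = [i, j, k]
                    nb[axis] += 1
                    if nb[axis] >= dims[axis]:
                        continue
                    b = ravel(*nb)
                    # 4 voxels sharing the edge along `axis`
                    others = [d for d in range(3) if d != axis]
                    vals = []
                    for da in (-1, 0):
                        for db in (-1, 0):
                            v = [i, j, k]
                            v[others[0]] += da
                            v[others[1]] += db
                            vals.append(sig(*v))
                    s = np.mean(vals) * pitch_mm * MM
                    if s > 0:
                        A[a, b] -= s
                        A[b, a] -= s
                        A[a, a] += s
                        A[b, b] += s
    return A


class TestAssembly:
    def test_uniform_interior_edge_conductance(self):
        sigma = np.zeros((5, 5, 5))
        sigma[1:-1, 1:-1, 1:-1] = 1.0
        sx, sy, sz = edge_conductances(sigma, 1.0)
        # edge fully inside the tissue: 1 S/m * 1 mm = 1e-3 S
        assert sx[2, 2, 2] == pytest.approx(1e-3)

    def test_mixed_tissue_air_edge_is_mean_of_four(self):
        sigma = np.zeros((4, 4, 4))
        sigma[1, 1:3, 1] = 2.0  # 2 tissue voxels, 2 air voxels share the edge
        sx, _, _ = edge_conductances(sigma, 1.0)
        assert sx[1, 2, 1] == pytest.approx(np.mean([2.0, 2.0, 0.0, 0.0]) * 1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            edge_conductances(-np.ones((3, 3, 3)), 1.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matrix_equals_dense_laplacian_oracle(self, seed):
        sigma = random_sigma((6, 6, 6), seed)
        system = assemble_system(sigma, 1.0)
        oracle = dense_laplacian_oracle(sigma, 1.0)
        A = system.matrix.toarray()
        ref = system.reference
        # grounding replaces the reference row/column and inactive nodes get
        # dummy diagonals; everything else must equal the oracle exactly
        keep = np.flatnonzero(system.active)
        keep = keep[keep != ref]
        assert np.allclose(A[np.ix_(keep, keep)], oracle[np.ix_(keep, keep)],
                           atol=1e-18)
        off = A - np.diag(np.diag(A))
        off_oracle = oracle - np.diag(np.diag(oracle))
        off[ref, :] = off[:, ref] = 0
        off_oracle[ref, :] = off_oracle[:, ref] = 0
        assert np.allclose(off, off_oracle, atol=1e-18)

    def test_symmetry_and_inactive_identity_rows(self):
        sigma = random_sigma((5, 5, 5), 1)
        system = assemble_system(sigma, 1.0)
        A = system.matrix
        assert abs(A - A.T).max() == 0.0
        inactive = ~system.active
        sub = A[inactive][:, inactive]
        assert (sub - sp.diags(sub.diagonal())).nnz == 0


class TestSolve:
    def test_zero_source_gives_zero_field(self):
        system = assemble_system(random_sigma((5, 5, 5), 0), 1.0)
        src = CurrentSource(nodes=((2, 2, 2), (2, 2, 3)), currents=(0.0, 0.0))
        f = solve(system, src)
        assert not f.phi.any()

    def test_unbalanced_source_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            CurrentSource(nodes=((1, 1, 1),), currents=(1.0,))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dense_linear_algebra_oracle_9cube(self, seed):
        """Direct solve of the independently assembled dense system."""
        sigma = random_sigma((9, 9, 9), seed)
        system = assemble_system(sigma, 1.0)
        src = CurrentSource.dipole((4, 4, 4), seed % 3, 1.0, 1.0)
        f = solve(system, src, method="direct")
        oracle = dense_laplacian_oracle(sigma, 1.0)
        b = src.rhs(system)
        ref = system.reference
        keep = np.flatnonzero(system.active)
        keep = keep[keep != ref]
        x = np.zeros(system.n_nodes)
        x[keep] = np.linalg.solve(oracle[np.ix_(keep, keep)], b[keep])
        rel = (np.linalg.norm(f.phi[keep] - x[keep])
               / np.linalg.norm(x[keep]))
        assert rel <= 1e-8

    def test_superposition(self):
        system = assemble_system(random_sigma((7, 7, 7), 2), 1.0)
        s1 = CurrentSource.dipole((3, 3, 3), 0, 1.0, 1.0)
        s2 = CurrentSource.dipole((4, 4, 4), 2, 0.7, 1.0)
        both = CurrentSource(nodes=s1.nodes + s2.nodes,
                             currents=s1.currents + s2.currents)
        f1 = solve(system, s1, method="direct")
        f2 = solve(system, s2, method="direct")
        f12 = solve(system, both, method="direct")
        assert np.allclose(f12.phi, f1.phi + f2.phi, atol=1e-10)

    def test_doubling_conductivity_halves_potentials(self):
        sigma = random_sigma((7, 7, 7), 3)
        src = CurrentSource.dipole((3, 3, 3), 1, 1.0, 1.0)
        f1 = solve(assemble_system(sigma, 1.0), src, method="direct")
        f2 = solve(assemble_system(2 * sigma, 1.0), src, method="direct")
        assert np.allclose(f2.phi, f1.phi / 2.0, atol=1e-12)

    def test_multigrid_and_sor_agree(self):
        sigma = random_sigma((17, 17, 17), 4)
        system = assemble_system(sigma, 1.0)
        src = CurrentSource.dipole((8, 8, 8), 2, 1.0, 1.0)
        f_mg = solve(system, src, method="multigrid", tol=1e-8)
        f_sor = solve(system, src, method="sor", tol=1e-8, max_cycles=500)
        scale = np.abs(f_mg.phi).max()
        assert np.abs(f_mg.phi - f_sor.phi).max() <= 1e-4 * scale

    def test_kirchhoff_current_law_at_nonsource_nodes(self):
        sigma = random_sigma((9, 9, 9), 5)
        system = assemble_system(sigma, 1.0)
        src = CurrentSource.dipole((4, 4, 4), 0, 1.0, 1.0)
        f = solve(system, src, tol=1e-6)
        b = src.rhs(system)
        r = b - system.matrix @ f.phi
        mask = np.ones(system.n_nodes, bool)
        for node in src.nodes:
            mask[system.ravel(node)] = False
        mask[system.reference] = False
        assert np.abs(r[mask]).max() <= 1e-6 * np.linalg.norm(b)

    def test_reported_residual_meets_tolerance(self):
        system = assemble_system(random_sigma((13, 13, 13), 6), 1.0)
        src = CurrentSource.dipole((6, 6, 6), 1, 1.0, 1.0)
        for method in ("direct", "multigrid", "sor"):
            f = solve(system, src, method=method, tol=1e-6, max_cycles=500)
            assert f.residual <= 1e-6
            assert f.phi[system.reference] == 0.0


class TestElectrodePotentials:
    def make_montage(self, system):
        # nine distinct surface nodes of the block model
        top = system.node_dims[2] - 2
        nodes = [(1 + i, 1, top) for i in range(9)]
        names = ElectrodeMontage.STANDARD_NAMES
        return ElectrodeMontage(electrodes=tuple(zip(names, nodes)))

    def test_zero_and_constant_fields(self):
        sigma = random_sigma((12, 12, 12), 7)
        system = assemble_system(sigma, 1.0)
        montage = self.make_montage(system)
        src = CurrentSource.dipole((5, 5, 5), 0, 1.0, 1.0)
        f = solve(system, src, method="direct")
        f.phi[:] = 0.0
        assert np.array_equal(potentials_at_electrodes(f, system, montage),
                              np.zeros(9))
        f.phi[:] = 3.14
        assert np.allclose(potentials_at_electrodes(f, system, montage), 3.14)

    def test_mirror_symmetry_flips_potential_sign(self):
        # symmetric conductor, dipole along x centered on the mirror plane
        # x = 4.5: the potential is antisymmetric up to the gauge constant,
        # so the sum over any mirrored node pair is the same constant
        sigma = np.zeros((9, 9, 9))
        sigma[1:-1, 1:-1, 1:-1] = 0.3
        system = assemble_system(sigma, 1.0)
        src = CurrentSource.dipole((4, 4, 4), 0, 1.0, 1.0)
        f = solve(system, src, method="direct")
        phi = f.phi.reshape(system.node_dims)
        sums = [phi[x, y, z] + phi[9 - x, y, z]
                for x, y, z in [(3, 4, 6), (2, 3, 5), (1, 6, 2), (3, 2, 2)]]
        assert np.ptp(sums) <= 1e-9 * np.abs(phi).max()
        # and mirrored pairs genuinely carry opposite deviations from it
        assert abs(phi[3, 4, 6] - sums[0] / 2) > 0
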