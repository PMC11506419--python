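"""Greedy sparse localization: selection, iteration, point extraction, tracks.

sklearn's OrthogonalMatchingPursuit serves as the independent cross-check
for the greedy support selection and least-squares refit.
"""

import numpy as np
import pytest

from cardioloc.ecg import AnalysisWindow, ECGRecord
from cardioloc.leadfield import LEADS_INDEPENDENT, CandidateGrid, LeadFieldMatrix
from cardioloc.omp import (localize_track, omp_iterate, omp_select,
                           result_to_point)


def random_lfm(m=8, n_points=10, seed=0):
    rng = np.random.default_rng(seed)
    L = rng.normal(size=(m, 3 * n_points))
    pts = rng.uniform(0, 50, size=(n_points, 3))
    nodes = np.arange(3 * n_points).reshape(n_points, 3)
    grid = CandidateGrid(node_indices=nodes, points_mm=pts, spacing=1)
    return LeadFieldMatrix(L=L, lead_labels=LEADS_INDEPENDENT, grid=grid,
                           pitch_mm=1.0)


class TestSelect:
    def test_exact_column_has_unit_correlation(self):
        lfm = random_lfm()
        phi = lfm.L[:, 7].copy()
        assert omp_select(phi, lfm.L, support=set()) == 7

    def test_orthogonal_to_all_but_one(self):
        L = np.eye(8)[:, :6]
        phi = np.zeros(8)
        phi[3] = 2.0
        assert omp_select(phi, L, support=set()) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(8, 30))
        phi = rng.normal(size=8)
        corr = np.abs(L.T @ phi) / (np.linalg.norm(phi)
                                    * np.linalg.norm(L, axis=0))
        assert omp_select(phi, L, support=set()) == int(np.argmax(corr))

    def test_tie_breaks_to_lowest_index(self):
        col = np.ones(8)
        L = np.stack([col, 2 * col, -col], axis=1)  # all perfectly correlated
        assert omp_select(col, L, support=set()) == 0

    def test_zero_observation_rejected(self):
        lfm = random_lfm()
        with pytest.raises(ValueError, match="zero"):
            omp_select(np.zeros(8), lfm.L, support=set())


class TestIterate:
    def test_one_sparse_exact_recovery(self):
        lfm = random_lfm(seed=1)
        phi = 0.37 * lfm.L[:, 11]
        res = omp_iterate(phi, lfm)
        assert res.support[0] == 11
        assert res.residual_norms[0] <= 1e-10 * np.linalg.norm(phi)
        pt = result_to_point(res, lfm.grid)
        assert np.allclose(pt, lfm.grid.points_mm[11 // 3])

    def test_two_sparse_low_coherence_recovery(self):
        # construct a dictionary with mutual coherence < 0.5 and verify both
        # true columns enter the support within two iterations
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        L = q + 0.05 * rng.normal(size=(12, 12))  # near-orthonormal columns
        Ln = L / np.linalg.norm(L, axis=0)
        G = np.abs(Ln.T @ Ln)
        np.fill_diagonal(G, 0)
        assert G.max() < 0.5
        from cardioloc.leadfield import LEADS_12

        grid = CandidateGrid(node_indices=np.arange(12).reshape(4, 3),
                             points_mm=rng.uniform(0, 10, (4, 3)), spacing=1)
        lfm = LeadFieldMatrix(L=L, lead_labels=LEADS_12, grid=grid,
                              pitch_mm=1.0)
        phi = 1.0 * L[:, 2] + 0.8 * L[:, 9]
        res = omp_iterate(phi, lfm)
        assert {2, 9} <= set(res.support[:2])

    @pytest.mark.parametrize("seed", range(100))
    def test_residual_norms_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        lfm = random_lfm(seed=seed)
        phi = rng.normal(size=8)
        res = omp_iterate(phi, lfm)
        norms = np.asarray(res.residual_norms)
        assert (np.diff(norms) <= 1e-12 * norms[0]).all()

    def test_weights_are_convex_combination(self):
        lfm = random_lfm(seed=2)
        res = omp_iterate(np.random.default_rng(0).normal(size=8), lfm)
        assert res.weights.sum() == pytest.approx(1.0)
        assert (res.weights >= 0).all()
        assert len(res.support) == len(set(res.support)) == 5

    def test_matches_sklearn_omp_support_and_fit(self):
        from sklearn.linear_model import OrthogonalMatchingPursuit

        rng = np.random.default_rng(7)
        lfm = random_lfm(m=8, n_points=6, seed=7)
        phi = rng.normal(size=8)
        res = omp_iterate(phi, lfm, n_iter=3)
        sk = OrthogonalMatchingPursuit(n_nonzero_coefs=3, fit_intercept=False)
        # sklearn normalizes selection by column norm the same way on
        # standardized columns; compare on a column-normalized dictionary
        Ln = lfm.L / np.linalg.norm(lfm.L, axis=0)
        lfm_n = LeadFieldMatrix(L=Ln, lead_labels=lfm.lead_labels,
                                grid=lfm.grid, pitch_mm=1.0)
        res_n = omp_iterate(phi, lfm_n, n_iter=3)
        sk.fit(Ln, phi)
        assert set(np.flatnonzero(sk.coef_)) == set(res_n.support)
        j_final = res_n.j_iterates[-1]
        assert np.allclose(j_final, sk.coef_, atol=1e-8)

    def test_permutation_equivariance(self):
        lfm = random_lfm(seed=3)
        rng = np.random.default_rng(4)
        phi = rng.normal(size=8)
        res = omp_iterate(phi, lfm)
        perm = rng.permutation(lfm.L.shape[1])
        lfm_p = LeadFieldMatrix(L=lfm.L[:, perm], lead_labels=lfm.lead_labels,
                                grid=lfm.grid, pitch_mm=1.0)
        res_p = omp_iterate(phi, lfm_p)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert [int(inv[c]) for c in res.support] == res_p.support


class TestResultToPoint:
    def test_single_nonzero_candidate(self):
        lfm = random_lfm(seed=8)
        res = omp_iterate(lfm.L[:, 4], lfm, n_iter=1)
        assert np.allclose(result_to_point(res, lfm.grid),
                           lfm.grid.points_mm[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_norm_scan(self, seed):
        rng = np.random.default_rng(seed)
        lfm = random_lfm(seed=seed)
        res = omp_iterate(rng.normal(size=8), lfm)
        norms = [np.linalg.norm(res.j_star[3 * i:3 * i + 3])
                 for i in range(lfm.grid.n)]
        assert np.allclose(result_to_point(res, lfm.grid),
                           lfm.grid.points_mm[int(np.argmax(norms))])


class TestLocalizeTrack:
    def make_record_from_j(self, lfm, j_of_t, fs=2000.0):
        """Forward-generate a 12-lead record whose independent leads are L j."""
        T = len(j_of_t)
        samples = np.zeros((12, T))
        order = ("I", "II", "III", "aVR", "aVL", "aVF",
                 "V1", "V2", "V3", "V4", "V5", "V6")
        ind = {lab: r for r, lab in enumerate(LEADS_INDEPENDENT)}
        for t, j in enumerate(j_of_t):
            phi = lfm.L @ j
            by = dict(zip(LEADS_INDEPENDENT, phi))
            full = {**by, "III": by["II"] - by["I"],
                    "aVR": -(by["I"] + by["II"]) / 2,
                    "aVL": by["I"] - by["II"] / 2,
                    "aVF": by["II"] - by["I"] / 2}
            samples[:, t] = [full[lab] for lab in order]
        return ECGRecord(samples=samples, fs=fs)

    def test_static_dipole_track_is_constant(self):
        lfm = random_lfm(seed=9)
        env = np.linspace(0, 1, 40)
        j = np.zeros(3 * lfm.grid.n)
        j[12] = 1.0
        rec = self.make_record_from_j(lfm, [e * j for e in env])
        track = localize_track(rec, AnalysisWindow(1, 39), lfm,
                               noise_floor_k=0.0)
        assert track.n_steps == 39
        _, pts = track.valid_points()
        assert np.allclose(pts, lfm.grid.points_mm[4])

    def test_moving_dipole_round_trip(self):
        lfm = random_lfm(n_points=8, seed=10)
        path = [0, 2, 2, 5, 7]
        js = []
        for ci in path:
            j = np.zeros(3 * lfm.grid.n)
            j[3 * ci] = 1.0
            js.append(j)
        rec = self.make_record_from_j(lfm, js)
        track = localize_track(rec, AnalysisWindow(0, 4), lfm,
                               amplitude_floor=0.0, noise_floor_k=0.0)
        assert track.n_steps == 5
        assert np.allclose(track.points_mm, lfm.grid.points_mm[path])

    def test_low_amplitude_steps_are_skipped(self):
        lfm = random_lfm(seed=11)
        j = np.zeros(3 * lfm.grid.n)
        j[0] = 1.0
        env = np.array([1e-5, 0.5, 1.0])
        rec = self.make_record_from_j(lfm, [e * j for e in env])
        track = localize_track(rec, AnalysisWindow(0, 2), lfm,
                               amplitude_floor=0.01, noise_floor_k=0.0)
        assert track.skipped.tolist() == [True, False, False]
        assert np.isnan(track.points_mm[0]).all()

    def test_csv_round_trip(self, tmp_path):
        lfm = random_lfm(seed=12)
        j = np.zeros(3 * lfm.grid.n)
        j[3] = 2.0
        rec = self.make_record_from_j(lfm, [j * e for e in (0.5, 1.0)])
        track = localize_track(rec, AnalysisWindow(0, 1), lfm,
                               noise_floor_k=0.0)
        path = tmp_path / "track.csv"
        track.to_csv(path)
        from cardioloc.omp import SourceTrack

        back = SourceTrack.from_csv(path)
        assert np.allclose(back.points_mm, track.points_mm, equal_nan=True)
        assert np.array_equal(back.skipped, track.skipped)
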