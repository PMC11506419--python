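"""Orthogonal-matching-pursuit source localization on the lead field matrix.

For each time step of the analysis window, the observed lead vector phi is
greedily decomposed over the lead-field dictionary: the column with maximal
normalized correlation with the residual is appended to the support, the
current density on the support is re-fit by least squares (the pseudoinverse
of the support submatrix), and the residual updated. After five iterations
the per-iteration estimates are combined by a residual-weighted average and
the candidate whose 3-component dipole sub-vector carries the largest norm
is reported as the source location for that time step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ecg import AnalysisWindow, ECGRecord
from .leadfield import CandidateGrid, LeadFieldMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OmpResult",
    "SourceTrack",
    "omp_select",
    "omp_iterate",
    "result_to_point",
    "localize_track",
]


@dataclass
class OmpResult:
    """Outcome of one per-time-step OMP run."""

    support: list[int]                 # selected column indices, in order
    j_iterates: list[np.ndarray]       # reconstructed 3N vectors per iteration
    residual_norms: list[float]        # ||phi_k|| after each iteration
    j_star: np.ndarray                 # residual-weighted average estimate
    weights: np.ndarray                # convex weights over iterations


@dataclass
class SourceTrack:
    """Estimated source point per analysis-window time step."""

    times_s: np.ndarray        # (W,)
    points_mm: np.ndarray      # (W, 3); NaN where skipped
    j_star: np.ndarray         # (W, 3N)
    residuals: np.ndarray      # (W,) final residual norms; NaN where skipped
    skipped: np.ndarray        # (W,) bool

    @property
    def n_steps(self) -> int:
        return len(self.times_s)

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, points) of non-skipped steps."""
        keep = ~self.skipped
        return self.times_s[keep], self.points_mm[keep]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "t_s": self.times_s,
            "x_mm": self.points_mm[:, 0],
            "y_mm": self.points_mm[:, 1],
            "z_mm": self.points_mm[:, 2],
            "residual": self.residuals,
            "skipped": self.skipped.astype(int),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SourceTrack":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times_s=df["t_s"].to_numpy(),
            points_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            j_star=np.zeros((len(df), 0)),
            residuals=df["residual"].to_numpy(),
            skipped=df["skipped"].to_numpy().astype(bool),
        )


def omp_select(phi: np.ndarray, L: np.ndarray, support: set[int] | list[int],
               signed: bool = False) -> int:
    """Index of the non-support column best correlated with phi.

    Correlation is ``phi . L_i / (||phi|| ||L_i||)``; by default the absolute
    value is maximized (a sign-flipped dipole is the same physical source).
    Ties break to the lowest column index.
    """
    phi = np.asarray(phi, dtype=float)
    nrm = np.linalg.norm(phi)
    if nrm == 0:
        raise ValueError("zero observation vector: nothing to correlate")
    colnorms = np.linalg.norm(L, axis=0)
    if (colnorms == 0).any():
        raise ValueError("lead field contains an all-zero column")
    corr = (L.T @ phi) / (nrm * colnorms)
    score = corr if signed else np.abs(corr)
    score = score.copy()
    score[list(support)] = -np.inf
    return int(np.argmax(score))


def omp_iterate(phi: np.ndarray, lfm: LeadFieldMatrix, n_iter: int = 5,
                signed: bool = False, eps_rel: float = 1e-12) -> OmpResult:
    """Run n_iter OMP iterations and residual-weighted averaging.

    Per iteration: select a column, refit ``j = pinv(L_support) phi0`` on the
    support (zeros elsewhere), update the residual ``phi0 - L j``. The final
    estimate is ``j* = sum_k w_k j_k`` with ``w_k \\propto 1/(||phi_k|| + eps)``
    normalized to 1, so better-fitting iterations dominate. A rank-deficient
    support drops the newly added column (logged) and continues.
    """
    L = lfm.L
    M, n_cols = L.shape
    if n_cols < n_iter:
        raise ValueError(f"need >= {n_iter} columns, have {n_cols}")
    phi0 = np.asarray(phi, dtype=float)
    phi0_norm = float(np.linalg.norm(phi0))
    if phi0_norm == 0:
        raise ValueError("zero observation vector")

    support: list[int] = []
    excluded: set[int] = set()
    resid = phi0.copy()
    j_iterates: list[np.ndarray] = []
    residual_norms: list[float] = []

    k = 0
    while k < n_iter:
        try:
            i_hat = omp_select(resid, L, set(support) | excluded, signed=signed)
        except ValueError:
            break  # residual hit exactly zero; keep completed iterations
        trial = support + [i_hat]
        Ls = L[:, trial]
        j_s, _, rank, _ = np.linalg.lstsq(Ls, phi0, rcond=None)
        if rank < len(trial):
            logger.warning("OMP: column %d makes the support rank-deficient; dropped",
                           i_hat)
            excluded.add(i_hat)
            continue
        support = trial
        j_full = np.zeros(n_cols)
        j_full[support] = j_s
        resid = phi0 - Ls @ j_s
        j_iterates.append(j_full)
        residual_norms.append(float(np.linalg.norm(resid)))
        k += 1
        if not np.isfinite(resid).all():
            raise FloatingPointError("OMP residual became non-finite")

    if not j_iterates:
        raise ValueError("OMP made no progress: no admissible columns")

    eps = eps_rel * phi0_norm
    w = 1.0 / (np.asarray(residual_norms) + eps)
    w = w / w.sum()
    j_star = np.einsum("k,kn->n", w, np.asarray(j_iterates))
    return OmpResult(support=support, j_iterates=j_iterates,
                     residual_norms=residual_norms, j_star=j_star, weights=w)


def result_to_point(result: OmpResult, grid: CandidateGrid) -> np.ndarray:
    """Candidate location whose 3-vector of j* has the largest Euclidean norm."""
    j = result.j_star
    if not np.any(j):
        raise ValueError("all-zero current density estimate")
    norms = np.linalg.norm(j.reshape(grid.n, 3), axis=1)
    return grid.points_mm[int(np.argmax(norms))].copy()


def localize_track(record: ECGRecord, window: AnalysisWindow,
                   lfm: LeadFieldMatrix, n_iter: int = 5,
                   amplitude_floor: float = 0.01,
                   noise_floor_k: float = 3.0, signed: bool = False
                   ) -> SourceTrack:
    """Per-time-step OMP over the rise-to-peak window.

    Small early-excitation amplitudes produce unstable estimates, so steps
    are skipped when their lead-vector RMS falls below ``amplitude_floor``
    times the window maximum, or below ``noise_floor_k`` times the baseline
    noise level measured on the pre-window (isoelectric) segment of the
    record — steps not significantly above the noise floor carry no usable
    source information.
    """
    if window.peak >= record.n_samples:
        raise ValueError("analysis window extends beyond the record")
    rows = [record.lead_labels.index(lab) for lab in lfm.lead_labels]
    sel = window.indices()
    Phi = record.samples[np.ix_(rows, sel)]  # (M, W)
    W = Phi.shape[1]
    step_rms = np.sqrt((Phi ** 2).mean(axis=0))
    floor = amplitude_floor * step_rms.max()
    if noise_floor_k > 0 and window.start >= 8:
        baseline = record.samples[np.ix_(rows, np.arange(window.start))]
        noise_rms = float(np.sqrt(baseline.var(axis=1).mean()))
        floor = max(floor, noise_floor_k * noise_rms)

    points = np.full((W, 3), np.nan)
    j_star = np.zeros((W, 3 * lfm.grid.n))
    residuals = np.full(W, np.nan)
    skipped = np.zeros(W, dtype=bool)
    for t in range(W):
        if step_rms[t] <= floor or step_rms[t] == 0.0:
            skipped[t] = True
            continue
        res = omp_iterate(Phi[:, t], lfm, n_iter=n_iter, signed=signed)
        points[t] = result_to_point(res, lfm.grid)
        j_star[t] = res.j_star
        residuals[t] = res.residual_norms[-1]
    return SourceTrack(times_s=sel / record.fs, points_mm=points,
                       j_star=j_star, residuals=residuals, skipped=skipped)
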