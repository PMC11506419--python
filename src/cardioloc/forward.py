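"""Quasi-static scalar-potential finite-difference (SPFD) forward solver.

At ECG frequencies (~1 Hz) displacement currents are negligible, so the
potential phi in the volume conductor obeys the Poisson equation
``div(sigma grad phi) = -div(J)`` with an insulating boundary
(``sigma grad phi . n = 0``) on the body surface. Discretized on voxel corner
nodes this is Kirchhoff's current law: for every node,
``sum_n S_n (phi_0 - phi_n) = I_0``, where ``S_n`` is the conductance of the
edge to the n-th of the 6 neighbors — the mean of the conductivities of the 4
voxels sharing the edge times the voxel pitch (area/length = pitch for cubic
voxels) — and ``I_0`` is the current injected at the node. Air-adjacent edges
have vanishing conductance, which realizes the insulating boundary naturally.

The resulting symmetric system is solved, after grounding one reference node,
by successive over-relaxation (SOR) sweeps accelerated with a geometric
multigrid V-cycle (Galerkin coarse operators, trilinear prolongation,
6 levels by default) until the relative l2 residual falls below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .voxelmodel import ElectrodeMontage

__all__ = [
    "SpfdSystem",
    "CurrentSource",
    "PotentialField",
    "ConvergenceError",
    "assemble_system",
    "edge_conductances",
    "solve",
    "potentials_at_electrodes",
]

MM = 1e-3  # mm -> m


class ConvergenceError(RuntimeError):
    """Raised when the iterative solver fails to reach tolerance."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def edge_conductances(sigma: np.ndarray, pitch_mm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge conductances (S) along x, y, z.

    ``sx[i, j, k]`` is the conductance of the edge from node (i, j, k) to
    (i+1, j, k): the mean of the 4 voxel conductivities sharing the edge
    (out-of-grid voxels count as air) times the pitch in meters.
    """
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("conductivity field contains negative values")
    h = pitch_mm * MM

    def mean4(pad_axes: tuple[int, int]) -> np.ndarray:
        pad = [(0, 0)] * 3
        for ax in pad_axes:
            pad[ax] = (1, 1)
        p = np.pad(sigma, pad)
        a, b = pad_axes
        sl = [slice(None)] * 3
        out = np.zeros(tuple(
            sigma.shape[i] + (1 if i in pad_axes else 0) for i in range(3)
        ))
        for da in (0, 1):
            for db in (0, 1):
                s = list(sl)
                s[a] = slice(da, p.shape[a] - 1 + da)
                s[b] = slice(db, p.shape[b] - 1 + db)
                out += p[tuple(s)]
        return 0.25 * out

    sx = mean4((1, 2)) * h
    sy = mean4((0, 2)) * h
    sz = mean4((0, 1)) * h
    return sx, sy, sz


@dataclass
class SpfdSystem:
    """Assembled SPFD conductance system on the node grid.

    Attributes
    ----------
    node_dims : (nx+1, ny+1, nz+1)
    matrix : grounded sparse conductance Laplacian (CSR, SPD on active nodes)
    active : flat boolean mask of nodes touching >= 1 conducting voxel
    reference : flat index of the grounded node (phi = 0 there)
    pitch_mm : voxel pitch
    """

    node_dims: tuple[int, int, int]
    matrix: sp.csr_matrix
    active: np.ndarray
    reference: int
    pitch_mm: float
    edge_s: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)
    _hierarchy: list | None = field(default=None, repr=False)
    _direct: object = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_dims))

    def ravel(self, node: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(int(v) for v in node), self.node_dims))

    def is_active(self, node: Sequence[int]) -> bool:
        return bool(self.active[self.ravel(node)])


@dataclass(frozen=True)
class CurrentSource:
    """Balanced set of nodal current injections (A).

    A dipole is a +I/-I pair on adjacent nodes; its moment is ``I * d * u``
    with ``d`` the pitch (mm), so a unit 1 A.mm moment uses I = 1/pitch_mm.
    """

    nodes: tuple[tuple[int, int, int], ...]
    currents: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.currents):
            raise ValueError("nodes and currents must have equal length")
        total = float(sum(self.currents))
        scale = max(1.0, max((abs(c) for c in self.currents), default=1.0))
        if abs(total) > 1e-12 * scale:
            raise ValueError(f"injected currents must sum to 0, got {total}")

    @classmethod
    def dipole(cls, node: Sequence[int], axis: int, moment_amm: float,
               pitch_mm: float) -> "CurrentSource":
        """Dipole of moment ``moment_amm`` (A.mm) along +axis at ``node``.

        +I is placed at ``node + e_axis`` and -I at ``node``, so the moment
        vector points along the positive axis.
        """
        a = tuple(int(v) for v in node)
        b = list(a)
        b[axis] += 1
        current = moment_amm / pitch_mm
        return cls(nodes=(tuple(b), a), currents=(current, -current))

    def rhs(self, system: SpfdSystem) -> np.ndarray:
        b = np.zeros(system.n_nodes)
        for node, cur in zip(self.nodes, self.currents):
            idx = system.ravel(node)
            if not system.active[idx]:
                raise ValueError(f"source node {tuple(node)} is not active")
            if idx == system.reference:
                raise ValueError(
                    "source coincides with the reference node; re-assemble with "
                    "a different reference_node"
                )
            b[idx] += cur
        return b


@dataclass
class PotentialField:
    """Node potentials (V) plus solver diagnostics."""

    phi: np.ndarray  # flat, full node grid; 0 at inactive nodes
    node_dims: tuple[int, int, int]
    iterations: int
    residual: float
    method: str
    history: list[float] = field(default_factory=list)

    def grid(self) -> np.ndarray:
        return self.phi.reshape(self.node_dims)

    def at_node(self, node: Sequence[int]) -> float:
        return float(self.grid()[tuple(int(v) for v in node)])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_system(sigma: np.ndarray, pitch_mm: float,
                    reference_node: Sequence[int] | None = None) -> SpfdSystem:
    """Build the grounded nodal conductance Laplacian from a sigma field."""
    sigma = np.asarray(sigma, dtype=float)
    sx, sy, sz = edge_conductances(sigma, pitch_mm)
    node_dims = tuple(s + 1 for s in sigma.shape)
    n = int(np.prod(node_dims))
    strides = (node_dims[1] * node_dims[2], node_dims[2], 1)

    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for axis, s_edge in enumerate((sx, sy, sz)):
        # flat index of the lower node of each edge along `axis`
        idx = np.indices(s_edge.shape).reshape(3, -1)
        i0 = (idx[0] * strides[0] + idx[1] * strides[1] + idx[2] * strides[2])
        i1 = i0 + strides[axis]
        c = s_edge.ravel()
        nz = c > 0
        i0, i1, c = i0[nz], i1[nz], c[nz]
        rows.append(i0); cols.append(i1); vals.append(-c)
        rows.append(i1); cols.append(i0); vals.append(-c)
        np.add.at(diag, i0, c)
        np.add.at(diag, i1, c)

    active = diag > 0
    if not active.any():
        raise ValueError("no conducting voxels: system has no active nodes")
    if reference_node is None:
        ref = int(np.flatnonzero(active)[0])
    else:
        ref = int(np.ravel_multi_index(tuple(int(v) for v in reference_node), node_dims))
        if not active[ref]:
            raise ValueError("reference node is not active")

    rows = np.concatenate(rows); cols = np.concatenate(cols); vals = np.concatenate(vals)
    # ground the reference: drop its row/col couplings, unit diagonal;
    # inactive nodes get unit diagonals too (decoupled identity rows)
    keep = (rows != ref) & (cols != ref)
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    d = diag.copy()
    # dummy diagonals (decoupled air nodes, grounded reference) are scaled to
    # the typical edge conductance so coarse Galerkin operators stay balanced
    s_typ = float(diag[active].mean())
    d[~active] = s_typ
    d[ref] = s_typ
    all_rows = np.concatenate([rows, np.arange(n)])
    all_cols = np.concatenate([cols, np.arange(n)])
    all_vals = np.concatenate([vals, d])
    A = sp.csr_matrix((all_vals, (all_rows, all_cols)), shape=(n, n))
    A.sum_duplicates()

    return SpfdSystem(node_dims=node_dims, matrix=A, active=active,
                      reference=ref, pitch_mm=pitch_mm, edge_s=(sx, sy, sz))


# ---------------------------------------------------------------------------
# Multigrid machinery
# ---------------------------------------------------------------------------

def _interp_1d(n: int) -> sp.csr_matrix:
    """1-D trilinear prolongation from the coarse grid of every-other node."""
    nc = (n - 1) // 2 + 1
    rows, cols, vals = [], [], []
    for f in range(n):
        i, r = divmod(f, 2)
        if r == 0:
            rows.append(f); cols.append(i); vals.append(1.0)
        elif i + 1 < nc:
            rows += [f, f]; cols += [i, i + 1]; vals += [0.5, 0.5]
        else:
            rows.append(f); cols.append(i); vals.append(1.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, nc))


class _Level:
    __slots__ = ("A", "Mf", "Mb", "P", "lu", "dims", "active")

    def __init__(self, A: sp.csr_matrix, dims: tuple[int, int, int], omega: float,
                 active: np.ndarray):
        self.A = A
        self.dims = dims
        self.active = active
        self.P = None
        self.lu = None
        lower = sp.tril(A, k=-1, format="csr")
        upper = sp.triu(A, k=1, format="csr")
        dinv = sp.diags(A.diagonal() / omega)
        self.Mf = (dinv + lower).tocsr()
        self.Mb = (dinv + upper).tocsr()


def _build_hierarchy(system: SpfdSystem, levels: int, omega: float,
                     coarse_size: int = 1500) -> list[_Level]:
    hier = [_Level(system.matrix, system.node_dims, omega, system.active)]
    s_typ = float(system.matrix.diagonal()[system.active].mean())
    while len(hier) < levels:
        dims = hier[-1].dims
        if min(dims) < 4 or hier[-1].A.shape[0] <= coarse_size:
            break
        P = sp.kron(sp.kron(_interp_1d(dims[0]), _interp_1d(dims[1])),
                    _interp_1d(dims[2])).tocsr()
        cdims = tuple((d - 1) // 2 + 1 for d in dims)
        # truncate interpolation at the conductor boundary: active fine nodes
        # must interpolate only from active coarse parents, else the coarse
        # correction cannot represent surface error modes
        act_f = hier[-1].active
        act_c = act_f.reshape(dims)[::2, ::2, ::2].reshape(-1)
        P = sp.diags(act_f.astype(float)) @ P @ sp.diags(act_c.astype(float))
        P.eliminate_zeros()
        rowsum = np.asarray(P.sum(axis=1)).ravel()
        scale = np.divide(1.0, rowsum, out=np.zeros_like(rowsum),
                          where=np.abs(rowsum) > 1e-12)
        P = (sp.diags(scale) @ P).tocsr()
        Ac = (P.T @ hier[-1].A @ P).tolil()
        dz = np.asarray(Ac.diagonal() == 0.0)
        Ac.setdiag(np.where(dz, s_typ, Ac.diagonal()))
        Ac = Ac.tocsr()
        hier[-1].P = P
        hier.append(_Level(Ac, cdims, omega, act_c))
    hier[-1].lu = spla.splu(hier[-1].A.tocsc())
    return hier


def _sor_forward(level: _Level, x: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = b - level.A @ x
    return x + spla.spsolve_triangular(level.Mf, r, lower=True)


def _sor_backward(level: _Level, x: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = b - level.A @ x
    return x + spla.spsolve_triangular(level.Mb, r, lower=False)


def _v_cycle(hier: list[_Level], lvl: int, b: np.ndarray, x: np.ndarray) -> np.ndarray:
    level = hier[lvl]
    if level.lu is not None:
        return level.lu.solve(b)
    x = _sor_forward(level, x, b)
    r = b - level.A @ x
    rc = level.P.T @ r
    ec = _v_cycle(hier, lvl + 1, rc, np.zeros_like(rc))
    x = x + level.P @ ec
    x = _sor_backward(level, x, b)
    return x


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def solve(system: SpfdSystem, source: CurrentSource, tol: float = 1e-6,
          method: Literal["auto", "multigrid", "sor", "direct"] = "auto",
          levels: int = 6, sor_omega: float = 1.5,
          max_cycles: int = 200) -> PotentialField:
    """Solve for the node potentials of a balanced current source.

    The relative l2 residual of the returned field is <= ``tol``; the
    potential is gauge-fixed to 0 at the system's reference node. ``auto``
    uses a sparse direct factorization below ~40k nodes and the SOR-smoothed
    multigrid above.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = source.rhs(system)
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return PotentialField(np.zeros(system.n_nodes), system.node_dims,
                              0, 0.0, "trivial")

    if method == "auto":
        method = "direct" if system.n_nodes <= 40_000 else "multigrid"

    A = system.matrix
    if method == "direct":
        if system._direct is None:
            system._direct = spla.splu(A.tocsc())
        x = system._direct.solve(b)
        res = float(np.linalg.norm(b - A @ x) / bnorm)
        iters, history = 1, [res]
    elif method == "multigrid":
        if system._hierarchy is None or len(system._hierarchy) > levels:
            system._hierarchy = _build_hierarchy(system, levels, sor_omega)
        hier = system._hierarchy
        x = np.zeros(system.n_nodes)
        history = []
        for cycle in range(1, max_cycles + 1):
            x = _v_cycle(hier, 0, b, x)
            res = float(np.linalg.norm(b - A @ x) / bnorm)
            history.append(res)
            if res <= tol:
                break
        else:
            raise ConvergenceError(
                f"multigrid failed to reach tol={tol} in {max_cycles} cycles "
                f"(residual {history[-1]:.3e})", history)
        iters = cycle
    elif method == "sor":
        level = _Level(A, system.node_dims, sor_omega, system.active)
        x = np.zeros(system.n_nodes)
        history = []
        max_sweeps = max_cycles * 100
        for sweep in range(1, max_sweeps + 1):
            x = _sor_forward(level, x, b)
            res = float(np.linalg.norm(b - A @ x) / bnorm)
            history.append(res)
            if res <= tol:
                break
        else:
            raise ConvergenceError(
                f"SOR failed to reach tol={tol} in {max_sweeps} sweeps "
                f"(residual {history[-1]:.3e})", history)
        iters = sweep
    else:
        raise ValueError(f"unknown method {method!r}")

    x = x.copy()
    x[~system.active] = 0.0
    x[system.reference] = 0.0
    return PotentialField(x, system.node_dims, iters, res, method, history)


def potentials_at_electrodes(field: PotentialField, system: SpfdSystem,
                             montage: ElectrodeMontage) -> np.ndarray:
    """Raw node potentials (V) at the 9 electrodes, in montage order."""
    out = np.empty(len(montage.electrodes))
    for i, (name, node) in enumerate(montage.electrodes):
        idx = system.ravel(node)
        if not system.active[idx]:
            raise ValueError(f"electrode {name} at node {node} is on an inactive node")
        out[i] = field.phi[idx]
    return out
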