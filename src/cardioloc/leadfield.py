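"""Lead-field matrix construction: candidate dipoles -> 12-lead potentials.

The lead field matrix L (M x 3N) maps the current-density vector j (3N,
three orthogonal dipole components per candidate point in the heart) to the
observed lead potentials Phi: ``L j = Phi``. Columns are per unit dipole
moment (1 A.mm).

Two construction modes are provided and must agree (reciprocity of the
symmetric conductance system): *direct* runs one forward solve per candidate
dipole (3N solves) and reads the electrodes; *reciprocal* injects each
lead's electrode weight pattern as a current source (M solves) and reads the
potential difference across each candidate's dipole edge. Reciprocal is the
default — M << 3N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .forward import CurrentSource, PotentialField, SpfdSystem, solve
from .voxelmodel import ElectrodeMontage, VoxelModel

__all__ = [
    "CandidateGrid",
    "LeadFieldMatrix",
    "place_candidates",
    "build_leadfield",
    "derive_leads",
    "reciprocal_lead_fields",
    "LEADS_12",
    "LEADS_INDEPENDENT",
    "lead_weight_matrix",
]

LEADS_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6")
# The 12-lead set has rank 8; this independent subset drives the inversion.
LEADS_INDEPENDENT = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


def lead_weight_matrix(leads: Sequence[str] = LEADS_12) -> np.ndarray:
    """Electrode weights (len(leads) x 9) over RA, LA, LL, V1..V6.

    Each row applied to the raw electrode potentials yields one lead;
    all rows sum to zero (common-mode rejection).
    """
    e = {name: i for i, name in enumerate(ElectrodeMontage.STANDARD_NAMES)}
    W = np.zeros((len(leads), 9))
    for r, lead in enumerate(leads):
        if lead == "I":
            W[r, e["LA"]], W[r, e["RA"]] = 1, -1
        elif lead == "II":
            W[r, e["LL"]], W[r, e["RA"]] = 1, -1
        elif lead == "III":
            W[r, e["LL"]], W[r, e["LA"]] = 1, -1
        elif lead == "aVR":
            W[r, e["RA"]] = 1
            W[r, e["LA"]] = W[r, e["LL"]] = -0.5
        elif lead == "aVL":
            W[r, e["LA"]] = 1
            W[r, e["RA"]] = W[r, e["LL"]] = -0.5
        elif lead == "aVF":
            W[r, e["LL"]] = 1
            W[r, e["RA"]] = W[r, e["LA"]] = -0.5
        elif lead.startswith("V") and lead[1:].isdigit():
            W[r, e[lead]] = 1
            W[r, e["RA"]] = W[r, e["LA"]] = W[r, e["LL"]] = -1.0 / 3.0
        else:
            raise ValueError(f"unknown lead {lead!r}")
    return W


def derive_leads(electrode_potentials: np.ndarray,
                 leads: Sequence[str] = LEADS_12) -> np.ndarray:
    """Derive ECG leads from the 9 raw electrode potentials.

    I = LA - RA, II = LL - RA, III = LL - LA, augmented leads against the
    mean of the two remaining limb electrodes, precordial leads against the
    Wilson central terminal (RA + LA + LL)/3.
    """
    v = np.asarray(electrode_potentials, dtype=float)
    if v.shape[0] != 9:
        raise ValueError(f"expected 9 electrode potentials, got {v.shape[0]}")
    return lead_weight_matrix(leads) @ v


@dataclass(frozen=True)
class CandidateGrid:
    """Regular sub-lattice of heart-interior nodes carrying 3-axis dipoles."""

    node_indices: np.ndarray  # (N, 3) int node triples
    points_mm: np.ndarray     # (N, 3) world coordinates
    spacing: int              # lattice spacing, voxels

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_indices",
                           np.atleast_2d(np.asarray(self.node_indices, dtype=int)))
        object.__setattr__(self, "points_mm",
                           np.atleast_2d(np.asarray(self.points_mm, dtype=float)))
        if len(self.node_indices) < 1:
            raise ValueError("candidate grid must contain at least one point")

    @property
    def n(self) -> int:
        return len(self.node_indices)

    def permuted(self, perm: np.ndarray) -> "CandidateGrid":
        return CandidateGrid(self.node_indices[perm], self.points_mm[perm],
                             self.spacing)


def interior_lattice(model: VoxelModel, heart_label: int,
                     spacing: int = 2) -> np.ndarray:
    """Node triples of the heart-interior sub-lattice, ordered by (z, y, x).

    A node qualifies when all 8 voxels around it carry the heart label, so
    every axis dipole edge stays inside the heart; of those, nodes on the
    sub-lattice anchored at the minimum interior index are kept.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    heart = model.labels == heart_label
    if not heart.any():
        raise ValueError(f"no voxels carry heart label {heart_label}")
    nx, ny, nz = model.node_dims
    padded = np.pad(heart, 1, constant_values=False)
    interior = np.ones((nx, ny, nz), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                interior &= padded[dx:dx + nx, dy:dy + ny, dz:dz + nz]
    idx = np.argwhere(interior)
    if len(idx) == 0:
        raise ValueError("heart region too thin: no interior candidate nodes")
    lo = idx.min(axis=0)
    idx = idx[((idx - lo) % spacing == 0).all(axis=1)]
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))  # by z, then y, then x
    return idx[order]


def place_candidates(model: VoxelModel, heart_label: int, spacing: int = 2,
                     near_points_mm: np.ndarray | None = None,
                     near_radius_mm: float | None = None) -> CandidateGrid:
    """Place candidate source nodes on a sub-lattice inside heart tissue.

    Optionally restrict the grid to nodes within ``near_radius_mm`` of any
    of ``near_points_mm`` (e.g. the estimation target region, so dipoles sit
    next to the basal heart rather than filling the whole ventricle).
    """
    idx = interior_lattice(model, heart_label, spacing)
    pts = model.node_position(idx)
    if near_points_mm is not None:
        if near_radius_mm is None:
            raise ValueError("near_radius_mm required with near_points_mm")
        ref = np.atleast_2d(np.asarray(near_points_mm, float))
        d = np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=2).min(axis=1)
        keep = d <= near_radius_mm
        if not keep.any():
            raise ValueError("no candidate nodes within the requested radius")
        idx, pts = idx[keep], pts[keep]
    return CandidateGrid(node_indices=idx, points_mm=pts, spacing=spacing)


@dataclass
class LeadFieldMatrix:
    """M x 3N lead field matrix with its column bookkeeping.

    Column ``3*i + a`` maps candidate point ``i``'s unit dipole (1 A.mm)
    along grid axis ``a`` (x, y, z) to the lead potentials (V).
    """

    L: np.ndarray
    lead_labels: tuple[str, ...]
    grid: CandidateGrid
    pitch_mm: float
    mode: str = "reciprocal"

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (len(self.lead_labels), 3 * self.grid.n):
            raise ValueError(
                f"L shape {self.L.shape} inconsistent with "
                f"{len(self.lead_labels)} leads x 3*{self.grid.n} candidates")
        colnorm = np.linalg.norm(self.L, axis=0)
        if (colnorm == 0).any():
            bad = int(np.flatnonzero(colnorm == 0)[0])
            raise ValueError(f"lead field column {bad} is all-zero")

    @property
    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.L, axis=0)

    def column_info(self, col: int) -> tuple[int, int]:
        """(candidate index, axis) of a column."""
        return divmod(col, 3)

    def save_hdf5(self, path: str | Path, attrs: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("L", data=self.L)
            f.create_dataset("candidates_mm", data=self.grid.points_mm)
            f.create_dataset("candidate_nodes", data=self.grid.node_indices)
            f.create_dataset("lead_labels",
                             data=np.array(self.lead_labels, dtype="S"))
            f.attrs["pitch_mm"] = self.pitch_mm
            f.attrs["spacing"] = self.grid.spacing
            f.attrs["mode"] = self.mode
            for k, v in (attrs or {}).items():
                f.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "LeadFieldMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            grid = CandidateGrid(
                node_indices=f["candidate_nodes"][()],
                points_mm=f["candidates_mm"][()],
                spacing=int(f.attrs["spacing"]),
            )
            return cls(
                L=f["L"][()],
                lead_labels=tuple(s.decode() for s in f["lead_labels"][()]),
                grid=grid,
                pitch_mm=float(f.attrs["pitch_mm"]),
                mode=str(f.attrs.get("mode", "reciprocal")),
            )


def reciprocal_lead_fields(system: SpfdSystem, montage: ElectrodeMontage,
                           leads: Sequence[str] = LEADS_INDEPENDENT,
                           **solve_kw) -> dict[str, PotentialField]:
    """One reciprocal solve per lead: inject the lead's electrode weights.

    Injecting the (zero-sum) electrode weight pattern w of a lead as nodal
    currents and solving gives a field psi with the property that the lead's
    reading for any dipole source equals the dipole current times the psi
    difference across the dipole edge.
    """
    if tuple(montage.names) != ElectrodeMontage.STANDARD_NAMES:
        raise ValueError("montage must carry the standard RA, LA, LL, V1..V6 order")
    W = lead_weight_matrix(leads)
    nodes = tuple(tuple(n) for _, n in montage.electrodes)
    fields: dict[str, PotentialField] = {}
    for r, lead in enumerate(leads):
        nz = np.flatnonzero(W[r])
        src = CurrentSource(nodes=tuple(nodes[i] for i in nz),
                            currents=tuple(float(W[r, i]) for i in nz))
        fields[lead] = solve(system, src, **solve_kw)
    return fields


def _dipole_edge_nodes(grid: CandidateGrid, system: SpfdSystem
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Flat node indices (N, 3) of each candidate and its +axis partners."""
    dims = system.node_dims
    base = np.ravel_multi_index(grid.node_indices.T, dims)
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    partners = base[:, None] + strides[None, :]
    return base, partners


def build_leadfield(system: SpfdSystem, grid: CandidateGrid,
                    montage: ElectrodeMontage,
                    leads: Sequence[str] = LEADS_INDEPENDENT,
                    mode: str = "reciprocal",
                    fields: dict[str, PotentialField] | None = None,
                    **solve_kw) -> LeadFieldMatrix:
    """Construct the lead field matrix by reciprocal (default) or direct solves.

    Precomputed reciprocal fields (from :func:`reciprocal_lead_fields`) may be
    passed to avoid re-solving.
    """
    electrode_nodes = {tuple(n) for _, n in montage.electrodes}
    for node in map(tuple, grid.node_indices):
        if node in electrode_nodes:
            raise ValueError(f"candidate node {node} coincides with an electrode")

    i_dip = 1.0 / system.pitch_mm  # current of a unit 1 A.mm dipole
    L = np.empty((len(leads), 3 * grid.n))

    if mode == "reciprocal":
        if fields is None:
            fields = reciprocal_lead_fields(system, montage, leads, **solve_kw)
        base, partners = _dipole_edge_nodes(grid, system)
        for r, lead in enumerate(leads):
            psi = fields[lead].phi
            L[r] = (i_dip * (psi[partners] - psi[base][:, None])).ravel()
    elif mode == "direct":
        for i, node in enumerate(grid.node_indices):
            for axis in range(3):
                src = CurrentSource.dipole(node, axis, 1.0, system.pitch_mm)
                f = solve(system, src, **solve_kw)
                pots = np.array([f.phi[system.ravel(n)]
                                 for _, n in montage.electrodes])
                L[:, 3 * i + axis] = derive_leads(pots, leads)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return LeadFieldMatrix(L=L, lead_labels=tuple(leads), grid=grid,
                           pitch_mm=system.pitch_mm, mode=mode)
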