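"""Voxelized body conductor: tissue labels, conductivities, electrodes, targets.

The body is represented on a regular cubic-voxel grid. Voxel ``(i, j, k)``
spans the eight corner *nodes* ``(i..i+1, j..j+1, k..k+1)``; scalar potentials
live on nodes, conductances on node-node edges (see :mod:`cardioloc.forward`).
Label 0 is air (non-conducting); the body must be strictly interior so every
grid face is air, which realizes the insulating boundary condition.

Coordinate convention: 0-based indices, world units mm, right-handed axes
(x: right -> left, y: posterior -> anterior, z: inferior -> superior). The
world position of the *center* of voxel ``(i, j, k)`` is
``origin + (index + 0.5) * pitch``; node ``(i, j, k)`` sits at
``origin + index * pitch``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

__all__ = [
    "VoxelModel",
    "ConductivityTable",
    "ElectrodeMontage",
    "TargetRegions",
    "ColeColeParams",
    "assign_conductivity",
    "evaluate_cole_cole",
    "surface_nodes",
    "DEFAULT_TISSUES",
    "DEFAULT_CONDUCTIVITY_TABLE",
    "COLE_COLE_PARAMS",
    "load_voxel_model",
    "save_voxel_model",
]


@dataclass(frozen=True)
class VoxelModel:
    """Labeled voxel volume with world geometry.

    Parameters
    ----------
    labels : ndarray of uint8/uint16, shape (nx, ny, nz)
        Tissue ID per voxel; 0 is air.
    pitch : float
        Voxel edge length in mm, > 0.
    origin : tuple of float
        World coordinate (mm) of the corner of voxel (0, 0, 0),
        i.e. of node (0, 0, 0).
    label_names : mapping, optional
        Tissue ID -> human-readable name.
    """

    labels: np.ndarray
    pitch: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {labels.shape}")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def node_dims(self) -> tuple[int, int, int]:
        nx, ny, nz = self.labels.shape
        return (nx + 1, ny + 1, nz + 1)

    def validate(self) -> None:
        """Check the strict-interior invariant: every grid face is all air."""
        lab = self.labels
        for ax in range(3):
            first = np.take(lab, 0, axis=ax)
            last = np.take(lab, lab.shape[ax] - 1, axis=ax)
            if first.any() or last.any():
                raise ValueError(
                    "body is not strictly interior: tissue voxels found on a "
                    f"grid face along axis {ax}"
                )

    def voxel_center(self, index: Sequence[int] | np.ndarray) -> np.ndarray:
        """World position (mm) of the center(s) of voxel index triple(s)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * self.pitch

    def node_position(self, index: Sequence[int] | np.ndarray) -> np.ndarray:
        """World position (mm) of node index triple(s)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * self.pitch

    def nearest_node(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        """Node index triple closest to a world point, clipped to the grid."""
        rel = (np.asarray(point_mm, float) - np.asarray(self.origin)) / self.pitch
        idx = np.rint(rel).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.node_dims) - 1)
        return tuple(int(v) for v in idx)


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue ID -> conductivity sigma (S/m) at a stated frequency."""

    entries: Mapping[int, float]
    frequency: float = 1.0

    def __post_init__(self) -> None:
        entries = {int(k): float(v) for k, v in self.entries.items()}
        for tid, sigma in entries.items():
            if sigma < 0:
                raise ValueError(f"negative conductivity for tissue {tid}: {sigma}")
        if entries.get(0, 0.0) != 0.0:
            raise ValueError("air (label 0) must map to exactly 0 S/m")
        entries[0] = 0.0
        object.__setattr__(self, "entries", entries)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Ordered 9-electrode montage (RA, LA, LL, V1..V6) on surface nodes."""

    electrodes: tuple[tuple[str, tuple[int, int, int]], ...]

    STANDARD_NAMES = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")

    def __post_init__(self) -> None:
        names = [name for name, _ in self.electrodes]
        if len(set(names)) != len(names):
            raise ValueError("electrode names must be unique")
        object.__setattr__(
            self,
            "electrodes",
            tuple((str(n), tuple(int(v) for v in node)) for n, node in self.electrodes),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.electrodes)

    @property
    def nodes(self) -> np.ndarray:
        return np.array([node for _, node in self.electrodes], dtype=int)

    def validate_on_surface(self, model: VoxelModel) -> None:
        surf = surface_nodes(model)
        for name, node in self.electrodes:
            if node not in surf:
                raise ValueError(f"electrode {name} at node {node} is not on the body surface")


@dataclass(frozen=True)
class TargetRegions:
    """LC/AC/RC target point sets (world mm) for the distance classifier."""

    regions: Mapping[str, np.ndarray]

    LABELS = ("LC", "AC", "RC")

    def __post_init__(self) -> None:
        regions = {}
        for key in self.LABELS:
            if key not in self.regions:
                raise ValueError(f"missing target region {key}")
            pts = np.atleast_2d(np.asarray(self.regions[key], dtype=float))
            if pts.size == 0 or pts.shape[1] != 3:
                raise ValueError(f"region {key} must be a nonempty (n, 3) point set")
            regions[key] = pts
        object.__setattr__(self, "regions", regions)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.regions[key]

    def validate_disjoint(self, atol: float = 1e-9) -> None:
        labels = self.LABELS
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = self.regions[labels[i]], self.regions[labels[j]]
                d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
                if (d < atol).any():
                    raise ValueError(f"regions {labels[i]} and {labels[j]} share points")


# ---------------------------------------------------------------------------
# Tissue dielectric data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColeColeParams:
    """4-term Cole-Cole dispersion parameters for one tissue.

    eps_inf is dimensionless; del_eps are the four dispersion magnitudes,
    tau their relaxation times in seconds, alpha the broadening exponents
    (0 <= alpha < 1), sigma_i the static ionic conductivity in S/m.
    """

    eps_inf: float
    del_eps: tuple[float, float, float, float]
    tau: tuple[float, float, float, float]
    alpha: tuple[float, float, float, float]
    sigma_i: float


def evaluate_cole_cole(params: ColeColeParams, frequency: float) -> float:
    """Effective tissue conductivity (S/m) from a 4-term Cole-Cole dispersion.

    The complex permittivity is

        eps(w) = eps_inf + sum_k del_eps_k / (1 + (j w tau_k)^(1 - alpha_k))
                 + sigma_i / (j w eps0)

    and the returned value is ``Re(j w eps0 eps(w))``, the real part of the
    complex conductivity, which the quasi-static solver uses.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    for k in range(4):
        if params.del_eps[k] < 0:
            raise ValueError("dispersion magnitudes must be non-negative")
        if params.tau[k] <= 0:
            raise ValueError("relaxation times must be positive")
        if not 0 <= params.alpha[k] < 1:
            raise ValueError("alpha exponents must lie in [0, 1)")
    if params.sigma_i < 0:
        raise ValueError("static conductivity must be non-negative")

    w = 2.0 * np.pi * frequency
    eps = complex(params.eps_inf)
    for de, tau, alpha in zip(params.del_eps, params.tau, params.alpha):
        eps += de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    eps += params.sigma_i / (1j * w * EPS0)
    return float((1j * w * EPS0 * eps).real)


# Representative 4-Cole-Cole dispersion parameters for the tissues the phantom
# uses (Gabriel-style values; the low-frequency table below is the solver
# default and these are provided so the table can be re-derived at any
# frequency of interest).
COLE_COLE_PARAMS: dict[str, ColeColeParams] = {
    "muscle": ColeColeParams(
        eps_inf=4.0,
        del_eps=(50.0, 7.0e3, 1.2e6, 2.5e7),
        tau=(7.23e-12, 353.68e-9, 318.31e-6, 2.274e-3),
        alpha=(0.10, 0.10, 0.10, 0.00),
        sigma_i=0.20,
    ),
    "heart": ColeColeParams(
        eps_inf=4.0,
        del_eps=(50.0, 1.2e3, 4.5e5, 2.5e7),
        tau=(7.96e-12, 159.15e-9, 72.34e-6, 4.547e-3),
        alpha=(0.10, 0.05, 0.22, 0.00),
        sigma_i=0.05,
    ),
    "lung": ColeColeParams(  # inflated lung
        eps_inf=2.5,
        del_eps=(18.0, 500.0, 2.5e5, 4.0e7),
        tau=(7.96e-12, 63.66e-9, 159.15e-6, 7.958e-3),
        alpha=(0.10, 0.10, 0.20, 0.00),
        sigma_i=0.03,
    ),
    "fat": ColeColeParams(
        eps_inf=2.5,
        del_eps=(9.0, 35.0, 3.3e4, 1.0e7),
        tau=(7.96e-12, 15.92e-9, 159.15e-6, 15.915e-3),
        alpha=(0.20, 0.10, 0.05, 0.01),
        sigma_i=0.035,
    ),
    "bone": ColeColeParams(  # cortical bone
        eps_inf=2.5,
        del_eps=(10.0, 180.0, 5.0e3, 1.0e5),
        tau=(13.26e-12, 79.58e-9, 159.15e-6, 15.915e-3),
        alpha=(0.20, 0.20, 0.20, 0.00),
        sigma_i=0.02,
    ),
    "blood": ColeColeParams(
        eps_inf=4.0,
        del_eps=(56.0, 5.2e3, 0.0, 0.0),
        tau=(8.38e-12, 132.63e-9, 159.15e-6, 15.915e-3),
        alpha=(0.10, 0.10, 0.0, 0.0),
        sigma_i=0.70,
    ),
}

# Default tissue IDs used by the synthetic phantom.
DEFAULT_TISSUES: dict[int, str] = {
    0: "air",
    1: "skin",
    2: "fat",
    3: "muscle",
    4: "lung",
    5: "heart",
    6: "bone",
    7: "blood",
}

# Default low-frequency (1 Hz) conductivities, S/m. Skin is fixed at 0.1 S/m;
# the rest are the Cole-Cole evaluations rounded to two significant figures.
DEFAULT_CONDUCTIVITY_TABLE = ConductivityTable(
    entries={
        0: 0.0,
        1: 0.10,   # skin (fixed, not Cole-Cole)
        2: 0.035,  # fat
        3: 0.20,   # muscle
        4: 0.030,  # lung (inflated)
        5: 0.050,  # heart
        6: 0.020,  # bone (cortical)
        7: 0.70,   # blood
    },
    frequency=1.0,
)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def assign_conductivity(model: VoxelModel, table: ConductivityTable) -> np.ndarray:
    """Map the label volume through the conductivity table.

    Returns a float64 sigma array of shape ``model.dims`` with sigma = 0
    exactly where label = 0. Raises ``KeyError`` naming any label that is
    absent from the table.
    """
    labels = model.labels
    present = np.unique(labels)
    unknown = [int(t) for t in present if int(t) not in table.entries]
    if unknown:
        raise KeyError(f"labels {unknown} have no conductivity table entry")
    lut = np.zeros(int(present.max()) + 1, dtype=float)
    for tid in present:
        lut[int(tid)] = table.entries[int(tid)]
    return lut[labels]


def surface_nodes(model: VoxelModel) -> set[tuple[int, int, int]]:
    """Nodes on the body surface: touching >= 1 tissue and >= 1 air voxel.

    A node touches up to 8 voxels (fewer on the grid boundary; out-of-grid
    counts as air). Returns a set of node index triples.
    """
    import warnings

    lab = model.labels
    if not lab.any():
        warnings.warn("model contains no tissue voxels; surface is empty")
        return set()
    tissue = (lab > 0)
    # pad so every node sees exactly 8 (possibly air) voxels
    padded = np.pad(tissue, 1, constant_values=False)
    nx, ny, nz = model.node_dims
    n_tissue = np.zeros((nx, ny, nz), dtype=np.int8)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                n_tissue += padded[dx:dx + nx, dy:dy + ny, dz:dz + nz]
    on_surface = (n_tissue > 0) & (n_tissue < 8)
    idx = np.argwhere(on_surface)
    return {tuple(int(v) for v in t) for t in idx}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_voxel_model(model: VoxelModel, path: str | Path) -> None:
    """Write a model as NIfTI (.nii/.nii.gz) or raw + JSON sidecar.

    For a ``.raw`` path, the labels are written in C order as uint16 and a
    ``<stem>.json`` sidecar carries ``dims``, ``pitch_mm``, ``origin_mm`` and
    ``label_names``.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.diag([model.pitch, model.pitch, model.pitch, 1.0])
        affine[:3, 3] = model.origin
        img = nib.Nifti1Image(model.labels.astype(np.uint16), affine)
        nib.save(img, str(path))
    else:
        model.labels.astype(np.uint16).tofile(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "dims": list(model.dims),
            "pitch_mm": model.pitch,
            "origin_mm": list(model.origin),
            "label_names": {str(k): v for k, v in model.label_names.items()},
        }, indent=2))


def load_voxel_model(path: str | Path) -> VoxelModel:
    """Load a model saved by :func:`save_voxel_model` (NIfTI or raw+JSON)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        pitch = float(affine[0, 0])
        labels = np.asarray(img.dataobj).astype(np.uint16)
        return VoxelModel(labels=labels, pitch=pitch, origin=tuple(affine[:3, 3]))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    labels = np.fromfile(path, dtype=np.uint16).reshape(sidecar["dims"])
    return VoxelModel(
        labels=labels,
        pitch=float(sidecar["pitch_mm"]),
        origin=tuple(sidecar["origin_mm"]),
        label_names={int(k): v for k, v in sidecar.get("label_names", {}).items()},
    )


def load_conductivity_table(path: str | Path) -> ConductivityTable:
    """Read the ``tissues:`` section of a YAML config into a table."""
    cfg = yaml.safe_load(Path(path).read_text())
    sec = cfg.get("tissues", cfg)
    return ConductivityTable(
        entries={int(k): float(v) for k, v in sec["entries"].items()},
        frequency=float(sec.get("frequency", 1.0)),
    )


def load_montage(path: str | Path) -> ElectrodeMontage:
    """Read the ``electrodes:`` section of a YAML config into a montage."""
    cfg = yaml.safe_load(Path(path).read_text())
    sec = cfg.get("electrodes", cfg)
    return ElectrodeMontage(electrodes=tuple(
        (name, tuple(node)) for name, node in sec.items()
    ) if isinstance(sec, dict) else tuple(
        (e["name"], tuple(e["node"])) for e in sec
    ))
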