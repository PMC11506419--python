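"""Synthetic torso phantom, PVC-like dipole trajectories, and ECG cohorts.

Stands in for the licensed anatomical body model and the clinical recordings:
a heterogeneous ellipsoid torso (skin shell, fat layer, muscle, two lungs,
heart, spine) on a 2 mm voxel grid, a pulmonary-valve annulus on the basal
heart surface partitioned into three 120-degree cusp sectors (LC/AC/RC), and
simulated ectopic excitations — a dipole starting in one cusp sector and
marching into the ventricular tissue while its moment rises — forward-modeled
into 12-lead ECGs with optional additive white Gaussian noise.

Everything is deterministic given the spec (geometry) and seeds (noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .ecg import ECGRecord, LEAD_ORDER
from .forward import SpfdSystem, assemble_system, solve
from .leadfield import LEADS_INDEPENDENT, reciprocal_lead_fields
from .voxelmodel import (DEFAULT_CONDUCTIVITY_TABLE, DEFAULT_TISSUES,
                         ConductivityTable, ElectrodeMontage, TargetRegions,
                         VoxelModel, assign_conductivity, surface_nodes)

__all__ = [
    "PhantomSpec",
    "SimulatedSubject",
    "Phantom",
    "build_phantom",
    "simulate_subject",
    "simulate_cohort",
    "STUDY_COHORT_COUNTS",
]

HEART_LABEL = 5

# Cohort composition of the clinical population these synthetic cohorts
# emulate: 15 left-cusp, 6 anterior-cusp, 6 right-cusp PVC origins.
STUDY_COHORT_COUNTS = {"LC": 15, "AC": 6, "RC": 6}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic torso phantom.

    All lengths in mm; the grid default (81 x 61 x 97 voxels at 2 mm pitch)
    keeps forward solves desktop-fast while preserving realistic organ
    proportions; pitch can be dropped to 1 mm for finer studies.
    """

    dims: tuple[int, int, int] = (81, 61, 97)
    pitch_mm: float = 2.0
    torso_semi: tuple[float, float, float] = (74.0, 54.0, 92.0)
    skin_thickness_mm: float = 4.0
    fat_thickness_mm: float = 4.0
    lung_semi: tuple[float, float, float] = (22.0, 34.0, 62.0)
    lung_offset: tuple[float, float, float] = (40.0, -3.0, 7.0)
    heart_semi: tuple[float, float, float] = (27.0, 29.0, 33.0)
    heart_center_offset: tuple[float, float, float] = (7.0, 13.0, 15.0)
    spine_radius_mm: float = 12.0
    spine_y_offset: float = -31.0
    annulus_radius_mm: float = 11.0
    annulus_axis: tuple[float, float, float] = (0.2, 0.3, 0.93)
    annulus_surface_frac: float = 0.75
    annulus_n_points: int = 48
    conductivity: ConductivityTable = DEFAULT_CONDUCTIVITY_TABLE
    seed: int = 0

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.dims, float) * self.pitch_mm / 2.0

    @property
    def heart_center_mm(self) -> np.ndarray:
        return self.center_mm + np.asarray(self.heart_center_offset)


@dataclass
class Phantom:
    """Bundle of everything :func:`build_phantom` produces."""

    model: VoxelModel
    montage: ElectrodeMontage
    regions: TargetRegions
    spec: PhantomSpec

    def conductivity_field(self) -> np.ndarray:
        return assign_conductivity(self.model, self.spec.conductivity)

    def assemble(self) -> SpfdSystem:
        return assemble_system(self.conductivity_field(), self.model.pitch)


def _inside_ellipsoid(centers: np.ndarray, center: np.ndarray,
                      semi: Sequence[float]) -> np.ndarray:
    rel = (centers - center) / np.asarray(semi)
    return (rel ** 2).sum(axis=-1) <= 1.0


def _annulus_frame(axis: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build the voxel phantom, its electrode montage and the cusp regions.

    Deterministic given the spec. Electrodes are the surface nodes nearest
    to standard anatomical proportions (limb electrodes near the torso
    corners, V1-V6 along the precordial arc at heart level).
    """
    dims = spec.dims
    idx = np.transpose(np.indices(dims), (1, 2, 3, 0)).astype(float)
    centers = (idx + 0.5) * spec.pitch_mm  # world voxel centers, origin (0,0,0)
    c0 = spec.center_mm

    labels = np.zeros(dims, dtype=np.uint8)
    torso = _inside_ellipsoid(centers, c0, spec.torso_semi)
    t_skin = np.asarray(spec.torso_semi) - spec.skin_thickness_mm
    t_fat = t_skin - spec.fat_thickness_mm
    inner_skin = _inside_ellipsoid(centers, c0, t_skin)
    inner_fat = _inside_ellipsoid(centers, c0, t_fat)
    labels[torso] = 1                        # skin shell
    labels[inner_skin] = 2                   # fat layer
    labels[inner_fat] = 3                    # muscle / soft tissue

    spine_c = c0 + np.array([0.0, spec.spine_y_offset, 0.0])
    spine = ((centers[..., 0] - spine_c[0]) ** 2
             + (centers[..., 1] - spine_c[1]) ** 2
             <= spec.spine_radius_mm ** 2) & inner_fat
    labels[spine] = 6                        # bone

    for side in (-1.0, 1.0):
        lc = c0 + np.asarray(spec.lung_offset) * np.array([side, 1.0, 1.0])
        lung = _inside_ellipsoid(centers, lc, spec.lung_semi) & inner_fat
        labels[lung] = 4

    heart_c = spec.heart_center_mm
    heart = _inside_ellipsoid(centers, heart_c, spec.heart_semi) & inner_fat
    labels[heart] = HEART_LABEL

    model = VoxelModel(labels=labels, pitch=spec.pitch_mm,
                       label_names=DEFAULT_TISSUES)
    model.validate()

    # --- pulmonary-valve annulus and cusp sectors -------------------------
    u, e1, e2 = _annulus_frame(spec.annulus_axis)
    r_u = 1.0 / np.sqrt(((u / np.asarray(spec.heart_semi)) ** 2).sum())
    ann_center = heart_c + spec.annulus_surface_frac * r_u * u
    theta = np.linspace(0.0, 2.0 * np.pi, spec.annulus_n_points, endpoint=False)
    pts = (ann_center[None, :]
           + spec.annulus_radius_mm * (np.cos(theta)[:, None] * e1[None, :]
                                       + np.sin(theta)[:, None] * e2[None, :]))
    vox = np.floor(pts / spec.pitch_mm).astype(int)
    vox = np.clip(vox, 0, np.asarray(dims) - 1)
    near_heart = np.zeros(len(pts), dtype=bool)
    reach = 2  # annulus points must sit in or within 2 voxels of heart tissue
    for k, v in enumerate(vox):
        sl = tuple(slice(max(0, v[d] - reach), v[d] + reach + 1) for d in range(3))
        near_heart[k] = (labels[sl] == HEART_LABEL).any()
    if not near_heart.all():
        raise ValueError("annulus lies outside the heart-tissue boundary region")
    sector = (np.degrees(theta) // 120).astype(int)  # 0: LC, 1: AC, 2: RC
    regions = TargetRegions(regions={
        "LC": pts[sector == 0], "AC": pts[sector == 1], "RC": pts[sector == 2],
    })
    regions.validate_disjoint()

    # --- electrodes -------------------------------------------------------
    surf = np.array(sorted(surface_nodes(model)))
    tree = cKDTree(surf * spec.pitch_mm)
    cx, cy, cz = c0
    hz = heart_c[2]
    targets = {
        "RA": (cx - 50, cy + 15, cz + 70),
        "LA": (cx + 50, cy + 15, cz + 70),
        "LL": (cx + 50, cy + 15, cz - 62),
        "V1": (cx - 10, cy + 60, hz + 6),
        "V2": (cx + 10, cy + 60, hz + 6),
        "V3": (cx + 19, cy + 60, hz - 2),
        "V4": (cx + 28, cy + 60, hz - 10),
        "V5": (cx + 42, cy + 60, hz - 10),
        "V6": (cx + 56, cy + 60, hz - 10),
    }
    electrodes = []
    for name in ElectrodeMontage.STANDARD_NAMES:
        _, i = tree.query(np.asarray(targets[name], float))
        electrodes.append((name, tuple(int(v) for v in surf[i])))
    nodes = [n for _, n in electrodes]
    if len(set(nodes)) != len(nodes):
        raise ValueError("electrode placement collapsed two electrodes onto one node")
    montage = ElectrodeMontage(electrodes=tuple(electrodes))

    return Phantom(model=model, montage=montage, regions=regions, spec=spec)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSubject:
    """One synthetic PVC: truth origin, dipole kinematics, noise, seed.

    The dipole launches from a seeded random point on the central half of
    the truth cusp's annulus arc (ectopic foci sit within a cusp, not at the
    commissures between cusps) and marches in a straight line toward the
    heart centroid while its moment amplitude follows a smoothstep rise
    from 0 to ``peak_moment_amm`` (0.02 A.mm default — the scale of a peak
    equivalent cardiac dipole).

    Positions are quantized to the heart-interior source lattice
    (``lattice_spacing`` voxels, matching the default inversion candidate
    grid) and the moment points along the dominant grid axis of the march —
    the source then is, at every sample, exactly one dictionary atom, the
    regime in which the greedy inverse is exact. ``moment_mode="march"``
    keeps the continuous oblique moment instead.
    """

    origin: str
    n_samples: int = 160
    fs: float = 2000.0
    peak_moment_amm: float = 0.02
    march_mm: float = 30.0
    lattice_spacing: int = 2
    moment_mode: str = "axis"            # "axis" or "march"
    snr_db: float | None = None
    baseline_wander_mv: float = 0.0
    seed: int = 0
    subject_id: str = ""
    trajectory_mm: np.ndarray | None = None   # explicit override, (T, 3)
    moment_dir: tuple[float, float, float] | None = None


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _default_trajectory(phantom: Phantom, subject: SimulatedSubject,
                        rng: np.random.Generator) -> np.ndarray:
    arc = phantom.regions[subject.origin]
    n = len(arc)
    central = np.arange(n // 4, n - n // 4)  # central half of the cusp arc
    start = arc[rng.choice(central)]
    heart_c = phantom.spec.heart_center_mm
    d = heart_c - start
    d = d / np.linalg.norm(d)
    u = np.linspace(0.0, 1.0, subject.n_samples)
    return start[None, :] + subject.march_mm * u[:, None] * d[None, :]


def simulate_subject(phantom: Phantom, system: SpfdSystem,
                     subject: SimulatedSubject,
                     fields: dict | None = None,
                     **solve_kw) -> ECGRecord:
    """Forward-model one subject's 12-lead ECG at 2 kHz.

    Per sample the instantaneous dipole (position snapped to the nearest
    node, moment split into its three axis components) is mapped to the
    eight independent leads through the reciprocal lead fields — numerically
    identical to a per-sample forward solve by reciprocity of the symmetric
    conductance system — then the remaining leads follow from the standard
    linear identities and white Gaussian noise is added at the requested
    per-lead SNR.
    """
    if subject.origin not in ("LC", "AC", "RC"):
        raise ValueError(f"unknown origin {subject.origin!r}")
    model = phantom.model
    if fields is None:
        fields = reciprocal_lead_fields(system, phantom.montage,
                                        LEADS_INDEPENDENT, **solve_kw)

    rng = np.random.default_rng(subject.seed)
    traj = (np.asarray(subject.trajectory_mm, float)
            if subject.trajectory_mm is not None
            else _default_trajectory(phantom, subject, rng))
    if traj.shape != (subject.n_samples, 3):
        raise ValueError("trajectory must have one 3-D point per sample")

    # the requested trajectory must stay in heart tissue (containing voxel)
    vox = np.floor((traj - np.asarray(model.origin)) / model.pitch).astype(int)
    oob = (vox < 0).any(axis=1) | (vox >= np.asarray(model.dims)).any(axis=1)
    vox = np.clip(vox, 0, np.asarray(model.dims) - 1)
    lab = model.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    bad_mask = oob | (lab != HEART_LABEL)
    if bad_mask.any():
        bad = int(np.flatnonzero(bad_mask)[0])
        raise ValueError(
            f"trajectory exits heart tissue at sample {bad} "
            f"(point {traj[bad]}, label {0 if oob[bad] else lab[bad]})")

    # quantize positions to the heart-interior source lattice
    from .leadfield import interior_lattice

    lat = interior_lattice(model, HEART_LABEL, subject.lattice_spacing)
    lat_pts = model.node_position(lat)
    tree = cKDTree(lat_pts)
    _, nearest = tree.query(traj)
    nodes = lat[nearest]

    # moment direction: dominant march axis (default) or the oblique march
    if subject.moment_dir is not None:
        mdir = np.asarray(subject.moment_dir, float)
    else:
        mdir = traj[-1] - traj[0]
        if np.linalg.norm(mdir) == 0:
            mdir = np.array([0.0, 0.0, 1.0])
        if subject.moment_mode == "axis":
            ax = int(np.argmax(np.abs(mdir)))
            mdir = np.sign(mdir[ax]) * np.eye(3)[ax]
        elif subject.moment_mode != "march":
            raise ValueError(f"unknown moment_mode {subject.moment_mode!r}")
    mdir = mdir / np.linalg.norm(mdir)

    env = _smoothstep(np.linspace(0.0, 1.0, subject.n_samples))
    moments = subject.peak_moment_amm * env[:, None] * mdir[None, :]  # A.mm

    dims = system.node_dims
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    base = nodes @ strides

    i_dip = 1.0 / model.pitch
    ind = np.empty((len(LEADS_INDEPENDENT), subject.n_samples))
    for r, lead in enumerate(LEADS_INDEPENDENT):
        psi = fields[lead].phi
        diffs = np.stack([psi[base + strides[a]] - psi[base] for a in range(3)],
                         axis=1)  # (T, 3)
        ind[r] = i_dip * (diffs * moments).sum(axis=1)

    by = dict(zip(LEADS_INDEPENDENT, ind))
    full = {**by,
            "III": by["II"] - by["I"],
            "aVR": -(by["I"] + by["II"]) / 2.0,
            "aVL": by["I"] - by["II"] / 2.0,
            "aVF": by["II"] - by["I"] / 2.0}
    samples = np.stack([full[lab] for lab in LEAD_ORDER]) * 1e3  # V -> mV

    rng = np.random.default_rng(subject.seed)
    if subject.baseline_wander_mv > 0:
        t = np.arange(subject.n_samples) / subject.fs
        f0 = rng.uniform(0.2, 0.6)
        phase = rng.uniform(0, 2 * np.pi, size=(samples.shape[0], 1))
        samples = samples + subject.baseline_wander_mv * np.sin(
            2 * np.pi * f0 * t[None, :] + phase)
    if subject.snr_db is not None:
        lead_rms = np.sqrt((samples ** 2).mean(axis=1, keepdims=True))
        noise_sd = lead_rms * 10.0 ** (-subject.snr_db / 20.0)
        samples = samples + noise_sd * rng.standard_normal(samples.shape)

    return ECGRecord(samples=samples, fs=subject.fs,
                     subject_id=subject.subject_id or subject.origin,
                     truth_origin=subject.origin)


def simulate_cohort(phantom: Phantom, system: SpfdSystem,
                    counts: dict[str, int] = STUDY_COHORT_COUNTS,
                    snr_db: float | None = None, seed: int = 0,
                    fields: dict | None = None,
                    subject_kw: dict | None = None,
                    **solve_kw) -> list[ECGRecord]:
    """Simulate a labeled cohort, reproducible from a single seed.

    ``counts`` maps origin labels to subject counts; the default mirrors the
    15/6/6 LC/AC/RC composition of the clinical population. Each subject
    receives an independent noise substream spawned from ``seed``.
    """
    for k, v in counts.items():
        if k not in ("LC", "AC", "RC") or v < 1:
            raise ValueError(f"bad cohort counts entry {k}={v}")
    if fields is None:
        fields = reciprocal_lead_fields(system, phantom.montage,
                                        LEADS_INDEPENDENT, **solve_kw)
    child_seeds = np.random.SeedSequence(seed).generate_state(sum(counts.values()))
    records = []
    i = 0
    for origin in ("LC", "AC", "RC"):
        for k in range(counts.get(origin, 0)):
            subj = SimulatedSubject(origin=origin, snr_db=snr_db,
                                    seed=int(child_seeds[i] % (2 ** 31)),
                                    subject_id=f"{origin}{k + 1:02d}",
                                    **(subject_kw or {}))
            records.append(simulate_subject(phantom, system, subj, fields=fields))
            i += 1
    return records
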