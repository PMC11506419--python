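# cardioloc

Non-invasive localization of ectopic heartbeats from the 12-lead ECG, aimed
at premature ventricular contractions (PVCs) arising at the pulmonary valve.
Catheter ablation of these beats needs to know *which cusp* of the valve —
left (LC), anterior (AC), or right (RC) — hosts the focus, a distinction the
surface ECG waveform alone resolves poorly. `cardioloc` attacks the problem
with volume-conductor physics: it forward-models how a cardiac current
dipole produces body-surface potentials in a voxelized torso, inverts the
measured leads time step by time step, and classifies the origin by the
distance between the estimated source trajectory and the three cusp sectors
of the valve annulus.

Intended users: computational electrophysiology and bioelectromagnetics
researchers who want a self-contained, testable reference pipeline for
voxel-based ECG source imaging — including a synthetic torso phantom and
ECG generator, since clinical recordings and licensed anatomical models
cannot be redistributed.

## Method

**Forward model.** At ECG frequencies (~1 Hz) the quasi-static scalar
potential satisfies ∇·(σ∇φ) = −∇·**J** in the body with the insulating
boundary σ∇φ·**n** = 0. The scalar-potential finite-difference (SPFD)
discretization places φ on voxel-corner nodes; each node obeys Kirchhoff's
current law Σₙ Sₙ(φ₀ − φₙ) = I₀, where the edge conductance Sₙ is the mean
conductivity of the four voxels sharing the edge times the voxel pitch.
The symmetric system is solved by SOR-smoothed geometric multigrid
(V-cycles, Galerkin coarse operators, six levels) to relative residual
≤ 10⁻⁶.

**Lead field matrix.** Unit dipoles along the three grid axes at N candidate
nodes inside the heart define the M × 3N lead field matrix **L** with
**L j** = **Φ**, where **j** stacks the candidate current densities and
**Φ** holds the M = 8 independent leads (I, II, V1–V6; the remaining four
follow linearly). **L** is built with M reciprocal solves — injecting each
lead's electrode weight pattern and reading the potential drop across every
candidate dipole edge — which the test suite checks against the 3N direct
dipole solves.

**Inverse.** For each sample in the rise-to-peak window of the (wavelet
denoised, baseline-corrected) ECG, orthogonal matching pursuit greedily
selects the dictionary column maximizing |φ·Lᵢ|/(‖φ‖‖Lᵢ‖), refits the
current density on the support by least squares, and updates the residual;
after five iterations a residual-weighted average of the iterates yields
ĵ*, and the candidate whose 3-vector in ĵ* has the largest norm is that
step's source estimate.

**Classification.** The minimum Euclidean distance d_r(t) from the source
track to each cusp region r ∈ {LC, AC, RC} is minimized over time; the
region with the smallest minimum wins. When LC and AC — whose propagation
patterns are similar — land within a 2 mm margin of each other, the region
whose minimum occurs *earlier* is called instead.

## Worked example

Build the synthetic torso (81×61×97 voxels at 2 mm: skin, fat, muscle,
lungs, heart, spine), its lead field, and classify three noiseless
synthetic PVCs, one per cusp:

```python
from cardioloc import (build_phantom, assemble_system, simulate_cohort,
                       place_candidates, build_leadfield, HEART_LABEL,
                       PipelineConfig)
from cardioloc.leadfield import reciprocal_lead_fields, LEADS_INDEPENDENT
from cardioloc.pipeline import process_subject

phantom = build_phantom()
system = assemble_system(phantom.conductivity_field(), phantom.model.pitch)
fields = reciprocal_lead_fields(system, phantom.montage, LEADS_INDEPENDENT)
grid = place_candidates(phantom.model, HEART_LABEL, spacing=2)
lfm = build_leadfield(system, grid, phantom.montage, fields=fields)
print(f"lead field: {lfm.L.shape[0]} leads x {lfm.L.shape[1]} columns "
      f"({grid.n} candidate sites)")

records = simulate_cohort(phantom, system,
                          counts={"LC": 1, "AC": 1, "RC": 1}, seed=42,
                          fields=fields)
cfg = PipelineConfig()
for rec in records:
    track, call = process_subject(rec, lfm, phantom, cfg)
    d = ", ".join(f"{k}={v:.1f}" for k, v in call.d_min.items())
    print(f"truth {rec.truth_origin} -> called {call.label} "
          f"({call.rule} rule; min distances mm: {d})")
```

Output (a few minutes; the eight reciprocal multigrid solves dominate):

```
lead field: 8 leads x 4392 columns (1464 candidate sites)
truth LC -> called LC (distance rule; min distances mm: LC=4.0, AC=11.9, RC=10.9)
truth AC -> called AC (distance rule; min distances mm: LC=10.5, AC=4.2, RC=11.8)
truth RC -> called RC (distance rule; min distances mm: LC=10.6, AC=6.7, RC=3.1)
```

Each subject's estimated source track passes within ~3–4 mm of its own cusp
sector and stays ≥ 6 mm from the others, so the distance rule calls all
three correctly.

The same pipeline is available from the shell:

```bash
cardioloc run --out runs/demo --snr 20 --seed 7
cardioloc simulate --cohort 2 --snr 20 --seed 3 --out cohort/
cardioloc preprocess --in cohort/ecg_LC01.csv --out clean.csv
```

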