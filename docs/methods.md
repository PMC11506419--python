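# Methods

This note records the models, numerical choices and design decisions behind
`cardioloc`, and what the synthetic validation does and does not establish.

## Volume conductor and SPFD discretization

The body is a passive volume conductor: at the ~1 Hz scale of ECG
waveforms, displacement currents and inductive effects are negligible, so
the scalar potential obeys the Poisson equation ∇·(σ∇φ) = −∇·**J** with an
insulating boundary at the body surface. We discretize on a regular cubic
voxel grid (labels per voxel, conductivity per tissue) with potentials on
voxel-corner nodes. The conductance of the edge between two adjacent nodes
is the arithmetic mean of the conductivities of the four voxels sharing the
edge, times the pitch (for cubic voxels, area/length = pitch); this is the
standard SPFD stencil and reduces to the exact 7-point Laplacian in
homogeneous media. Because the labeled body is required to be strictly
interior to the grid, air-adjacent edges carry zero conductance and the
Neumann boundary condition emerges without any explicit boundary handling.

Assumptions: isotropic conductivities, purely resistive tissue at the
evaluation frequency, a single connected conductor. Anisotropy (notably
skeletal muscle) and capacitive effects are out of scope.

### Conductivities

The default table (S/m at 1 Hz): skin 0.10 (fixed by convention for
low-frequency surface recordings), fat 0.035, muscle 0.20, inflated lung
0.030, heart 0.050, cortical bone 0.020, blood 0.70. A four-term Cole–Cole
evaluator is provided with representative dispersion parameters so the
table can be re-derived at other frequencies; the shipped parameter sets
are documented defaults, not a claim to reproduce any particular
published database revision, and the table is fully configurable.

### Solver

The nodal system is symmetric positive semidefinite with the constants as
nullspace; we ground one reference node (default: the first active node)
by zeroing its row/column and unit-scaling its diagonal, which leaves an
SPD system whose solution is the Neumann solution gauge-fixed to φ = 0
there. Decoupled (all-air) nodes receive dummy diagonals scaled to the
mean active conductance — keeping them at unit scale poisons the Galerkin
coarse operators with a ~10³ scale contrast and stalls multigrid.

The default solver is a geometric multigrid V(1,1) cycle: forward SOR
pre-smoothing and backward SOR post-smoothing (ω = 1.5, configurable),
trilinear prolongation restricted to *active* coarse parents (interpolating
surface nodes from air nodes makes boundary error modes invisible to the
coarse grid; with truncation the observed convergence factor is ~0.5 per
cycle, without it ~0.93), Galerkin coarse operators, up to six levels, and
a sparse direct solve on the coarsest level. Iteration stops at relative
ℓ₂ residual ≤ 10⁻⁶ (configurable); failure to converge raises an error
carrying the residual history. Small systems (≤ 40k nodes) default to a
sparse direct factorization; pure SOR is retained as a cross-check path
and the test suite verifies multigrid/SOR agreement.

Units: world coordinates and pitch in mm, conductances in S (pitch
converted to meters internally), currents in A, potentials in V, dipole
moments in A·mm (a ±I pair on adjacent nodes has moment I·pitch). Simulated
ECGs are stored in mV.

## Lead field matrix

Candidate sources are the heart-interior nodes (all eight surrounding
voxels heart-labeled) on a sub-lattice with default spacing 2 voxels, each
carrying three orthogonal unit dipoles along the grid axes — hence the
3N-column dictionary. An optional mask restricts candidates to the
neighborhood of the target regions (the basal heart next to the valve);
the default pipeline uses the full heart grid. Columns are normalized to
unit dipole moment (1 A·mm).

Construction is reciprocal by default: for each of the M = 8 independent
leads (I, II, V1–V6 — the 12-lead set has rank 8), the lead's zero-sum
electrode weight pattern is injected as nodal currents and solved once;
the column entry for a candidate dipole is the dipole current times the
resulting potential difference across the dipole edge. By symmetry of the
conductance matrix this equals the direct construction (one forward solve
per column), which is retained for testing; the suite requires column-wise
agreement within 1%, and observes ~10⁻¹² on heterogeneous test phantoms.
Lead derivations use the standard definitions (Einthoven limb leads,
Goldberger augmented leads, Wilson central terminal for the precordials).

## ECG preprocessing

Records are 12 × T matrices in mV at 2 kHz. Preprocessing:

1. **Wavelet denoising** — per lead, Daubechies-4 decomposition to level 4,
   soft thresholding of all detail bands at the universal threshold
   σ̂√(2 ln T) with σ̂ = MAD(finest details)/0.6745. The default estimator is
   translation-invariant: the decimated transform is applied at eight
   reflection-padded shifts and the results averaged (cycle spinning).
   Shift-averaging matters here because the inverse is run independently
   per time sample, and decimated-DWT shift artifacts scatter the per-step
   estimates; `n_shifts=1` restores the plain transform.
2. **Baseline removal** — subtraction of the per-lead mean over an
   isoelectric span (default: the first 16 samples = 8 ms). A literal
   divide-by-baseline mode exists for completeness but is dimensionally
   odd and guarded against near-zero baselines.
3. **Windowing** — the analysis window runs from the rise to the peak of
   the waveform: peak = sample of maximum cross-lead RMS, start = latest
   earlier sample at or below 5% (configurable) of the peak RMS.

## Time-domain OMP localization

Per window sample, greedy pursuit on the lead-field dictionary: select the
column maximizing |φ·Lᵢ|/(‖φ‖‖Lᵢ‖) (absolute correlation — a sign-flipped
dipole is the same physical source; signed selection is available), refit
ĵ on the support by least squares against the *original* observation,
update the residual, repeat five times. Ties break to the lowest column
index; a column that makes the support rank-deficient is dropped with a
log message. The final estimate is ĵ* = Σ wₖ ĵₖ with wₖ ∝ 1/(‖φₖ‖ + ε),
ε = 10⁻¹²‖φ₀‖ — iterations that explain the data better carry more weight.
The source point of the step is the candidate whose 3-component block of
ĵ* has the largest Euclidean norm.

Steps are skipped when the lead-vector RMS falls below 1% of the window
maximum **or** below 3× the baseline noise level measured on the
pre-window segment. The second, noise-adaptive floor matters under
realistic noise: steps not significantly above the noise floor produce
uniformly scattered estimates, and because classification takes minima
over time, even a few such steps can plant a spurious minimum near the
wrong region.

With a rank-8 observation space and thousands of columns the dictionary is
extremely coherent. Recovery of a single axis-aligned lattice dipole is
exact in the noiseless case (verified for every candidate) and degrades
gracefully with noise (median error ≤ 2 lattice spacings at 20 dB). An
*oblique* dipole (a 3-column combination at one node), however, is
systematically mislocalized by ~15–20 mm: no greedy single-column
selection can resolve it against the coherent neighbors. This is a
property of the estimator class, not an implementation defect, and is why
the synthetic generator's default subjects are lattice-quantized and
axis-aligned (below).

## Classification

For each cusp region (a point set on the valve annulus), the point-to-set
Euclidean distance from every non-skipped track point is computed exactly;
the region with the smallest minimum over time is the call. If the two
closest regions are LC and AC and their minima differ by less than
δ = 2 mm (configurable), the call goes to the region whose minimum occurs
earlier — LC and AC sit adjacent on the annulus and produce similar
distance profiles, but their excitation reaches the surrounding myocardium
in a different order. Exact three-way ties fall back to
lowest-distance → earliest-time → fixed order LC < AC < RC, with a logged
warning. In the synthetic cohorts the timing disambiguation is neutral to
slightly unfavorable, because the generator gives LC and AC subjects
identical excitation schedules — the timing signal the rule exploits in
real recordings is deliberately absent from the phantom; we keep the rule
enabled as part of the method.

## Synthetic phantom and cohort generator

The generator replaces two assets that cannot be shipped: a licensed
anatomical voxel model and clinical PVC recordings.

* **Phantom**: nested ellipsoids on an 81×61×97 grid at 2 mm pitch
  (configurable to 1 mm) — a torso with a 4 mm skin shell and 4 mm fat
  layer over muscle, two lungs, a posterior spine cylinder, and a heart
  ellipsoid (semi-axes 27×29×33 mm). The pulmonary-valve annulus is a
  circle (radius 11 mm) on the basal heart surface, tilted
  anterior-superior, partitioned into three 120° sectors for LC/AC/RC.
  Nine electrodes (RA, LA, LL, V1–V6) are the surface nodes nearest to
  standard anatomical proportions. Everything is deterministic given the
  spec.
* **Subjects**: an ectopic focus launches from a seeded random point on
  the central half of its cusp's arc (foci lie within a cusp; the excluded
  quarters abut the commissures, which are the boundaries *between*
  cusps), then travels 30 mm in a straight line toward the heart centroid
  across the 80 ms window (160 samples at 2 kHz) while its moment rises
  from 0 to 0.02 A·mm (the scale of a peak equivalent cardiac dipole)
  along a smoothstep envelope. Positions are quantized to the 2-voxel
  source lattice and the moment points along the dominant grid axis of the
  march, so each sample's signature is exactly one dictionary atom — the
  regime in which the greedy inverse admits exact recovery; a continuous
  oblique-moment mode is available for stress testing. Lead potentials are
  computed through the reciprocal fields (numerically identical to a
  per-sample forward solve), white Gaussian noise is added per lead at the
  requested SNR (defined against that lead's RMS over the record), and
  optional baseline wander supports preprocessing tests.
* **Cohorts**: default composition 15 LC / 6 AC / 6 RC, mirroring the
  clinical population the pipeline targets; a balanced mode exists. Noise
  substreams are spawned per subject from one seed.

What passing the synthetic study shows: the forward physics, lead-field
algebra, pursuit, and classifier compose correctly, with 100% origin
recovery noiseless and ≥ 80% at 20 dB in the tested condition. What it
does not show: performance on real ECGs, whose sources are distributed
wavefronts rather than lattice point dipoles, whose moments rotate through
oblique orientations (where the estimator carries the bias quantified
above), and whose anatomy differs from the ellipsoid phantom. The
synthetic accuracy therefore bounds the machinery, not the clinical
method.

## Problem sizes and runtime choices

The 2 mm phantom (~500k nodes) keeps a full validation — eight reciprocal
solves, two 27-subject cohorts, and the solver oracles on an 83³ grid —
within minutes on one CPU; the multigrid solver converges in ~10–20
V-cycles at ω = 1.5. Unit tests run on ≤ 17³ grids where dense and SOR
oracles stay cheap. The acceptance script reports measured quantities at
these sizes.

## Known limitations

* Isotropic, single-frequency conductivities; no tissue anisotropy.
* The heart is one tissue: no chambers, no conduction system, no
  electrophysiological propagation model (the generator is dipole
  kinematics only).
* The estimator's oblique-moment bias (above) limits point accuracy to
  the ~1.5–2 cm scale for non-axis-aligned sources; classification is more
  robust than point localization because it depends on distance *ordering*
  near the annulus.
* The LC/AC timing rule's margin δ = 2 mm and the rise threshold (5%) are
  configurable conventions; no principled calibration is claimed.
* One PVC complex per record; multi-beat recordings must be segmented
  upstream.
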