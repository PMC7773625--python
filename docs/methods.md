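# Methods

This note records the models, numerical choices and design decisions behind
`atriafib`, and what the synthetic test bed does and does not establish
about real data.

## Universal atrial coordinates

Each atrial surface is mapped to the unit square by two discrete-harmonic
fields (cotangent-weight P1 finite elements, no mass lumping) with
landmark-fixed Dirichlet data. Solves are exact at the boundary nodes; the
reduced sparse systems are solved directly and checked against a relative
residual of 1e-10.

**LA.** One manual seed marks the septal end of the mitral rim. The mitral
rim is split at the seed and its arc-length antipode into a posterior half
(beta = 0) and an anterior half (beta = 1). A roof separating line — a
concatenated geodesic from the septal junction, anterior of the superior
pulmonary veins, to the lateral junction — carries beta = 0.5 and splits
the chamber into posterior and anterior sub-meshes, which are solved
separately and concatenated (the Dirichlet data is expressed in final
coordinates, so no rescaling step is needed and continuity across the roof
line is exact). The septal and lateral segments of that line carry
alpha = 0 and alpha = 1. The path search forbids the posterior cap
containing the veins, which is how the line is forced anterior of them;
the cap threshold is derived from the PV rim positions with a 3-edge margin.

**RA.** Two manual seeds mark the centres of the lateral and septal
tricuspid half-rims. beta is a full-mesh solve with IVC = 0 and SVC = 1;
the tricuspid rim and the TV-to-IVC seam path are also held at beta = 0
(the valve shares the inferior edge with the IVC — without this, beta is
non-monotone south of the IVC and the flattening folds there). alpha winds
around the chamber: the surface is cut open along a seam of geodesics from
the posterior TV junction to the IVC and from the IVC to the SVC — the
boundary paths along which the coordinate system is discontinuous — and
the two sides of the cut carry alpha = 0 (lateral) and alpha = 1 (septal).
Cutting duplicates the seam vertices (the coordinate is double-valued
there); the reported per-vertex field carries the side average, and all
downstream consumers treat seam-incident elements by nearest-regular-
neighbour replacement.

**Structure pinning.** PV rims (LA) and the CS rim (RA) are pinned to
circles around configurable atlas centres; appendage tips are pinned to a
point. Defaults live in `LA_ATLAS_DEFAULTS` / `RA_ATLAS_DEFAULTS` and were
chosen at the natural (pin-free) locations of the synthetic anatomy family,
which minimises the distortion the pins introduce; with deposited data the
table should be edited to the dataset-average locations. The circle phase
and winding are taken from a provisional pin-free solve (monotonised, since
pin-free hole images are slit-like), and the default radius is the
provisional RMS radius clamped to [0.02, 0.045] so neighbouring pins cannot
overlap.

**Folds.** Harmonic maps with pinned interior structures are not globally
injective: a small halo of orientation-flipped triangles (well under 1% of
elements on the test anatomies) can remain around the pins after a local
untangling pass (fold-incident free vertices are relaxed onto convex
neighbour averages; relaxed vertices are no longer exactly harmonic and
are counted in the diagnostics). Flipped, degenerate and seam-incident
elements are excluded as interpolation sources during mapping and are
back-filled from their nearest regular neighbour, so no element is left
undefined. Diagnostics (`flipped_triangles`, `degenerate_triangles`,
`relaxed_vertices`, `seam_vertices`) are attached to every `UACField`.

## Fibres in the UAC basis

Per element, `e_alpha` is the normalised in-plane P1 gradient of alpha and
`e_beta = n x e_alpha`. Fibre angles theta in [0, pi) are measured from
`e_alpha` for the LA and from `e_beta` for the RA (so theta ~ 0 means
lateral-septal in the LA and IVC-SVC in the RA). Fibres are axial (sense-
free): every average or interpolation runs on the doubled angle — the unit
vector (cos 2 theta, sin 2 theta) is interpolated and halved — because raw
angles are discontinuous at the 0/pi wrap. Mapping between anatomies
samples the source field at target element centroids in coordinate space,
locating them in the source connectivity (a k-d-tree candidate search with
snap-to-nearest fallback, counts reported).

## Circular statistics and comparison metrics

Axial mean and standard deviation use the doubled-angle resultant:
mu = 0.5 atan2(S, C) wrapped to [0, pi), s = 0.5 sqrt(-2 ln R). A zero
resultant returns mu = 0 by convention with s = inf. Field comparison uses
the acute angle E = arccos(|F1.F2|/(|F1||F2|)) in [0, pi/2] and
Q_{pi/8} = the unweighted fraction of elements with E < pi/8 (strict; area
weighting is deliberately not applied, mirroring element-wise treatment).
Directional classes split theta at pi/4 and 5 pi/6, with boundary values
counted in the reference-axis class. Named regions are axis-aligned boxes
in coordinate space (shipped defaults partition the square; structure
boxes are carved out of the walls) and should be pinned explicitly when
reproducing any regional numbers from external data.

## Synthetic anatomies and fibre patterns

Shells are ellipsoids (default LA radii 35 x 30 x 28 mm) triangulated from
a subdivided icosahedron, with circular rim openings (four PVs + MV, or
SVC/IVC/TV/CS), a Gaussian appendage bump, and optional smooth random
radial perturbations (a few long-wavelength lobes, relative amplitude
~4-5% for "different anatomy" experiments). The epicardial shell is a
0.5 mm normal offset with identical connectivity (the 0.1 mm bilayer
offset used in simulation is a separate, bookkeeping constant). Randomness
is `numpy.random.default_rng` (PCG64); fixed seeds reproduce bit-identical
meshes and fields.

Fibre patterns are smooth functions theta(alpha, beta): the LA default is a
posterior-anterior (pi/2) band on the roof over a lateral-septal (0)
background; the RA default is a lateral pectinate-like band over an
IVC-SVC background. Perturbations add wrapped-normal noise on the doubled
angle with standard deviation 1/kappa radians ("concentration" kappa,
default 8, i.e. ~3.6 degrees of angle noise); a configurable noise-region
box (default: the roof) lowers kappa (default 2, ~14 degrees) to emulate a
structure whose fibre direction genuinely varies between subjects. The
vector sample cloud copies each element's fibre onto nearby regular-grid
points at a 0.4 mm default pitch, emulating reconstructed DT-MRI primary
eigenvectors without their tensor-estimation noise. What passing recovery
tests show is therefore that the *registration and averaging machinery* is
unbiased and convergent under controlled variability — not that real
DT-MRI noise has these properties.

## Streamlines

Streamlines integrate the sense-free direction (cos theta, sin theta) in
coordinate space with fixed-step RK4 (default step 0.005 UAC units, 2000
steps maximum, bidirectional; sign chosen to continue the previous step).
Metric distortion of the flattening is deliberately ignored, so regular 2D
spacing is not regular 3D spacing. Thinning is greedy in descending length
with a minimum point-distance criterion; the lift to 3D is barycentric,
splitting polylines that jump across the seam.

## Monodomain simulation

Propagation is the monodomain reaction-diffusion equation with the
in-plane conductivity tensor sigma_T (I - n n^T) + (sigma_L - sigma_T)
f f^T; baseline sigma_L = 0.4 S/m, sigma_T = 0.1 S/m (4:1) with 0.04 S/m
for the 10:1 study. Conductivities become diffusivities through
sigma / (chi C_m) with chi = 140 mm^-1 and C_m = 0.01 uF/mm^2, giving
D_L ~ 0.29 mm^2/ms and a longitudinal CV of ~0.54 mm/ms on refined sheets.
The spatial discretisation is P1 FEM with lumped mass; time stepping is
operator-split with explicit membrane reaction and implicit (LU-factorised)
diffusion by default; an explicit-diffusion option is guarded by a
Gershgorin CFL check. The default reaction time step is 0.02 ms, matching
common practice; the desk-scale experiments in the tests and the
acceptance script use 0.05-0.1 ms, at which the implicit scheme remains
stable and the CV anisotropy law holds within a few percent.

The membrane is pluggable; the default is a two-variable excitable model
(Mitchell-Schaeffer form, normalised voltage) with tau_in = 0.3,
tau_out = 5, tau_open = 100, tau_close = 60 ms and gate 0.13, giving an
AF-like action potential of roughly 90 ms. The `eta` excitability factor
scales the inward current; eta ~ 0.7 shortens the wavelength enough to
sustain re-entry on a 6-7 cm chamber, standing in for the doubled
inward-rectifier conductance used for the same purpose in biophysically
detailed models. No claim of ionic fidelity is made: conclusions exercised
here depend on anisotropy and wavelength, which the surrogate controls
explicitly.

Bilayers duplicate a surface at a 0.1 mm offset (endocardium outward for
the LA, epicardium inward for the RA) with node-to-node linear coupling
kappa_c (1/ms, mass-weighted). The default kappa_c = 3/ms gives
sub-millisecond transmural activation delay; the published value of the
coupling coefficient is not printed in the source literature, so it is a
config parameter.

Pacing follows the stated protocol (1 s lead-in, 5 beats at 700 ms cycle
length, activation map from beat 5; sites given in UAC so they port across
anatomies) with the stimulus a >= 8-node disc of 2 mm nominal radius for
2 ms; "auto" amplitude bisects the tissue-level capture threshold and
applies a 1.5x margin. The desk-scale experiments shorten this to 2 beats
at 400 ms after a 200 ms lead-in on ~2.5 mm meshes — chosen so the whole
suite runs on one CPU in minutes; the full protocol remains the default.
LAT is the linearly-interpolated first rising crossing of the midpoint
between resting and peak voltage. LAT maps are compared by the median
absolute difference (ms) and the maximum absolute difference as a
percentage of the reference map's total activation time, excluding
never-activated nodes pairwise.

## Arrhythmia metrics

Initial conditions encode four Archimedean spirals (two posterior, two
anterior, alternating chirality; cycle 180 ms, pitch 0.08 UAC/rad) as a
pseudo-activation-time field; node states are read off a paced single-cell
template at the corresponding phase, identically on both layers. Phase is
computed by delay embedding (tau = 10 ms, per-node mean removed) rather
than a Hilbert transform — streaming-friendly and free of edge artefacts;
the upstream method it stands in for is not printed in the source
literature. Phase singularities are triangles whose oriented wrapped
vertex-phase differences sum to +-2 pi; charge is the winding sign and the
location the face centroid in UAC. Density maps are unsmoothed 32 x 32
histograms of detections normalised by the number of analysed snapshots
(5 ms cadence; both configurable), so the map integral equals the mean
simultaneous PS count; maps are compared with the Pearson correlation over
cells (undefined for constant maps, flagged as NaN). The experiment
records termination when no node remains above threshold.

## Desk-scale problem sizes

The tests and `scripts/acceptance.py` use: strips of a few hundred to a
few thousand vertices for closed-form checks; 1.5 mm-edge synthetic LAs
(~9 k vertices, ~18 k elements) for coordinates, registration and atlas
construction; a 0.25 mm sheet for the CV law; and a 2.5 mm-edge LA
(~2.4 k vertices per layer) for the pacing and 2 s spiral-wave
experiments. These sizes are the package's choice of desk-scale defaults;
all of them are parameters, and the full-protocol values remain the library
defaults.

## Known limitations

- No transmural (third) coordinate; strictly surface-based.
- The landmark/path recipe is this package's own; coordinates are
  compatible in convention but not bit-compatible with externally
  deposited coordinate fields.
- Four-PV anatomies only; no interatrial connections; homogeneous membrane
  properties (no PV/appendage repolarisation gradients).
- The membrane surrogate has no ionic detail; absolute LAT differences and
  PS counts are not comparable to values computed with biophysically
  detailed models, only directions of effect and map-level statistics are.
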