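# Methods

This note documents the models, numerical choices and limitations behind
`cecglead`, in the order the pipeline runs them.

## Volume conductor

The thorax is a stylised five-tissue conductor assembled from parametric
solids in the body frame (x left→right shoulder, y back→front, z up,
metres):

| compartment    | shape              | centre (m)           | semi-axes (m)          | σ (S/m) |
|----------------|--------------------|----------------------|------------------------|---------|
| thoracic wall  | elliptic cylinder  | (0, 0, 0)            | (0.17, 0.12, 0.21)     | 0.1     |
| heart wall     | ellipsoid          | (0.10, 0.03, 0)      | (0.055, 0.045, 0.065)  | 0.2     |
| blood          | ellipsoid (nested) | (0.10, 0.03, 0)      | 0.62 × heart           | 0.5     |
| lungs (×2)     | ellipsoid          | (±0.08, −0.05, 0.08) | (0.040, 0.045, 0.115)  | 0.05    |
| sub-diaphragm  | torso below z-top  | z < −0.10            | —                      | 0.1     |

The heart-base position (0.1, 0.03, 0) m and the conductivities are the
anchored physiological inputs; the torso cross-section is a free parameter
chosen so that position sits comfortably inside a plausible trunk (~42 cm
tall). Ribs, spine, aorta and liver are deliberately absent: their
conductivities are close to the wall/abdomen values they are merged into,
and organ shapes are smooth idealisations. Respiration-dependent lung
conductivity is out of scope.

**Meshing.** Quasi-uniform points are placed on every material interface
(Fibonacci lattices on ellipsoids, staggered rings plus Vogel-spiral caps
on the cylinder) and on an interior jittered grid, then tetrahedralized
with Delaunay (`scipy.spatial`); the outer solids are convex, so the hull
is the domain. Tets are labelled by the compartment containing their
centroid; because interfaces carry their own points, per-label volumes
converge to the analytic solid volumes under refinement (<1 % between the
0.018 m and 0.015 m presets). The interior resolution default is 0.015 m
(~130k tets, mirroring the ~10⁵-element scale of CT-derived models) with
interfaces at half that spacing; tests and the acceptance study use a
0.02 m/0.011 m preset (~56k tets) to keep runtimes in seconds. The jitter
seed (default 0) makes meshes bit-reproducible. A homogeneous ball built
the same way (optionally with a refined central lattice to resolve discrete
sources) is the analytic oracle geometry.

## Forward solver

Standard P1 tetrahedral FEM for ∇·σ∇φ = I_SV with per-element constant σ
and a homogeneous Neumann condition. The singular pure-Neumann system is
bordered with one Lagrange multiplier enforcing a zero area-weighted mean
of φ over the boundary — a gauge choice rather than a grounding vertex, so
potential *differences* (lead voltages) are gauge-free. The bordered matrix
is factorized once per mesh (`splu`) and reused for all right-hand sides;
the relative solve residual is checked against 10⁻⁸.

The dipole is realized as point-monopole pairs ±p_k/δ separated by
δ = 2 mm and distributed barycentrically to the vertices of their
containing tets. The default realization splits the moment into three
axis-aligned pairs, which makes the discrete load *exactly linear* in the
moment vector — the property that lets the three-solve lead-field basis
reproduce any direct solve to solver precision, so time-varying dipoles
never require re-solves. A single moment-aligned pair is available
(`mode="aligned"`); halving δ on a source-resolving mesh changes surface
potentials by <1 %, confirming the dipole limit. Barycentric distribution
preserves the dipole moment exactly on any mesh; only near-field detail
depends on local resolution.

Against the closed form φ(R,θ) = 3p·cosθ/(4πσR²) for a centred dipole in a
0.1 m, 0.2 S/m ball, the surface potential at ~61k tets has 3.0 % relative
L2 error (4.4 % at ~25k), and the pole value is within 2 % of 2.387 mV.

Surface fields: E = −∇φ is constant per element; boundary-vertex values
average the owning tets of incident boundary triangles with one-third
triangle-area weights, and the tangential component removes the projection
on the area-weighted vertex normal. Equatorial tangential magnitudes match
the differentiated closed form within a few percent.

## Capacitive electrode

The electrode patch is the set of boundary triangles whose centroid lies
within the plate radius of its centre (Euclidean distance; in the
gap ≪ radius regime geodesic corrections are negligible). The rigid plate
sits parallel to the local mean normal at the nominal gap above the closest
surface point, giving a per-vertex gap profile d(x) and specific
capacitance Ce = ε₀εᵣ/d. Defaults: radius 0.01 m (2 cm plate), gap 1 mm (a
thin cotton layer; electrically air-dominated, εᵣ = 1). The regime
requirement plate-diameter > gap is recorded as a warning, not enforced.

Ve is the discrete Ce-weighted area mean of V over the patch. Exact
consequences used as test anchors: an equipotential surface pins Ve to the
surface value; uniform coupling reduces Ve to the plain area-weighted mean;
uniform Ce rescaling (hence ω, and normal motion over a uniform gap)
cancels entirely.

Motion sensitivities are explicit finite differences of the Ve formula —
normal: recompute Ce with d → d+Δ at fixed V; tangential: re-centre the
patch a step along the surface at fixed gap. The tangential difference
agrees with the coupling-weighted mean tangential field to first order,
which motivates the artifact susceptibility score: |coupling-weighted mean
tangential E| under the plate. The amplifier's input impedance, triboelectric
charge and fabric dielectrics are not modelled.

## Lead optimization

Candidate centres are a deterministic greedy minimum-distance subsample of
the patch vertices (spacing default 2 cm = plate diameter): candidates are
≥ spacing apart and every patch vertex is within spacing of one, so the
grid covers the patch. All non-overlapping pairs are scored; the combined
objective is

    combined = amplitude − λ·L·susceptibility,  L = separation,

with λ = 0 by default — the headline criterion is pure R-wave amplitude,
and the artifact criterion is exposed as a tunable penalty because no
canonical weighting exists. Ties break deterministically (lower
susceptibility, then lexicographic centres). On the sphere oracle the
winner's axis lies within one grid step of the dipole axis and matches an
independent brute-force re-evaluation exactly.

Amplitude-vs-angle rotates the lead about the midpoint surface normal
(orthogonalized against the lead axis so the 180° rotation swaps the
electrodes exactly), keeping midpoint and separation fixed and snapping
endpoints to patch vertices; how sub-optimal leads are placed is otherwise
unconstrained, and this choice keeps them comparable to the optimum. The
backrest patch is the lowest-y 35 % of the boundary clipped to
|z| ≤ 0.16 m — an armchair backrest's footprint; without the height clip
the amplitude-maximal pair lands on the meshed torso's rim where rotated
leads leave the surface.

## Signal synthesis

The cardiac cycle is a sum of Gaussian dipole components on the unit cycle,
scaled by the cycle length (60 bpm default):

| wave | centre (s) | width (s) | moment (×p) | direction |
|------|-----------|-----------|-------------|-----------|
| P    | 0.210     | 0.025     | 0.12        | +axis     |
| Q    | 0.300     | 0.009     | 0.15        | −axis     |
| R    | 0.330     | 0.012     | 1.00        | +axis     |
| S    | 0.360     | 0.009     | 0.18        | −axis     |
| T    | 0.600     | 0.040     | 0.35        | +axis     |

with p = 2.0×10⁻⁵ A·m along the reference heart axis (azimuth 5π/6,
elevation 3π/4 — the elevation convention is the polar angle from +z; the
azimuth is referenced to +x). Only the R-instant magnitude and direction
are anchored to measured data; the other components are generic shape
plumbing chosen so they contribute <1 % at the R centre. All component
directions are collinear with the heart axis — a simplification that makes
the trace a scaled projection of the loop; real P/T axes deviate by tens of
degrees, which would change wave-amplitude ratios between leads but not the
R-led analyses here.

Traces are sampled at 2.3 kHz and averaging-downsampled to 72 Hz (each
output sample is the mean of the input samples in its half-open interval —
an exact specification of the non-integer 2300/72 ratio). Motion events are
a seeded Poisson process (2/min default), each a 0.5 s raised-cosine rigid
retreat of one plate by up to 0.5 mm; Ve is recomputed per sample from the
perturbed Ce while the surface potential keeps evolving, so artifacts
vanish identically on equipotential surfaces and are confined exactly to
event windows. Noise is white Gaussian added after downsampling, with σ
calibrated as VR·10^(−SNR/20) from the trace's own mean R amplitude; the
calibration round-trips through the estimator within ±1 dB. The end-to-end
study targets 21 dB so that the *measured* SNR of every trace sits at or
above the 20 dB operating point characteristic of a good non-contact lead.
The acquisition filter is the identity (no published response to emulate);
respiration wander and powerline interference are not modelled.

## QRS detection and scoring

The Pan–Tompkins chain uses the canonical parameters — 5–15 Hz band-pass
(3rd-order Butterworth, zero-phase), five-point derivative, squaring,
150 ms integration window, 200 ms refractory, 360 ms T-wave slope test
(reject if the local slope is under half the previous QRS's), search-back
at 1.66× the running RR mean with a halved threshold — all specified in
seconds and rounded to the trace rate, so the detector runs unchanged at
72 Hz. Thresholds are adaptive running estimates seeded from the first two
seconds, making detection invariant under amplitude scaling. Fiducials are
refined to the strongest band-passed deflection within ±100 ms.

SNR estimation follows 20·log₁₀(VR/σ_N): VR is the mean peak |value|
within ±80 ms of each beat; σ_N is the SD over the [R+0.45·RR, R+0.80·RR]
windows, which operationalises "between the T and P waves" for the default
wave timings (both fractions are configurable).

Detections are matched to ground truth by greedy nearest one-to-one
matching within 100 ms (no canonical tolerance exists; 100 ms is well
under half the shortest plausible RR). SE and both PPV variants are
reported: with the published counts TP = 13,948, FN = 139, FP = 259 the
total-error variant gives 97.23 % (97.2255 unrounded) and the standard
variant 98.18 %; they coincide only when FN = 0.

## Study analog and what it shows

The pipeline's default study — ten 15-minute, 60 bpm traces on the
optimal back lead with two motion events per minute and 21 dB target
noise — yields measured SNR ≈ 21 dB, SE and standard PPV ≥ 99 % over 9000
beats, while the same acquisition on a lead rotated ~85° off-axis at the
identical absolute noise floor collapses to single-digit SNR and far lower
sensitivity. This demonstrates the mechanism (lead choice → amplitude →
SNR → detection quality) under controlled conditions; it does not certify
performance on real recordings, whose artifacts (electrode pop, baseline
wander, myographic noise, imperfect ground truth) are richer than this
generator's.

## Numerical notes and edge cases

- Degenerate Delaunay configurations are prevented by seeded point jitter;
  exactly flat hull slivers (volume < 10⁻¹² of the maximum) are dropped
  before boundary extraction, which re-derives watertightness from face
  counts.
- A zero dipole magnitude short-circuits to a zero load/potential; the
  pipeline aborts at lead optimization with "no admissible signal".
- Electrode patches are empty when the plate radius is below the local
  triangle size; couplings raise a geometry error, and the optimizer drops
  such candidates (the surface resolution presets keep plates ≥ mesh size).
- All randomness (mesh jitter, motion events, noise) flows through explicit
  integer seeds; re-running any stage with the same inputs is
  bit-reproducible.
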