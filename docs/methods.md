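# Methods

## Scope and overall design

`corofuse` implements the geometry-and-physiology side of a dynamic
coronary FFR-CT workflow: everything from per-phase vessel geometry to the
FFR number. Image-space processing (vessel segmentation, centerline
extraction from CT volumes) is out of scope — inputs are assumed geometric
(meshes, centerlines, radii, HU time series). The full 3D transient CFD that
a production pipeline would run on the fused geometry is replaced by a
reduced-order network solver; boundary-condition bundles (YAML + an
OpenFOAM-dialect snippet) are exported so users can still run an external 3D
solve on the same inputs.

## Geometry primitives

Centerlines are ordered polylines with a cumulative arc-length parameter s
(mm). Curvature κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|² are
evaluated with central finite differences on the (possibly non-uniform) s
grid, one-sided at the endpoints. Where the curve is locally straight the
Frenet frame is undefined; torsion is set to 0 there — the planar-curve
limit — which also keeps the torsion factor of the fusion weight finite.
Closed-form checks (circle, helix) agree within 1 % at 200-point sampling
and converge under refinement.

Bifurcations follow the modified Murray law r_p^2.6 = r_d1^2.6 + r_d2^2.6;
the same exponent partitions flow between daughters (Q₁/Q₂ =
(r₁/r₂)^2.6), which keeps branch-level Reynolds numbers consistent with the
radius law.

Lengths are millimetres everywhere; conversion to SI happens at exactly two
sites (the Reynolds-number and the resistance/Womersley computations), so a
unit mix-up cannot occur through the public interface.

## Synthetic dynamics

The generator emulates what an 11-frame gated acquisition would deliver.
Vessels are tubes of configurable length (default 60 mm), radius (2 mm),
and resolution (61 axial × 24 circumferential vertices), built on
rotation-minimizing frames so bent centerlines do not twist the mesh.
Cross-sections are ellipses obeying exact sectional volume conservation
π a(t) b(t) = A0 (1 + ε_r(t)); radial strain follows ε_r(t) =
a_r·sin(2πt/T) with amplitude a_r ≤ 0.05 (default 0.04), so the first and
last frame coincide (periodicity) while both are kept because the fusion
sums run over all 11 indices. Ellipticity modulation and a bulk lateral
shift add realistic non-radial motion without violating the strain bound. An
optional smooth random radius modulation (low-order Fourier series, seeded)
roughens the wall; all randomness flows through one explicit seed and the
same seed reproduces vertex arrays bit-for-bit.

Stenoses are Gaussian narrowings parameterized by fractional *area*
severity: the throat area is (1 − severity)·A_ref by construction (radius
scaled by √(1−severity·g(s))).

What the generator does **not** emulate: plaque eccentricity and wall
irregularity beyond smooth modulation, vessel lengthening/shortening over
the cycle (phases share arc length up to the bend shift), imaging noise and
segmentation error, and branching trees as deforming meshes (the network
solver accepts branching topologies, but the mesh generator emits single
vessels). Passing tests therefore demonstrate correctness of the algorithms
under clean periodic motion, not robustness to segmentation artifacts.

Skinning weights minimize the biharmonic energy tr(WᵀKW) with
K = L M⁻¹ L, L the cotangent stiffness matrix and M the lumped barycentric
mass of the wall mesh, under anchor constraints. The default anchor rule
constrains the ring of vertices nearest each centerline-segment midpoint to
that segment. Negative intermediate weights are clamped to 0 and rows
renormalized, keeping the linear-blend-skinning step a convex combination —
this is what makes blending reproduce any single global rigid motion
exactly. The LBS update itself is computed in displacement form
v′ = v + Σ_j w_j((R_j − I)v + t_j), which is algebraically identical under
partition of unity but returns bitwise-identical vertices for identity
transforms. The phase generator builds phases analytically from the
cross-section law rather than via estimated inter-phase transforms (nothing
constrains how such transforms would be estimated from images); the skinning
machinery is exposed and tested as a standalone deformation tool.

LV phantoms are icospheres (5120 faces at the default subdivision) scaled so
their *discrete* enclosed volume matches the target volume curve
V(t) = ESV + (EDV − ESV)(1 + cos 2πt/T)/2; EDV/ESV recovery is then limited
only by float round-off, and the divergence-theorem volume operator is
validated separately against closed forms. The aortic-root phantom
prescribes a diastolic area excess whose z-integral equals the requested
regurgitant volume exactly.

## Inlet profile and personalization

Defaults: V_d,max = 1.0 at t/T = 0.7, V_s,max = 0.4 at t/T = 0.3,
σ_d = 0.15, σ_s = 0.1, T = 60/HR. The Gaussians are evaluated on the single
cycle without periodic images; the neglected tails at the period edges are
≤ e⁻⁸. Time is taken modulo T, so the duplicated frame at t = T samples the
cycle start — consistent with the duplicated geometry frame.

DSVR is reported as the peak velocity over the diastolic window divided by
the peak over the systolic window (systole = t/T ∈ [0, 0.4] by default,
configurable). No closed formula is imposed; note that the *total* velocity
peaks slightly after the systolic component's own peak (≈ t/T = 0.32 for
defaults), so the windowed-peak DSVR (≈ 2.31) differs from the naive ratio
of component peaks.

Contrast ratios R_i = (HU_i − HU_base)/(HU_peak − HU_base) are passed
through unclamped; overshoot above 1 is visible to the caller rather than
silently truncated. The calibration factor α defaults to 1 in the pipeline;
a flow-matching helper (`calibration_factor`) chooses α so the mean
personalized inlet flow equals the coronary allocation when inlet area and
Q_cor are known.

## Fusion weights

The three term coefficients α, β, γ have no established values; the package
defaults to 1.0 each (terms treated as equally informative) and records them
in every output manifest. Further numerical choices:

* |dA/ds| in the acceleration term — a signed derivative would let
  acceleration cancel deceleration in what is meant to be a complexity
  score;
* torsion guard ε = 10⁻⁸ mm⁻¹ in the denominator κ + ε;
* weight floor δ = 10⁻⁶ added to every w_geo, so a geometrically featureless
  vessel degrades gracefully to flow-only (base) weighting instead of 0/0 in
  the normalization;
* per-phase arc quantities are aligned on the phase-0 grid by *normalized*
  arc length s/L before weighting, so phase-dependent lengthening cannot
  misalign sections;
* per-phase flow is Q_i = Vp_i·v_scale·A_inlet with v_scale = 200 mm/s
  mapping the dimensionless profile to a typical resting coronary mean
  velocity; this puts local Reynolds numbers in the physiological few-hundred
  range against Re_ref = 500. Along an unbranched vessel the flow is carried
  unchanged; for trees, `murray_flow_split` supplies the branch flows.

Fusion of the surfaces multiplies a scalar weight by a mesh; this is
interpreted as vertexwise weighted averaging over corresponding vertices,
which the shared topology of a phase sequence guarantees is well defined.
Each vertex inherits the weight of its nearest phase-0 centerline station.
Consequences verified by tests: normalization Σ_i w_i^norm(s) = 1 to 1e−9,
convexity (fused vertices, r_eff, κ_eff inside per-phase envelopes),
permutation equivariance, and delta-weight recovery of a single phase.

## Cardiac function

Volumes use V = (1/3)∮ r·n dS per triangle; meshes must be watertight and
outward-oriented (a negative result raises rather than silently flipping
sign). Regurgitant volume uses the area-based surrogate
RV = ∫(A(z,t_dia) − A(z,t_AVC))dz with the trapezoid rule, clamped below at
0 with a warning — a negative raw integral signals noise, not antegrade
gain; a hook accepts a user-supplied retrograde-flow series for the direct
time-integral definition. RV is further clamped to ≤ SV in the metrics
pipeline. The Bramwell–Hill compliance coefficient β is dimensionless in the
linearized form used here, default 0.5, with the reference pressure P0
defaulting to the diastolic cuff pressure (80 mmHg in the demo config). The
monotone diastolic-decay outlet waveform P(t) = P_sys·e^(−t/τ) + P_dia is
taken at face value; no systolic upstroke is synthesized, and τ defaults to
the attached Windkessel's Rd·C when not supplied.

## Boundary conditions

The two-harmonic inlet waveform's sine terms integrate to zero, so the raw
printed form has cycle mean A₃·CO_eff = 0.1·CO_eff — inconsistent with
CO_eff being the mean flow. The default mode therefore rescales f by 1/A₃ so
the cycle-mean flow equals CO_eff; `raw` mode preserves the printed form
verbatim, and the chosen mode is recorded in exports. The aorta carries the
3-element Windkessel and coronary branches the 2-element model. The
Windkessel ODE dP_d/dt = (Q − P_d/Rd)/C integrates with an implicit
trapezoid scheme at Δt ≤ T/1000 (unconditionally stable, second order),
repeating cycles until cycle-to-cycle max|ΔP| < 0.1 %; the constant-flow
fixed point P = Q(Rp + Rd) and the RC decay match closed forms to 0.1 %.

Womersley profiles use the flow-normalized oscillatory solution
φ(x) = [1 − J₀(βx)/J₀(β)] / [1 − 2J₁(β)/(βJ₀(β))], β = i^{3/2}α — numerator
and denominator are both O(α²) as α → 0, avoiding the catastrophic
cancellation of the unnormalized form and converging exactly to the
parabolic Poiseuille shape. The returned profile is renormalized numerically
so it carries exactly the instantaneous Q, and a `simplified` mode exposes
the flat real-Bessel shape for comparison. The wall elastic modulus E
("patient age and risk factors") has no formula; it is a config value with
default 10⁶ Pa, as is the wall thickness h = 0.5 mm and the perfusion
territory ratio α_res = 1.

## Reduced-order FFR

The network solver is deliberately quasi-static: inertia and Womersley
effects are neglected because FFR is built from *time-averaged* pressures,
which at coronary scale are dominated by resistive losses. Per branch,
R = ∫8μ/(πr_eff⁴)ds by composite trapezoid; a stenosis detected within a
branch (throat area < 95 % of the upstream maximum) adds the expansion loss
ΔP = K_t·(ρ/2)·(Q/A_min − Q/A_ref)² with K_t = 1.52 as a pressure step at
the throat. At each time sample, leaf flows and the inlet pressure solve the
junction-conservation + path-pressure-consistency system (scipy `hybr`;
residual tolerance 10⁻⁶ of the pressure scale); 3-element outlet states
advance with an implicit step between samples and cycles repeat until the
inlet pressure is cycle-periodic to 0.1 %. For pure-resistance networks the
solution matches a direct linear-circuit solve to 1e−8.

The distal FFR evaluation point defaults to one local diameter beyond the
minimal-area point (overridable by arc position). The demo pipeline closes
the system with an autoregulation-style calibration: the microvascular
outlet resistance is chosen so the *healthy* vessel at the prescribed
(hyperemic, default 3× resting) coronary flow sees the Bramwell–Hill mean
aortic pressure; FFR deficits then arise purely from stenotic and geometric
losses. Blood is Newtonian with ρ = 1060 kg/m³, μ = 3.71×10⁻³ Pa·s.

## Problem sizes and determinism

Default study sizes — 11 phases of a 61×24-vertex tube, 5120-face LV
icospheres, 81 time samples per cycle, ≤ 1001-step Windkessel integration —
were chosen so a full pipeline runs in well under a second while every
discretization-sensitive check (volume convergence, taper-resistance
convergence, Frenet refinement) still has room to demonstrate order-of-
accuracy behaviour. All randomness flows through explicit
`numpy.random.default_rng(seed)` instances; reports are written with fixed
float formatting (17 significant digits) and sorted JSON keys, so reruns
with one seed are byte-identical.

## Known limitations

* The reduced solver reports no wall shear stress or velocity fields; those
  require the exported-CFD route.
* The quasi-static closure underestimates pulsatile augmentation of
  trans-stenotic losses at high Womersley numbers.
* Fusion weight coefficients (α, β, γ) are study conditions, not fitted
  quantities; different choices change the fused geometry within the
  per-phase convexity envelope but are not validated against patient data
  here.
* The synthetic generator's motion model is smooth and periodic by
  construction; real gated reconstructions exhibit phase-binning artifacts
  the pipeline has not been exercised against.
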