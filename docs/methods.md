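# Methods

This note documents the model, the numerical choices and the design
decisions behind `edlsim`, and what the synthetic test bed does and does not
show about real data.

## Source model

The equivalent dipole layer (EDL) sits on the closed surface `Sv` bounding
the ventricular myocardium: the epicardial shell and the (flipped)
endocardial shells merged into one outward-oriented surface enclosing the
wall volume. During depolarization the local transmembrane potential is a
0→1 step at the local activation time δ; the layer strength is calibrated so
that a fully activated element reproduces the physiological potential step
across the wavefront:

- potential step ΔV = 40 mV (default),
- myocardial conductivity σ = 0.2 S/m,
- nominal strength M = ΔV·σ = 8 mA/m ≡ 8 μA/mm.

Units are mm / mV / mA/m / S/m throughout. This system needs no length
conversions: solid angles are scale-invariant and M/σ is already in mV.

A triangle whose three vertices activate at δ1 ≤ δ2 ≤ δ3 is weighted by the
fraction of its area already activated at t, assuming δ varies linearly over
the triangle. The fraction is piecewise quadratic in t (0 below δ1, rising
`(t−δ1)²/((δ2−δ1)(δ3−δ1))`, falling `1−(δ3−t)²/((δ3−δ2)(δ3−δ1))`, 1 above
δ3); coincident vertex times are handled as the continuous limits, so a
synchronous triangle is a step. The default time step is 1 ms (the waveform
is smooth under the fraction weighting; halving the step changes peak
amplitudes by well under 1%).

## Volume conductor

Potentials in the piecewise-homogeneous torso (thorax 0.2, lungs 0.04,
blood 0.6 S/m, air 0 outside) are computed with a boundary-element method:

- The infinite-medium term of a source triangle at observation point y is
  `−Ω(y, tri)/(4πσ_s)` per unit strength, with Ω the signed solid angle by
  the analytic arctangent formula; closed outward surfaces subtend +4π from
  inside.
- Interface potentials solve the standard second-kind collocation system
  with the potential linear per triangle (each vertex collects Ω/3 of its
  incident triangles). The singular auto-solid-angle is fixed by closure:
  principal-value row sums over the observation point's own surface are
  forced to 2π, which absorbs the local curvature without local analytic
  integration.
- The insulated-torso operator annihilates constants; the system is deflated
  by a rank-one mean projector and the reference potential is fixed as zero
  mean over the 64 torso electrodes (cardiac observation points use the same
  reference).
- The ventricular and patch surfaces are *not* conductivity interfaces
  (σ_myocardium = σ_thorax), so one interface factorization serves any
  number of source surfaces.

The myocardial wall must not touch an interface: the blood-pool surfaces
are shrunk 1.5 mm inside the endocardia so collocation points never fall on
the source layer. Electrodes are snapped to torso mesh vertices, making
electrode potentials rows of the interface solution.

Verification anchors (all in the test suite): solid-angle closure to 1e-9;
a uniform closed layer is invisible externally and produces the full −M/σ
step inside the wall; a small central cap in a homogeneous sphere matches
the analytic dipole-in-sphere surface potential to well under 2%; the
homogeneous-far-boundary limit reproduces the unbounded-medium kernel to 1%.

## Activation

Fastest-route activation: multi-source Dijkstra (via a virtual source node)
on the graph of mesh edges, with traversal time = length / velocity.
Defaults: 0.85 m/s along the surface; transmural edges pair each endocardial
vertex with its nearest epicardial vertex and run 2.5× slower. Normal
activation starts at seven endocardial foci (four LV: septal, anterior,
posterior, apex; three RV: septal, apex, inferior), all at onset 0 ms —
the septal-dominant pattern of early human ventricular activation, chosen
so the free walls activate by spread rather than direct breakthrough.
The earliest focus defines the QRS time origin. The graph metric uses mesh
edges only (no geodesic refinement); shortest-path tie-breaking cannot
affect δ values.

## The patch

A diseased region is a closed surface component embedded mid-wall. Nodes of
the host surface within `radius` of the centre are displaced along the
inward normal by a cosine taper (`depth` at the centre, 0 at the rim — a
smooth rim-continuous profile that avoids degenerate triangles). The patch
surface consists of the winding-flipped copies of all changed triangles
(inner face, coinciding bit-for-bit with the dent) and the original copies
(outer face), glued along the undisplaced rim vertices; no stitching strip
is needed and the outer shape of the model is preserved vertex-for-vertex.

**Distance-matrix reuse.** Ventricular activation is always computed on the
unpatched geometry and transferred to the dented model through the shared
vertex indexing — the dent is a modelling artifice, not a shortened
conduction path (physically: anisotropy under a diseased region increases,
so no speed-up is expected there). The same principle governs the patch
graph: its edges carry the *original* (undented) lengths.

**Patch activation.** Nodes of the connection set inherit the ventricular δ
exactly; remaining patch nodes get fastest-route times from the connected
set at the patch velocity. Connection types: the full inner face
(continuous substrate), the rim only (type-1 isolating layer), or the
latest-activating quarter of the rim (type 2; pointwise by δ, not a
contiguous arc). Through-thickness edges between opposing inner/outer
nodes carry only the *excess* crossing time `w·(1/v_patch − 1/v_normal)`,
where w is the local dent depth. The inherited inner-face time already
includes traversal of that tissue at normal speed (it is the unpatched
arrival time at the original outer position), so only the slow-down excess
is added. Consequence: at the normal velocity with full connection the
patch metric degenerates to the unpatched metric and the patched model
reproduces the unpatched body-surface potentials to machine precision —
the built-in equivalence check of the construction — while slower patch
velocities yield genuinely delayed outer-face activation. A config switch
(`thickness_mode`) offers the pure-surface (`"none"`) and physical
(`w/v_patch`, `"physical"`) variants.

Dyssynchronous activation adds independent per-node offsets, uniform on
[0, jitter_max] ms (the stated ranges are hard bounds; a truncated-normal
switch exists), to non-connected nodes of the delayed base map at 0.45 m/s,
from a seeded generator. Strength scaling multiplies the patch's layer
strength by the fraction of electrically active tissue (f = 0.5 → 4 mA/m);
potentials superpose linearly over components.

## Electrograms and leads

Unipolar electrograms are simulated at points offset 0.5 mm from the
surface nodes (the potential jumps across the layer itself); the offset
side is configurable — inward for interior potentials, outward for the
electro-anatomical-mapping analogue where a catheter touches the surface.
Bipolar electrograms subtract direct mesh neighbours (the synthetic
analogue of ~5 mm electrode spacing); the per-node bipolar voltage is the
maximum absolute neighbour difference over time. LAT annotation: the
prescribed δ ("simulated" mode), the instant of maximal absolute bipolar
amplitude ("electrogram"), or the maximal unipolar downslope (equivalent
variant). A deflection-count fractionation index is exposed as a
descriptive metric only. The 12-lead ECG derives from labelled members of
the 64-electrode grid (Einthoven/Goldberger/Wilson; WCT = mean of RA, LA,
LL).

One caveat found while validating the low-voltage behaviour: with the
electrode *inside* the slab of a fully silenced patch, the recorded bipolar
voltage can exceed the healthy surroundings, because the electrode then
sits in the undamped near field of the bare dented wall and rim-adjacent
channels mix inside/outside-the-layer steps of ~M/σ. With the catheter-side
(outward) placement the expected behaviour holds: bipolar voltage over the
diseased region is lower than the surroundings and decreases with the
active-tissue fraction.

## Synthetic anatomy

Nested ellipsoids approximate an adult thorax: torso 160×110×300 mm
semi-axes; two lungs; a biventricular wall (epicardial shell 45×40×60 mm,
LV cavity on the patient's left, thinner-walled RV on the right) with
blood pools; 64 electrodes as an 8×6 anterior + 8×2 posterior grid with a
documented 12-lead subset (V1–V6 on the third anterior row; RA/LA/LL at
grid corners). The seed drives a 0.05 mm symmetry-breaking vertex
perturbation; generation is bit-reproducible per (parameters, seed).
Default resolutions: subdivision-3 icospheres (1280 triangles) for torso
and epicardium, subdivision-2 (320) elsewhere — about 1300 interface nodes,
which a desktop solves densely in seconds. Patch landmarks (RV/LV free
wall, tricuspid region, RVOT) are unit directions from the heart centre
resolved to the nearest epicardial vertex.

What the generator does **not** emulate: real wall-thickness heterogeneity
and trabeculation, fibre-direction anisotropy, His-Purkinje geometry,
atria, repolarization, and patient-specific torso shape. Passing tests
therefore validate the *mechanics* of the method (equivalence, calibration,
superposition, statistics) and qualitative substrate effects, not clinical
waveform morphology; the normal 12-lead patterns are those of a simplified
activation sequence, and only *changes* relative to that reference are
interpreted.

## Simulation study

The study driver sweeps delayed (0.25–0.65 m/s), dyssynchronous
(0.45 m/s + 30–90 ms jitter) and discontinuous (type-1/2) patch activation
over four patch locations against one normal reference, summarizing the
per-simulation QRS-CC. Per-lead Pearson CCs are computed over the QRS
window (first activation − 5 ms to last activation + 5 ms); the summary
QRS-CC of a simulation is the most-affected-lead (minimum) CC, with
all-leads-concatenated CC as a config alternative. QRS duration is taken
from the activation maps (total activation duration), not from BSP
thresholds. Group tests: Mann-Whitney U (two-sided, mid-rank ties) plus
Welch and pooled t variants; normality is reported descriptively.

The default grid documents its own reconstruction of a 153-member design:
4 locations × 3 connection types × (6 delayed velocities + 6 jitter draws)
plus a 9-step strength-scaling series. The acceptance script runs a
reduced sweep (one epicardial free-wall patch, 20 delayed velocities, full
inner connection) sized to finish in seconds on one CPU; the test suite
uses 20 simulations per group for the delayed-vs-dyssynchronous
comparison. All randomness (anatomy perturbation, jitter) derives from the
study seed; reruns are bit-identical.

## Known limitations

- The patch represents sub-epicardial or sub-endocardial disease; a
  transmural scar needs the hole-plus-patch combination, not implemented.
- The excess-time thickness model makes delayed effects conservative for
  thin patches (delays are bounded by the slow-down excess across the
  slab); the `"physical"` mode gives larger delays but sacrifices the
  exact normal-velocity equivalence.
- Electrode snapping to mesh vertices distorts the grid at coarse torso
  resolutions (test fixtures); use subdivision ≥ 3 for layout-sensitive
  work.
- No filtering is applied to simulated potentials.
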