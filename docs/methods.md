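# Methods

This note documents the models behind `cortexstim`, the parameters that
matter, the numerical choices, and what the synthetic morphologies do and
do not capture.

## Coordinate frame and units

Right-handed frame with Z increasing downward from the cortical surface at
Z = 0; the electrode plate lies in the Z = 0 plane.  All geometry is in
micrometres, currents in μA (positive = anodal), resistivities in Ω·cm,
potentials in mV, activating-function values in pA/μm².  Network units are
mV, ms, μF/cm², mS/cm², μA/cm².

## Extracellular field

The plate integral ∬ dx dy / r over the electrode has the exact
antiderivative

    F(u, v) = u ln(v + r) + v ln(u + r) − |Z| atan(uv / (|Z| r)),

evaluated at the four corners, so plate potentials are computed in closed
form rather than by numerical quadrature; adaptive 2D quadrature is kept in
the test suite as an independent oracle (agreement ~1e−13 relative).  The
closed form is what makes Monte-Carlo placement averaging affordable: one
placement of a ~3000-compartment arbor needs ~10⁴ potential evaluations.

The medium is infinite and homogeneous.  A hemi-infinite medium with an
insulating boundary above the plate would scale the field by 2; this is
exposed as `medium_factor` (default 1) rather than hard-coded, because only
relative comparisons across cell types are claimed, not absolute field
magnitudes.  `ρ_e` defaults to 300 Ω·cm and is a configuration parameter;
absolute thresholds inherit whatever uncertainty it carries, which is why
the activating-function threshold is calibrated (below) rather than derived.

## Activating function

For each axonal compartment the local fiber direction is a least-squares
line through path-neighbours up to 10 μm away along the tree (singular
vector of the centred neighbour cloud, sign-aligned with the parent edge).
Reconstruction jitter is amplified twice by a second difference; sampling
the potential along the *smoothed* tangent at the local spacing h,

    f = d/(4 ρ_i) · (Φ(p − h t) − 2 Φ(p) + Φ(p + h t)) / h²,

suppresses it.  Against the analytic second derivative of a monopole field
along a straight fiber the error is < 0.01% at h = 0.5 μm.

Conventions at special points, chosen where the continuum formula is
silent:

* **Terminals** use the first-difference form (Φ(neighbour) − Φ(end)) / h².
  A fiber ending responds to the first spatial derivative of the potential;
  dividing by h² (not h) keeps units commensurate with interior values at
  the cost of making terminal values h-dependent.  This normalization is a
  convention, and terminal sensitivity is consequential: endings near the
  electrode are the most easily driven structures in the model.
* **Branch points** evaluate the first-difference term along every incident
  edge and keep the maximum depolarizing value.
* Only f > 0 (depolarizing) is compared with the threshold; the
  hyperpolarized side cannot initiate spikes.
* Diameters are 2 × reconstruction radius clamped to [1, 10] μm; synthetic
  fixtures use d = 2 μm.

Compartment spacing defaults to 1 μm for analysis (equal to the node
length k, making trigger-length discretization exact); synthetic arbors are
generated at 5 μm and resampled.  Halving the spacing changes trigger
lengths of smooth fixtures by < 5%.

## Trigger area and spike probability

Supra-threshold compartments contribute the length of their parent edge;
the total is the trigger length L.  Myelinated axons fire when the trigger
area contains a node of Ranvier: with node length k = 1 μm and internodal
distance D = 100 μm, each k-segment is a node with probability k/D
independently, so p = 1 − ((D−k)/D)^(L/k).  The exponent N = L/k is left
real-valued — the closed form is continuous in L and agrees with a
Bernoulli-segment simulation to Monte-Carlo accuracy.  Unmyelinated axons
expose their whole membrane: any L > 0 fires, at a 20-fold higher threshold
(lower sodium-channel density).  This binary rule makes unmyelinated types
(Martinotti-like arbors especially, with their many near-surface terminals)
saturate at low currents — a genuine model property, not an artifact.

## Threshold calibration

The threshold current I(d) for driving the activating function at the axon
initial segment (the proximal 30 μm of axon; its extent is our choice) to a
target f is f / f_unit(d) by linearity.  Two electrode placements probe two
different signatures:

* **Axial** (default, electrode above the soma on the initial-segment
  axis, as a penetration track would be): the proximal fiber *end* responds
  to the first derivative of the monopole potential, which scales as 1/d²,
  so I(d) grows quadratically (log–log slope 2.00 on the default fixture)
  and only cathodal current depolarizes the end (anodal thresholds are
  ~50× higher, carried by interior nodes at 1/d³).
* **Soma-level** (horizontal offset): the anodal activating profile is
  hyperpolarizing everywhere on a vertical initial segment, so thresholds
  exist only for cathodal current; the interior-node scaling gives a cubic
  far field.

The second derivative of a 1/r potential along an interior stretch can
never produce a quadratic current–distance law; the quadratic form is the
fiber-end signature.  This is why the axial geometry is the calibration
default.

Fitting the threshold against a reference curve is a one-parameter linear
least-squares problem with the closed-form solution
f̂ = Σ I_ref G / Σ G², G(d) the pool mean of 1/f_unit.  Self-generated
reference data recover f_th = 3 pA/μm² to machine precision; the package
ships that value as the calibrated default so it runs without external
data (the empirical reference is an input file, not bundled).

## Placement ensembles

For "a type-T cell at planar distance R": rotations about the vertical
axis through the soma are uniform on [0, 2π); soma depth is uniform on
[Z_min, Z_min + c·L_s] with L_s the layer size, c = 0.1 (basket cells 0.4),
and Z_min either the layer top (compact arbors) or the arbor's vertical
reach above the soma (large cells — nothing may protrude above the pial
surface; offending placements are rejected).  Averaging order is fixed:
per-reconstruction probability over its own placements first, then the mean
across reconstructions.  Defaults of 12 rotations × 10 depth shifts put the
standard error of a binary outcome near 0.03; the bundled experiment
pipelines use 8 × 6 to keep end-to-end runs at desk scale.

Current sweeps exploit linearity: f at current I > 0 is I times the +1 μA
profile (|I| times the −1 μA profile for cathodal I), so each placement is
evaluated once per polarity and rescaled over the whole grid.  Placement
geometry (tangents, stencil sample points) is precomputed per morphology
and transformed rigidly per placement (`FStencil`).

A current curve is classified anodal-preferring / weak-preference /
cathodal-preferring by the asymmetry of the areas under its two polarity
branches, with a ±0.25 neutral band.

## Synthetic morphologies

Three archetypes stand in for reconstruction pools (deterministic given a
seed; statistics verified over 20 seeds):

* `vertical_dominant` (pyramidal-like): ascending trunk plus mostly
  vertical side branches; > 50% of cable within 30° of vertical.
* `isotropic_local` (basket-like): wobbly branches in uniformly random
  directions confined to a sphere around the soma; > 90% of cable within
  the confinement radius.
* `horizontal_layer1` (Martinotti-like): ascending trunk to a set height,
  then long horizontal collaterals at that height; > 40% of cable
  horizontal in the top region.

What they reproduce: the orientation and laminar-density contrasts that
drive polarity preference and depth dependence.  What they do not: true
branch statistics, bouton distributions, per-cell diameter taper,
intermittent myelination, and the sheer cable length of real interneuron
axons (tens of millimetres).  Passing tests therefore demonstrate the
mechanics of the method and its qualitative predictions, not quantitative
agreement with any specific reconstruction dataset — absolute probability
levels shift with arbor density, as the basket-cell pool makes obvious.

## Column network

Traub–Miles-style Hodgkin–Huxley kinetics with a high-threshold calcium
current feeding a calcium-gated AHP potassium current (spike-frequency
adaptation) in regular-spiking cells; fast-spiking cells have no
adaptation currents; interneurons have lower leak conductance (more
excitable).  The removable singularities of the rate functions (V = −54,
−52, −27 mV) are evaluated by their limits.  The synaptic gate obeys
ds/dt = α S(V_pre)(1 − s) − β s with S a steep sigmoid at +20 mV; the decay
term is proportional to s, which keeps s in [0, 1] (AMPA decay 2 ms, GABA_A
10 ms).  Key defaults (mS/cm² unless noted): g_Na 100, g_K 80, g_L 0.15
(interneurons 0.08), g_Ca 1, g_AHP 1, τ_Ca 300 ms, V_L −67 mV.  All cells
are silent at rest; RS cells show strictly increasing inter-spike intervals
under constant drive; FS intervals vary by < 2%.

Integration is fixed-step Heun (RK2) at dt = 0.025 ms with additive
√dt-scaled white noise (default amplitude 0); halving dt moves
deterministic spike times by < 0.1 ms.  Spikes are upward 0 mV crossings
deduplicated by a 2 ms hold.

The reduced column has three layers (II/III, IV, V) × (60 excitatory, 20
basket, 10 Martinotti) cells.  Connection weights are total conductance
budgets divided by expected indegree, so behavior is size-robust; the edge
list follows the canonical microcircuit (recurrent excitation within each
layer, layer IV and Va excitatory drive to II/III, basket inhibition within
the layer, Martinotti cross-layer inhibition onto layer IV and II/III).
Two deliberately asymmetric choices, made where the design was open:

* **Basket inhibition is strong and somatic-like** (budget 2.0, connection
  probability 0.5): when most of an excitatory cell's basket partners fire
  in the first millisecond, their GABA arrives before the cell's own
  marginally supra-threshold seeded spike and vetoes it.
* **Martinotti inhibition is weak and distal-like** (budget 0.2): a
  standing brake that cannot silence the column on its own — consistent
  with dendrite-targeting inhibition.

Stimulation is a 0.2 ms current pulse per selected cell (each cell selected
independently with its population's estimated probability).  The pulse
amplitude is calibrated by bisection on an isolated cell until one spike
within 2 ms.  Excitatory cells receive 1.1× the calibrated threshold
(latency ≈ 1.7 ms, vetoable by concurrent inhibition); interneurons receive
2× (latency ≈ 0.5 ms), reflecting the short-latency responsiveness of
highly excitable interneurons.  This latency ordering is what converts
"many baskets seeded" into "excitatory spikes suppressed" at strong
currents, producing the interior maximum of the response curve; at
moderate currents few baskets are seeded, recurrent excitation reverberates
for tens of milliseconds, and the response exceeds the seeded fraction.

Population response is spikes per cell within a 40 ms window; current
sweeps rebuild the wiring per network seed and average three independent
stimulus draws per seed.  Default experiment sizes (5 network seeds × 3
draws × 7 currents, 60 ms simulations) complete in a few minutes on one
core.

## Known limitations

* Single-compartment threshold logic: no axonal conduction block at strong
  currents, no antidromic propagation, no strength–duration (chronaxie)
  dependence — the 200 μs pulse enters only through the calibration data
  the threshold is matched to.
* Absolute probabilities depend on ρ_e, the medium factor and arbor
  density; only relative/qualitative contrasts across cell types and
  polarities are robust.
* The density grid marks a voxel from sample points, not swept cable, so
  very coarse sampling can under-fill voxels.
* Network parameters are a reduced, behaviorally constrained
  parameterization, not a fit to any particular intracellular dataset.
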