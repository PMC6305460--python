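# Methods

This note documents the models implemented in `neuroforward`, their
assumptions, the choices made where the design was open, and what the test
fixtures do and do not emulate.

## Morphology and discretization

A morphology is a rooted tree of *sections* (3D polylines with per-point
diameters); each section is split into `nseg` equal-arc-length *segments*.
Per segment we store start/mid/end points, the frustum lateral surface area
`π (d₀+d₁)/2 · slant` integrated over the polyline pieces it covers, and
the axial resistance of each half (midpoint → start / end) from the exact
linear-taper form `ρ_a l / (π r₀ r₁)` (ρ_a in Ω·cm, geometry in µm,
resistances in MΩ). Because no published convention exists for how
non-cylindrical frusta are area-weighted in compartmental simulators, the
slant-surface form is used throughout; for cylinders it is exact.

Children attach to a parent section at a relative arc position χ ∈ [0, 1]:
χ = 1 joins the parent's end node (series resistance `R_f + R_n` of the
two facing halves), χ = 0 on the root joins the start node, and χ ∈ (0, 1) clamps the
connection node to the potential of the parent segment containing χ — the
voltage drop is then across the child's half-resistance only, and a
straight *virtual* current element from the parent midpoint to the child
start point carries the child's axial current. Multiple children at one
node form a branch point.

Coordinates follow the cortical-depth convention: z vertical, surface at
z = 0, depths negative.

**SWC dialect.** Standard 7 columns, 1-based ids, parents preceding
children. A 1- or 3-point soma is collapsed to a single
spherical-equivalent section: a z-aligned cylinder of length = diameter
centered on the root sample, whose lateral area πd² equals the sphere
surface. Type codes map 1/2/3/4 → soma/axon/dend/apic; unknown codes warn
and map to dend. On write, the soma becomes one spherical sample and each
branch drops its first point when it coincides with an already-written
parent sample; on read, one section is built per unbranched same-type run,
so a section with a mid-run branch point legitimately splits in a
round-trip (geometry is preserved; segment bookkeeping may differ).

**Fixtures.** `make_ball_and_stick` (default 20 µm soma, 400 × 2 µm apical
stick, 8 segments) and `make_stylized_pyramidal` (soma at the origin, 1 mm
apical trunk, bifurcating tuft, an oblique branch at χ = 0.5 — exercising
virtual currents — and two basals; entirely in the xz-plane, spanning
≥ 1 mm vertically). Branch angles carry ±5° of seeded jitter; a fixed seed
reproduces byte-identical SWC.

## Passive cable solver

The compartment system
`C_n dV_n/dt = −g_L,n (V_n − E_L) − [L V]_n − Σ_k g_k(t)(V_n − e_k) + I_stim,n`
uses the axial conductance Laplacian `L` built from the connection nodes:
a node joining members with conductances `g_i` is eliminated analytically
(its potential is the conductance-weighted mean), producing pairwise
couplings `g_i g_j / Σ g`; clamped (χ) nodes couple each child to its
parent segment through the child resistance alone. Integration is
Crank–Nicolson with the synaptic conductances evaluated at the half step
(implicit in V), second-order in dt and unconditionally stable; the
observed convergence order on the RC test is 2.0. Defaults: c_m = 1 µF/cm²,
g_L = 1e-4 S/cm² (τ_m = 10 ms), E_L = V_init = −77 mV, ρ_a = 150 Ω·cm,
dt = 0.0625 ms (16 kHz). Divergence (|V| > 1e3 mV) raises an error naming
dt.

The transmembrane current is **defined** as the net axial current into each
segment's node, `I_m = −L V`. Since `L` is a Laplacian, `Σ_n I_m,n = 0`
holds exactly at every step — the discrete statement that current
monopoles do not exist — rather than approximately as a sum of channel
currents. With a current clamp, the electrode current is implicitly
returned through the cell's membrane, keeping the extracellular source
distribution conservative.

Synapses are deterministic bi-exponential conductances
`g(t) = g_max N (e^{−t/τ_d} − e^{−t/τ_r})`, peak-normalized so the maximum
is `g_max` at `t_peak = τ_r τ_d/(τ_d − τ_r) ln(τ_d/τ_r)`. Probabilistic
release and short-term plasticity are deliberately out of scope; only the
deterministic kernels with AMPA-like (0.2/1.7 ms, 0 mV) and GABA_A-like
(0.2/8.3 ms, −80 mV) defaults are provided. Spike detection reports upward
crossings of θ_AP = −10 mV separated by a refractory interval (2 ms
default in the network).

## Axial currents

`axial_currents` walks the connection nodes: boundary nodes solve the
node potential from Kirchhoff's law `Σ_k (V_k − V_x)/R_k = 0` and emit one
half-path element per member (parent midpoint → node, node → child
midpoint); χ-attachments emit the virtual element (parent midpoint → child
start) plus the within-child half. Positive current flows along the
element vector `d_m` (upstream node → downstream midpoint), so each
element's dipole is `I_m d_m` with no extra signs, and the summed axial
dipole equals the transmembrane dipole `Σ r_n I_n` identically (machine
precision; the tests bound it at 1e-9 nAm). If a child's start point does
not coincide geometrically with its node, a gap element is emitted so the
identity holds for arbitrary (even inconsistent) geometry.

## Extracellular kernels

All kernels are linear maps in mV per nA (geometry µm, σ in S/m). Potential
singularities are prevented by clamping the source–contact distance (point
sources) or the perpendicular distance (line sources) to the segment
radius. Kernels and their validation oracles:

- **point / line / soma-as-point** in a homogeneous medium; the line form
  is the closed-form integral of the point kernel along the segment axis
  (implemented with `asinh` for numerical robustness) and is verified
  against adaptive quadrature; soma-as-point uses the point kernel for the
  soma row and line kernels elsewhere.
- **disc averaging**: each contact's row becomes the mean over `m` points
  drawn uniformly in area on the disc of radius `r_contact` oriented by
  the contact normal; seeded, the seed recorded in the kernel metadata.
  Defaults m = 50 for depth probes, m = 500 for wide ECoG discs.
- **anisotropic**: `φ = I / 4π√(σ_yσ_zΔx² + σ_xσ_zΔy² + σ_xσ_yΔz²)`;
  note the potential along the high-conductivity axis is *larger* (only
  the transverse conductivities enter there). Line sources use 64-point
  Gauss–Legendre quadrature of the point kernel (no closed form).
- **method of images, two-layer** (cortical surface at z = h): direct term
  plus one image weighted by `W_TS = (σ_T − σ_S)/(σ_T + σ_S)`; an
  insulating surface doubles the surface potential, a perfectly conducting
  one nulls it.
- **method of images, three-layer** (MEA chip below z = 0, tissue slab,
  saline above z = h): the doubly-mirrored image expansion derived from
  repeated reflection in the two planes — one image family at `z′ + 2nh`
  with weight `(W_TS W_TG)^{|n|}` and one at `−z′ + 2nh` with weights
  `W_TS^n W_TG^{n−1}` (n ≥ 1) / `W_TS^{|n|} W_TG^{|n|+1}` (n ≤ 0) —
  truncated at `n_images` reflections each way (default 20; convergence is
  geometric in `|W_TS W_TG|`). Validated by its reductions: all-equal →
  homogeneous, σ_S = σ_T → single lower boundary, σ_G = σ_T → the
  two-layer surface model. Line sources are permitted only in the special
  case σ_G = 0 with contacts at z = 0 (mirrored segments); sources must
  lie inside the slab.
- **one-sphere**: a monopole inside a sphere (σ_in) embedded in σ_out;
  Legendre series with boundary coefficients
  `c_n = (n+1)(σ_in−σ_out)(r_s/R)^n / (R(nσ_in+(n+1)σ_out))`, truncated at
  100 terms, everything expressed in radius ratios for overflow-free
  evaluation. Continuity across the surface and the homogeneous and
  large-R limits are tested.

Unsupported combinations (anisotropic layered media, frequency-dependent
conductivity, meshed geometries) raise errors rather than approximate.

## Current dipole moments

`p(t) = Σ_n r_n I_n(t)` as a matrix product (µm · nA → 1e-6 nAm); a
monopole residue above 1e-6 nA triggers a warning because `p` then depends
on the origin. Per-element dipoles `p_m = I_m d_m` support the multi-dipole
ECoG path and near-field magnetics. Population dipoles are elementwise
sums on a common time axis; for head models, population dipoles are placed
on the vertical axis at `r_1 + z̄_soma` (mm) and single-cell dipoles at the
cell's area-weighted center ("center of areas").

## Head models (EEG/ECoG)

Infinite medium: `φ_p = p·R / 4πσR³`. The four-sphere model (defaults:
radii 79/80/85/90 mm; conductivities 0.3/1.5/0.015/0.3 S/m; air outside)
solves, per harmonic order n, the radial two-point boundary-value problem:
shell potentials `A_s (r/r_s)^n + B_s (r_{s−1}/r)^{n+1}` with continuity of
φ and of σ∂φ/∂r at the three interfaces and zero radial current at the
scalp — a batched 7×7 linear solve per order, all basis functions bounded
by 1 so the system is well conditioned to high n. The free-space source
expansions are `(p/4πσ₁) Σ n r_z^{n−1} r^{−(n+1)} P_n` (radial) and
`−(p_t/4πσ₁) Σ r_z^{n−1} r^{−(n+1)} P_n^1 cos φ` (tangential, scipy's
Condon–Shortley sign convention); radial and tangential components share
the same shell coefficients up to the factor n. An arbitrary dipole is
decomposed about its own radial axis; the degenerate on-center location is
rejected (radial axis undefined). Default truncation n_max = 300 — for a
dipole at 78 mm observed at the 90 mm scalp the neglected tail is
~(78/90)³⁰⁰ ≈ 1e-19; near-interface (ECoG) use warrants raising n_max.
Correctness rests on the oracles the series must pass: the infinite-medium
limit (equal σ, distant outer shell, < 1%), interface continuity, and
azimuthal symmetry for radial dipoles.

Multi-dipole ECoG sums the four-sphere potential over one dipole per axial
current: each element is small enough for the dipole approximation even
micrometres from the contact, where the whole-cell dipole is not.

`SurfaceGrid` carries measurement points with local orthonormal
`(r̂, θ̂, φ̂)` triads; the 9-site arc layout spans polar angles ±π/4 in
steps of π/16 in the xz-plane (adjacent-site arc separation
r₄π/16 ≈ 18 mm) with φ̂ = +ŷ everywhere, including the apex.

## Magnetic fields (MEG)

Far field: `B_p = μ₀/4π · p×R/R³` (magnetization in tissue is negligible,
μ = μ₀; internally the field is assembled as H and multiplied by μ).
Near field: `B = μ₀/4π Σ_m I_m d_m × (r − r_m)/|r − r_m|³`, neglecting
extracellular volume currents. Output in tesla; gradiometer modeling and
spherical-conductor volume-current corrections are out of scope. The tests
pin the textbook symmetries: a radial dipole yields a purely azimuthal
field vanishing above the dipole and mirror-symmetric about the apex; a
tangential dipole yields the butterfly pattern — θ̂-component maximal at
the apex, radial component antisymmetric about it; flux through a closed
surface vanishes.

## Network wiring and simulation

Populations place somata uniformly in area within a 210 µm radius and draw
depths from N(z̄, σ_z̄), redrawing any placement whose morphology would
protrude above z = 0 or below the bottom boundary (−2082 µm default; an
error after 1e4 consecutive rejections flags an infeasible window); each
cell gets a uniform rotation about its vertical axis. Connectivity is
independent Bernoulli(C_YX) without autapses; the expected connection
count obeys `K = ln(1−C)/ln(1 − 1/(N_X N_Y))` with its exact inverse.
Multapse counts, delays and conductances come from capped normal
distributions — the cap is a support restriction implemented by redraw
(≤ 1000 sweeps, then an error), not clipping — with hard floors
δ_min = 0.3 ms and g_min = 0 nS, multapse counts rounded to integers.

Synapse placement weights each target segment by membrane area times a
layer mixture: the normal density centered at each layer's mid-depth with
SD = layer thickness / 2, weighted by the layer specificity
`L_YX^L = Δs_X^L Δs_Y^L / Σ_L Δs_X^L Δs_Y^L` (normalized product of
presynaptic axon and postsynaptic dendrite+soma cable length per layer).
The specificity notation leaves the density's center ambiguous; centering
on the layer mid-depth is this package's documented reading. Extrinsic
drive places n_ext synapses area-proportionally on dendritic/apical
compartments, each firing as an independent Poisson process at ν_ext.

`run_network` advances all cells of a population in one batched
Crank–Nicolson solve per step; bi-exponential conductances are tracked by
per-kernel rise/decay state pairs updated by exact exponential decay, so an
event is a pair of state increments. Somatic upward crossings of −10 mV
(2 ms refractory) schedule conductance events on all the cell's targets
after the drawn delay (an error if a delay is below dt, since the event
could not be resolved); events are bucketed per time step and applied in
deterministic order, so identical seeds reproduce identical rasters and
signals bit for bit. Extracellular potentials (probe kernel matrix ×
instantaneous `I_m = −L V`) and per-population dipole moments are
accumulated every step — nothing per-compartment is stored, the
3/(N·nseg) memory reduction of keeping `p` instead of `I_m`. Execution is
serial by design; seed-reproducibility does not depend on scheduling.

**What the demo network emulates, and what it does not.** The
two-population demo (excitatory + inhibitory ball-and-stick cells at a
1:5 size ratio, reference sizes 2400/480 scaled down ×10 by default,
×20 in the acceptance script for speed) exercises the full wiring and
event machinery with AMPA/GABA_A-like kernels. Because the cells are
passive (no spike-generating conductances — active channels are outside
this package's scope), reaching the −10 mV detection threshold requires
much stronger extrinsic drive (150 synapses at 120 Hz, ~1 nS each) than a
cortical neuron with active membranes would need; spike *rates* and LFP
amplitudes are therefore illustrative, while the connectivity statistics,
causality (postsynaptic events ≥ δ_min after presynaptic spikes), signal
decomposition and determinism claims are quantitative. Passing tests show
the wiring distributions and forward maps are correct; they do not certify
biological realism of the demo's activity regime.

## Numerical conventions and edge cases

- Units: µm (geometry), Ω·cm (ρ_a), MΩ, mV, nA, ms, µS/nS/nF internally;
  S/m for conductivities; mm and nAm inside head/field models; outputs mV
  (LFP), µV (EEG), T (MEG).
- Kernel singularities clamp to the segment radius; zero-length segments,
  zero normals, sources outside their model's validity domain, and
  mismatched shapes raise errors.
- Far-field consistency between full kernels and dipole approximations is
  asserted in RMS amplitude over a 750 µm circle (5%) and pointwise at
  3 mm (5%): the pointwise residue at 750 µm is the genuine quadrupole
  term, of order (source extent)/R, i.e. tens of percent for cells
  comparable in size to the radius — for the 1.4 mm pyramidal fixture the
  750 µm circle lies inside the cell's own extent, where no multipole
  truncation can converge.
- Probe continuity checks on layered/spherical models use offsets small
  enough (1e-9·r for shells, 1e-6·R for the sphere) that the smooth radial
  variation of the potential over the probe step does not mask the
  discontinuity being tested.
- Test and acceptance problem sizes (fixture cells with ≲ 40 segments,
  10⁵-draw statistics, a 120 + 24 cell network for 150 ms) are chosen so
  the whole suite runs in seconds on one core while every statistical
  tolerance retains ≥ 4σ headroom.
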