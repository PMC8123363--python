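# Methods

## Dielectric models

A lossy phase is described by its conductivity σ (S/m) and relative
permittivity ε_r; its complex permittivity at angular frequency ω = 2πf is
ε* = ε₀ε_r − jσ/ω with ε₀ = 8.8541878128 × 10⁻¹² F/m.  The Clausius–
Mossotti factor f_CM = (ε*_p − ε*_m)/(ε*_p + 2ε*_m) is evaluated directly
in complex arithmetic; its real part is bounded by [−1/2, 1] and its
imaginary part by ±3/4 for any passive sphere, bounds the spectrum
container enforces as invariants.

**Beads.**  Polystyrene spheres conduct almost entirely along their
surface; the effective conductivity is σ_p = σ_bulk + 2K_s/r with
σ_bulk = 10⁻¹⁶ S/m and surface conductance K_s = 2 × 10⁻⁹ S.  K_s is
treated as a conductance (siemens) so that 2K_s/r has units of S/m; this
reproduces the conventional 2.5 × 10⁻³ S/m (3.2 µm) and 1.667 × 10⁻³ S/m
(4.8 µm, usually quoted truncated as 1.6 × 10⁻³) values.  Because quoted
crossover and tracing frequencies for the 4.8 µm bead trace back to the
truncated conductivity, the fixtures expose both routes: `ps_4p8um`
(surface-conductance form, crossover ≈286 kHz) and `ps_4p8um_printed`
(σ_p = 1.6 × 10⁻³ S/m as a bulk value, crossover ≈275 kHz).  Comparisons
against the reference values use the printed variant.

**Cells.**  Keratinocytes and fibroblasts are modelled as single-shell
spheres: a cytoplasm core (keratinocyte: σ = 0.12 S/m, ε_r = 50;
fibroblast: σ = 0.75 S/m, ε_r = 75) coated by a thin membrane
(keratinocyte: σ = 10⁻⁶ S/m, ε_r = 9.04; fibroblast: σ = 4.7 × 10⁻³ S/m,
ε_r = 53).  Measured cell dimensions are triplets (5.97, 5.97, 11.95) and
(70, 70, 7) µm; the model uses the volume-equivalent radius
r_eq = (abc)^{1/3}/2 (3.76 and 16.2 µm).  The two layers reduce to one
equivalent permittivity by the confocal formula
ε*_eq = ε*_mem (γ³ + 2K)/(γ³ − K), K = (ε*_cyt − ε*_mem)/(ε*_cyt + 2ε*_mem),
γ = r/(r − d).  Membrane thickness d is not directly measurable here and
defaults to 7 nm (standard lipid bilayer); the high-frequency crossover is
insensitive to d across 4–10 nm (property-tested), because at tens of MHz
the membrane is capacitively transparent and the crossover is set by the
cytoplasm–medium contrast.  Ellipsoidal (depolarisation-factor) and
multi-shell models are out of scope.

**Crossover finding.**  Re[f_CM](f) is scanned on a log-spaced grid
(default 400 points); every sign change is bracketed and refined by
bisection to relative tolerance 10⁻⁶.  An analytic oracle for homogeneous
spheres — ω² = −(σ_p−σ_m)(σ_p+2σ_m)/((ε_p−ε_m)(ε_p+2ε_m)) — provides an
independent check; the root finder agrees with it to 0.1% over 1,000
random parameter draws.  Regime labels use a static band
|Re[f_CM]| ≤ 0.01 for "crossover"; the band is a labelling convention, not
a physical constant.

## Field solve

The chamber is a 280 × 80 µm rectangle with two tapered electrodes
(base 100 µm, height 4 µm, 75° sidewalls, 80 µm gap) on its floor; the
taper annotation of 15° is the complement of the sidewall angle and is not
an independent parameter.  Electrodes sit flush against the side walls,
with the outer faces on the domain boundary; only the inner sidewall is
tapered.  The fluid is a single homogeneous phase, so the electro-
quasistatic potential obeys the real Laplace equation with Dirichlet
values on the whole electrode boundary and zero normal derivative on every
other wall — one real solve serves all drive frequencies, which enter only
through Re[f_CM].

Discretisation: uniform grid (default 0.5 µm → 561 × 161 nodes), 5-point
Laplacian with mirror ghost nodes for the Neumann walls, direct sparse
factorisation; the discrete residual must be below 10⁻⁸ of the drive
scale.  The discrete maximum principle, the parallel-plate closed form
(two full-height plates: |E| = ΔV/gap within 1%), polarity antisymmetry
and <1% change under grid halving are all regression-tested.  The drive
±10 V is interpreted as phasor amplitude, so |E_rms|² = |E|²/2 enters the
force; field and ∇|E_rms|² are centred differences of the nodal potential,
zeroed inside the electrodes, and sampled bilinearly between nodes.

## Particle tracing

The quiescent chamber (no inlet, zero pressure head, no-slip walls) has
the unique flow solution u ≡ 0; the fluid velocity field is therefore a
constant zero by default and overridable.  With Stokes drag 6πµr and
particle response time τ_p = ρ_p(2r)²/(18µ) ≈ 0.6 µs for a 3.2 µm bead,
inertia is negligible over 20 s runs: the default integrator is the
overdamped limit v = u + F_DEP/(6πµr).  An inertial mode advances the
linear drag equation exactly over each step (exponential integrator) and
agrees with the overdamped mode to <1 µm in final position — a consistency
check, not a different physical regime.  Defaults: viscosity
8.9 × 10⁻⁴ Pa·s, water density 997 kg/m³, polystyrene 1050 kg/m³, cells
1100 kg/m³.

Releases come from grids specified as (start, step, stop) µm triplets per
axis (left grid x ∈ {30, 75, 120}, right grid x ∈ {150, 195, 240}, both
y ∈ {30, 60}), released at rest at t = 0.  The step size adapts so no step
moves a particle more than half a grid cell, capped at 10 ms; a step that
would still jump more than two cells is halved, and step underflow below
1 ps aborts with an error.  Walls and electrodes freeze particles
permanently at first contact (contact point located by bisecting the
offending step).  One extension beyond plain freeze-on-contact is needed:
∇|E_rms|² diverges at the electrode corners, and a displacement-capped
integrator approaching this attractor enters a limit cycle that straddles
the corner without touching the solid, shrinking dt to microseconds.  When
an entire 64-step window is velocity-limited yet the net window
displacement is below 0.05 grid cells, the particle is declared trapped
and frozen at the attractor — physically the corner capture the cycle is
orbiting.

Classification of a finished trajectory: net displacement below 2 µm is
"crossover" (static); otherwise ending within 3 µm of a tapered inner
corner — the high-field spots — or having approached them is positive DEP,
and retreating from them into the low-field region is negative DEP.  The
two thresholds are implementation constants.  Simulated instantaneous
velocities are reported but their magnitudes are not validated against any
external reference; they depend on mesh details near the corner
singularity.

## Track kinematics

Track summaries reduce a per-frame coordinate series to one signed speed,
one acceleration and one coordinate position per cell.  Since reported
speeds can be negative, speed is the mean finite-difference velocity of
the positions projected on the track's principal displacement axis (the
leading PCA direction of the coordinates), with the axis oriented
canonically toward +x so the sign reflects the direction of travel rather
than always being positive; acceleration is the mean second difference of
the same projection, and coordinate position is the mean x coordinate (the
quantity is a single scalar per cell and this is the convention adopted).
A linearity flag (>95% of positional variance along the principal axis)
records when the 1D projection captures essentially all of the motion.
Time-reversal negates the speed; rigid translations shift only the
coordinate position.

## Synthetic data

Experimental inputs are emulated, not read from instruments.  Bead
mixtures are uniform draws over the fluid region (rejection sampling
against the electrode polygons) with equal treatment of the two sizes — a
1:1 mixed suspension.  Cell tracks follow a constant-velocity model at
video rate (1/30 s frame interval) with isotropic Gaussian position noise
(default 0.5 µm, a typical centroid-tracking jitter).  All randomness
derives from one explicit `numpy.random.default_rng` seed.  What passing
tests show: the summariser recovers known velocities within the analytic
standard error √2·σ/T (T the track duration) across 20 seeds.  What they
do not show: real cell tracks are not constant-velocity, noise is not
isotropic Gaussian, and tracking software may report per-frame extremes
rather than means — so agreement on synthetic tracks validates the
computation, not the biology.

## Problem sizes

The shipped analyses use the 0.5 µm grid (561 × 161 nodes, direct solve
≈2 s), 12 released particles per frequency and 20 s of simulated time
(≈1 s per frequency), and 400-point frequency grids; these sizes resolve
the electrode gap and the crossover structure while keeping every analysis
step interactive.
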