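# Methods

This note records the models behind `puckerpath`, the choices that were
genuinely open, and what the synthetic fixtures do and do not emulate.

## Cremer–Pople coordinates and the conformer table

A six-membered ring in the order O5 → C1 → C2 → C3 → C4 → C5 (O5 is
atom 1) is reduced to (Q, θ, φ): positions are centred, the mean plane
is fixed by the two Fourier sums R′ = Σ rⱼ sin(2πj/6) and
R″ = Σ rⱼ cos(2πj/6), and the out-of-plane displacements zⱼ = rⱼ·n̂ are
decomposed into the m = 2 mode (q₂, φ₂) and the alternating m = 3 mode
(q₃).  Then Q² = q₂² + q₃², tan θ = q₂/q₃ and φ = φ₂.  With this origin
convention ⁴C₁ is the north pole (θ = 0°) and ¹C₄ the south pole.
Angles are degrees at the API surface; radians appear only internally
and as metadynamics CVs.

Rings with Q below 0.05 Å are treated as planar: θ and φ are then
noise-dominated, and the accessors raise rather than return garbage.

The 38 canonical conformers are not hand-typed.  Each class has an
ideal displacement pattern — alternating signs for chairs, a para pair
for boats, the pure-q₂ phases at odd multiples of 30° for skew-boats, a
single displaced atom for envelopes, an adjacent up/down pair for
half-chairs — and pushing those patterns through the same Fourier
analysis yields the canonical (θ, φ) grid with class latitudes
0 / 50.77 / 54.74 / 90 / 125.26 / 129.23 / 180°.  The packaged TSV is
written from this generator and a test asserts file == generator.
Classification is nearest-neighbour by great-circle distance on the
(θ, φ) sphere, ties broken by table order.  A known caveat: φ
conventions differ between Cremer–Pople variants by a phase; this
package uses the convention above consistently, and its anchor is that
the eight conformers compatible with a planar C3–C4–C5–O5 fragment
(³,ᴼB, E₁, ²H₁, ²E, B₃,ᴼ, ¹E, ¹H₂, E₂) all fall within 3° of the PL
path θ = 90 + 39·cos(φ − 270°), which they do.

The inverse construction (`geometry_from_cp`) assigns the exact zⱼ
pattern of the target (Q, θ, φ) over a planar hexagon placed clockwise
(so the mean-plane normal is +ẑ) and then relaxes the six in-plane
polar radii toward ideal bond lengths (C–C 1.52 Å, C–O 1.43 Å) by least
squares.  Because the radii never enter the mean-plane definition, the
puckering coordinates of the result are exact by construction, not just
converged.

## Sampling engine

The sampler propagates a fictitious particle directly in CV space —
a surrogate for forces we deliberately do not compute.  Units:
kcal/mol, Å (or rad), ps; k_B = 0.0019872041 kcal/(mol·K); default
temperature 300 K.  The integrator is BAOAB with friction 1 ps⁻¹,
fictitious mass 1 (kcal/mol)·ps²/unit², and dt = 0.005 ps; dt is stable
for every packaged landscape (curvatures ≲ 200 kcal/mol/unit²) and is
exposed, not hidden.  The hill/time bookkeeping n_hills × stride × dt
is logged for every run because published hill counts and simulation
times only reconcile for a stated dt.

Well-tempered metadynamics: one Gaussian per `stride` steps with
heights h₀·exp(−V_bias/ΔT).  The well-tempered parameter ΔT carries
energy units (kcal/mol) — the conformational runs use 15, the reaction
runs 30 — and the dimensionless bias factor γ = 1 + ΔT/(k_B T) is
reported alongside.  Hill evaluation is an exact vectorised sum over
the history (no grids or splines); at ≤10⁴ hills that costs
microseconds per step.  The FES estimate is
F(s) = −(k_B T + ΔT)/ΔT·V_bias(s), anchored to min 0; with
`average_from` the estimate is averaged over the last fraction of hill
depositions, which collapses to a single weighted hill sum and damps
the hill-granularity ripple by roughly a factor of three.

## Umbrella sampling and WHAM

Windows restrain CV1 with ½k(s − c)².  The published protocol fixes
the nine centers (−0.75 → 1.25 Å, step 0.25 Å) but not the force
constant; the default follows the standard design rule
k = k_B T/(spacing/2)² ≈ 38 kcal/mol/Å², which puts the restrained σ at
half the window spacing and guarantees neighbour overlap.  One third of
each window is discarded as equilibration (the 2.5/7.5 ps pattern).
WHAM is direct self-consistent iteration on the window constants to
1e-8 kcal/mol over 101 bins spanning the sampled range; adjacent-window
histogram overlap below 0.01 aborts with a diagnostic naming the gap.
Error bars beyond a block standard error are out of scope by design
(no MBAR, no autocorrelation analysis).

## Surrogate landscapes

The headline free energies of the real enzyme come from DFT-level
QM/MM sampling and are not recomputable at desk scale.  The package
therefore encodes the *layout* of those surfaces as analytic
landscapes and asks whether its own sampling and analysis machinery
recovers the constructed numbers — a parameter-recovery design.

**Reaction surface** over (CV1, CV2): stationary points MC (−1.0, 1.1)
at 0, TS (0.7, 0.3) at 19, IC (1.8, 1.7) at −1, PC (1.8, 3.4) at −5
kcal/mol, on a 26 kcal/mol plateau with a quadratic confinement bowl.
The MC → TS → IC channel bends sharply, which defeats straight
anisotropic Gaussian valleys: every component's pull at the TS points
into the bend and no stationary balance exists.  The construction
instead exploits the fact that three points are always concyclic: the
channel trough is carved by two Gaussians written in polar coordinates
about the MC/TS/IC circumcircle (Gaussian in radius and in arc angle).
On the circle their radial gradient vanishes identically, so the bend
carries an exact saddle where the two arc dips meet.  Amplitudes, well
centers and the trough radius are then solved from the stationarity
system (four target values, zero gradients) by a bounded least-squares
root solve from a fixed hand-built start; the solve is deterministic
and reaches residuals ~1e-14.  A build-time audit verifies every
declared point: |∇F| < 1e-5, |F − target| < 0.1, Hessian signature
(minima positive definite, TS index 1), and a dense-grid scan that no
nearby cell undercuts a declared minimum.  The IC → PC leg is a
straight valley with a pass near +2 kcal/mol — the reported "flat
region" hosting the intermediate, deep enough for the 0.5 kcal/mol IC
detection rule.

**Conformational surface** over (φ, θ) in radians, φ periodic: the ¹C₄
chair is a line on the Mercator plane, so its basin is a φ-independent
Gaussian band at θ = π, with point wells at ⁵S₁ (π/2, π/2) and ᴼS₂
(11π/6, π/2) at +0.5 and +2.0 kcal/mol.  The plateau is 4.5 kcal/mol —
barriers of a few kcal/mol between basins, consistent with a landscape
a sub-nanosecond metadynamics run can traverse, and deliberately small
so the sampled area stays desk-scale.  A θ wall below 0.85 rad closes
off the featureless northern hemisphere; nothing in the recovered gaps
depends on it.  The band's flat φ direction is exempted from the
curvature audit (its Hessian eigenvalue is 0 up to well tails).

**1D profile for umbrella sampling**: a single broad Gaussian ridge
(σ = 1.0 Å, top near CV1 = 0.8 Å) against a quartic wall at −0.75 Å;
the ridge amplitude is calibrated by a Brent root find so the forward
barrier from the minimum is exactly 17.7 kcal/mol.  The width matters:
the ridge-top curvature (≈ −18 kcal/mol/Å²) stays below the window
force constant, so no window sits on an inverted effective potential —
the same condition a practitioner checks before running umbrella
sampling on a real barrier.

## Free-energy-surface analysis

Minima are found by persistence: cells are merged in order of
increasing F with a union–find, and a basin's depth is the gap between
its minimum and the saddle where it merges into a deeper basin; the
default floor of 0.5 kcal/mol discards sampling dimples.  The MFEP is
the minimax path — the 8-connected grid path minimising the maximum F,
computed by a Dijkstra-type search with the deterministic key
(bottleneck, cumulative F, lexicographic index) — refined by
steepest-descent relaxation from the saddle into both flanking basins,
recursively per segment.  The bottleneck energy is invariant under
monotone transformations of F, which the tests exploit as an oracle
(exhaustive path enumeration on 3×4 grids; exhaustive
threshold-connectivity scans on 5×5).  ΔG‡ = F(TS) − F(start),
ΔG⁰ = F(end) − F(start); interior path basins at least 0.5 kcal/mol
below both flanking maxima are reported as intermediates.  Observables
are averaged around the path in a CV box of ±0.1 Å per dimension by
default; empty boxes are reported as missing, never interpolated.

## Synthetic fixtures: what they do and do not show

The fixtures emulate *structure*, not chemistry: ring geometries have
exact puckering coordinates but idealised bond lengths and no
substituents; pucker trajectories are great-circle interpolations with
Gaussian angular noise; the reaction distance series interpolates the
stage values of the six catalytic distances with monotone cubics and
σ = 0.01 Å noise, with CV columns computed from the distance columns
so internal consistency is exact.  Passing tests therefore demonstrate
that the analysis pipeline is correct and that the sampling engine
recovers constructed free-energy layouts under the published hill
schedules — they do not validate any electronic-structure claim, nor
the real enzyme's energetics.

## Problem sizes and numerical choices

Reaction recovery uses 2500 hills per seed, three seeds, means over
seeds (each run is ~250k Langevin steps); conformational recovery uses
4000 hills per seed, three seeds; umbrella sampling uses 22500 steps
per window.  These sizes put single-seed scatter at roughly ±1 kcal/mol
on a 19 kcal/mol barrier and ±0.4 on sub-kcal/mol gaps, which the
seed-averaging absorbs.  WHAM uses 101 bins and direct iteration
(typically <1000 iterations).  Grids default to 101×101 (121 for the
periodic pucker surface).  Classification ties and path ties are broken
deterministically (table order; lexicographic index).  All randomness
flows through numpy `default_rng` seeds, and every generator and
sampler is bitwise reproducible per seed.

## Known limitations

* The sampler is a Langevin surrogate in CV space; there is no
  molecular mechanics, no QM, and no multiple-walker support.
* 2D WHAM, MBAR, string/NEB methods in continuous space, and committor
  analysis are out of scope.
* The conformer table covers pyranose (six-membered) rings only.
* The φ convention caveat above applies when comparing against plots
  produced with a different Cremer–Pople phase convention.
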