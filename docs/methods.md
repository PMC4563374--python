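# Methods

## Model and assumptions

`sphereflock` simulates `n` self-propelled point agents constrained to a
sphere of radius `r` in discrete time. The state of agent `i` at step `k` is
a position `p_i(k)` with `|p_i| = r`, a unit heading `d_i(k)` in the tangent
plane at `p_i`, and a speed `v_i(k)`. The update is strictly synchronous:
every quantity at step `k+1` is computed from the complete step-`k` state.

One step consists of kinematics, noise, cooperation, and response:

1. **Kinematics.** Each agent moves along the great circle through `p_i` in
   direction `d_i` by arc length `v_i Δt`, via the closed-form rotation
   `p' = cos(θ) p + sin(θ) r d` with `θ = v_i Δt / r`. The arc-length
   contract — geodesic distance travelled equals `v_i Δt` — holds exactly,
   and the construction cannot leave the sphere for any arc. The equivalent
   tangent-displacement parameterization `l = r tan(θ)` (move `l` along the
   tangent, re-project radially) is exposed as a diagnostic only; the
   rotation form is numerically preferable because it has no pole at
   `θ = π/2`.
2. **Parallel transport.** The heading is carried along the arc as
   `d⁻ = −sin(θ) p/r + cos(θ) d`, the agent's *approaching direction* at the
   new position. Transport preserves `p × d` exactly (to rounding), which
   tests exploit as a conservation oracle. On a sphere this step is not
   optional: the old heading is generally not tangent at the new position.
3. **Noise.** Each agent's approaching direction is rotated within its
   tangent plane by an angle drawn uniformly from `[−η, η]` radians — one
   draw per agent per step, shared by all neighbors observing that agent
   (not per observer pair). The in-plane frame is `x = d⁻`,
   `y = (p/|p|) × d⁻`, making "swing by ϑ" exact: the angle between the
   noised and original direction is `|ϑ|`.
4. **Cooperation (SDA).** `ζ_i` is the arithmetic mean of the noised
   approaching directions over the neighbor set
   `N_i = {j : GCD(p_i, p_j) < r0}` (strict inequality, self included, so
   `|N_i| ≥ 1` and `|ζ_i| ≤ 1`). The rule is pluggable: anything mapping
   (new positions, noised approaching directions) to per-agent vectors with
   `|ζ| ≤ 1` can replace it without touching the stepping code.
5. **Response.** The new heading is the unit component of `ζ_i`
   perpendicular to the new position. When that component is degenerate
   (`|ζ|` below tolerance, or `ζ` radial) the agent keeps its noise-free
   transported heading — this preserves heading continuity, and with
   `α > 0` such an agent has `v ≈ 0` anyway ("hesitation"). The new speed is
   `v0 |ζ_i|^α`; `α = 0` short-circuits to constant speed `v0`. This power
   law is the unique form consistent with both the constant-speed reduction
   and the requirement that unpolarized agents stall.

Initial conditions are uniform-random positions on the sphere, uniform-random
tangent headings, and `v_i(0) = 0` — so the first step moves nobody and the
first alignment averages the initial headings. A constructor option starts
agents at `v0` instead (off by default).

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| `n` | agent count | — | (required) |
| `r` | sphere radius | length | 1 |
| `v0` | maximum speed; `v0 ≪ r` assumed | length/time | 0.02 |
| `r0` | interaction (geodesic) radius | length | 0.4 |
| `eta` | noise half-width | radians | 0 |
| `alpha` | speed-adaptivity exponent | — | 1 |
| `dt` | time interval per step | time | 1 |
| `steps` | iterations | — | 600 |
| `seed` | RNG seed (init + noise) | — | 0 |

Defaults mirror the regime the phenomenology was established in: unit
sphere, `v0 = 0.02` (a step is 2% of the radius), terminal step 600 — order
parameters equilibrate within a few hundred steps while the scale measures
keep shrinking slowly, so step 600 is a stable, affordable read-out point.
Sweeps default to 40 replicates per grid point; the shipped tests and the
acceptance script use 5 replicates with assertions sized accordingly, which
keeps the full suite within minutes on one CPU at an unchanged grid.

## Observables

* `φ = |⟨d_i⟩|` — planar order parameter; on a sphere it approaches 1 only
  if the swarm collapses to a small patch, so it systematically
  under-reports spherical order (kept for comparison).
* `φ_m = |⟨(p_i × d_i)/r⟩|` — each term is a unit angular-momentum vector,
  so `φ_m ∈ [0, 1]`, with 1 exactly when all agents circulate one oriented
  great circle. The normalization by `r` is adopted so that this extreme
  case gives exactly 1.
* `φ_ζ = ⟨|ζ_i|⟩` — mean local polarization. For `α = 1`,
  `φ_ζ(k) = ⟨v_i(k+1)⟩ / v0` holds to rounding (asserted to 1e-12); for
  `α ≠ 1` the two quantities are reported separately.
* Manifold centroid — radial projection of the mean Euclidean position;
  undefined (flagged, not NaN-silent) when the mean position is at the
  center within tolerance. `c` is the mean geodesic distance to it.
* Rotation axis `ω = m/|m|`; the principal plane is its orthogonal plane
  through the center. `e` is the mean Euclidean distance of agents to that
  plane; `e → 0` means convergence onto the principal great circle. `e` and
  `c` standard deviations use the n−1 divisor.
* Local density `ρ_i` — fraction of the swarm within geodesic distance of
  agent `i`; the vicinity radius is not pinned down by the model, so it
  defaults to `r0` and is configurable.

## Numerical choices

* Every dot product fed to `arccos` is clamped to `[−1, 1]`.
* Neighbor search compares Gram-matrix entries against `cos(r0/r)` —
  monotonicity of `arccos` makes this exact, and no `arccos` over n² pairs
  is needed. All-pairs is used throughout: at `n ≤ ~2000` a BLAS matmul
  beats spatial indexing on a sphere.
* Positions are rescaled to radius `r` and headings re-orthogonalized
  against them after every step (toggleable). The raw iteration alone keeps
  drift ≤ 1e-6·r over 10⁶ agent-steps (tested); with renormalization
  constraints hold to 1e-12.
* Tie-break in peak detection: the smaller radius wins on exact ties; a
  peak on the grid boundary (monotone curve) is flagged rather than
  reported silently.
* Sweep seeds derive from `SeedSequence([base_seed, grid_index, replicate])`
  reduced below 2³¹, decoupling grid cells so results are independent of
  execution order; replicates re-randomize both initial conditions and
  noise streams.
* Noise draws are addressed by `(seed, step)` through a fresh generator per
  step, so any step of any run can be replayed exactly.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself (uniform initial states;
uniform tangent-plane noise), which is the model's own study design — there
is no external data. Passing tests therefore demonstrate the mathematical
correctness of the kinematics and the reproducibility of the stochastic
phenomenology under these idealized conditions; they say nothing about real
animal groups, fluids, or vehicles, where agents have volume, inertia,
anisotropic sensing, and non-uniform noise. The flat-limit agreement with
the planar Vicsek-with-adaptive-velocity model (radius 1e4, unit patch,
relative error ≤ 1e-3) ties the spherical implementation to the established
planar baseline but is a consistency check, not a physical validation.

Monotonicity and transition-location assertions run at 5 replicates instead
of 40; replicate means then carry Monte-Carlo noise of order 0.005–0.05, so
adjacent-grid-point comparisons allow a slack of 0.03 (order parameters) /
0.06 (plane-distance scale) alongside strict endpoint-trend assertions. The
noise-degradation check contrasts η = 0.4 rad against zero noise in the
adaptive-speed regime (`α = 2`): the systematic effect of very weak noise
(η = 0.04, a common weak-noise illustration) on `φ_ζ` is ≈ η²/6 ≈ 3e-4,
below replicate resolution at this scale, while η = 0.4 produces an effect
an order of magnitude above it.

## Known limitations

* O(n²) memory and time per step; fine to a few thousand agents, not for
  10⁵.
* No volume exclusion, no inertia, no continuous-time limit, no boundary
  conditions on sub-regions of the sphere.
* Only the direction-alignment rule ships; the rule interface accepts
  others (cohesion, repulsion, leadership) but none are provided.
* `φ_ζ` is meaningful for cohesive swarms; once the swarm fragments it
  stays high regardless of global order, so it must be read together with
  `φ_m`.
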