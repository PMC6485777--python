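# Methods

`planaxis` simulates anterior–posterior (AP) axis control in regenerating
planaria as the interplay of three components: directional ("vector")
transport of morphogens along the net polarity of nerve axons, a
Hill-kinetics regulatory network coupling the transported and diffusible
factors, and a continuous-time Markov chain that converts wound-edge
morphogen levels into the probability that a blastema becomes a head, a
tail, or fails. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Transport model

Each morphogen concentration `C_i(x, t)` (relative "model nM") obeys, on a
closed domain,

    dC_i/dt = R_i(C, G) − ∇·φ_i,
    φ_i = −D_i ∇C_i + α_i u C_i,

where `D_i` is a diffusivity (bounded by `D_max = 1.5e-11 m²/s`), `α_i` a
signed motor-protein convection coefficient (+ kinesin, anterograde;
− dynein, retrograde), and `u(x, y)` the unit-bounded nerve-polarity field.
The body edge and every wound are zero-flux boundaries, so total mass is
conserved when reactions are off (verified to 1e-6 relative over days of
simulated time).

Discretization is finite-volume on either a uniform 1D interval grid or a
Lloyd-relaxed Voronoi mesh clipped to a worm-shaped outline (the reference
body is 1.2 cm long, ~2.5 mm wide, meshed with ~1750 cells). Diffusive face
fluxes use two-point centroid differences (Voronoi face normals align with
centroid connectors); convective fluxes are first-order upwind on the sign
of `α u·n̂`, with the face `u` the arithmetic mean of the two adjacent
cells. Upwinding was chosen for positivity under explicit Euler; its
numerical diffusion (`~vΔx/2`, a few percent of `D` at reference
resolution) is accepted and quantified by the step-halving invariance test.

Time stepping is explicit Euler at half the diffusive stability limit
`Δt < Δx²/(3 D_max)` (`Δx` = minimum centroid spacing). Because convection
can become the binding explicit constraint on coarse meshes (large bodies
at fixed cell count), the integrator additionally caps `Δt` by the exact
per-cell flux bound `1/Σ_faces[(D/d + outflow speed)·A/V]`; at reference
resolution this cap is inactive. Negative concentrations produced by the
explicit update are clipped to zero and counted (clip events are reported
in run logs). Solutions at `Δt` and `Δt/2` agree within 0.5% after 4.5
simulated days.

## Nerve map and production field

The transport field stands in for manually traced axon-polarity maps and is
generated parametrically:

* **1H (one-headed) plan** — an AP-aligned component concentrated in two
  ventral-nerve-cord (VNC) stripes at `y = ±350 µm` (Gaussian half-width
  175 µm) pointing toward the tail, blended with a commissural component in
  the lateral margins pointing outward (±y). The axial magnitude profile is
  a blend of a linear ramp (weight 0.4) and a saturating rise over 0.08·L
  behind the head: transport is weak at the anterior tip and near full
  strength by ~a fifth of the body.
* **2H (two-headed) plan** — the 1H construction mirrored about a midbody
  symmetry line (default 0.5·L); each half points from its head toward the
  line, making the x-component antisymmetric.

The neural production map `G` is the positive part of the discrete
divergence of `u`, normalized to max 1, computed with the same face sums as
the solver, so morphogen is synthesized exactly where the transport
operator sees axons originate. With the ramp+saturation profile, `G` is
largest behind the head and decays toward the tail (≈9:1) — the model's
proxy for the anterior-weighted distribution of nerve somata. This
anterior weighting is load-bearing: it grades the Hh flux arriving at
posterior-facing wounds by fragment position, which is what separates the
two AP outcome trends (below).

What the generator does **not** emulate: true traced anatomy (branching,
asymmetries, brain lobes), axon turnover during regeneration, and any
remodeling of the nerve map after cutting — fragments keep the field they
inherited. Passing tests therefore demonstrate consistency of the
transport-logic predictions, not anatomical fidelity of any specific worm.

## Regulatory network

Nine species; rates are sums of growth channels `r·Π(Hill factors)·[G if
neural]` and decay channels `δ·C·Π(Hill factors)` — a superset of a single
product form, needed twice (see below). Hill activators are
`(C/K)ⁿ/(1+(C/K)ⁿ)`, inhibitors `1/(1+(C/K)ⁿ)`.

* **Hh** — neural production (`×G`), kinesin transport (α = +4e-7 m/s at
  unit field), plain decay (τ ≈ 9 h). Accumulates in a spike at every
  posterior-facing wound; spike height scales with the fragment's total
  neural production.
* **Wnt** — two growth channels: a basal channel repressed by *active* Ptc,
  where Ptc's effective level is itself Hill-inhibited by Hh (the gate
  opens where Hh spikes), and an Hh-activated channel; decay has a basal
  term plus a Notum-activated term (Notum clears Wnt at the anterior).
  The basal channel is essential: it is the Wnt pool whose de-repression
  under Notum loss abolishes heads.
* **βCat** — constitutive synthesis (fast, 8e-3 nM/s); three decay
  channels: slow basal turnover, an APC-dependent destruction-complex
  channel Hill-inhibited by Wnt *and* by cAMP (steep, n = 4 on cAMP), and a
  second APC-dependent channel inhibited by Wnt only. The cAMP-independent
  channel is what keeps βCat at an intermediate (head-blocking but not
  tail-inducing) level when cAMP is raised, yielding the observed headless
  rather than two-tailed outcome. βCat runs on a hundreds-of-nM scale to
  meet the tail sigmoid midpoint (300 nM).
* **ERK** — constitutive synthesis sharply Hill-inhibited by βCat
  (K = 25 nM, n = 4); O(1 nM) scale against the head sigmoid midpoint
  (0.75 nM). ERK is purely a βCat reporter, per the network logic that
  βCat is ultimately what inhibits ERK signaling.
* **NRF** — βCat-induced, neural, dynein-transported (α = −4e-7 m/s);
  accumulates at anterior-facing wounds.
* **Notum** — induced by NRF, hence anterior-localized; this is the chain
  that lets a fresh anterior wound clear Wnt, de-protect βCat, de-repress
  ERK and commit to head — and it reproduces the Notum paradox: Notum
  tracks βCat (via NRF), so two-headed βCat-knockdown worms have *low*
  Notum while headless APC-knockdown worms have *high* Notum.
* **cAMP** — uniform second messenger, steady state 1.0 (the only nonzero
  initial condition); pharmacology acts as growth multipliers (×0.25 down,
  ×5 up).
* **Ptc, APC** — constitutive unit-level species; their knockdowns act by
  removing the Wnt gate and the destruction scaffold respectively.

All other initial conditions are zero; the homeostatic gradient
self-assembles during a 4.5-day initialization (anterior: ERK ≈ 1.4 nM,
βCat ≈ 13 nM; posterior: βCat ≈ 500 nM). Interventions multiply the
growth channels of their target species during their schedule window
(RNAi ×0; cAMP pharmacology ×0.25 or ×5). A full βCat knockdown uses a
7-day initialization plus a 7-day whole-worm re-initialization (the
long-lived protein pool must decay before cutting); the partial knockdown
re-initializes 48 h; all other interventions start at the cut.

### How the phenotypes arise

At a wound the Markov sigmoids read ERK (head) and βCat (tail). The
regimes of wound βCat are: < ~25 nM → ERK high → head; ~30–150 nM → dead
band (neither); > ~200 nM sustained → tail. Untreated anterior wounds
crash βCat (Notum arrives by dynein-hauled NRF, Wnt is cleared,
destruction is de-inhibited) while posterior wounds protect it (Hh spike →
Wnt → destruction inhibited) — one head, one tail. Each intervention moves
specific wounds between regimes; the ten-intervention table and both AP
trends (partial-βCat: 2H toward the head, via residual βCat; cAMP-down:
2H toward the tail, via the G-graded protection margin at posterior
wounds) emerge from the same parameterization with no per-experiment
retuning.

## Markov chain of regeneration

Forward rates are logistic in the wound-edge means (`C1 = 0.75 nM`,
`κ1 = 0.05 nM` for ERK→head; `C2 = 300 nM`, `κ2 = 40 nM` for βCat→tail);
reverse rates are constants `β_HB = β_TB = 5e-3`. All rates are per hour.
A prescribed wound-signal pulse `C_wound(t) = 1 − 1/(1+exp(−(t−t_f)/g))`
(`t_f = 90 h`, `g = 12 h`) gates the ODEs

    dp_H/dt = (α_BH p_B − β_HB p_H) C_wound,   p_B = 1 − p_H − p_T,

integrated by explicit Euler on the solver's own time grid from the
recorded wound series; normalization holds by construction to 1e-9.
Fragment class frequencies multiply the two end distributions (terminal
original heads/tails contribute certainty), mapping state pairs to
{2H, 1H, 0H, 0T, 2T, 00}; a tail-at-anterior/head-at-posterior pair is
counted as 1H with a reversed-orientation annotation.

A structural consequence worth stating plainly: because each wound's
probability equilibrates at `α/(α+β) ≤ 1/(1+5e-3) ≈ 0.995`, a fragment
with two cut lines can never exceed ~99.0% for any single class. The
wild-type five-fragment prediction therefore reports 98–99.5% 1H per
fragment (100% per cut line after rounding), not a literal 100%.

## Numerical and interface choices

* Wound-edge sampling: arithmetic mean over the single layer of cells
  adjacent to a cut line's boundary faces, per facing (anterior-facing ⇔
  outward normal x < 0; near-degenerate faces inherit their cut's majority
  tag).
* Cutting removes cells within half a kerf (default: one mean cell size)
  of the cut polyline and additionally severs any surviving face crossed
  by the cut, guaranteeing separation on irregular meshes; surviving cells
  keep their field values.
* Steady state is declared when the maximum relative change per simulated
  hour falls below 1e-4; the standard schedules run fixed durations and
  record the flag.
* Problem sizes: headline analyses use 100 cells in 1D (Δx = 120 µm,
  Δt = 160 s) and ~1750 Voronoi cells in 2D; the fragment-size failure
  scan uses 240 cells so sub-millimeter fragments retain several cells.
  Mesh generation is seeded and all pipelines are deterministic:
  identical configs reproduce outputs byte-identically.
* Degenerate inputs: all-zero divergence yields a zero production map with
  a warning; outlines too thin for VNC stripes fall back to a pure axial
  field with a warning; cuts that remove every cell, or none, are errors.

## Known limitations

* The regulatory constants are this package's own calibration against the
  qualitative phenotype table; they are not literature measurements, and
  alternative parameterizations satisfying the same table exist.
* Normalized gradient profiles are not strictly scale-invariant: across
  0.5–2.4 cm bodies polarity and concentration magnitudes (within ×2) are
  preserved, but the anterior ERK zone has an absolute width, so profiles
  gain detail with size.
* The partial-βCat 2H trend is carried mostly by the terminal fragments;
  with production tied to div u, the mid-body βCat profile is too flat to
  grade interior fragments strongly.
* No tissue mechanics, blastema growth, or nerve-map remodeling after
  wounding; the wound signal is a prescribed pulse, not a simulated
  species.
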