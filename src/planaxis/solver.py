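"""Explicit finite-volume solver for reaction-transport morphogen dynamics.

Each morphogen obeys, on a closed domain,

    dC_i/dt = R_i(C, G) - div(phi_i),    phi_i = -D_i grad(C_i) + a_i u C_i

where R_i collects Hill-modulated production and decay, D_i is the
diffusivity, a_i the motor-protein convection coefficient (signed: + kinesin,
- dynein) and u the nerve-polarity transport field.  Fluxes are evaluated per
face: two-point centroid-difference gradients for diffusion and first-order
upwinding on the sign of u . n̂ for convection; boundary faces carry zero
flux.  Time stepping is explicit Euler, stable for

    dt < dx^2 / (3 D_max)

and all simulations default to half that limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh
from .nerve import ProductionField, VectorField

__all__ = [
    "AdvanceResult",
    "InstabilityError",
    "SolverPolicy",
    "advance",
    "effective_dt",
    "flux_divergence",
    "reaction_rate",
    "stability_dt",
]

SECONDS_PER_HOUR = 3600.0


class InstabilityError(RuntimeError):
    """A concentration exceeded the overflow guard (diverging solution)."""

    def __init__(self, species: str, value: float):
        super().__init__(
            f"instability: species {species!r} reached |C| = {value:.3g}"
        )
        self.species = species


@dataclass
class SolverPolicy:
    """Time-stepping policy.

    dt : explicit step (s); None derives ``safety x dx^2/(3 D_max)``.
    safety : fraction of the stability limit used when dt is None.
    steady_tol : relative change per simulated hour below which the final
        state is flagged as steady.
    """

    dt: float | None = None
    safety: float = 0.5
    steady_tol: float = 1e-4
    overflow: float = 1e12

    def __post_init__(self):
        if not 0 < self.safety <= 1:
            raise ValueError("safety must lie in (0, 1]")

    def resolve_dt(self, mesh: Mesh, d_max: float) -> float:
        limit = stability_dt(mesh, d_max, safety=1.0)
        if self.dt is None:
            return self.safety * limit
        if self.dt > limit:
            raise ValueError(
                f"requested dt = {self.dt:.6g} s exceeds the stability limit "
                f"dx^2/(3 D_max) = {limit:.6g} s"
            )
        return self.dt


def stability_dt(mesh: Mesh, d_max: float, safety: float = 1.0) -> float:
    """Explicit-Euler stability limit ``safety * dx^2 / (3 D_max)``."""
    if d_max <= 0:
        raise ValueError("D_max must be positive")
    return safety * mesh.dx**2 / (3.0 * d_max)


class _Transport:
    """Cached per-mesh face quantities for fast flux evaluation."""

    def __init__(self, mesh: Mesh, u: VectorField):
        self.mesh = mesh
        inter = mesh.interior_faces
        self.inter = inter
        self.a = mesh.face_cells[inter, 0]
        self.b = mesh.face_cells[inter, 1]
        self.inv_dist = 1.0 / mesh.face_dist[inter]
        self.s = u.face_normal_component()[inter]  # u . n̂ at interior faces

    def explicit_dt_bound(self, D: float, alpha: float) -> float:
        """Largest stable explicit step for this species' fluxes.

        Per-cell bound 1 / sum_faces[(D/d + outflow speed) A / V]: the exact
        positivity condition for upwind convection plus two-point diffusion.
        On coarse meshes convection, not diffusion, can bind.
        """
        m = self.mesh
        area = m.face_measure[self.inter]
        out_a = D * self.inv_dist + np.maximum(alpha * self.s, 0.0)
        out_b = D * self.inv_dist + np.maximum(-alpha * self.s, 0.0)
        load = np.zeros(m.n_cells)
        np.add.at(load, self.a, out_a * area)
        np.add.at(load, self.b, out_b * area)
        load /= m.measure
        peak = load.max()
        return np.inf if peak <= 0 else 1.0 / peak

    def neg_div_flux(self, C: np.ndarray, D: float, alpha: float) -> np.ndarray:
        phi = np.zeros(self.mesh.n_faces)
        flux = np.zeros(len(self.inter))
        if D != 0.0:
            flux -= D * (C[self.b] - C[self.a]) * self.inv_dist
        if alpha != 0.0:
            v = alpha * self.s
            upwind = np.where(v > 0, C[self.a], C[self.b])
            flux += v * upwind
        phi[self.inter] = flux
        return -self.mesh.divergence(phi)


def flux_divergence(
    C: np.ndarray,
    u: VectorField,
    D: float,
    alpha: float,
    mesh: Mesh,
) -> np.ndarray:
    """Per-cell -div(phi) for one species (see module docstring).

    Diffusive face flux uses the two-point centroid-difference gradient;
    convective flux upwinds on the sign of ``alpha * (u . n̂)`` with the face
    u taken as the arithmetic mean of the two adjacent cells.  Boundary
    faces are closed (zero flux), so the domain integral vanishes.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("concentration field contains non-finite values")
    return _Transport(mesh, u).neg_div_flux(C, D, alpha)


def _hill_activator(C: np.ndarray, K: float, n: float) -> np.ndarray:
    r = (C / K) ** n
    return r / (1.0 + r)


def _hill_inhibitor(C: np.ndarray, K: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + (C / K) ** n)


def _term_factor(term, C_all: dict) -> np.ndarray:
    """Hill factor of one regulatory term, with optional gating.

    A gated term uses the effective concentration
    ``C_reg / (1 + (C_gate/K_gate)^n_gate)``: the gate species inactivates
    the regulator (e.g. Hh inactivating Ptc) before the Hill factor applies.
    """
    if term.K <= 0 or term.n <= 0:
        raise ValueError(
            f"regulatory term on {term.regulator!r}: K and n must be positive"
        )
    C = C_all[term.regulator]
    if term.gate is not None:
        C = C * _hill_inhibitor(C_all[term.gate], term.gate_K, term.gate_n)
    if term.role.endswith("activator"):
        return _hill_activator(C, term.K, term.n)
    return _hill_inhibitor(C, term.K, term.n)


def reaction_rate(
    C_all: dict,
    spec,
    G: ProductionField | np.ndarray | None,
    growth_multiplier: float = 1.0,
) -> np.ndarray:
    """Reaction part of dC_i/dt for one species.

    Growth channels: ``r * prod(Hill factors) [* G if neural]`` summed over
    channels; decay channels: ``delta * C * prod(Hill factors)`` summed.
    ``growth_multiplier`` scales every growth channel (RNAi/pharmacological
    interventions).
    """
    C = C_all[spec.name]
    rate = np.zeros_like(C)
    gvals = G.values if isinstance(G, ProductionField) else G
    for ch in spec.growth:
        term = np.full_like(C, ch.rate * growth_multiplier)
        for t in ch.factors:
            term = term * _term_factor(t, C_all)
        if spec.neural:
            if gvals is None:
                raise ValueError(
                    f"neural species {spec.name!r} requires a production map"
                )
            term = term * gvals
        rate += term
    for ch in spec.decay:
        term = np.full_like(C, ch.rate)
        for t in ch.factors:
            term = term * _term_factor(t, C_all)
        rate -= term * C
    return rate


def effective_dt(
    model, mesh: Mesh, u: VectorField, policy: SolverPolicy
) -> float:
    """Time step ``advance`` will actually use: the policy step, tightened by
    the per-species explicit flux bound when convection binds."""
    dt = policy.resolve_dt(mesh, model.d_max)
    for s in model.species:
        if s.D != 0.0 or s.alpha != 0.0:
            bound = _Transport(mesh, u).explicit_dt_bound(s.D, s.alpha)
            dt = min(dt, 0.9 * bound)
    return dt


@dataclass
class AdvanceResult:
    state: dict
    steady: bool
    dt: float
    n_steps: int
    clip_events: int = 0
    final_rel_change_per_hour: float = field(default=np.nan)


def advance(
    state: dict,
    model,
    mesh: Mesh,
    u: VectorField,
    G: ProductionField | None,
    policy: SolverPolicy,
    duration: float,
    growth_multipliers: dict | None = None,
    observer=None,
    observe_every: int = 1,
) -> AdvanceResult:
    """March the coupled reaction-transport system for ``duration`` seconds.

    ``growth_multipliers`` maps species name -> factor applied to all growth
    channels (intervention hook).  ``observer(t, state)`` is called after
    every ``observe_every``-th step (and once at t = 0) to sample wound-edge
    time series.  Negative concentrations arising from the explicit update
    are clipped to zero and counted.
    """
    growth_multipliers = growth_multipliers or {}
    dt = effective_dt(model, mesh, u, policy)
    transports = {
        s.name: _Transport(mesh, u)
        for s in model.species
        if (s.D != 0.0 or s.alpha != 0.0)
    }
    n_steps = max(int(np.ceil(duration / dt)), 0)
    state = {k: np.array(v, dtype=float, copy=True) for k, v in state.items()}
    clip_events = 0
    rel_change = np.nan
    if observer is not None:
        observer(0.0, state)
    for step in range(n_steps):
        rates = {}
        for s in model.species:
            r = reaction_rate(
                state, s, G, growth_multipliers.get(s.name, 1.0)
            )
            if s.name in transports:
                r = r + transports[s.name].neg_div_flux(
                    state[s.name], s.D, s.alpha
                )
            rates[s.name] = r
        max_rel = 0.0
        for s in model.species:
            C = state[s.name]
            dC = dt * rates[s.name]
            new = C + dC
            neg = new < 0
            if neg.any():
                clip_events += int(neg.sum())
                new = np.where(neg, 0.0, new)
            peak = np.abs(new).max()
            if peak > policy.overflow:
                raise InstabilityError(s.name, peak)
            denom = np.abs(C).max()
            if denom > 0:
                max_rel = max(max_rel, np.abs(new - C).max() / denom)
            state[s.name] = new
        rel_change = max_rel / dt * SECONDS_PER_HOUR
        if observer is not None and (step + 1) % observe_every == 0:
            observer((step + 1) * dt, state)
    return AdvanceResult(
        state=state,
        steady=bool(rel_change < policy.steady_tol) if n_steps else True,
        dt=dt,
        n_steps=n_steps,
        clip_events=clip_events,
        final_rel_change_per_hour=rel_change,
    )
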