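"""Finite-volume transport, Hill kinetics and explicit time stepping."""

import numpy as np
import pytest

from planaxis import (
    NerveMapParams,
    SolverPolicy,
    VectorField,
    advance,
    build_1d_grid,
    build_2d_mesh,
    flux_divergence,
    generate_field,
    production_from_divergence,
    reaction_rate,
    stability_dt,
)
from planaxis.network import (
    DecayChannel,
    GrowthChannel,
    NetworkModel,
    RegulatoryTerm,
    SpeciesSpec,
)
from planaxis.solver import InstabilityError, _hill_activator, _hill_inhibitor

DAY = 86400.0


def single_species_model(name="A", D=1.5e-11, alpha=0.0, r=0.0, delta=0.0,
                         neural=False, initial=0.0):
    growth = [GrowthChannel("basal", r)] if r else []
    decay = [DecayChannel("basal", delta)] if delta else []
    return NetworkModel(
        [SpeciesSpec(name, D=D, alpha=alpha, neural=neural,
                     initial=initial, growth=growth, decay=decay)]
    )


class TestStabilityLimit:
    def test_printed_formula(self):
        mesh = build_1d_grid(0.012, 40)  # dx = 3e-4 m
        assert stability_dt(mesh, 1.5e-11, safety=1.0) == pytest.approx(2000.0)

    def test_safety_scaling(self):
        mesh = build_1d_grid(0.012, 40)
        assert stability_dt(mesh, 1.5e-11, safety=0.5) == pytest.approx(1000.0)

    def test_quadratic_in_dx(self):
        coarse = build_1d_grid(0.012, 40)
        fine = build_1d_grid(0.012, 80)
        ratio = stability_dt(coarse, 1e-11) / stability_dt(fine, 1e-11)
        assert ratio == pytest.approx(4.0)

    def test_nonpositive_diffusivity_rejected(self):
        mesh = build_1d_grid(0.012, 40)
        with pytest.raises(ValueError):
            stability_dt(mesh, 0.0)

    def test_dt_above_limit_refused_with_limit(self):
        mesh = build_1d_grid(0.012, 40)
        policy = SolverPolicy(dt=5000.0)
        with pytest.raises(ValueError, match="2000"):
            policy.resolve_dt(mesh, 1.5e-11)


class TestFluxDivergence:
    def test_uniform_field_no_advection_is_zero(self, grid1d):
        u = VectorField(np.zeros(grid1d.n_cells), grid1d)
        out = flux_divergence(np.full(grid1d.n_cells, 3.3), u, 1e-11, 0.0, grid1d)
        np.testing.assert_allclose(out, 0.0, atol=1e-20)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_closed_boundary_conserves_mass(self, seed, worm_outline):
        mesh = build_2d_mesh(worm_outline, 250, seed=seed)
        rng = np.random.default_rng(seed)
        C = rng.uniform(0, 10, mesh.n_cells)
        u = generate_field(mesh, NerveMapParams())
        out = flux_divergence(C, u, 1.5e-11, 3e-7, mesh)
        total = float((out * mesh.measure).sum())
        scale = float((np.abs(out) * mesh.measure).sum()) + 1e-30
        assert abs(total) / scale < 1e-9

    def test_nan_input_fails_fast(self, grid1d):
        u = VectorField(np.zeros(grid1d.n_cells), grid1d)
        C = np.zeros(grid1d.n_cells)
        C[3] = np.nan
        with pytest.raises(ValueError):
            flux_divergence(C, u, 1e-11, 0.0, grid1d)

    def test_advection_diffusion_equilibrium_profile(self):
        """Closed 1D domain with constant drift: C(x) ~ exp(v x / D)."""
        n = 40
        mesh = build_1d_grid(0.012, n)
        u = VectorField(np.ones(n), mesh)
        v, D = 1e-9, 1.5e-11
        model = single_species_model(D=D, alpha=v, initial=1.0)
        policy = SolverPolicy()
        res = advance(
            model.initial_state(n), model, mesh, u, None, policy, 1.2e7
        )
        C = res.state["A"]
        assert np.exp(v * 0.012 / D) == pytest.approx(2.2255, abs=1e-3)
        # closed-form ratio between the first and last cell centroids
        span = mesh.points[-1, 0] - mesh.points[0, 0]
        expected_ratio = np.exp(v * span / D)
        assert C[-1] / C[0] == pytest.approx(expected_ratio, rel=0.02)


class TestReactionRate:
    def test_half_saturation(self):
        assert _hill_activator(np.array([2.0]), 2.0, 3.0)[0] == pytest.approx(0.5)
        assert _hill_inhibitor(np.array([2.0]), 2.0, 3.0)[0] == pytest.approx(0.5)

    def test_linear_birth_death(self):
        model = single_species_model(r=1.0, delta=0.1, neural=True)
        spec = model.species[0]
        C_all = {"A": np.array([10.0, 0.0, 5.0])}
        rate = reaction_rate(C_all, spec, np.ones(3))
        np.testing.assert_allclose(rate, 1.0 - 0.1 * C_all["A"])

    def test_single_activator_hand_evaluation(self):
        """r = 1, one growth activator at half saturation, delta = 0.1,
        C_i = 2 -> rate = 1 * 0.5 - 0.1 * 2 = 0.3."""
        spec = SpeciesSpec(
            "A",
            growth=[
                GrowthChannel(
                    "g", 1.0,
                    [RegulatoryTerm("B", K=4.0, n=2.0, role="growth-activator")],
                )
            ],
            decay=[DecayChannel("d", 0.1)],
        )
        NetworkModel([spec, SpeciesSpec("B")])
        C_all = {"A": np.array([2.0]), "B": np.array([4.0])}
        rate = reaction_rate(C_all, spec, None)
        assert rate[0] == pytest.approx(0.3)

    def test_invalid_hill_parameters_rejected(self):
        with pytest.raises(ValueError):
            RegulatoryTerm("B", K=-1.0, n=2.0, role="growth-inhibitor")
        with pytest.raises(ValueError):
            RegulatoryTerm("B", K=1.0, n=0.0, role="growth-inhibitor")


class TestAdvance:
    def test_pure_decay_matches_closed_form(self):
        delta = 2e-5
        model = single_species_model(delta=delta, initial=8.0, D=1.5e-11)
        n = 100
        mesh = build_1d_grid(0.012, n)
        u = VectorField(np.zeros(n), mesh)
        t_end = 5 * np.log(2) / delta  # five half-lives
        res = advance(
            model.initial_state(n), model, mesh, u, None, SolverPolicy(), t_end
        )
        expected = 8.0 * np.exp(-delta * res.n_steps * res.dt)
        np.testing.assert_allclose(res.state["A"], expected, rtol=0.01)

    def test_zero_rates_zero_fields_fixed_point(self, grid1d):
        model = single_species_model(initial=2.5)
        u = VectorField(np.zeros(grid1d.n_cells), grid1d)
        res = advance(
            model.initial_state(grid1d.n_cells), model, grid1d, u, None,
            SolverPolicy(), 2 * DAY,
        )
        np.testing.assert_array_equal(res.state["A"], 2.5)

    def test_step_size_invariance(self, grid1d, field1d, production1d, model):
        """Halving dt leaves 4.5-day fields unchanged within 0.5%."""
        state0 = model.initial_state(grid1d.n_cells)
        full = advance(
            state0, model, grid1d, field1d, production1d,
            SolverPolicy(safety=0.5), 4.5 * DAY,
        )
        half = advance(
            state0, model, grid1d, field1d, production1d,
            SolverPolicy(safety=0.25), 4.5 * DAY,
        )
        for name in ("ERK", "bcat", "Wnt", "Hh"):
            a, b = full.state[name], half.state[name]
            scale = np.abs(b).max()
            assert np.abs(a - b).max() / scale < 5e-3

    def test_mass_conserved_without_reactions(self, grid1d):
        model = single_species_model(D=1.5e-11, alpha=3e-7)
        u = generate_field(grid1d, NerveMapParams())
        state = {"A": np.linspace(1.0, 3.0, grid1d.n_cells)}
        m0 = float((state["A"] * grid1d.measure).sum())
        res = advance(state, model, grid1d, u, None, SolverPolicy(), 5 * DAY)
        m1 = float((res.state["A"] * grid1d.measure).sum())
        assert m1 == pytest.approx(m0, rel=1e-6)

    def test_non_negativity(self, grid1d, field1d, production1d, model):
        res = advance(
            model.initial_state(grid1d.n_cells), model, grid1d, field1d,
            production1d, SolverPolicy(), 2 * DAY,
        )
        for name, C in res.state.items():
            assert np.all(C >= 0), name

    def test_instability_reports_species(self):
        n = 10
        mesh = build_1d_grid(0.012, n)
        u = VectorField(np.zeros(n), mesh)
        model = single_species_model(r=1e9, initial=1.0, D=1.5e-11)
        model.species[0].growth[0].rate = 1e9
        with pytest.raises(InstabilityError, match="A"):
            advance(
                model.initial_state(n), model, mesh, u, None,
                SolverPolicy(overflow=1e6), 5 * DAY,
            )


class TestBruteForceOracle:
    """One explicit step must match a dense, loop-based reimplementation of
    the flux and kinetics on a small mesh, cellwise to 1e-12."""

    def brute_force_step(self, mesh, u, G, model, state, dt, mult=None):
        mult = mult or {}
        new = {}
        s_face = u.face_normal_component()
        for spec in model.species:
            C = state[spec.name]
            rate = np.zeros_like(C)
            for ch in spec.growth:
                term = np.full_like(C, ch.rate * mult.get(spec.name, 1.0))
                for t in ch.factors:
                    reg = state[t.regulator].copy()
                    if t.gate is not None:
                        reg = reg / (
                            1.0 + (state[t.gate] / t.gate_K) ** t.gate_n
                        )
                    h = (reg / t.K) ** t.n
                    term *= h / (1 + h) if t.role.endswith("activator") else 1 / (1 + h)
                if spec.neural:
                    term *= G.values
                rate += term
            for ch in spec.decay:
                term = np.full_like(C, ch.rate)
                for t in ch.factors:
                    reg = state[t.regulator]
                    h = (reg / t.K) ** t.n
                    term *= h / (1 + h) if t.role.endswith("activator") else 1 / (1 + h)
                rate -= term * C
            # flux divergence, face by face
            for f in range(mesh.n_faces):
                a, b = mesh.face_cells[f]
                if b < 0:
                    continue
                grad = (C[b] - C[a]) / mesh.face_dist[f]
                phi = -spec.D * grad
                v = spec.alpha * s_face[f]
                phi += v * (C[a] if v > 0 else C[b])
                rate[a] -= phi * mesh.face_measure[f] / mesh.measure[a]
                rate[b] += phi * mesh.face_measure[f] / mesh.measure[b]
            new[spec.name] = np.maximum(C + dt * rate, 0.0)
        return new

    def test_one_step_equivalence(self, model):
        n = 25
        mesh = build_1d_grid(0.012, n)
        u = generate_field(mesh, NerveMapParams())
        G = production_from_divergence(u, mesh)
        rng = np.random.default_rng(11)
        state = {
            s.name: rng.uniform(0, 5, n).astype(float) for s in model.species
        }
        policy = SolverPolicy()
        from planaxis.solver import effective_dt

        dt = effective_dt(model, mesh, u, policy)
        res = advance(state, model, mesh, u, G, policy, duration=dt)
        assert res.n_steps == 1
        expected = self.brute_force_step(mesh, u, G, model, state, res.dt)
        for name in state:
            np.testing.assert_allclose(
                res.state[name], expected[name], rtol=1e-12, atol=1e-15
            )

    def test_2d_step_equivalence(self, worm_outline, model):
        mesh = build_2d_mesh(worm_outline, 30, seed=9)
        u = generate_field(mesh, NerveMapParams())
        G = production_from_divergence(u, mesh)
        rng = np.random.default_rng(13)
        state = {
            s.name: rng.uniform(0, 5, mesh.n_cells).astype(float)
            for s in model.species
        }
        from planaxis.solver import effective_dt

        policy = SolverPolicy()
        res = advance(state, model, mesh, u, G, policy,
                      duration=effective_dt(model, mesh, u, policy))
        expected = self.brute_force_step(mesh, u, G, model, state, res.dt)
        for name in state:
            np.testing.assert_allclose(
                res.state[name], expected[name], rtol=1e-12, atol=1e-15
            )
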