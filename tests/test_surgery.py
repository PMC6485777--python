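"""Schedules, wound sampling, scenario library and pipeline behavior."""

import numpy as np
import pytest

from planaxis import (
    CutLine,
    NerveMapParams,
    SimulationSchedule,
    build_1d_grid,
    default_network,
    fragment_outcome,
    generate_field,
    make_schedule,
    production_from_divergence,
    run_schedule,
    scenario_library,
    wound_edge_concentration,
)
from planaxis.surgery import DAY, HOUR, check_scenario

L = 0.012


class TestSchedules:
    def test_default_untreated(self):
        s = make_schedule(None)
        assert s.init_duration == pytest.approx(4.5 * DAY)
        assert s.reinit_duration == 0.0
        assert s.post_cut_duration == pytest.approx(4.5 * DAY)
        assert s.post_cut_interventions == ()

    def test_full_bcat_timeline(self):
        s = make_schedule("RNAi-bcat-full")
        assert s.init_duration == pytest.approx(7 * DAY)
        assert s.reinit_duration == pytest.approx(7 * DAY)
        assert s.reinit_interventions == ("RNAi-bcat-full",)

    def test_partial_bcat_timeline(self):
        s = make_schedule("RNAi-bcat-partial")
        assert s.reinit_duration == pytest.approx(48 * HOUR)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            make_schedule("RNAi-unobtainium")

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            SimulationSchedule(init_duration=-1.0)


class TestWoundSampling:
    def test_uniform_field_mean(self, untreated_result):
        fs = untreated_result.fragments[1]
        fs_copy_state = fs.state["cAMP"]
        # cAMP is spatially uniform, so any wound mean equals the field value
        for lab in fs.fragment.cut_labels:
            got = wound_edge_concentration(fs, lab, "cAMP")
            assert got == pytest.approx(float(fs_copy_state.mean()), rel=1e-3)

    def test_arithmetic_mean_of_wound_cells(self, untreated_result):
        fs = untreated_result.fragments[1]
        lab = fs.fragment.cut_labels[0]
        cells = fs.fragment.wound_cells(lab)
        manual = float(np.mean(fs.state["ERK"][cells]))
        assert wound_edge_concentration(fs, lab, "ERK") == pytest.approx(manual)

    def test_unknown_label_raises(self, untreated_result):
        with pytest.raises(KeyError):
            wound_edge_concentration(
                untreated_result.fragments[0], "nope", "ERK"
            )


class TestScenarioLibrary:
    def test_five_transverse_positions(self):
        cuts = scenario_library()["five-transverse"].cuts(L)
        xs = [c.points[0, 0] for c in cuts]
        assert xs == pytest.approx([0.2 * L, 0.4 * L, 0.6 * L, 0.8 * L])

    def test_marginal_rectangle_between_vnc_and_edge(self):
        plan = scenario_library()["marginal-rectangle-vnc-free"]
        ring = plan.cuts(L)[0].points
        y = ring[:, 1]
        params = NerveMapParams()
        assert y.min() > params.vnc_offset + params.stripe_sigma
        # ~1 mm long edge parallel to the AP axis
        assert np.ptp(ring[:, 0]) == pytest.approx(1.0e-3)

    def test_dual_decapitation_spans_symmetry_line(self):
        plan = scenario_library()["2h-dual-decapitation-with-line"]
        xs = sorted(c.points[0, 0] for c in plan.cuts(L))
        assert xs[0] < 0.5 * L < xs[1]

    def test_body_plan_mismatch_rejected(self):
        plan = scenario_library()["2h-short-head"]
        with pytest.raises(ValueError, match="2H"):
            check_scenario(plan, "1H")

    def test_unknown_scenario_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            scenario_library()["spiral-cut"]


class TestPipeline:
    def test_uncut_worm_reaches_steady_state(
        self, model, grid1d, field1d, production1d
    ):
        res = run_schedule(
            model, grid1d, field1d, production1d, make_schedule(None), []
        )
        assert len(res.fragments) == 1
        assert res.fragments[0].advance_info.steady

    def test_post_cut_intervention_leaves_pre_cut_untouched(
        self, model, grid1d, field1d, production1d, untreated_result
    ):
        cuts = scenario_library()["five-transverse"].cuts(L)
        treated = run_schedule(
            model, grid1d, field1d, production1d,
            make_schedule("RNAi-Wnt"), cuts,
        )
        for name, ref in untreated_result.pre_cut_state.items():
            np.testing.assert_array_equal(treated.pre_cut_state[name], ref)

    def test_fragments_evolve_independently(self, untreated_result):
        # fragment states have distinct buffers of fragment-local size
        sizes = [fs.mesh.n_cells for fs in untreated_result.fragments]
        for fs in untreated_result.fragments:
            for arr in fs.state.values():
                assert arr.shape == (fs.mesh.n_cells,)
        assert sum(sizes) < untreated_result.mesh.n_cells  # kerf removed

    def test_erk_repolarizes_within_72_hours(
        self, model, grid1d, field1d, production1d
    ):
        """Each fragment's ERK maximum sits at its anterior-facing wound
        within 72 h of cutting."""
        cuts = scenario_library()["five-transverse"].cuts(L)
        sched = SimulationSchedule(post_cut_duration=72 * HOUR)
        res = run_schedule(
            model, grid1d, field1d, production1d, sched, cuts
        )
        for fs in res.fragments[1:]:  # fragments with an anterior-facing wound
            lab = fs.fragment.cut_labels[0]
            wound_cells = fs.fragment.wound_cells(lab, "anterior")
            erk = fs.state["ERK"]
            assert erk[wound_cells].max() >= 0.95 * erk.max()

    def test_notum_localizes_to_anterior_wounds(self, untreated_result):
        """After a transverse cut, Notum peaks at anterior-facing wound
        edges (dynein-hauled NRF accumulates there and induces it)."""
        fs = untreated_result.fragments[2]
        ant = fs.fragment.wound_cells(fs.fragment.cut_labels[0], "anterior")
        post = fs.fragment.wound_cells(fs.fragment.cut_labels[1], "posterior")
        notum = fs.state["Notum"]
        assert notum[ant].mean() > 5 * notum[post].mean()
        assert notum[ant].max() >= 0.9 * notum.max()

    def test_full_bcat_reinit_depletes_bcat(
        self, model, grid1d, field1d, production1d, untreated_result
    ):
        cuts = scenario_library()["five-transverse"].cuts(L)
        res = run_schedule(
            model, grid1d, field1d, production1d,
            make_schedule("RNAi-bcat-full"), cuts,
        )
        treated = res.pre_cut_state["bcat"]
        ref = untreated_result.pre_cut_state["bcat"]
        assert treated.max() < 0.1 * ref.max()


class TestFragmentOutcome:
    def test_end_fragments_have_terminal_ends(self, untreated_result):
        head = untreated_result.fragments[0]
        tail = untreated_result.fragments[-1]
        assert head.fragment.has_head and not head.fragment.has_tail
        assert tail.fragment.has_tail and not tail.fragment.has_head

    def test_unscorable_layout_raises(self, untreated_result, markov_params):
        fs = untreated_result.fragments[0]
        # pretend the terminal head was also wounded away
        fs_bad = type(fs)(
            fragment=fs.fragment, state=fs.state, u=fs.u, G=fs.G, series={}
        )
        fs_bad.fragment.has_head = False
        try:
            with pytest.raises(ValueError, match="scored ends"):
                fragment_outcome(fs_bad, markov_params)
        finally:
            fs_bad.fragment.has_head = True


class TestSteadyStatePolarity:
    def test_homeostatic_gradient_polarities(self, untreated_result):
        """Intact-worm steady state: ERK and Notum peak anteriorly, Wnt and
        beta-catenin peak posteriorly."""
        s = untreated_result.pre_cut_state
        x = untreated_result.mesh.points[:, 0]
        n = len(x)
        ant, post = x < 0.2 * x.max(), x > 0.8 * x.max()
        assert np.argmax(s["ERK"]) < 0.2 * n
        assert np.argmax(s["Notum"]) < 0.2 * n
        assert np.argmax(s["bcat"]) > 0.8 * n
        assert np.argmax(s["Wnt"]) > 0.8 * n
        assert s["ERK"][ant].mean() > 5 * s["ERK"][post].mean()
        assert s["bcat"][post].mean() > 5 * s["bcat"][ant].mean()

    def test_notum_paradox(self, model, grid1d, field1d, production1d,
                           untreated_result):
        """Notum tracks beta-catenin, not head outcome: a full beta-catenin
        knockdown regenerates two heads with depressed Notum, while APC
        knockdown blocks heads yet shows elevated Notum."""
        cuts = scenario_library()["five-transverse"].cuts(L)
        ref = untreated_result.fragments[2]
        ref_notum = ref.state["Notum"].mean()

        full = run_schedule(
            model, grid1d, field1d, production1d,
            make_schedule("RNAi-bcat-full"), cuts,
        )
        fs = full.fragments[2]
        dist, _ = fragment_outcome(fs)
        assert dist.modal_class == "2H"
        assert fs.state["Notum"].mean() < 0.5 * ref_notum

        apc = run_schedule(
            model, grid1d, field1d, production1d,
            make_schedule("RNAi-APC"), cuts,
        )
        fs = apc.fragments[2]
        dist, _ = fragment_outcome(fs)
        assert dist.modal_class in ("0H", "2T")
        assert fs.state["Notum"].mean() > 1.5 * ref_notum
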