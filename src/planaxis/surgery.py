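"""Virtual amputation experiments: schedules, cutting, wound sampling.

An experiment runs in phases on a whole-body mesh: an initialization phase
establishes the homeostatic steady-state gradients (default 4.5 simulated
days); an optional re-initialization phase lets an intervention act on the
intact worm (7 days for a full beta-catenin knockdown, 48 h for a partial
one); the body is then cut and every fragment evolves independently behind
closed wound boundaries for a post-cut phase (default 4.5 days), during
which wound-edge ERK and beta-catenin are sampled each solver step for the
Markov outcome model.

The scenario library parameterizes the named cut geometries used throughout:
transverse fragmentations, L-shaped nerve-diverting cuts, marginal
rectangles excluding/including the ventral nerve cord, and the two-headed
cutting battery around the midbody symmetry line.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .markov import (
    MarkovParams,
    OutcomeDistribution,
    TERMINAL_HEAD,
    TERMINAL_TAIL,
    WoundOutcome,
    fragment_distribution,
    integrate_outcome,
)
from .mesh import CutLine, Fragment, Mesh, cut_mesh
from .network import NetworkModel, intervention_catalog
from .nerve import ProductionField, VectorField
from .solver import AdvanceResult, SolverPolicy, advance

__all__ = [
    "DAY",
    "HOUR",
    "CutPlan",
    "FragmentState",
    "SimulationSchedule",
    "SurgeryResult",
    "fragment_outcome",
    "make_schedule",
    "run_schedule",
    "scenario_library",
    "wound_edge_concentration",
]

HOUR = 3600.0
DAY = 86400.0


@dataclass
class SimulationSchedule:
    """Phase durations (seconds) and the intervention labels active in each
    phase.  The cut happens once, between re-initialization and post-cut."""

    init_duration: float = 4.5 * DAY
    reinit_duration: float = 0.0
    post_cut_duration: float = 4.5 * DAY
    init_interventions: tuple = ()
    reinit_interventions: tuple = ()
    post_cut_interventions: tuple = ()

    def __post_init__(self):
        for d in (self.init_duration, self.reinit_duration, self.post_cut_duration):
            if d < 0:
                raise ValueError("phase durations must be non-negative")


def make_schedule(intervention_label: str | None = None) -> SimulationSchedule:
    """Standard timeline for one intervention (or untreated when None).

    Most interventions start at the time of cutting.  A full beta-catenin
    knockdown uses a 7-day initialization plus a 7-day whole-worm
    re-initialization with synthesis blocked (its long-lived protein pool
    must decay before cutting); the partial knockdown uses a 48-hour
    re-initialization.
    """
    if intervention_label is None:
        return SimulationSchedule()
    cat = intervention_catalog()
    if intervention_label not in cat:
        raise KeyError(f"unknown intervention {intervention_label!r}")
    iv = cat[intervention_label]
    if iv.schedule == "full":
        return SimulationSchedule(
            init_duration=7 * DAY,
            reinit_duration=7 * DAY,
            reinit_interventions=(iv.label,),
            post_cut_interventions=(iv.label,),
        )
    if iv.schedule == "partial":
        return SimulationSchedule(
            reinit_duration=48 * HOUR,
            reinit_interventions=(iv.label,),
            post_cut_interventions=(iv.label,),
        )
    return SimulationSchedule(post_cut_interventions=(iv.label,))


def _multipliers(labels) -> dict:
    cat = intervention_catalog()
    mult: dict = {}
    for lab in labels:
        iv = cat[lab]
        mult[iv.target] = mult.get(iv.target, 1.0) * iv.multiplier
    return mult


@dataclass
class FragmentState:
    """One fragment with its fields and its wound-edge time series."""

    fragment: Fragment
    state: dict
    u: VectorField
    G: ProductionField
    series: dict = dc_field(default_factory=dict)
    advance_info: AdvanceResult | None = None

    @property
    def mesh(self) -> Mesh:
        return self.fragment.mesh


@dataclass
class SurgeryResult:
    fragments: list
    pre_cut_state: dict
    pre_cut_steady: bool
    mesh: Mesh
    schedule: SimulationSchedule


def wound_edge_concentration(
    fs: FragmentState, cut_label: str, species: str, facing: str | None = None
) -> float:
    """Mean concentration over the cells adjacent to one cut line."""
    cells = fs.fragment.wound_cells(cut_label, facing)
    return float(np.mean(fs.state[species][cells]))


def run_schedule(
    model: NetworkModel,
    mesh: Mesh,
    u: VectorField,
    G: ProductionField,
    schedule: SimulationSchedule,
    cuts: list[CutLine],
    policy: SolverPolicy | None = None,
    kerf: float | None = None,
    observe_every: int = 1,
    body_plan: str = "1H",
) -> SurgeryResult:
    """Execute a full experiment timeline and return the final fragments.

    Wound-edge ERK and beta-catenin means are recorded per (cut line,
    facing) every ``observe_every``-th solver step of the post-cut phase.
    On a two-headed body plan the posterior tip is an original head, so a
    fragment retaining it carries a terminal head flag instead of a tail.
    """
    policy = policy or SolverPolicy()
    state = model.initial_state(mesh.n_cells)
    res = advance(
        state, model, mesh, u, G, policy, schedule.init_duration,
        growth_multipliers=_multipliers(schedule.init_interventions),
    )
    if schedule.reinit_duration > 0:
        res = advance(
            res.state, model, mesh, u, G, policy, schedule.reinit_duration,
            growth_multipliers=_multipliers(schedule.reinit_interventions),
        )
    pre_cut_state = res.state
    pre_cut_steady = res.steady

    frags = cut_mesh(mesh, cuts, kerf=kerf)
    if body_plan == "2H":
        for fr in frags:
            if fr.has_tail:
                fr.has_tail = False
                fr.has_head = True
    post_mult = _multipliers(schedule.post_cut_interventions)
    out = []
    for fr in frags:
        fstate = {k: v[fr.orig_cells].copy() for k, v in pre_cut_state.items()}
        fu = u.restrict(fr.orig_cells, fr.mesh)
        fG = G.restrict(fr.orig_cells, fr.mesh)
        series = {
            (lab, facing): {"t": [], "ERK": [], "bcat": []}
            for lab, sides in fr.wounds.items()
            for facing in sides
        }

        def observer(t, st, fr=fr, series=series):
            for (lab, facing), rec in series.items():
                cells = fr.wounds[lab][facing]
                rec["t"].append(t / HOUR)
                rec["ERK"].append(float(st["ERK"][cells].mean()))
                rec["bcat"].append(float(st["bcat"][cells].mean()))

        info = advance(
            fstate, model, fr.mesh, fu, fG, policy,
            schedule.post_cut_duration,
            growth_multipliers=post_mult,
            observer=observer if series else None,
            observe_every=observe_every,
        )
        series = {
            key: {k: np.asarray(v) for k, v in rec.items()}
            for key, rec in series.items()
        }
        out.append(
            FragmentState(fr, info.state, fu, fG, series=series, advance_info=info)
        )
    return SurgeryResult(out, pre_cut_state, pre_cut_steady, mesh, schedule)


def fragment_outcome(
    fs: FragmentState, params: MarkovParams | None = None
) -> tuple[OutcomeDistribution, dict]:
    """Score one fragment with the Markov chain model.

    The fragment's two ends (anterior first) are terminal original head/tail
    flags or integrated cut-line outcomes; fragments whose wound layout does
    not reduce to two ends (e.g. L-cut geometries) cannot be scored this way.
    """
    params = params or MarkovParams()
    wound_outcomes: dict = {}
    ends = []  # (mean x, triple)
    for (lab, facing), rec in fs.series.items():
        wo = integrate_outcome(rec["t"], rec["ERK"], rec["bcat"], params)
        wound_outcomes[(lab, facing)] = wo
        cells = fs.fragment.wounds[lab][facing]
        ends.append((float(fs.mesh.points[cells, 0].mean()), wo.final))
    if fs.fragment.has_head:
        ends.append((float(fs.mesh.points[:, 0].min()) - 1.0, TERMINAL_HEAD))
    if fs.fragment.has_tail:
        ends.append((float(fs.mesh.points[:, 0].max()) + 1.0, TERMINAL_TAIL))
    if len(ends) != 2:
        raise ValueError(
            f"fragment has {len(ends)} scored ends; the two-ended Markov "
            "scoring applies to transverse-cut protocols"
        )
    ends.sort(key=lambda e: e[0])
    dist = fragment_distribution([ends[0][1], ends[1][1]])
    return dist, wound_outcomes


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------


@dataclass
class CutPlan:
    """A named cut geometry parameterized against a body outline."""

    name: str
    body_plan: str  # "1H" | "2H" | "any"
    description: str
    _builder: callable = None
    _focus: callable = None
    meta: dict = dc_field(default_factory=dict)

    def cuts(self, L: float, half_width: float = 1.25e-3) -> list[CutLine]:
        return self._builder(L, half_width)

    def focus_index(self, fragments: list) -> int:
        """Index of the fragment this scenario scores."""
        if self._focus is None:
            return 0
        return self._focus(fragments)


def _transverse_cuts(fracs, L, label_prefix="cut"):
    return [
        CutLine.transverse(f * L, f"{label_prefix}{i + 1}")
        for i, f in enumerate(fracs)
    ]


def _contains_x(fragments, x):
    for i, fr in enumerate(fragments):
        pts = fr.mesh.points[:, 0] if isinstance(fr, FragmentState) else None
        mesh = fr.mesh if hasattr(fr, "mesh") else fr
        xs = mesh.points[:, 0]
        if xs.min() <= x <= xs.max():
            return i
    raise ValueError("no fragment spans the requested axial position")


def _l_cut(L, w, direction):
    """L-shaped incision freeing a lateral flap containing a VNC.

    ``direction='forward'``: the midline leg runs toward the tail, so the
    flap attaches at its posterior base and the diverted VNC points from the
    free (anterior) end into the flap -- the free end sits upstream of the
    transport and is predicted to form a head.  ``'backward'`` mirrors the
    geometry toward the head; transport converges on the free (posterior)
    end, predicting a tail.  ``'control'`` reproduces the forward geometry
    lateral to the VNC so the flap carries no cord.
    """
    y_cut = 2.0e-4 if direction != "control" else 6.5e-4
    if direction in ("forward", "control"):
        x0, x1 = 0.45 * L, 0.75 * L
    else:
        x0, x1 = 0.55 * L, 0.25 * L
    transverse = CutLine(
        np.array([[x0, y_cut], [x0, 2.0 * w]]), "l-transverse"
    )
    longitudinal = CutLine(
        np.array([[x0, y_cut], [x1, y_cut]]), "l-longitudinal"
    )
    return [transverse, longitudinal]


def _rectangle(L, w, y_lo, y_hi, x0_frac=0.40, length=1.0e-3):
    """Closed rectangular incision; the interior becomes a free fragment
    with its ~1 mm long edge along the AP axis."""
    x0 = x0_frac * L
    x1 = x0 + length
    ring = np.array(
        [
            [x0, y_lo],
            [x1, y_lo],
            [x1, y_hi],
            [x0, y_hi],
            [x0, y_lo],
        ]
    )
    return [CutLine(ring, "rect")]


def _rect_focus(fragments, y_lo, y_hi, x0, x1):
    cx = (x0 + x1) / 2
    cy = (y_lo + y_hi) / 2
    best, best_d = None, np.inf
    for i, fr in enumerate(fragments):
        mesh = fr.mesh if hasattr(fr, "mesh") else fr
        c = mesh.points.mean(axis=0)
        d = np.hypot(c[0] - cx, c[1] - cy)
        inside = (
            (mesh.points[:, 0] > x0)
            & (mesh.points[:, 0] < x1)
            & (mesh.points[:, 1] > y_lo)
            & (mesh.points[:, 1] < y_hi)
        ).all()
        if inside and d < best_d:
            best, best_d = i, d
    if best is None:
        raise ValueError("no fragment lies inside the rectangle")
    return best


def scenario_library() -> dict[str, CutPlan]:
    """Named cut geometries of the standard experiment battery."""
    plans = [
        CutPlan(
            "five-transverse",
            "1H",
            "four transverse cuts at 0.2/0.4/0.6/0.8 L giving five equal "
            "fragments",
            lambda L, w: _transverse_cuts([0.2, 0.4, 0.6, 0.8], L),
        ),
        CutPlan(
            "three-transverse",
            "any",
            "two transverse cuts at L/3 and 2L/3",
            lambda L, w: _transverse_cuts([1 / 3, 2 / 3], L),
        ),
        CutPlan(
            "l-cut-forward",
            "1H",
            "L-incision diverting a forward-polarity VNC into a lateral "
            "flap (head predicted at the free end)",
            lambda L, w: _l_cut(L, w, "forward"),
            meta={"free_end_facing": "anterior", "vnc_band": (2.0e-4, 7.0e-4)},
        ),
        CutPlan(
            "l-cut-backward",
            "1H",
            "mirrored L-incision diverting a backward-polarity VNC (tail "
            "predicted at the free end)",
            lambda L, w: _l_cut(L, w, "backward"),
            meta={"free_end_facing": "posterior", "vnc_band": (2.0e-4, 7.0e-4)},
        ),
        CutPlan(
            "l-cut-control",
            "1H",
            "L-incision lateral to the VNC (flap carries no cord)",
            lambda L, w: _l_cut(L, w, "control"),
            meta={"free_end_facing": "anterior", "vnc_band": (6.5e-4, 1.2e-3)},
        ),
        CutPlan(
            "marginal-rectangle-vnc-free",
            "1H",
            "~1 mm rectangle from the lateral margin, strictly between the "
            "VNC stripe and the body edge",
            lambda L, w: _rectangle(L, w, 6.5e-4, 1.18e-3),
            lambda frs: _rect_focus(
                frs, 6.5e-4, 1.18e-3, 0.40 * 0.012, 0.40 * 0.012 + 1e-3
            ),
        ),
        CutPlan(
            "marginal-rectangle-vnc",
            "1H",
            "~1 mm rectangle of the same shape containing a VNC stripe",
            lambda L, w: _rectangle(L, w, 1.2e-4, 6.0e-4),
            lambda frs: _rect_focus(
                frs, 1.2e-4, 6.0e-4, 0.40 * 0.012, 0.40 * 0.012 + 1e-3
            ),
        ),
        CutPlan(
            "2h-short-head",
            "2H",
            "single decapitation: short head fragment ending well before "
            "the symmetry line",
            lambda L, w: _transverse_cuts([0.15], L),
            lambda frs: 0,
        ),
        CutPlan(
            "2h-head-before-line",
            "2H",
            "head fragment whose posterior cut does not cross the symmetry "
            "line",
            lambda L, w: _transverse_cuts([0.35], L),
            lambda frs: 0,
        ),
        CutPlan(
            "2h-head-across-line",
            "2H",
            "head fragment whose posterior cut crosses the symmetry line",
            lambda L, w: _transverse_cuts([0.65], L),
            lambda frs: 0,
        ),
        CutPlan(
            "2h-dual-decapitation-with-line",
            "2H",
            "both heads amputated; the remaining fragment contains the "
            "symmetry line",
            lambda L, w: _transverse_cuts([0.15, 0.85], L),
            lambda frs: 1,
        ),
        CutPlan(
            "2h-dual-decapitation-without-line",
            "2H",
            "two cuts on the same side of the symmetry line; the scored "
            "fragment excludes it",
            lambda L, w: _transverse_cuts([0.10, 0.40], L),
            lambda frs: 1,
        ),
        CutPlan(
            "2h-diagonal",
            "2H",
            "diagonal cut through the midpoint at > 45 degrees to the "
            "symmetry line",
            lambda L, w: [
                CutLine(
                    np.array([[0.35 * L, -2.0 * w], [0.65 * L, 2.0 * w]]),
                    "diag",
                )
            ],
            lambda frs: 0,
        ),
    ]
    return {p.name: p for p in plans}


def check_scenario(plan: CutPlan, body_plan: str):
    if plan.body_plan not in ("any", body_plan):
        raise ValueError(
            f"scenario {plan.name!r} requires a {plan.body_plan} body plan, "
            f"got {body_plan}"
        )
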