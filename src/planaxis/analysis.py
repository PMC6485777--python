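"""Figure-level analyses: phenotype batteries, AP trends, scaling, sensitivity.

These routines wrap the surgery + Markov pipeline into the standard
experiment batteries: the five-fragment intervention phenotype table, the
anterior-posterior 2H-frequency trends under partial beta-catenin knockdown
and cAMP inhibition, body-size scaling with fragment-size failure scans,
geometric readouts for the 2D cutting scenarios (gradient axes and L-cut
free-end identity), and local one-at-a-time parameter sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .markov import MarkovParams
from .mesh import CutLine, Mesh, build_1d_grid
from .network import NetworkModel, default_network
from .nerve import NerveMapParams, generate_field, production_from_divergence
from .solver import InstabilityError, SolverPolicy
from .surgery import (
    FragmentState,
    SurgeryResult,
    fragment_outcome,
    make_schedule,
    run_schedule,
    scenario_library,
)

__all__ = [
    "ScalingResult",
    "SensitivityResult",
    "classify_lcut_free_end",
    "fragment_size_scan",
    "gradient_axis",
    "run_1d_experiment",
    "scaling_sweep",
    "sensitivity_local",
    "trend_experiment",
]


def run_1d_experiment(
    intervention: str | None = None,
    scenario: str = "five-transverse",
    L: float = 0.012,
    n_cells: int = 100,
    body_plan: str = "1H",
    model: NetworkModel | None = None,
    markov: MarkovParams | None = None,
    policy: SolverPolicy | None = None,
    nerve_params: NerveMapParams | None = None,
):
    """Full 1D pipeline for one intervention and cut scenario.

    Returns ``(SurgeryResult, [OutcomeDistribution per fragment])``.
    """
    mesh = build_1d_grid(L, n_cells)
    params = nerve_params or NerveMapParams(body_plan=body_plan)
    u = generate_field(mesh, params)
    G = production_from_divergence(u, mesh)
    model = model or default_network()
    plan = scenario_library()[scenario]
    res = run_schedule(
        model,
        mesh,
        u,
        G,
        make_schedule(intervention),
        plan.cuts(L),
        policy=policy,
        body_plan=body_plan,
    )
    dists = [fragment_outcome(fs, markov)[0] for fs in res.fragments]
    return res, dists


def trend_experiment(
    intervention: str,
    n_fragments: int = 5,
    L: float = 0.012,
    n_cells: int = 100,
    model: NetworkModel | None = None,
) -> np.ndarray:
    """Per-fragment 2H probability, ordered anterior -> posterior.

    ``intervention`` is an intervention label (or "untreated"); the body is
    cut into ``n_fragments`` equal pieces.
    """
    label = None if intervention in (None, "untreated") else intervention
    fracs = [k / n_fragments for k in range(1, n_fragments)]
    mesh = build_1d_grid(L, n_cells)
    u = generate_field(mesh, NerveMapParams())
    G = production_from_divergence(u, mesh)
    cuts = [CutLine.transverse(f * L, f"cut{i+1}") for i, f in enumerate(fracs)]
    res = run_schedule(
        model or default_network(), mesh, u, G, make_schedule(label), cuts
    )
    return np.array(
        [fragment_outcome(fs)[0].probs["2H"] for fs in res.fragments]
    )


def gradient_axis(fs: FragmentState, species: str = "ERK"):
    """Least-squares linear gradient of a field over a fragment.

    Returns ``(gradient vector, angle to the AP axis in degrees in [0, 90])``.
    """
    pts = fs.mesh.points - fs.mesh.points.mean(axis=0)
    c = fs.state[species]
    A = np.column_stack([np.ones(len(c)), pts])
    coef, *_ = np.linalg.lstsq(A, c, rcond=None)
    g = coef[1:]
    ang = np.degrees(np.arctan2(abs(g[1]), abs(g[0])))
    return g, float(ang)


def classify_lcut_free_end(
    result: SurgeryResult,
    plan,
    markov: MarkovParams | None = None,
) -> dict:
    """Head/tail identity of the free end of an L-cut flap.

    Samples the wound cells of the transverse leg on the flap side (facing
    from the scenario metadata), restricted to the lateral band holding the
    diverted nerve cord, and compares the head score ERK/C1 against the tail
    score bcat/C2 (the Markov sigmoid midpoints).
    """
    markov = markov or MarkovParams()
    facing = plan.meta["free_end_facing"]
    y_lo, y_hi = plan.meta["vnc_band"]
    fs = max(result.fragments, key=lambda f: f.mesh.n_cells)
    cells = fs.fragment.wound_cells("l-transverse", facing)
    y = np.abs(fs.mesh.points[cells, 1])
    band = cells[(y >= y_lo) & (y <= y_hi)]
    if band.size == 0:
        band = cells
    erk = float(fs.state["ERK"][band].mean())
    bcat = float(fs.state["bcat"][band].mean())
    head_score = erk / markov.C1
    tail_score = bcat / markov.C2
    return {
        "identity": "head" if head_score > tail_score else "tail",
        "ERK": erk,
        "bcat": bcat,
        "head_score": head_score,
        "tail_score": tail_score,
    }


@dataclass
class ScalingResult:
    """Per-body-length regeneration summary of the scaling sweep."""

    lengths: list = dc_field(default_factory=list)
    records: dict = dc_field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for L in self.lengths:
            for k, rec in enumerate(self.records[L]["fragments"]):
                rows.append(
                    {
                        "length_m": L,
                        "fragment": k,
                        "modal_class": rec["modal"],
                        "p_1h": rec["p_1h"],
                    }
                )
        return pd.DataFrame(rows)


def scaling_sweep(
    lengths,
    n_fragments: int = 3,
    n_cells: int = 100,
    model: NetworkModel | None = None,
) -> ScalingResult:
    """Initialize, cut and score bodies of different lengths.

    The cell count is held constant so resolution scales with the body, and
    normalized ERK profiles (vs x/L) are recorded to assess gradient scale
    invariance.
    """
    lengths = sorted(lengths)
    model = model or default_network()
    out = ScalingResult(lengths=list(lengths))
    for L in lengths:
        mesh = build_1d_grid(L, n_cells)
        u = generate_field(mesh, NerveMapParams())
        G = production_from_divergence(u, mesh)
        fracs = [k / n_fragments for k in range(1, n_fragments)]
        cuts = [
            CutLine.transverse(f * L, f"cut{i+1}") for i, f in enumerate(fracs)
        ]
        try:
            res = run_schedule(model, mesh, u, G, make_schedule(None), cuts)
        except InstabilityError as err:
            raise RuntimeError(f"solver failed at L = {L} m") from err
        frag_recs = []
        for fs in res.fragments:
            dist, _ = fragment_outcome(fs)
            frag_recs.append(
                {"modal": dist.modal_class, "p_1h": dist.probs["1H"]}
            )
        out.records[L] = {
            "fragments": frag_recs,
            "x_over_L": mesh.points[:, 0] / L,
            "erk_profile": res.pre_cut_state["ERK"].copy(),
            "bcat_profile": res.pre_cut_state["bcat"].copy(),
        }
    return out


def fragment_size_scan(
    fragment_lengths,
    L: float = 0.012,
    n_cells: int = 240,
    center: float = 0.5,
    model: NetworkModel | None = None,
) -> pd.DataFrame:
    """Non-1H probability of a mid-body fragment as its length shrinks.

    Cuts a fragment of each requested length centered at ``center * L`` and
    scores it; small fragments (around a millimeter and below) lose the room
    to re-polarize their gradients and start failing.
    """
    mesh = build_1d_grid(L, n_cells)
    u = generate_field(mesh, NerveMapParams())
    G = production_from_divergence(u, mesh)
    model = model or default_network()
    rows = []
    for ell in fragment_lengths:
        cuts = [
            CutLine.transverse(center * L - ell / 2, "a"),
            CutLine.transverse(center * L + ell / 2, "b"),
        ]
        res = run_schedule(model, mesh, u, G, make_schedule(None), cuts)
        mid = [
            fs
            for fs in res.fragments
            if not fs.fragment.has_head and not fs.fragment.has_tail
        ][0]
        dist, _ = fragment_outcome(mid)
        rows.append(
            {
                "fragment_length_m": ell,
                "n_cells": mid.mesh.n_cells,
                "modal_class": dist.modal_class,
                "p_1h": dist.probs["1H"],
                "p_non_1h": 1.0 - dist.probs["1H"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    """One-at-a-time local sensitivity records."""

    baseline: dict = dc_field(default_factory=dict)
    records: list = dc_field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _sensitivity_metrics(res: SurgeryResult) -> dict:
    """Scalar outputs tracked by the sensitivity analysis: wound-edge ERK and
    bcat of the middle fragment plus its class probabilities."""
    mid = res.fragments[len(res.fragments) // 2]
    dist, wos = fragment_outcome(mid)
    metrics = {f"p_{c}": p for c, p in dist.probs.items()}
    for (lab, facing), rec in sorted(mid.series.items()):
        metrics[f"ERK_{facing}"] = float(rec["ERK"][-1])
        metrics[f"bcat_{facing}"] = float(rec["bcat"][-1])
    return metrics


def sensitivity_local(
    params: list[str],
    factor: float = 0.2,
    scenario: str = "five-transverse",
    L: float = 0.012,
    n_cells: int = 100,
    model: NetworkModel | None = None,
) -> SensitivityResult:
    """Local one-at-a-time sensitivity of the untreated pipeline.

    Each parameter (dotted path into the network) is multiplied by
    ``1 +/- factor`` in turn and the scenario re-run; deltas are recorded
    against the baseline.  A perturbation that destabilizes the solver is
    recorded as failed rather than raised.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    base_model = (model or default_network()).copy()
    mesh = build_1d_grid(L, n_cells)
    u = generate_field(mesh, NerveMapParams())
    G = production_from_divergence(u, mesh)
    cuts = scenario_library()[scenario].cuts(L)

    def run(m):
        return run_schedule(m, mesh, u, G, make_schedule(None), cuts)

    baseline = _sensitivity_metrics(run(base_model))
    out = SensitivityResult(baseline=baseline)
    for path in params:
        for direction in (1 + factor, 1 - factor):
            m = base_model.copy()
            m.set_param(path, m.get_param(path) * direction)
            rec = {"parameter": path, "factor": direction}
            try:
                metrics = _sensitivity_metrics(run(m))
                rec["failed"] = False
                for k, v in metrics.items():
                    rec[f"delta_{k}"] = v - baseline[k]
            except (InstabilityError, ValueError) as err:
                rec["failed"] = True
                rec["error"] = str(err)
            out.records.append(rec)
    return out
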