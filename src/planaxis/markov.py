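"""Markov chain model of regeneration outcomes.

A blastema at a wound starts in state B and can transition to head (H) or
tail (T).  The forward rates are sigmoid functions of the wound-edge
concentrations of the instructive morphogens,

    a_BH = 1 / (1 + exp(-(C_ERK  - C1) / k1)),   C1 = 0.75 nM, k1 = 0.05 nM
    a_BT = 1 / (1 + exp(-(C_bcat - C2) / k2)),   C2 = 300 nM,  k2 = 40 nM

with small constant reverse rates b_HB = b_TB = 5e-3.  All rates are per
hour.  The state probabilities obey

    dp_H/dt = (a_BH p_B - b_HB p_H) C_wound
    dp_T/dt = (a_BT p_B - b_TB p_T) C_wound
    p_B     = 1 - p_H - p_T

where C_wound is a prescribed transient wound-signal pulse

    C_wound(t) = 1 - 1 / (1 + exp(-(t - t_f) / g)),  t_f = 90 h, g = 12 h

that closes the window in which blastema identity can change (interventions
later than ~72 h after amputation have little effect).

Fragment-level heteromorphosis frequencies come from multiplying the end
probabilities of the (at most two) scored ends of a fragment: pre-existing
terminal heads/tails are terminally differentiated and contribute certain
outcomes; each cut line contributes its integrated (p_H, p_T, p_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkovParams",
    "OutcomeDistribution",
    "WoundOutcome",
    "OUTCOME_CLASSES",
    "fragment_distribution",
    "integrate_outcome",
    "transition_rate_head",
    "transition_rate_tail",
    "wound_signal",
]

OUTCOME_CLASSES = ("2H", "1H", "0H", "0T", "2T", "00")

#: head/tail/failure triple of a terminally differentiated original head
TERMINAL_HEAD = np.array([1.0, 0.0, 0.0])
TERMINAL_TAIL = np.array([0.0, 1.0, 0.0])


@dataclass
class MarkovParams:
    """Sigmoid midpoints/widths (nM), reverse rates (1/h) and wound-pulse
    timing (h) of the regeneration Markov chain."""

    C1: float = 0.75
    kappa1: float = 0.05
    C2: float = 300.0
    kappa2: float = 40.0
    beta_HB: float = 5.0e-3
    beta_TB: float = 5.0e-3
    g: float = 12.0
    t_f: float = 90.0

    def __post_init__(self):
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("sigmoid widths must be positive")
        if self.beta_HB < 0 or self.beta_TB < 0:
            raise ValueError("reverse rates must be non-negative")
        if self.t_f <= 0 or self.g <= 0:
            raise ValueError("wound-pulse parameters must be positive")


def _sigmoid(z):
    # overflow-safe logistic
    z = np.clip(z, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


def transition_rate_head(C_ERK, p: MarkovParams):
    """Blastema -> head rate (1/h) from wound-edge ERK concentration."""
    return _sigmoid((np.asarray(C_ERK, dtype=float) - p.C1) / p.kappa1)


def transition_rate_tail(C_bcat, p: MarkovParams):
    """Blastema -> tail rate (1/h) from wound-edge beta-catenin."""
    return _sigmoid((np.asarray(C_bcat, dtype=float) - p.C2) / p.kappa2)


def wound_signal(t_hours, p: MarkovParams):
    """Transient wound-signal pulse gating identity transitions.

    Monotonically decreasing from ~1 at wounding to ~0 well past ``t_f``;
    exactly 0.5 at ``t = t_f``.
    """
    t = np.asarray(t_hours, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since cut must be non-negative")
    return 1.0 - _sigmoid((t - p.t_f) / p.g)


@dataclass
class WoundOutcome:
    """Head/tail/failure probability trajectory at one cut-line wound."""

    t_hours: np.ndarray
    p_H: np.ndarray
    p_T: np.ndarray

    @property
    def p_B(self) -> np.ndarray:
        return 1.0 - self.p_H - self.p_T

    @property
    def final(self) -> np.ndarray:
        return np.array([self.p_H[-1], self.p_T[-1], self.p_B[-1]])


def integrate_outcome(
    t_hours: np.ndarray,
    erk_series: np.ndarray,
    bcat_series: np.ndarray,
    p: MarkovParams,
) -> WoundOutcome:
    """Integrate the outcome ODEs over a wound-edge concentration series.

    The series is sampled on the transport solver's time grid (hours since
    the cut); integration is explicit Euler on the same grid, and the
    normalization p_H + p_T + p_B = 1 holds by construction.
    """
    t = np.asarray(t_hours, dtype=float)
    erk = np.asarray(erk_series, dtype=float)
    bc = np.asarray(bcat_series, dtype=float)
    if not (len(t) == len(erk) == len(bc)):
        raise ValueError("time and concentration series must align")
    if len(t) < 2:
        raise ValueError("need at least two samples to integrate")
    a_H = transition_rate_head(erk, p)
    a_T = transition_rate_tail(bc, p)
    if np.any((a_H < 0) | (a_H > 1) | (a_T < 0) | (a_T > 1)):
        raise ValueError("transition rates must lie in [0, 1]")
    cw = wound_signal(t, p)
    p_H = np.zeros_like(t)
    p_T = np.zeros_like(t)
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        p_B = 1.0 - p_H[i] - p_T[i]
        dH = (a_H[i] * p_B - p.beta_HB * p_H[i]) * cw[i]
        dT = (a_T[i] * p_B - p.beta_TB * p_T[i]) * cw[i]
        p_H[i + 1] = p_H[i] + dt * dH
        p_T[i + 1] = p_T[i] + dt * dT
    return WoundOutcome(t, p_H, p_T)


#: map of (end-1 state, end-2 state) -> heteromorphosis class, where states
#: are H, T, B and end-1 is the anterior end of the fragment
_PAIR_CLASS = {
    ("H", "T"): "1H",
    ("T", "H"): "1H",  # reversed-orientation one-headed regenerate
    ("H", "H"): "2H",
    ("T", "T"): "2T",
    ("H", "B"): "0T",
    ("B", "H"): "0T",
    ("T", "B"): "0H",
    ("B", "T"): "0H",
    ("B", "B"): "00",
}


@dataclass
class OutcomeDistribution:
    """Class probabilities for one fragment, with the probability that a 1H
    outcome is reversed (head at the original-posterior end)."""

    probs: dict = field(default_factory=dict)
    p_reversed_1h: float = 0.0

    @property
    def modal_class(self) -> str:
        return max(OUTCOME_CLASSES, key=lambda c: self.probs.get(c, 0.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.probs.get(c, 0.0) for c in OUTCOME_CLASSES])


def fragment_distribution(
    ends: list,
) -> OutcomeDistribution:
    """Combine the scored ends of a fragment into class probabilities.

    ``ends`` holds one or two (p_H, p_T, p_B) triples ordered anterior ->
    posterior; a terminal (uncut) original head or tail is passed as
    ``TERMINAL_HEAD`` / ``TERMINAL_TAIL``.  A single-ended fragment (one cut,
    other end terminal head or tail supplied by the caller) must still pass
    both triples; passing a single end scores that end alone against an
    implicitly intact body and is rejected.
    """
    if len(ends) != 2:
        raise ValueError("a scored fragment has exactly two ends")
    ends = [np.asarray(e, dtype=float) for e in ends]
    for e in ends:
        if e.shape != (3,):
            raise ValueError("each end is a (p_H, p_T, p_B) triple")
        if abs(e.sum() - 1.0) > 1e-9 or np.any(e < -1e-12):
            raise ValueError("end probabilities must be a distribution")
    states = ("H", "T", "B")
    probs = dict.fromkeys(OUTCOME_CLASSES, 0.0)
    p_rev = 0.0
    for i, si in enumerate(states):
        for j, sj in enumerate(states):
            pr = ends[0][i] * ends[1][j]
            cls = _PAIR_CLASS[(si, sj)]
            probs[cls] += pr
            if (si, sj) == ("T", "H"):
                p_rev += pr
    return OutcomeDistribution(probs=probs, p_reversed_1h=p_rev)
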