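"""Scoring and classification of MR solutions.

Two complementary assessments are implemented. The Q factor is an empirical
quality score computed from the final refinement R statistics,

    Q = exp(-[(1 - w) * Rfree_final + (w / 2) * R_final]),    w = 0.75,

mapped to a solution probability by a logistic in Q calibrated so the band
edges Q = 0.75 / Q = 0.25 correspond to P = 0.99 / 0.01: above the band a
solution is taken as definitely correct, below it as very unlikely. The
second assessment classifies the Rfree trajectory of a restrained-refinement
run as good / marginal / poor from the final value and how much it fell.
Final ranking is by final Rfree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "RefinementTrace",
    "ScoringConfig",
    "SolutionScore",
    "q_factor",
    "p_solution",
    "classify_mrbump",
    "rank_solutions",
    "score_solution",
]


@dataclass
class RefinementTrace:
    """Per-cycle R and Rfree values of one refinement run (fractions)."""

    r: list[float]
    rfree: list[float]
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.r = [float(x) for x in self.r]
        self.rfree = [float(x) for x in self.rfree]
        if len(self.r) != len(self.rfree) or len(self.r) < 1:
            raise ValueError("r and rfree must have equal length >= 1")
        if any(not 0 <= x <= 1 for x in self.r + self.rfree):
            raise ValueError("R values must lie in [0, 1]")
        # physically suspicious but permitted
        self.flagged = any(x > 0.75 for x in self.r + self.rfree)

    @property
    def n_cycles(self) -> int:
        return len(self.r)

    @property
    def r_initial(self) -> float:
        return self.r[0]

    @property
    def r_final(self) -> float:
        return self.r[-1]

    @property
    def rfree_initial(self) -> float:
        return self.rfree[0]

    @property
    def rfree_final(self) -> float:
        return self.rfree[-1]


@dataclass
class ScoringConfig:
    """All scoring constants in one place.

    ``w`` weights R against Rfree inside the Q exponent. The trajectory
    classification compares the final Rfree and its total drop against the
    (inclusive) thresholds below.
    """

    w: float = 0.75
    q_definite: float = 0.75
    q_unlikely: float = 0.25
    p_edge: float = 0.99          # P at q_definite (1 - p_edge at q_unlikely)
    good_rfree_max: float = 0.45
    good_drop_min: float = 0.05
    marginal_rfree_max: float = 0.52
    marginal_drop_min: float = 0.02
    report_prob_cap: float = 0.990

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        if not self.q_unlikely < self.q_definite:
            raise ValueError("q_unlikely must be below q_definite")


@dataclass
class SolutionScore:
    q: float
    p: float
    mrbump_class: str
    rank: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1 or not 0 <= self.p <= 1:
            raise ValueError("q and p must lie in [0, 1]")


def q_factor(trace: RefinementTrace, config: ScoringConfig | None = None) -> float:
    """Empirical solution quality from the final R and Rfree of a trace.

    Strictly decreasing in both final statistics; bounded in (0, 1].
    """
    config = config or ScoringConfig()
    if not trace.rfree:
        raise ValueError("Rfree required")
    w = config.w
    return math.exp(-((1.0 - w) * trace.rfree_final + (w / 2.0) * trace.r_final))


def p_solution(q: float, config: ScoringConfig | None = None) -> float:
    """Probability that a solution with quality ``q`` is correct.

    Logistic in q, centred on the middle of the [q_unlikely, q_definite]
    band and scaled so the band edges map to ``p_edge`` and ``1 - p_edge``.
    Monotone non-decreasing in q; never capped here (display capping is the
    report layer's job).
    """
    config = config or ScoringConfig()
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    mid = 0.5 * (config.q_definite + config.q_unlikely)
    width = config.q_definite - config.q_unlikely
    k = 2.0 * math.log(config.p_edge / (1.0 - config.p_edge)) / width
    return 1.0 / (1.0 + math.exp(-k * (q - mid)))


def q_band(q: float, config: ScoringConfig | None = None) -> str:
    """'definite' above the band, 'unlikely' below it, 'intermediate' inside."""
    config = config or ScoringConfig()
    if q > config.q_definite:
        return "definite"
    if q < config.q_unlikely:
        return "unlikely"
    return "intermediate"


def classify_mrbump(trace: RefinementTrace, config: ScoringConfig | None = None) -> str:
    """Classify a refinement trajectory as ``good``/``marginal``/``poor``.

    The assessment uses the final Rfree and its change over the run:
    good when the final value is at or below ``good_rfree_max`` and the
    total fall is at least ``good_drop_min``; marginal under the weaker
    thresholds; poor otherwise. Boundaries are inclusive ("at least as good
    as the threshold"), so a flat high trace can never classify good.
    """
    config = config or ScoringConfig()
    if trace.n_cycles < 2:
        raise ValueError("classification needs at least 2 cycles")
    final = trace.rfree_final
    drop = trace.rfree_initial - final
    if final <= config.good_rfree_max and drop >= config.good_drop_min:
        return "good"
    if final <= config.marginal_rfree_max and drop >= config.marginal_drop_min:
        return "marginal"
    return "poor"


def score_solution(trace: RefinementTrace, config: ScoringConfig | None = None) -> SolutionScore:
    config = config or ScoringConfig()
    q = q_factor(trace, config)
    return SolutionScore(
        q=q,
        p=p_solution(q, config),
        mrbump_class=classify_mrbump(trace, config) if trace.n_cycles >= 2 else "poor",
    )


def rank_solutions(
    scores: Iterable[tuple[str, RefinementTrace, SolutionScore]],
) -> list[tuple[str, RefinementTrace, SolutionScore]]:
    """Rank by ascending final Rfree; ties by Q descending, then model index.

    Returns a new list with ``rank`` assigned 1..n.
    """
    entries = list(scores)
    entries.sort(key=lambda e: (e[1].rfree_final, -e[2].q, e[0]))
    out = []
    for rank, (idx, trace, score) in enumerate(entries, start=1):
        out.append((idx, trace, SolutionScore(score.q, score.p, score.mrbump_class, rank)))
    return out
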