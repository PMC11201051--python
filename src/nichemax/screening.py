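"""Two-stage environmental-variable screening.

Stage 1 repeatedly fits the niche model and removes every variable whose
percent contribution is (numerically) zero, until all survivors
contribute.  Stage 2 computes pairwise Pearson correlations of the
surviving variables at the presence points and, for every pair with
|r| above the threshold (default 0.8), discards the member with the
smaller contribution.  Pairs are processed in decreasing |r| so the
outcome is deterministic; a variable with zero variance at the presence
points is dropped outright as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import GridStack, extract_values
from .maxent import DegenerateModelError, TrainConfig, fit
from .occurrence import OccurrenceSet

EPSILON_ZERO = 1e-6  # percentage points; "zero contribution" cut-off


@dataclass
class ScreeningRound:
    variables_in: list[str]
    contributions: pd.Series
    dropped: list[str]


@dataclass
class ScreeningReport:
    """Audit trail of both screening stages."""

    rounds: list[ScreeningRound] = field(default_factory=list)
    correlation_matrix: pd.DataFrame | None = None
    correlation_decisions: list[dict] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)
    final_contributions: pd.Series | None = None

    def rounds_frame(self) -> pd.DataFrame:
        rows = []
        for i, rnd in enumerate(self.rounds):
            for v in rnd.variables_in:
                rows.append({"round": i, "variable": v,
                             "percent_contribution": rnd.contributions[v],
                             "dropped": v in rnd.dropped})
        return pd.DataFrame(rows)

    def decision_log(self) -> list[dict]:
        log = []
        for i, rnd in enumerate(self.rounds):
            for v in rnd.dropped:
                log.append({"stage": "zero_contribution", "round": i,
                            "variable": v,
                            "contribution": float(rnd.contributions[v])})
        log.extend(self.correlation_decisions)
        return log


def drop_zero_contribution(stack: GridStack, occ: OccurrenceSet,
                           config: TrainConfig,
                           epsilon_zero: float = EPSILON_ZERO
                           ) -> ScreeningReport:
    """Iteratively remove zero-contribution variables.

    Each round fits the model on the current variable set and drops all
    variables contributing less than ``epsilon_zero`` percent; the loop
    ends when nothing is dropped or one variable remains.  Raises
    :class:`DegenerateModelError` if every variable is zero in round 1.
    """
    if len(stack.names) < 2:
        raise ValueError("screening needs at least 2 variables")
    report = ScreeningReport()
    current = list(stack.names)
    while True:
        model, _ = fit(stack, occ, config, variables=current)
        contrib = model.percent_contribution()
        dropped = [v for v in current if contrib[v] < epsilon_zero]
        if len(dropped) == len(current):
            if not report.rounds:
                raise DegenerateModelError(
                    "all variables have zero contribution in round 1")
            dropped = []  # keep the last surviving set rather than emptying it
        report.rounds.append(ScreeningRound(list(current), contrib, dropped))
        if not dropped or len(current) - len(dropped) <= 1:
            current = [v for v in current if v not in dropped] or current
            break
        current = [v for v in current if v not in dropped]
    report.final_variables = list(current)
    report.final_contributions = report.rounds[-1].contributions[current]
    return report


def correlation_filter(values: pd.DataFrame, contributions: pd.Series,
                       threshold: float = 0.8,
                       report: ScreeningReport | None = None
                       ) -> ScreeningReport:
    """Drop the lower-contribution member of each highly correlated pair.

    ``values`` holds presence-point variable values (one column per
    variable); pairs are visited in decreasing |r| and a decision is
    made only when both members are still alive.  Contribution ties drop
    the variable later in input order.
    """
    report = report or ScreeningReport()
    variables = [c for c in values.columns if c in contributions.index]
    if not variables:
        raise ValueError("no variables shared between values and contributions")
    order = {v: i for i, v in enumerate(variables)}
    alive = dict.fromkeys(variables, True)

    # degenerate variables first: zero variance makes r undefined
    for v in variables:
        if np.std(values[v].to_numpy(dtype=float)) == 0.0:
            alive[v] = False
            report.correlation_decisions.append(
                {"stage": "correlation", "variable": v, "reason": "degenerate"})

    live = [v for v in variables if alive[v]]
    corr = values[live].corr(method="pearson")
    report.correlation_matrix = corr

    pairs = []
    for i, a in enumerate(live):
        for b in live[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                pairs.append((a, b, r))
    pairs.sort(key=lambda p: (-abs(p[2]), order[p[0]], order[p[1]]))

    for a, b, r in pairs:
        if not (alive[a] and alive[b]):
            continue
        ca, cb = float(contributions[a]), float(contributions[b])
        if ca > cb:
            loser = b
        elif cb > ca:
            loser = a
        else:  # tie: drop the later variable in input order
            loser = b if order[b] > order[a] else a
        alive[loser] = False
        report.correlation_decisions.append(
            {"stage": "correlation", "variable": loser, "reason": "collinear",
             "pair": [a, b], "r": r,
             "kept": a if loser == b else b})
    report.final_variables = [v for v in variables if alive[v]]
    report.final_contributions = contributions[report.final_variables]
    return report


def screen_variables(stack: GridStack, occ: OccurrenceSet, config: TrainConfig,
                     threshold: float = 0.8,
                     epsilon_zero: float = EPSILON_ZERO) -> ScreeningReport:
    """Run both screening stages and return the combined report."""
    report = drop_zero_contribution(stack, occ, config, epsilon_zero)
    survivors = report.final_variables
    values, _ = extract_values(stack.subset(survivors), occ)
    contributions = report.final_contributions
    return correlation_filter(values[survivors], contributions, threshold,
                              report=report)
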