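"""Train/test splitting, replicate model runs, and AUC grading.

Model accuracy is judged by the presence-vs-background AUC: the
probability that a random test presence outscores a random background
cell (ties count 1/2).  Replicate runs re-split the occurrences, refit,
and average both the AUC and the logistic suitability maps cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid_io import EnvGrid, GridStack
from .maxent import MaxentModel, TrainConfig, fit_maxent, prepare_training
from .occurrence import OccurrenceSet

#: AUC grading bands, half-open [lo, hi); the top band closes at 1.0
AUC_BANDS = ((0.1, 0.6, "failure"), (0.6, 0.7, "poor"), (0.7, 0.8, "average"),
             (0.8, 0.9, "good"), (0.9, 1.0 + 1e-12, "excellent"))


@dataclass(frozen=True)
class SplitSpec:
    """Replicated random train/test partition of the occurrence set."""

    test_fraction: float = 0.25
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


def split_data(occ: OccurrenceSet, spec: SplitSpec, replicate_index: int
               ) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Disjoint, exhaustive train/test split, deterministic per replicate.

    Test size is floor(test_fraction · n); the remainder trains.
    """
    n = len(occ)
    n_test = int(np.floor(spec.test_fraction * n))
    if n_test < 1 or n - n_test < 1:
        raise ValueError(f"n = {n} too small for a non-empty split at "
                         f"fraction {spec.test_fraction}")
    rng = np.random.default_rng([spec.seed, replicate_index])
    perm = rng.permutation(n)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    df = occ.records
    return (OccurrenceSet(df.iloc[train_idx].reset_index(drop=True)),
            OccurrenceSet(df.iloc[test_idx].reset_index(drop=True)))


def auc(presence_scores, background_scores) -> float:
    """Pairwise AUC: mean over pairs of 1[p > b] + ½·1[p = b].

    Computed via midranks (the Mann–Whitney identity), so it is exact
    and invariant under strictly monotone transforms of all scores.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[:p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def auc_grade(value: float) -> str:
    """Grade label for an AUC value per the conventional bands."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if value < 0.1:
        return "below scale"
    for lo, hi, label in AUC_BANDS:
        if lo <= value < hi:
            return label
    return "excellent"


@dataclass
class EvaluationResult:
    """Per-replicate test AUCs plus the cell-wise mean suitability map."""

    replicate_aucs: list[float]
    mean_map: EnvGrid
    models: list[MaxentModel] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.replicate_aucs))

    @property
    def grade(self) -> str:
        return auc_grade(self.mean_auc)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"replicate": np.arange(len(self.replicate_aucs)),
                           "test_auc": self.replicate_aucs})
        df.attrs["mean_auc"] = self.mean_auc
        df.attrs["grade"] = self.grade
        return df


def replicate_runs(stack: GridStack, occ: OccurrenceSet, config: TrainConfig,
                   spec: SplitSpec, keep_models: bool = False
                   ) -> EvaluationResult:
    """Refit across random splits; report test AUCs and the mean map.

    The background sample (drawn once with ``config.seed``) is shared by
    all replicates and serves as the pseudo-absence set for the test
    AUC.  The downstream suitability map is the arithmetic mean of the
    replicate logistic maps.
    """
    full = prepare_training(stack, occ, config)
    bg_table = full.background
    sum_map = None
    aucs: list[float] = []
    models: list[MaxentModel] = []
    for r in range(spec.replicates):
        train, test = split_data(occ, spec, r)
        data = prepare_training(stack, train, config)
        model = fit_maxent(data.F_pres, data.F_bg, data.space, config)
        test_tab, _ = _extract(stack, test)
        test_scores = model.score_table(test_tab)
        bg_scores = model.score_table(bg_table)
        aucs.append(auc(test_scores, bg_scores))
        grid = model.project(stack)
        sum_map = grid.values if sum_map is None else sum_map + grid.values
        if keep_models:
            models.append(model)
    mean_map = EnvGrid(stack.header, "mean_suitability",
                       sum_map / spec.replicates)
    return EvaluationResult(aucs, mean_map, models)


def _extract(stack: GridStack, occ: OccurrenceSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    from .grid_io import extract_values
    vals, rej = extract_values(stack, occ)
    if vals.empty:
        raise ValueError("no test presences fall on valid cells")
    return vals, rej
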