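"""Full-grid prediction, dual-criterion ranking and consensus selection.

Every analyte's reduced model is interpolated over the full factor grid
(225 conditions for the default space); negative predictions are clamped to
zero.  Conditions are then ranked two ways — by total predicted peak area
summed over analytes, and by the number of analytes for which a condition is
among their top-m (default 3) predicted responses — and the consensus
optimum is the condition of best combined standing in both lists, preferring
smaller total solvent volume among equals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition, FactorSpace, enumerate_grid
from .modeling import FittedModel

__all__ = [
    "PredictionGrid",
    "RankingReport",
    "predict_grid",
    "rank_total_area",
    "rank_top3_counts",
    "consensus_select",
    "ranking_report",
]


@dataclass
class PredictionGrid:
    """Clamped predictions for every (condition, analyte) pair.

    `predicted` and `clamped` are frames with one row per condition (in
    deterministic enumeration order) and one column per analyte.
    """

    conditions: list[Condition]
    predicted: pd.DataFrame
    clamped: pd.DataFrame

    @property
    def analytes(self) -> list[str]:
        return list(self.predicted.columns)

    def totals(self) -> np.ndarray:
        return self.predicted.to_numpy().sum(axis=1)


def predict_grid(
    models: list[FittedModel],
    space: FactorSpace | None = None,
) -> PredictionGrid:
    """Interpolate each model over the full factor grid, clamping negatives."""
    space = space or FactorSpace()
    conditions = enumerate_grid(space)
    pred = {}
    clamp = {}
    for m in models:
        raw = m.predict(conditions)
        clamp[m.analyte] = raw < 0
        pred[m.analyte] = np.maximum(raw, 0.0)
    return PredictionGrid(
        conditions=conditions,
        predicted=pd.DataFrame(pred),
        clamped=pd.DataFrame(clamp),
    )


def rank_total_area(grid: PredictionGrid, k: int = 10) -> list[Condition]:
    """Top-k conditions by total predicted area over analytes.

    Stable descending sort; ties resolve to enumeration order.
    """
    totals = grid.totals()
    order = np.argsort(-totals, kind="stable")
    return [grid.conditions[i] for i in order[:k]]


def _top_m_indices(values: np.ndarray, m: int) -> np.ndarray:
    """Competition-ranked top-m: every index tied with the m-th value is in."""
    if m >= len(values):
        return np.arange(len(values))
    threshold = np.sort(values)[::-1][m - 1]
    return np.flatnonzero(values >= threshold)


def rank_top3_counts(
    grid: PredictionGrid,
    top_m: int = 3,
    k: int = 10,
) -> list[tuple[Condition, int]]:
    """Top-k conditions by how many analytes place them in their own top-m.

    For each analyte the top_m conditions by predicted value are found
    (competition ranking: ties at the m-th place broaden the set); each
    condition's score is the number of analytes selecting it.
    """
    counts = np.zeros(len(grid.conditions), dtype=int)
    vals = grid.predicted.to_numpy()
    for j in range(vals.shape[1]):
        counts[_top_m_indices(vals[:, j], top_m)] += 1
    order = np.argsort(-counts, kind="stable")
    return [(grid.conditions[i], int(counts[i])) for i in order[:k]]


def consensus_select(
    by_total: list[Condition],
    by_counts: list[Condition] | list[tuple[Condition, int]],
    space: FactorSpace | None = None,
) -> Condition:
    """Pick the consensus optimum from the two top lists.

    Conditions present in both lists are ranked by combined standing (sum of
    their positions in each list); among conditions of equal standing the one
    with the smaller total solvent volume (X2 + X4) wins, a practical
    preference for limiting solvent use.
    """
    if not by_total or not by_counts:
        raise ValueError("both ranking lists must be non-empty")
    counts_conds = [c[0] if isinstance(c, tuple) else c for c in by_counts]
    pos_total = {c: i for i, c in reversed(list(enumerate(by_total)))}
    pos_counts = {c: i for i, c in reversed(list(enumerate(counts_conds)))}
    common = [c for c in by_total if c in pos_counts]
    if not common:
        raise ValueError(
            "the two ranking criteria share no conditions in their top lists; "
            "inspect both rankings before selecting an optimum"
        )
    return min(
        common,
        key=lambda c: (
            pos_total[c] + pos_counts[c],
            c.total_solvent_volume,
            pos_total[c],
        ),
    )


def ranking_report(
    grid: PredictionGrid,
    top_m: int = 3,
    k: int = 10,
) -> pd.DataFrame:
    """Per-condition summary: totals, top-m counts, and both rank positions."""
    totals = grid.totals()
    counts = np.zeros(len(grid.conditions), dtype=int)
    vals = grid.predicted.to_numpy()
    for j in range(vals.shape[1]):
        counts[_top_m_indices(vals[:, j], top_m)] += 1
    order_total = np.argsort(-totals, kind="stable")
    order_counts = np.argsort(-counts, kind="stable")
    rank_total = np.empty(len(totals), dtype=int)
    rank_total[order_total] = np.arange(1, len(totals) + 1)
    rank_counts = np.empty(len(counts), dtype=int)
    rank_counts[order_counts] = np.arange(1, len(counts) + 1)
    return pd.DataFrame(
        {
            "ext_solvent": [c.x1 for c in grid.conditions],
            "ext_volume_ul": [c.x2 for c in grid.conditions],
            "disp_solvent": [c.x3 for c in grid.conditions],
            "disp_volume_ul": [c.x4 for c in grid.conditions],
            "total_area": totals,
            "top3_count": counts,
            "rank_total": rank_total,
            "rank_counts": rank_counts,
        }
    )
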