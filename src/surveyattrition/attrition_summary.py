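"""Per-item attrition statistics and the three-phase curve heuristic.

The :class:`AttritionTable` carries, for every analyzed item, the number and
percentage of respondents, skips, and incremental/cumulative dropouts.  All
percentages use the **starter count** as denominator (so item 1 plots at or
near 100%), matching how attrition bar charts and step curves are normally
drawn; pass ``conditional=True`` for denominators relative to the previous
item's respondents.

:func:`estimate_phases` is a labeled *heuristic* segmentation of the
attrition curve into Eysenbach's three phases — a curiosity plateau, an
attrition phase of steep decline, and a stable participation phase — based
on per-item incremental dropout proportions crossing a threshold.  It
formalizes what is usually judged by eye and makes no inferential claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np
import pandas as pd

from surveyattrition.survey_data import (
    SKIPPED,
    CellGrid,
    ResponseMatrix,
    classify_cells,
)


class ConfigError(ValueError):
    """An analysis option refers to something that does not exist."""


@dataclass(frozen=True)
class AttritionTable:
    """Per-item attrition summary; one row per analyzed item.

    Columns of :attr:`table`:

    - ``n_respondents`` / ``pct_respondents`` — subjects answering the item
    - ``n_skips`` / ``pct_skips`` — subjects skipping it (answered later)
    - ``n_incremental_dropouts`` — subjects whose dropout point is the item
    - ``n_cumulative_dropouts`` / ``pct_dropouts`` — dropped at or before it
    """

    table: pd.DataFrame
    n_starters: int
    n_completers: int
    group: Hashable | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class PhaseSegmentation:
    """Heuristic three-phase split of an attrition curve (1-based items).

    ``curiosity_end`` is the last item of the initial plateau,
    ``attrition_end`` the last item of the steep-decline phase, and
    ``stable_rate`` the mean respondent percentage afterwards (NaN when the
    attrition phase runs to the final item).  ``degenerate`` flags curves
    where no item crosses the threshold (all curiosity).
    """

    curiosity_end: int
    attrition_end: int
    stable_rate: float
    threshold: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.curiosity_end <= self.attrition_end:
            raise ValueError("phase boundaries out of order")


def _single_table(rm: ResponseMatrix, grid: CellGrid, conditional: bool,
                  group: Hashable | None = None) -> AttritionTable:
    n_starters = rm.n_subjects
    n_items = rm.n_items
    positions = np.arange(1, n_items + 1)
    n_resp = rm.answered.sum(axis=0).astype(int)
    n_skip = (grid.states == SKIPPED).sum(axis=0).astype(int)
    n_inc = np.array([(grid.dropout_point == q).sum() for q in positions])
    n_cum = np.cumsum(n_inc)
    denom = np.full(n_items, max(n_starters, 1), dtype=float)
    if conditional:
        denom[1:] = np.maximum(n_resp[:-1], 1)
    table = pd.DataFrame(
        {
            "position": positions,
            "item": rm.item_labels,
            "n_respondents": n_resp,
            "pct_respondents": np.round(100 * n_resp / denom, 2),
            "n_skips": n_skip,
            "pct_skips": np.round(100 * n_skip / denom, 2),
            "n_incremental_dropouts": n_inc,
            "n_cumulative_dropouts": n_cum,
            "pct_dropouts": np.round(100 * n_cum / denom, 2),
        }
    )
    return AttritionTable(table, n_starters, int(grid.is_completer.sum()), group)


def summarize_attrition(
    rm: ResponseMatrix,
    by_group: pd.Series | None = None,
    conditional: bool = False,
) -> AttritionTable | dict[Hashable, AttritionTable]:
    """Tabulate per-item respondents, skips, and dropouts.

    Parameters
    ----------
    rm
        A validated response matrix.
    by_group
        Optional per-subject group labels aligned to ``rm.subject_ids``
        (a pandas Series indexed by subject id, or any sequence of length
        ``n_subjects``).  When given, returns a dict of group →
        :class:`AttritionTable`, each with group-specific starter
        denominators so unequal group sizes do not distort comparisons.
    conditional
        Use the previous item's respondent count as the percentage
        denominator instead of the starter count.
    """
    grid = classify_cells(rm)
    if by_group is None:
        return _single_table(rm, grid, conditional)

    if isinstance(by_group, pd.Series):
        missing = [s for s in rm.subject_ids if s not in by_group.index]
        if missing:
            raise ConfigError(
                f"group labels missing for {len(missing)} subjects "
                f"(first: {missing[0]!r})"
            )
        labels = by_group.loc[rm.subject_ids].to_numpy()
    else:
        labels = np.asarray(by_group)
        if len(labels) != rm.n_subjects:
            raise ConfigError("group label vector length != n_subjects")

    out: dict[Hashable, AttritionTable] = {}
    for g in pd.unique(labels):
        mask = labels == g
        sub = ResponseMatrix(
            [s for s, m in zip(rm.subject_ids, mask) if m],
            rm.item_labels,
            rm.answered[mask],
        )
        out[g] = _single_table(sub, classify_cells(sub), conditional, group=g)
    return out


def estimate_phases(at: AttritionTable, threshold: float = 0.05) -> PhaseSegmentation:
    """Heuristic curiosity / attrition / stable segmentation.

    An item belongs to the attrition phase when its incremental dropout
    proportion (of starters) exceeds ``threshold``.  ``curiosity_end`` is
    the last item before the first exceedance; the attrition phase is the
    longest contiguous run of exceedances, bridging single-item gaps;
    ``stable_rate`` is the mean respondent percentage after it.  When no
    item exceeds the threshold the segmentation is degenerate (all
    curiosity) and flagged.
    """
    tab = at.table
    n_items = len(tab)
    if n_items < 3:
        raise ConfigError("phase estimation needs at least 3 items")
    inc_prop = tab["n_incremental_dropouts"].to_numpy() / max(at.n_starters, 1)
    above = inc_prop > threshold
    if not above.any():
        return PhaseSegmentation(n_items, n_items, float("nan"), threshold,
                                 degenerate=True)

    first = int(np.argmax(above)) + 1  # 1-based first exceedance
    # runs of above-threshold items, bridging gaps of exactly one item
    idx = np.flatnonzero(above) + 1
    runs: list[list[int]] = [[int(idx[0])]]
    for j in idx[1:]:
        if j - runs[-1][-1] <= 2:
            runs[-1].append(int(j))
        else:
            runs.append([int(j)])
    best = max(runs, key=lambda r: (r[-1] - r[0] + 1, -r[0]))
    attrition_end = best[-1]
    curiosity_end = max(first - 1, 1)
    if attrition_end < n_items:
        stable_rate = float(tab["pct_respondents"].to_numpy()[attrition_end:].mean())
    else:
        stable_rate = float("nan")
    return PhaseSegmentation(curiosity_end, attrition_end, stable_rate, threshold)
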