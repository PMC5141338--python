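"""Stage-3 contingency analyses of factors associated with dropout.

Two workflows:

- :func:`response_vs_next_dropout` — did a subject's *answer* to item q
  predict whether they answered the next analyzed item?  The outcome is
  the observed answered-indicator at the later item, so a subject who
  merely skipped it counts as "No", exactly as a respondent-count table
  would show.
- :func:`completer_outcome_test` — are completers and noncompleters
  distributed differently on a downstream binary outcome (e.g. obtained
  the screening test the survey addressed)?

Both produce an r x c contingency table tested by Pearson's chi-square
without continuity correction; when any expected cell count falls below 5
a 2 x 2 table falls back to Fisher's exact test (larger sparse tables keep
the chi-square and raise a ``low_expected`` flag, since no exact r x c
test is available here).  Test statistics come from scipy.stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from surveyattrition.survey_data import (
    ResponseMatrix,
    SubjectCovariates,
    classify_cells,
)
from surveyattrition.attrition_summary import ConfigError

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """The contingency table has no variation to test."""


@dataclass(frozen=True)
class ContingencyResult:
    """A tested r x c contingency table.

    ``row_pcts`` are within-row percentages (each row sums to 100 up to
    rounding); ``method`` records whether Pearson's chi-square or Fisher's
    exact test produced ``p_value``; ``min_expected`` is the smallest
    expected cell count under independence, the usual validity check for
    the chi-square approximation.
    """

    table: pd.DataFrame
    row_pcts: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    method: str
    min_expected: float
    low_expected: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Counts and row percentages side by side for export."""
        pct = self.row_pcts.add_suffix(" (%)")
        return pd.concat([self.table, pct], axis=1)


def _test_table(table: pd.DataFrame, correction: bool = False) -> ContingencyResult:
    counts = table.to_numpy(dtype=float)
    if counts.sum() == 0 or (counts.sum(axis=1) == 0).any() or (
        counts.sum(axis=0) == 0
    ).any():
        raise DegenerateTableError("table has an empty row or column margin")
    if min(counts.shape) < 2:
        raise DegenerateTableError("need at least 2 rows and 2 columns")

    expected = stats.contingency.expected_freq(counts)
    min_exp = float(expected.min())
    low = min_exp < 5
    if low and counts.shape == (2, 2):
        _, p = stats.fisher_exact(counts.astype(int))
        chi2, _, dof, _ = stats.chi2_contingency(counts, correction=correction)
        method = "fisher"
        low = False
    else:
        chi2, p, dof, _ = stats.chi2_contingency(counts, correction=correction)
        method = "chi-square"
        if low:
            logger.warning(
                "expected cell count %.2f < 5 in a %dx%d table; chi-square "
                "approximation may be poor", min_exp, *counts.shape
            )
    row_pcts = table.div(table.sum(axis=1), axis=0) * 100
    return ContingencyResult(
        table=table, row_pcts=row_pcts.round(2), statistic=float(chi2),
        df=int(dof), p_value=float(p), method=method,
        min_expected=min_exp, low_expected=low,
    )


def contingency_test(table: pd.DataFrame | np.ndarray,
                     correction: bool = False) -> ContingencyResult:
    """Test an arbitrary counts table (chi-square, Fisher fallback on 2x2)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    return _test_table(table, correction=correction)


def response_vs_next_dropout(
    rm: ResponseMatrix,
    q: int | str,
    responses: pd.Series,
    q_next: int | str | None = None,
    correction: bool = False,
) -> ContingencyResult:
    """Cross-tabulate the answer category at item q against answering q_next.

    Parameters
    ----------
    rm
        Response matrix.
    q
        The earlier item (label or 1-based position).
    responses
        Per-subject answer category at item q, indexed by subject id; a
        category must be defined for every subject who answered q.
        Categories with zero members are dropped with a warning.
    q_next
        The later item; defaults to the item immediately after q.
    """
    from surveyattrition.sequential_glmm import _item_position

    pos_q = _item_position(rm, q)
    pos_next = _item_position(rm, q_next) if q_next is not None else pos_q + 1
    if pos_next <= pos_q:
        raise ConfigError("q_next must come after q in survey order")
    if pos_next > rm.n_items:
        raise ConfigError("q_next is past the final analyzed item")

    answered_q = rm.answered[:, pos_q - 1] == 1
    subj = [s for s, a in zip(rm.subject_ids, answered_q) if a]
    missing = [s for s in subj if s not in responses.index]
    if missing:
        raise ConfigError(
            f"{len(missing)} subjects answered item {q!r} but have no "
            f"response category (first: {missing[0]!r})"
        )
    cats = responses.loc[subj]
    answered_next = pd.Series(
        rm.answered[answered_q, pos_next - 1] == 1, index=subj
    ).map({True: "Yes", False: "No"})

    table = pd.crosstab(cats, answered_next)
    for col in ("Yes", "No"):
        if col not in table.columns:
            table[col] = 0
    table = table[["Yes", "No"]]
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        logger.warning("dropping %d empty response categories", len(empty))
        table = table.drop(index=empty)
    table.index.name = f"response at {rm.item_labels[pos_q - 1]}"
    table.columns.name = f"answered {rm.item_labels[pos_next - 1]}"
    return _test_table(table, correction=correction)


def completer_outcome_test(
    rm: ResponseMatrix,
    covs: SubjectCovariates,
    outcome: str,
    correction: bool = False,
) -> ContingencyResult:
    """2 x 2 test of completion status against a binary outcome.

    A completer is a subject whose last answered item is the final
    analyzed item.  Raises :class:`DegenerateTableError` when the outcome
    (or completion status) is constant.
    """
    aligned = covs.aligned_to(rm)
    if outcome not in aligned.columns:
        raise ConfigError(f"unknown outcome column {outcome!r}")
    out = aligned[outcome]
    if out.isna().any():
        raise ConfigError(f"outcome {outcome!r} has missing values")
    grid = classify_cells(rm)
    status = pd.Series(
        np.where(grid.is_completer, "completer", "noncompleter"),
        index=aligned.index, name="completion",
    )
    table = pd.crosstab(status, out)
    if table.shape[1] < 2:
        raise DegenerateTableError(f"outcome {outcome!r} is constant")
    if table.shape[0] < 2:
        raise DegenerateTableError("all subjects have the same completion status")
    return _test_table(table, correction=correction)
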