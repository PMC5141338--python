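"""Data model, file I/O, and answered/skip/dropout cell semantics.

A survey response dataset is a binary subjects × ordered-items indicator
matrix: ``answered[i, q] = 1`` when subject *i* answered analyzed item *q*.
Items are indexed by position in the analyzed sequence (1-based in all
user-facing output); conditional/branched items are expected to be excluded
by the caller before loading, and a label map preserves the survey's
original question names.

Every not-answered cell is classified as either a **skip** (an answered
item exists strictly later for that subject) or a **dropout** (no answered
item at or after that position).  The **dropout point** is
``last_answered + 1``; a completer's dropout point is ``n_items + 1``.
Subjects who answered nothing never started the survey (nonresponse, not
dropout attrition) and are excluded at load time with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANSWERED = 1
SKIPPED = 2
DROPPED = 3

STATE_NAMES = {ANSWERED: "answered", SKIPPED: "skipped", DROPPED: "dropped"}


class FormatError(ValueError):
    """The input file could not be parsed in the requested layout."""


class DataError(ValueError):
    """The file parsed but its content violates the data contract."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Validated per-subject, per-ordered-item answered indicators.

    Attributes
    ----------
    subject_ids : list
        Unique subject identifiers, order preserved from the source.
    item_labels : list of str
        Analyzed item labels in survey order (e.g. ``["Q1", "Q2", "Q4"]``).
    answered : ndarray of shape (n_subjects, n_items)
        0/1 indicator, no missing codes.
    n_excluded : int
        Subjects dropped at load time because they answered no item.
    """

    subject_ids: list
    item_labels: list[str]
    answered: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.answered, dtype=np.int8)
        if arr.ndim != 2:
            raise DataError("answered must be a 2-D subjects x items array")
        if arr.shape != (len(self.subject_ids), len(self.item_labels)):
            raise DataError(
                f"answered shape {arr.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.item_labels)} items"
            )
        if not np.isin(arr, (0, 1)).all():
            raise DataError("answered must contain only 0/1")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataError("subject_ids must be unique")
        if arr.shape[0] and not (arr.sum(axis=1) >= 1).all():
            raise DataError("every subject must have at least one answered item")
        object.__setattr__(self, "answered", arr)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame, one row per subject, indexed by subject id."""
        return pd.DataFrame(
            self.answered, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.item_labels,
        )


@dataclass(frozen=True)
class CellGrid:
    """Classified cell states plus derived per-subject indices.

    ``states`` holds ANSWERED / SKIPPED / DROPPED codes per cell.
    ``last_answered`` and ``dropout_point`` are 1-based item positions;
    ``dropout_point = n_items + 1`` marks a completer.
    """

    states: np.ndarray
    last_answered: np.ndarray
    dropout_point: np.ndarray
    n_items: int

    @property
    def is_completer(self) -> np.ndarray:
        return self.dropout_point == self.n_items + 1

    def to_long_frame(self, rm: ResponseMatrix) -> pd.DataFrame:
        """Canonical long-form export: subject_id, item, position, state."""
        n_subj, n_items = self.states.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(rm.subject_ids, n_items),
                "item": np.tile(rm.item_labels, n_subj),
                "position": np.tile(np.arange(1, n_items + 1), n_subj),
                "state": [STATE_NAMES[s] for s in self.states.ravel()],
            }
        )


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject attributes (group labels, demographics, outcomes).

    Rows not matching any subject in the companion :class:`ResponseMatrix`
    are dropped with a warning at alignment time.
    """

    table: pd.DataFrame  # indexed by subject_id

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_column: str = "subject_id") -> "SubjectCovariates":
        if id_column not in df.columns:
            raise DataError(f"covariate table lacks id column {id_column!r}")
        if df[id_column].duplicated().any():
            raise DataError("duplicate subject_id in covariate table")
        return cls(df.set_index(id_column))

    def aligned_to(self, rm: ResponseMatrix) -> pd.DataFrame:
        """Covariates reindexed to the response matrix's subjects."""
        missing = [s for s in rm.subject_ids if s not in self.table.index]
        if missing:
            raise DataError(
                f"{len(missing)} subjects lack covariate rows (first: {missing[0]!r})"
            )
        extra = self.table.index.difference(pd.Index(rm.subject_ids))
        if len(extra):
            logger.warning(
                "dropping %d covariate rows with no matching subject", len(extra)
            )
        return self.table.loc[rm.subject_ids]


def _coerce_answered(series: pd.Series, answered_codes: Iterable) -> np.ndarray:
    """Map raw response codes to 0/1, raising on unknown codes."""
    answered_set = set(answered_codes)
    not_answered = {0, "0", "no", "n", False}
    vals = series.to_numpy()
    out = np.empty(len(vals), dtype=np.int8)
    for i, v in enumerate(vals):
        if pd.isna(v):
            out[i] = 0
        elif v in answered_set:
            out[i] = 1
        elif v in not_answered:
            out[i] = 0
        else:
            raise DataError(f"unknown response code {v!r}")
    return out


def load_responses(
    path: str | Path,
    layout: str = "wide",
    answered_codes: Iterable = (1, "1", "yes", "y", True),
    id_column: str | None = None,
    sep: str | None = None,
) -> ResponseMatrix:
    """Load a delimited text file of item-level responses.

    Parameters
    ----------
    path
        CSV/TSV file.  The delimiter is autodetected from the extension
        (``.tsv`` → tab) unless ``sep`` is given.
    layout
        ``"wide"`` — one row per subject; the first column (or
        ``id_column``) is the subject id and every other column is an item
        in survey order.  ``"long"`` — columns ``subject_id, item_index,
        answered`` (an ``item_label`` column is honored if present); absent
        (subject, item) pairs are treated as not answered.
    answered_codes
        Values counting as "answered"; any other non-null, non-zero code
        raises :class:`DataError` naming the code.

    Subjects with zero answered items are excluded and counted in
    ``n_excluded`` (a log record is emitted).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path} is empty")

    if layout == "wide":
        idc = id_column or df.columns[0]
        if idc not in df.columns:
            raise FormatError(f"id column {idc!r} not found")
        items = [c for c in df.columns if c != idc]
        if not items:
            raise FormatError("wide layout needs at least one item column")
        answered = np.column_stack(
            [_coerce_answered(df[c], answered_codes) for c in items]
        )
        subject_ids = df[idc].tolist()
        if len(set(subject_ids)) != len(subject_ids):
            raise DataError("duplicate subject rows in wide layout")
    elif layout == "long":
        required = {"subject_id", "item_index", "answered"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"long layout needs columns {sorted(required)}; got {list(df.columns)}"
            )
        if df.duplicated(["subject_id", "item_index"]).any():
            raise DataError("duplicate (subject, item) pairs in long layout")
        df = df.copy()
        df["answered"] = _coerce_answered(df["answered"], answered_codes)
        wide = (
            df.pivot(index="subject_id", columns="item_index", values="answered")
            .sort_index(axis=1)
            .fillna(0)
            .astype(np.int8)
        )
        if "item_label" in df.columns:
            label_map = (
                df.drop_duplicates("item_index").set_index("item_index")["item_label"]
            )
            items = [str(label_map.get(ix, f"item{ix}")) for ix in wide.columns]
        else:
            items = [f"item{ix}" for ix in wide.columns]
        answered = wide.to_numpy()
        subject_ids = wide.index.tolist()
    else:
        raise FormatError(f"unknown layout {layout!r}")

    keep = np.asarray(answered).sum(axis=1) >= 1
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "excluded %d subject(s) with zero answered items (never started)",
            n_excluded,
        )
    subject_ids = [s for s, k in zip(subject_ids, keep) if k]
    return ResponseMatrix(subject_ids, [str(c) for c in items], answered[keep], n_excluded)


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    """Write a wide-layout CSV round-trippable through :func:`load_responses`."""
    rm.to_frame().to_csv(path)


def classify_cells(rm: ResponseMatrix) -> CellGrid:
    """Partition every cell into answered / skipped / dropped.

    For subject *i* with last answered position ``L`` (1-based):
    ``dropout_point = L + 1``; not-answered cells at positions < ``L`` are
    SKIPPED, all cells at positions ≥ ``dropout_point`` are DROPPED.  The
    classification is deterministic and independent of subject order.
    """
    ans = rm.answered
    n_subj, n_items = ans.shape
    positions = np.arange(1, n_items + 1)
    # max over answered positions; every subject has >= 1 answered item
    last_answered = (ans * positions).max(axis=1).astype(np.int64)
    dropout_point = last_answered + 1

    states = np.full_like(ans, DROPPED, dtype=np.int8)
    states[ans == 1] = ANSWERED
    skip_mask = (ans == 0) & (positions[None, :] < last_answered[:, None])
    states[skip_mask] = SKIPPED
    return CellGrid(states, last_answered, dropout_point, n_items)
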