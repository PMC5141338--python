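"""Attrition figures: bar charts, stacked skip charts, and step curves.

Four figure families, all driven solely by :class:`AttritionTable` or
survival outputs so that every number shown is also available as a
coordinate table:

- ``respondents_pct`` / ``dropouts_count`` / ``dropouts_pct`` — per-item
  bar charts;
- ``stacked_skips`` — skip percentages shaded on top of respondent bars;
- ``grouped`` — side-by-side group bars (percentage scale by default,
  since raw counts mislead when group sizes differ);
- ``attrition_curve`` — a survival-type step function of the respondent
  percentage that, unlike a true survival curve, may rise where items are
  skipped; optional vertical lines mark the heuristic phase boundaries;
- ``km_curves`` — per-group Kaplan–Meier curves from the log-rank output.

Figures are deterministic for fixed inputs; ``render`` always returns the
underlying coordinate table and can write it next to the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import matplotlib

matplotlib.use("Agg")  # headless by design; import order matters
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from surveyattrition.attrition_summary import (
    AttritionTable,
    ConfigError,
    PhaseSegmentation,
)
from surveyattrition.attrition_survival import LogRankResult

#: Okabe–Ito color-blind-safe palette (supports up to 8 groups).
PALETTE = ("#0072B2", "#D55E00", "#009E73", "#CC79A7",
           "#F0E442", "#56B4E9", "#E69F00", "#000000")

KINDS = ("respondents_pct", "dropouts_count", "dropouts_pct",
         "stacked_skips", "grouped", "attrition_curve", "km_curves")


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and where to put it."""

    kind: str
    path: str | Path | None = None
    phases: PhaseSegmentation | None = None
    title: str | None = None
    fmt: str = "png"
    grouped_scale: str = "pct"  # or "count"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown plot kind {self.kind!r}; choose from {KINDS}")


def _bar(ax, at: AttritionTable, column: str, ylabel: str) -> pd.DataFrame:
    tab = at.table
    ax.bar(tab["position"], tab[column], color=PALETTE[0])
    ax.set_xticks(tab["position"])
    ax.set_xticklabels(tab["item"], rotation=45, ha="right")
    ax.set_xlabel("item")
    ax.set_ylabel(ylabel)
    return tab[["position", "item", column]].copy()


def step_coordinates(at: AttritionTable) -> pd.DataFrame:
    """Attrition step-curve coordinates: respondent pct held between items."""
    tab = at.table
    return pd.DataFrame(
        {
            "position": np.concatenate([[0], tab["position"].to_numpy()]),
            "pct_respondents": np.concatenate(
                [[100.0], tab["pct_respondents"].to_numpy()]
            ),
        }
    )


def render(
    data: AttritionTable | Mapping[Hashable, AttritionTable] | LogRankResult,
    spec: PlotSpec,
) -> pd.DataFrame:
    """Draw one figure and return its coordinate table.

    ``grouped`` and ``km_curves`` require group-stratified input (a dict of
    per-group tables, or a :class:`LogRankResult`); the other kinds take a
    single pooled :class:`AttritionTable`.  When ``spec.path`` is set the
    figure is written there (format from ``spec.fmt``) and the coordinate
    table beside it as ``<path>.csv``.
    """
    fig, ax = plt.subplots(figsize=(7.5, 4.5), dpi=150)
    try:
        if spec.kind == "km_curves":
            if not isinstance(data, LogRankResult):
                raise ConfigError("km_curves needs a LogRankResult")
            frames = []
            for color, (g, km) in zip(PALETTE, data.km_curves.items()):
                ax.step(km["time"], km["survival"], where="post",
                        label=str(g), color=color)
                f = km.copy()
                f.insert(0, "group", g)
                frames.append(f)
            ax.set_xlabel("item (dropout time)")
            ax.set_ylabel("proportion still participating")
            ax.set_ylim(0, 1.02)
            ax.legend()
            coords = pd.concat(frames, ignore_index=True)
        elif spec.kind == "grouped":
            if not isinstance(data, Mapping):
                raise ConfigError("grouped plot needs a dict of per-group tables")
            if len(data) > len(PALETTE):
                raise ConfigError(f"at most {len(PALETTE)} groups supported")
            sizes = {g: at.n_starters for g, at in data.items()}
            if len(set(sizes.values())) > 1 and spec.grouped_scale == "count":
                import logging

                logging.getLogger(__name__).warning(
                    "group sizes differ (%s); raw-count comparison is skewed — "
                    "consider the default percentage scale", sizes
                )
            col = ("pct_dropouts" if spec.grouped_scale == "pct"
                   else "n_incremental_dropouts")
            groups = list(data)
            width = 0.8 / len(groups)
            frames = []
            for k, (g, color) in enumerate(zip(groups, PALETTE)):
                tab = data[g].table
                ax.bar(tab["position"] + (k - (len(groups) - 1) / 2) * width,
                       tab[col], width=width, label=str(g), color=color)
                f = tab[["position", "item", col]].copy()
                f.insert(0, "group", g)
                frames.append(f)
            ax.set_xticks(data[groups[0]].table["position"])
            ax.set_xticklabels(data[groups[0]].table["item"], rotation=45,
                               ha="right")
            ax.set_ylabel("% dropped out" if spec.grouped_scale == "pct"
                          else "dropouts")
            ax.legend()
            coords = pd.concat(frames, ignore_index=True)
        elif isinstance(data, AttritionTable):
            if spec.kind == "respondents_pct":
                coords = _bar(ax, data, "pct_respondents", "% answering")
                ax.set_ylim(0, 105)
            elif spec.kind == "dropouts_count":
                coords = _bar(ax, data, "n_incremental_dropouts", "dropouts")
            elif spec.kind == "dropouts_pct":
                coords = _bar(ax, data, "pct_dropouts", "% dropped out")
                ax.set_ylim(0, 105)
            elif spec.kind == "stacked_skips":
                tab = data.table
                ax.bar(tab["position"], tab["pct_respondents"],
                       color=PALETTE[0], label="answered")
                ax.bar(tab["position"], tab["pct_skips"],
                       bottom=tab["pct_respondents"], color=PALETTE[1],
                       label="skipped")
                ax.set_xticks(tab["position"])
                ax.set_xticklabels(tab["item"], rotation=45, ha="right")
                ax.set_ylabel("% of starters")
                ax.set_ylim(0, 105)
                ax.legend()
                coords = tab[["position", "item", "pct_respondents",
                              "pct_skips"]].copy()
            elif spec.kind == "attrition_curve":
                coords = step_coordinates(data)
                ax.step(coords["position"], coords["pct_respondents"],
                        where="post", color=PALETTE[0])
                ax.set_xlabel("item")
                ax.set_ylabel("% answering")
                ax.set_ylim(0, 105)
            else:
                raise ConfigError(
                    f"kind {spec.kind!r} needs group-stratified input"
                )
        else:
            raise ConfigError(
                f"input of type {type(data).__name__} does not match kind "
                f"{spec.kind!r}"
            )

        if spec.phases is not None and spec.kind != "km_curves":
            for x, label in ((spec.phases.curiosity_end + 0.5, "curiosity"),
                             (spec.phases.attrition_end + 0.5, "attrition")):
                ax.axvline(x, color="0.4", linestyle="--", linewidth=1)
            ax.set_title(spec.title or
                         "phases: curiosity | attrition | stable (heuristic)")
        elif spec.title:
            ax.set_title(spec.title)

        fig.tight_layout()
        if spec.path is not None:
            path = Path(spec.path)
            fig.savefig(path, format=spec.fmt,
                        metadata=_stable_metadata(spec.fmt))
            coords.to_csv(path.with_suffix(path.suffix + ".csv"), index=False)
    finally:
        plt.close(fig)
    return coords


def _stable_metadata(fmt: str) -> dict | None:
    """Strip volatile metadata so identical inputs give identical bytes."""
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None
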