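"""Equiplot rendering: one dot per social stratum per survey year.

An equiplot shows, for each period, the outcome prevalence in every
category of an ordered SES dimension on a common horizontal axis, with a
line spanning the lowest-to-highest category so that both the level and
the spread (the inequality) are visible at a glance. Complements the
SII/RII, which summarize the gradient in two numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .survey import PrevalenceEstimate

__all__ = ["EquiplotData", "build_equiplot", "render_equiplot"]


@dataclass(frozen=True)
class EquiplotData:
    """Tidy points behind one equiplot panel.

    ``table`` has one row per (year, category): columns ``year``,
    ``category`` (the ordered code), ``rank`` (1..K ascending SES),
    ``label`` (e.g. S1..S6 for schooling, I1..I5 for income) and
    ``prevalence``.
    """

    outcome: str
    dimension: str
    table: pd.DataFrame


def build_equiplot(
    prevalences: list[PrevalenceEstimate],
    outcome: str,
    dimension: str,
) -> EquiplotData:
    """Assemble equiplot points from per-category prevalence estimates.

    ``prevalences`` must contain exactly one estimate per category per
    year for ``outcome``, each with the category code under
    ``cell[dimension]``. Categories are ordered ascending by their code
    (SES rank); a category present in one year but missing in another is
    an error naming it.
    """
    rows = []
    for est in prevalences:
        if est.outcome != outcome or dimension not in est.cell:
            continue
        rows.append(
            {
                "year": est.year,
                "category": est.cell[dimension],
                "prevalence": est.estimate,
            }
        )
    if not rows:
        raise ValueError(
            f"no estimates for outcome {outcome!r} by {dimension!r}"
        )
    table = pd.DataFrame(rows)
    dup = table.duplicated(["year", "category"])
    if dup.any():
        raise ValueError(
            f"duplicate estimates for {table.loc[dup, ['year', 'category']].values.tolist()}"
        )
    categories = sorted(table["category"].unique().tolist())
    years = sorted(table["year"].unique().tolist())
    for year in years:
        present = set(table.loc[table["year"] == year, "category"])
        missing = [c for c in categories if c not in present]
        if missing:
            raise ValueError(
                f"year {year!r} is missing categories {missing} of {dimension!r}"
            )
    rank = {c: i + 1 for i, c in enumerate(categories)}
    prefix = dimension[:1].upper() or "C"
    table["rank"] = table["category"].map(rank)
    table["label"] = table["rank"].map(lambda r: f"{prefix}{r}")
    table = table.sort_values(["year", "rank"]).reset_index(drop=True)
    return EquiplotData(outcome=outcome, dimension=dimension, table=table)


def render_equiplot(data: EquiplotData, path: str | Path) -> Path:
    """Draw the dot-line equiplot as an SVG; the tidy table goes to a
    CSV of the same stem so the plot is testable without image diffs."""
    path = Path(path)
    table = data.table
    years = sorted(table["year"].unique())
    ranks = sorted(table["rank"].unique())
    cmap = plt.get_cmap("viridis", len(ranks))

    fig, ax = plt.subplots(figsize=(7, 1.2 + 0.8 * len(years)))
    for i, year in enumerate(years):
        sub = table[table["year"] == year]
        x = 100 * sub["prevalence"].to_numpy()
        ax.hlines(i, x.min(), x.max(), color="0.6", lw=2, zorder=1)
        ax.scatter(
            x,
            [i] * len(sub),
            c=[cmap(r - 1) for r in sub["rank"]],
            s=70,
            zorder=2,
            edgecolor="white",
        )
    for r in ranks:
        lab = table.loc[table["rank"] == r, "label"].iloc[0]
        ax.scatter([], [], c=[cmap(r - 1)], s=70, label=lab)
    ax.set_yticks(range(len(years)), [str(y) for y in years])
    ax.set_xlabel("prevalence (%)")
    ax.set_ylim(-0.7, len(years) - 0.3)
    ax.set_title(f"{data.outcome} by {data.dimension}")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    table.to_csv(path.with_suffix(".csv"), index=False)
    return path
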