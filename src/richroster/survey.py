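"""Seeded survey layout and printable survey document.

The survey randomizes the roster into panels of photograph cells. The same
seed later drives data entry, so the permutation algorithm is part of the
data contract: a Fisher-Yates shuffle driven by numpy's seeded 64-bit
PCG64 generator, stable across runs and platforms. No bit-compatibility
with any other language's RNG is promised.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_uppercase
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError

__all__ = [
    "SurveySpec",
    "PanelLayout",
    "seeded_order",
    "layout_panels",
    "render_survey",
    "layout_to_frame",
    "layout_from_frame",
]

DEFAULT_HEADER = (
    "Name: ______________  Date: ______________\n"
    "ID: ____  HHID: ____  RID: ____  Game: ____  Order: ____\n"
)


@dataclass(frozen=True)
class SurveySpec:
    """Parameters of one survey build: seed, panel grid, optional explicit
    order (which takes precedence over the seed), and the free-text header
    printed at the top of the document."""

    seed: int = 1
    n_panels: int = 2
    n_rows: int = 4
    n_cols: int = 5
    ordered: tuple[str, ...] | None = None
    header_template: str = DEFAULT_HEADER


@dataclass(frozen=True)
class PanelLayout:
    """Assignment of roster IDs to (panel, row, col) cells.

    Panels are labeled "A", "B", ... in document order; rows and columns
    are 1-based. Every roster ID appears exactly once.
    """

    n_rows: int
    n_cols: int
    panels: tuple[str, ...]
    assignment: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @property
    def ordered_ids(self) -> list[str]:
        """IDs in panel order, row-major — the order the survey prints."""
        return sorted(
            self.assignment,
            key=lambda i: (
                self.panels.index(self.assignment[i][0]),
                self.assignment[i][1],
                self.assignment[i][2],
            ),
        )

    def ids_for_panel(self, panel: str) -> dict[tuple[int, int], str]:
        """Map (row, col) -> ID for one panel's occupied cells."""
        if panel not in self.panels:
            raise ValidationError(f"panel {panel!r} not in layout {self.panels}")
        return {
            (r, c): i
            for i, (p, r, c) in self.assignment.items()
            if p == panel
        }

    def ordered_for(self, order: Sequence[str]) -> list[str]:
        """IDs in the row-major order of the panels as presented to a
        respondent (e.g. order="BA" lists panel B first)."""
        out: list[str] = []
        for panel in order:
            cells = self.ids_for_panel(panel)
            out.extend(cells[rc] for rc in sorted(cells))
        return out


def seeded_order(
    ids: Sequence[str],
    seed: int,
    ordered: Sequence[str] | None = None,
) -> list[str]:
    """Reproducible random order of the roster.

    An explicit ``ordered`` list takes precedence over the seed and is
    returned verbatim after checking it is a permutation of ``ids``.
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("roster is empty")
    if len(set(ids)) != len(ids):
        raise ValidationError("roster contains duplicate IDs")
    if ordered is not None:
        ordered = list(ordered)
        if sorted(ordered) != sorted(ids):
            raise ValidationError("ordered is not a permutation of the roster")
        return ordered
    rng = np.random.default_rng(seed)
    return [ids[i] for i in rng.permutation(len(ids))]


def layout_panels(
    ordered_ids: Sequence[str],
    n_panels: int,
    n_rows: int,
    n_cols: int,
) -> PanelLayout:
    """Fill panels A, B, ... row-major with the ordered roster.

    Trailing cells stay empty; a roster larger than the grid capacity is a
    :class:`CapacityError`.
    """
    ordered_ids = list(ordered_ids)
    capacity = n_panels * n_rows * n_cols
    if len(ordered_ids) > capacity:
        raise CapacityError(len(ordered_ids), capacity)
    if n_panels > len(ascii_uppercase):
        raise ValidationError("at most 26 panels supported")
    panels = tuple(ascii_uppercase[:n_panels])
    assignment: dict[str, tuple[str, int, int]] = {}
    for k, pid in enumerate(ordered_ids):
        panel = panels[k // (n_rows * n_cols)]
        within = k % (n_rows * n_cols)
        assignment[pid] = (panel, within // n_cols + 1, within % n_cols + 1)
    return PanelLayout(n_rows=n_rows, n_cols=n_cols, panels=panels,
                       assignment=assignment)


def layout_to_frame(layout: PanelLayout) -> pd.DataFrame:
    """Tabular form of a layout: columns (id, panel, row, col, position)."""
    rows = []
    for pos, pid in enumerate(layout.ordered_ids, start=1):
        panel, r, c = layout.assignment[pid]
        rows.append({"id": pid, "panel": panel, "row": r, "col": c,
                     "position": pos})
    return pd.DataFrame(rows, columns=["id", "panel", "row", "col", "position"])


def layout_from_frame(frame: pd.DataFrame) -> PanelLayout:
    """Rebuild a :class:`PanelLayout` from its CSV/DataFrame form."""
    panels = tuple(sorted(frame["panel"].unique()))
    assignment = {
        str(row.id): (str(row.panel), int(row.row), int(row.col))
        for row in frame.itertuples()
    }
    return PanelLayout(
        n_rows=int(frame["row"].max()),
        n_cols=int(frame["col"].max()),
        panels=panels,
        assignment=assignment,
    )


def _survey_html(layout: PanelLayout, spec: SurveySpec) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Roster survey</title>",
        "<style>table{border-collapse:collapse;margin:1em 0}"
        "td{border:1px solid #000;padding:8px;min-width:70px;text-align:center}"
        "pre{font-size:12pt}</style></head><body>",
        f"<pre>{html.escape(spec.header_template)}</pre>",
        f"<p>Seed: <b>{spec.seed}</b></p>",
    ]
    for panel in layout.panels:
        cells = layout.ids_for_panel(panel)
        parts.append(f"<h2>Panel {panel}</h2><table>")
        for r in range(1, layout.n_rows + 1):
            parts.append("<tr>")
            for c in range(1, layout.n_cols + 1):
                pid = cells.get((r, c), "")
                label = f"{html.escape(pid)}<br>____" if pid else "&nbsp;"
                parts.append(f"<td>{label}</td>")
            parts.append("</tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)


def render_survey(
    layout: PanelLayout,
    spec: SurveySpec,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the printable survey and its machine-readable layout.

    Produces ``survey.html`` (self-contained; one table per panel in label
    order, header text, and the seed printed so later data entry can be
    matched to this randomization) and ``layout.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    html_path = out_dir / "survey.html"
    html_path.write_text(_survey_html(layout, spec), encoding="utf-8")
    csv_path = out_dir / "layout.csv"
    layout_to_frame(layout).to_csv(csv_path, index=False)
    return {"survey": html_path, "layout": csv_path}


def build_survey(
    ids: Sequence[str],
    spec: SurveySpec,
    out_dir: str | Path,
) -> PanelLayout:
    """Convenience: seeded order -> panel layout -> rendered survey."""
    order = seeded_order(ids, spec.seed, spec.ordered)
    layout = layout_panels(order, spec.n_panels, spec.n_rows, spec.n_cols)
    render_survey(layout, spec, out_dir)
    return layout
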