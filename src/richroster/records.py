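"""Game records: entry, checksum validation, compilation, payouts.

One record = one respondent x one question. For the three RICH economic
games — giving (G), leaving/taking (L), and costly reduction (R) —
allocations are coin counts; custom questions may carry free text.
Records are stored one CSV per focal x game so a re-entry simply
overwrites the erroneous file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConflictError, MissingDataError, RichRosterError, ValidationError
from .survey import DEFAULT_HEADER, PanelLayout

RICH_GAMES = ("G", "L", "R")

PROJECT_DIRS = (
    "RawPhotos",
    "StandardizedPhotos",
    "Survey",
    "Results",
    "ResultsPhotos",
    "ClassifiedPhotos",
)

RECORD_COLUMNS = [
    "PID", "Game", "HHID", "RID", "Name", "Date", "Order", "Seed",
    "AID", "Value",
]

__all__ = [
    "RICH_GAMES",
    "RecordHeader",
    "GameRecord",
    "SummaryRow",
    "PayoutConfig",
    "make_record",
    "write_record",
    "read_record",
    "checksum",
    "compile_game",
    "compile_directory",
    "annotate_classified",
    "calculate_payouts",
    "setup_project",
]


@dataclass(frozen=True)
class RecordHeader:
    """Header block of one record. Only ``pid`` and ``game`` are required;
    ``order`` is the panel sequence as presented to the respondent (e.g.
    "BA" means panel B was shown first) and ``seed`` ties the record back
    to the survey randomization it was collected under."""

    pid: str
    game: str
    hhid: str = ""
    rid: str = ""
    name: str = ""
    date: str = ""
    order: str = ""
    seed: int = 0

    def __post_init__(self):
        if not self.pid or not self.game:
            raise ValidationError("both focal ID and game code are required")


@dataclass(frozen=True)
class GameRecord:
    """One respondent x one question: header plus an ordered allocation per
    roster recipient (coin counts for RICH games, text otherwise)."""

    header: RecordHeader
    allocations: tuple[tuple[str, object], ...]

    @property
    def is_rich(self) -> bool:
        return self.header.game in RICH_GAMES

    def value_for(self, aid: str):
        for a, v in self.allocations:
            if a == aid:
                return v
        raise KeyError(aid)

    def to_frame(self) -> pd.DataFrame:
        h = self.header
        return pd.DataFrame(
            [
                {
                    "PID": h.pid, "Game": h.game, "HHID": h.hhid, "RID": h.rid,
                    "Name": h.name, "Date": h.date, "Order": h.order,
                    "Seed": h.seed, "AID": aid, "Value": value,
                }
                for aid, value in self.allocations
            ],
            columns=RECORD_COLUMNS,
        )


@dataclass(frozen=True)
class SummaryRow:
    """Per-focal compilation summary: self vs. other allocation split, the
    checksum (their sum), and whether it matches the expected coin total."""

    pid: str
    self_total: int
    other_total: int
    checksum: int
    expected: int
    passed: bool


@dataclass(frozen=True)
class PayoutConfig:
    """Which games enter the payout and the per-coin monetary values:
    GV for giving-game coins, LV for leaving-game coins, KV for coins kept
    for self in the reduction game, RV for the reduction inflicted per
    token. ``coins_per_token`` is the purchase price, in kept-value coins,
    of one reduction token (used when refunding tokens aimed at absent
    recipients)."""

    games: str = "GLR"
    GV: float = 1.0
    LV: float = 1.0
    KV: float = 1.0
    RV: float = 1.0
    coins_per_token: float = 1.0
    floor: float | None = None

    def __post_init__(self):
        if not self.games or any(g not in RICH_GAMES for g in self.games):
            raise ValidationError("games must be a nonempty subset of 'GLR'")
        if min(self.GV, self.LV, self.KV, self.RV) < 0:
            raise ValidationError("coin values must be >= 0")


def make_record(
    header: RecordHeader,
    allocations: Mapping[str, object],
    layout: PanelLayout,
    extra_games: Iterable[str] = (),
) -> GameRecord:
    """Build a full record from sparse manual entry.

    Recipients follow the row-major order of the panels as the respondent
    saw them (``header.order``, defaulting to document order). Recipients
    absent from the sparse input get 0 (RICH games) or "" (custom
    questions). RICH allocations must be non-negative integers; unknown
    game codes must have been registered at project setup.
    """
    game = header.game
    if game not in RICH_GAMES and game not in set(extra_games):
        raise ValidationError(
            f"game code {game!r} is neither a RICH game (G/L/R) nor a "
            "registered custom question"
        )
    order = header.order or "".join(layout.panels)
    if sorted(order) != sorted(layout.panels):
        raise ValidationError(
            f"panel order {order!r} is not a permutation of panels {layout.panels}"
        )
    recipients = layout.ordered_for(order)
    unknown = set(allocations) - set(recipients)
    if unknown:
        raise ValidationError(f"allocations reference IDs not on the roster: {sorted(unknown)}")
    rich = game in RICH_GAMES
    rows: list[tuple[str, object]] = []
    for aid in recipients:
        value = allocations.get(aid, 0 if rich else "")
        if rich:
            try:
                value = int(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"RICH games accept only numerical values; got {value!r} for {aid}"
                ) from None
            if value < 0:
                raise ValidationError(f"negative allocation {value} for {aid}")
        rows.append((aid, value))
    return GameRecord(header=header, allocations=tuple(rows))


def record_path(results_dir: str | Path, record: GameRecord) -> Path:
    return Path(results_dir) / f"{record.header.game}_{record.header.pid}.csv"


def write_record(record: GameRecord, results_dir: str | Path) -> Path:
    """Write ``<Game>_<PID>.csv``; rerunning overwrites the prior file,
    which is how erroneous entries are corrected."""
    path = record_path(results_dir, record)
    path.parent.mkdir(parents=True, exist_ok=True)
    record.to_frame().to_csv(path, index=False)
    return path


def read_record(path: str | Path) -> GameRecord:
    frame = pd.read_csv(path, keep_default_na=False)
    first = frame.iloc[0]
    header = RecordHeader(
        pid=str(first["PID"]), game=str(first["Game"]),
        hhid=str(first["HHID"]), rid=str(first["RID"]),
        name=str(first["Name"]), date=str(first["Date"]),
        order=str(first["Order"]), seed=int(first["Seed"] or 0),
    )
    rich = header.game in RICH_GAMES
    allocations = tuple(
        (str(row.AID), int(row.Value) if rich else row.Value)
        for row in frame.itertuples()
    )
    return GameRecord(header=header, allocations=allocations)


def checksum(record: GameRecord, expected_total: int) -> SummaryRow:
    """Sum every allocation (self included) and compare with the number of
    coins issued; a mismatch flags a collection or entry mistake."""
    if not record.is_rich:
        raise ValidationError("checksums apply to RICH (coin-count) games only")
    self_total = sum(
        int(v) for a, v in record.allocations if a == record.header.pid
    )
    total = sum(int(v) for _, v in record.allocations)
    other = total - self_total
    return SummaryRow(
        pid=record.header.pid,
        self_total=self_total,
        other_total=other,
        checksum=total,
        expected=expected_total,
        passed=total == expected_total,
    )


def _is_filled(value) -> bool:
    if isinstance(value, str):
        return value.strip() != ""
    return int(value) != 0


def compile_game(
    records: Sequence[GameRecord],
    expected_total: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compile one game's records into a summary table and an edge list.

    The edge list holds one row per nonzero (or non-empty, for custom
    questions) allocation to another person; self-allocations are carried
    in the summary's self/other split rather than as self-loops. Rows are
    ordered by focal, then by the recipient's position in the record.
    """
    by_focal: dict[str, GameRecord] = {}
    conflicts = []
    for rec in records:
        pid = rec.header.pid
        if pid in by_focal and by_focal[pid] != rec:
            conflicts.append(pid)
        by_focal[pid] = rec
    if conflicts:
        raise ConflictError(
            f"distinct records supplied for the same focal(s): {sorted(set(conflicts))}"
        )

    summary_rows, edge_rows = [], []
    for pid in sorted(by_focal):
        rec = by_focal[pid]
        if rec.is_rich:
            # self/other totals are always reported; the pass verdict
            # needs the issued coin count
            s = checksum(rec, expected_total if expected_total is not None else -1)
            summary_rows.append(
                {"PID": s.pid, "SelfTotal": s.self_total,
                 "OtherTotal": s.other_total, "Checksum": s.checksum,
                 "Expected": s.expected if expected_total is not None else pd.NA,
                 "Pass": s.passed if expected_total is not None else pd.NA}
            )
        for aid, value in rec.allocations:
            if aid != pid and _is_filled(value):
                edge_rows.append({"PID": pid, "AID": aid, "Value": value})
    summary = pd.DataFrame(
        summary_rows,
        columns=["PID", "SelfTotal", "OtherTotal", "Checksum", "Expected", "Pass"],
    )
    edges = pd.DataFrame(edge_rows, columns=["PID", "AID", "Value"])
    return summary, edges


def compile_directory(
    results_dir: str | Path,
    game: str,
    expected_total: int | None = None,
    write: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compile every ``<game>_*.csv`` under ``results_dir`` and, unless
    ``write=False``, store ``<game>_summary.csv`` and ``<game>_edgelist.csv``
    next to them."""
    results_dir = Path(results_dir)
    records = [read_record(p) for p in sorted(results_dir.glob(f"{game}_*.csv"))
               if not p.name.endswith(("_summary.csv", "_edgelist.csv"))]
    summary, edges = compile_game(records, expected_total)
    if write:
        summary.to_csv(results_dir / f"{game}_summary.csv", index=False)
        edges.to_csv(results_dir / f"{game}_edgelist.csv", index=False)
    return summary, edges


def annotate_classified(
    edges: Sequence,
    header: RecordHeader,
    layout: PanelLayout,
    value_map: Mapping[str, object] | None = None,
) -> GameRecord:
    """Convert classifier output into a record with the manual-entry
    schema, so compilation is agnostic to how data were entered.

    ``edges`` are the classifier's per-recipient results (anything with
    ``aid`` and ``color_label`` attributes, or (aid, label) pairs).
    ``value_map`` optionally maps color labels to stored values, e.g.
    ``{"green": 1}`` for a binary single-color question; by default the
    color label itself is stored.
    """
    pairs = []
    for e in edges:
        aid = getattr(e, "aid", None)
        label = getattr(e, "color_label", None)
        if aid is None:
            aid, label = e
        pairs.append((str(aid), str(label)))
    allocations = {
        aid: (value_map[label] if value_map is not None else label)
        for aid, label in pairs
    }
    return make_record(header, allocations, layout,
                       extra_games=() if header.game in RICH_GAMES else (header.game,))


def calculate_payouts(
    compiled: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    config: PayoutConfig,
    respondents: Iterable[str],
) -> pd.DataFrame:
    """Monetary payout per respondent across the configured games.

    Giving (G): every coin on a photograph pays its occupant GV — coins
    kept on the focal's own photo included. Leaving (L): identical
    accounting at LV. Reduction (R): coins the focal kept pay KV each;
    every reduction token placed on a recipient subtracts RV from that
    recipient. Coins or tokens directed at rostered individuals who never
    appear as respondents (absent from ``respondents``) are refunded to
    the donor at the same per-coin value (for reduction tokens, the
    purchase price ``coins_per_token`` valued at KV).
    """
    respondents = sorted(set(respondents))
    present = set(respondents)
    payout = {pid: 0.0 for pid in respondents}

    def credit(pid: str, amount: float):
        payout[pid] = payout.get(pid, 0.0) + amount

    for game in config.games:
        if game not in compiled:
            raise MissingDataError(f"no compiled data for game {game!r}")
        summary, edges = compiled[game]
        per_coin = {"G": config.GV, "L": config.LV}.get(game)
        if game in ("G", "L"):
            for row in summary.itertuples():
                credit(row.PID, per_coin * float(row.SelfTotal))
            for row in edges.itertuples():
                coins = float(row.Value)
                if row.AID in present:
                    credit(row.AID, per_coin * coins)
                else:
                    credit(row.PID, per_coin * coins)  # refund to donor
        else:  # reduction game
            for row in summary.itertuples():
                credit(row.PID, config.KV * float(row.SelfTotal))
            for row in edges.itertuples():
                tokens = float(row.Value)
                if row.AID in present:
                    credit(row.AID, -config.RV * tokens)
                else:
                    credit(row.PID, config.KV * config.coins_per_token * tokens)

    frame = pd.DataFrame(
        {"ID": respondents, "Payout": [payout[p] for p in respondents]}
    )
    if config.floor is not None:
        frame["Payout"] = frame["Payout"].clip(lower=config.floor)
    return frame


def setup_project(
    path: str | Path,
    extra_games: Iterable[str] = (),
    force: bool = False,
) -> Path:
    """Create the project directory tree.

    Results subfolders are made for the three RICH games plus any custom
    questions in ``extra_games``; a default ``Survey/header.txt`` template
    is written. An existing non-empty tree is refused unless ``force``.
    """
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not force:
        raise RichRosterError(
            f"{root} already exists and is not empty; pass force=True to reuse it"
        )
    for name in PROJECT_DIRS:
        (root / name).mkdir(parents=True, exist_ok=True)
    for game in (*RICH_GAMES, *extra_games):
        (root / "Results" / game).mkdir(parents=True, exist_ok=True)
    header = root / "Survey" / "header.txt"
    if not header.exists():
        header.write_text(DEFAULT_HEADER, encoding="utf-8")
    return root
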