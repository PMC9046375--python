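"""Record entry, checksums, compilation, annotation, payouts, setup."""

import numpy as np
import pytest

from richroster.errors import (
    ConflictError,
    MissingDataError,
    RichRosterError,
    ValidationError,
)
from richroster.records import (
    PayoutConfig,
    RecordHeader,
    annotate_classified,
    calculate_payouts,
    checksum,
    compile_directory,
    compile_game,
    make_record,
    read_record,
    setup_project,
    write_record,
)
from richroster.survey import layout_panels

IDS = ["AAR", "RKM", "CT1", "LCK", "SR1", "EW1", "SK1", "AY1", "MB1"]


@pytest.fixture
def small_layout():
    return layout_panels(IDS, 1, 3, 3)


def header(pid="AAR", game="G", **kw):
    return RecordHeader(pid=pid, game=game, order="A", seed=1, **kw)


class TestMakeRecord:
    def test_sparse_input_fills_zeros(self, small_layout):
        rec = make_record(header(), {}, small_layout)
        assert len(rec.allocations) == len(IDS)
        assert all(v == 0 for _, v in rec.allocations)

    def test_single_value_other_rows_zero(self, small_layout):
        rec = make_record(header(), {"RKM": "2"}, small_layout)
        assert rec.value_for("RKM") == 2
        assert sum(v for _, v in rec.allocations) == 2

    def test_text_in_rich_game_rejected(self, small_layout):
        with pytest.raises(ValidationError, match="numerical"):
            make_record(header(), {"RKM": "friend"}, small_layout)

    def test_text_allowed_in_registered_custom_game(self, small_layout):
        rec = make_record(
            header(game="Friends"), {"RKM": "close"}, small_layout,
            extra_games=["Friends"],
        )
        assert rec.value_for("RKM") == "close"
        assert rec.value_for("CT1") == ""

    def test_unregistered_game_rejected(self, small_layout):
        with pytest.raises(ValidationError, match="registered"):
            make_record(header(game="Secrets"), {}, small_layout)

    def test_missing_header_fields_rejected(self):
        with pytest.raises(ValidationError):
            RecordHeader(pid="", game="G")

    def test_record_order_follows_presentation(self):
        layout = layout_panels(IDS, 3, 1, 3)  # panels A, B, C of 3 each
        rec = make_record(
            RecordHeader(pid="AAR", game="G", order="CAB"), {}, layout
        )
        aids = [a for a, _ in rec.allocations]
        assert aids == IDS[6:] + IDS[:3] + IDS[3:6]

    def test_round_trips_through_csv(self, small_layout, tmp_path):
        rec = make_record(header(hhid="H7", rid="R2"), {"CT1": 3}, small_layout)
        path = write_record(rec, tmp_path)
        assert path.name == "G_AAR.csv"
        assert read_record(path) == rec


class TestChecksum:
    def test_entry_error_worked_case(self, small_layout):
        """Entries summing to 19 against 20 distributed coins fail with
        checksum 19 — the canonical data-entry discrepancy."""
        rec = make_record(
            header(), {"RKM": 1, "CT1": 1, "LCK": 2, "AAR": 15}, small_layout
        )
        row = checksum(rec, expected_total=20)
        assert row.checksum == 19
        assert not row.passed

    def test_all_zero_record_passes_expected_zero(self, small_layout):
        row = checksum(make_record(header(), {}, small_layout), 0)
        assert row.passed and row.checksum == 0

    def test_self_kept_twenty(self, small_layout):
        rec = make_record(header(), {"AAR": 20}, small_layout)
        row = checksum(rec, 20)
        assert row.passed and row.self_total == 20 and row.other_total == 0

    def test_any_single_corruption_flips_a_pass(self, small_layout, rng):
        """Injecting +/-1 into any one allocation of a passing record
        always flips the checksum to fail."""
        base = {"RKM": 5, "CT1": 3, "AAR": 12}
        rec = make_record(header(), base, small_layout)
        assert checksum(rec, 20).passed
        for aid in IDS:
            for delta in (+1, -1):
                value = (base.get(aid, 0)) + delta
                if value < 0:
                    continue
                corrupted = make_record(header(), {**base, aid: value}, small_layout)
                assert not checksum(corrupted, 20).passed


class TestCompile:
    def test_self_allocations_excluded_from_edges(self, small_layout):
        recs = [
            make_record(header(pid="AAR"), {"RKM": 2, "CT1": 1, "LCK": 1, "AAR": 16},
                        small_layout),
            make_record(header(pid="RKM"), {"AAR": 3, "CT1": 2, "SR1": 1, "RKM": 14},
                        small_layout),
        ]
        summary, edges = compile_game(recs, expected_total=20)
        assert len(edges) == 6
        assert summary["Pass"].all()
        assert set(edges["PID"]) == {"AAR", "RKM"}

    def test_all_zero_records(self, small_layout):
        recs = [make_record(header(pid=p), {}, small_layout) for p in ("AAR", "RKM")]
        summary, edges = compile_game(recs, expected_total=0)
        assert edges.empty and summary["Pass"].all()
        _, edges20 = compile_game(recs, expected_total=20)
        assert edges20.empty

    def test_seven_green_token_edge_list(self, small_layout):
        """A binary-tie record with tokens on seven alters compiles to
        exactly those seven directed edges."""
        alters = ["RKM", "CT1", "LCK", "SR1", "EW1", "SK1", "AY1"]
        rec = make_record(header(), {a: 1 for a in alters}, small_layout)
        _, edges = compile_game([rec])
        assert edges["AID"].tolist() == sorted(
            alters, key=lambda a: [x for x, _ in rec.allocations].index(a)
        )
        assert len(edges) == 7
        assert (edges["PID"] == "AAR").all()

    def test_conflicting_duplicates_rejected(self, small_layout):
        a = make_record(header(), {"RKM": 1}, small_layout)
        b = make_record(header(), {"RKM": 2}, small_layout)
        with pytest.raises(ConflictError, match="AAR"):
            compile_game([a, b])

    def test_directory_compilation_latest_write_wins(self, small_layout, tmp_path):
        write_record(make_record(header(), {"RKM": 1}, small_layout), tmp_path)
        write_record(make_record(header(), {"RKM": 4, "AAR": 16}, small_layout),
                     tmp_path)
        summary, edges = compile_directory(tmp_path, "G", expected_total=20)
        assert summary.loc[0, "Pass"]
        assert edges.loc[0, "Value"] == 4
        assert (tmp_path / "G_summary.csv").exists()
        assert (tmp_path / "G_edgelist.csv").exists()


class TestAnnotate:
    def test_seven_edges_become_record(self, small_layout):
        edges = [(a, "green") for a in ("RKM", "CT1", "LCK", "SR1", "EW1", "SK1", "AY1")]
        rec = annotate_classified(
            edges, RecordHeader(pid="AAR", game="Friends", order="A"),
            small_layout,
        )
        filled = [a for a, v in rec.allocations if v != ""]
        assert len(filled) == 7 and rec.value_for("RKM") == "green"

    def test_empty_edges_all_blank(self, small_layout):
        rec = annotate_classified(
            [], RecordHeader(pid="AAR", game="Friends"), small_layout
        )
        assert all(v == "" for _, v in rec.allocations)

    def test_compile_round_trips_edges(self, small_layout):
        edges = [("RKM", "green"), ("SK1", "green")]
        rec = annotate_classified(
            edges, RecordHeader(pid="AAR", game="Friends"), small_layout
        )
        _, compiled = compile_game([rec])
        assert set(zip(compiled["AID"], compiled["Value"])) == set(edges)

    def test_entry_mode_equivalence(self, small_layout):
        """Manual entry and annotated classifier output compile to the
        same tables for any 0/1 allocation."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            chosen = [i for i in IDS if i != "AAR" and rng.random() < 0.5]
            manual = make_record(header(), {a: 1 for a in chosen}, small_layout)
            auto = annotate_classified(
                [(a, "green") for a in chosen], header(), small_layout,
                value_map={"green": 1},
            )
            s1, e1 = compile_game([manual], 20)
            s2, e2 = compile_game([auto], 20)
            assert e1.equals(e2) and s1.equals(s2)


class TestPayouts:
    def _compiled(self, records, game="G", expected=20):
        return {game: compile_game(records, expected)}

    def test_keep_all_twenty_at_half_value(self, small_layout):
        rec = make_record(header(), {"AAR": 20}, small_layout)
        table = calculate_payouts(
            self._compiled([rec]), PayoutConfig(games="G", GV=0.5), ["AAR"]
        )
        assert table.set_index("ID").loc["AAR", "Payout"] == pytest.approx(10.0)

    def test_mutual_full_transfers_conserve_total(self, small_layout):
        recs = [
            make_record(header(pid="AAR"), {"RKM": 20}, small_layout),
            make_record(header(pid="RKM"), {"AAR": 20}, small_layout),
        ]
        table = calculate_payouts(
            self._compiled(recs), PayoutConfig(games="G", GV=0.5), ["AAR", "RKM"]
        )
        assert table["Payout"].sum() == pytest.approx(2 * 20 * 0.5)

    def test_absent_recipient_refunds_donor(self, small_layout):
        rec = make_record(header(), {"RKM": 5, "AAR": 15}, small_layout)
        table = calculate_payouts(
            self._compiled([rec]), PayoutConfig(games="G", GV=1.0), ["AAR"]
        )
        # 15 kept + 5 refunded (RKM never appeared as a respondent)
        assert table.set_index("ID").loc["AAR", "Payout"] == pytest.approx(20.0)

    def test_reduction_game_accounting(self, small_layout):
        rec = make_record(header(game="R"), {"AAR": 15, "RKM": 5}, small_layout)
        compiled = {"R": compile_game([rec], 20)}
        table = calculate_payouts(
            compiled, PayoutConfig(games="R", KV=0.5, RV=1.0), ["AAR", "RKM"]
        ).set_index("ID")
        assert table.loc["AAR", "Payout"] == pytest.approx(7.5)
        assert table.loc["RKM", "Payout"] == pytest.approx(-5.0)

    def test_floor_clips_negative_payouts(self, small_layout):
        rec = make_record(header(game="R"), {"RKM": 5}, small_layout)
        compiled = {"R": compile_game([rec], 5)}
        table = calculate_payouts(
            compiled, PayoutConfig(games="R", RV=1.0, floor=0.0), ["AAR", "RKM"]
        )
        assert (table["Payout"] >= 0).all()

    def test_self_totals_survive_compile_without_expected_total(self, small_layout):
        """Payouts must include self-kept coins even when the compiler was
        not told the issued coin count (no checksum verdict)."""
        recs = [
            make_record(header(), {"RKM": 5, "AAR": 15}, small_layout),
            make_record(header(pid="RKM"), {"AAR": 20}, small_layout),
        ]
        compiled = {"G": compile_game(recs)}  # no expected_total
        table = calculate_payouts(
            compiled, PayoutConfig(games="G", GV=0.5), ["AAR", "RKM"]
        )
        assert table["Payout"].sum() == pytest.approx(0.5 * 20 * 2)
        assert table.set_index("ID").loc["AAR", "Payout"] == pytest.approx(17.5)

    def test_missing_game_data_rejected(self):
        with pytest.raises(MissingDataError):
            calculate_payouts({}, PayoutConfig(games="G"), ["AAR"])

    def test_conservation_on_random_ledgers(self, small_layout, rng):
        """With every recipient a respondent, total G payout equals
        GV x coins x focals; invariant over 50 random ledgers."""
        coins, gv = 20, 0.5
        for _ in range(50):
            recs = []
            for pid in IDS:
                cuts = np.sort(rng.integers(0, coins + 1, size=len(IDS) - 1))
                parts = np.diff(np.concatenate([[0], cuts, [coins]]))
                recs.append(
                    make_record(
                        header(pid=pid),
                        dict(zip(IDS, (int(p) for p in parts))),
                        small_layout,
                    )
                )
            table = calculate_payouts(
                self._compiled(recs, expected=coins),
                PayoutConfig(games="G", GV=gv), IDS,
            )
            assert table["Payout"].sum() == pytest.approx(gv * coins * len(IDS))

    def test_refund_neutrality(self, small_layout, rng):
        """Total payout is the same whether a coin goes to an absent
        recipient or stays with the donor."""
        for _ in range(50):
            k = int(rng.integers(0, 21))
            to_absent = make_record(header(), {"RKM": k, "AAR": 20 - k}, small_layout)
            kept = make_record(header(), {"AAR": 20}, small_layout)
            totals = [
                calculate_payouts(
                    self._compiled([rec]), PayoutConfig(games="G", GV=0.7), ["AAR"]
                )["Payout"].sum()
                for rec in (to_absent, kept)
            ]
            assert totals[0] == pytest.approx(totals[1])


class TestSetupProject:
    def test_creates_tree_with_extra_game(self, tmp_path):
        root = setup_project(tmp_path / "RICH", extra_games=["Friends"])
        for sub in ("RawPhotos", "StandardizedPhotos", "Survey", "Results",
                    "ResultsPhotos", "ClassifiedPhotos"):
            assert (root / sub).is_dir()
        for game in ("G", "L", "R", "Friends"):
            assert (root / "Results" / game).is_dir()
        assert (root / "Survey" / "header.txt").exists()

    def test_rerun_without_force_refused(self, tmp_path):
        setup_project(tmp_path / "RICH")
        with pytest.raises(RichRosterError):
            setup_project(tmp_path / "RICH")
        setup_project(tmp_path / "RICH", force=True)
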