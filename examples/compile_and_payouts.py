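"""Record entry, checksum validation, compilation and payouts.

Enters giving-game (G) records for three respondents, shows how the
checksum catches an entry error, compiles the edge list, and calculates
payouts including the refund of coins aimed at a roster member who never
played.
"""

from richroster import (
    PayoutConfig,
    RecordHeader,
    calculate_payouts,
    checksum,
    compile_game,
    make_record,
)
from richroster.survey import layout_panels

ids = ["AAR", "RKM", "CT1", "LCK", "SR1", "EW1"]
layout = layout_panels(ids, 1, 2, 3)
COINS = 20

records = [
    make_record(RecordHeader(pid="AAR", game="G"),
                {"RKM": 2, "CT1": 1, "LCK": 1, "AAR": 16}, layout),
    make_record(RecordHeader(pid="RKM", game="G"),
                {"AAR": 3, "SR1": 2, "RKM": 15}, layout),
    # entry error: only 19 coins accounted for
    make_record(RecordHeader(pid="CT1", game="G"),
                {"AAR": 1, "EW1": 3, "CT1": 15}, layout),
]

for rec in records:
    row = checksum(rec, COINS)
    status = "ok" if row.passed else f"FAIL (checksum {row.checksum}, expected {row.expected})"
    print(f"{row.pid}: self={row.self_total} other={row.other_total} -> {status}")

# fix the bad record and compile
records[2] = make_record(RecordHeader(pid="CT1", game="G"),
                         {"AAR": 1, "EW1": 4, "CT1": 15}, layout)
summary, edges = compile_game(records, COINS)
print(f"\nEdge list ({len(edges)} directed transfers):")
print(edges.to_string(index=False))

# EW1 received coins but never played: their coins refund to the donor
respondents = ["AAR", "RKM", "CT1"]
payouts = calculate_payouts({"G": (summary, edges)},
                            PayoutConfig(games="G", GV=0.5), respondents)
print("\nPayouts at GV=0.5 per coin (EW1 absent, coins refunded to donors):")
print(payouts.to_string(index=False))
print("Total:", payouts["Payout"].sum(), "=", f"0.5 x {COINS} coins x {len(respondents)} focals")
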