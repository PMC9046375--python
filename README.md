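# richroster

Tools for collecting **roster-based dyadic data** with physical photograph
boards: network-structured economic games (the RICH giving, leaving and
reduction games), binary tie nominations, and Likert-style peer ratings in
which respondents place coins or colored tokens on the photographs of
community members.

Roster designs yield high-quality recognition-based network data, but
data collection and entry scale with the square of the sample size. This
package moves the expensive parts to software:

- **standardize** — batch-convert heterogeneous raw portraits into
  fixed-size, fixed-aspect, bordered roster photographs, driven by
  coordinates (no GUI required).
- **survey** — seeded randomization of the roster onto lettered panels
  and a printable survey document; the same seed later drives data entry,
  so the two always agree on who sits where.
- **rectify** — correct rotation, skew and shear in hand-held board
  photographs from four clicked corners via a projective homography, and
  cut the rectified array into per-recipient cells.
- **classify** — decide, per recipient cell and token color, whether a
  token was placed, by comparing hue-density mass between the blank
  (control) and allocated photographs.
- **records** — manual/automated entry with checksum validation,
  compilation into summary tables and edge lists, and payout calculation
  with refunds for absent recipients.
- **fixtures** — synthetic rosters, boards, tokens and distortions with
  exact ground truth, so the whole pipeline is testable without field
  photographs.

## The classifier

Each recipient cell is processed as: excise a border fraction (clothing
guard) → Gaussian blur (σ = `iso_blur` px) → convert to HSL → keep pixels
with saturation > `lower_saturation_threshold` and luminance strictly
inside (`lower_luminance_threshold`, `upper_luminance_threshold`) → form
the normalized 1°-bin hue density of the survivors. For a token color
with hue interval [ℓ, u] (wrapping through 0/360 allowed), the mass

&nbsp;&nbsp;&nbsp;&nbsp;m = Σ<sub>b ∈ [ℓ,u]</sub> density(b)

is integrated on both exposures and the divergence is the signed rise
Δ = m(allocated) − m(blank). A directed tie PID → AID is coded when
Δ > `thresh` (default 0.05); with several colors (up to five) the color
with the largest Δ wins. Cool hues (green, navy, purple) separate cleanly
from skin tones; warm token colors (red, orange) conflict with skin hue
and are not recommended.

## Worked example

`examples/classify_board.py` renders a 39-recipient two-panel board with
20 planted green tokens, distorts each exposure with a random projective
warp, rectifies from the known corners, and classifies every cell:

```
PID  AID  color  divergence
AA0  BB7  green  0.162
AA0  CA2  green  0.200
AA0  CB8  green  0.173
AA0  DA3  green  0.128
AA0  EB0  green  0.143
... (20 ties total)
Planted 20 ties; classifier found 20, 20 correct, 0 false positives.
```

Each row is a directed tie from the focal respondent (PID) to a
recipient (AID); the divergence is the rise in green hue mass for that
cell, all comfortably above the 0.05 threshold.

`examples/compile_and_payouts.py` shows the accounting half — the
checksum catching a record whose entries sum to 19 against 20 issued
coins, and payouts at GV = 0.5 per coin with coins aimed at an absent
recipient refunded to their donors:

```
CT1: self=15 other=4 -> FAIL (checksum 19, expected 20)
...
 ID  Payout
AAR    10.5
CT1    10.0
RKM     9.5
Total: 30.0 = 0.5 x 20 coins x 3 focals
```

The other examples cover portrait standardization and survey building.
A command-line interface mirrors the library (`richroster --help`):
`setup`, `standardize`, `survey`, `rectify`, `classify`, `compile`,
`payouts`, `simulate`.

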