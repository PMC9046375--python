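# Methods

## Setting

A focal respondent faces one or more lettered panels (A, B, …), each a
grid of standardized participant photographs, and allocates coins
(economic games) or colored tokens (binary ties, Likert ratings) onto
them. The package covers the full data path: portrait standardization,
seeded board layout, photograph rectification, token classification, and
record compilation with checksum validation and payouts.

## Portrait standardization

Rotation is quadrant-coded (upper-left none, upper-right 90° CW,
lower-right 180°, lower-left 270° CW; points exactly on a midline count
as upper/left — a deterministic tie-break). The user's bounding box is
reconciled with the target aspect ratio `asr` (height/width) by
*expanding* the shorter-relative axis about the box center, then clamping
to the image: expansion preserves everything the user selected, whereas
cropping could cut the face. Resampling is bilinear in both directions
(deterministic); the output is always `size_out × round(size_out·asr)`
pixels with `border_px` black pixels painted on every side.
Re-standardizing an already standardized photo full-frame is idempotent
to within resampling error (mean absolute channel difference < 2, tested).

## Survey layout and the ordering contract

`seeded_order` is a Fisher–Yates shuffle driven by numpy's PCG64
generator seeded with the survey seed; an explicit `ordered` list takes
precedence over the seed. Cells fill row-major within panel A, then B,
etc. The load-bearing invariant, enforced by tests, is that the survey
document, `layout.csv`, and the data-entry recipient order derived from
the same `(ids, seed, grid)` are identical; the panel *presentation*
order per respondent (header field `Order`, e.g. "BA") permutes panel
blocks, never cells within a block. We promise stability of this
permutation across runs and platforms, not bit-compatibility with any
other language's RNG. The printable survey is self-contained HTML (every
browser prints it to PDF); tests and downstream code read only
`layout.csv`.

## Rectification

Four corner clicks in strict top-left, top-right, bottom-right,
bottom-left order define the board. Convexity and order are validated by
the signs of successive edge cross-products; a mis-ordered sequence is an
error, never silently reordered. The homography is the exact direct
linear solve of the 8-unknown system from the 4 correspondences,
normalized to H₃₃ = 1 (corner reproduction < 1e−6 px, tested against an
independent least-squares estimator). Backward warping samples each
output pixel at H⁻¹(x, y) with bilinear interpolation; forward mode
splats source pixels to nearest output cells and leaves holes black —
it exists only for speed. Output size defaults to the clicked quad's
bounding box (preserves approximate scale). Grid cutting places
boundaries at `round(k·W/n)`, guaranteeing full coverage without overlap
for non-divisible dimensions.

## Token classification

Pipeline per recipient cell (identical for blank and allocated
exposures): border excision → Gaussian blur → optional luminance
equalization → HSL conversion → saturation/luminance masking → normalized
1°-bin hue density → interval mass. Decisions and defaults:

- **Density estimator**: a 1°-bin histogram rather than a KDE. The
  interval integral is then an exact bin sum (verified against a
  per-pixel counting oracle), and the spatial blur already smooths; a
  circular-kernel KDE would add a bandwidth parameter with no benefit at
  this bin width.
- **Divergence**: the signed difference of mass proportions
  Δ = m(allocated) − m(blank), one-sided, with `thresh` on the (0, 1)
  proportion scale. A ratio-based percent change is unstable when the
  blank mass is ≈ 0 (the common case); the difference of proportions is
  bounded and directly comparable to `thresh`.
- **Multi-color tie-break**: argmax of Δ among the (≤ 5) colors, emitted
  only if the winner clears `thresh`.
- **Blur**: Gaussian with σ = `iso_blur` px per RGB channel before HSL
  conversion; `iso_blur = 0` disables it.
- **Histogram balancing**: rank-based equalization of the luminance
  channel with hue and saturation held fixed; equalizing RGB channels
  independently would shift hues.
- **Defaults**: `thresh` 0.05, saturation floor 0.10, luminance band
  (0.05, 0.95), `iso_blur` 3 px, `border_frac` 0.15. These are tunable
  starting values; users should check them per field site with
  `inspect_hue` on real token pixels.
- **Degenerate cells**: an empty retained set has mass 0, so a fully
  grey/black/white cell can never register a tie.
- The focal's own cell is classified like any other; self-ties are left
  to downstream filtering (the records layer reports self vs. other
  splits separately anyway).

Hue intervals wrap: (350, 10) covers red through 0°, and bounds are
canonicalized mod 360 so (−10, 10) is the same interval. Cool token hues
are recommended — warm tokens (red/orange, hue ≈ 10–40°) overlap skin
tones and degrade separation.

## Records and payouts

Records are one CSV per focal × game (`<Game>_<ID>.csv`); re-entry
overwrites, which is the error-correction path. RICH games (G giving,
L leaving/taking, R reduction) accept only non-negative integer coin
counts; registered custom questions accept text. The checksum sums every
allocation including self and must equal the coins issued; any single ±1
corruption flips a passing record to fail (tested exhaustively on a
record). Compiled edge lists contain only nonzero allocations to
*others*; self-allocations live in the summary's self/other split, so no
self-loops appear. Self/other totals are computed even when no expected
coin count is supplied (the pass verdict is then left blank), because
payouts need them.

Payouts: G and L value every coin on a photograph at GV and LV to its
occupant (self-kept included; all L-game coins are valued at LV — the
design gives no reason to price focal-moved coins differently). R values
kept coins at KV and subtracts RV per reduction token received. Coins or
tokens aimed at rostered individuals who never appear as respondents are
refunded to the donor at the same per-coin value; for reduction tokens
the refund is the purchase price, `coins_per_token` (default 1) valued at
KV, since the exchange rate between coins and tokens is a site-level
choice. The refund rule applies to every configured game. Negative
payouts from reductions are allowed unless a floor is set. Conservation
(total payout = value × coins × focals when everyone responds) and refund
neutrality are property-tested on random ledgers.

## Synthetic fixtures

The generator emulates the study design used to validate the classifier:
39 recipients on two 4×5 panels, 64×80 px cells, portraits with ≥ 10 %
of pixels in the 10–40° skin-hue band (the warm-token stress case), a
low-saturation backdrop and warm-hued clothing. Tokens are filled disks
at 0.18 of the cell's short side — inside the 15 % border excision —
painted at hue 120 (green), 230 (navy) or 280 (purple) with ±3° jitter,
matching the shipped intervals green 100–140, navy 200–260, purple
260–300. Lighting differences between exposures are a global ±0.02
luminance offset (equal-channel shift, hue-invariant — exactly the
nuisance the blank/allocated comparison absorbs). Distortion displaces
each board corner by up to 18 px (≈ 6 % of board size) under a projective
warp whose true corner quad is returned for rectification. Portrait
clothing avoids the token hue bands; a field site would likewise choose
token colors absent from the boards.

Not emulated: real faces, camera sensor noise, specular highlights on
laminated photographs, token shadows, or non-projective lens distortion.
Perfect recovery on these fixtures therefore demonstrates correctness of
the pipeline (geometry, color accounting, thresholds), not robustness to
every field condition; the classifier's parameters remain site-tunable
for that reason.

## Validation experiments

`run_validation_experiment` replays the two perfect-recovery designs at
full scale: 26 rounds × 20 green tokens (520 planted ties, 494 empty
cells) and 26 rounds × 9 tokens each of navy/purple/green (702 ties, 312
empty cells), one focal per round, tokens never on the focal's own cell,
allocations drawn without replacement per round. `distortion_robustness`
additionally warps both exposures independently, rectifies from the true
corners and requires the edge list to be *identical* to the flat render's
(5 rounds). All run in seconds on one CPU at these native sizes — no
scaling down is involved. `scripts/acceptance.py` recomputes all tallies
from scratch with seeds derived from its `--seed`.

## Known limitations

- Corner clicks must be supplied (as coordinates/JSON); there is no
  automatic board detection.
- Hue thresholds are per-site tuning, not learned; overlapping intervals
  across colors only warn.
- The survey renderer targets logical correctness (layout, seed, header),
  not typographic fidelity.
- Panel presentation order between respondents is recorded, never
  generated; randomize it in the field protocol.
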