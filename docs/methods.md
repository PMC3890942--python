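# Methods

## The paradigm being modelled

Two players share an invisible one-dimensional space of 600 units that
wraps around. Each is embodied as a 4-unit avatar whose position they
control continuously; a binary tactile channel vibrates whenever their
avatar overlaps any object. Three kinds of object can be encountered:
the partner's avatar (touching it stimulates *both* players — this mutual
contingency is the paradigm's defining feature), the partner's shadow
lure (rigidly attached 150 units from the partner's avatar; it moves
identically but stimulates only the toucher), and the player's own static
object. Trials last 60 s, sampled every 10 ms (6000 steps). Each player
may click once per trial to assert "this is my partner"; a correct click
(on the partner's avatar) earns the team a point, any other click loses
one, and not clicking is neutral.

All geometry and timing lives in `EnvConfig`; every parameter below is a
config field with the stated default.

## Core measures

**Overlap.** Objects are centre points; two objects overlap when their
wrapped centre distance is strictly below `body_length` (4 units). The
strict inequality is a deliberate convention: abutting objects do not
stimulate. For 4-unit segments of equal length the segment-overlap
criterion coincides with this centre-distance criterion, so the two
readings are not distinguishable and nothing hangs on the choice.

**Contacts.** A contact is a maximal run of uninterrupted stimulation,
half-open over steps `[start, end)`. Each object type overlapping at
least one step inside the run contributes exactly once to that contact,
regardless of re-entry, mirroring the player's experience of one
continuous vibration. Counting is therefore per (contact, type) pair: one
contact may increment several type counters.

**Click attribution.** Relative positions are sampled at a single step
exactly `click_lookback` = 1 s (100 steps) before the click, clamped to
step 0 for earlier clicks (the behaviour near the trial start is
otherwise undefined; clamping is this package's convention). An object is
"in range" when the absolute signed wrapped displacement between centres
is ≤ `target_range` = 70 units, bounds inclusive, centre to centre.
Priority is avatar → shadow → static → none. Because
2·`target_range` < `shadow_offset` (140 < 150), avatar and shadow can
never both be in range — this is validated at configuration time — while
a static object can co-occur with either and loses to both.

**Movement binarization.** Per-step displacement is the absolute wrapped
difference |dx| (direction is irrelevant to moving-vs-still); a step is
raw-moving when |dx| > `move_threshold` = 0.5 units (strictly), i.e. an
eighth of the body length. Pauses shorter than `min_pause_steps` = 50
(500 ms) are treated as micro-saccades within a turn and set back to
moving; only runs of ≥ 50 motionless steps survive as genuine pauses.
The first step of a series has no predecessor and starts as raw-still;
like any short pause it is absorbed unless it belongs to a long
motionless run. Binarization is applied to the *full* trial before any
windowing, so pause merging sees context on both sides of a window
boundary (the alternative — binarizing each window in isolation —
differs only for pauses straddling the boundary; one convention had to
be fixed).

**Turn-taking.** For binary series B₁, B₂ over T steps,
D = B₁ NAND B₂, C₁ = Σ(B₁ ∧ D), C₂ = Σ(B₂ ∧ D), TT = 4·C₁·C₂/T².
By AM–GM, 4·C₁·C₂ ≤ (C₁+C₂)² ≤ T², so TT ∈ [0, 1], with TT = 1 exactly
when C₁ = C₂ = T/2 — a perfect exchange of activity and passivity. The
per-click TT uses the window `[click − W, click)` with
W = min(`tt_window` steps, click step): the click step itself is
excluded, and clicks earlier than 10 s into the trial use the truncated
window with T equal to its actual length (the formula normalizes by T,
so truncation is well defined). A click at step 0 has no window and is
an error at the library level; the pipeline records its TT as missing.

**Classification and scoring.** Joint Success: both players' retained
clicks target the avatar. Single Success: exactly one does (the partner
clicked wrongly or not at all). Wrong-only: clicks exist, none correct.
No-clicks otherwise. Per-click categories (joint_success /
single_success / wrong) drive rating summaries; a click with target
"none" is a wrong click for scoring, which is the only reading under
which published per-team click counts reproduce their printed scores.
Accuracy for a player with zero clicks is explicitly undefined (`None`),
never 0%. Medians over players use the midpoint convention for even
counts.

## Inference

**Variance-gated comparisons.** Each group comparison first runs a
two-sided F-test of equal variances: F = larger sample variance /
smaller, p = 2·SF(F; df₁, df₂). At gate level α = 0.05 (a standard
default recorded in the result object; nothing in the analysed design
fixes it) the comparison proceeds with pooled-variance Student's t
(df = n₁+n₂−2) when equality stands, Welch's t with Welch–Satterthwaite
df otherwise. All p-values are one-tailed and the hypothesized direction
must be stated explicitly per comparison; no direction is ever inferred
from the data. Degenerate inputs (both groups constant) raise rather
than silently returning a number; a single constant group yields F = ∞,
p = 0, and the Welch branch, which remains well defined. The suite
verifies by simulation (10 000 null replicates) that the gated procedure's
type-I error stays at the nominal α.

**Click synchrony.** For jointly successful trials the pairwise
distribution takes |t₁ − t₂| within each trial; the randomized null
enumerates *all* cross-trial pairings of player-1 and player-2 click
times (i ≠ j), deterministically — no sampling, so no seed sensitivity
(a seed is accepted only for optional subsampling of very large
cross-pair sets). Both histograms share 2-s bins starting at 0 and are
normalized to unit mass. Only interactively generated timing produces an
excess of short pairwise delays; entrainment to any shared external
signal would survive the cross-trial shuffle.

**Exclusion reruns.** Removing one player removes their clicks and
ratings and *re-derives* trial categories from the remaining clicks (a
Joint Success legitimately becomes a Single Success), then recomputes
all per-category means; the result reports full, excluded and delta
summaries.

## The simulator and what it does (not) emulate

Controllers receive only their own position and their own previous-step
stimulation — the informational situation of a human player — and emit a
velocity (applied per step, no inertia; the real trackball's kinematics
are not modelled) plus an optional click; only the first click is
retained. The shadow offset is +150 units for both players; only the
distance matters to any analysis, but the sign convention is recorded in
log headers.

Three scripted behaviours:

- *Stationary*: parks; a pure control.
- *Scanner*: sweeps `span` units at `speed`, optionally halting at first
  contact and clicking after 110 consecutive contact steps (~1.1 s, long
  enough that the 1-s lookback falls inside the halt).
- *Turn-taker*: seeks until first stimulation, then exchanges
  fixed-length movement bursts with its partner. Mutual avatar contact
  is symmetric, so both agents register the engagement on the same step;
  that shared event serves as the cycle clock from which complementary
  bursts (role 0 active first) are scheduled. An instantaneous
  "move-only-when-unstimulated" rule cannot coordinate roles here,
  precisely because both stim channels fire together during mutual
  contact — the shared-onset clock is the design choice that makes the
  described alternation (one stimulated and passive while the other
  moves, then roles reversed) reproducible. While active the agent
  strokes ±2 units around its engagement anchor at 0.8 units/step
  (> `move_threshold`, so it binarizes as moving); it clicks after a
  per-trial number of completed exchanges plus a small per-player delay.

The tournament generator (`generate_dataset`) draws per-trial parameters
from a seeded generator: turn-taker pairs start 20–140 units apart
(below the 150-unit shadow offset, so neither seeker can cross a lure
before meeting the partner), with burst lengths 400–600 steps and 1–5
exchanges before clicking — the spread of exchange counts is what makes
click times vary *across* trials while staying tightly coupled *within*
a trial, the structure the synchrony contrast needs. Scanner teams pair
one halting scanner with a stationary partner, with the partner's
avatar, partner's shadow and scanner's own static placed ≥ 80 units
apart: since 80 − `body_length` > `target_range`, the object the scanner
halts on is the only object in attribution range at its click, so the
generator's ground-truth label (read from the simulator's overlap state
at the click step — a different rule from the analysis-side lookback
attribution) is unambiguous. Synthetic questionnaires draw PAS/CR levels
from category-conditioned distributions (joint-success clicks skew to
level 4, wrong clicks to 2–3) with a 1% chance of a missing answer.

What this does **not** emulate: human motor noise and strategy
diversity, learning across trials, near-miss geometry where a moving
partner sits just outside attribution range at lookback, ratings driven
by experience rather than by construction. Passing label-recovery tests
therefore show the analysis chain is correct under the stated
generative conditions, not that it is robust to every behaviour real
dyads produce. Group means and p-values of the original human study
depend on raw data that were never deposited and are deliberately not
regression targets; the printed tournament table and study-wide totals
in `percross.datasets` are the only human-data inputs used, for the
desk-scale checks.

## Numerical and I/O choices

Positions are continuous doubles wrapped into [0, L) at every step; the
antipodal displacement tie at exactly L/2 resolves to +L/2. Trial logs
serialize times as integer milliseconds and positions with 17
significant digits, so read(write(rec)) is bit-exact (pandas is read
with `float_precision="round_trip"`). Stimulation and overlaps are
always re-derived from positions, making the recording's internal
invariants (stim = OR of overlaps, rigid avatar–shadow link, mutual
contact symmetry) true by construction rather than by bookkeeping.
Analysis outputs are plain CSV/JSON with a manifest of SHA-256 checksums;
a rerun with the same inputs and seed is byte-identical.

## Problem sizes used by the test suite

The suite validates the full pipeline on a generated 17-team × 15-trial
mixed tournament (255 simulated trials of 6000 steps), the oracle
equivalences on 200 random instances per operation, the TT bound on
10 000 random series pairs, and the type-I calibration on 10 000 null
replicates — sizes chosen so the whole suite runs in well under a minute
while leaving the statistical margins of every stochastic assertion
wide (the TT contrast between turn-taker and scanner clicks, for
example, separates by ~1.0 with near-zero within-group spread).

## Known limitations

- Agents are scripted, not adaptive; no learned or noisy human-like
  controllers.
- The trackball gain of the original interface is unknown, so absolute
  speeds are in units/step and only relative dynamics are meaningful.
- No multiple-testing correction is applied anywhere (the analysed
  design applies none); directions must be supplied by the analyst.
- Free-text questionnaire fields are carried through I/O but never
  interpreted.
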