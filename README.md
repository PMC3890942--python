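# percross

Simulation and analysis toolkit for the **perceptual crossing paradigm**:
a minimal dyadic interaction experiment in which two players, each reduced
to a 4-unit avatar on an invisible 600-unit line that wraps around, try to
find each other using nothing but binary tactile contact. Each avatar
drags an insensate "shadow" lure rigidly attached 150 units away — it
moves exactly like the avatar but touching it stimulates only the toucher
— and each player additionally owns a private static object. The only
thing that distinguishes the partner's avatar from the lures is *social
contingency*: the avatar responds, in real time, to being touched.

The package is aimed at researchers studying dyadic coordination and
minimal social cognition who want a tested, reusable implementation of the
paradigm's behavioural analyses, plus a simulator with scripted agents
that generates trial recordings with known ground truth for validating
those analyses.

## What it computes

- **Contact segmentation.** A *contact* is a maximal run of uninterrupted
  tactile stimulation; every object type overlapping anywhere inside the
  run (partner avatar, partner shadow, own static) is counted once per
  contact (`segment_contacts`, `count_contacts_by_type`).
- **Click-target attribution.** A click is assigned to the object within
  ±70 units of the player's avatar one second before the click, with
  priority avatar → shadow → static → none; since 2·70 < 150 the avatar
  and its shadow are never simultaneously attributable
  (`assign_click_target`).
- **Turn-taking.** Trajectories are binarized to moving/non-moving
  (movement = |dx| > 0.5 units/step; pauses shorter than 50 steps are kept
  as movement), and for two binary series B₁, B₂ over T steps with
  D = B₁ NAND B₂, C₁ = Σ(B₁ ∧ D), C₂ = Σ(B₂ ∧ D):

  TT = 4·C₁·C₂ / T², TT ∈ [0, 1]

  computed over the 10 s window preceding each click
  (`binarize_movement`, `turn_taking_score`, `tt_before_click`).
- **Trial classification and scoring.** Joint Success (both clicks on the
  partner's avatar), Single Success (exactly one), Wrong-only, No-clicks;
  team score = #correct − #wrong clicks; clicking accuracy and per-contact
  click probabilities (`classify_trial`, `team_score`,
  `click_probability_per_contact`).
- **Subjective ratings.** Relative-frequency tables of 4-level awareness
  (PAS) and confidence (CR) ratings per click category
  (`rating_frequency_table`).
- **Inference.** Variance-gated one-tailed two-sample t-tests (F-test
  gate at α = 0.05 choosing pooled Student vs. Welch), the click-synchrony
  randomization contrast (within-trial vs. all cross-trial inter-click
  delays), and player-exclusion sensitivity reruns (`gated_comparison`,
  `synchrony_analysis`, `exclude_player_rerun`).
- **Simulation.** Closed-loop trials with scripted agents — stationary,
  sweeping scanners, and turn-takers that engage on first contact and
  exchange fixed-length movement bursts — plus a tournament generator with
  ground-truth click targets (`simulate_trial`, `generate_dataset`).

## Worked example

```python
from percross import segment_contacts, count_contacts_by_type
from percross.datasets import CONTACT_EXAMPLE

overlaps = {k: v for k, v in CONTACT_EXAMPLE.items() if k != "stim"}
contacts = segment_contacts(CONTACT_EXAMPLE["stim"], overlaps)
for c in contacts:
    print(f"contact steps [{c.start}, {c.end}): types {sorted(c.types)}")
print("counts per type:", count_contacts_by_type(contacts))
```

prints

```
contact steps [0, 3): types ['avatar', 'static']
contact steps [6, 10): types ['avatar', 'static']
contact steps [12, 15): types ['shadow']
counts per type: {'avatar': 2, 'shadow': 1, 'static': 2}
```

The 18-step stimulation series contains three uninterrupted runs; the
first two each involve the partner's avatar and the player's own static
object (each counted once per run, despite the static object re-entering
twice within the second run), the last only the shadow lure — hence
avatar = 2, static = 2, shadow = 1 contacts.

A full synthetic tournament, end to end:

```sh
python examples/04_tournament_pipeline.py
```

```
trial outcomes : {'JointSuccess': 19, 'WrongOnly': 15, 'SingleSuccess': 6}
team scores    : {0: 20, 1: -6, 2: 19, 3: -4}
clicks by type : {'avatar': 44, 'shadow': 8, 'static': 7, 'none': 0}
...
```

Turn-taker teams (0, 2) accumulate Joint Successes and high scores;
scanner teams (1, 3) click whatever they halt on and drift negative.
The remaining example scripts cover turn-taking scores, click
attribution, and the gated-test/synchrony inference steps.

A thin CLI wraps the same pipeline for shell use:

```sh
percross simulate --teams 4 --trials 10 --scenario mixed --seed 42 --out out/ds
percross analyze  --in out/ds --out out/report
percross report   --in out/report
```

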