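# crocmotion

Color-tag video tracking and movement classification for behavioral assays
of crocodilian hatchlings, with the downstream statistics for comparing
species, phases, and conditions.

## The problem

Hatchling behavioral predispositions (exploration, neophobia, activity) are
measured in arena assays — novel object, open field, and shelter trials —
by filming an animal that carries two small colored stickers: one on the
head (red or blue) and one at the tail-base (green). From the raw frames
the pipeline must (1) locate both tags per frame, (2) separate genuine
locomotion from head movements performed from a stationary body, and
(3) score each trial with its condition-specific variable, feeding exact
nonparametric comparisons and repeatability analyses at small sample sizes
(11 animals per species).

## The method

**Tracking.** Each tag is segmented in HSV (per-tag hue interval,
saturation >= 0.5, value >= 0.3); 8-connected components under 5 px are
discarded and the largest component's centroid is kept. A missing tag is a
first-class observation — the shelter variable is *defined* by tag absence
(one tag missing = partially concealed, both missing = fully concealed).

**Movement classification.** Frame *i* is compared with frame *i − 30*
(half a second at 60 f/s). With *HL* the segment between the two head-tag
positions and *TbL* its tail-base counterpart, an event is recorded when
|HL| ≥ 5 px (≈ 6.39 mm at 1.278 mm/px). The recorded distance runs from the
previously recorded position (an anchor that advances only on events and
survives occlusion). The event is

* **walking** if |AHL − ATbL| < 45° (head and body headings agree;
  angles measured with right = 0°, screen-up = +90°),
* **head movement without walking** if the difference is ≥ 45°, the
  tail-base is missing, or |TbL| < 5 px (a head turn happens from a stable
  position).

Per-trial sums of the two labels are merged into a single *movement
component* by correlation-matrix PCA (for two variables: eigenvalues
1 ± |r|, PC1 loadings √((1+|r|)/2)), checked by Bartlett's sphericity test,
positivized (shift by |min|, square root), and compared with exact Wilcoxon
signed-rank / rank-sum tests (dynamic-programming exact p-values, midranks,
Holm correction) and one-way random-effects ICC for phase-to-phase
repeatability.

**Synthetic ground truth.** A scriptable simulator (rest / walk /
head-turn / shelter bouts) renders frames with anti-aliased tag discs on
textured cardboard, so the whole chain — detection, classification,
metrics — is validated against exact scripted kinematics.

## Worked example

Simulate a one-minute trial, track it from rendered frames, and classify:

```python
from crocmotion import (ArenaGeometry, BehaviorScript, Bout,
                        simulate_trajectory, render_frames, track_sequence,
                        analyze_track, shelter_usage, roaming_range)
from crocmotion.tag_detection import DEFAULT_COLOR_SPECS

geo = ArenaGeometry()           # 960x540 px, 60 f/s, 1.278 mm/px
script = BehaviorScript(bouts=[
    Bout("rest", 300),
    Bout("walk", 600, speed_px_per_frame=2.0),
    Bout("head_turn", 450, turn_deg_per_frame=3.0),
    Bout("shelter", 450),
    Bout("walk", 600, speed_px_per_frame=1.0),
    Bout("rest", 300),
])
truth = simulate_trajectory(script, geo, seed=42)
track = track_sequence(render_frames(truth, geo, seed=42),
                       DEFAULT_COLOR_SPECS, center_xy=geo.center_xy)
s = analyze_track(track)
print(f"scripted walk path : {truth.total_walk_path_px:.1f} px")
print(f"measured walking   : {s.total_walking_px:.1f} px")
print(f"measured head mov. : {s.total_head_movement_px:.1f} px")
print(f"scripted shelter   : {truth.total_hidden_s:.2f} s")
print(f"measured shelter   : {shelter_usage(track, geo.fps):.2f} s")
```

prints

```
scripted walk path : 1800.0 px
measured walking   : 1865.6 px
measured head mov. : 843.7 px
scripted shelter   : 7.50 s
measured shelter   : 7.50 s
```

The two walk bouts scripted 1800 px of path; the classifier recovers it
within 4% (the small excess is lag-window mixing at bout boundaries, where
a comparison window straddles a walk and a head-turn bout). The head-turn
bout contributes only to the head-movement total, and the 450 hidden frames
are recovered exactly as 7.50 s of shelter usage.

The same pipeline is scriptable from the shell:

```
croc-motion simulate --script script.json --seed 3 --out trial/
croc-motion track    --frames trial/frames --config config.yaml --out track.csv
croc-motion analyze  --track track.csv --meta meta.csv --out metrics.csv
croc-motion stats    --metrics metrics.csv --out report/
```

`stats` writes `pca.json` (eigenvalues, loadings, Bartlett test),
`tests.csv` (exact Wilcoxon comparisons with Holm-adjusted p), `icc.csv`,
and `model_ready.csv` (transformed movement component plus design factors,
ready for external mixed-model software).

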