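# Methods

`crocmotion` re-implements, as a tested library, a color-tag tracking and
movement-classification pipeline for behavioral assays of crocodilian
hatchlings (novel object, novel environment: open field, novel environment:
shelter), together with the statistical chain applied to its per-trial
output. This note documents the model, the parameters that matter, the
synthetic-data generator used for validation, and the design choices made
where the procedure was genuinely open.

## Tracking model

Each trial is a sequence of RGB frames (defaults: 960x540 px at 60 f/s,
1 px = 1.278 mm on the arena floor). The animal carries two round adhesive
stickers, ~1 cm in diameter: a head tag (red or blue) and a tail-base tag
(green). Per frame, each tag is segmented in HSV space (per-tag hue
interval, minimum saturation 0.5, minimum value 0.3), connected components
are labeled with 8-connectivity, components below `min_blob_area_px = 5` are
discarded, and the centroid of the largest surviving component is reported.
An exact area tie is broken toward the component nearest the tag's position
in the previous frame (or the arena center when there is none); this
temporal-coherence rule is this package's own policy for ambiguous frames —
how the original assays resolved multiple color-matching regions is not
documented, and manual correction files (frame, tag, x, y) remain the
authoritative fix. Absence of a tag is recorded as a first-class missing
value, never imputed by default: the shelter variable is defined by tag
absence. Optional gap interpolation (`max_gap > 0`) exists for trajectory
work but is refused by the shelter metric.

Numeric conventions: pixel units, origin top-left, x rightward, y downward,
0-based contiguous frame indices; pixel (x, y) covers the unit square
[x, x+1) x [y, y+1), so centroids add 0.5 to mean pixel indices. Hue is
computed only on pixels passing an integer saturation/value prefilter, which
is what makes full-resolution tracking run at several hundred frames per
second on one core.

## Movement classification

Frame `i` is compared with frame `i - lag` (`lag_frames = 30`, half a second).
The head line HL joins the head-tag positions at the two frames; the
tail-base line TbL does the same for the tail-base tag. Compass angles
(AHL, ATbL) use right = 0°, screen-up = +90° (image y negated), range
(-180°, 180°].

An event is recorded only when |HL| >= `min_displacement_px` (5 px ~ 6.39 mm).
The event's recorded distance is measured from the *previously recorded
position* (the anchor), not from the head position at `i - lag`: the anchor
starts at the first detected head position, jumps to the current head
position after every event, and is left untouched by sub-threshold frames
and by frames where a tag is missing (so a shelter entry/exit never counts
as locomotion). Labeling is mutually exclusive:

* head movement without walking — the tail-base tag is missing at either
  frame, or |TbL| < 5 px (a head turn is performed from a stable body), or
  the circular difference |AHL - ATbL| is >= 45°;
* walking — otherwise (|AHL - ATbL| < 45°, body and head translating
  together).

Exactly 45° is assigned to head movement, making the tie deterministic. The
two per-trial totals are the sums of recorded distances per label.

## Condition variables

* mean dist. to object (px): mean head-to-object distance over frames with a
  detected head. The object position is a piecewise-constant timeline
  starting at the arena center and updated by manual object corrections.
* roaming range (px): max minus min head-to-center distance over detected
  frames.
* shelter usage (s): frames with exactly one tag (partial concealment) plus
  frames with no tag (full concealment), divided by fps. Defined purely by
  detectability; no geometric shelter mask.

Frames without a detected head are excluded from the two distance metrics —
whether the original analysis averaged over all frames or detected frames
only is not documented; exclusion is the only policy that remains defined
when detection fails, and it is recorded here as this package's choice.

## Statistical chain

The two movement totals are standardized and merged by PCA on their 2x2
correlation matrix. For two variables the decomposition is closed-form:
eigenvalues 1 ± |r|, standardized PC1 loadings ±sqrt((1+|r|)/2) (reported
with nonnegative sign when r >= 0). Varimax rotation of a single retained
component is the identity and is applied as such. Bartlett's sphericity test
uses chi2 = -(n - 1 - (2p+5)/6) ln det(R) on df = p(p-1)/2 = 1. Component
scores are shifted by the absolute value of the most negative score and
square-rooted before export to mixed-model software (`model_ready.csv`);
mixed-model fitting itself (GLMM, Kenward-Roger, AIC reduction) is out of
scope and delegated to that software.

Exact Wilcoxon tests: zero differences are dropped (classic convention,
flagged in the result), ties take midranks, and the two-sided exact p-value
is defined by reflection, P(|T - E[T]| >= |T_obs - E[T]|), under the
uniform null over sign assignments (signed-rank) or group assignments
(rank-sum). The null distribution is computed by dynamic programming over
doubled midranks (exact integers), so "exact" holds at any n; the test suite
additionally verifies equality with literal 2^n / C(n, n_a) enumeration at
small n and at the study's n = 11 per group. Z is the standardized linear
statistic with tie-corrected variance. Repeatability across phases uses the
one-way random-effects, single-measure, consistency ICC,
ICC(1) = (MSB - MSW)/(MSB + MSW) for k = 2, with F = MSB/MSW on
(n-1, n) degrees of freedom; the variant is recorded in the output so
alternative ICC forms can be compared. Holm's sequential Bonferroni
correction is applied across the pairwise comparisons of one report.

## Synthetic trials

The generator scripts an animal as an ordered list of bouts:

* walk — head and tail translate rigidly at 0.5-3 px/frame (0.04-0.23 m/s
  at the default calibration, hatchling walking pace) along a heading with
  Gaussian jitter (sigma 0.5°/frame, far inside the 45° split, so scripted
  walking is classifiable as walking); walls reflect the heading 20 px
  before the frame edge. True path length is exact (speed x frames).
* head_turn — the head rotates about the fixed tail-base at 1-4°/frame;
  contributes zero true walking.
* rest — both tags jitter with sigma 0.2 px, far below the 5-px event
  threshold.
* shelter — both tags hidden (or only the tail in partial-occlusion mode).

Rendering draws anti-aliased discs (radius 4 px, the 1-cm sticker at
default calibration) on a cardboard-tone background with ±8/255 uniform
pixel noise — textured enough to exercise segmentation, but with saturation
well below the 0.5 threshold. The texture is drawn once per trial, not per
frame. Frames stream as arrays (a 10-minute trial never exists in memory at
once); a PNG writer serves the CLI path.

What the generator does not emulate: the animal's body (only the two tags
are drawn), uneven lighting, motion blur, lens distortion, camera noise,
sticker deformation, or reflections off the arena walls. Passing recovery
tests therefore validates the *geometry and logic* of the pipeline — the
event rules, anchor semantics, occlusion handling, metric definitions — not
robustness to real-video segmentation failures, which the manual-correction
path exists for.

## Problem sizes and tolerances in the test suite

Validation trials are 3,600 frames (1 minute at 60 f/s) rather than the
10-minute assay length — bout statistics, not duration, drive every code
path — with 20 random scripts in the end-to-end recovery test. Recovery
tolerances: walking within 10% of scripted path length (chord-vs-arc error
from heading jitter plus bout-boundary lag mixing stays well inside this),
exact zero walking for scripts without walk bouts, and shelter seconds
within one frame period per shelter bout (edge frames of each bout). The
classifier is proven equal to a direct-transcription oracle on 1,000 random
tracks of up to 2,000 frames, including integer-rounded tracks that provoke
exact 45° ties. Exact-test p-values are proven equal to full enumeration at
n <= 12 and n = 11 per group. ICC recovery uses 200 simulated subjects with
known variance ratios (tolerance ~3 Monte-Carlo standard errors). PCA and
calibration checks are closed-form to 1e-9.

## Known limitations

* Detection assumes the two tags are the only saturated regions of their
  hues; a colored object in frame would need its own hue interval excluded.
* The anchor rule means a trial's first event flushes the distance
  accumulated since the anchor was set, so totals are not invariant to
  cropping the start of a track.
* Whether the original software also updated its anchor on sub-threshold
  frames, and how it treated exactly-45° differences, is unknowable from
  its description; both choices here are deterministic and documented above.
* `shelter_usage` counts any detection failure as concealment, exactly as
  the variable is defined; on noisy real video this overestimates shelter
  time unless tracks are manually corrected first.
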