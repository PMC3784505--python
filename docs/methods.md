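# Model and methods

`vibrisim` simulates a rat-like agent in a 2-D plane whose whisker and head
movements are both overt expressions of spatial attention.  A head-centric
salience map — fed by whisker contact and by an endogenous stochastic source,
and shaped by inhibition — selects an attended region; that region sets each
whisker's maximum protraction angle (a "minimal impingement, maximal
contact" transform) and, at every oscillator tick, becomes the target of a
head movement that brings the snout tip (the *fovea*) onto it.  The package
also reproduces three behavioural analyses of active vibrissal touch:
head-turning asymmetry (HTA), contact-induced asymmetry (CIA) and spread
reduction (SR).

## Physical plane model

The head is a rigid rod from the neck joint to the fovea (separation
`fovea_neck_sep` = 50 mm); its bearing is the neck-to-fovea direction.  The
fovea is the controlled point; the neck is dragged along the line toward the
new fovea position so the separation is preserved exactly.

Fourteen whiskers (seven per side) are constant-curvature arcs.  Their bases
lie on *mystacial pad arcs*: the snout outline is modelled as an ellipse
with its rostral tip at the fovea, semi-axes 30 mm (longitudinal) by 12 mm
(lateral); base points sit at ellipse parameters 15°–75° from the tip,
evenly spaced, the most caudal base most posterior.  Length (44 → 8 mm) and
rest curvature (−0.01 → +0.08 mm⁻¹) interpolate linearly from caudal to
rostral.  Protraction angles are measured from the caudal direction of the
midline, increasing rostrally (≈180° points straight ahead); the allowed
range is 30°–175°.

Bending against oriented rectangular obstacles is quasistatic: the signed
curvature of an intersecting whisker is offset caudally by the smallest
Δκ ∈ [0, 0.25 mm⁻¹] (bisection, tolerance 10⁻⁴ mm⁻¹, shaft discretised at
1 mm) at which no shaft vertex lies inside any obstacle.  The afferent
contact signal is `c = tanh(g_i · δ)` where δ is the displacement of the
shaft point 5 mm from the base and `g_i = k_g √(L_i/1 mm)` approximately
normalises signal strength across whiskers.  `k_g` (default 0.25) is set by
a calibration procedure (`calibrate_sensing_gain`): a log-grid search such
that the median nonzero contact signal over 60 s of arena exploration falls
in [0.5, 0.8].  When a whisker base is pressed against or into an obstacle
face no curvature offset can clear the shaft; the solver then clamps at the
bound and flags the sample (`clamped` column).  The no-penetration guarantee
(clearance to 0.01 mm at 1 mm vertex spacing) applies to all non-clamped
samples.

## Attention fields

All fields live on a fixed head-frame grid, x ∈ [−40, +40] mm (positive
ahead of the fovea), y ∈ [−60, +60] mm (positive left), 2 mm cells.  The
symmetric longitudinal extent serves the endogenous channel: candidate
attention targets can fall beside and behind the head even when the space
ahead is occluded by an obstacle — with a forward-biased grid the agent
facing a wall has almost no viable endogenous targets and wall-follows
indefinitely.

**Tactile input.** Each contact adds a Gaussian blob (width 8 mm, read as
2σ) of height `c_i` at the contact location; over-unity values clip to 1.

**Endogenous ('other') input.** At each oscillator tick one blob (width
20 mm, height 0.5) appears at a random location, drawn uniformly over the
grid but rejection-sampled to locations not inside or occluded by
obstacles: the source stands in for motivational and non-tactile sensory
systems, which propose attainable targets.  Between ticks the input is
empty.

**Excitation with memory.** Each channel's excitation map updates as

```
E' = clip( max( W(E), I, g·N ), 0, 1 )
```

taken entry-wise over the three operands: the remapped history `W(E)`, the
input `I`, and a coloured-noise field `g·N` (gain 0.025; per-cell AR(1)
process with coefficient `exp(−2π·8 Hz·dt)` and unit stationary variance).
Because the noise enters through the maximum it perturbs the map without
accumulating; an additive formulation turns each cell into a reflected
random walk whose background level swamps the caudal-biased arbitration
below.  The warp `W` compensates the pose change since the previous sample
(affine bilinear resample) and applies a 1 mm Gaussian reconstruction
filter, making it deliberately lossy: an unrefreshed contact blob fades in
roughly half a second, which is what bounds the maps' memory — no explicit
decay factor is used.  The endogenous map is rebuilt from the fresh input
blob at each tick (its history is dropped) so that it always holds a single
active region, i.e. a single candidate target.

**Inhibition and salience.** Obstacle inhibition is 1 inside obstacles and
in their occlusion shadow from the fovea's viewpoint.  Inhibition of return
adds Gaussian blobs (width 20 mm, gain 0.5) at the fovea locations visited
at the last 32 ticks (4 s memory), capped at 0.66.  The combined inhibition
is `H = min(1, H_obs + min(H_ior, 0.66))` and each channel's salience is
`S = E ∘ (1 − H)`.  The channel with the higher salience peak is re-selected
at each tick (ties keep the previous channel); the selected map drives both
head and whisker movement.

## Motor output

**Head.** At each tick the fovea is sent toward the salience peak (ties:
nearest, then lowest cell index; an empty map keeps the fovea in place)
along a quintic minimum-jerk trajectory of duration 0.175 s with zero
endpoint velocities.  Because the tick period (0.125 s) is shorter, each
movement is interrupted by the next plan, which restarts from the current
position.

**Whiskers (salience → protraction).** For every whisker and grid cell the
base angle `θ(i,e)` at which the unperturbed arc passes through the cell
center is precomputed (the grid is head-fixed, so this inversion is done
once; accuracy ≈ 0.1 mm).  Cells beyond the whisker's reach propose the
maximum angle — the whisker "reaches" forward when it cannot touch any part
of the attended region.  Cells whose geometric angle falls caudal of the
minimum protraction angle are excluded from the vote entirely: the whisker
can never meet them at an allowed angle, and clipping them to the minimum
would hand exactly those unmeetable locations the largest caudal-bias
weight (which, empirically, lets rear targets slam both whisker fields
caudal and corrupts the spread-reduction analysis through a selection
artifact).  Active cells — those with salience at or above the activity
floor of four noise gains (0.1); below that the many weakly noisy cells,
amplified by the caudal bias, would outvote the attended region — vote with
weight

```
w_e = (2 S_e)² · 500^(−(θ_prop − 30)/(175 − 30))
```

and the arbitrated angle is the weighted mean of the proposals, so each
whisker tends to reach the first part of the active region it would meet
during protraction.  A whisker with no active votes falls back to its
nominal angle.  The commanded maximum protraction is

```
θ_max,i = θ_nom,i + γ · C · (θ̂_i − θ_nom,i)
```

with modulation strength γ = 0.5 and C the Michelson contrast of the
selected map, `(max − mean)/(max + mean)` clipped to [0, 1].  The Michelson
form was chosen over the plain `max − mean`: both vanish on uniform maps,
but the plain form is capped by the blob amplitude (≈0.45 for the
endogenous channel) and halves the modulation; with the Michelson form the
simulated head-turning asymmetry lands inside the bracket of the published
behavioural regressions.

**Whisking.** The oscillator ticks at 8 Hz; the whisking drive is 0 during
the first 30 % of each cycle and 1 for the remaining 70 %, its falling edge
at the tick so maximum protraction occurs at the tick.  The commanded base
angle pursues `θ_max,i` (drive high) or `θ_max,i − A_i` (drive low, with
amplitude A 30°–45° caudal → rostral) through a first-order lag with time
constant 25 ms, Euler-integrated at 125 Hz.

## Behavioural experiments

The *measured* protraction angle follows the behavioural-lab convention:
the angle of the chord from the whisker base to the point two thirds along
the (possibly bent) shaft, relative to the midline.  Base angles are logged
alongside as the bending-free control measure.

**HTA** — 30 s with no obstacles; attention is driven only by the
endogenous channel.  Per sample, the left-minus-right difference of the
side-mean measured angles is regressed (OLS) on the head turn rate: the
central difference of the unwrapped bearing, converted to deg/ms and
smoothed with the same zero-phase second-order 2 Hz Butterworth filter used
throughout (turn-rate units are not standardised across studies; deg/ms is
the convention under which the published behavioural slopes correspond to
tens of degrees of asymmetry at realistic head speeds).  With modulation
off (γ = 0) the slope is zero.

**CIA** — 3600 s inside a 400 mm square arena (four 20 mm thick walls).
Side-mean *base* angles and the fovea/neck positions are low-pass filtered
(2 Hz, zero-phase) and down-sampled to one sample per whisk (the sample
nearest each tick).  Base angles are used because the shaft-angle variant
measures physical deflection against the walls rather than whisker control
— with it, the map near contact is dominated by bending and the γ = 0
control is no longer flat.  Whisks with the nose within 25 mm of exactly
one wall and ≥100 mm from the others form the NEAR set; whisks ≥100 mm from
every wall form FAR, whose grand mean over both sides is the baseline.  For
each NEAR whisk the nearest wall point is expressed nose-relative in the
head frame and the left relative angle is accumulated in 4 mm bins;
right-side data are mirrored and pooled.

**SR** — 100 trials.  Each trial drives the fovea in a straight line
(constant speed, uniform 10–50 mm/s) toward a wall angled uniformly within
±10° of perpendicular, from 50 mm to 5 mm nose-wall distance (or one whisk
after the second contact whisk on both sides, whichever is first); whisker
control stays active.  Whisks are the intervals between ticks; per side,
the first two whisks with contact are the first/second contact whisks and
the whisk before the first is the pre-contact whisk.  A side-sample is
selected when no whisker on either side contacts during that side's
pre-contact whisk and at least two whiskers on that side contact during its
first contact whisk.  The spread (measured angle of the fifth-from-rear
minus the rearmost whisker) is summarised by its min/mean/max within each
whisk and averaged over selected side-samples; the analysis is repeated on
base angles as the bending control (spread is lower overall, the pattern
unchanged).

## Reproducibility and problem sizes

All randomness flows from one master seed through independent spawned
streams (tactile noise, endogenous noise, endogenous target locations,
trial randomisation), so runs are bitwise reproducible and mirror-image
runs (mirrored world, mirrored streams) mirror the entire log to numerical
precision.  The test suite exercises the experiments at reduced scale — the
CIA checks run 10 min of simulated time with whisk counts rescaled to the
hour, and γ = 0 controls run 5 min — sizes chosen so the stochastic
quantities are estimated within their tolerance bands; `scripts/acceptance.py`
runs the full published scales (30 s HTA, 3600 s CIA, 100 SR trials).

## Known limitations

* The simulated world is 2-D and quasistatic: no whisker inertia, no
  whisker-whisker collision, no body, no modulation of whisk frequency or
  amplitude, and no within-whisk contact reflexes.
* When the fovea presses against a wall face, whiskers commanded forward
  can be geometrically trapped (no curvature offset clears the shaft);
  those samples are clamped and flagged (~15 % of arena samples) and are
  excluded from the no-penetration guarantee.
* The endogenous channel is a stochastic proxy for motivation and
  non-tactile senses; there is no vision or anticipatory memory, so the
  model shows no forward "reaching" toward obstacles ahead of the snout,
  and the contralateral protraction increase near walls, though present, is
  small (≈ +1°) — near-wall whisks split between tactile and endogenous
  attention, and the latter express no asymmetry toward the wall.
* Several components are reconstructions where the governing account is
  qualitative (the warp's loss, the activity floor, the contrast
  definition, the pad-arc geometry); each is documented above with its
  rationale, and the behavioural signatures were verified to be robust to
  the uncritical ones.
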