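# vibrisim

A closed-loop 2-D simulator of rat active whisker sensing, built around a
salience-map model of tactile spatial attention.

Rats sweep their facial whiskers rhythmically (~8 Hz "whisking") and
continuously re-aim them: whisker fields shift toward the side the head is
turning to (head-turning asymmetry, HTA), retract toward a touched surface
while the opposite side reaches out (contact-induced asymmetry, CIA), and
bunch together over the first whisks of a contact (spread reduction, SR).
`vibrisim` implements the hypothesis that one mechanism underlies all three:
whisker and head movements are overt expressions of a single attended
region of peri-snout space.

The model keeps two head-centric salience maps on a 120 × 80 mm grid (2 mm
cells) — a tactile channel fed by whisker contact and an endogenous
stochastic channel standing in for motivation and the other senses.  Each
excitation map `E` evolves by a remapped leaky maximum,

    E' = clip( max( W(E), I, g·N ), 0, 1 ),      S = E ∘ (1 − H),

where `W` is a lossy world-fixing image warp, `I` the input blobs, `g·N`
coloured noise, and `H` combines absolute inhibition inside/behind
obstacles with capped inhibition of return over recently visited
locations.  The channel with the higher salience peak is re-selected at
each oscillator tick; its peak becomes the target of a minimum-jerk head
movement, and its activity sets each whisker's maximum protraction angle
θ_max,i = θ_nom,i + γ·C·(θ̂_i − θ_nom,i), where θ̂_i is a salience- and
caudal-bias-weighted vote over the protraction angles at which the whisker
would touch each active cell ("minimal impingement, maximal contact").
Whisker–obstacle interaction is quasistatic beam bending with a saturating
afferent signal c = tanh(g_i δ).

The package is a library (`import vibrisim`) with a thin CLI (`vibrisim`),
and ships the three behavioural experiments with the exact analysis
pipelines used on laboratory video data.  See `docs/methods.md` for the
full model account.

## Worked example

```sh
python examples/head_turning_asymmetry.py
```

```
n = 3751 samples
slope: -68.4 deg per (deg/ms) of turn rate
Pearson r: -0.59
Published behavioural regressions bracket this slope between about -115 and -30 in the same units.
```

Thirty seconds of free-space exploration (obstacles absent, attention
driven only by the stochastic channel) produce 3751 samples of paired
(turn rate, left-minus-right mean protraction) observations.  The negative
slope is HTA: for every deg/ms of leftward head turn, the left whisker
field is held about 68° more caudal than the right — the whiskers lead the
head into the space it is turning toward.  Other examples:

```sh
python examples/whisker_bending.py       # quasistatic bending + contact signal
python examples/free_exploration.py      # stochastic orienting
python examples/arena_thigmotaxis.py     # emergent wall-following
python examples/wall_approach_spread.py  # spread reduction during approach
```

or from the shell, e.g. a full CIA experiment with a parameter override:

```sh
vibrisim exp cia --seed 1 --param modulation_strength=0 --out out/
```

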