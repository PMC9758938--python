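# Methods

This note documents the generative model behind the simulator, the
analysis conventions, the parameter defaults and why they were chosen, and
what the in-silico validations do and do not establish about real
recordings.

## The monitored tube

A tube of length `L = 90 mm` is spanned by 17 infrared beams, evenly
spaced with one beam-width margin at each wall (spacing `d = L/18 = 5 mm`).
The monitor reports, once per second, the number of beam interruptions
("counts") and a beam index for the fly.  We store the beam **last
crossed** rather than the beam nearest the fly: the two differ by at most
one index, but only the last-crossed convention guarantees the invariant
`counts[k] ≥ |position[k] − position[k−1]|` (a fly must interrupt every
beam separating two reported positions), and it matches how a beam monitor
actually localizes a fly — by the beam it last occluded.  The invariant is
property-tested for every protocol and parameter set.

Counts are assumed pooled per tube (a single per-second number), which is
what all downstream analyses consume.

Time bases: activity is integer seconds (the monitor's resolution);
stimulus events are integer milliseconds.  Zeitgeber time is
`ZT = (t/3600 + zt0) mod 24` with ZT0 = lights-on; under 12:12 LD the dark
phase is ZT12–24.

## Locomotion model

Each fly is a 1-D random walk in continuous position `x ∈ [0, L]` with
reflecting walls.  Per second:

1. movement occurs with probability `clamp(p_move · phase + β_eff, 0, 1)`,
   where `phase` is `light_factor` when the tube is illuminated and
   `dark_factor` otherwise;
2. a moving fly is displaced by `N(drift, (step_scale · d)²)`;
3. crossings are the beam coordinates on the (possibly wall-reflected)
   path, and the reported position is the beam last crossed.

Drift terms (all in beam widths per moving second):

* `food_bias` toward the nearest tube end — both ends are food-plugged in
  the two-choice assay;
* `ethanol_dark_boost` toward the ethanol end (the high-index end) during
  the dark phase;
* `blue_aversion` away from the currently blue-lit zone (innate
  avoidance);
* a learned, position-bound bias: while a fly experiences blue light on a
  side, its aversion to that *physical side* grows by `learn_rate` per
  second up to `learn_cap`, and the drift is proportional to the
  left/right aversion difference.  Because the learned bias is bound to
  position, not color, interchanging the zone colors mid-session sends the
  learned preference back to chance — the signature that distinguishes
  place learning from pure photophobia.

### Startle and habituation

A lights-off transition sets the startle increment to
`β_eff = β · κ^load`; the habituation load then rises by one and relaxes
toward zero with time constant `τ_rec` between stimuli, while `β_eff`
itself decays with time constant `τ = 12 s`, so the elevated movement
probability is visible for a few tens of seconds — consistent with a
response window of about 30 s, which is also the analysis window.  The
load recursion before stimulus *m* at a fixed interval *T* is
`N_m = (N_{m−1} + 1) · e^{−T/τ_rec}`, verified in the tests against this
closed form.  Short inter-trial intervals let less load decay between
stimuli, so 1-min trains desensitize more than 5-min trains; `κ = 1`
switches habituation off entirely.

Negative responders (freezing) carry a negative β, clamped at zero
movement probability; non-responders carry β = 0.  `make_cohort` draws
each fly's class from a `(p_none, p_negative)` mixture and adds
mean-preserving lognormal jitter to baseline activity (CV 0.4 by default),
which is what produces the positive correlation between pre- and
post-stimulus activity across flies.

## Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| `p_move` | 0.25 (generic) | 1/s | moderate walking fraction; line presets use 0.06–0.12 for tube-confined daytime activity |
| `step_scale` | 1.2 | beam widths | steps around one beam width generate realistic count magnitudes |
| `startle_gain` β | 0.35–0.6 | Δ movement prob. | sized so responder deltas are a few tenths of a count/s |
| `startle_tau` τ | 12 | s | response decays within ~30 s |
| `habit_decay` κ | 0.6–0.75 (presets) | – | visible desensitization within a 2-h session |
| `habit_recovery` τ_rec | 600–1200 | s | recovery slow enough that 1-min trains accumulate load, fast enough that 30-min trains do not |
| `light_factor`/`dark_factor` | 1.0 / 0.5 | – | reduced dark-phase locomotion under LD |
| `ethanol_dark_boost` | 0.04 (assay preset) | beam widths | sized so the hourly ethanol-end occupancy vs ZT correlation is a weak but statistically significant effect (r ≈ 0.2 at 15 flies × 48 h) — a mild circadian modulation, not a dominant one |
| `blue_aversion` | 0.4 (innate preset) | beam widths | strong immediate avoidance (blue occupancy ≈ 25% from hour 1) |
| `learn_rate`, `learn_cap` | 2·10⁻⁴, 0.3 | 1/s, beam widths | aversion saturates after ~1.5 h of blue exposure, giving a gradual learning curve over a 5-h session |

Line presets (`csorc`, `w1118`, `fragile_x`) combine these into a weakly
active, mostly unresponsive red-eyed wild type (responder mixture
0.59/0.08/0.33 none/negative/positive), a more active and more responsive
white-eyed line that also desensitizes at 5-min intervals (0.31/0.12
mixture, κ = 0.6, τ_rec = 1200 s), and a fragile-X-like line with balanced
increase/decrease responding.  With these presets the simulated ITI
contrast expresses the intended line difference: the red-eyed preset shows
no epoch trend at 5-min ITI but a significant negative trend at 1-min,
while the white-eyed preset already trends downward at 5-min.

## Analysis conventions

* **Delta index**: pre window `[t−30, t)`, post window `(t, t+30]`,
  stimulus second excluded; delta = post − pre (positive = more movement
  after darkness).  Windows are second-aligned.
* **No change** means exact equality of the two 30-s sums — counts are
  integers, so exact-zero deltas are well defined and common for inactive
  flies.
* **Dead-fly exclusion** removes flies with zero counts in every pre and
  post window of the session; activity outside the windows does not rescue
  a fly (the rule is window-based by construction).
* **Epochs** are half-open `[kL, (k+1)L)` bins of stimulus time, origin at
  the first stimulus; the habituation trend test runs on per-fly epoch
  means (one value per fly per epoch).
* **Speed** is the mean per-second absolute beam displacement — the only
  speed measure recoverable from a stored trace.
* **Linear trend**: centered-score contrast, F on (1, N−k) df against the
  pooled within-group MS; slope is per unit epoch; R² is contrast SS over
  *between-group* SS (the "post test for trend" convention — values near 1
  mean the between-epoch differences are almost perfectly linear), not
  over total SS.
* **Occupancy** uses the position channel only ("time spent"), with the
  tube ends scored as the outer two beams; the food assay discards the
  first ~12 h (CO₂ recovery/settling) and starts scoring at ZT0; the ZT of
  a bin is the ZT of its start; the ZT correlation pools fly×bin points.
* **Controller**: tick = 1 s (the acquisition resolution — sub-second
  reaction is unmodellable from the data); the zone boundary defaults to
  beam 9, the midpoint of 17, with hysteresis for a fly sitting exactly on
  the boundary so the LEDs do not chatter; a command is emitted only when
  a tube's color changes; the whole tube takes the occupied zone's color;
  a zone swap remaps colors, not the accumulated zone labels.  The
  read→decide→write loop has exactly one tick of latency: the color during
  second *t* reflects the zone occupied at *t − 1*.  This contract is
  re-verified by brute force on every simulated closed-loop session in the
  tests.

## Validation scale

The test suite validates the pipeline at the scale the protocols
prescribe: 200 replicate null cohorts of 58 flies for type-I calibration
of the startle test (rejection rate within [3%, 7%] at nominal 5%), 100
replicates per gain level for monotone parameter recovery with a
10×-replicated Monte-Carlo oracle, 200 replicates of 96-fly 1-min-ITI
sessions for habituation trend power (≥ 80%) with a matched κ = 1
calibration arm, 50 and 200 replicates of the 15-fly × 48-h ethanol assay
for power and calibration, 50 closed-loop sessions for the latency
contract, and 96-fly closed-loop sessions for the three preference curve
shapes.  The whole suite runs in a few minutes on one CPU because the
simulator is vectorized across flies and replicates.

## Known limitations

* Per-second movement is Bernoulli without bout structure; real flies rest
  in long bouts, so the simulated fraction of exactly-zero deltas for
  weakly active flies is lower than live recordings show, and the
  unresponsive-trial percentages printed by the acceptance script are
  accordingly smaller than live-fly values.
* Freezing responses are floored at zero movement probability, so a
  mixture with balanced positive/negative responder shares retains a small
  positive mean delta (response asymmetry), rather than averaging exactly
  to zero.
* There is no between-session carryover, so a line that arrives already
  desensitized ("floor effect from the first trial") is not reproduced.
* Kinematics are 1-D; jumps, grooming and wall-following are not
  modelled, and the food interaction is purely positional — no ingestion
  is simulated.
* Trial-to-trial within-fly gain variability is not modelled (the
  heterogeneity knob jitters flies, not trials); the paired-trial
  variance structure of real data is therefore simplified.

These limitations mean the passing tests establish internal correctness
and statistical calibration of the pipeline on data with the assumed
structure — not that the generator is a quantitative model of fly
behaviour.
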