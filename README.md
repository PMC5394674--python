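# pairschool

Tools for studying pair schooling in burst-and-glide swimmers (zebrafish-style
locomotion) as a minimum-time optimal-control problem, and for extracting the
empirical interaction rules — social forcemaps — that such a controller
predicts.

The package covers the full loop:

1. **Kinematics** — smooth tracked positions (170 ms moving average), finite
   differences, segmentation of the saw-tooth speed profile into glide phases,
   and a joint fit of the viscous drag constant shared across all glides.
2. **Controller** — the bang-bang schooling policy: burst at the maximal
   available acceleration or glide passively, switching on the surface where
   gliding alone reaches cohesion.
3. **Simulator** — a closed-loop leader–follower pair on a quasi-1-D ring,
   with Markov non-social episodes and alternating leadership.
4. **Forcemap** — focal-frame projection, quasi-1-D filtering, occupancy-
   weighted binned mean accelerations, temporal-shuffle amplitude correction,
   distance profiles and quadrant summaries.
5. **Predictability** — fraction of explained linear variation
   `f = (T − U)/T`, autoregressive vs social predictability of acceleration,
   and lagged velocity cross-correlation (leadership).
6. **Synthio** — tracker-dialect file I/O and synthetic fixtures with known
   ground truth, so every stage is testable without recordings.

## The model

A gliding fish decelerates under viscous drag, `dv/dt = −α v` with
`α = 2.7 s⁻¹`; a bursting fish accelerates towards its aerobic ceiling,
`a = a_max (1 − v/v_max)` with `a_max = 60 cm s⁻²`, `v_max = 30 cm s⁻¹`.
Given its own speed `v_F`, the partner's speed `v_P` and the signed gap
`d = x_P − x_F`, the time-optimal policy for reaching *maximal cohesion*
(same position, same speed) is bang-bang.  For `v_F ≥ v_P` a pure glide
closes exactly

    d*(v_F, v_P) = (v_F − v_P)/α − (v_P/α) · ln(v_F/v_P)

before the speeds match, so the decision function is `T = d − d*`
(`T = d` for a slower focal fish): burst while `T > 0`, glide otherwise,
and always glide when ahead of the partner (`d < 0`), whose position in the
rear blind angle cannot be estimated reliably.

Closing the loop with a non-social burst–glide leader and a follower that
obeys this rule (except during non-social episodes, 20% of time, 15 s mean)
reproduces the headline statistics of real pairs: mean speeds ≈ 13 cm/s,
median inter-fish distance ≈ 4–5 cm, and forcemaps whose peak amplitude is
diluted from the 60 cm/s² burst rule down to ≈ 25 cm/s².

## Worked example

Simulate a 30-minute pair recording, then analyse it with the same pipeline
that would be applied to tracked video:

```bash
$ pairschool simulate --seed 7 --out run7.csv
mean speeds: 12.57, 12.57 cm/s
median distance: 4.41 cm

$ pairschool fitdrag run7.csv
alpha_hat = 2.3187 1/s
fraction_explained = 0.7986
n_segments = 3060

$ pairschool forcemap run7.csv --shuffle 10 --wrap-length 140 --out map7.csv
k = 0.319; peak |force| = 33.29 cm/s^2
```

The two fish swim at ≈ 12.6 cm/s and track each other at a median gap of
4.4 cm.  The drag fit pools 3060 glide segments from both fish and recovers
a shared decay constant of 2.32 s⁻¹ — below the generating 2.7 s⁻¹ because
the 170 ms smoothing filter flattens the fastest part of each decay, the
same bias the full pipeline imposes on real recordings — while exponential
decay explains ~80% of the linear variation in glide speeds.  The forcemap
extraction finds that a temporally shuffled pair would produce 31.9% of the
observed map occupancy by chance (`k = 0.319`), so force amplitudes are
scaled by `1/(1 − k) ≈ 1.47`, giving a corrected single-run peak of
33 cm/s².

The same steps are available as library calls (`simulate_pair`,
`fit_shared_drag`, `bin_forcemap`, `quadrant_analysis`, ...); see the module
docstrings and `docs/methods.md`.

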