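# Methods

## The model

`affatp` simulates response learning under *associative two-process* (ATP)
accounts of conditioning: behavior is driven both by direct
stimulus–response (S–R, "retrospective") associations and by a
stimulus–expectancy–response (S–E–R, "prospective") chain in which the
learned *outcome expectancy* of a stimulus acts as an internal cue for
responding. When different correct mappings yield different outcomes
(differential outcomes training), the expectancies differ, and novel stimuli
paired with a familiar outcome can cue the response associated with that
outcome without any direct S–R learning — transfer of control.

### Dual-channel critic

Stimulus valuation is computed by a temporal-difference (TD) value network
with two channels:

* **Magnitude channel.** A tapped-delay-line (complete serial compound)
  representation: stimulus onset starts a clock, and each step-since-onset is
  a feature with its own weight. The TD error is the Euler discretization of
  the continuous-time TD error with per-step discount `gamma = 1 − dt/tau`;
  with the default `tau = 200` steps and a 10-step cue→reward interval the
  discount over the interval is ≥ 0.95, so the converged prediction at the
  reinforcer-delivery step equals the reinforcer magnitude *R* and earlier
  taps hold `gamma^k R` — the prediction transfers backward to cue onset, as
  in TD accounts of phasic dopamine. Weights are updated only by the
  **non-negative part** of the TD error (`w += alpha_mag * max(0, delta) *
  trace`), so the channel learns but never unlearns: acquisition is
  permanent, as in amygdala-style accounts of conditioned value. Eligibility
  traces decay by `trace_decay * gamma` per step (default 0.9).

* **Omission channel.** One value per stimulus identity, updated by a
  *signed* prediction error scored either when the reinforcer arrives or at
  the *expected reward time* — the step at which the stimulus's magnitude
  prediction peaks (no omission can be experienced before some expectation
  exists; an `expectation_floor` of 0.05 gates scoring). The error is

      delta_om = (V_mag − r) − V_om

  where `V_mag` is the magnitude prediction at the scored step and `r` the
  delivered reward. Its fixed point is `V_om = (1 − lambda) · V_mag`: the
  omission probability *as a fraction of the acquired magnitude*, hence the
  omission probability itself at unit magnitude. Weights are clipped at zero
  from below. The omission learning rate (default 0.2) must exceed the
  magnitude rate (default 0.05): fast, reversible omission expectancy over
  slow, permanent magnitude acquisition is what produces the savings effect.

The **inverted omission error** `−delta_om = r − (V_mag − V_om)` doubles as
the dopamine-like gating factor for response learning: it is exactly the
reward prediction error of the *net* expected value, positive when reward
arrives against pessimistic expectation and negative when an expected reward
is omitted.

### Expectancy readouts: valuation vs. classification

The channel outputs are read out twice, for two different jobs:

* **Valuation (E1/E2).** `E2 = clip(V_om, 0, 1)` is a semi-linear relay of
  the omission value (≈ the omission probability), and
  `E1 = max(0, V_mag − E2)`, so at unit magnitude `E1 ≈ R − (1 − p) = p`,
  which coincides with the product valuation `Q = p·R` at `R = 1`. These are
  the quantities logged per trial and compared against `product_valuation`.

* **Classification (optimism/pessimism).** Response cueing uses steeply
  transformed activations: `pessimism = sigma_g(V_om)` (logistic, gain 10,
  threshold 0.25, with the zero-input baseline subtracted and renormalized so
  never-valued stimuli are strictly silent), which *strongly inhibits* the
  magnitude cue, `optimism = sigma_g(max(0, V_mag − 1.5 · pessimism))`. A
  half-rewarded stimulus (omission value ≈ 0.5) therefore registers as
  almost purely pessimistic, while a reliably rewarded one is almost purely
  optimistic; both activations below 0.5 label the stimulus neutral, and
  ties go to the pessimistic judgment. Using a saturating-but-graded
  (semi-linear) transform rather than a hard threshold is deliberate: a
  step function would make classification exact but destroy the graded
  recovery that produces savings.

Two calibration choices here were genuinely open and are the package's own:
the classification threshold 0.25 is the midpoint of the two omission
probabilities the standard protocol trains (0 and 0.5), which makes the
classification robust to fluctuation of the fast (hence noisy) omission
estimate; and the inhibition weight 1.5 makes the transformed omission
signal fully suppress the magnitude cue for a half-rewarded stimulus —
with weaker inhibition, residual optimism leaks the wrong response at
transfer. The valuation readout always uses unit-weight subtraction, per the
`E1 ≈ R − (1 − p)` identity.

### Actor

Both routes are linear response drives: `w_sr` (stimulus × response) and
`w_er` (expectancy class × response), combined additively with mixing
coefficients. Both are trained by the same three-factor rule

    dw = rate · pre · post · gating

with the chosen response's activation as the post-synaptic factor and the
inverted omission error as the gating factor. Selection is softmax over the
summed drives (temperature 0.2) with ε-uniform exploration (ε = 0.1 during
training, 0 during probes) — a seedable stand-in for winner-take-all lateral
inhibition with the same endpoint; ties resolve through the softmax draw.

The default route mixing is prospective-dominant (`sr_weight = 0.1`,
`er_weight = 1.0`). This is a deliberate design choice, not a neutral one:
response inhibition in this model works *through the value system* (omission
expectancy suppresses the optimistic cue), so if a strong S–R habit residual
carried responding, extinction would never suppress behavior and the savings
effect could not manifest behaviorally. The retrospective route remains as a
weaker habit route — sufficient for discrimination learning in the
common-outcomes control, where the expectancy code carries no information.
`actor_rate` defaults to 0.05.

### Architectures

* `aff_atp` — the individual model.
* `social_aff_atp` (extended common currency): observed (Other's)
  stimulus–outcome events are routed into the *same* critic as
  self-experienced ones; social pre-processing is modeled as a
  `social_context` flag on trials, and vicarious outcome perception is
  veridical. With no social input this wiring is bit-identical to `aff_atp`.
* `svs_atp` (social-valuation-specific): observed events train a *separate*
  social critic that shares the prediction-error arithmetic (a single
  `PredictionErrorUnit` instance consumed by both critics, exposed to
  instrumentation) but projects to separate sE1/sE2 relay nodes with their
  own actor rows, never to the self E1/E2 rows.

The dissociation prediction follows structurally: under `svs_atp` the social
pavlovian phase builds stimulus valuations whose relay nodes have no
response associations (those were formed on the self rows during
discrimination training), so transfer probes draw a response at chance; the
bridged variant in which social value nodes feed the non-social nodes
directly is left as a configuration extension point and is not implemented.

## Protocols and defaults

One trial is discretized as sample window (5 steps), delay (3 steps, the
conventional example delay), choice window (5 steps, reinforcer at its 3rd
step), ITI (10 steps). Stimuli are one-hot symbols without perceptual
similarity. Reward realization (Bernoulli draw against the outcome's
delivery probability λ) happens in the experiment runner, not the schedule,
so identical trial streams can be replayed across architectures; all
randomness descends from one seed split into per-phase streams.

* **Differential-outcomes discrimination**: S1–R1 rewarded with λ = 1.0,
  S2–R2 with λ = 0.5, 100 trials per mapping, randomized order. The
  **nondifferential control** replaces both outcomes with their 50/50
  mixture (λ = 0.75 for both), equating overall reinforcement rate while
  removing the differential cue — the control used for both the
  chance-transfer check and the acquisition-speed comparison.
* **Pavlovian pairing**: S3 with the λ = 1.0 outcome, S4 with the λ = 0.5
  outcome, 120 trials per pairing — enough for the λ = 0.5 pairing's
  magnitude value to converge at the default learning rate (a λ = 0.5 cue
  needs roughly 90–120 trials; with fewer, its omission value underestimates
  and the stimulus misclassifies). Socially observed in the social variant.
* **Transfer test**: S3 and S4 re-presented with R1/R2, 10 probes each, no
  feedback and no exploration by default, so measured choices reflect the
  pre-learning bias carried by the S–E and E–R associations (feedback is
  config-optional). Theory-preferred choices: S3→R1, S4→R2.
* **Savings**: acquisition (budget 400 trials), extinction (150), and
  reacquisition (budget 400) of S1–R1 at λ = 1.0 against a distractor
  response; trials-to-criterion is the first trial at which a 20-trial
  sliding window reaches ≥ 90% correct (the conventional criterion), with
  a phase that never reaches criterion contributing its budget plus a flag.

## What the synthetic protocols do and do not show

All inputs are generated schedules over abstract symbols; there is no
perceptual front end, no reaction-time model, no punishment channel, and no
within-trial response dynamics. Passing tests therefore show that the
*associative architecture* produces the qualitative phenomena (differential
expectancy classification, transfer of control, extinction savings, the
ECC/SVS dissociation) under idealized discriminanda — not that the model
fits any organism's trial-level data. Stochastic reward schedules leave the
fast omission value genuinely fluctuating at convergence (a property of the
model, not a numerical artifact), which is why converged quantities are
reported as tails averaged over the final 100 of 500 trials and multiple
seeds.

## Numerical choices and degenerate inputs

The TD update is one-step-delayed so the reward delivered at a step credits
the features active at that step; eligibility traces are cleared between
trials (the ITI is long). Omission scoring requires an existing expectation
(peak magnitude ≥ 0.05). Weight updates are elementwise and rectified
(magnitude) or zero-clipped (omission); no weight decay anywhere. Empty
schedules, zero-trial phases, never-trained stimuli, and unreachable
criteria all return flagged results rather than raising. Checkpoints
round-trip weights exactly through JSON.

## Known limitations

* Trials-to-criterion under the nondifferential control frequently never
  reaches the 90% criterion within the default budget: with an uninformative
  expectancy code, only the weak habit route discriminates. This is reported
  as a flagged budget value, and is itself the differential-outcomes effect
  in acquisition speed.
* The savings index is occasionally non-positive on seeds whose acquisition
  happens to be near the 20-trial window floor; the effect is a distribution
  over seeds, not a per-run guarantee.
* With λ near 0 no magnitude value is ever acquired, so the omission value
  is 0 (nothing expected, nothing to omit) — the omission channel estimates
  the omission probability only of *acquired* expectations.
* The competitive social scenario (comparing Other's outcome to one's own)
  and the action-prediction pathway of simulation-based accounts are out of
  scope.
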