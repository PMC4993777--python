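# affatp

Actor–critic simulations of **affective associative two-process (ATP)
learning**: a dual-channel temporal-difference value network that classifies
stimuli by reward-acquisition vs. reward-omission expectancy, and an
experiment harness for differential-outcomes training, transfer of control
(individual and *social*), and the extinction savings effect.

## The scientific problem

In differential-outcomes training, different correct stimulus–response
mappings earn different outcomes (here: reward probabilities λ = 1.0
vs. λ = 0.5). ATP theory holds that the learned outcome expectancy *E*
becomes an internal cue — behavior runs over a prospective S–E–R chain
alongside the retrospective S–R route — so stimuli *classified* by a common
outcome can cue responses they were never trained on (transfer of control,
TOC). This package implements a neural-computational account of those
expectancies and uses it to test a social hypothesis: if social and
non-social stimuli share one valuation circuit (*extended common currency*,
ECC), then merely **observing** another agent's stimulus–outcome pairings
should produce transfer of control in the observer; if social value lives in
a dedicated circuit with separate outputs (*social-valuation-specific*,
SVS), it should not.

The critic values every stimulus along two dimensions:

* **magnitude** `V_mag` — temporally discounted reinforcer strength, learned
  by TD with tapped-delay-line features and *rectified* errors: it learns
  but never unlearns;
* **omission** `V_om` — the probability of reward omission as a fraction of
  the acquired magnitude, learned fast and reversibly from signed errors
  `δ_om = (V_mag − r) − V_om` scored at the expected reward time.

The optimistic/pessimistic expectancy pair is read out as
`E2 = clip(V_om, 0, 1)` and `E1 = max(0, V_mag − E2) ≈ R − (1 − p)`, which
at unit magnitude equals the product valuation `Q = p·R`. The inverted
omission error `r − (V_mag − V_om)` gates a three-factor Hebbian rule that
trains both response routes; selection is softmax winner-take-all.

## Worked example

Training the critic on a single cue at several reward probabilities
(`python examples/01_expectancy_learning.py`):

```
lambda   v_mag   v_om     E1      Q=lam*R   label
 0.25   0.996  0.770   0.227   0.250     pessimistic
 0.50   1.000  0.533   0.467   0.500     pessimistic
 0.75   1.000  0.242   0.758   0.750     optimistic
 1.00   1.000  0.000   1.000   1.000     optimistic
```

The magnitude channel converges to the unit reinforcer magnitude regardless
of λ (it encodes *what* the reward is, not how often it comes); the omission
channel converges to 1 − λ; and the optimistic expectancy E1 tracks the
closed-form product valuation Q. The half-rewarded cue is classified by its
omission expectation — a pessimistic affective judgment.

The social dissociation (`python examples/03_social_dissociation.py`):

```
social_aff_atp   social transfer accuracy: median 0.90 over 10 seeds
svs_atp          social transfer accuracy: median 0.53 over 10 seeds
median accuracy gap (ECC - SVS): 0.38  (dissociation if > 0.2)
```

Both agents observe the same pavlovian pairings on another agent; only the
common-currency wiring turns that vicarious knowledge into correct
first-presentation choices (S3→R1, S4→R2) at transfer, because only there do
the observed stimuli reach the expectancy nodes that already carry response
associations. `examples/02_individual_transfer.py` shows the individual
effect and its common-outcomes control (median 0.90 vs. 0.50), and
`examples/04_savings.py` the extinction savings effect (median savings index
20 trials over 10 seeds).

## Command line

```
affatp run social-toc --variant ecc --seed 7 --out runs/
affatp sweep --experiment social-toc --variant ecc --variant svs --seeds 40 --out sweep.csv
affatp report sweep.csv
```

Each run writes a per-trial records CSV, a summary JSON, and a manifest with
the config hash and seeds; identical invocations are byte-identical.

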