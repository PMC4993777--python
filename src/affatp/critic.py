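"""Dual-channel temporal-difference value network.

The critic values each stimulus along two dimensions:

* a **magnitude** channel — a tapped-delay-line (complete serial compound) TD
  value function that learns the temporally discounted reinforcer magnitude.
  Its weights are updated only by the non-negative part of the TD error, so the
  channel learns but never unlearns (amygdala-like permanence of acquisition).
* an **omission** channel — a per-stimulus value updated by a *signed*
  prediction error scored at the time reward was expected (the step at which
  the magnitude prediction peaks) or actually delivered.  Because the error
  target is the difference between the magnitude prediction and the delivered
  reward, the converged omission value is the omission probability times the
  acquired magnitude: with unit reinforcers it estimates 1 - lambda
  (OFC-like fast, reversible expectancy learning).

The omission channel's inverted prediction error (reward received minus net
expected value) is the dopamine-like gating signal for the actor's
three-factor rule, and its output inhibits the magnitude output to yield the
optimistic/pessimistic expectancy pair E1/E2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .schedules import PhaseSchedule, TrialTiming, sample_trial_stream

__all__ = [
    "CriticParams",
    "CriticState",
    "PredictionErrors",
    "PredictionErrorUnit",
    "ExpectancySignal",
    "critic_step",
    "compute_expectancies",
    "run_conditioning_trial",
    "train_on_schedule",
    "extinguish",
    "save_checkpoint",
    "load_checkpoint",
    "sigmoid",
]

OPTIMISTIC = "optimistic"
PESSIMISTIC = "pessimistic"
NEUTRAL = "neutral"


def sigmoid(x: float | np.ndarray, gain: float = 1.0, threshold: float = 0.0):
    return 1.0 / (1.0 + np.exp(-gain * (np.asarray(x, dtype=float) - threshold)))


@dataclass(frozen=True)
class CriticParams:
    """Learning-rule constants.

    tau is the TD time constant: the per-step discount is gamma = 1 - dt/tau
    (Euler discretization of the continuous-time TD error).  The default
    tau = 200 steps gives gamma ~ 0.995, i.e. discount >= 0.95 over the
    ~10-step sample-to-reward interval.  The omission learning rate must
    exceed the magnitude rate (fast, flexible omission expectancy against
    slow, permanent magnitude acquisition) — this asymmetry is what produces
    the savings effect.
    """

    alpha_mag: float = 0.05
    alpha_om: float = 0.2
    tau: float = 200.0
    dt: float = 1.0
    trace_decay: float = 0.9
    sigmoid_gain: float = 10.0
    sigmoid_threshold: float = 0.25
    inhibition: float = 1.5
    expectation_floor: float = 0.05  # min peak magnitude before omission can be scored
    neutral_floor: float = 0.5  # classification scores below this on both channels -> neutral

    def __post_init__(self) -> None:
        if not self.alpha_om > self.alpha_mag:
            raise ValueError("omission learning rate must exceed magnitude rate")
        if not (0.0 < self.dt < self.tau):
            raise ValueError("need 0 < dt < tau")
        if not (0.0 <= self.trace_decay < 1.0):
            raise ValueError("trace decay must lie in [0, 1)")
        if self.sigmoid_gain <= 0:
            raise ValueError("sigmoid gain must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 - self.dt / self.tau


@dataclass
class CriticState:
    """Weights, traces, and one-step TD bookkeeping for a set of stimuli.

    Magnitude weights are (n_stimuli, n_taps): one tapped-delay-line value per
    stimulus.  Omission weights are (n_stimuli,): one omission value per
    stimulus identity.
    """

    stimuli: tuple[str, ...]
    n_taps: int
    w_mag: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_om: np.ndarray = field(default=None)  # type: ignore[assignment]
    traces: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: int = 0
    # pending previous step (features, reward, value) for the one-step-delayed TD update
    _prev: tuple[np.ndarray, float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.stimuli)
        if self.w_mag is None:
            self.w_mag = np.zeros((n, self.n_taps))
        if self.w_om is None:
            self.w_om = np.zeros(n)
        if self.traces is None:
            self.traces = np.zeros((n, self.n_taps))

    def index(self, stimulus: str) -> int:
        return self.stimuli.index(stimulus)

    def features(self, stimulus: str, tap: int) -> np.ndarray:
        """One-hot (stimulus, steps-since-onset) feature array; zeros past the line."""
        x = np.zeros_like(self.w_mag)
        if 0 <= tap < self.n_taps:
            x[self.index(stimulus), tap] = 1.0
        return x

    def peak_magnitude(self, stimulus: str) -> float:
        """The stimulus's acquired reinforcer-magnitude valuation (peak tap)."""
        return float(self.w_mag[self.index(stimulus)].max(initial=0.0))

    def expected_reward_tap(self, stimulus: str, floor: float) -> int | None:
        """The step-since-onset at which reward is expected, if any expectation exists."""
        row = self.w_mag[self.index(stimulus)]
        if row.max(initial=0.0) < floor:
            return None
        return int(row.argmax())

    def omission_value(self, stimulus: str) -> float:
        return float(self.w_om[self.index(stimulus)])

    def reset_trial(self) -> None:
        """Clear eligibility traces and pending TD bookkeeping between trials."""
        self.traces[:] = 0.0
        self._prev = None


class PredictionErrorUnit:
    """The prediction-error arithmetic as a shareable node.

    Separate value functions (e.g. self and simulated-other critics) can hold a
    reference to the *same* unit, modeling shared dopaminergic error computation
    with separate value representations.  Call counters expose the sharing to
    instrumentation and tests.
    """

    def __init__(self) -> None:
        self.magnitude_calls = 0
        self.omission_calls = 0

    def magnitude_error(
        self, reward: float, gamma: float, value_next: float, value_prev: float
    ) -> float:
        self.magnitude_calls += 1
        return reward + gamma * value_next - value_prev

    def omission_error(
        self, magnitude_prediction: float, reward: float, omission_value: float
    ) -> float:
        self.omission_calls += 1
        return (magnitude_prediction - reward) - omission_value


@dataclass(frozen=True)
class PredictionErrors:
    delta_mag: float
    delta_om: float

    @property
    def gating(self) -> float:
        """Inverted omission error: the dopamine-like third factor for the actor."""
        return -self.delta_om


@dataclass(frozen=True)
class ExpectancySignal:
    """Expectancy readouts for one stimulus.

    E1/E2 are the value-preserving relay outputs (E2 is the semi-linear
    omission relay, so E1 ~= R - (1 - p) at unit magnitude); optimism/pessimism
    are the steeply transformed classification activations that cue responses,
    with the transformed omission signal strongly inhibiting the magnitude cue.
    """

    v_mag_out: float
    v_om_out: float
    E1: float
    E2: float
    optimism: float
    pessimism: float
    label: str

    @property
    def cue_vector(self) -> np.ndarray:
        """Pre-synaptic activations for expectancy-response learning."""
        return np.array([self.optimism, self.pessimism])


def _classify(v_mag: float, v_om: float, params: CriticParams) -> ExpectancySignal:
    E2 = float(np.clip(v_om, 0.0, 1.0))  # semi-linear relay ~ omission probability
    # valuation readout: unit-weight subtraction, E1 ~= R - (1 - p); the
    # `inhibition` weight applies only to the classification pathway below
    E1 = max(0.0, v_mag - E2)
    # Classification activations: steep logistic with its zero-input baseline
    # subtracted, so relays of never-valued stimuli are strictly silent.
    base = float(sigmoid(0.0, params.sigmoid_gain, params.sigmoid_threshold))
    pessimism = (
        float(sigmoid(v_om, params.sigmoid_gain, params.sigmoid_threshold)) - base
    ) / (1.0 - base)
    pessimism = max(0.0, pessimism)
    inhibited_mag = max(0.0, v_mag - params.inhibition * pessimism)
    optimism = (
        float(sigmoid(inhibited_mag, params.sigmoid_gain, params.sigmoid_threshold))
        - base
    ) / (1.0 - base)
    optimism = max(0.0, optimism)
    if max(optimism, pessimism) < params.neutral_floor:
        label = NEUTRAL
    elif pessimism >= optimism:
        label = PESSIMISTIC
    else:
        label = OPTIMISTIC
    return ExpectancySignal(v_mag, v_om, E1, E2, optimism, pessimism, label)


def compute_expectancies(
    state: CriticState, params: CriticParams, stimulus: str
) -> ExpectancySignal:
    """Expectancy outputs for a stimulus from the current weights."""
    return _classify(state.peak_magnitude(stimulus), state.omission_value(stimulus), params)


def critic_step(
    state: CriticState,
    params: CriticParams,
    stimulus_features: np.ndarray,
    reward_signal: float,
    dt: float | None = None,
    pe_unit=None,
) -> tuple[CriticState, PredictionErrors, ExpectancySignal]:
    """One discretized TD update of both channels.

    `stimulus_features` is the (n_stimuli, n_taps) one-hot array active at this
    step; `reward_signal` is the reinforcer magnitude delivered at this step.
    The magnitude TD error credits the features active when the reward arrived
    (one-step-delayed update), rectified before the weight update so the channel
    never unlearns.  The omission error is scored when reward arrives or at the
    expected reward time, whichever happens, and is applied signed.

    Returns the (mutated) state with this step's errors and expectancy outputs.
    `pe_unit`, when given, supplies the prediction-error arithmetic (shared
    error nodes across value functions); see `affatp.architectures`.
    """
    x = np.asarray(stimulus_features, dtype=float)
    if x.shape != state.w_mag.shape:
        raise ValueError(
            f"feature shape {x.shape} does not match weights {state.w_mag.shape}"
        )
    if not np.all(np.isfinite(x)) or not np.isfinite(reward_signal):
        raise ValueError("non-finite critic inputs")
    if reward_signal < 0:
        raise ValueError("negative reward signal (punishment channel not modeled)")
    if dt is not None and dt != params.dt:
        params = CriticParams(**{**asdict(params), "dt": dt})
    gamma = params.gamma
    if pe_unit is None:
        pe_unit = PredictionErrorUnit()

    value_now = float((state.w_mag * x).sum())

    # --- magnitude channel: finish the previous step's TD update -------------
    delta_mag = 0.0
    if state._prev is not None:
        x_prev, r_prev, v_prev = state._prev
        delta_mag = pe_unit.magnitude_error(r_prev, gamma, value_now, v_prev)
        state.traces *= params.trace_decay * gamma
        state.traces += x_prev
        state.w_mag += params.alpha_mag * max(0.0, delta_mag) * state.traces

    # --- omission channel: score at delivery or at the expected reward time --
    delta_om = 0.0
    active = np.nonzero(x.any(axis=1))[0]
    if active.size:
        s = int(active[0])
        tap = int(np.nonzero(x[s])[0][0])
        expected_tap = state.expected_reward_tap(
            state.stimuli[s], params.expectation_floor
        )
        if reward_signal > 0 or tap == expected_tap:
            v_mag_here = float(state.w_mag[s, tap])
            delta_om = pe_unit.omission_error(
                v_mag_here, reward_signal, float(state.w_om[s])
            )
            state.w_om[s] = max(0.0, state.w_om[s] + params.alpha_om * delta_om)

    state._prev = (x, float(reward_signal), float((state.w_mag * x).sum()))
    state.t += 1

    errors = PredictionErrors(delta_mag=delta_mag, delta_om=delta_om)
    if active.size:
        expectancy = compute_expectancies(state, params, state.stimuli[int(active[0])])
    else:
        expectancy = _classify(0.0, 0.0, params)
    return state, errors, expectancy


def run_conditioning_trial(
    state: CriticState,
    params: CriticParams,
    stimulus: str,
    delivered_reward: float,
    timing: TrialTiming | None = None,
    pe_unit=None,
) -> PredictionErrors:
    """Run the critic through one trial of a stimulus followed (or not) by a
    reinforcer at the timing's reward step.  Returns the trial's omission-scored
    errors (the gating signal for instrumental learning on this trial).
    """
    timing = timing or TrialTiming()
    state.reset_trial()
    trial_delta_om = 0.0
    trial_delta_mag = 0.0
    for step in range(timing.n_steps):
        r = delivered_reward if step == timing.reward_step else 0.0
        x = state.features(stimulus, step)
        _, errors, _ = critic_step(state, params, x, r, pe_unit=pe_unit)
        trial_delta_mag += errors.delta_mag
        if errors.delta_om != 0.0:
            trial_delta_om = errors.delta_om
    # flush the final pending step so the reward-step tap is credited
    _, errors, _ = critic_step(
        state, params, np.zeros_like(state.w_mag), 0.0, pe_unit=pe_unit
    )
    trial_delta_mag += errors.delta_mag
    state.reset_trial()
    return PredictionErrors(delta_mag=trial_delta_mag, delta_om=trial_delta_om)


def train_on_schedule(
    state: CriticState,
    params: CriticParams,
    schedule: PhaseSchedule,
    rng: np.random.Generator,
    pe_unit=None,
) -> list[PredictionErrors]:
    """Pavlovian training: realize each trial's outcome and condition the critic."""
    out = []
    for trial in sample_trial_stream(schedule, int(rng.integers(2**31))):
        reward = trial.outcome.realize(rng)
        out.append(
            run_conditioning_trial(
                state, params, trial.sample_stimulus, reward, trial.timing, pe_unit
            )
        )
    return out


def extinguish(
    state: CriticState,
    params: CriticParams,
    schedule: PhaseSchedule,
    pe_unit=None,
) -> CriticState:
    """Extinction: present the schedule's stimuli with reward withheld.

    Omission values rise toward the (intact) magnitude values, so E1 falls
    toward zero while the magnitude weights are untouched — responding is
    inhibited, not unlearned.
    """
    for trial in schedule.trials:
        run_conditioning_trial(
            state, params, trial.sample_stimulus, 0.0, trial.timing, pe_unit
        )
    return state


# --- checkpointing -----------------------------------------------------------


def save_checkpoint(
    state: CriticState, params: CriticParams, path: str | Path
) -> None:
    """JSON checkpoint (exact round trip of weights, params, step counter)."""
    payload = {
        "stimuli": list(state.stimuli),
        "n_taps": state.n_taps,
        "w_mag": state.w_mag.tolist(),
        "w_om": state.w_om.tolist(),
        "t": state.t,
        "params": asdict(params),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_checkpoint(path: str | Path) -> tuple[CriticState, CriticParams]:
    payload = json.loads(Path(path).read_text())
    params = CriticParams(**payload["params"])
    state = CriticState(
        stimuli=tuple(payload["stimuli"]),
        n_taps=int(payload["n_taps"]),
        w_mag=np.array(payload["w_mag"], dtype=float),
        w_om=np.array(payload["w_om"], dtype=float),
        t=int(payload["t"]),
    )
    return state, params
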