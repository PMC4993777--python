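"""Agent architectures: individual, extended-common-currency, and
social-valuation-specific wirings of the dual-channel critic and the actor.

* ``AFF_ATP`` — the individual model: one critic, one actor.
* ``SOCIAL_AFF_ATP`` (extended common currency, ECC) — observed (Other's)
  stimulus-outcome events are routed into the *same* self critic, so social
  valuations recruit the existing non-social value function and its E1/E2
  relay nodes.  With no social input this is identical to ``AFF_ATP``.
* ``SVS_ATP`` (social-valuation-specific) — observed events are routed into a
  *separate* social critic whose outputs project to separate sE1/sE2 relay
  nodes with their own response-association rows.  Both critics share the same
  prediction-error unit (shared error computation, separate representations).
  Because sE1/sE2 never acquired response associations during instrumental
  training, a social pavlovian phase cannot cue self responses at transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actor import ActorState, select_response, three_factor_update
from .critic import (
    CriticParams,
    CriticState,
    ExpectancySignal,
    PredictionErrorUnit,
    compute_expectancies,
    run_conditioning_trial,
)
from .schedules import OBSERVED, PAVLOVIAN, OutcomeSpec, Trial, TrialTiming

__all__ = [
    "AFF_ATP",
    "SOCIAL_AFF_ATP",
    "SVS_ATP",
    "VARIANTS",
    "ArchitectureConfig",
    "Agent",
    "make_architecture",
    "product_valuation",
    "PredictionErrorUnit",
]

AFF_ATP = "aff_atp"
SOCIAL_AFF_ATP = "social_aff_atp"
SVS_ATP = "svs_atp"
VARIANTS = (AFF_ATP, SOCIAL_AFF_ATP, SVS_ATP)
_ALIASES = {"ecc": SOCIAL_AFF_ATP, "svs": SVS_ATP, "individual": AFF_ATP}


def resolve_variant(name: str) -> str:
    key = name.strip().lower().replace("-", "_")
    key = _ALIASES.get(key, key)
    if key not in VARIANTS:
        raise ValueError(f"unknown architecture variant {name!r}; choose from {VARIANTS}")
    return key


def product_valuation(p: float, R: float) -> float:
    """Closed-form stimulus valuation Q = p * R (probability times magnitude).

    Serves as the reference against which the converged optimistic expectancy
    E1 is compared at unit magnitude (E1 ~= R - (1 - p) = p at R = 1).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if R < 0:
        raise ValueError(f"magnitude must be >= 0, got {R}")
    return p * R


@dataclass(frozen=True)
class ArchitectureConfig:
    variant: str = AFF_ATP
    stimuli: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    responses: tuple[str, ...] = ("R1", "R2")
    critic_params: CriticParams = field(default_factory=CriticParams)
    actor_rate: float = 0.05
    temperature: float = 0.2
    epsilon: float = 0.1
    sr_weight: float = 0.1
    er_weight: float = 1.0
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", resolve_variant(self.variant))


class Agent:
    """A wired architecture exposing ``observe`` (pavlovian) and ``choose`` /
    ``learn_instrumental`` (instrumental) entry points.

    Routing: self-context events always update the self critic.  Observed
    events update the self critic under ECC wiring and the social critic under
    SVS wiring (never both).  Expectancy cues for choice concatenate the self
    relay activations (E1, E2) with, under SVS, the social relay activations
    (sE1, sE2) on their own actor rows.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0) -> None:
        self.config = config
        self.variant = config.variant
        self.params = config.critic_params
        n_taps = config.timing.n_steps
        self.pe_unit = PredictionErrorUnit()
        self.self_critic = CriticState(stimuli=config.stimuli, n_taps=n_taps)
        self.social_critic = (
            CriticState(stimuli=config.stimuli, n_taps=n_taps)
            if self.variant == SVS_ATP
            else None
        )
        labels = ("E1", "E2", "sE1", "sE2") if self.variant == SVS_ATP else ("E1", "E2")
        self.actor = ActorState(
            stimuli=config.stimuli,
            responses=config.responses,
            expectancy_labels=labels,
            temperature=config.temperature,
            epsilon=config.epsilon,
            sr_weight=config.sr_weight,
            er_weight=config.er_weight,
        )
        self.rng = np.random.default_rng(seed)

    # --- routing -------------------------------------------------------------

    def _critic_for(self, social_context: str) -> CriticState:
        if social_context == OBSERVED and self.variant == SVS_ATP:
            return self.social_critic
        return self.self_critic

    def expectancy(self, stimulus: str) -> ExpectancySignal:
        """Self-relay expectancy signal for a stimulus (valuation readout)."""
        return compute_expectancies(self.self_critic, self.params, stimulus)

    def social_expectancy(self, stimulus: str) -> ExpectancySignal | None:
        if self.social_critic is None:
            return None
        return compute_expectancies(self.social_critic, self.params, stimulus)

    def cue_activations(self, stimulus: str) -> np.ndarray:
        """Pre-synaptic expectancy activations over the actor's rows."""
        e = self.expectancy(stimulus)
        if self.variant != SVS_ATP:
            return e.cue_vector
        s = self.social_expectancy(stimulus)
        return np.concatenate([e.cue_vector, s.cue_vector])

    # --- pavlovian learning ---------------------------------------------------

    def observe(
        self, trial: Trial, rng: np.random.Generator | None = None
    ) -> tuple[float, float]:
        """Process one pavlovian trial (self-experienced or observed on Other).

        Returns (delivered reward, trial gating signal).  Vicarious outcome
        perception is veridical: the observer registers exactly the Other's
        delivered reward.
        """
        if trial.phase_kind != PAVLOVIAN:
            raise ValueError("observe() takes pavlovian trials")
        rng = rng or self.rng
        reward = trial.outcome.realize(rng)
        critic = self._critic_for(trial.social_context)
        errors = run_conditioning_trial(
            critic, self.params, trial.sample_stimulus, reward, trial.timing, self.pe_unit
        )
        return reward, errors.gating

    # --- instrumental behavior ------------------------------------------------

    def choose(
        self, trial: Trial, rng: np.random.Generator | None = None, explore: bool = True
    ) -> str:
        rng = rng or self.rng
        return select_response(
            self.actor,
            trial.sample_stimulus,
            self.cue_activations(trial.sample_stimulus),
            trial.available_responses,
            rng,
            explore=explore,
        )

    def learn_instrumental(
        self, trial: Trial, response: str, rng: np.random.Generator | None = None
    ) -> float:
        """Realize the chosen response's outcome, condition the critic on the
        experienced stimulus->reward sequence, and apply the three-factor
        update to both routes.  Returns the delivered reward."""
        rng = rng or self.rng
        cue = self.cue_activations(trial.sample_stimulus)
        outcome = trial.contingency.get(response, OutcomeSpec.null())
        reward = outcome.realize(rng)
        errors = run_conditioning_trial(
            self.self_critic,
            self.params,
            trial.sample_stimulus,
            reward,
            trial.timing,
            self.pe_unit,
        )
        three_factor_update(
            self.actor,
            cue,
            trial.sample_stimulus,
            response,
            errors.gating,
            rate=self.config.actor_rate,
        )
        return reward


def make_architecture(config: ArchitectureConfig, seed: int = 0) -> Agent:
    """Instantiate an agent for the given variant (contract-checked)."""
    return Agent(config, seed=seed)
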