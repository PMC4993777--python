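"""Response learning over the retrospective (S-R) and prospective (E-R) routes.

Both weight matrices are trained by the same three-factor rule: pre-synaptic
activation x post-synaptic (chosen-response) activation x a dopamine-like
gating signal (the critic's inverted omission prediction error).  Selection is
softmax over the summed route drives with optional epsilon-uniform exploration
— a seedable stand-in for the winner-take-all lateral-inhibition endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ActorState", "three_factor_update", "select_response", "response_probabilities"]


@dataclass
class ActorState:
    stimuli: tuple[str, ...]
    responses: tuple[str, ...]
    expectancy_labels: tuple[str, ...] = ("E1", "E2")
    w_er: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_sr: np.ndarray = field(default=None)  # type: ignore[assignment]
    temperature: float = 0.2
    epsilon: float = 0.1
    sr_weight: float = 1.0  # route-mixing coefficients (additive combination)
    er_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.w_er is None:
            self.w_er = np.zeros((len(self.expectancy_labels), len(self.responses)))
        if self.w_sr is None:
            self.w_sr = np.zeros((len(self.stimuli), len(self.responses)))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")

    def response_index(self, response: str) -> int:
        return self.responses.index(response)

    def stimulus_index(self, stimulus: str) -> int:
        return self.stimuli.index(stimulus)


def three_factor_update(
    actor: ActorState,
    expectancy_activations: np.ndarray,
    stimulus: str,
    response: str,
    gating: float,
    rate: float = 0.1,
) -> ActorState:
    """Hebbian pre x post association gated by the prediction-error factor.

    The chosen response's post-synaptic activation is 1; rows with zero
    pre-synaptic activation are untouched, and zero gating changes nothing.
    """
    if not np.isfinite(gating):
        raise ValueError("gating factor must be finite")
    j = actor.response_index(response)
    pre = np.asarray(expectancy_activations, dtype=float)
    if pre.shape != (len(actor.expectancy_labels),):
        raise ValueError(
            f"expectancy activations shape {pre.shape} does not match rows "
            f"{actor.expectancy_labels}"
        )
    actor.w_er[:, j] += rate * gating * pre
    actor.w_sr[actor.stimulus_index(stimulus), j] += rate * gating
    return actor


def _net_drive(
    actor: ActorState,
    stimulus: str | None,
    expectancy_activations: np.ndarray | None,
    available: tuple[str, ...],
) -> np.ndarray:
    idx = [actor.response_index(r) for r in available]
    drive = np.zeros(len(available))
    if stimulus is not None and stimulus in actor.stimuli:
        drive += actor.sr_weight * actor.w_sr[actor.stimulus_index(stimulus), idx]
    if expectancy_activations is not None:
        pre = np.asarray(expectancy_activations, dtype=float)
        drive += actor.er_weight * pre @ actor.w_er[:, idx]
    return drive


def response_probabilities(
    actor: ActorState,
    stimulus: str | None,
    expectancy_activations: np.ndarray | None,
    available_responses: tuple[str, ...],
    explore: bool = True,
) -> np.ndarray:
    """Selection distribution: softmax(net drive / temperature) mixed with
    epsilon-uniform exploration.  Always a proper distribution."""
    if not available_responses:
        raise ValueError("no available responses")
    drive = _net_drive(actor, stimulus, expectancy_activations, available_responses)
    z = drive / actor.temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    if explore and actor.epsilon > 0:
        p = (1 - actor.epsilon) * p + actor.epsilon / len(p)
    return p


def select_response(
    actor: ActorState,
    stimulus: str | None,
    expectancy_activations: np.ndarray | None,
    available_responses: tuple[str, ...],
    rng: np.random.Generator,
    explore: bool = True,
) -> str:
    """Winner-take-all choice via the softmax draw (ties resolved by the draw)."""
    p = response_probabilities(
        actor, stimulus, expectancy_activations, available_responses, explore
    )
    return available_responses[int(rng.choice(len(p), p=p))]
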