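"""Trial schedules for differential-outcomes and transfer-of-control protocols.

A schedule is a deterministic, seedable description of a training phase: which
abstract stimuli (S1, S2, ...) are shown, which responses (R1, R2, ...) are
available, and which response (if any) is followed by which reinforcer.
Reinforcers are (magnitude, delivery-probability) pairs; the Bernoulli draw
against the delivery probability happens in the experiment runner, not here,
so the same trial stream can be replayed across model variants.
"""

from __future__ import annotations

import csv
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "OutcomeSpec",
    "TrialTiming",
    "Trial",
    "PhaseSchedule",
    "TOCProtocol",
    "build_differential_outcomes_phase",
    "build_pavlovian_phase",
    "build_transfer_phase",
    "build_toc_protocol",
    "sample_trial_stream",
    "default_toc_config",
    "load_protocol_config",
    "schedule_to_csv",
]

INSTRUMENTAL = "instrumental"
PAVLOVIAN = "pavlovian"
TRANSFER = "transfer"

SELF = "self"
OBSERVED = "observed"


@dataclass(frozen=True)
class OutcomeSpec:
    """A reinforcer: identity, magnitude R, and per-trial delivery probability lambda."""

    outcome_id: str
    magnitude: float = 1.0
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"delivery probability must lie in [0, 1], got {self.probability}"
            )
        if self.magnitude < 0.0:
            raise ValueError(f"reinforcer magnitude must be >= 0, got {self.magnitude}")

    @classmethod
    def null(cls) -> "OutcomeSpec":
        """The no-reward outcome (zero magnitude)."""
        return cls(outcome_id="null", magnitude=0.0, probability=0.0)

    @property
    def is_null(self) -> bool:
        return self.magnitude == 0.0

    def realize(self, rng: np.random.Generator) -> float:
        """Draw the delivered reward for one trial (magnitude or 0)."""
        if self.is_null:
            return 0.0
        return self.magnitude if rng.random() < self.probability else 0.0


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event timing in simulation steps.

    The sample stimulus is on for `sample` steps, removed for `delay` steps,
    then response options appear for `choice_window` steps.  The reinforcer,
    when delivered, arrives a fixed two steps into the choice window.
    """

    sample: int = 5
    delay: int = 3
    choice_window: int = 5
    iti: int = 10

    def __post_init__(self) -> None:
        if min(self.sample, self.choice_window) < 1 or min(self.delay, self.iti) < 0:
            raise ValueError(f"invalid trial timing: {self}")

    @property
    def choice_onset(self) -> int:
        return self.sample + self.delay

    @property
    def reward_step(self) -> int:
        return self.choice_onset + 2

    @property
    def n_steps(self) -> int:
        """Steps the value network runs per trial (through reward + one flush step)."""
        return self.reward_step + 2

    @property
    def trial_length(self) -> int:
        return self.sample + self.delay + self.choice_window + self.iti


@dataclass(frozen=True)
class Trial:
    phase_kind: str
    sample_stimulus: str
    available_responses: tuple[str, ...] = ()
    contingency: Mapping[str, OutcomeSpec] = field(default_factory=dict)
    social_context: str = SELF
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self) -> None:
        if self.phase_kind not in (INSTRUMENTAL, PAVLOVIAN, TRANSFER):
            raise ValueError(f"unknown phase kind {self.phase_kind!r}")
        if self.social_context not in (SELF, OBSERVED):
            raise ValueError(f"unknown social context {self.social_context!r}")
        rewarded = [k for k, o in self.contingency.items() if not o.is_null]
        if self.phase_kind == PAVLOVIAN:
            if self.available_responses:
                raise ValueError("pavlovian trials afford no responses")
            if set(self.contingency) != {self.sample_stimulus}:
                raise ValueError(
                    "pavlovian trials pair exactly the sample stimulus with one outcome"
                )
        else:
            if len(self.available_responses) < 2:
                raise ValueError(
                    f"{self.phase_kind} trials need >= 2 available responses"
                )
            if len(rewarded) > 1:
                raise ValueError("at most one rewarded response per stimulus")
            unknown = set(self.contingency) - set(self.available_responses)
            if unknown:
                raise ValueError(f"contingency names unavailable responses {unknown}")

    @property
    def rewarded_response(self) -> str | None:
        for resp, out in self.contingency.items():
            if not out.is_null:
                return resp
        return None

    @property
    def outcome(self) -> OutcomeSpec:
        """The (single) non-null outcome this trial can deliver, or the null outcome."""
        for out in self.contingency.values():
            if not out.is_null:
                return out
        return OutcomeSpec.null()


@dataclass(frozen=True)
class PhaseSchedule:
    """An ordered set of trial templates, each repeated `n_per_template` times."""

    templates: tuple[Trial, ...]
    n_per_template: int
    order_policy: str = "randomized"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order_policy not in ("randomized", "blocked"):
            raise ValueError(f"unknown order policy {self.order_policy!r}")
        if self.n_per_template < 0:
            raise ValueError("n_per_template must be >= 0")

    @property
    def n_trials(self) -> int:
        return len(self.templates) * self.n_per_template

    @property
    def trials(self) -> tuple[Trial, ...]:
        """The full trial list in template-blocked order."""
        return tuple(t for t in self.templates for _ in range(self.n_per_template))

    @property
    def stimuli(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.templates:
            seen.setdefault(t.sample_stimulus, None)
        return tuple(seen)

    @property
    def outcome_ids(self) -> frozenset[str]:
        return frozenset(
            t.outcome.outcome_id for t in self.templates if not t.outcome.is_null
        )


def sample_trial_stream(schedule: PhaseSchedule, rng_seed: int | None = None) -> list[Trial]:
    """Expand a schedule into an ordered trial stream.

    `blocked` keeps template order; `randomized` permutes under `rng_seed`
    (falling back to the schedule's own seed).  Reward realizations are *not*
    drawn here.
    """
    trials = list(schedule.trials)
    if schedule.order_policy == "blocked":
        return trials
    seed = schedule.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    return [trials[i] for i in rng.permutation(len(trials))]


def build_differential_outcomes_phase(
    mappings: Sequence[tuple[str, str, OutcomeSpec]],
    n_per_template: int,
    seed: int = 0,
    timing: TrialTiming | None = None,
    order_policy: str = "randomized",
    social_context: str = SELF,
    responses: Sequence[str] | None = None,
) -> PhaseSchedule:
    """Discrimination-training schedule: each stimulus has one correct response
    rewarded per its OutcomeSpec; all other stimulus-response mappings go
    unrewarded.  ``responses`` may name extra (never-rewarded) options beyond
    those appearing as correct responses.
    """
    timing = timing or TrialTiming()
    stimuli = [m[0] for m in mappings]
    if len(set(stimuli)) != len(stimuli):
        raise ValueError(f"duplicate stimulus in mappings: {stimuli}")
    if responses is None:
        responses = tuple(dict.fromkeys(m[1] for m in mappings))
    else:
        responses = tuple(responses)
        missing = {m[1] for m in mappings} - set(responses)
        if missing:
            raise ValueError(f"correct responses {missing} not in response set")
    templates = []
    for stim, correct, outcome in mappings:
        if outcome.is_null:
            raise ValueError(f"correct mapping for {stim} must carry a non-null outcome")
        templates.append(
            Trial(
                phase_kind=INSTRUMENTAL,
                sample_stimulus=stim,
                available_responses=responses,
                contingency={correct: outcome},
                social_context=social_context,
                timing=timing,
            )
        )
    return PhaseSchedule(tuple(templates), n_per_template, order_policy, seed)


def build_pavlovian_phase(
    pairings: Sequence[tuple[str, OutcomeSpec]],
    n_per_template: int,
    seed: int = 0,
    timing: TrialTiming | None = None,
    order_policy: str = "randomized",
    social_context: str = SELF,
) -> PhaseSchedule:
    """Passive stimulus->outcome pairing phase (optionally observed on another agent)."""
    timing = timing or TrialTiming()
    templates = tuple(
        Trial(
            phase_kind=PAVLOVIAN,
            sample_stimulus=stim,
            contingency={stim: outcome},
            social_context=social_context,
            timing=timing,
        )
        for stim, outcome in pairings
    )
    return PhaseSchedule(templates, n_per_template, order_policy, seed)


def build_transfer_phase(
    probes: Sequence[str],
    responses: Sequence[str],
    n_per_template: int,
    seed: int = 0,
    timing: TrialTiming | None = None,
    feedback: Mapping[str, tuple[str, OutcomeSpec]] | None = None,
    order_policy: str = "randomized",
) -> PhaseSchedule:
    """Transfer-test schedule: pavlovian-phase stimuli re-presented with the
    discrimination-phase response options.  By default no feedback is given
    (choice is measured before any transfer-phase learning); `feedback` may map
    a probe stimulus to its (correct response, outcome).
    """
    timing = timing or TrialTiming()
    feedback = feedback or {}
    templates = tuple(
        Trial(
            phase_kind=TRANSFER,
            sample_stimulus=stim,
            available_responses=tuple(responses),
            contingency=(
                {feedback[stim][0]: feedback[stim][1]} if stim in feedback else {}
            ),
            timing=timing,
        )
        for stim in probes
    )
    return PhaseSchedule(templates, n_per_template, order_policy, seed)


@dataclass(frozen=True)
class TOCProtocol:
    """The three-phase transfer-of-control protocol."""

    discrimination: PhaseSchedule
    pavlovian: PhaseSchedule
    transfer: PhaseSchedule
    differential: bool
    predicted_choices: Mapping[str, str]  # probe stimulus -> theory-preferred response

    @property
    def phases(self) -> tuple[PhaseSchedule, PhaseSchedule, PhaseSchedule]:
        return (self.discrimination, self.pavlovian, self.transfer)


def default_toc_config(
    differential: bool = True,
    social: bool = False,
    seed: int = 0,
    n_discrimination: int = 100,
    n_pavlovian: int = 120,
    n_transfer: int = 10,
    transfer_feedback: bool = False,
) -> dict:
    """The standard protocol: S1-R1 rewarded with probability 1.0, S2-R2 with 0.5
    (differential outcomes by reward probability); S3/S4 paired with the same two
    outcomes in the pavlovian phase; S3/S4 probed with R1/R2 at transfer.

    The nondifferential control replaces both outcomes with their 50/50 mixture
    (delivery probability 0.75 for both mappings), equating overall reinforcement
    rate while removing the differential expectancy cue.
    """
    if differential:
        o1 = {"outcome_id": "O1", "magnitude": 1.0, "probability": 1.0}
        o2 = {"outcome_id": "O2", "magnitude": 1.0, "probability": 0.5}
    else:
        o1 = o2 = {"outcome_id": "O1", "magnitude": 1.0, "probability": 0.75}
    return {
        "seed": seed,
        "phases": {
            "discrimination": {
                "mappings": [
                    {"stimulus": "S1", "response": "R1", "outcome": o1},
                    {"stimulus": "S2", "response": "R2", "outcome": o2},
                ],
                "n_per_template": n_discrimination,
            },
            "pavlovian": {
                "pairings": [
                    {"stimulus": "S3", "outcome": o1},
                    {"stimulus": "S4", "outcome": o2},
                ],
                "n_per_template": n_pavlovian,
                "social": social,
            },
            "transfer": {
                "probes": ["S3", "S4"],
                "n_per_template": n_transfer,
                "feedback": transfer_feedback,
            },
        },
        "timing": {},
    }


def build_toc_protocol(config: dict) -> TOCProtocol:
    """Build the three phase schedules from a protocol config (see
    `default_toc_config` for the shape).  Raises if a pavlovian outcome was not
    used in the discrimination phase (transfer would be undefined).
    """
    timing = TrialTiming(**config.get("timing", {}))
    seed = int(config.get("seed", 0))
    phases = config["phases"]

    disc = phases["discrimination"]
    mappings = [
        (m["stimulus"], m["response"], OutcomeSpec(**m["outcome"]))
        for m in disc["mappings"]
    ]
    discrimination = build_differential_outcomes_phase(
        mappings, int(disc["n_per_template"]), seed=seed, timing=timing
    )

    pav = phases["pavlovian"]
    pairings = [(p["stimulus"], OutcomeSpec(**p["outcome"])) for p in pav["pairings"]]
    pavlovian = build_pavlovian_phase(
        pairings,
        int(pav["n_per_template"]),
        seed=seed + 1,
        timing=timing,
        social_context=OBSERVED if pav.get("social", False) else SELF,
    )

    unused = pavlovian.outcome_ids - discrimination.outcome_ids
    if unused:
        raise ValueError(
            f"pavlovian outcomes {sorted(unused)} never occur in the discrimination "
            "phase; transfer of control is undefined for them"
        )

    # Theory-preferred transfer choices: each probe cues the response whose
    # discrimination-phase mapping shared its outcome.
    outcome_to_response = {
        m[2].outcome_id: m[1] for m in mappings
    }
    predicted = {stim: outcome_to_response[out.outcome_id] for stim, out in pairings}

    tr = phases["transfer"]
    responses = tuple(dict.fromkeys(m[1] for m in mappings))
    feedback = None
    if tr.get("feedback", False):
        pair_outcomes = dict(pairings)
        feedback = {s: (predicted[s], pair_outcomes[s]) for s in tr["probes"]}
    transfer = build_transfer_phase(
        tr["probes"],
        responses,
        int(tr["n_per_template"]),
        seed=seed + 2,
        timing=timing,
        feedback=feedback,
    )

    differential = len({m[2].outcome_id for m in mappings}) > 1
    return TOCProtocol(discrimination, pavlovian, transfer, differential, predicted)


def load_protocol_config(path: str | Path) -> dict:
    """Load a protocol config from TOML or YAML."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def schedule_to_csv(
    schedule: PhaseSchedule, path: str | Path, rng_seed: int | None = None
) -> None:
    """Write the expanded trial stream, one row per trial."""
    stream = sample_trial_stream(schedule, rng_seed)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "phase",
                "trial_index",
                "stimulus",
                "social_context",
                "responses",
                "rewarded_response",
                "magnitude",
                "lambda",
            ]
        )
        for i, t in enumerate(stream):
            out = t.outcome
            writer.writerow(
                [
                    t.phase_kind,
                    i,
                    t.sample_stimulus,
                    t.social_context,
                    "|".join(t.available_responses),
                    t.rewarded_response or "",
                    out.magnitude,
                    out.probability,
                ]
            )
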