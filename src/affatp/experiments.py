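"""Protocol runners and summary metrics.

Every runner logs one record per trial and reduces the log to metrics with
``compute_metrics`` (a pure function of the records, so results can always be
recomputed from the per-trial CSV).  All randomness flows from the single seed
passed in: it is split into independent per-phase streams, so adding probe
trials never perturbs the training-phase draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architectures import Agent, ArchitectureConfig, make_architecture
from .schedules import (
    INSTRUMENTAL,
    PAVLOVIAN,
    SELF,
    TRANSFER,
    OutcomeSpec,
    PhaseSchedule,
    TOCProtocol,
    Trial,
    TrialTiming,
    build_toc_protocol,
    default_toc_config,
    sample_trial_stream,
)

__all__ = [
    "ExperimentResult",
    "run_phase",
    "run_toc",
    "run_social_toc",
    "run_savings",
    "compute_metrics",
    "sweep",
    "DEFAULT_CRITERION",
]

# Accuracy criterion: >= 90% correct over a 20-trial sliding window.
DEFAULT_CRITERION = (0.9, 20)

RECORD_COLUMNS = [
    "phase",
    "trial_index",
    "stimulus",
    "social_context",
    "response",
    "reward",
    "rewarded",
    "correct",
    "E1",
    "E2",
    "delta_om_gating",
]


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    metrics: dict
    seed: int
    config: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @property
    def empty(self) -> bool:
        return len(self.records) == 0


def _phase_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_phase(
    agent: Agent,
    schedule: PhaseSchedule,
    rng: np.random.Generator,
    phase_label: str,
    correct_response: dict[str, str] | None = None,
    explore: bool = True,
    learn: bool = True,
) -> list[dict]:
    """Run one phase, returning per-trial records.

    Pavlovian trials update the critic through the agent's routing; trials
    affording responses run choice and, when ``learn`` and the trial carries a
    contingency, instrumental learning.  ``correct_response`` designates the
    response scored as correct per stimulus (defaults to the rewarded one).
    """
    correct_response = correct_response or {}
    records: list[dict] = []
    stream = sample_trial_stream(schedule, int(rng.integers(2**31)))
    for i, trial in enumerate(stream):
        stim = trial.sample_stimulus
        if trial.phase_kind == PAVLOVIAN:
            reward, gating = agent.observe(trial, rng)
            response, correct = None, None
        else:
            response = agent.choose(trial, rng, explore=explore)
            if learn:
                # the experienced outcome of an unrewarded mapping is "no reward",
                # which the critic must register (extinction runs through here)
                reward = agent.learn_instrumental(trial, response, rng)
            else:
                reward = 0.0
            gating = np.nan
            target = correct_response.get(stim, trial.rewarded_response)
            correct = None if target is None else (response == target)
        exp = agent.expectancy(stim)
        records.append(
            {
                "phase": phase_label,
                "trial_index": i,
                "stimulus": stim,
                "social_context": trial.social_context,
                "response": response,
                "reward": reward,
                "rewarded": reward > 0,
                "correct": correct,
                "E1": exp.E1,
                "E2": exp.E2,
                "delta_om_gating": gating,
            }
        )
    return records


def compute_metrics(
    records: pd.DataFrame,
    criterion: tuple[float, int] = DEFAULT_CRITERION,
) -> dict:
    """Deterministic summary of a per-trial log.

    * ``trials_to_criterion_<phase>`` — trials until the sliding-window
      accuracy criterion is first met (None, flagged, if never met).
    * ``transfer_accuracy`` — mean correct over transfer-phase trials.
    * ``transfer_first_presentation`` — mean correct over each probe
      stimulus's first transfer trial (the pre-learning choice bias).
    Metrics are order-invariant given intact per-phase trial indices.
    """
    metrics: dict = {"flags": []}
    if len(records) == 0:
        metrics["flags"].append("empty-records")
        return metrics
    acc_level, window = criterion
    for phase, grp in records.groupby("phase", sort=False):
        grp = grp.sort_values("trial_index")
        correct = grp["correct"].dropna()
        if len(correct) == 0:
            continue
        vals = correct.to_numpy(dtype=float)
        key = f"trials_to_criterion_{phase}"
        metrics[key] = None
        if len(vals) >= window:
            rolling = np.convolve(vals, np.ones(window), mode="valid") / window
            hits = np.nonzero(rolling >= acc_level)[0]
            if hits.size:
                metrics[key] = int(hits[0] + window)
        if metrics[key] is None:
            metrics["flags"].append(f"criterion-not-reached:{phase}")
        metrics[f"accuracy_{phase}"] = float(vals.mean())
    transfer = records[records["phase"].str.startswith("transfer")]
    tcorrect = transfer["correct"].dropna()
    if len(tcorrect):
        metrics["transfer_accuracy"] = float(tcorrect.astype(float).mean())
        firsts = (
            transfer.dropna(subset=["correct"])
            .sort_values("trial_index")
            .groupby("stimulus", sort=False)
            .first()["correct"]
        )
        metrics["transfer_first_presentation"] = float(firsts.astype(float).mean())
    return metrics


def run_toc(
    agent: Agent,
    protocol: TOCProtocol,
    seed: int,
    criterion: tuple[float, int] = DEFAULT_CRITERION,
) -> ExperimentResult:
    """Run the three-phase transfer-of-control protocol on an untrained agent.

    Transfer choices are measured with exploration off and (by default) no
    feedback, so transfer accuracy reflects the pre-learning choice bias
    carried by the S-E and E-R associations alone.
    """
    rngs = _phase_rngs(seed, 3)
    records: list[dict] = []
    records += run_phase(
        agent, protocol.discrimination, rngs[0], "discrimination", explore=True
    )
    records += run_phase(agent, protocol.pavlovian, rngs[1], "pavlovian")
    transfer_feedback = any(t.contingency for t in protocol.transfer.templates)
    records += run_phase(
        agent,
        protocol.transfer,
        rngs[2],
        "transfer",
        correct_response=dict(protocol.predicted_choices),
        explore=False,
        learn=transfer_feedback,
    )
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    metrics = compute_metrics(df, criterion)
    metrics["differential"] = protocol.differential
    return ExperimentResult(df, metrics, seed, {"variant": agent.variant})


def run_social_toc(
    variant: str,
    protocol: TOCProtocol | None = None,
    seed: int = 0,
    config: ArchitectureConfig | None = None,
    criterion: tuple[float, int] = DEFAULT_CRITERION,
) -> ExperimentResult:
    """Social transfer of control: the pavlovian phase is observed on the
    Other and routed per the architecture variant (ECC vs SVS)."""
    if protocol is None:
        protocol = build_toc_protocol(default_toc_config(social=True, seed=seed))
    config = config or ArchitectureConfig(variant=variant)
    if config.variant != variant and variant:
        config = replace(config, variant=variant)
    agent = make_architecture(config, seed=seed)
    result = run_toc(agent, protocol, seed, criterion)
    result.config["variant"] = agent.variant
    return result


def _savings_trial(rewarded: bool, timing: TrialTiming) -> Trial:
    contingency = (
        {"R1": OutcomeSpec("O1", magnitude=1.0, probability=1.0)} if rewarded else {}
    )
    return Trial(
        phase_kind=INSTRUMENTAL,
        sample_stimulus="S1",
        available_responses=("R1", "R2"),
        contingency=contingency,
        timing=timing,
    )


def run_savings(
    agent: Agent | None = None,
    n_acquisition: int = 400,
    n_extinction: int = 150,
    n_reacquisition: int = 400,
    criterion: tuple[float, int] = DEFAULT_CRITERION,
    seed: int = 0,
    config: ArchitectureConfig | None = None,
) -> ExperimentResult:
    """Acquisition -> extinction -> reacquisition of a single rewarded mapping.

    The savings index is acquisition minus reacquisition trials-to-criterion;
    fast omission unlearning over intact magnitude weights makes it positive.
    A phase that never reaches criterion contributes its trial budget and a
    flag instead of crashing.
    """
    config = config or ArchitectureConfig(stimuli=("S1",), responses=("R1", "R2"))
    agent = agent or make_architecture(config, seed=seed)
    timing = agent.config.timing
    rngs = _phase_rngs(seed, 3)
    phases = [
        ("acquisition", n_acquisition, True),
        ("extinction", n_extinction, False),
        ("reacquisition", n_reacquisition, True),
    ]
    records: list[dict] = []
    for label, n, rewarded in phases:
        schedule = PhaseSchedule(
            templates=(_savings_trial(rewarded, timing),),
            n_per_template=n,
            order_policy="blocked",
        )
        records += run_phase(
            agent,
            schedule,
            rngs.pop(0),
            label,
            correct_response={"S1": "R1"},
        )
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    metrics = compute_metrics(df, criterion)
    tc_acq = metrics.get("trials_to_criterion_acquisition")
    tc_reacq = metrics.get("trials_to_criterion_reacquisition")
    if tc_acq is None:
        tc_acq = n_acquisition
    if tc_reacq is None:
        tc_reacq = n_reacquisition
    metrics["savings_index"] = tc_acq - tc_reacq
    return ExperimentResult(df, metrics, seed, {"variant": agent.variant})


def sweep(
    experiment: str,
    variants: tuple[str, ...],
    seeds: range | list[int],
    social: bool | None = None,
    protocol_config: dict | None = None,
) -> pd.DataFrame:
    """Multi-seed sweep producing a tidy long-format frame
    (seed, variant, metric, value)."""
    rows = []
    for variant in variants:
        for seed in seeds:
            if experiment in ("toc", "social-toc"):
                cfg = protocol_config or default_toc_config(
                    social=(experiment == "social-toc" if social is None else social),
                    seed=seed,
                )
                cfg = {**cfg, "seed": seed}
                protocol = build_toc_protocol(cfg)
                result = run_social_toc(variant, protocol, seed=seed)
            elif experiment == "savings":
                result = run_savings(seed=seed)
            else:
                raise ValueError(f"unknown experiment {experiment!r}")
            for metric, value in result.metrics.items():
                if isinstance(value, (int, float, np.floating, np.integer, bool)):
                    rows.append(
                        {
                            "seed": seed,
                            "variant": variant,
                            "metric": metric,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)
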