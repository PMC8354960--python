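"""Synthetic participants: a two-population attractor model of value-based choice.

Each choice option is represented by one population of an attractor network
with self-excitation, mutual inhibition and background noise; the first
population whose rectified activity crosses threshold determines the choice
(winner-takes-all).  Post-decision activity decays exponentially during the
inter-trial interval, so short ITIs leave a residual head start for the
previous winner — the mechanism behind choice repetition.  A polarization
offset emulates transcranial direct-current stimulation: depolarization
(anodal, positive offset) raises both populations' drive and slows the decay
of residual activity; hyperpolarization (cathodal) does the opposite.

Subjective value is hyperbolically discounted over distance (distance is a
time proxy in the coin game): V = value / (1 + k * distance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import design
from ._kernel import LF, SN, integrate_race
from .design import SessionPlan, TrialSpec

__all__ = [
    "AgentParams",
    "AgentState",
    "PopulationSpec",
    "DesignConfig",
    "CohortResult",
    "DEFAULT_2021",
    "subjective_value",
    "analytic_indifference_ratio",
    "analytic_indifference_profile",
    "simulate_decision",
    "apply_iti_decay",
    "simulate_session",
    "simulate_cohort",
    "hysteresis_probe",
    "CHOICE_LOG_COLUMNS",
]

CHOICE_LOG_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "stim",
    "sham_order",
    "trial_index",
    "triplet_id",
    "role",
    "sn_value",
    "lf_value",
    "sn_distance",
    "extra_distance",
    "iti_before_ms",
    "choice",
    "dt_ms",
    "timed_out",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the attractor agent (the committed "default-2021" set).

    Units: rates in 1/s, activities in arbitrary units with threshold 1,
    times in seconds except the millisecond fields t0 and tau_decay.
    """

    leak: float = 4.0  # 1/s
    w_self: float = 5.0  # self-excitation gain
    w_inh: float = 7.0  # mutual inhibition gain
    noise_sd: float = 0.8  # activity units / sqrt(s)
    threshold: float = 1.0  # activity units
    dt: float = 0.001  # s
    t0: float = 500.0  # non-decision time, ms
    tau_decay: float = 250.0  # ITI decay time constant, ms
    polarization: float = 0.0  # current activity offset (0 = sham)
    stim_polarization: float = 0.3  # |offset| applied for anodal/cathodal blocks
    decay_pol_gain: float = 1.5  # tau_decay scaling: tau * (1 + gain * polarization)
    k_discount: float = 0.15  # 1/field
    value_gain: float = 0.30  # input units per unit subjective value
    max_time: float = 4.0  # s, decision timeout

    def __post_init__(self):
        for name in ("leak", "noise_sd", "threshold", "dt", "tau_decay", "value_gain", "max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t0 < 0 or self.k_discount < 0:
            raise ValueError("t0 and k_discount must be non-negative")

    def with_stim(self, stim: str) -> "AgentParams":
        """Return a copy with the polarization offset for a stimulation condition."""
        offset = {"sham": 0.0, "anodal": self.stim_polarization, "cathodal": -self.stim_polarization}
        if stim not in offset:
            raise ValueError(f"unknown stimulation condition {stim!r}")
        return dataclasses.replace(self, polarization=offset[stim])

    @property
    def effective_tau_decay(self) -> float:
        """Decay time constant under the current polarization, ms."""
        factor = max(1.0 + self.decay_pol_gain * self.polarization, 0.05)
        return self.tau_decay * factor


DEFAULT_2021 = AgentParams()


@dataclass
class AgentState:
    """Activities of the two populations; rest state is (0, 0)."""

    x_sn: float = 0.0
    x_lf: float = 0.0
    last_choice: Optional[str] = None

    def copy(self) -> "AgentState":
        return AgentState(self.x_sn, self.x_lf, self.last_choice)


class DecisionResult(NamedTuple):
    choice: str  # "SN" | "LF"
    dt_ms: float
    state: AgentState
    timed_out: bool


def subjective_value(value: float, total_distance: float, k_discount: float) -> float:
    """Hyperbolically discounted value: value / (1 + k * distance)."""
    if value <= 0:
        raise ValueError("value must be positive")
    if total_distance < 1 or k_discount < 0:
        raise ValueError("total_distance must be >= 1 and k_discount >= 0")
    return value / (1.0 + k_discount * total_distance)


def analytic_indifference_ratio(sn_distance: int, extra_distance: int, k_discount: float) -> float:
    """Ratio sn/lf at which both discounted values are equal."""
    return (1.0 + k_discount * sn_distance) / (1.0 + k_discount * (sn_distance + extra_distance))


def analytic_indifference_profile(k_discount: float) -> design.IndifferenceProfile:
    """The agent's true r*(d), averaged over the two SN distances and clipped."""
    lo, hi = design.MIDPOINT_CLIP
    r = {
        d: float(
            np.clip(
                np.mean(
                    [analytic_indifference_ratio(ds, d, k_discount) for ds in design.SN_DISTANCES]
                ),
                lo,
                hi,
            )
        )
        for d in design.DISTANCES
    }
    return design.IndifferenceProfile(r_star=r, degenerate_flags={d: False for d in design.ANCHOR_DISTANCES})


def _trial_inputs(trial: TrialSpec, params: AgentParams) -> tuple[float, float]:
    v_sn = subjective_value(trial.sn_value, trial.sn_distance, params.k_discount)
    v_lf = subjective_value(trial.lf_value, trial.lf_distance, params.k_discount)
    return params.value_gain * v_sn, params.value_gain * v_lf


def simulate_decision(
    trial: TrialSpec, state: AgentState, params: AgentParams, rng: np.random.Generator
) -> DecisionResult:
    """Run one decision from the given residual state.

    Euler–Maruyama integration of the two-unit race until threshold crossing;
    the reported decision time adds the non-decision time t0.  Timeouts are
    resolved by the larger current activity and flagged.
    """
    if not (np.isfinite(state.x_sn) and np.isfinite(state.x_lf)):
        raise ValueError("agent state must be finite")
    input_sn, input_lf = _trial_inputs(trial, params)
    max_steps = int(round(params.max_time / params.dt))
    seed = int(rng.integers(0, 2**31))
    choice_code, steps, x_sn, x_lf, timed_out = integrate_race(
        state.x_sn,
        state.x_lf,
        input_sn,
        input_lf,
        params.polarization,
        params.leak,
        params.w_self,
        params.w_inh,
        params.noise_sd,
        params.threshold,
        params.dt,
        max_steps,
        seed,
    )
    choice = "SN" if choice_code == SN else "LF"
    dt_ms = steps * params.dt * 1000.0 + params.t0
    return DecisionResult(choice, dt_ms, AgentState(x_sn, x_lf, choice), timed_out)


def apply_iti_decay(state: AgentState, iti: float, params: AgentParams) -> AgentState:
    """Exponential decay of residual activity over the inter-trial interval.

    Depolarization slows the decay (tau scaled by 1 + gain * polarization),
    hyperpolarization speeds it up.
    """
    if iti < 0:
        raise ValueError("iti must be non-negative")
    factor = float(np.exp(-iti / params.effective_tau_decay))
    return AgentState(state.x_sn * factor, state.x_lf * factor, state.last_choice)


def simulate_session(
    plan: SessionPlan,
    schedule: dict,
    params: AgentParams,
    rng_seed,
    state_log: Optional[list] = None,
) -> pd.DataFrame:
    """Play every block of one session and log complete choice records.

    ``schedule`` maps block number -> list of TrialSpec; block 1 is the
    measurement block (sham).  The agent state resets to rest at each block
    start and decays through the ITI between consecutive trials.
    """
    if not isinstance(rng_seed, np.random.Generator):
        rng_seed = np.random.default_rng(rng_seed)
    rng = rng_seed
    expected_blocks = set(plan.stim_by_block) | {1}
    if set(schedule) - expected_blocks:
        raise ValueError(f"schedule blocks {sorted(schedule)} do not match plan blocks {sorted(expected_blocks)}")
    rows = []
    for block in sorted(schedule):
        stim = "sham" if block == 1 else plan.stim_by_block[block]
        block_params = params.with_stim(stim)
        state = AgentState()
        for idx, trial in enumerate(schedule[block]):
            if idx > 0:
                iti = trial.iti_before
                if iti is None:
                    raise ValueError("only the first trial of a block may lack an ITI")
                state = apply_iti_decay(state, iti, block_params)
            if state_log is not None:
                state_log.append((block, idx, state.x_sn, state.x_lf))
            result = simulate_decision(trial, state, block_params, rng)
            state = result.state
            rows.append(
                (
                    plan.participant_id,
                    plan.session,
                    block,
                    stim,
                    plan.sham_order,
                    idx,
                    trial.triplet_id,
                    trial.role,
                    trial.sn_value,
                    trial.lf_value,
                    trial.sn_distance,
                    trial.extra_distance,
                    trial.iti_before,
                    result.choice,
                    result.dt_ms,
                    result.timed_out,
                )
            )
    df = pd.DataFrame(rows, columns=CHOICE_LOG_COLUMNS)
    df["iti_before_ms"] = df["iti_before_ms"].astype("Float64")
    return df


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant variability of discounting and residual decay."""

    k_mean: float = 0.15
    k_sd: float = 0.05
    tau_mean: float = 250.0
    tau_sd: float = 50.0
    k_bounds: tuple = (0.02, 1.0)
    tau_bounds: tuple = (50.0, 1500.0)

    def __post_init__(self):
        if self.k_sd < 0 or self.tau_sd < 0:
            raise ValueError("population SDs must be >= 0")

    def draw(self, base: AgentParams, rng: np.random.Generator) -> AgentParams:
        k = float(np.clip(rng.normal(self.k_mean, self.k_sd), *self.k_bounds))
        tau = float(np.clip(rng.normal(self.tau_mean, self.tau_sd), *self.tau_bounds))
        return dataclasses.replace(base, k_discount=k, tau_decay=tau)


@dataclass(frozen=True)
class DesignConfig:
    """Per-session trial counts of the simulated experiment."""

    n_measurement_trials: int = 150
    n_triplets_per_block: int = 40
    n_experimental_blocks: int = 4

    def __post_init__(self):
        if min(self.n_measurement_trials, self.n_triplets_per_block, self.n_experimental_blocks) < 1:
            raise ValueError("design counts must be >= 1")


@dataclass
class CohortResult:
    records: pd.DataFrame
    participant_params: dict  # pid -> AgentParams
    profiles: dict  # (pid, session) -> IndifferenceProfile
    excluded: list  # pids that failed the eligibility screen
    plans: list


def _participant_seed(master_seed: int, pid: int, session: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(pid, session, stage))


def simulate_cohort(
    n_participants: int,
    design_config: DesignConfig = DesignConfig(),
    params_population: PopulationSpec = PopulationSpec(),
    rng_seed: int = 0,
    base_params: AgentParams = DEFAULT_2021,
) -> CohortResult:
    """Run the full two-session experiment for a cohort of synthetic agents.

    Per participant and session: measurement block -> indifference-point
    estimation -> (session 1 only) eligibility screen -> four experimental
    blocks built from the estimated profile under the counterbalanced
    stimulation plan.  Ineligible agents are excluded and reported.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = int(rng_seed)
    plans = design.make_session_plans(n_participants)
    plans_by_pid: dict = {}
    for p in plans:
        plans_by_pid.setdefault(p.participant_id, {})[p.session] = p

    pop_rng = np.random.default_rng(np.random.SeedSequence(entropy=master, spawn_key=(0,)))
    frames = []
    participant_params = {}
    profiles = {}
    excluded = []
    for pid in sorted(plans_by_pid):
        params = params_population.draw(base_params, pop_rng)
        participant_params[pid] = params
        eligible = True
        for session in (1, 2):
            plan = plans_by_pid[pid][session]
            design_rng = np.random.default_rng(_participant_seed(master, pid, session, 0))
            play_rng = np.random.default_rng(_participant_seed(master, pid, session, 1))
            meas = design.make_measurement_trials(design_config.n_measurement_trials, design_rng)
            meas_df = simulate_session(plan, {1: meas}, params, play_rng)
            profile = design.estimate_indifference_profile(meas_df)
            profiles[(pid, session)] = profile
            if session == 1 and not design.check_eligibility(profile).eligible:
                excluded.append(pid)
                eligible = False
                break
            blocks = design.make_triplet_blocks(
                profile,
                design_config.n_triplets_per_block,
                design_config.n_experimental_blocks,
                design_rng,
            )
            schedule = {b: trials for b, trials in enumerate(blocks, start=2)}
            exp_df = simulate_session(plan, schedule, params, play_rng)
            frames.append(pd.concat([meas_df, exp_df], ignore_index=True))
        if not eligible:
            continue
    if not frames:
        raise RuntimeError("all simulated participants were ineligible")
    records = pd.concat(frames, ignore_index=True)
    return CohortResult(records, participant_params, profiles, excluded, plans)


def hysteresis_probe(
    params: AgentParams,
    iti: float,
    n_triplets: int,
    rng_seed,
    stim: str = "sham",
) -> tuple[float, float]:
    """Repetition index (percentage points) and mean target decision time (ms)
    for bias->target pairs at a given ITI.

    Bias trials use the agent's analytic indifference profile shifted by
    +/- 0.30; targets are neutral.  Only pairs with a successful bias choice
    enter the index, mirroring the analysis pipeline's filter.
    """
    rng = np.random.default_rng(rng_seed)
    p = params.with_stim(stim)
    profile = analytic_indifference_profile(p.k_discount)
    feas = design.check_eligibility(profile)
    sn_set = sorted(feas.sn_feasible_distances)
    lf_set = sorted(feas.lf_feasible_distances)
    if not sn_set or not lf_set:
        raise ValueError("agent discounting leaves no feasible bias distances")
    lf_after = {True: [0, 0], False: [0, 0]}  # bias_lf -> [n, n_lf_choices]
    dts = []
    for _ in range(n_triplets):
        bias_lf = bool(rng.random() < 0.5)
        d = int(rng.choice(lf_set if bias_lf else sn_set))
        shift = -design.BIAS_SHIFT if bias_lf else design.BIAS_SHIFT
        lo, hi = design.LF_VALUE_RANGE
        bias = _make_probe_trial(profile.r_star[d] + shift, d, int(rng.integers(lo, hi + 1)), rng)
        res = simulate_decision(bias, AgentState(), p, rng)
        success = (res.choice == "LF") == bias_lf
        d_t = int(rng.choice(design.DISTANCES))
        target = _make_probe_trial(profile.r_star[d_t], d_t, int(rng.integers(lo, hi + 1)), rng)
        state = apply_iti_decay(res.state, iti, p)
        tres = simulate_decision(target, state, p, rng)
        dts.append(tres.dt_ms)
        if success:
            lf_after[bias_lf][0] += 1
            lf_after[bias_lf][1] += tres.choice == "LF"
    if lf_after[True][0] == 0 or lf_after[False][0] == 0:
        raise RuntimeError("no successful bias trials in one condition")
    ri = 100.0 * lf_after[True][1] / lf_after[True][0] - 100.0 * lf_after[False][1] / lf_after[False][0]
    return ri, float(np.mean(dts))


def _make_probe_trial(ratio, extra, lf_value, rng) -> TrialSpec:
    sn_distance = int(rng.choice(design.SN_DISTANCES))
    sn_value = min(max(int(np.floor(ratio * lf_value + 0.5)), 1), lf_value - 1)
    return TrialSpec(
        sn_value=sn_value,
        lf_value=lf_value,
        sn_distance=sn_distance,
        extra_distance=extra,
        iti_before=design.SHORT_ITI,
        role="target",
    )
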