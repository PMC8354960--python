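"""Trial construction for the coin-collection decision game.

The game presents, on every trial, a small coin near the avatar (SN) against
a larger coin further away (LF).  A measurement block samples a wide range of
value ratios and distances; from its choices we fit per-distance psychometric
functions whose midpoints are the indifference ratios r*(d).  Experimental
blocks are then built from triplets — two bias trials engineered around
r*(d) +/- 0.30 followed by one neutral target at r*(d) — with a fixed short
inter-trial interval (ITI) before the target so that residual activity from
the bias decision can carry over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "TrialSpec",
    "PsychometricFit",
    "IndifferenceProfile",
    "EligibilityReport",
    "SessionPlan",
    "GRID_SIZE",
    "SN_DISTANCES",
    "ANCHOR_DISTANCES",
    "DISTANCES",
    "LF_VALUE_RANGE",
    "RATIO_RANGE",
    "SHORT_ITI",
    "LONG_ITI",
    "BIAS_SHIFT",
    "SN_FEASIBLE_BOUND",
    "LF_FEASIBLE_BOUND",
    "make_measurement_trials",
    "fit_psychometric",
    "estimate_indifference_profile",
    "interpolate_profile",
    "check_eligibility",
    "make_triplet_blocks",
    "make_session_plans",
    "realize_on_grid",
    "trials_to_frame",
]

GRID_SIZE = 20
SN_DISTANCES = (2, 3)
ANCHOR_DISTANCES = (1, 4, 8, 12)
DISTANCES = tuple(range(1, 13))
LF_VALUE_RANGE = (65, 85)
RATIO_RANGE = (0.20, 0.95)
SHORT_ITI = 500
LONG_ITI = 1500
BIAS_SHIFT = 0.30
SN_FEASIBLE_BOUND = 0.70  # r*(d) must lie below this for an SN-bias trial
LF_FEASIBLE_BOUND = 0.30  # ... and above this for an LF-bias trial
MIDPOINT_CLIP = (0.05, 0.95)
MIN_PSYCHOMETRIC_TRIALS = 10
_SEPARATION_SLOPE = 150.0  # |slope| beyond which the fit is treated as separated


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TrialSpec:
    """One decision problem between the small/near and large/far coin."""

    sn_value: int
    lf_value: int
    sn_distance: int
    extra_distance: int
    iti_before: Optional[int]  # ms; None for the first trial of a block
    role: str  # measurement | bias_SN | bias_LF | target
    triplet_id: Optional[int] = None

    def __post_init__(self):
        if not (1 <= self.sn_value < self.lf_value):
            raise ValueError(
                f"sn_value must satisfy 1 <= sn < lf, got {self.sn_value}/{self.lf_value}"
            )
        if self.sn_distance not in SN_DISTANCES:
            raise ValueError(f"sn_distance must be in {SN_DISTANCES}")
        if not 1 <= self.extra_distance <= 12:
            raise ValueError("extra_distance must be in 1..12")
        if self.iti_before is not None and self.iti_before not in (SHORT_ITI, LONG_ITI):
            raise ValueError(f"iti_before must be {SHORT_ITI} or {LONG_ITI} ms")
        if self.role not in ("measurement", "bias_SN", "bias_LF", "target"):
            raise ValueError(f"unknown trial role {self.role!r}")

    @property
    def ratio(self) -> float:
        return self.sn_value / self.lf_value

    @property
    def lf_distance(self) -> int:
        return self.sn_distance + self.extra_distance


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit of P(choose LF) against the SN/LF value ratio."""

    midpoint: float  # ratio at which P(LF) = 0.5, clipped to [0.05, 0.95]
    slope: float  # logistic slope on ratio; negative when behaviour is sane
    n_trials: int
    converged: bool


@dataclass
class IndifferenceProfile:
    """Per-distance indifference ratios r*(d), d = 1..12.

    Anchors (d = 1, 4, 8, 12) are fitted directly; the rest are linear
    interpolants.  ``degenerate_flags`` marks anchors whose psychometric fit
    did not converge (all-one-side or separated choice data).
    """

    r_star: dict
    anchor_distances: tuple = ANCHOR_DISTANCES
    degenerate_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [d for d in DISTANCES if d not in self.r_star]
        if missing:
            raise ValueError(f"profile is missing distances {missing}")
        lo, hi = MIDPOINT_CLIP
        for d in DISTANCES:
            if not lo - 1e-12 <= self.r_star[d] <= hi + 1e-12:
                raise ValueError(f"r*({d})={self.r_star[d]} outside clip range {MIDPOINT_CLIP}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_star[d] for d in DISTANCES])


@dataclass(frozen=True)
class EligibilityReport:
    eligible: bool
    sn_feasible_distances: frozenset
    lf_feasible_distances: frozenset


@dataclass(frozen=True)
class SessionPlan:
    """Stimulation layout of one session (Fig.-style counterbalancing).

    Four scenarios: the real-stimulation polarity alternates across the two
    sessions of a participant, and the real blocks are either the first
    (blocks 2-3) or the last (blocks 4-5) pair of experimental blocks, with
    that order flipping between sessions.
    """

    participant_id: int
    session: int  # 1 or 2
    scenario: int  # 1..4
    stim_by_block: Mapping[int, str]  # blocks 2..5 -> sham | anodal | cathodal

    @property
    def real_stim(self) -> str:
        for s in self.stim_by_block.values():
            if s != "sham":
                return s
        raise ValueError("plan has no real-stimulation block")

    @property
    def sham_order(self) -> str:
        return "sham_first" if self.stim_by_block[2] == "sham" else "sham_second"


def make_measurement_trials(n_trials: int, rng_seed) -> list[TrialSpec]:
    """Measurement-block trials: uniform distances, LF values and ratios.

    sn_distance ~ U{2,3}, extra_distance ~ U{1,4,8,12}, lf_value ~ U{65..85},
    ratio ~ U[0.20, 0.95] with sn_value = round(ratio * lf_value); all ITIs
    are the short 500 ms.
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise ValueError("n_trials must be a positive integer")
    rng = _as_rng(rng_seed)
    trials = []
    for _ in range(n_trials):
        sn_distance = int(rng.choice(SN_DISTANCES))
        extra = int(rng.choice(ANCHOR_DISTANCES))
        lf_value = int(rng.integers(LF_VALUE_RANGE[0], LF_VALUE_RANGE[1] + 1))
        ratio = float(rng.uniform(*RATIO_RANGE))
        sn_value = min(max(_round_half_up(ratio * lf_value), 1), lf_value - 1)
        trials.append(
            TrialSpec(
                sn_value=sn_value,
                lf_value=lf_value,
                sn_distance=sn_distance,
                extra_distance=extra,
                iti_before=SHORT_ITI,
                role="measurement",
            )
        )
    return trials


def _extract_ratio_choice(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pull (ratio, chose_lf, extra_distance) out of a record table or list."""
    if isinstance(records, pd.DataFrame):
        ratio = (records["sn_value"] / records["lf_value"]).to_numpy(float)
        chose_lf = (records["choice"] == "LF").to_numpy()
        extra = records["extra_distance"].to_numpy()
    else:
        ratio = np.array([r["sn_value"] / r["lf_value"] for r in records], float)
        chose_lf = np.array([r["choice"] == "LF" for r in records])
        extra = np.array([r["extra_distance"] for r in records])
    if np.any(ratio <= 0) or np.any(ratio >= 1):
        raise ValueError("value ratios must lie strictly in (0, 1)")
    return ratio, chose_lf, extra


def fit_psychometric(records) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(LF) on the value ratio.

    Degenerate data (all-LF, all-SN, or perfectly separated choices) yields
    ``converged=False`` with the midpoint clipped into [0.05, 0.95].
    """
    ratio, chose_lf, extra = _extract_ratio_choice(records)
    if len(ratio) < MIN_PSYCHOMETRIC_TRIALS:
        raise ValueError(
            f"need at least {MIN_PSYCHOMETRIC_TRIALS} trials, got {len(ratio)}"
        )
    if len(np.unique(extra)) != 1:
        raise ValueError("records mix several distances; fit one distance at a time")
    n = len(ratio)
    lo, hi = MIDPOINT_CLIP
    if chose_lf.all():
        return PsychometricFit(midpoint=hi, slope=np.nan, n_trials=n, converged=False)
    if not chose_lf.any():
        return PsychometricFit(midpoint=lo, slope=np.nan, n_trials=n, converged=False)

    y = chose_lf.astype(float)

    def nll(theta):
        p = expit(theta[0] + theta[1] * ratio)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    res = minimize(nll, x0=np.array([0.0, -1.0]), method="BFGS")
    intercept, slope = res.x
    midpoint = float(np.clip(-intercept / slope, lo, hi)) if slope != 0 else 0.5
    separated = abs(slope) > _SEPARATION_SLOPE
    return PsychometricFit(
        midpoint=midpoint,
        slope=float(slope),
        n_trials=n,
        converged=bool(res.success) and not separated,
    )


def interpolate_profile(anchors: Mapping[int, float]) -> dict:
    """Linear interpolation of anchor indifference ratios onto d = 1..12."""
    xs = sorted(anchors)
    ys = [anchors[d] for d in xs]
    values = np.interp(np.arange(1, 13), xs, ys)
    lo, hi = MIDPOINT_CLIP
    return {d: float(np.clip(v, lo, hi)) for d, v in zip(DISTANCES, values)}


def estimate_indifference_profile(records) -> IndifferenceProfile:
    """Fit the four anchor distances and interpolate the full r*(d) profile."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    anchors = {}
    flags = {}
    for d in ANCHOR_DISTANCES:
        sub = records[records["extra_distance"] == d]
        if len(sub) < MIN_PSYCHOMETRIC_TRIALS:
            raise ValueError(
                f"insufficient measurement data at anchor distance {d} "
                f"({len(sub)} trials)"
            )
        fit = fit_psychometric(sub)
        anchors[d] = fit.midpoint
        flags[d] = not fit.converged
    return IndifferenceProfile(
        r_star=interpolate_profile(anchors),
        anchor_distances=ANCHOR_DISTANCES,
        degenerate_flags=flags,
    )


def check_eligibility(profile: IndifferenceProfile) -> EligibilityReport:
    """A participant is usable when both bias types have >= 2 feasible distances.

    SN-bias trials need r*(d) < 0.7 (so that r* + 0.30 stays below 1); LF-bias
    trials need r*(d) > 0.3 (so that r* - 0.30 stays above 0).
    """
    sn_ok = frozenset(d for d in DISTANCES if profile.r_star[d] < SN_FEASIBLE_BOUND)
    lf_ok = frozenset(d for d in DISTANCES if profile.r_star[d] > LF_FEASIBLE_BOUND)
    return EligibilityReport(
        eligible=len(sn_ok) >= 2 and len(lf_ok) >= 2,
        sn_feasible_distances=sn_ok,
        lf_feasible_distances=lf_ok,
    )


def _make_trial_from_ratio(ratio, sn_distance, extra, lf_value, iti, role, triplet_id):
    sn_value = min(max(_round_half_up(ratio * lf_value), 1), lf_value - 1)
    return TrialSpec(
        sn_value=sn_value,
        lf_value=lf_value,
        sn_distance=sn_distance,
        extra_distance=extra,
        iti_before=iti,
        role=role,
        triplet_id=triplet_id,
    )


def make_triplet_blocks(
    profile: IndifferenceProfile,
    n_triplets_per_block: int,
    n_blocks: int,
    rng_seed,
    first_triplet_id: int = 0,
) -> list[list[TrialSpec]]:
    """Experimental blocks of bias/bias/target triplets.

    Each triplet draws one bias type (both bias trials share it), bias ratios
    r*(d) +/- 0.30 at a distance drawn from the feasible set for that type,
    and a neutral target at r*(d) with d uniform on 1..12.  The ITI before
    the target is always short; the two remaining ITIs of the triplet are
    {500, 1500} ms in randomised order.
    """
    if n_triplets_per_block < 1 or n_blocks < 1:
        raise ValueError("n_triplets_per_block and n_blocks must be >= 1")
    report = check_eligibility(profile)
    if not report.eligible:
        raise ValueError("profile is not eligible for bias-trial construction")
    rng = _as_rng(rng_seed)
    sn_set = sorted(report.sn_feasible_distances)
    lf_set = sorted(report.lf_feasible_distances)
    blocks = []
    triplet_id = first_triplet_id
    for _ in range(n_blocks):
        block: list[TrialSpec] = []
        for t in range(n_triplets_per_block):
            bias_lf = bool(rng.random() < 0.5)
            role = "bias_LF" if bias_lf else "bias_SN"
            feasible = lf_set if bias_lf else sn_set
            if not feasible:  # pragma: no cover - ruled out by eligibility
                raise RuntimeError(f"empty feasible set for {role}")
            other_itis = [SHORT_ITI, LONG_ITI]
            rng.shuffle(other_itis)
            for j in range(2):
                d = int(rng.choice(feasible))
                shift = -BIAS_SHIFT if bias_lf else BIAS_SHIFT
                ratio = profile.r_star[d] + shift
                iti = None if (t == 0 and j == 0) else other_itis[j]
                lf_value = int(rng.integers(LF_VALUE_RANGE[0], LF_VALUE_RANGE[1] + 1))
                block.append(
                    _make_trial_from_ratio(ratio, int(rng.choice(SN_DISTANCES)), d, lf_value, iti, role, triplet_id)
                )
            d = int(rng.choice(DISTANCES))
            lf_value = int(rng.integers(LF_VALUE_RANGE[0], LF_VALUE_RANGE[1] + 1))
            block.append(
                _make_trial_from_ratio(
                    profile.r_star[d], int(rng.choice(SN_DISTANCES)), d, lf_value, SHORT_ITI, "target", triplet_id
                )
            )
            triplet_id += 1
        blocks.append(block)
    return blocks


_SCENARIOS = {
    # (session-1 real stim, session-1 real blocks first?), session 2 flips both
    1: ("anodal", True),
    2: ("anodal", False),
    3: ("cathodal", True),
    4: ("cathodal", False),
}


def _session_stim(real: str, real_first: bool) -> dict:
    if real_first:
        return {2: real, 3: real, 4: "sham", 5: "sham"}
    return {2: "sham", 3: "sham", 4: real, 5: real}


def make_session_plans(n_participants: int) -> list[SessionPlan]:
    """Cyclically counterbalanced two-session plans (4 scenarios)."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_participants % 4 != 0:
        warnings.warn(
            f"{n_participants} participants cannot balance 4 scenarios exactly",
            UserWarning,
            stacklevel=2,
        )
    plans = []
    other = {"anodal": "cathodal", "cathodal": "anodal"}
    for pid in range(1, n_participants + 1):
        scenario = (pid - 1) % 4 + 1
        real1, first1 = _SCENARIOS[scenario]
        plans.append(SessionPlan(pid, 1, scenario, _session_stim(real1, first1)))
        plans.append(SessionPlan(pid, 2, scenario, _session_stim(other[real1], not first1)))
    return plans


def realize_on_grid(trial: TrialSpec, avatar_position, rng_seed):
    """Place the two coins on the 20x20 grid.

    Movement is restricted to horizontally/vertically adjacent fields, so the
    path length to a coin is its Manhattan distance.  The SN coin sits at
    Manhattan distance sn_distance, the LF coin at sn_distance +
    extra_distance, and the avatar->coin vectors must subtend at least 90
    degrees (dot product <= 0) so that approaching one coin recedes from the
    other.
    """
    ax, ay = avatar_position
    if not (0 <= ax < GRID_SIZE and 0 <= ay < GRID_SIZE):
        raise ValueError("avatar must lie inside the 20x20 grid")
    rng = _as_rng(rng_seed)

    def ring(dist):
        cells = []
        for dx in range(-dist, dist + 1):
            dy = dist - abs(dx)
            for sy in ({dy, -dy}):
                x, y = ax + dx, ay + sy
                if 0 <= x < GRID_SIZE and 0 <= y < GRID_SIZE:
                    cells.append((x, y))
        return cells

    sn_cells = ring(trial.sn_distance)
    lf_cells = ring(trial.lf_distance)
    pairs = [
        (c1, c2)
        for c1 in sn_cells
        for c2 in lf_cells
        if (c1[0] - ax) * (c2[0] - ax) + (c1[1] - ay) * (c2[1] - ay) <= 0
    ]
    if not pairs:
        raise ValueError(
            f"no coin placement at distances {trial.sn_distance}/{trial.lf_distance} "
            f"from avatar {avatar_position}; re-draw the avatar position"
        )
    return pairs[int(rng.integers(len(pairs)))]


def trials_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    """Tabulate TrialSpecs (schedule CSV layout, one row per trial)."""
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            {
                "trial_index": i,
                "triplet_id": t.triplet_id,
                "role": t.role,
                "sn_value": t.sn_value,
                "lf_value": t.lf_value,
                "sn_distance": t.sn_distance,
                "extra_distance": t.extra_distance,
                "iti_before_ms": t.iti_before,
            }
        )
    return pd.DataFrame(rows)
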