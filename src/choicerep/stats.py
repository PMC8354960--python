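"""The preregistered analysis pipeline for the choice-repetition experiment.

Confirmatory stages: pooling the two sham sessions (after a paired-t gate),
keeping target trials whose bias manipulation succeeded, the one-tailed
paired t on LF-choice percentages after LF vs SN bias (H1.1), the
log-decision-time repetition-vs-switch contrast (H1.2), and one-way
repeated-measures ANOVAs of the repetition index and of log decision times
over the three stimulation conditions with Holm-corrected post hocs (H2.1,
H2.2).  Effect sizes are Hedges g (averaged-SD standardizer with small-sample
correction) for paired contrasts and partial eta squared for ANOVAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectReport",
    "RepetitionSummary",
    "FilterResult",
    "PreregisteredReport",
    "filter_bias_success",
    "repetition_by_participant",
    "repetition_summary",
    "dt_contrast",
    "paired_t",
    "hedges_g_av",
    "rm_anova",
    "holm_correct",
    "pool_sham",
    "required_n_paired",
    "manipulation_check",
    "preregistered_report",
]


@dataclass
class EffectReport:
    """One test summary: statistic, df, p, tail and an effect size."""

    label: str
    statistic: float
    df: float | tuple
    p: float
    tail: str  # "one" | "two"
    effect_size: float
    effect_size_type: str  # "hedges_g" | "partial_eta2"
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


@dataclass(frozen=True)
class RepetitionSummary:
    pct_lf_after_lf: float
    pct_lf_after_sn: float
    repetition_index: float  # percentage points
    n_targets_used: int


@dataclass
class FilterResult:
    targets: pd.DataFrame  # retained targets with bias_type/bias_choice/repeat columns
    success_rate: pd.DataFrame  # per participant (x session) bias success rate, %


_BIAS_ROLES = {"bias_SN": "SN", "bias_LF": "LF"}


def _experimental(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["role"].isin(["bias_SN", "bias_LF", "target"])]


def filter_bias_success(records: pd.DataFrame, mode: str = "preceding") -> FilterResult:
    """Keep target trials whose bias trial(s) were chosen bias-consistently.

    ``mode="preceding"`` (the default) conditions only on the second bias
    trial — the one immediately before the target; ``mode="both"`` requires
    both bias trials of the triplet to have succeeded.  Also reports each
    participant's bias success rate over all bias trials.
    """
    if mode not in ("preceding", "both"):
        raise ValueError("mode must be 'preceding' or 'both'")
    exp = _experimental(records)
    if exp.empty:
        raise ValueError("no experimental-block records")
    keys = ["participant_id", "session", "block", "triplet_id"]
    rows = []
    for key, trip in exp.groupby(keys, sort=True):
        roles = trip["role"].tolist()
        if len(trip) != 3 or roles[2] != "target" or not all(r in _BIAS_ROLES for r in roles[:2]):
            raise ValueError(f"broken triplet structure at {dict(zip(keys, key))}: roles={roles}")
        if roles[0] != roles[1]:
            raise ValueError(f"mixed bias types in triplet {dict(zip(keys, key))}")
        bias_type = _BIAS_ROLES[roles[1]]
        b1_ok = trip.iloc[0]["choice"] == bias_type
        b2_ok = trip.iloc[1]["choice"] == bias_type
        ok = b2_ok if mode == "preceding" else (b1_ok and b2_ok)
        target = trip.iloc[2]
        rows.append(
            dict(
                target,
                bias_type=bias_type,
                bias_choice=trip.iloc[1]["choice"],
                bias_success=bool(ok),
                repeat=bool(target["choice"] == trip.iloc[1]["choice"]),
            )
        )
    targets = pd.DataFrame(rows)
    bias_trials = exp[exp["role"].isin(_BIAS_ROLES)]
    ok = bias_trials["choice"] == bias_trials["role"].map(_BIAS_ROLES)
    success = (
        ok.groupby([bias_trials["participant_id"], bias_trials["session"]])
        .mean()
        .mul(100.0)
        .rename("success_pct")
        .reset_index()
    )
    return FilterResult(targets=targets[targets["bias_success"]].reset_index(drop=True), success_rate=success)


def repetition_by_participant(targets: pd.DataFrame) -> pd.DataFrame:
    """Per-participant LF percentages after LF and after SN bias."""
    rows = []
    for pid, sub in targets.groupby("participant_id"):
        after_lf = sub[sub["bias_type"] == "LF"]
        after_sn = sub[sub["bias_type"] == "SN"]
        if after_lf.empty or after_sn.empty:
            missing = "LF" if after_lf.empty else "SN"
            raise ValueError(f"participant {pid} has no targets after {missing} bias")
        rows.append(
            {
                "participant_id": pid,
                "pct_lf_after_lf": 100.0 * (after_lf["choice"] == "LF").mean(),
                "pct_lf_after_sn": 100.0 * (after_sn["choice"] == "LF").mean(),
                "n_targets": len(sub),
            }
        )
    df = pd.DataFrame(rows)
    df["repetition_index"] = df["pct_lf_after_lf"] - df["pct_lf_after_sn"]
    return df


def repetition_summary(targets: pd.DataFrame) -> RepetitionSummary:
    """Group summary: percentages computed per participant, then averaged."""
    per = repetition_by_participant(targets)
    return RepetitionSummary(
        pct_lf_after_lf=float(per["pct_lf_after_lf"].mean()),
        pct_lf_after_sn=float(per["pct_lf_after_sn"].mean()),
        repetition_index=float(per["repetition_index"].mean()),
        n_targets_used=int(per["n_targets"].sum()),
    )


def hedges_g_av(m1: float, sd1: float, m2: float, sd2: float, n: int) -> float:
    """Hedges g for paired designs with the averaged-SD standardizer.

    g = (m1 - m2) / sqrt((sd1^2 + sd2^2) / 2) * J,  J = 1 - 3 / (4(n-1) - 1).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return (m1 - m2) / np.sqrt((sd1**2 + sd2**2) / 2.0) * j


def paired_t(x, y, tail: str = "two", label: str = "paired_t") -> EffectReport:
    """Classical paired t-test with Hedges g.

    One-tailed tests assume the a-priori direction x > y: the one-tailed p is
    half the two-tailed p when t > 0 and 1 minus that otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    diff = x - y
    n = len(x)
    if np.allclose(diff, 0.0):
        t, p2 = 0.0, 1.0
    elif np.std(diff, ddof=1) == 0:
        raise ValueError("differences have zero variance with nonzero mean")
    else:
        t, p2 = sps.ttest_rel(x, y)
        t, p2 = float(t), float(p2)
    p = p2 if tail == "two" else (p2 / 2.0 if t > 0 else 1.0 - p2 / 2.0)
    sd1, sd2 = np.std(x, ddof=1), np.std(y, ddof=1)
    g = hedges_g_av(x.mean(), sd1, y.mean(), sd2, n) if sd1 > 0 and sd2 > 0 else 0.0
    return EffectReport(
        label=label,
        statistic=t,
        df=n - 1,
        p=float(p),
        tail=tail,
        effect_size=float(g),
        effect_size_type="hedges_g",
        means={"x": float(x.mean()), "y": float(y.mean())},
        sds={"x": float(sd1), "y": float(sd2)},
        n=n,
    )


def dt_contrast(targets: pd.DataFrame, tail: str = "one") -> EffectReport:
    """Repetition-vs-switch decision times on the log scale.

    Targets are classed as repetitions (choice equals the preceding bias
    choice) or switches; per-participant means of log(dt) enter a paired t
    (one-tailed by default: switches slower).  Raw-scale millisecond means
    and SDs are reported alongside.
    """
    per = []
    for pid, sub in targets.groupby("participant_id"):
        rep = sub[sub["repeat"]]
        swi = sub[~sub["repeat"]]
        if rep.empty or swi.empty:
            kind = "repeat" if rep.empty else "switch"
            raise ValueError(f"participant {pid} has no {kind} targets")
        per.append(
            {
                "participant_id": pid,
                "log_repeat": np.log(rep["dt_ms"]).mean(),
                "log_switch": np.log(swi["dt_ms"]).mean(),
                "raw_repeat": rep["dt_ms"].mean(),
                "raw_switch": swi["dt_ms"].mean(),
            }
        )
    per = pd.DataFrame(per)
    report = paired_t(per["log_switch"], per["log_repeat"], tail=tail, label="dt_repetition_vs_switch")
    n = len(per)
    # effect size on the raw millisecond scale, as reported descriptively
    report.effect_size = float(
        hedges_g_av(
            per["raw_switch"].mean(),
            per["raw_switch"].std(ddof=1),
            per["raw_repeat"].mean(),
            per["raw_repeat"].std(ddof=1),
            n,
        )
    ) if per["raw_switch"].std(ddof=1) > 0 and per["raw_repeat"].std(ddof=1) > 0 else 0.0
    report.means = {"repeat_ms": float(per["raw_repeat"].mean()), "switch_ms": float(per["raw_switch"].mean())}
    report.sds = {"repeat_ms": float(per["raw_repeat"].std(ddof=1)), "switch_ms": float(per["raw_switch"].std(ddof=1))}
    return report


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA (1 or 2 within factors) with partial eta squared.

    Requires a complete balanced design; returns a tidy table with columns
    Source, F, df1, df2, p, np2.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    counts = data.groupby([subject, *within], observed=True).size()
    full = 1
    for w in within:
        full *= data[w].nunique()
    per_subject = counts.groupby(level=0).size()
    if (per_subject != full).any() or (counts < 1).any():
        raise ValueError("design is unbalanced: every subject must contribute every cell")
    if (counts > 1).any():
        data = data.groupby([subject, *within], observed=True, as_index=False)[dv].mean()
    rows = []
    if len(within) == 1:
        table = pg.rm_anova(data=data, dv=dv, within=within[0], subject=subject, detailed=True)
        err = table[table["Source"] == "Error"].iloc[0]
        eff = table[table["Source"] != "Error"].iloc[0]
        # pingouin omits F/p when the within-subject variance is exactly zero
        f = eff["F"] if "F" in table.columns else np.nan
        p = eff["p_unc"] if "p_unc" in table.columns else np.nan
        rows.append((str(eff["Source"]), f, float(eff["DF"]), float(err["DF"]), p))
    else:
        table = pg.rm_anova(data=data, dv=dv, within=within, subject=subject, detailed=False)
        for _, r in table.iterrows():
            rows.append((str(r["Source"]), r["F"], float(r["ddof1"]), float(r["ddof2"]), r["p_unc"]))
    out = []
    for source, f, df1, df2, p in rows:
        f = 0.0 if np.isnan(f) else float(f)  # zero effect and zero error SS
        np2 = f * df1 / (f * df1 + df2) if (f * df1 + df2) > 0 else 0.0
        out.append(
            {
                "Source": source,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p": float(p) if np.isfinite(p) else 1.0,
                "np2": float(np2),
            }
        )
    return pd.DataFrame(out)


def _anova_effect(table: pd.DataFrame, source: str, label: str, n: int) -> EffectReport:
    row = table[table["Source"] == source].iloc[0]
    return EffectReport(
        label=label,
        statistic=float(row["F"]),
        df=(row["df1"], row["df2"]),
        p=float(row["p"]),
        tail="two",
        effect_size=float(row["np2"]),
        effect_size_type="partial_eta2",
        n=n,
    )


def holm_correct(p_values) -> np.ndarray:
    """Step-down Holm adjustment of a family of p-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pool_sham(records: pd.DataFrame) -> tuple[pd.DataFrame, EffectReport, bool]:
    """Gate check before pooling the two sham sessions.

    Compares per-participant LF percentages in sham target trials across the
    two sessions with a paired t.  Pooling happens regardless (the sham label
    already spans both sessions); a True flag marks a significant difference,
    mirroring the preregistration's conditional wording.
    """
    sham_targets = records[(records["stim"] == "sham") & (records["role"] == "target")]
    pct = (
        sham_targets.assign(lf=(sham_targets["choice"] == "LF") * 100.0)
        .groupby(["participant_id", "session"])["lf"]
        .mean()
        .unstack("session")
    )
    if pct.isna().any().any() or pct.shape[1] != 2:
        raise ValueError("every participant needs sham target trials in both sessions")
    report = paired_t(pct[1], pct[2], tail="two", label="sham_session1_vs_session2_lf_pct")
    flagged = report.p < 0.05
    return records, report, bool(flagged)


def required_n_paired(d: float, alpha: float = 0.05, power: float = 0.80, tails: str = "two") -> int:
    """Smallest n giving the target power for a paired t with effect size d.

    Power is computed from the noncentral t distribution with noncentrality
    d * sqrt(n) and df = n - 1.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    for n in range(3, 100000):
        df = n - 1
        ncp = d * np.sqrt(n)
        if tails == "two":
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            achieved = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        else:
            tcrit = sps.t.ppf(1 - alpha, df)
            achieved = sps.nct.sf(tcrit, df, ncp)
        if achieved >= power:
            return n
    raise RuntimeError("no n below 100000 reaches the target power")  # pragma: no cover


def manipulation_check(records: pd.DataFrame) -> pd.DataFrame:
    """LF-choice percentage by trial role, per participant and for the group."""
    exp = _experimental(records)
    per = (
        exp.assign(lf=(exp["choice"] == "LF") * 100.0)
        .groupby(["participant_id", "role"])["lf"]
        .mean()
        .unstack("role")
    )
    group = per.mean().to_frame().T
    group.index = ["group_mean"]
    return pd.concat([per, group])


@dataclass
class PreregisteredReport:
    """Structured output of the full confirmatory + exploratory pipeline."""

    effects: dict = field(default_factory=dict)  # label -> EffectReport
    anova_tables: dict = field(default_factory=dict)  # label -> DataFrame
    summaries: dict = field(default_factory=dict)
    sham_pool_flagged: bool = False

    def to_json(self, **kwargs) -> str:
        payload = {
            "effects": {k: v.to_dict() for k, v in sorted(self.effects.items())},
            "anova_tables": {k: v.to_dict(orient="records") for k, v in sorted(self.anova_tables.items())},
            "summaries": {k: v for k, v in sorted(self.summaries.items())},
            "sham_pool_flagged": self.sham_pool_flagged,
        }
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)


def _stage(name):
    """Decorator-less stage wrapper: re-raise with the pipeline stage name."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def preregistered_report(records: pd.DataFrame, filter_mode: str = "preceding") -> PreregisteredReport:
    """Run the preregistered confirmatory analyses and the exploratory block.

    Order: sham pooling gate -> bias-success filter -> H1.1 (one-tailed
    paired t on LF% after LF vs SN bias, sham only) -> H1.2 (log-dt
    repetition-vs-switch contrast, sham only) -> H2.1 (one-way rm-ANOVA of
    the repetition index over tDCS, post hocs Holm-corrected, H2.1.1/H2.1.2)
    -> H2.2 (one-way rm-ANOVA of log dt over tDCS, H2.2.1/H2.2.2) ->
    exploratory checks (sham order, overall LF%, bias success, tDCS x type).
    """
    report = PreregisteredReport()
    stims = set(records["stim"].unique())
    if not {"sham", "anodal", "cathodal"} <= stims:
        raise ValueError(f"dataset must contain all three stimulation conditions, got {sorted(stims)}")

    with _stage("pool_sham"):
        _, gate, flagged = pool_sham(records)
        report.effects["sham_pooling_gate"] = gate
        report.sham_pool_flagged = flagged

    with _stage("filter_bias_success"):
        filt = filter_bias_success(records, mode=filter_mode)
        targets = filt.targets
        report.summaries["bias_success_pct_mean"] = float(filt.success_rate["success_pct"].mean())

    sham_targets = targets[targets["stim"] == "sham"]

    with _stage("H1.1"):
        per = repetition_by_participant(sham_targets)
        report.effects["H1.1"] = paired_t(
            per["pct_lf_after_lf"], per["pct_lf_after_sn"], tail="one", label="H1.1"
        )
        summ = repetition_summary(sham_targets)
        report.summaries["sham_repetition"] = {
            "pct_lf_after_lf": summ.pct_lf_after_lf,
            "pct_lf_after_sn": summ.pct_lf_after_sn,
            "repetition_index": summ.repetition_index,
            "n_targets_used": summ.n_targets_used,
        }

    with _stage("H1.2"):
        rep = dt_contrast(sham_targets, tail="one")
        rep.label = "H1.2"
        report.effects["H1.2"] = rep

    with _stage("H2.1"):
        per_stim = []
        for stim, sub in targets.groupby("stim"):
            ri = repetition_by_participant(sub)[["participant_id", "repetition_index"]]
            ri["stim"] = stim
            per_stim.append(ri)
        ri_long = pd.concat(per_stim, ignore_index=True)
        table = rm_anova(ri_long, dv="repetition_index", within="stim", subject="participant_id")
        report.anova_tables["H2.1"] = table
        report.effects["H2.1"] = _anova_effect(table, "stim", "H2.1", ri_long["participant_id"].nunique())
        wide = ri_long.pivot(index="participant_id", columns="stim", values="repetition_index")
        post = {
            "H2.1.1": paired_t(wide["anodal"], wide["sham"], tail="one", label="H2.1.1"),
            "H2.1.2": paired_t(wide["sham"], wide["cathodal"], tail="one", label="H2.1.2"),
        }
        adj = holm_correct([post["H2.1.1"].p, post["H2.1.2"].p])
        for (k, eff), p_adj in zip(post.items(), adj):
            eff.p = float(p_adj)
            report.effects[k] = eff

    with _stage("H2.2"):
        all_targets = records[records["role"] == "target"]
        logdt = (
            all_targets.assign(logdt=np.log(all_targets["dt_ms"]))
            .groupby(["participant_id", "stim"], as_index=False)["logdt"]
            .mean()
        )
        table = rm_anova(logdt, dv="logdt", within="stim", subject="participant_id")
        report.anova_tables["H2.2"] = table
        report.effects["H2.2"] = _anova_effect(table, "stim", "H2.2", logdt["participant_id"].nunique())
        wide = logdt.pivot(index="participant_id", columns="stim", values="logdt")
        post = {
            "H2.2.1": paired_t(wide["sham"], wide["anodal"], tail="one", label="H2.2.1"),
            "H2.2.2": paired_t(wide["cathodal"], wide["sham"], tail="one", label="H2.2.2"),
        }
        adj = holm_correct([post["H2.2.1"].p, post["H2.2.2"].p])
        for (k, eff), p_adj in zip(post.items(), adj):
            eff.p = float(p_adj)
            report.effects[k] = eff

    with _stage("exploratory"):
        exp = _experimental(records)
        lf_all = (
            exp.assign(lf=(exp["choice"] == "LF") * 100.0)
            .groupby(["participant_id", "sham_order", "stim"], as_index=False)["lf"]
            .mean()
        )
        sham_by_order = (
            lf_all[lf_all["stim"] == "sham"]
            .pivot(index="participant_id", columns="sham_order", values="lf")
        )
        report.effects["exploratory_sham_order"] = paired_t(
            sham_by_order["sham_first"], sham_by_order["sham_second"], tail="two",
            label="exploratory_sham_order",
        )
        lf_stim = (
            exp.assign(lf=(exp["choice"] == "LF") * 100.0)
            .groupby(["participant_id", "stim"], as_index=False)["lf"]
            .mean()
        )
        table = rm_anova(lf_stim, dv="lf", within="stim", subject="participant_id")
        report.anova_tables["exploratory_overall_lf"] = table
        report.effects["exploratory_overall_lf"] = _anova_effect(
            table, "stim", "exploratory_overall_lf", lf_stim["participant_id"].nunique()
        )
        bias_trials = exp[exp["role"].isin(_BIAS_ROLES)]
        ok = (bias_trials["choice"] == bias_trials["role"].map(_BIAS_ROLES)) * 100.0
        succ = (
            pd.DataFrame(
                {
                    "participant_id": bias_trials["participant_id"],
                    "stim": bias_trials["stim"],
                    "ok": ok,
                }
            )
            .groupby(["participant_id", "stim"], as_index=False)["ok"]
            .mean()
        )
        table = rm_anova(succ, dv="ok", within="stim", subject="participant_id")
        report.anova_tables["exploratory_bias_success"] = table
        report.effects["exploratory_bias_success"] = _anova_effect(
            table, "stim", "exploratory_bias_success", succ["participant_id"].nunique()
        )
        dt_long = (
            targets.assign(
                logdt=np.log(targets["dt_ms"]),
                trial_type=np.where(targets["repeat"], "repetition", "switch"),
            )
            .groupby(["participant_id", "stim", "trial_type"], as_index=False)["logdt"]
            .mean()
        )
        table = rm_anova(dt_long, dv="logdt", within=["stim", "trial_type"], subject="participant_id")
        report.anova_tables["exploratory_stim_by_type_dt"] = table

    return report
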