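import numpy as np
import pandas as pd
import pytest

import choicerep as cr
from choicerep.stats import (
    dt_contrast,
    filter_bias_success,
    hedges_g_av,
    holm_correct,
    manipulation_check,
    paired_t,
    pool_sham,
    preregistered_report,
    repetition_by_participant,
    repetition_summary,
    required_n_paired,
    rm_anova,
)

from conftest import make_toy_targets, make_toy_triplets


def oneway_rm_oracle(wide: np.ndarray):
    """Brute-force sums-of-squares decomposition, subject as blocking factor."""
    n, k = wide.shape
    grand = wide.mean()
    ss_total = ((wide - grand) ** 2).sum()
    ss_cond = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    return f, df1, df2, ss_cond / (ss_cond + ss_err)


def long_from_wide(wide: np.ndarray) -> pd.DataFrame:
    n, k = wide.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": list("abcdefg"[:k]) * n,
            "value": wide.ravel(),
        }
    )


class TestFilterBiasSuccess:
    def test_all_successful_pass_through(self):
        df = make_toy_triplets(["SN", "SN", "SN", "SN"], bias_type="SN")
        res = filter_bias_success(df)
        assert len(res.targets) == 4
        assert res.success_rate["success_pct"].iloc[0] == 100.0

    def test_failed_second_bias_drops_target(self):
        df = make_toy_triplets(["SN", "SN", "LF", "SN"], bias_type="SN")
        res = filter_bias_success(df, mode="preceding")
        assert len(res.targets) == 3

    def test_both_mode_requires_both_bias_trials(self):
        df = make_toy_triplets(["SN", "SN", "LF", "SN"], bias_type="SN")
        # first bias trial always succeeds in the toy log, so 'both' matches
        res = filter_bias_success(df, mode="both")
        assert len(res.targets) == 3

    def test_broken_triplet_raises(self):
        df = make_toy_triplets(["SN", "SN"]).iloc[:-1]  # drop the last target
        with pytest.raises(ValueError, match="triplet"):
            filter_bias_success(df)

    def test_cohort_success_rate_plausible(self, small_cohort):
        res = filter_bias_success(small_cohort.records)
        rates = res.success_rate["success_pct"]
        assert ((rates > 50) & (rates < 100)).all()


class TestRepetitionSummary:
    def test_toy_counts(self):
        targets = make_toy_targets(
            ["LF", "LF", "LF", "LF", "SN", "SN", "SN", "SN"],
            ["LF", "LF", "LF", "SN", "LF", "SN", "SN", "SN"],
        )
        s = repetition_summary(targets)
        assert s.pct_lf_after_lf == pytest.approx(75.0)
        assert s.pct_lf_after_sn == pytest.approx(25.0)
        assert s.repetition_index == pytest.approx(50.0)

    def test_group_index_is_mean_difference(self):
        frames = [
            make_toy_targets(["LF", "SN"] * 4, ["LF", "SN"] * 4, participant_id=1),
            make_toy_targets(["LF", "SN"] * 4, ["SN", "LF"] * 4, participant_id=2),
        ]
        s = repetition_summary(pd.concat(frames, ignore_index=True))
        assert s.repetition_index == pytest.approx(
            s.pct_lf_after_lf - s.pct_lf_after_sn
        )

    def test_missing_condition_raises(self):
        targets = make_toy_targets(["LF"] * 4, ["LF"] * 4)
        with pytest.raises(ValueError, match="SN"):
            repetition_summary(targets)


class TestPairedT:
    def test_identical_samples(self):
        e = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert e.statistic == 0.0 and e.p == 1.0

    def test_hand_computed_t(self):
        y = np.array([10.0, 12.0, 9.0, 11.0])
        x = y + np.array([1.0, 2.0, 3.0, 4.0])
        e = paired_t(x, y)
        assert e.statistic == pytest.approx(2.5 / (1.2909944 / 2), abs=1e-4)
        assert e.df == 3

    def test_one_tailed_halves_p(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=10)
        x = y + rng.normal(0.5, 0.3, size=10)
        two = paired_t(x, y, tail="two")
        one = paired_t(x, y, tail="one")
        assert two.statistic > 0
        assert one.p == pytest.approx(two.p / 2)

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestHedgesG:
    def test_zero_for_equal_means(self):
        assert hedges_g_av(5.0, 1.0, 5.0, 2.0, 20) == 0.0

    def test_sign_and_shrinkage(self):
        g = hedges_g_av(6.0, 1.5, 5.0, 1.5, 10)
        d = (6.0 - 5.0) / 1.5
        assert g > 0 and abs(g) < abs(d)

    def test_rejects_bad_sd(self):
        with pytest.raises(ValueError):
            hedges_g_av(1.0, 0.0, 2.0, 1.0, 10)


class TestDtContrast:
    def test_identical_dts_are_null(self):
        targets = pd.concat(
            [
                make_toy_targets(["LF", "SN"] * 3, ["LF", "SN", "SN", "LF", "LF", "SN"], participant_id=p)
                for p in (1, 2, 3)
            ],
            ignore_index=True,
        )
        e = dt_contrast(targets, tail="two")
        assert e.statistic == 0.0 and e.effect_size == 0.0

    def test_scaling_dt_leaves_t_unchanged(self):
        rng = np.random.default_rng(3)
        frames = []
        for p in (1, 2, 3, 4):
            bias = ["LF", "SN"] * 5
            choice = [rng.choice(["LF", "SN"]) for _ in range(10)]
            if all(c == b for c, b in zip(choice, bias)):
                choice[0] = "SN"
            if not any(c == b for c, b in zip(choice, bias)):
                choice[0] = "LF"
            dts = rng.lognormal(6.6, 0.3, size=10)
            frames.append(make_toy_targets(bias, choice, dts, participant_id=p))
        targets = pd.concat(frames, ignore_index=True)
        t1 = dt_contrast(targets, tail="two").statistic
        targets2 = targets.assign(dt_ms=targets["dt_ms"] * 2)
        t2 = dt_contrast(targets2, tail="two").statistic
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_cohort_repeats_faster_than_switches(self, small_report):
        e = small_report.effects["H1.2"]
        assert e.means["repeat_ms"] < e.means["switch_ms"]
        assert e.statistic > 0


class TestRmAnova:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        wide = rng.normal(size=(4, 3)) + np.array([0.0, 0.4, 0.9])
        table = rm_anova(long_from_wide(wide), dv="value", within="cond", subject="subject")
        f, df1, df2, np2 = oneway_rm_oracle(wide)
        row = table.iloc[0]
        assert row["F"] == pytest.approx(f, abs=1e-10)
        assert (row["df1"], row["df2"]) == (df1, df2)
        assert row["np2"] == pytest.approx(np2, abs=1e-10)

    def test_constant_within_subject_gives_zero_f(self):
        wide = np.repeat(np.array([[1.0], [2.0], [3.0], [4.0]]), 3, axis=1)
        table = rm_anova(long_from_wide(wide), dv="value", within="cond", subject="subject")
        assert table.iloc[0]["F"] == 0.0

    def test_two_way_additive_has_null_interaction(self):
        # cell means are exactly additive (per-cell residuals demeaned), so
        # the interaction sum of squares vanishes while its error term stays
        # positive
        rng = np.random.default_rng(17)
        resid = rng.normal(0, 0.1, size=(5, 2, 2))
        resid -= resid.mean(axis=0, keepdims=True)
        subj_effect = {0: 0.0, 1: 1.0, 2: -0.5, 3: 0.3, 4: 2.0}
        rows = []
        for s in range(5):
            for i, a in enumerate(("a1", "a2")):
                for j, b in enumerate(("b1", "b2")):
                    rows.append(
                        {
                            "subject": s,
                            "A": a,
                            "B": b,
                            "value": subj_effect[s] + 0.5 * i + 0.2 * j + resid[s, i, j],
                        }
                    )
        table = rm_anova(pd.DataFrame(rows), dv="value", within=["A", "B"], subject="subject")
        inter = table[table["Source"] == "A * B"].iloc[0]
        assert inter["F"] == pytest.approx(0.0, abs=1e-8)

    def test_two_level_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        wide = rng.normal(size=(8, 2)) + np.array([0.0, 0.6])
        table = rm_anova(long_from_wide(wide), dv="value", within="cond", subject="subject")
        t = paired_t(wide[:, 1], wide[:, 0]).statistic
        assert table.iloc[0]["F"] == pytest.approx(t**2, abs=1e-8)

    def test_missing_cell_rejected(self):
        df = long_from_wide(np.random.default_rng(0).normal(size=(4, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, dv="value", within="cond", subject="subject")


class TestHolm:
    def test_worked_example(self):
        assert holm_correct([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_correct([0.03]) == pytest.approx([0.03])

    def test_equal_ps_scale_by_m(self):
        assert holm_correct([0.02, 0.02, 0.02]) == pytest.approx([0.06, 0.06, 0.06])
        assert holm_correct([0.6, 0.6]) == pytest.approx([1.0, 1.0])


class TestPoolSham:
    @staticmethod
    def sham_frame(lf_counts_by_session, n=10, participant_id=1):
        frames = []
        for session, k in lf_counts_by_session.items():
            choices = ["LF"] * k + ["SN"] * (n - k)
            f = make_toy_targets(["LF", "SN"] * (n // 2), choices, participant_id=participant_id)
            f["session"] = session
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_identical_sessions_not_flagged(self):
        df = pd.concat(
            [self.sham_frame({1: 5, 2: 5}, participant_id=p) for p in range(1, 5)],
            ignore_index=True,
        )
        _, report, flagged = pool_sham(df)
        assert report.statistic == 0.0 and not flagged

    def test_large_offset_is_flagged(self):
        df = pd.concat(
            [
                self.sham_frame({1: 9 - (p % 2), 2: 2 + (p % 2)}, participant_id=p)
                for p in range(1, 7)
            ],
            ignore_index=True,
        )
        _, report, flagged = pool_sham(df)
        assert flagged and report.p < 0.05

    def test_pooled_trial_count_is_conserved(self, small_cohort):
        rec = small_cohort.records
        sham = rec[(rec["stim"] == "sham") & (rec["role"] == "target")]
        by_session = sham.groupby("session").size()
        assert by_session.sum() == len(sham)


class TestPower:
    def test_preregistered_sample_size(self):
        assert required_n_paired(0.4, alpha=0.05, power=0.80, tails="two") == 52

    def test_large_effect_small_sample(self):
        assert required_n_paired(2.0, alpha=0.05, power=0.80, tails="two") == 5

    def test_monotone_in_effect_size(self):
        ns = [required_n_paired(d) for d in np.arange(0.2, 1.05, 0.1)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_achieved_power_brackets_target(self):
        from scipy import stats as sps

        def power(n, d=0.4, alpha=0.05):
            df, ncp = n - 1, d * np.sqrt(n)
            tc = sps.t.ppf(1 - alpha / 2, df)
            return sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp)

        n = required_n_paired(0.4)
        assert power(n) >= 0.80 > power(n - 1)

    def test_rejects_nonpositive_d(self):
        with pytest.raises(ValueError):
            required_n_paired(0.0)


class TestManipulationCheck:
    def test_always_lf_toy(self):
        df = make_toy_triplets(["LF", "LF"], bias_type="LF")
        table = manipulation_check(df)
        assert (table.loc["group_mean"] == 100.0).all()

    def test_cohort_role_ordering(self, small_cohort):
        table = manipulation_check(small_cohort.records)
        g = table.loc["group_mean"]
        assert g["bias_LF"] > g["target"] > g["bias_SN"]


class TestPreregisteredReport:
    def test_report_complete_and_serialisable(self, small_report):
        for hid in ("H1.1", "H1.2", "H2.1", "H2.1.1", "H2.1.2", "H2.2", "H2.2.1", "H2.2.2"):
            assert hid in small_report.effects
        payload = small_report.to_json()
        import json

        parsed = json.loads(payload)
        assert set(parsed) == {"effects", "anova_tables", "summaries", "sham_pool_flagged"}

    def test_hysteresis_without_polarization_sensitivity(self):
        # an agent with strong hysteresis but no tDCS response: H1 significant,
        # H2 stimulation ANOVAs null (the qualitative human-data pattern)
        import dataclasses

        base = dataclasses.replace(cr.DEFAULT_2021, stim_polarization=0.0)
        cohort = cr.simulate_cohort(
            8,
            cr.DesignConfig(n_measurement_trials=120, n_triplets_per_block=16),
            rng_seed=12,
            base_params=base,
        )
        rep = preregistered_report(cohort.records)
        assert rep.effects["H1.1"].p < 0.01
        assert rep.effects["H1.2"].p < 0.05
        assert rep.effects["H2.1"].p > 0.05
        assert rep.effects["H2.2"].p > 0.05

    def test_missing_condition_rejected(self, small_cohort):
        sham_only = small_cohort.records.query("stim == 'sham'")
        with pytest.raises(ValueError, match="stimulation conditions"):
            preregistered_report(sham_only)
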