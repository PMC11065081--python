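"""Reliability-statistic tests: closed forms, an independent ICC oracle,
simulation recovery, and report-table structure."""

import math

import numpy as np
import pandas as pd
import pytest

import pulsevar as pv
from pulsevar.reliability import icc_consistency_anova


def _pairs(x1, x2, name="m"):
    return pv.PairedMeasurements(name, np.asarray(x1, float), np.asarray(x2, float))


class TestPairedT:
    def test_identical_sessions(self):
        t, p = pv.paired_t(_pairs([1, 2, 3], [1, 2, 3]))
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_example(self):
        # d = (1, 1, 1, -1): mean .5, sd 1, n 4 -> t = 1; p from t with 3 df
        t, p = pv.paired_t(_pairs([0, 0, 0, 0], [1, 1, 1, -1]))
        assert t == pytest.approx(1.0)
        assert p == pytest.approx(0.3910, abs=5e-4)

    def test_zero_variance_nonzero_mean_flags_infinite_t(self):
        t, p = pv.paired_t(_pairs([0, 0, 0], [1, 1, 1]))
        assert math.isinf(t) and p == 0.0

    def test_type_one_error_rate_under_null(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            subj = rng.normal(0, 1, 40)
            x1 = subj + rng.normal(0, 0.5, 40)
            x2 = subj + rng.normal(0, 0.5, 40)
            _, p = pv.paired_t(_pairs(x1, x2))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.015)


class TestICC:
    def test_perfect_agreement(self):
        res = pv.icc_absolute(_pairs([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res.icc == pytest.approx(1.0)

    def test_reversed_sessions_negative(self):
        res = pv.icc_absolute(_pairs([1, 2, 3, 4], [4, 3, 2, 1]))
        assert res.icc < 0
        assert res.icc == pytest.approx(
            icc_consistency_anova([1, 2, 3, 4], [4, 3, 2, 1]))

    def test_matches_brute_force_anova_oracle(self, rng):
        x1 = rng.normal(10, 3, 25)
        x2 = x1 + rng.normal(0.2, 1.0, 25)
        res = pv.icc_absolute(_pairs(x1, x2))
        assert res.icc == pytest.approx(icc_consistency_anova(x1, x2), rel=1e-12)

    def test_matches_pingouin_all_forms(self, rng):
        pg = pytest.importorskip("pingouin")
        x1 = rng.normal(10, 3, 30) + rng.normal(0, 1, 30)
        x2 = x1 + rng.normal(0.3, 1.2, 30)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(30), 2),
            "raters": np.repeat([1, 2], 30),
            "ratings": np.concatenate([x1, x2])})
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings").set_index("Type")
        for form, pg_type in [("2,1", "ICC(A,1)"), ("3,1", "ICC(C,1)"),
                              ("1,1", "ICC(1,1)")]:
            res = pv.icc_absolute(_pairs(x1, x2), form=form)
            row = table.loc[pg_type]
            assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
            assert res.ci_low == pytest.approx(row["CI95"][0], abs=5e-3)
            assert res.ci_high == pytest.approx(row["CI95"][1], abs=5e-3)

    def test_zero_variance_flagged_undefined(self):
        res = pv.icc_absolute(_pairs([5, 5, 5], [5, 5, 5]))
        assert not res.defined and math.isnan(res.icc)

    def test_affine_invariance(self, rng):
        x1 = rng.normal(10, 3, 20)
        x2 = x1 + rng.normal(0, 1, 20)
        a, b = 2.5, -7.0
        r1 = pv.icc_absolute(_pairs(x1, x2))
        r2 = pv.icc_absolute(_pairs(a * x1 + b, a * x2 + b))
        assert r2.icc == pytest.approx(r1.icc, rel=1e-10)
        assert r2.ci_low == pytest.approx(r1.ci_low, rel=1e-8)

    def test_simulation_recovery_and_coverage(self):
        # Variance-components truth 0.87 at the cohort's scale (n=111):
        # near-unbiased estimation and ~95% CI coverage.
        rng = np.random.default_rng(77)
        b, w = math.sqrt(0.87), math.sqrt(0.13)
        ests, covered = [], 0
        reps = 200
        for _ in range(reps):
            subj = rng.normal(0, b, 111)
            x1 = subj + rng.normal(0, w, 111)
            x2 = subj + rng.normal(0, w, 111)
            res = pv.icc_absolute(_pairs(x1, x2))
            ests.append(res.icc)
            covered += res.ci_low <= 0.87 <= res.ci_high
        assert np.mean(ests) == pytest.approx(0.87, abs=0.02)
        assert covered / reps == pytest.approx(0.95, abs=0.04)


class TestGradeMunro:
    @pytest.mark.parametrize("icc, grade", [
        (0.95, "excellent"), (0.90, "excellent"), (0.87, "good"),
        (0.70, "good"), (0.53, "moderate"), (0.50, "moderate"), (0.49, "low"),
        (-0.2, "low"),
    ])
    def test_bands(self, icc, grade):
        assert pv.grade_munro(icc) == grade


class TestAbsoluteReliability:
    def test_sem_identical_sessions_zero(self):
        assert pv.sem(_pairs([1, 2, 3], [1, 2, 3])) == 0.0

    def test_sem_forced_arithmetic(self):
        # d = (-1, 0, -2): sd(d) = 1, sem = 1/sqrt(3)
        p = _pairs([1, 2, 3], [0, 2, 1])
        assert pv.sem(p) == pytest.approx(1 / math.sqrt(3), abs=1e-4)

    def test_sem_converges_to_within_noise_over_root_n(self, rng):
        sw, n = 0.7, 200_000
        subj = rng.normal(10, 3, n)
        p = _pairs(subj + rng.normal(0, sw, n), subj + rng.normal(0, sw, n))
        assert pv.sem(p) == pytest.approx(sw * math.sqrt(2) / math.sqrt(n), rel=0.02)

    def test_sem_pct_worked_examples(self):
        assert round(pv.sem_pct(0.48, (132.65 + 131.91) / 2), 2) == 0.36
        assert round(pv.sem_pct(0.19, (60.65 + 60.19) / 2), 2) == 0.31
        assert pv.sem_pct(0.0, 100.0) == 0.0

    def test_srd_factor_sqrt2_and_conventional(self):
        assert round(pv.srd(0.19), 2) == 0.27
        assert pv.srd(0.0) == 0.0
        assert pv.srd(1.0, factor="conventional") == pytest.approx(1.96 * math.sqrt(2))

    def test_srd_pct_uses_unrounded_srd(self):
        gm = (33.32 + 34.07) / 2
        assert round(pv.srd_pct(pv.srd(1.13), gm), 2) == 4.74


class TestBlandAltman:
    def test_identical_sessions(self):
        assert pv.bland_altman(_pairs([1, 2, 3], [1, 2, 3])) == (0.0, 0.0, 0.0)

    def test_forced_two_point_limits(self):
        bias, lo, hi = pv.bland_altman(_pairs([0, 0], [1, -1]))
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * math.sqrt(2), abs=1e-9)
        assert lo == pytest.approx(-hi)

    def test_limit_width_converges(self, rng):
        sw, n = 0.7, 200_000
        subj = rng.normal(10, 3, n)
        p = _pairs(subj + rng.normal(0, sw, n), subj + rng.normal(0, sw, n))
        _, lo, hi = pv.bland_altman(p)
        assert hi - lo == pytest.approx(2 * 1.96 * sw * math.sqrt(2), rel=0.02)


class TestReliabilityTable:
    def test_single_stratum_equals_overall(self):
        df = pv.simulate_metric_cohort(pv.CohortSimConfig(n_participants=30, seed=8))
        df["antihypertensive"] = 0
        overall = pv.reliability_table(df)
        stratified = pv.reliability_table(df, stratify_by="antihypertensive")
        for a, b in zip(overall, stratified):
            assert a.metric_name == b.metric_name
            assert a.icc == pytest.approx(b.icc)
            assert a.sem == pytest.approx(b.sem)

    def test_strata_partition_participants(self):
        df = pv.simulate_metric_cohort(pv.CohortSimConfig(n_participants=40, seed=9))
        results = pv.reliability_table(df, stratify_by="antihypertensive")
        ns = {}
        for r in results:
            ns.setdefault(r.metric_name, 0)
            ns[r.metric_name] += r.n
        assert all(n == 40 for n in ns.values())

    def test_srd_over_sem_is_root_two_on_every_row(self):
        df = pv.simulate_metric_cohort(pv.CohortSimConfig(n_participants=25, seed=10))
        for r in pv.reliability_table(df):
            assert r.srd / r.sem == pytest.approx(math.sqrt(2))
            assert r.icc_ci_low <= r.icc <= r.icc_ci_high
            assert r.loa_low <= r.bias <= r.loa_high

    def test_tiny_stratum_emits_flagged_row(self):
        df = pv.simulate_metric_cohort(pv.CohortSimConfig(n_participants=10, seed=2))
        df["antihypertensive"] = [0] * 16 + [1] * 4  # one participant in stratum 1
        # force stratum membership consistent per participant
        df = df.sort_values(["participant_id", "session"]).reset_index(drop=True)
        df["antihypertensive"] = np.repeat(
            [0] * 8 + [1] * 2, 2)
        results = pv.reliability_table(df, stratify_by="antihypertensive",
                                       metrics=["sbp_arv"])
        flagged = [r for r in results if r.stratum == "1"]
        assert len(flagged) == 1 and not flagged[0].defined

    def test_stratum_specific_reliability_ordering(self):
        # Strata simulated with true ICCs 0.93 vs 0.81 should rank in that
        # order in the vast majority of replicates at the cohort's strata
        # sizes (60 + 39).
        comps_hi = {"sbp_arv": (1.7, *pv.variance_components_from_icc(1.0, 0.93))}
        comps_lo = {"sbp_arv": (1.7, *pv.variance_components_from_icc(1.0, 0.81))}
        ordered = 0
        reps = 200
        for rep in range(reps):
            cfg = pv.CohortSimConfig(
                n_participants=99, seed=10_000 + rep,
                metric_components=dict(comps_hi),
                strata_components={1: comps_lo},
                antihypertensive_fraction=39 / 99)
            df = pv.simulate_metric_cohort(cfg)
            res = {r.stratum: r.icc for r in pv.reliability_table(
                df, stratify_by="antihypertensive", metrics=["sbp_arv"])}
            ordered += res["0"] > res["1"]
        assert ordered / reps >= 0.95

    def test_scale_equivariance_of_absolute_indices(self, rng):
        x1 = rng.normal(100, 10, 30)
        x2 = x1 + rng.normal(0, 2, 30)
        r1 = pv.reliability_result(_pairs(x1, x2))
        r2 = pv.reliability_result(_pairs(3 * x1, 3 * x2))
        assert r2.sem == pytest.approx(3 * r1.sem)
        assert r2.srd == pytest.approx(3 * r1.srd)
        assert r2.bias == pytest.approx(3 * r1.bias)
        assert r2.sem_pct == pytest.approx(r1.sem_pct)
        assert r2.srd_pct == pytest.approx(r1.srd_pct)
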