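import numpy as np
import pandas as pd
import pytest

from hemiconn.cohort import CohortSpec, cohort_table, simulate_cohort
from hemiconn.metrics import cohort_metric_tables
from hemiconn.stats import (
    BatteryConfig, association_regression, battery_to_json, fdr_bh,
    group_main_effect, hemisphere_repeated_test, interaction_screen,
    posthoc_pairwise, run_full_battery,
)


def oracle_fixture():
    """Deterministic covariate fixture; the frozen t/p values below were
    computed from this exact table with an independent reference
    implementation of the same linear models."""
    rng = np.random.default_rng(20260926)
    n = 24
    age = np.round(rng.uniform(60, 90, n), 1)
    sex = (rng.random(n) < 0.5).astype(int)
    icvd = np.round(rng.normal(0, 5000, n), 0)
    tr = np.round(rng.normal(12900, 500, n), 0)
    te = np.round(rng.normal(68, 3, n), 1)
    left = np.round(rng.uniform(0.2, 0.5, n), 4)
    right = np.round(left + rng.normal(0.01, 0.02, n), 4)
    score = np.round(rng.normal(40, 10, n), 1)
    ai = np.round((right - left) / (right + left), 5)
    return pd.DataFrame(dict(age=age, sex=sex, icvd=icvd, tr=tr, te=te,
                             left=left, right=right, score=score, ai=ai))


COVARS = ["age", "sex", "icvd", "tr", "te"]


class TestHemisphereRepeatedTest:
    def test_identical_hemispheres_give_t0_p1(self):
        d = oracle_fixture()
        res = hemisphere_repeated_test(d["left"], d["left"], d[COVARS])
        assert res.stat == 0.0 and res.p_raw == 1.0

    def test_matches_reference_lm_oracle(self):
        d = oracle_fixture()
        res = hemisphere_repeated_test(d["left"], d["right"], d[COVARS])
        assert res.stat == pytest.approx(4.3354986599, abs=1e-8)
        assert res.p_raw == pytest.approx(0.0003984822075, rel=1e-8)
        assert res.df == (18,)
        assert "rightward" in res.direction

    def test_t_squared_equals_repeated_measures_F(self):
        """The paired-difference t equals the two-level within-factor F
        (t^2 = F), checked against an independent RSS-comparison route."""
        d = oracle_fixture()
        res = hemisphere_repeated_test(d["left"], d["right"], d[COVARS])
        y = (d["right"] - d["left"]).to_numpy()
        C = d[COVARS].to_numpy(dtype=float)
        C = C - C.mean(axis=0)
        X1 = np.column_stack([np.ones(len(y)), C])
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = np.sum((y - X1 @ b1) ** 2)
        b0, *_ = np.linalg.lstsq(C, y, rcond=None)
        rss0 = np.sum((y - C @ b0) ** 2)
        df = len(y) - X1.shape[1]
        F = (rss0 - rss1) / (rss1 / df)
        assert res.stat ** 2 == pytest.approx(F, abs=1e-8)

    def test_constant_covariate_named(self):
        d = oracle_fixture()
        d["te"] = 68.0
        with pytest.raises(ValueError, match="'te'"):
            hemisphere_repeated_test(d["left"], d["right"], d[COVARS])

    def test_collinear_covariate_named(self):
        d = oracle_fixture()
        d["icvd"] = 2.0 * d["age"] + 1.0
        with pytest.raises(ValueError, match="collinear"):
            hemisphere_repeated_test(d["left"], d["right"], d[COVARS])

    def test_planted_rightward_shift_gives_positive_t(self, rng):
        cov = pd.DataFrame({"age": rng.uniform(60, 90, 40),
                            "sex": rng.integers(0, 2, 40)})
        left = rng.uniform(0.3, 0.5, 40)
        res = hemisphere_repeated_test(left, left + 0.05 + rng.normal(0, 0.01, 40), cov)
        assert res.stat > 0 and res.p_raw < 1e-6


class TestInteractionScreen:
    @staticmethod
    def sim(effect_in_f_only, n=240, seed=0):
        rng = np.random.default_rng(seed)
        group = np.repeat(["NC", "MCI", "AD"], n // 3)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        ai = rng.normal(0, 0.01, n)
        boost = {"NC": 0.0, "MCI": 0.0, "AD": 0.02}
        for g in ("NC", "MCI", "AD"):
            m = group == g
            if effect_in_f_only:
                ai[m & (sex == "F")] += boost[g]
            else:
                ai[m] += boost[g]
        cov = pd.DataFrame({"age": rng.uniform(60, 90, n),
                            "icv": rng.normal(1.4e6, 1e5, n)})
        return ai, group, sex, cov

    def test_female_only_effect_sets_stratify_flag(self):
        ai, group, sex, cov = self.sim(effect_in_f_only=True, seed=5)
        res = interaction_screen(ai, group, sex, cov)
        assert res.stat_kind == "F" and res.df[0] == 2
        assert res.extra["stratify_by_sex"]

    def test_common_effect_leaves_flag_unset(self):
        ai, group, sex, cov = self.sim(effect_in_f_only=False, seed=6)
        res = interaction_screen(ai, group, sex, cov)
        assert not res.extra["stratify_by_sex"]

    def test_single_sex_rejected(self):
        ai, group, sex, cov = self.sim(False)
        with pytest.raises(ValueError, match="both sexes"):
            interaction_screen(ai, group, np.full_like(sex, "M"), cov)

    def test_empty_cell_reported(self):
        ai, group, sex, cov = self.sim(False)
        sex = sex.copy()
        sex[group == "AD"] = "M"
        with pytest.raises(ValueError, match="empty sex x group cell"):
            interaction_screen(ai, group, sex, cov)


class TestGroupMainEffect:
    def test_identical_groups_give_near_zero_F(self, rng):
        base = rng.normal(0, 0.01, 30)
        ai = np.concatenate([base, base, base])
        group = np.repeat(["NC", "MCI", "AD"], 30)
        cov = pd.DataFrame({"age": np.tile(rng.uniform(60, 90, 30), 3)})
        res = group_main_effect(ai, group, cov)
        assert res.stat == pytest.approx(0.0, abs=1e-16)
        assert res.p_raw == pytest.approx(1.0)

    def test_stratified_analysis_drops_other_sex(self):
        ai, group, sex, cov = TestInteractionScreen.sim(True, seed=7)
        res = group_main_effect(ai, group, cov, stratum="F", sex=sex)
        assert res.p_raw < 0.01
        res_m = group_main_effect(ai, group, cov, stratum="M", sex=sex)
        assert res_m.p_raw > res.p_raw

    def test_fewer_than_two_groups_rejected(self, rng):
        cov = pd.DataFrame({"age": rng.uniform(60, 90, 20)})
        with pytest.raises(ValueError, match="2 groups"):
            group_main_effect(rng.normal(size=20), np.full(20, "AD"), cov)


class TestPosthoc:
    def test_bonferroni_times_three_and_cap(self, rng):
        n = 90
        group = np.repeat(["NC", "MCI", "AD"], 30)
        ai = rng.normal(0, 0.01, n)
        ai[group == "AD"] += 0.02
        cov = pd.DataFrame({"age": rng.uniform(60, 90, n)})
        out = posthoc_pairwise(ai, group, cov)
        assert [r.effect for r in out] == ["AD-NC", "AD-MCI", "MCI-NC"]
        for r in out:
            assert r.adjustment == "bonferroni"
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))
        adnc = out[0]
        assert adnc.stat > 0 and adnc.p_adjusted < 0.05

    def test_adjusted_preserves_raw_ordering(self, rng):
        group = np.repeat(["NC", "MCI", "AD"], 20)
        ai = rng.normal(0, 0.01, 60)
        cov = pd.DataFrame({"age": rng.uniform(60, 90, 60)})
        out = posthoc_pairwise(ai, group, cov)
        raw = [r.p_raw for r in out]
        adj = [r.p_adjusted for r in out]
        assert np.array_equal(np.argsort(raw), np.argsort(adj)) or \
            len(set(adj)) < 3  # ties at the cap


class TestFdrBH:
    def test_hand_step_up_case(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        reject, crit = fdr_bh(p, q=0.05)
        assert reject.all() and crit == 5

    def test_all_ones_rejects_nothing(self):
        reject, crit = fdr_bh(np.ones(10))
        assert not reject.any() and crit == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.1, 1.2]))

    def test_matches_independent_step_up_oracle(self):
        def oracle(p, q):
            m = len(p)
            order = np.argsort(p)
            ps = p[order]
            ks = np.nonzero(ps <= (np.arange(1, m + 1) * q / m))[0]
            mask = np.zeros(m, dtype=bool)
            if len(ks):
                mask[order[:ks.max() + 1]] = True
            return mask
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = rng.integers(1, 60)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            mask, _ = fdr_bh(p, 0.05)
            assert np.array_equal(mask, oracle(p, 0.05))


class TestAssociationRegression:
    def test_matches_reference_lm_oracle(self):
        d = oracle_fixture()
        res = association_regression(d["ai"], d["score"], d[COVARS])
        assert res.stat == pytest.approx(1.3071671174, abs=1e-8)
        assert res.p_raw == pytest.approx(0.2085612071, rel=1e-8)
        assert res.df == (17,)

    def test_constant_ai_rejected(self):
        d = oracle_fixture()
        with pytest.raises(ValueError, match="constant"):
            association_regression(np.full(24, 0.1), d["score"], d[COVARS])

    def test_zero_variance_score_rejected(self):
        d = oracle_fixture()
        with pytest.raises(ValueError, match="zero variance"):
            association_regression(d["ai"], np.full(24, 5.0), d[COVARS])

    def test_incomplete_cases_dropped(self):
        d = oracle_fixture()
        score = d["score"].to_numpy().astype(float)
        score[:3] = np.nan
        res = association_regression(d["ai"], score, d[COVARS])
        assert res.extra["n_complete"] == 21


@pytest.fixture(scope="module")
def battery_inputs():
    spec = CohortSpec(n_per_group={"NC": 24, "MCI": 24, "AD": 16},
                      n_nodes=24, density=0.4, seed=11)
    subs, _ = simulate_cohort(spec)
    mtab, atab = cohort_metric_tables([(r.id, l, w) for r, l, w in subs])
    return mtab, atab, cohort_table(subs)


class TestFullBattery:
    def test_id_mismatch_listed(self, battery_inputs):
        mtab, atab, ctab = battery_inputs
        bad = ctab.copy()
        bad.loc[0, "id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            run_full_battery(mtab, atab, bad)

    def test_bundle_structure_and_provenance(self, battery_inputs):
        mtab, atab, ctab = battery_inputs
        res = run_full_battery(mtab, atab, ctab)
        for g in ("NC", "MCI", "AD"):
            assert f"{g}/e_glob" in res["within"]
            assert f"{g}/e_loc" in res["within"]
        assert res["within"]["AD/e_nodal/0"].adjustment == "fdr_bh"
        assert "e_glob" in res["group"] and "e_loc" in res["posthoc"]
        assert len(res["posthoc"]["e_glob"]) == 3
        assert all(r.adjustment == "bonferroni" for r in res["posthoc"]["e_glob"])
        assert "e_glob/ravlt_total" in res["associations"]

    def test_planted_ad_effect_flagged(self, battery_inputs):
        mtab, atab, ctab = battery_inputs
        res = run_full_battery(mtab, atab, ctab)
        assert res["within"]["AD/e_glob"].stat > 0
        assert res["within"]["AD/e_glob"].extra["significant"]
        assert res["group"]["e_glob"].p_raw < 0.05
        adnc = [r for r in res["posthoc"]["e_glob"] if r.effect == "AD-NC"][0]
        assert adnc.stat > 0 and adnc.p_adjusted < 0.05

    def test_rerun_is_byte_identical(self, battery_inputs):
        import json
        mtab, atab, ctab = battery_inputs
        a = json.dumps(battery_to_json(run_full_battery(mtab, atab, ctab)),
                       sort_keys=True)
        b = json.dumps(battery_to_json(run_full_battery(mtab, atab, ctab)),
                       sort_keys=True)
        assert a == b

    def test_null_cohort_completes_with_empty_screen(self):
        zeros = {"NC": 0.0, "MCI": 0.0, "AD": 0.0}
        spec = CohortSpec(n_per_group={"NC": 16, "MCI": 16, "AD": 12},
                          n_nodes=16, density=0.5, seed=21,
                          global_asym_delta=zeros, nodal_asym_delta=zeros,
                          subject_asym_sd=0.0)
        subs, _ = simulate_cohort(spec)
        mtab, atab = cohort_metric_tables([(r.id, l, w) for r, l, w in subs])
        res = run_full_battery(mtab, atab, cohort_table(subs))
        assert res["screened_nodes"] == []
        # no nodal association family without screened nodes
        assert not any(k.startswith("e_nodal") for k in res["associations"])
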