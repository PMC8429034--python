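import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncpair.association import (chisq_clinical, cox_independence,
                                 immune_drug_correlations,
                                 ranksum_by_subgroup, subgroup_survival,
                                 summarize_counts)
from lncpair.evaluation import km_logrank
from lncpair.io import survival_cohort
from lncpair.reference import (REFERENCE_GROUP_SIZES,
                               load_reference_clinical_counts)


def expand_reference_cohort():
    """Rebuild a per-patient table from the published per-level counts."""
    counts = load_reference_clinical_counts()
    n = REFERENCE_GROUP_SIZES["overall"]
    cols = {}
    for var in counts["variable"].unique():
        block = counts[counts["variable"] == var]
        levels = []
        for grp in ("high", "low"):
            for _, row in block.iterrows():
                levels.extend([row["level"]] * int(row[f"{grp}_n"]))
        cols[var] = levels
    groups = (["high"] * REFERENCE_GROUP_SIZES["high"]
              + ["low"] * REFERENCE_GROUP_SIZES["low"])
    idx = [f"P{i:03d}" for i in range(n)]
    clinical = pd.DataFrame(cols, index=idx)
    clinical["os_time"] = 1.0
    clinical["os_event"] = 0
    return pd.Series(groups, index=idx, name="risk_group"), clinical


class TestChisqClinical:
    def test_two_by_two_statistic_by_hand(self):
        # table (10,0 / 0,10): every expected count is 5, sum (O-E)^2/E = 20
        idx = [f"S{j}" for j in range(20)]
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=idx)
        clinical = pd.DataFrame({"var": ["a"] * 10 + ["b"] * 10,
                                 "os_time": 1.0, "os_event": 0}, index=idx)
        assoc, _ = chisq_clinical(groups, clinical, ["var"])
        assert assoc["statistic"].iloc[0] == pytest.approx(20.0)

    def test_independent_variable_null_p(self, rng):
        ps = []
        for _ in range(40):
            idx = [f"S{j}" for j in range(120)]
            groups = pd.Series(rng.choice(["high", "low"], 120), index=idx)
            clinical = pd.DataFrame(
                {"var": rng.choice(["a", "b", "c"], 120),
                 "os_time": 1.0, "os_event": 0}, index=idx)
            assoc, _ = chisq_clinical(groups, clinical, ["var"])
            ps.append(assoc["p"].iloc[0])
        # under the null p is uniform: mean ~0.5, not piling up near 0
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_reference_grade_and_stage_below_printed_bound(self):
        groups, clinical = expand_reference_cohort()
        assoc, _ = chisq_clinical(groups, clinical, ["grade", "stage"])
        assert (assoc["p"] < 0.001).all()

    def test_unknown_levels_reported_but_untested(self):
        groups, clinical = expand_reference_cohort()
        assoc, summary = chisq_clinical(groups, clinical, ["grade"])
        levels = set(summary["level"])
        assert {"GX", "Unknown"} <= levels
        # test statistic computed on G1-G4 only
        block = load_reference_clinical_counts()
        g = block[block["variable"] == "grade"].set_index("level")
        tab = g.loc[["G1", "G2", "G3", "G4"], ["high_n", "low_n"]].T
        stat = stats.chi2_contingency(tab.to_numpy(), correction=False)[0]
        assert assoc["statistic"].iloc[0] == pytest.approx(stat)


class TestSummaryPercentages:
    def test_reference_percentages_reproduced(self):
        counts = load_reference_clinical_counts()
        out = summarize_counts(counts[["variable", "level", "overall_n",
                                       "high_n", "low_n"]])
        for col in ("overall", "high", "low"):
            assert np.allclose(out[f"{col}_pct"], counts[f"{col}_pct"])

    def test_gender_fraction_example(self):
        counts = load_reference_clinical_counts()
        out = summarize_counts(counts[["variable", "level", "overall_n",
                                       "high_n", "low_n"]])
        row = out[(out["variable"] == "gender") & (out["level"] == "female")]
        assert row["overall_pct"].iloc[0] == 35.1  # 186/530

    def test_summary_from_real_groups_matches_counts(self, default_result,
                                                     default_cohort):
        surv = survival_cohort(default_cohort.clinical)
        _, summary = chisq_clinical(default_result.risk.groups, surv, ["grade"])
        n_high = (default_result.risk.groups == "high").sum()
        block = summary[summary["variable"] == "grade"]
        assert block["high_n"].sum() == n_high
        assert np.allclose(block["high_pct"],
                           np.round(100.0 * block["high_n"] / n_high, 1))


class TestRanksum:
    def test_toy_u_statistic_by_enumeration(self):
        # scores (1,2,3) vs (4,5,6): all 9 cross pairs lose -> U = 0
        idx = [f"S{j}" for j in range(6)]
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=idx)
        clinical = pd.DataFrame({"age": [70, 70, 70, 50, 50, 50],
                                 "os_time": 1.0, "os_event": 0}, index=idx)
        row = ranksum_by_subgroup(scores, clinical, "age")
        assert row["statistic"] == pytest.approx(0.0)

    def test_identical_distributions_p_one(self):
        idx = [f"S{j}" for j in range(8)]
        scores = pd.Series([1.0, 2.0, 3.0, 4.0] * 2, index=idx)
        clinical = pd.DataFrame({"gender": ["female"] * 4 + ["male"] * 4,
                                 "os_time": 1.0, "os_event": 0}, index=idx)
        row = ranksum_by_subgroup(scores, clinical, "gender")
        assert row["p"] == pytest.approx(1.0)

    def test_empty_subgroup_raises_with_name(self):
        idx = ["S0", "S1"]
        scores = pd.Series([1.0, 2.0], index=idx)
        clinical = pd.DataFrame({"m_stage": ["M0", "M0"],
                                 "os_time": 1.0, "os_event": 0}, index=idx)
        with pytest.raises(ValueError, match="M1"):
            ranksum_by_subgroup(scores, clinical, "m_stage")

    def test_planted_grade_signal_age_null(self, default_result,
                                           default_cohort):
        surv = survival_cohort(default_cohort.clinical)
        scores = default_result.risk.scores
        grade = ranksum_by_subgroup(scores, surv, "grade")
        age = ranksum_by_subgroup(scores, surv, "age")
        assert grade["p"] < 0.05      # grade tied to risk by construction
        assert age["p"] > 0.05        # age independent of risk


class TestCoxIndependence:
    def test_hr_identity_on_every_row(self, default_result, default_cohort):
        surv = survival_cohort(default_cohort.clinical)
        rows = cox_independence(default_result.risk.scores, surv)
        assert set(rows["model"]) == {"univariate", "multivariate"}
        assert (rows["hr_low"] <= rows["hr"] + 1e-12).all()
        assert (rows["hr"] <= rows["hr_high"] + 1e-12).all()
        assert np.allclose(np.sqrt(rows["hr_low"] * rows["hr_high"]),
                           rows["hr"], rtol=1e-6)

    def test_risk_score_significant_both_models(self, default_result,
                                                default_cohort):
        surv = survival_cohort(default_cohort.clinical)
        rows = cox_independence(default_result.risk.scores, surv)
        rs = rows[rows["variable"] == "risk_score"]
        assert (rs["p"] < 0.01).all()
        assert (rs["hr"] > 1).all()

    def test_duplicated_covariate_warns(self, default_result, default_cohort,
                                        caplog):
        surv = survival_cohort(default_cohort.clinical).copy()
        # duplicate the risk score through a covariate slot: grade becomes
        # a deterministic copy of the score's sign pattern
        scores = default_result.risk.scores
        surv["grade"] = np.where(scores.loc[surv.index] > scores.median(),
                                 "G4", "G1")
        surv["stage"] = np.where(scores.loc[surv.index] > scores.median(),
                                 "IV", "I")
        with caplog.at_level("WARNING", logger="lncpair"):
            cox_independence(scores, surv)
        assert "collinear" in caplog.text


class TestSubgroupSurvival:
    def test_whole_cohort_subgroup_reproduces_global_logrank(
            self, default_result, default_cohort):
        surv = survival_cohort(default_cohort.clinical)
        g = default_result.risk.groups
        global_res = km_logrank(g, surv)
        # a dichotomization whose two sides jointly cover the cohort
        tab = subgroup_survival(g, surv, variables=["gender"])
        pooled_n = tab["n"].sum()
        assert pooled_n == len(surv)
        # and running the machinery on an all-in-one subgroup matches
        clin2 = surv.copy()
        clin2["gender"] = "female"
        tab2 = subgroup_survival(g, clin2, variables=["gender"])
        row = tab2[tab2["subgroup"] == "female"].iloc[0]
        assert row["statistic"] == pytest.approx(global_res.statistic)
        assert row["p"] == pytest.approx(global_res.p)

    def test_sparse_subgroup_skipped_with_note(self, default_result,
                                               default_cohort):
        surv = survival_cohort(default_cohort.clinical).copy()
        g = default_result.risk.groups
        surv["m_stage"] = "M0"
        surv.iloc[0, surv.columns.get_loc("m_stage")] = "M1"
        tab = subgroup_survival(g, surv, variables=["m_stage"])
        m1 = tab[tab["subgroup"] == "M1"].iloc[0]
        assert m1["note"] != ""
        assert np.isnan(m1["p"])


class TestImmuneDrug:
    def test_monotone_infiltration_rho_one(self):
        idx = [f"S{j}" for j in range(10)]
        scores = pd.Series(np.arange(10.0), index=idx)
        groups = pd.Series(["high"] * 5 + ["low"] * 5, index=idx)
        inf = pd.DataFrame([np.arange(10.0) ** 2], index=["Tregs"],
                           columns=idx)
        out = immune_drug_correlations(scores, groups, infiltration=inf)
        assert out["statistic"].iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        idx = ["a", "b", "c"]
        scores = pd.Series([1.0, 2.0, 3.0], index=idx)
        groups = pd.Series(["low", "low", "high"], index=idx)
        inf = pd.DataFrame([[3.0, 2.0, 1.0]], index=["Tregs"], columns=idx)
        out = immune_drug_correlations(scores, groups, infiltration=inf)
        # brute-force rank formula on (1,2,3)/(3,2,1): rho = -1
        assert out["statistic"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_overlapping_samples_raises(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series(["high", "low"], index=["a", "b"])
        inf = pd.DataFrame([[0.1, 0.2]], index=["Tregs"], columns=["a", "x"])
        with pytest.raises(ValueError, match="overlap"):
            immune_drug_correlations(scores, groups, infiltration=inf)

    def test_bh_option_adds_adjusted_column(self, default_result,
                                            default_cohort):
        out = immune_drug_correlations(
            default_result.risk.scores, default_result.risk.groups,
            infiltration=default_cohort.infiltration, bh=True)
        assert "p_adj" in out.columns
        sp = out[out["test"] == "spearman"]
        assert (sp["p_adj"] >= sp["p"] - 1e-15).all()
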