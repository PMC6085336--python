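import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncgx.clinical import (
    consensus_rank,
    label_sensitive,
    multivariate_cox,
    predict_patients,
    sensitivity_summary,
    treated_km,
    univariate_cox,
    weighted_rank,
)
from lncgx.dataio import ClinicalTable, FeatureMatrix, ValidationError
from lncgx.lenp import LENPModel


def make_clinical(n, types=None, stages=None, rng_seed=0, times=None, events=None,
                  treatments=None, ages=None):
    rng = np.random.default_rng(rng_seed)
    idx = [f"P{i:03d}" for i in range(n)]
    return ClinicalTable(pd.DataFrame(
        {
            "cancer_type": types if types is not None else ["BRCA"] * n,
            "stage": stages if stages is not None else ["II"] * n,
            "age": ages if ages is not None else rng.integers(30, 91, n),
            "os_time": times if times is not None else rng.exponential(500, n),
            "os_event": events if events is not None else np.ones(n, dtype=int),
            "treatments": treatments if treatments is not None else [[]] * n,
        },
        index=idx,
    ))


def identity_model(agent, feature):
    return LENPModel(
        agent_id=agent, scope="pan", features=[feature],
        coefficients=np.array([1.0]), intercept=0.0, alpha=0.5, lam=0.1,
        response_metric="ic50", feature_means=np.array([0.0]),
        feature_sds=np.array([1.0]),
    )


class TestStageFilter:
    def test_stage_one_cohort_is_emptied(self):
        clin = make_clinical(6, stages=["I"] * 6)
        expr = FeatureMatrix(pd.DataFrame(
            np.zeros((6, 1)), index=clin.patient_ids, columns=["L1"]
        ), normalized=True)
        out = predict_patients({"d": identity_model("d", "L1")}, expr, clin)
        assert out.empty

    def test_stage_one_laml_retained(self):
        clin = make_clinical(4, types=["LAML", "LAML", "BRCA", "BRCA"],
                             stages=["I", "II", "I", "II"])
        expr = FeatureMatrix(pd.DataFrame(
            np.zeros((4, 1)), index=clin.patient_ids, columns=["L1"]
        ), normalized=True)
        out = predict_patients({"d": identity_model("d", "L1")}, expr, clin)
        assert list(out.index) == ["P000", "P001", "P003"]

    def test_deterministic_repeat(self, small_sim):
        from lncgx.simdata import simulate_tumor_cohort
        cfg, expr, _, _, truth = small_sim
        texpr, clin = simulate_tumor_cohort(cfg, truth)
        model = identity_model("d", texpr.feature_ids[0])
        a = predict_patients({"d": model}, texpr, clin)
        b = predict_patients({"d": model}, texpr, clin)
        pd.testing.assert_frame_equal(a, b)


class TestLabelSensitive:
    def test_quartile_of_eight(self):
        preds = pd.DataFrame({"d": [1.0, 2, 3, 4, 5, 6, 7, 8]},
                             index=[f"P{i}" for i in range(8)])
        labels = label_sensitive(preds)
        assert labels["d"].sum() == 2
        assert labels.loc[["P0", "P1"], "d"].all()

    def test_all_tied_degenerate_flagged(self, caplog):
        preds = pd.DataFrame({"d": [2.0] * 8})
        with caplog.at_level("WARNING"):
            labels = label_sensitive(preds)
        assert labels["d"].all()
        assert "degenerate" in caplog.text

    @given(st.permutations(list(range(12))))
    def test_monotone_transform_invariance(self, values):
        preds = pd.DataFrame({"d": [float(v) for v in values]})
        transformed = pd.DataFrame({"d": [np.expm1(v / 3) for v in values]})
        pd.testing.assert_frame_equal(
            label_sensitive(preds), label_sensitive(transformed)
        )

    def test_sensitive_count_is_quartile_ceiling(self):
        rng = np.random.default_rng(0)
        n = 103
        preds = pd.DataFrame({"d": rng.standard_normal(n)})
        labels = label_sensitive(preds)
        assert labels["d"].sum() == int(np.ceil(n / 4))


class TestSensitivitySummary:
    def test_quarter_of_four(self):
        preds = pd.DataFrame({"d": [1.0, 2, 3, 4, 10, 11, 12, 13]},
                             index=[f"P{i}" for i in range(8)])
        types = pd.Series(["A"] * 4 + ["B"] * 4, index=preds.index)
        labels = label_sensitive(preds)
        pct, ks = sensitivity_summary(labels, preds, types)
        assert pct.at["A", "d"] == pytest.approx(50.0)  # 2 of 4
        assert pct.at["B", "d"] == pytest.approx(0.0)
        shifted = ks[(ks["cancer_type"] == "A")]
        assert (shifted["direction"] == "more_sensitive").all()

    def test_planted_shift_detected_by_ks(self):
        rng = np.random.default_rng(1)
        preds = pd.DataFrame({"d": np.concatenate([
            rng.normal(-2, 1, 50), rng.normal(0, 1, 150)
        ])}, index=[f"P{i}" for i in range(200)])
        types = pd.Series(["LOW"] * 50 + ["REST"] * 150, index=preds.index)
        labels = label_sensitive(preds)
        _, ks = sensitivity_summary(labels, preds, types)
        row = ks[(ks["cancer_type"] == "LOW")].iloc[0]
        assert row["p"] < 1e-6 and row["direction"] == "more_sensitive"


class TestConsensusRank:
    def test_weighted_formula(self):
        assert weighted_rank([10, 20], [1.0, 0.5]) == pytest.approx(13.3333, abs=1e-3)

    def test_two_drug_type(self):
        n = 10
        rng = np.random.default_rng(2)
        preds = pd.DataFrame(
            {"d1": rng.permutation(n) + 1.0, "d2": rng.permutation(n) + 1.0},
            index=[f"P{i}" for i in range(n)],
        )
        types = pd.Series(["T"] * n, index=preds.index)
        approved = {"T": {"first_line": ["d1"], "second_line": ["d2"]}}
        cs = consensus_rank(preds, types, approved)
        p = preds.index[0]
        expected = weighted_rank(
            [preds["d1"].rank()[p], preds["d2"].rank()[p]], [1.0, 0.5]
        )
        assert cs.scores.at[p, "consensus_rank"] == pytest.approx(expected)
        assert (cs.scores["category"] == "sensitive").sum() == 3  # ceil(0.3*10)

    def test_single_drug_identity(self):
        preds = pd.DataFrame({"d1": [5.0, 1.0, 3.0]}, index=["a", "b", "c"])
        types = pd.Series(["T"] * 3, index=preds.index)
        cs = consensus_rank(preds, types, {"T": {"first_line": ["d1"], "second_line": []}})
        assert cs.scores["consensus_rank"].tolist() == [3.0, 1.0, 2.0]

    def test_unconfigured_type_skipped(self):
        preds = pd.DataFrame({"d1": [1.0, 2.0, 1.5, 2.5]},
                             index=["a", "b", "c", "d"])
        types = pd.Series(["T", "T", "U", "U"], index=preds.index)
        cs = consensus_rank(preds, types, {"T": {"first_line": ["d1"], "second_line": []}})
        assert set(cs.scores.index) == {"a", "b"}

    def test_rank_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        preds = pd.DataFrame({"d1": rng.standard_normal(20)},
                             index=[f"P{i}" for i in range(20)])
        types = pd.Series(["T"] * 20, index=preds.index)
        approved = {"T": {"first_line": ["d1"], "second_line": []}}
        a = consensus_rank(preds, types, approved).scores
        b = consensus_rank(np.exp(preds / 2), types, approved).scores
        pd.testing.assert_frame_equal(a, b)


class TestUnivariateCox:
    def test_known_hazard_recovered(self):
        rng = np.random.default_rng(4)
        n = 1000
        score = rng.standard_normal(n)
        hazard = 0.002 * np.exp(np.log(2) * score)
        times = rng.exponential(1 / hazard)
        clin = make_clinical(n, times=times, events=np.ones(n, dtype=int))
        s = pd.Series(score, index=clin.patient_ids)
        out = univariate_cox(s, clin)
        assert 1.7 <= out["hr"] <= 2.3

    def test_scale_invariance_of_hr_per_sd(self):
        rng = np.random.default_rng(5)
        n = 300
        score = rng.standard_normal(n)
        times = rng.exponential(1 / (0.002 * np.exp(0.5 * score)))
        clin = make_clinical(n, times=times, events=np.ones(n, dtype=int))
        s = pd.Series(score, index=clin.patient_ids)
        out1 = univariate_cox(s, clin)
        out2 = univariate_cox(2 * s, clin)
        assert out1["hr"] == pytest.approx(out2["hr"], rel=1e-8)

    def test_no_events_rejected(self):
        clin = make_clinical(20, events=np.zeros(20, dtype=int))
        with pytest.raises(ValidationError):
            univariate_cox(pd.Series(np.arange(20.0), index=clin.patient_ids), clin)


class TestMultivariateCox:
    def test_resistance_only_effect_recovered(self):
        rng = np.random.default_rng(6)
        n = 600
        preds = pd.DataFrame({"d1": rng.standard_normal(n)},
                             index=[f"P{i:03d}" for i in range(n)])
        types = pd.Series(["T"] * n, index=preds.index)
        cs = consensus_rank(preds, types, {"T": {"first_line": ["d1"], "second_line": []}})
        cat = cs.scores["category"].map(
            {"sensitive": 0, "partial_response": 1, "partial_resistance": 2,
             "resistance": 3}
        ).to_numpy()
        times = rng.exponential(1 / (0.002 * np.exp(0.5 * cat)))
        stages = rng.choice(["II", "III", "IV"], n)
        clin = make_clinical(n, stages=stages, times=times,
                             events=np.ones(n, dtype=int))
        out = multivariate_cox(cs, clin)
        assert out.loc["resistance", "hr"] > 1
        assert out.loc["resistance", "p"] < 1e-6
        for cov in ["stage", "old_age"]:
            assert out.loc[cov, "ci_low"] <= 1 <= out.loc[cov, "ci_high"]

    def test_degenerate_stage_dropped(self, caplog):
        rng = np.random.default_rng(7)
        n = 80
        preds = pd.DataFrame({"d1": rng.standard_normal(n)},
                             index=[f"P{i:03d}" for i in range(n)])
        types = pd.Series(["T"] * n, index=preds.index)
        cs = consensus_rank(preds, types, {"T": {"first_line": ["d1"], "second_line": []}})
        clin = make_clinical(n)  # all stage II
        with caplog.at_level("WARNING"):
            out = multivariate_cox(cs, clin)
        assert "stage" not in out.index

    def test_age_sixty_five_is_old(self):
        # boundary convention: exactly 65 dichotomizes to old
        from lncgx.clinical import AGE_CUTOFF
        assert (pd.Series([64, 65, 66]) >= AGE_CUTOFF).tolist() == [False, True, True]


class TestTreatedKM:
    def make_cohort(self, n, hr, seed, drug="d1"):
        rng = np.random.default_rng(seed)
        score = rng.standard_normal(n)
        resistant = score >= np.median(score)
        hazard = 0.002 * np.where(resistant, hr, 1.0)
        times = rng.exponential(1 / hazard)
        clin = make_clinical(n, times=times, events=np.ones(n, dtype=int),
                             treatments=[[drug]] * n)
        preds = pd.Series(score, index=clin.patient_ids)
        return preds, clin

    def test_group_sizes_differ_by_at_most_one(self):
        preds, clin = self.make_cohort(21, 1.0, 8)
        out = treated_km(preds, clin, "d1")
        assert abs(out["n_sensitive"] - out["n_resistant"]) <= 1
        assert out["n_resistant"] == 11  # odd n: median patient is resistant

    def test_planted_hazard_detected(self):
        preds, clin = self.make_cohort(200, 3.0, 9)
        out = treated_km(preds, clin, "d1")
        assert out["logrank_p"] < 0.01
        assert out["hr"] > 1.5

    def test_untreated_patients_excluded(self):
        preds, clin = self.make_cohort(40, 1.0, 10)
        with pytest.raises(ValidationError):
            treated_km(preds, clin, "other_drug")
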