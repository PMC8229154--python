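import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cognet.errors import DegenerateError, ValidationError
from cognet.modeling import (DomainModel, compare_groups, compose_domain_network,
                             count_generated, find_hubs, model_report,
                             stepwise_fit, ttest_from_summary)


def _frame(X):
    return pd.DataFrame(X, columns=[f"IC{j + 1}" for j in range(X.shape[1])])


class TestStepwise:
    def test_exact_dependence_selects_single_predictor(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(30, 10)))
        y = 2.0 * X["IC3"].to_numpy()
        m = stepwise_fit(X, y)
        assert m.ic_ids == ["IC3"]
        assert m.coefficient("IC3") == pytest.approx(2.0, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)
        lo, hi = m.table.loc["IC3", ["ci_low", "ci_high"]]
        assert lo <= 2.0 <= hi

    def test_pure_noise_response_generates_nothing(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(40, 6)))
        y = rng.normal(size=40)
        m = stepwise_fit(X, y, domain="delayed_recall")
        assert not m.generated and m.ic_ids == [] and m.r2 == 0.0

    def test_collinear_candidate_refused(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(50, 3))
        X = _frame(np.column_stack([base, base[:, 0]]))    # IC4 duplicates IC1
        y = 1.5 * base[:, 0] + 0.1 * rng.normal(size=50)
        m = stepwise_fit(X, y)
        assert not {"IC1", "IC4"} <= set(m.ic_ids)
        assert any("ill-conditioned" in n for n in m.notes)

    def test_orthogonal_candidates_reduce_to_marginal_screening(self):
        rng = np.random.default_rng(5)
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = _frame(q)                                       # exactly orthogonal
        beta = np.array([4.0, 0, 0, -3.0, 0, 0, 5.0, 0])
        y = q @ beta + 0.3 * rng.normal(size=n)
        m = stepwise_fit(X, y)
        marginal = {c for j, c in enumerate(X.columns)
                    if stats.pearsonr(q[:, j], y).pvalue <= 0.05}
        assert set(m.ic_ids) == marginal == {"IC1", "IC4", "IC7"}

    def test_parameter_validation(self):
        X = _frame(np.random.default_rng(0).normal(size=(10, 3)))
        y = np.zeros(10)
        with pytest.raises(ValidationError):
            stepwise_fit(X, y, alpha_enter=0.2, alpha_remove=0.1)
        with pytest.raises(ValidationError):
            stepwise_fit(X.iloc[:2], y[:2])
        y2 = y.copy()
        y2[0] = np.nan
        with pytest.raises(ValidationError):
            stepwise_fit(X, y2)


class TestComposite:
    def _maps(self):
        rng = np.random.default_rng(6)
        return {f"IC{i + 1}": rng.normal(size=50) for i in range(4)}

    def _model(self, coeffs):
        table = pd.DataFrame({"B": pd.Series(coeffs), "ci_low": -1.0,
                              "ci_high": 1.0, "p": 0.01})
        return DomainModel(domain="abstraction", ic_ids=list(coeffs),
                           table=table, intercept=0.0, r2=0.1, model_p=0.04,
                           generated=True)

    def test_single_negative_coefficient_composite(self):
        maps = self._maps()
        m = self._model({"IC2": -0.025})
        cm = compose_domain_network(m, maps)
        np.testing.assert_allclose(cm.values, -0.025 * maps["IC2"], atol=1e-12)

    def test_linearity_in_models(self):
        maps = self._maps()
        both = compose_domain_network(self._model({"IC1": 0.3, "IC3": -0.7}), maps)
        single = [compose_domain_network(self._model({k: v}), maps)
                  for k, v in [("IC1", 0.3), ("IC3", -0.7)]]
        np.testing.assert_allclose(both.values,
                                   single[0].values + single[1].values, atol=1e-12)

    def test_missing_map_and_ungenerated_model(self):
        maps = self._maps()
        with pytest.raises(ValidationError):
            compose_domain_network(self._model({"IC9": 1.0}), maps)
        empty = DomainModel(domain="delayed_recall", ic_ids=[],
                            table=pd.DataFrame(), intercept=np.nan, r2=0.0,
                            model_p=np.nan, generated=False)
        with pytest.raises(ValidationError):
            compose_domain_network(empty, maps)


def _fake_model(domain, ics, generated=True):
    if not generated:
        return DomainModel(domain=domain, ic_ids=[], table=pd.DataFrame(),
                           intercept=np.nan, r2=0.0, model_p=np.nan,
                           generated=False)
    table = pd.DataFrame({"B": 1.0, "ci_low": 0.5, "ci_high": 1.5, "p": 0.01},
                         index=ics)
    return DomainModel(domain=domain, ic_ids=ics, table=table, intercept=0.0,
                       r2=0.5, model_p=0.001, generated=True)


class TestHubs:
    def test_disjoint_models_have_no_hubs(self):
        models = [_fake_model("a", ["IC1", "IC2"]), _fake_model("b", ["IC3"])]
        assert find_hubs(models) == []

    def test_shared_component_ranks_first(self):
        models = [_fake_model("a", ["IC5", "IC1"]), _fake_model("b", ["IC5"]),
                  _fake_model("c", ["IC5", "IC1"])]
        hubs = find_hubs(models)
        assert hubs[0] == ("IC5", ["a", "b", "c"])
        assert hubs[1] == ("IC1", ["a", "c"])

    def test_requires_two_generated_models(self):
        with pytest.raises(ValidationError):
            find_hubs([_fake_model("a", ["IC1"]), _fake_model("b", [], False)])


class TestGroupComparison:
    def test_shift_direction_sets_t_sign(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 2))
        X = pd.DataFrame(np.vstack([base[:15] + [1.0, -1.0], base[15:]]))
        g = np.array(["PD"] * 15 + ["Ctr"] * 15)
        res = compare_groups(X, g)
        assert res["t"].iloc[0] > 0 and res["t"].iloc[1] < 0
        assert (res["df"] == 28).all()

    def test_single_subject_group_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValidationError):
            compare_groups(X, np.array(["PD"] * 4 + ["Ctr"]))

    def test_zero_variance_rejected(self):
        X = pd.DataFrame(np.ones((6, 1)))
        with pytest.raises(DegenerateError):
            compare_groups(X, np.array(["PD"] * 3 + ["Ctr"] * 3))

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(np.concatenate([rng.normal(0, 5, 10),
                                         rng.normal(0, 0.5, 40)])[:, None])
        g = np.array(["PD"] * 10 + ["Ctr"] * 40)
        student = compare_groups(X, g, variant="student")
        welch = compare_groups(X, g, variant="welch")
        assert welch["df"].iloc[0] < student["df"].iloc[0]


class TestSummaryTtest:
    def test_equal_means_null(self):
        t, df, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0 and df == 20 and p == pytest.approx(1.0)

    def test_summary_matches_raw_data_identity(self):
        rng = np.random.default_rng(9)
        def exact(n, mean, sd):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return x * sd + mean
        a, b = exact(14, 2.3, 1.1), exact(9, 1.7, 0.8)
        t_raw = stats.ttest_ind(a, b).statistic
        t_sum, _, p_sum = ttest_from_summary(2.3, 1.1, 14, 1.7, 0.8, 9)
        assert t_sum == pytest.approx(t_raw, abs=1e-10)

    def test_swap_symmetry(self):
        t1, _, p1 = ttest_from_summary(3.0, 1.0, 8, 2.0, 1.5, 11)
        t2, _, p2 = ttest_from_summary(2.0, 1.5, 11, 3.0, 1.0, 8)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_validation(self):
        with pytest.raises(ValidationError):
            ttest_from_summary(1, 1, 1, 2, 1, 5)
        with pytest.raises(ValidationError):
            ttest_from_summary(1, 0, 5, 2, 1, 5)


def test_model_report_counts_generated_domains():
    models = {
        "attention": _fake_model("attention", ["IC1", "IC2"]),
        "delayed_recall": _fake_model("delayed_recall", [], generated=False),
        "naming": _fake_model("naming", ["IC3"]),
    }
    rep = model_report(models)
    assert count_generated(models) == 2
    assert rep.loc[rep.domain == "delayed_recall", "ic_id"].tolist() == ["NA"]
    assert len(rep) == 4
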