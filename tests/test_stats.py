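import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from remindersim import stats as st

from .oracles import mixed_anova_oracle, within_anova_oracle


# ---------------------------------------------------------------------------
# t-tests and effect sizes


@pytest.mark.parametrize("tail", [st.TWO_SIDED, st.GREATER, st.LESS])
def test_one_sample_t_matches_scipy(rng, tail):
    x = rng.normal(0.4, 1.1, size=35)
    res = st.one_sample_t(x, mu0=0.1, tail=tail)
    ref = sps.ttest_1samp(x, 0.1, alternative={"two-sided": "two-sided",
                                               "greater": "greater", "less": "less"}[tail])
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.effect_size == pytest.approx(res.statistic / math.sqrt(x.size), abs=1e-12)


def test_paired_t_matches_scipy(rng):
    x = rng.normal(1.0, 2.0, size=40)
    y = x + rng.normal(-0.5, 1.0, size=40)
    res = st.paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.effect_size_label == "d_z"
    d = (x - y).mean() / (x - y).std(ddof=1)
    assert res.effect_size == pytest.approx(d, abs=1e-12)


def test_zero_variance_is_flagged_not_crashed():
    res = st.one_sample_t([1.0, 1.0, 1.0], mu0=1.0)
    assert math.isnan(res.statistic) and res.note == "zero variance"


def test_effect_size_from_t_identity():
    assert st.cohen_d_from_t(10.32, 300) == pytest.approx(0.5958, abs=5e-4)
    assert st.cohen_d_from_t(0.0, 50) == 0.0
    with pytest.raises(ValueError):
        st.cohen_d_from_t(1.0, 1)


# ---------------------------------------------------------------------------
# 2x2 ANOVA


def _mixed_fixture(rng, n_per_group=12):
    rows = []
    values, group_of = {}, {}
    for g, label in enumerate(["g1", "g2"]):
        for i in range(n_per_group):
            sid = f"{label}_s{i}"
            x = rng.normal(g * 0.5, 1.0, size=2) + np.array([0.0, 0.8]) + rng.normal(0, 0.7)
            values[sid] = (float(x[0]), float(x[1]))
            group_of[sid] = label
            for j, lvl in enumerate(["w1", "w2"]):
                rows.append({"subject": sid, "within": lvl, "between": label, "value": x[j]})
    return pd.DataFrame(rows), values, group_of


def _within_fixture(rng, n=14):
    rows = []
    values = {}
    for i in range(n):
        sid = f"s{i}"
        base = rng.normal(0, 0.8)
        cells = {}
        for a in (0, 1):
            for b in (0, 1):
                x = base + 0.6 * a - 0.3 * b + 0.2 * a * b + rng.normal(0, 1.0)
                cells[(a, b)] = float(x)
                rows.append({"subject": sid, "A": f"a{a}", "B": f"b{b}", "value": x})
        values[sid] = cells
    return pd.DataFrame(rows), values


def test_mixed_anova_matches_loop_oracle(rng):
    for _ in range(10):
        data, values, group_of = _mixed_fixture(rng)
        table = st.anova_2x2(data, "mixed")
        oracle = mixed_anova_oracle(values, group_of)
        for effect, key in [("between", "between"), ("within", "within"),
                            ("within:between", "interaction")]:
            row = table.row(effect)
            ss, ss_err, df_err = oracle[key]
            assert row["ss"] == pytest.approx(ss, abs=1e-10)
            assert row["ss_error"] == pytest.approx(ss_err, abs=1e-10)
            assert row["df2"] == df_err
            assert row["partial_eta_sq"] == pytest.approx(ss / (ss + ss_err), abs=1e-12)


def test_mixed_anova_t_squared_identities(rng):
    """Between F equals the squared pooled two-sample t on subject means;
    interaction F equals the squared t on difference scores."""
    data, values, group_of = _mixed_fixture(rng)
    table = st.anova_2x2(data, "mixed")
    means = {s: sum(v) / 2 for s, v in values.items()}
    diffs = {s: v[1] - v[0] for s, v in values.items()}
    g1 = [s for s, g in group_of.items() if g == "g1"]
    g2 = [s for s, g in group_of.items() if g == "g2"]
    t_b = sps.ttest_ind([means[s] for s in g1], [means[s] for s in g2]).statistic
    t_i = sps.ttest_ind([diffs[s] for s in g1], [diffs[s] for s in g2]).statistic
    assert table.row("between")["F"] == pytest.approx(t_b**2, abs=1e-10)
    assert table.row("within:between")["F"] == pytest.approx(t_i**2, abs=1e-10)


def test_mixed_anova_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    data, _, _ = _mixed_fixture(rng)
    table = st.anova_2x2(data, "mixed")
    ref = pingouin.mixed_anova(
        data=data, dv="value", within="within", subject="subject", between="between"
    ).set_index("Source")
    assert table.row("between")["F"] == pytest.approx(ref.loc["between", "F"], abs=1e-6)
    assert table.row("within")["F"] == pytest.approx(ref.loc["within", "F"], abs=1e-6)
    assert table.row("within:between")["F"] == pytest.approx(ref.loc["Interaction", "F"], abs=1e-6)
    assert table.row("within")["partial_eta_sq"] == pytest.approx(ref.loc["within", "np2"], abs=1e-6)


def test_within_anova_matches_loop_oracle(rng):
    for _ in range(10):
        data, values = _within_fixture(rng)
        table = st.anova_2x2(data, "within", within=("A", "B"))
        oracle = within_anova_oracle(values)
        for effect, key in [("A", "A"), ("B", "B"), ("A:B", "interaction")]:
            row = table.row(effect)
            ss, ss_err, df_err = oracle[key]
            assert row["ss"] == pytest.approx(ss, abs=1e-10)
            assert row["ss_error"] == pytest.approx(ss_err, abs=1e-10)
            assert row["df2"] == df_err


def test_within_anova_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM

    data, _ = _within_fixture(rng)
    table = st.anova_2x2(data, "within", within=("A", "B"))
    ref = AnovaRM(data, depvar="value", subject="subject", within=["A", "B"]).fit()
    anova = ref.anova_table
    assert table.row("A")["F"] == pytest.approx(anova.loc["A", "F Value"], abs=1e-8)
    assert table.row("B")["F"] == pytest.approx(anova.loc["B", "F Value"], abs=1e-8)
    assert table.row("A:B")["F"] == pytest.approx(anova.loc["A:B", "F Value"], abs=1e-8)


def test_constant_data_gives_zero_f(rng):
    data, _, _ = _mixed_fixture(rng)
    data["value"] = 3.0
    table = st.anova_2x2(data, "mixed")
    assert all(row["F"] == 0.0 for row in table.rows)


def test_incomplete_subjects_are_rejected(rng):
    data, _, _ = _mixed_fixture(rng)
    with pytest.raises(ValueError):
        st.anova_2x2(data.iloc[1:], "mixed")
    wdata, _ = _within_fixture(rng)
    with pytest.raises(ValueError):
        st.anova_2x2(wdata.iloc[1:], "within", within=("A", "B"))


# ---------------------------------------------------------------------------
# correlations


def test_pearson_r_limits_and_scipy_agreement(rng):
    x = rng.normal(size=30)
    assert st.pearson_r(x, x).statistic == pytest.approx(1.0)
    assert st.pearson_r(x, -x).statistic == pytest.approx(-1.0)
    y = x + rng.normal(size=30)
    res = st.pearson_r(x, y)
    ref = sps.pearsonr(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
    flagged = st.pearson_r(x, np.full(30, 2.0))
    assert math.isnan(flagged.statistic) and flagged.note == "zero variance"


def test_pearson_r_sampling_check(rng):
    cov = np.array([[1.0, 0.4], [0.4, 1.0]])
    xy = rng.multivariate_normal([0, 0], cov, size=10_000)
    res = st.pearson_r(xy[:, 0], xy[:, 1])
    assert res.statistic == pytest.approx(0.40, abs=0.02)


def test_fisher_z_properties_and_value():
    assert st.fisher_z_independent(0.5, 40, 0.5, 60).statistic == 0.0
    a = st.fisher_z_independent(0.29, 63, 0.63, 78)
    b = st.fisher_z_independent(0.63, 78, 0.29, 63)
    assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
    assert a.statistic == pytest.approx(-2.5568, abs=1e-3)
    with pytest.raises(ValueError):
        st.fisher_z_independent(1.0, 40, 0.2, 40)


@pytest.mark.parametrize("method", ["pearson_filon_1898", "fisher_1925"])
def test_dependent_z_zero_under_symmetric_equality(method):
    res = st.dependent_nonoverlapping_z(
        0.4, 0.4, r13=0.3, r14=0.2, r23=0.2, r24=0.3, n=100, method=method
    )
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_dependent_z_reduces_to_independent_comparison_when_uncorrelated():
    r1, r2, n = 0.35, 0.15, 5000
    dep = st.dependent_nonoverlapping_z(r1, r2, 0.0, 0.0, 0.0, 0.0, n, method="fisher_1925")
    ind = st.fisher_z_independent(r1, n, r2, n)
    assert dep.statistic == pytest.approx(ind.statistic, rel=1e-3)
    pf = st.dependent_nonoverlapping_z(r1, r2, 0.0, 0.0, 0.0, 0.0, n, method="pearson_filon_1898")
    assert pf.statistic == pytest.approx(ind.statistic, rel=0.05)


def test_dependent_z_rejects_inconsistent_matrix():
    # r12 = r13 = 0.9 with r23 = -0.9 cannot come from a real correlation matrix
    with pytest.raises(ValueError):
        st.dependent_nonoverlapping_z(0.9, 0.0, r13=0.9, r14=0.0, r23=-0.9, r24=0.0, n=50)


def test_dependent_z_type_one_error_rate(rng):
    """Under a null with equal correlations, the test rejects at ~alpha."""
    R = np.array(
        [[1.0, 0.4, 0.2, 0.25], [0.4, 1.0, 0.3, 0.2], [0.2, 0.3, 1.0, 0.4], [0.25, 0.2, 0.4, 1.0]]
    )
    L = np.linalg.cholesky(R)
    n, reps = 200, 2000
    rejections = 0
    X = rng.standard_normal((reps, n, 4)) @ L.T
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    def corr(i, j):
        return (Xc[:, :, i] * Xc[:, :, j]).mean(axis=1) / (sd[:, i] * sd[:, j])
    r12, r34 = corr(0, 1), corr(2, 3)
    r13, r14, r23, r24 = corr(0, 2), corr(0, 3), corr(1, 2), corr(1, 3)
    for k in range(reps):
        res = st.dependent_nonoverlapping_z(
            r12[k], r34[k], r13[k], r14[k], r23[k], r24[k], n, method="pearson_filon_1898"
        )
        rejections += res.p_value < 0.05
    assert 0.035 <= rejections / reps <= 0.065


# ---------------------------------------------------------------------------
# mixed models


def _lmm_data(rng, n=100, effect=0.7):
    rows = []
    for i in range(n):
        intercept = rng.normal(0, 1.0)
        meta = rng.normal(-5, 10)
        for framing, x in (("gain", 0.0), ("loss", 1.0)):
            y = 1.0 + intercept - effect * x + 0.02 * meta + rng.normal(0, 1.0)
            rows.append({"participant_id": f"s{i}", "framing": framing, "bias": y,
                         "metabias": meta})
    return pd.DataFrame(rows)


def test_lmm_lrt_aic_identity_and_effect_detection(rng):
    data = _lmm_data(rng)
    m0 = st.lmm_random_intercept(data, "bias", (), "participant_id")
    m1 = st.lmm_random_intercept(data, "bias", ("C(framing)",), "participant_id")
    cmp = st.compare_models(m0, m1)
    # chi-square and AIC difference are the same information
    assert cmp.chi_square == pytest.approx((m0.aic - m1.aic) + 2 * cmp.df, abs=1e-9)
    assert cmp.df == 1 and cmp.p_value < 0.05
    same = st.compare_models(m0, m0)
    assert same.chi_square == 0.0 and same.p_value == 1.0
    with pytest.raises(ValueError):
        st.compare_models(m1, m0)


def test_lmm_printed_aic_arithmetic():
    # likelihood-ratio statistics implied by AIC bookkeeping with one added term
    assert (2630.50 - 2623.20) + 2.0 == pytest.approx(9.30, abs=1e-9)
    assert (2623.20 - 2601.70) + 2.0 == pytest.approx(23.50, abs=1e-9)


# ---------------------------------------------------------------------------
# power


def test_required_n_for_the_within_design():
    assert st.required_n_paired_t(0.41, 0.05, 0.80, st.TWO_SIDED) == 49


@pytest.mark.parametrize("d_z", [0.3, 0.41, 0.5])
def test_required_n_is_the_smallest_sufficient_n(d_z):
    n = st.required_n_paired_t(d_z)
    assert st.paired_t_power(d_z, n) >= 0.80
    assert st.paired_t_power(d_z, n - 1) < 0.80
    approx = ((sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) / d_z) ** 2
    assert abs(n - approx) <= 3


def test_required_n_input_validation():
    with pytest.raises(ValueError):
        st.required_n_paired_t(-0.1)
    with pytest.raises(ValueError):
        st.required_n_paired_t(0.4, alpha=0.9, power=0.5)
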