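"""Inferential battery: t-tests, 2×2 ANOVAs, correlation comparisons,
random-intercept model selection, and paired-t power.

Everything except the mixed-effects fit is implemented at the formula level
so each statistic's definition is explicit and auditable: t statistics with
``d = mean/SD`` (equivalently ``t/√n``) effect sizes, sums-of-squares 2×2
ANOVAs with partial η², Fisher's z for independent correlations, and the
classical Pearson–Filon / Fisher-transformed statistics for dependent,
non-overlapping correlations.  Mixed models go through statsmodels'
``MixedLM`` with full maximum likelihood so that AIC differences and
likelihood-ratio tests are mutually consistent (``χ² = ΔAIC + 2·Δk`` holds
by construction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

TWO_SIDED = "two-sided"
GREATER = "greater"
LESS = "less"
_TAILS = (TWO_SIDED, GREATER, LESS)


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    effect_size: float | None = None
    effect_size_label: str | None = None
    n: int | tuple[int, int] | None = None
    tail: str = TWO_SIDED
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_label": self.effect_size_label,
            "n": list(self.n) if isinstance(self.n, tuple) else self.n,
            "tail": self.tail,
            "note": self.note,
        }


def _tail_p_from_t(t: float, df: float, tail: str) -> float:
    if tail == TWO_SIDED:
        return float(2.0 * sps.t.sf(abs(t), df))
    if tail == GREATER:
        return float(sps.t.sf(t, df))
    if tail == LESS:
        return float(sps.t.cdf(t, df))
    raise ValueError(f"bad tail {tail!r}")


def cohen_d_from_t(t: float, n: int) -> float:
    """d (one-sample) or d_z (paired) recovered from a t statistic: t/√n."""
    if n < 2:
        raise ValueError("need n >= 2")
    return t / math.sqrt(n)


def one_sample_t(x, mu0: float = 0.0, tail: str = TWO_SIDED, name: str = "one_sample_t") -> StatResult:
    """One-sample t-test with effect size d = (mean − mu0) / SD."""
    if tail not in _TAILS:
        raise ValueError(f"bad tail {tail!r}")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    if sd == 0.0:
        return StatResult(
            name, float("nan"), n - 1, float("nan"), float("nan"), "d", n, tail,
            note="zero variance",
        )
    t = (mean - mu0) / (sd / math.sqrt(n))
    return StatResult(name, t, n - 1, _tail_p_from_t(t, n - 1, tail), (mean - mu0) / sd, "d", n, tail)


def paired_t(x, y, tail: str = TWO_SIDED) -> StatResult:
    """Paired t-test on x − y with effect size d_z = mean diff / SD of diffs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(x - y, 0.0, tail, name="paired_t")
    return StatResult(
        res.test_name, res.statistic, res.df, res.p_value, res.effect_size, "d_z",
        res.n, res.tail, res.note,
    )


# ---------------------------------------------------------------------------
# 2x2 ANOVA


@dataclass(frozen=True)
class AnovaTable:
    design: str
    rows: tuple[dict, ...]

    def row(self, effect: str) -> dict:
        for r in self.rows:
            if r["effect"] == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))


def _anova_row(effect, ss, df1, ss_err, df2) -> dict:
    ms, ms_err = ss / df1, ss_err / df2
    f = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else float("inf"))
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    denom = ss + ss_err
    return {
        "effect": effect,
        "ss": float(ss),
        "df1": float(df1),
        "ss_error": float(ss_err),
        "df2": float(df2),
        "F": float(f),
        "p": p,
        "partial_eta_sq": float(ss / denom) if denom > 0 else 0.0,
    }


def _pivot_within(data, subject, factor, value) -> pd.DataFrame:
    wide = data.pivot(index=subject, columns=factor, values=value)
    if wide.shape[1] != 2:
        raise ValueError(f"factor {factor!r} must have exactly two levels")
    if wide.isna().any().any():
        raise ValueError("unbalanced data: every subject needs both factor levels")
    return wide.sort_index().reindex(sorted(wide.columns), axis=1)


def anova_2x2(
    data: pd.DataFrame,
    design: str,
    subject: str = "subject",
    within: str | tuple[str, str] = "within",
    between: str | None = "between",
    value: str = "value",
) -> AnovaTable:
    """Sums-of-squares 2×2 ANOVA with partial η² per effect.

    ``design="mixed"`` takes one two-level within factor and one two-level
    between factor (each subject contributing both within levels).
    ``design="within"`` takes two within factors (``within`` is then a pair
    of column names; every subject contributes all four cells).  Incomplete
    subjects are rejected.  In the mixed design the between-factor F equals
    the squared pooled two-sample t on subject means and the interaction F
    equals the squared t on within-subject difference scores.
    """
    if design == "mixed":
        if between is None:
            raise ValueError("mixed design needs a between factor")
        wide = _pivot_within(data, subject, within, value)
        groups = data.groupby(subject, sort=True)[between].agg(lambda s: s.unique())
        if any(len(g) != 1 for g in groups):
            raise ValueError("between-factor level must be constant within subject")
        group = groups.map(lambda g: g[0]).loc[wide.index]
        levels = sorted(group.unique())
        if len(levels) != 2:
            raise ValueError("between factor must have exactly two levels")

        m = wide.mean(axis=1).to_numpy()
        d = (wide.iloc[:, 1] - wide.iloc[:, 0]).to_numpy()
        g = (group == levels[1]).to_numpy()
        n1, n2 = int((~g).sum()), int(g.sum())
        if n1 == 0 or n2 == 0:
            raise ValueError("both between groups must be non-empty")
        n_tot = n1 + n2

        grand_m = m.mean()
        group_m = np.array([m[~g].mean(), m[g].mean()])
        ss_between = 2.0 * (n1 * (group_m[0] - grand_m) ** 2 + n2 * (group_m[1] - grand_m) ** 2)
        ss_subj = 2.0 * ((m[~g] - group_m[0]) ** 2).sum() + 2.0 * ((m[g] - group_m[1]) ** 2).sum()

        d_bar = d.mean()
        group_d = np.array([d[~g].mean(), d[g].mean()])
        ss_within = n_tot * d_bar**2 / 2.0
        ss_inter = (n1 * (group_d[0] - d_bar) ** 2 + n2 * (group_d[1] - d_bar) ** 2) / 2.0
        ss_err = (((d[~g] - group_d[0]) ** 2).sum() + ((d[g] - group_d[1]) ** 2).sum()) / 2.0

        rows = (
            _anova_row(between, ss_between, 1, ss_subj, n_tot - 2),
            _anova_row(within, ss_within, 1, ss_err, n_tot - 2),
            _anova_row(f"{within}:{between}", ss_inter, 1, ss_err, n_tot - 2),
        )
        return AnovaTable("mixed", rows)

    if design == "within":
        if not isinstance(within, (tuple, list)) or len(within) != 2:
            raise ValueError("within design needs a pair of within-factor names")
        fa, fb = within
        cells = data.pivot_table(
            index=subject, columns=[fa, fb], values=value, aggfunc="first", sort=True
        )
        if cells.shape[1] != 4 or cells.isna().any().any():
            raise ValueError("unbalanced data: every subject needs all four cells")
        cells = cells.sort_index().reindex(sorted(cells.columns), axis=1)
        x = cells.to_numpy().reshape(len(cells), 2, 2)  # subject x A x B
        n = x.shape[0]
        if n < 2:
            raise ValueError("need at least two subjects")

        grand = x.mean()
        subj = x.mean(axis=(1, 2))
        a_marg = x.mean(axis=(0, 2))
        b_marg = x.mean(axis=(0, 1))
        cell = x.mean(axis=0)
        m_ia = x.mean(axis=2)
        m_ib = x.mean(axis=1)

        ss_a = 2.0 * n * ((a_marg - grand) ** 2).sum()
        ss_as = 2.0 * ((m_ia - subj[:, None] - a_marg[None, :] + grand) ** 2).sum()
        ss_b = 2.0 * n * ((b_marg - grand) ** 2).sum()
        ss_bs = 2.0 * ((m_ib - subj[:, None] - b_marg[None, :] + grand) ** 2).sum()
        ss_ab = n * ((cell - a_marg[:, None] - b_marg[None, :] + grand) ** 2).sum()
        resid = (
            x
            - m_ia[:, :, None]
            - m_ib[:, None, :]
            + subj[:, None, None]
            - cell[None, :, :]
            + a_marg[None, :, None]
            + b_marg[None, None, :]
            - grand
        )
        ss_abs = (resid**2).sum()

        rows = (
            _anova_row(fa, ss_a, 1, ss_as, n - 1),
            _anova_row(fb, ss_b, 1, ss_bs, n - 1),
            _anova_row(f"{fa}:{fb}", ss_ab, 1, ss_abs, n - 1),
        )
        return AnovaTable("within", rows)

    raise ValueError(f"design must be 'mixed' or 'within', got {design!r}")


# ---------------------------------------------------------------------------
# correlations


def pearson_r(x, y, tail: str = TWO_SIDED) -> StatResult:
    """Pearson product–moment correlation with a t-based p-value."""
    if tail not in _TAILS:
        raise ValueError(f"bad tail {tail!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            "pearson_r", float("nan"), n - 2, float("nan"), float("nan"), "r", n, tail,
            note="zero variance",
        )
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = _tail_p_from_t(t, n - 2, tail)
    return StatResult("pearson_r", r, n - 2, p, r, "r", n, tail)


def fisher_z_independent(r1: float, n1: int, r2: float, n2: int, tail: str = TWO_SIDED) -> StatResult:
    """Fisher's z-test comparing correlations from two independent samples."""
    if tail not in _TAILS:
        raise ValueError(f"bad tail {tail!r}")
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need more than three observations per sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if tail == TWO_SIDED:
        p = 2.0 * sps.norm.sf(abs(z))
    elif tail == GREATER:
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return StatResult("fisher_z_independent", float(z), None, float(p), None, None, (n1, n2), tail)


def _nonoverlap_cov(r12, r34, r13, r14, r23, r24) -> float:
    """Asymptotic n·cov(r12, r34) for two non-overlapping correlations.

    Classical large-sample covariance (Pearson–Filon / Olkin–Siotani form)
    of two sample correlations sharing no variable, as a function of the six
    population correlations among the four variables.
    """
    return (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r34 * r13 * r23 + r34 * r14 * r24)
    )


def dependent_nonoverlapping_z(
    r12: float,
    r34: float,
    r13: float,
    r14: float,
    r23: float,
    r24: float,
    n: int,
    method: str = "pearson_filon_1898",
    tail: str = TWO_SIDED,
) -> StatResult:
    """Compare r12 against r34 measured on the same sample of four variables.

    ``pearson_filon_1898`` works on the raw correlations with their
    asymptotic variances; ``fisher_1925`` applies the comparison after the
    variance-stabilizing Fisher transform, with the covariance carried
    through as the correlation between the two transformed estimates.
    """
    if n <= 4:
        raise ValueError("need n > 4")
    corr = np.array(
        [
            [1.0, r12, r13, r14],
            [r12, 1.0, r23, r24],
            [r13, r23, 1.0, r34],
            [r14, r24, r34, 1.0],
        ]
    )
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("inconsistent correlation matrix (not positive semi-definite)")
    cov = _nonoverlap_cov(r12, r34, r13, r14, r23, r24)

    if method == "pearson_filon_1898":
        var = (1.0 - r12**2) ** 2 + (1.0 - r34**2) ** 2 - 2.0 * cov
        if var <= 0:
            raise ValueError("degenerate correlation structure")
        z = (r12 - r34) * math.sqrt(n) / math.sqrt(var)
    elif method == "fisher_1925":
        denom = (1.0 - r12**2) * (1.0 - r34**2)
        c = cov / denom if denom > 0 else 0.0
        c = max(-0.999999, min(0.999999, c))
        z = (math.atanh(r12) - math.atanh(r34)) * math.sqrt((n - 3) / (2.0 - 2.0 * c))
    else:
        raise ValueError(f"unknown method {method!r}")

    if tail == TWO_SIDED:
        p = 2.0 * sps.norm.sf(abs(z))
    elif tail == GREATER:
        p = sps.norm.sf(z)
    elif tail == LESS:
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"bad tail {tail!r}")
    return StatResult(f"dependent_nonoverlapping_{method}", float(z), None, float(p), None, None, n, tail)


# ---------------------------------------------------------------------------
# mixed models


@dataclass(frozen=True)
class FittedLMM:
    formula: str
    k_fixed: int
    log_likelihood: float
    aic: float
    n_obs: int
    n_groups: int
    params: dict
    converged: bool


@dataclass(frozen=True)
class ModelComparison:
    k0: int
    k1: int
    aic0: float
    aic1: float
    chi_square: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "k0": self.k0,
            "k1": self.k1,
            "aic0": self.aic0,
            "aic1": self.aic1,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
        }


def lmm_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed_terms: tuple[str, ...] | list[str],
    group: str,
) -> FittedLMM:
    """Random-intercept linear mixed model, fitted by full maximum likelihood.

    ``fixed_terms`` are formula terms added to the intercept (empty tuple =
    intercept-only).  ML rather than REML so that log-likelihoods, AICs and
    likelihood-ratio tests are comparable across fixed-effect structures.
    AIC counts the fixed effects plus the two variance parameters.
    """
    import statsmodels.formula.api as smf

    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    result = None
    last_error: Exception | None = None
    # the random-intercept variance can sit on the boundary, where some
    # optimizers produce a singular Hessian; fall through to sturdier ones
    for method in ("lbfgs", "bfgs", "powell"):
        model = smf.mixedlm(formula, data, groups=data[group])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=False, method=method, maxiter=500)
            break
        except np.linalg.LinAlgError as err:  # pragma: no cover - data dependent
            last_error = err
    if result is None:  # pragma: no cover
        raise RuntimeError(f"mixed-model fit failed: {last_error}")
    k_fixed = len(result.fe_params)
    llf = float(result.llf)
    k_total = k_fixed + 2  # random-intercept variance + residual variance
    return FittedLMM(
        formula=formula,
        k_fixed=k_fixed,
        log_likelihood=llf,
        aic=-2.0 * llf + 2.0 * k_total,
        n_obs=int(result.nobs),
        n_groups=int(model.n_groups),
        params={name: float(v) for name, v in result.fe_params.items()},
        converged=bool(result.converged),
    )


def compare_models(m0: FittedLMM, m1: FittedLMM) -> ModelComparison:
    """Likelihood-ratio test of nested ML fits; χ² floored at zero.

    By construction ``χ² = ΔAIC + 2·Δk`` where ΔAIC = AIC(m0) − AIC(m1).
    """
    if m1.k_fixed < m0.k_fixed:
        raise ValueError("m1 must be the larger (or equal) model")
    if m0.n_obs != m1.n_obs:
        raise ValueError("models must be fitted to the same data")
    df = m1.k_fixed - m0.k_fixed
    chi = max(0.0, 2.0 * (m1.log_likelihood - m0.log_likelihood))
    p = float(sps.chi2.sf(chi, df)) if df > 0 else 1.0
    return ModelComparison(m0.k_fixed, m1.k_fixed, m0.aic, m1.aic, chi, df, p)


# ---------------------------------------------------------------------------
# power


def paired_t_power(d_z: float, n: int, alpha: float = 0.05, tail: str = TWO_SIDED) -> float:
    """Power of a paired t-test at effect size d_z via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d_z * math.sqrt(n)
    if tail == TWO_SIDED:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    if tail == GREATER:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(tcrit, df, nc))
    raise ValueError(f"bad tail {tail!r}")


def required_n_paired_t(
    d_z: float, alpha: float = 0.05, power: float = 0.80, tail: str = TWO_SIDED
) -> int:
    """Smallest n whose paired t-test reaches the target power."""
    if d_z <= 0:
        raise ValueError("d_z must be positive")
    if not 0 < alpha < 1 or not alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    hi = 2
    while paired_t_power(d_z, hi, alpha, tail) < power:
        hi *= 2
        if hi > 10_000_000:
            raise RuntimeError("required sample size out of range")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(d_z, mid, alpha, tail) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
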