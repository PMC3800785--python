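"""Group summaries, correlation matrices, and ANOVA-style linear models.

The comparison machinery used to separate the two species: per-group
descriptive statistics with t-based 95% confidence intervals, Pearson
correlation matrices for the morphometric variables, least-squares fits with
categorical predictors under treatment (reference-level) coding, coefficient
t-tests, and nested-model F-tests.  Model fitting is delegated to statsmodels
OLS; the nested F statistic is computed from residual sums of squares
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: The six acoustic variables compared between species, in report order.
ACOUSTIC_VARIABLES = [
    "peak_frequency_hz",
    "burst_rate_hz",
    "mean_pulses_per_burst",
    "phrase1_s",
    "phrase2_s",
    "phrase3_s",
]


class StatsError(Exception):
    """Invalid input to a statistical routine."""


@dataclass
class GroupSummary:
    """mean, 95% CI, range, SD, and n for one group of values."""

    mean: float
    ci_low: float | None
    ci_high: float | None
    min: float
    max: float
    sd: float
    n: int

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "min": self.min,
            "max": self.max,
            "sd": self.sd,
            "n": self.n,
        }


def summarize(values) -> GroupSummary:
    """Descriptive summary with a t-based 95% confidence interval.

    SD uses the n-1 denominator; the CI is mean ± t(0.975, n-1)·sd/√n.  A
    single value yields a summary with the CI flagged absent (``None``).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) == 0:
        raise StatsError("summarize needs a non-empty 1-D collection of values")
    n = len(v)
    mean = float(v.mean())
    if n == 1:
        return GroupSummary(mean, None, None, mean, mean, 0.0, 1)
    sd = float(v.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupSummary(
        mean, float(mean - half), float(mean + half), float(v.min()), float(v.max()), sd, n
    )


def corr_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric columns.

    Requires at least 3 complete records.  Zero-variance columns produce NaN
    entries (flagged undefined) rather than an error.
    """
    df = table[columns] if columns is not None else table.select_dtypes("number")
    if df.shape[1] < 2:
        raise StatsError("corr_matrix needs at least 2 numeric columns")
    complete = df.dropna()
    if len(complete) < 3:
        raise StatsError("corr_matrix needs at least 3 complete records")
    return complete.corr(method="pearson")


@dataclass
class ModelFit:
    """A least-squares fit with categorical predictors (treatment coding)."""

    response: str
    factors: list[str]
    interaction: bool
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rss: float
    df_resid: int
    r_squared: float
    n: int
    standardized_residuals: np.ndarray = field(repr=False)
    sm_result: object = field(repr=False, default=None)

    def coefficient(self, name_fragment: str) -> tuple[float, float, float, float]:
        """(estimate, se, t, p) of the first coefficient whose name contains the fragment."""
        for name in self.params.index:
            if name_fragment in name:
                return (
                    float(self.params[name]),
                    float(self.bse[name]),
                    float(self.tvalues[name]),
                    float(self.pvalues[name]),
                )
        raise KeyError(f"no coefficient matching {name_fragment!r} in {list(self.params.index)}")

    def conf_int(self, name_fragment: str, alpha: float = 0.05) -> tuple[float, float]:
        est, se, _, _ = self.coefficient(name_fragment)
        half = sps.t.ppf(1 - alpha / 2, self.df_resid) * se
        return est - half, est + half


def fit_lm(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    interaction: bool = False,
) -> ModelFit:
    """OLS fit of ``response`` on categorical ``factors``.

    Treatment coding with the alphabetically first level as reference, so a
    two-level species factor's coefficient is the between-species difference.
    ``interaction=True`` adds the full interaction of the listed factors.
    """
    if response not in table.columns:
        raise StatsError(f"response column {response!r} not in table")
    for f in factors:
        if f not in table.columns:
            raise StatsError(f"factor column {f!r} not in table")
        if table[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has fewer than 2 observed levels")
    terms = [f"C({f})" for f in factors]
    if interaction:
        terms.append(":".join(f"C({f})" for f in factors))
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise StatsError(
            f"rank-deficient design for {formula!r}: a term is collinear "
            "(likely the interaction with an empty factor-level cell)"
        )
    if model.nobs <= model.exog.shape[1]:
        raise StatsError("n must exceed the number of estimated coefficients")
    res = model.fit()
    # a zero-variance response (all values equal) is fit perfectly; avoid the
    # 0/0 in the centered-TSS R-squared
    if res.centered_tss > 0:
        r_squared = float(res.rsquared)
    else:
        r_squared = 1.0
    influence = res.get_influence()
    return ModelFit(
        response=response,
        factors=list(factors),
        interaction=interaction,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        r_squared=r_squared,
        n=int(res.nobs),
        standardized_residuals=influence.resid_studentized_internal,
        sm_result=res,
    )


@dataclass
class FTestResult:
    """Nested-model F-test: F, numerator/denominator df, p-value."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


def f_test_nested(reduced: ModelFit, full: ModelFit) -> FTestResult:
    """F-test comparing a reduced model to a full model it is nested in.

    F = ((RSS_r - RSS_f)/(df_r - df_f)) / (RSS_f/df_f), with the p-value from
    the F(df_r - df_f, df_f) distribution.  Identical models give F = 0,
    p = 1.
    """
    if reduced.response != full.response or reduced.n != full.n:
        raise StatsError("models must share the same response and records")
    if not set(reduced.params.index) <= set(full.params.index):
        missing = set(reduced.params.index) - set(full.params.index)
        raise StatsError(f"models are not nested: reduced has terms {sorted(missing)}")
    df_num = reduced.df_resid - full.df_resid
    if df_num < 0:
        raise StatsError("the reduced model has more parameters than the full model")
    if df_num == 0:
        return FTestResult(0.0, 0, full.df_resid, 1.0)
    if full.df_resid <= 0:
        raise StatsError("the full model has no residual degrees of freedom")
    f = ((reduced.rss - full.rss) / df_num) / (full.rss / full.df_resid)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df_num, full.df_resid))
    return FTestResult(float(f), int(df_num), int(full.df_resid), p)


@dataclass
class SpeciesComparison:
    """Per-variable group summaries plus the species-coefficient t-test."""

    variable: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    coefficient: float | None
    t_statistic: float | None
    p_value: float | None
    ranges_overlap: bool | None = None


def compare_species_features(
    features_a: pd.DataFrame | list,
    features_b: pd.DataFrame | list,
    label_a: str = "a",
    label_b: str = "b",
    variables: list[str] | None = None,
) -> list[SpeciesComparison]:
    """Compare the six acoustic variables between two groups of calls.

    Accepts two DataFrames (or lists of :class:`~cicadasong.features.CallFeatures`)
    and returns, per variable, both group summaries and the species-coefficient
    t-test from an OLS fit with species as the sole predictor.  Groups of size
    1 get summaries only, with the test flagged absent.  The six tests form
    one family; no multiple-testing correction is applied.
    """

    def to_frame(feats) -> pd.DataFrame:
        if isinstance(feats, pd.DataFrame):
            return feats
        return pd.DataFrame([f.to_dict() for f in feats])

    a, b = to_frame(features_a), to_frame(features_b)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both groups must be non-empty")
    variables = variables or [v for v in ACOUSTIC_VARIABLES if v in a.columns and v in b.columns]
    results = []
    for var in variables:
        va, vb = a[var].dropna(), b[var].dropna()
        sa, sb = summarize(va), summarize(vb)
        coef = t = p = None
        if len(va) >= 2 and len(vb) >= 2:
            # internal group labels stay distinct even if the display labels
            # coincide (e.g. comparing one species against itself)
            stacked = pd.DataFrame(
                {"value": pd.concat([va, vb], ignore_index=True),
                 "species": ["grp_a"] * len(va) + ["grp_b"] * len(vb)}
            )
            fit = fit_lm(stacked, "value", ["species"])
            coef_name = [c for c in fit.params.index if "species" in c][0]
            coef = float(fit.params[coef_name])
            t = float(fit.tvalues[coef_name])
            p = float(fit.pvalues[coef_name])
        overlap = not (sa.max < sb.min or sb.max < sa.min)
        results.append(
            SpeciesComparison(var, sa, sb, coef, t, p, ranges_overlap=overlap)
        )
    return results


def comparison_report(results: list[SpeciesComparison], label_a: str, label_b: str) -> str:
    """Plain-text table of a species comparison."""
    lines = [
        f"Species comparison: {label_a} (A) vs {label_b} (B)",
        "(six acoustic variables tested as one family; no multiplicity correction)",
        "",
    ]
    for r in results:
        lines.append(f"{r.variable}:")
        for tag, s in (("A", r.summary_a), ("B", r.summary_b)):
            ci = f"[{s.ci_low:.3f}, {s.ci_high:.3f}]" if s.has_ci else "[n/a]"
            lines.append(
                f"  {tag}: mean={s.mean:.3f} CI95={ci} range=({s.min:.3f}, {s.max:.3f}) "
                f"sd={s.sd:.3f} n={s.n}"
            )
        if r.t_statistic is not None:
            lines.append(
                f"  species effect: {r.coefficient:+.3f}  t={r.t_statistic:.2f}  "
                f"p={r.p_value:.3g}  ranges overlap: {'yes' if r.ranges_overlap else 'no'}"
            )
        else:
            lines.append("  species effect: test absent (a group has n < 2)")
        lines.append("")
    return "\n".join(lines)
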