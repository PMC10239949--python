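"""Statistical plan for the cohort analyses.

Implements the study-style plan: Shapiro-Wilk-gated test selection
(parametric mean +/- SEM vs rank-based median (IQR)), per-timepoint
Mann-Whitney comparisons with Bonferroni adjustment, a random-intercept
mixed model for the longitudinal group comparison of the estimated
proportion of air, lamb-adjusted linear regression of the alveolar-arterial
gradient on aeration, paired before/after comparisons, baseline-referenced
five-breath-block families with a Dunnett-style adjustment, and the exact
paired-t minimal detectable difference used for power statements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestResult",
    "RegressionResult",
    "normality_gate",
    "timepoint_group_tests",
    "repeated_measures_group_model",
    "lamb_adjusted_regression",
    "paired_compare",
    "blocks_vs_baseline",
    "paired_mdd",
    "paired_t_power",
    "bonferroni",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with its summary statistics."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    estimate: float | None = None  # mean or median of (differences)
    spread: float | None = None  # SEM for parametric summaries
    iqr: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError("p_value must lie in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be smaller than the raw p")


@dataclass(frozen=True)
class RegressionResult:
    """Lamb-adjusted regression summary."""

    r2: float
    p_value: float
    slope: float
    slope_se: float
    lamb_intercepts: dict = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2 <= 1.0 + 1e-9:
            raise ValueError("r2 must lie in [0, 1]")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return float(min(1.0, m * p))


def normality_gate(sample: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> tuple[str, dict]:
    """Choose parametric vs rank testing from a Shapiro-Wilk test.

    Returns ("parametric", summary) when normality is not rejected at
    ``alpha`` (summary = mean +/- SEM) or ("rank", summary) otherwise
    (summary = median with IQR).  Degenerate samples (n < 3 or constant)
    force the rank branch.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        choice = "rank"
        p_norm = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_norm = float(stats.shapiro(x).pvalue)
        choice = "parametric" if p_norm >= alpha else "rank"
    if choice == "parametric":
        summary = {
            "style": "mean_sem",
            "mean": float(x.mean()),
            "sem": float(x.std(ddof=1) / np.sqrt(x.size)),
            "shapiro_p": p_norm,
        }
    else:
        q1, med, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75])) if x.size else (np.nan,) * 3
        summary = {"style": "median_iqr", "median": med, "iqr": (q1, q3), "shapiro_p": p_norm}
    return choice, summary


def timepoint_group_tests(
    table: pd.DataFrame,
    value: str = "grade",
    group: str = "group",
    time: str = "time_min",
) -> pd.DataFrame:
    """Mann-Whitney group comparison at each timepoint, Bonferroni-adjusted.

    ``table`` is long-format with one row per observation.  Timepoints where
    either group is empty are skipped; the Bonferroni factor is the number of
    timepoints actually tested.
    """
    levels = sorted(table[group].unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    rows = []
    for t, sub in table.groupby(time):
        a = sub.loc[sub[group] == levels[0], value].dropna().to_numpy()
        b = sub.loc[sub[group] == levels[1], value].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = float(a.size * b.size / 2), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"time_min": t, "U": u, "p_value": p, "n1": a.size, "n2": b.size})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def _fit_mixed(formula: str, df: pd.DataFrame):
    """REML random-intercept fit with an optimizer fallback.

    The default BFGS fit occasionally lands on a degenerate boundary
    (zero random-effect variance with undefined standard errors); retry
    with Powell before giving up.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["lamb"])
        try:
            fit = model.fit(reml=True)
            retry = not np.all(np.isfinite(fit.bse[fit.model.exog_names]))
        except np.linalg.LinAlgError:
            retry = True
            fit = None
        if retry:
            try:
                fit = model.fit(reml=True, method="powell")
            except np.linalg.LinAlgError as err:
                raise ValueError(f"singular mixed-model fit: {err}") from None
    if fit is None or not np.all(np.isfinite(fit.params)):
        raise ValueError("singular mixed-model fit; check the design")
    return fit


def _mixed_model_pvals(fit, n_groups: int) -> dict[str, float]:
    """Effect p-values from a fitted random-intercept model.

    The group (between-lamb) effect uses a between-within t reference with
    denominator df = n_lambs - 2, which matches the classical split-plot
    analysis for balanced designs and keeps the small-sample size honest;
    the time effect uses a Wald chi-square over its indicator contrasts.
    """
    params = fit.params
    names = list(fit.model.exog_names)
    out: dict[str, float] = {}
    grp = [n for n in names if n.startswith("group") or n.startswith("C(group)")]
    if grp:
        tval = params[grp[0]] / fit.bse[grp[0]]
        df = max(1, n_groups - 2)
        out["group"] = float(2 * stats.t.sf(abs(tval), df))
        out["group_estimate"] = float(params[grp[0]])
    tnames = [n for n in names if n.startswith("C(time")]
    if tnames:
        idx = [names.index(n) for n in tnames]
        beta = params.iloc[idx].to_numpy()
        cov = np.asarray(fit.cov_params())[np.ix_(idx, idx)]
        chi2 = float(beta @ np.linalg.solve(cov, beta))
        out["time"] = float(stats.chi2.sf(chi2, len(idx)))
    return out


def repeated_measures_group_model(
    table: pd.DataFrame,
    value: str = "epa",
    group: str = "group",
    time: str = "time_min",
    lamb: str = "lamb_id",
) -> dict[str, float]:
    """Longitudinal group comparison via a random-intercept mixed model.

    Fits ``value ~ C(time) + group`` with a random intercept per lamb by
    REML and reports main-effect p-values for time and group.  Tolerates
    missing cells (unlike a classical repeated-measures ANOVA).  Raises on a
    singular fit.
    """
    df = table[[value, group, time, lamb]].dropna().copy()
    if df[lamb].nunique() < 4 or df[time].nunique() < 2:
        raise ValueError("need >= 2 lambs per group and >= 2 timepoints")
    df = df.rename(columns={value: "y", group: "group", time: "time", lamb: "lamb"})
    fit = _fit_mixed("y ~ C(time) + group", df)
    pvals = _mixed_model_pvals(fit, df["lamb"].nunique())
    pvals["n_lambs"] = float(df["lamb"].nunique())
    pvals["n_obs"] = float(len(df))
    pvals["random_intercept_var"] = float(fit.cov_re.iloc[0, 0])
    return pvals


def lamb_adjusted_regression(
    table: pd.DataFrame,
    outcome: str = "aado2",
    predictor: str = "epa",
    lamb: str = "lamb_id",
    per_lamb_slopes: bool = False,
) -> RegressionResult:
    """Linear regression of an outcome on aeration, adjusted per lamb.

    Fits ``outcome ~ predictor + C(lamb)`` (fixed lamb intercepts, common
    slope) and reports the overall R-squared and the predictor's p-value.
    With ``per_lamb_slopes=True`` the slope is allowed to vary by lamb and
    the p-value refers to the average slope.
    """
    df = table[[outcome, predictor, lamb]].dropna().copy()
    if df[lamb].nunique() < 2:
        raise ValueError("need >= 2 lambs")
    if df.groupby(lamb).size().min() < 3:
        raise ValueError("need >= 3 observations per lamb")
    df = df.rename(columns={outcome: "y", predictor: "x", lamb: "lamb"})
    formula = "y ~ x * C(lamb)" if per_lamb_slopes else "y ~ x + C(lamb)"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design (constant predictor within lambs?)")
    slope = float(fit.params["x"])
    return RegressionResult(
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues["x"]),
        slope=slope,
        slope_se=float(fit.bse["x"]),
        lamb_intercepts={
            k: float(v) for k, v in fit.params.items() if k.startswith("C(lamb)")
        },
        n=len(df),
    )


def paired_compare(before: np.ndarray, after: np.ndarray) -> TestResult:
    """Before/after comparison with normality-gated test selection.

    Shapiro-Wilk gates the paired differences: paired t-test (mean +/- SEM of
    differences) when normality is not rejected, Wilcoxon signed-rank
    (median (IQR) of differences) otherwise.  All-zero differences return
    p = 1 with a note.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    d = a - b
    if np.all(d == 0):
        return TestResult(
            test_name="paired_t",
            statistic=0.0,
            p_value=1.0,
            n=d.size,
            estimate=0.0,
            spread=0.0,
            note="all differences zero; no test performed",
        )
    choice, summary = normality_gate(d)
    if choice == "parametric":
        res = stats.ttest_rel(a, b)
        return TestResult(
            test_name="paired_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=d.size,
            estimate=summary["mean"],
            spread=summary["sem"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False)
    note = "" if np.ptp(d) > 0 else "degenerate constant differences"
    return TestResult(
        test_name="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=d.size,
        estimate=summary["median"],
        iqr=summary["iqr"],
        note=note,
    )


def _dunnett_adjust(z_stats: np.ndarray, n_mc: int = 200_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo Dunnett-style family-wise p-values.

    Evaluates the null distribution of max |t| over the family under the
    shared-baseline correlation structure (each contrast correlates 0.5 with
    every other through the common pre-event block) using standard-normal
    draws, then reports P(max |T| >= |t_k|) per contrast.
    """
    m = z_stats.size
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_mc)
    own = rng.standard_normal((n_mc, m))
    tmax = np.abs((shared[:, None] + own) / np.sqrt(2.0)).max(axis=1)
    return np.array([float(np.mean(tmax >= abs(z))) for z in z_stats])


def blocks_vs_baseline(
    table: pd.DataFrame,
    metric: str,
    lamb: str = "lamb_id",
    block: str = "block",
    baseline: str = "pre",
    adjust: str = "dunnett",
    seed: int = 0,
) -> pd.DataFrame:
    """Compare each post-event block to the pre-event baseline across lambs.

    Fits ``metric ~ C(block)`` with a random intercept per lamb (baseline as
    the reference level) and adjusts the per-block p-values for the family,
    either by a Monte-Carlo Dunnett max-|t| evaluation (default) or by
    Bonferroni.  With a single post block the family reduces to one paired
    contrast.  Raises if the baseline block is missing.
    """
    df = table[[metric, lamb, block]].dropna().copy()
    if baseline not in set(df[block]):
        raise ValueError(f"baseline block {baseline!r} missing")
    blocks = [b for b in df[block].unique() if b != baseline]
    if not blocks:
        raise ValueError("no post-event blocks to compare")
    df = df.rename(columns={metric: "y", lamb: "lamb", block: "blk"})
    fit = _fit_mixed(f"y ~ C(blk, Treatment('{baseline}'))", df)
    rows = []
    zs = []
    n_lambs = df["lamb"].nunique()
    t_df = max(1, n_lambs - 1)
    for b in blocks:
        name = f"C(blk, Treatment('{baseline}'))[T.{b}]"
        est = float(fit.params[name])
        se = float(fit.bse[name])
        tval = est / se
        p_raw = float(2 * stats.t.sf(abs(tval), t_df))
        zs.append(tval)
        rows.append({"block": b, "estimate": est, "se": se, "t": tval, "p_value": p_raw})
    out = pd.DataFrame(rows)
    if adjust == "dunnett":
        out["p_adjusted"] = np.maximum(out["p_value"], _dunnett_adjust(np.array(zs), seed=seed))
    elif adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    else:
        raise ValueError("adjust must be 'dunnett' or 'bonferroni'")
    return out


def paired_t_power(delta: float, n: int, sd: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided paired t-test.

    ``delta`` is the true mean paired difference, ``sd`` the SD of the
    differences, ``n`` the number of pairs; power is evaluated from the
    noncentral-t distribution.
    """
    if n < 2 or sd <= 0:
        raise ValueError("need n >= 2 pairs and sd > 0")
    df = n - 1
    ncp = delta / (sd / np.sqrt(n))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if np.isnan(power):  # far tail: noncentral-t underflow, power is ~1
        power = 1.0 if abs(ncp) > tcrit else 0.0
    return power


def paired_mdd(n: int, sd: float, power: float = 0.80, alpha: float = 0.05) -> float:
    """Minimal detectable difference of a two-sided paired t-test.

    The smallest true mean paired difference delta such that the test at
    level ``alpha`` with ``n`` pairs and difference-SD ``sd`` reaches the
    target ``power``, found by exact noncentral-t power inversion.  Scales
    linearly with ``sd``.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("power and alpha must lie in (0, 1)")
    if paired_t_power(0.0, n, sd, alpha) >= power:
        raise ValueError("infeasible: null power already exceeds the target")
    # the required noncentrality is near t_{1-a/2} + z_power; bracket widely
    hi_ncp = stats.t.ppf(1.0 - alpha / 2.0, n - 1) + stats.norm.ppf(power) + 4.0
    hi = hi_ncp * sd / np.sqrt(n)
    delta = optimize.brentq(
        lambda d: paired_t_power(d, n, sd, alpha) - power, 0.0, hi, xtol=1e-12
    )
    return float(delta)
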