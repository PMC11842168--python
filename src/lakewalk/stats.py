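"""Statistical layer over the simulation grids.

Provides the analyses used to interrogate the success surfaces: a binomial
GLM (logit link) on per-path success with likelihood-ratio model selection
and odds ratios, Pearson chi-squared between-group comparisons of success
counts, Kruskal-Wallis with Dunn's pairwise post hoc (Holm-Bonferroni
adjusted) for passage-time distributions, and per-cell exact binomial
comparison of simulated versus observed migration success.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .basins import TelemetryRecord
from .experiments import GridCell

__all__ = [
    "GlmFit",
    "TestResult",
    "fit_success_glm",
    "lrt",
    "chisq_success",
    "kruskal_dunn",
    "holm_adjust",
    "compare_to_telemetry",
]


@dataclass
class TestResult:
    """A single hypothesis-test outcome."""

    name: str
    statistic: float
    df: float | None
    p_value: float
    adjusted_p: float | None = None
    groups: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class GlmFit:
    """A fitted binomial GLM on per-path success.

    ``odds_ratios`` holds exp(coefficient) with a Wald confidence interval
    for every non-intercept term. The default CI level is 95%; a 97.5%
    option is provided as a faithful-replication switch for reports that
    quote intervals at that level.
    """

    formula: str
    params: pd.Series
    bse: pd.Series
    llf: float
    df_model: int
    n_obs: int
    odds_ratios: pd.DataFrame
    ci_level: float
    separation: bool = False
    result: object = field(default=None, repr=False)


def _odds_ratio_table(res, ci_level: float) -> pd.DataFrame:
    ci = res.conf_int(alpha=1.0 - ci_level)
    ci.columns = ["lo", "hi"]
    with np.errstate(over="ignore"):  # separation inflates coefficients
        tab = pd.DataFrame(
            {
                "odds_ratio": np.exp(res.params),
                "ci_lo": np.exp(ci["lo"]),
                "ci_hi": np.exp(ci["hi"]),
                "p_value": res.pvalues,
            }
        )
    return tab.drop(index=[i for i in tab.index if i.lower() == "intercept"])


def fit_success_glm(
    records: pd.DataFrame,
    formula: str = "success ~ basin + step_length + turn_sd",
    ci_level: float = 0.95,
) -> GlmFit:
    """Fit a logit-link binomial GLM to per-path success outcomes.

    ``records`` is a long-format table with one row per simulated path
    (columns referenced by the formula; ``success`` boolean/0-1). Complete
    separation is detected from exploding coefficients or standard errors
    and flagged; odds-ratio confidence intervals are suppressed in that
    case.
    """
    if ci_level not in (0.95, 0.975):
        if not (0.5 < ci_level < 1.0):
            raise ValueError("ci_level must be in (0.5, 1)")
    data = records.copy()
    data["success"] = data["success"].astype(int)
    if data["success"].nunique() > 2:
        raise ValueError("response must be binary per path")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=data, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    separation = bool(
        np.any(np.abs(res.params.values) > 15.0) or np.any(res.bse.values > 100.0)
    )
    tab = _odds_ratio_table(res, ci_level)
    if separation:
        tab[["ci_lo", "ci_hi"]] = np.nan
    return GlmFit(
        formula=formula,
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        df_model=int(res.df_model),
        n_obs=int(res.nobs),
        odds_ratios=tab,
        ci_level=ci_level,
        separation=separation,
        result=res,
    )


def lrt(nested: GlmFit, full: GlmFit) -> TestResult:
    """Likelihood-ratio test between nested binomial GLMs.

    statistic = 2 (LL_full - LL_nested); the p-value is the chi-squared
    upper tail with df equal to the parameter-count difference.
    """
    df = full.df_model - nested.df_model
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    if nested.n_obs != full.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    stat = 2.0 * (full.llf - nested.llf)
    if df == 0:
        return TestResult("LRT", stat, 0, 1.0)
    p = float(scipy.stats.chi2.sf(stat, df))
    return TestResult("LRT", float(stat), df, p)


def backward_select(
    records: pd.DataFrame,
    full_formula: str,
    terms: list[str],
    alpha: float = 0.05,
    ci_level: float = 0.95,
) -> tuple[GlmFit, list[TestResult]]:
    """Backward elimination by LRT: drop, one at a time, the term whose
    removal least (and non-significantly) worsens the fit; stop when every
    remaining term is significant at ``alpha``."""
    response = full_formula.split("~")[0].strip()
    current = list(terms)
    history: list[TestResult] = []
    fit = fit_success_glm(records, f"{response} ~ {' + '.join(current)}", ci_level)
    while len(current) > 1:
        best = None
        for t in current:
            reduced_terms = [u for u in current if u != t]
            # a term may only be dropped if no retained interaction contains it
            if any(t in u.split(":") for u in reduced_terms if ":" in u):
                continue
            reduced = fit_success_glm(
                records, f"{response} ~ {' + '.join(reduced_terms)}", ci_level
            )
            test = lrt(reduced, fit)
            test.groups = (t,)
            if best is None or test.p_value > best[0].p_value:
                best = (test, t, reduced)
        if best is None or best[0].p_value < alpha:
            break
        history.append(best[0])
        current.remove(best[1])
        fit = best[2]
    return fit, history


def chisq_success(counts: pd.DataFrame | np.ndarray) -> TestResult:
    """Pearson chi-squared on a groups x {success, failure} count table,
    without continuity correction (the multi-group convention)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two groups")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate table: empty row or column")
    stat, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
    return TestResult("chi-squared", float(stat), int(df), float(p))


def holm_adjust(p_values: list[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, never below raw p)."""
    return multipletests(p_values, method="holm")[1]


def kruskal_dunn(samples: dict[str, np.ndarray]) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis rank test followed by Dunn's pairwise comparisons.

    Returns the omnibus result and one TestResult per group pair with the
    Dunn Z statistic and Holm-Bonferroni adjusted p-value. Ranks use the
    standard tie correction.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")

    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and all(
        a.size == arrays[0].size for a in arrays
    ) and np.unique(arrays[0]).size == 1:
        omnibus = TestResult("Kruskal-Wallis", 0.0, len(names) - 1, 1.0)
    else:
        h, p = scipy.stats.kruskal(*arrays)
        omnibus = TestResult("Kruskal-Wallis", float(h), len(names) - 1, float(p))

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = ranks[i : i + a.size].mean()
        i += a.size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairwise = []
    raw_p = []
    for a_name, b_name in combinations(names, 2):
        na, nb = len(samples[a_name]), len(samples[b_name])
        se = math.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a_name] - mean_ranks[b_name]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z)) if se > 0 else 1.0
        pairwise.append(
            TestResult("Dunn", float(z), None, float(p), groups=(a_name, b_name))
        )
        raw_p.append(p)
    adjusted = holm_adjust(raw_p)
    for t, ap in zip(pairwise, adjusted):
        t.adjusted_p = float(ap)
    return omnibus, pairwise


def compare_to_telemetry(
    cells: list[GridCell],
    records: list[TelemetryRecord],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Compare each simulation cell of one lake with observed outcomes.

    For every cell: a two-sided exact binomial test of the cell's success
    count against the observed success proportion, a flag for whether the
    observed rate lies inside the cell's binomial confidence interval, and
    the analogous interval check for mean passage time (using the cell's
    t-interval for the mean).
    """
    if not records:
        raise ValueError("no telemetry records supplied")
    lakes = {r.lake for r in records}
    if len(lakes) != 1:
        raise ValueError(f"records span several lakes: {sorted(lakes)}")
    (lake,) = lakes
    mism = [c.basin for c in cells if c.basin != lake]
    if mism:
        raise ValueError(f"cells from other basins present: {sorted(set(mism))}")

    n_fish = len(records)
    n_obs_succ = sum(r.success for r in records)
    p_emp = n_obs_succ / n_fish
    obs_days = np.array(
        [r.passage_days for r in records if r.success], dtype=float
    )
    emp_mean_days = float(obs_days.mean()) if obs_days.size else math.nan

    rows = []
    for c in cells:
        bt = scipy.stats.binomtest(c.n_success, c.n_sims, p_emp if p_emp > 0 else 1e-12)
        ci = scipy.stats.binomtest(c.n_success, c.n_sims).proportion_ci(
            confidence_level=ci_level
        )
        rate_inside = ci.low <= p_emp <= ci.high
        if c.passage_times.size > 1:
            m = c.mean_passage_days
            half = scipy.stats.t.ppf(
                0.5 + ci_level / 2.0, c.passage_times.size - 1
            ) * c.se_passage_days
            time_inside = (
                not math.isnan(emp_mean_days) and m - half <= emp_mean_days <= m + half
            )
        else:
            time_inside = False
        rows.append(
            {
                "lake": lake,
                "step_length_m": c.step_length,
                "turn_sd_deg": c.turn_sd,
                "sim_success_pct": c.success_rate,
                "obs_success_pct": 100.0 * p_emp,
                "binom_p": float(bt.pvalue),
                "rate_within_ci": bool(rate_inside),
                "sim_mean_passage_days": c.mean_passage_days,
                "obs_mean_passage_days": emp_mean_days,
                "passage_within_ci": bool(time_inside),
                "n_fish": n_fish,
            }
        )
    return pd.DataFrame(rows)
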