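"""Hormone and colour time-course statistics.

Covers the statistical battery applied to the testosterone manipulation
study:

* :func:`anova_time` — the change in plasma testosterone across the three
  sampling timepoints (pre-implant, week 1, week 4). Because every female is
  sampled repeatedly but some cells are missing, the model is a female-blocked
  two-factor fixed-effects ANOVA (female + timepoint) on the available
  records; the timepoint F uses the partial (type-III) sum of squares. With
  44 records from 18 females at 3 timepoints this yields the (2, 24) design.
* :func:`pairwise_adjusted` — Tukey–Kramer-adjusted pairwise comparisons of
  the timepoint least-squares means on the ANOVA error df.
* :func:`freeman_halton_exact` — the Freeman–Halton extension of Fisher's
  exact test to r x c tables (full enumeration of tables with the observed
  margins; Monte-Carlo fallback for large totals).
* :func:`fdr_bh` — Benjamini–Hochberg step-up false-discovery-rate
  adjustment.
* :func:`fit_timecourse` / :func:`per_morph_trend` — REML linear mixed models
  of each colour variable over weeks with linear and quadratic time, morph,
  and morph x time interactions as fixed effects and a per-female random
  intercept.

Hormone panels and time-course data are tidy DataFrames; see
``HORMONE_COLUMNS`` and ``TIMECOURSE_COLUMNS``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TIMEPOINT_ORDER",
    "HORMONE_COLUMNS",
    "TIMECOURSE_COLUMNS",
    "AnovaResult",
    "PairwiseResult",
    "ExactTestResult",
    "LMMResult",
    "anova_time",
    "pairwise_adjusted",
    "freeman_halton_exact",
    "fdr_bh",
    "fit_timecourse",
    "per_morph_trend",
]

logger = logging.getLogger(__name__)

#: Blood-sampling timepoints relative to the testosterone implant.
TIMEPOINT_ORDER = ("pre", "week1", "week4")

HORMONE_COLUMNS = ("female_id", "timepoint", "testosterone")
TIMECOURSE_COLUMNS = ("female_id", "week", "morph", "value")


@dataclass(frozen=True)
class AnovaResult:
    """Timepoint F test from the female-blocked hormone ANOVA."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    lsmeans: dict          # timepoint -> (least-squares mean, standard error)
    n_records: int
    n_females: int


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey–Kramer-adjusted pairwise timepoint comparison."""

    pair: tuple[str, str]
    estimate: float        # lsmean(first) - lsmean(second)
    t_statistic: float
    df: int
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class ExactTestResult:
    """Freeman–Halton exact test of independence in an r x c table."""

    p_value: float
    n_tables: int
    row_margins: tuple[int, ...]
    col_margins: tuple[int, ...]
    method: str = "enumeration"


@dataclass(frozen=True)
class LMMResult:
    """REML mixed-model fit of one colour variable over time."""

    response: str
    fixed_effects: pd.DataFrame   # term, F, df_num, df_den, p_value
    coefficients: pd.Series
    coefficient_se: pd.Series
    intercept_variance: float
    residual_variance: float
    n_obs: int
    n_females: int
    converged: bool


# ---------------------------------------------------------------------------
# hormone ANOVA


def _validate_hormone_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HORMONE_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"hormone panel is missing columns {missing}")
    df = panel.loc[:, list(HORMONE_COLUMNS)].dropna(subset=["testosterone"]).copy()
    if (df["testosterone"] <= 0).any():
        raise ValueError("testosterone concentrations must be positive")
    dup = df.duplicated(subset=["female_id", "timepoint"])
    if dup.any():
        raise ValueError(
            "duplicate (female, timepoint) records: "
            f"{df.loc[dup, ['female_id', 'timepoint']].to_dict('records')}"
        )
    unknown = set(df["timepoint"]) - set(TIMEPOINT_ORDER)
    if unknown:
        raise ValueError(f"unknown timepoints {sorted(unknown)}; "
                         f"expected {TIMEPOINT_ORDER}")
    return df


def _hormone_design(df: pd.DataFrame):
    """Design matrix [1 | female dummies | timepoint dummies] (treatment coding)."""
    females = sorted(df["female_id"].unique())
    tps = [t for t in TIMEPOINT_ORDER if t in set(df["timepoint"])]
    if len(tps) < 2:
        raise ValueError("at least 2 timepoints with data are required")
    counts = df["timepoint"].value_counts()
    if (counts[tps] < 2).any():
        raise ValueError("each timepoint needs at least 2 observations")
    n = len(df)
    f_idx = pd.Categorical(df["female_id"], categories=females).codes
    t_idx = pd.Categorical(df["timepoint"], categories=tps).codes
    Xf = np.zeros((n, len(females) - 1))
    for j in range(1, len(females)):
        Xf[f_idx == j, j - 1] = 1.0
    Xt = np.zeros((n, len(tps) - 1))
    for j in range(1, len(tps)):
        Xt[t_idx == j, j - 1] = 1.0
    X = np.column_stack([np.ones(n), Xf, Xt])
    names = (["Intercept"]
             + [f"female[{f}]" for f in females[1:]]
             + [f"timepoint[{t}]" for t in tps[1:]])
    return X, names, females, tps


def _fit_hormone_model(panel: pd.DataFrame):
    df = _validate_hormone_panel(panel)
    X, names, females, tps = _hormone_design(df)
    y = df["testosterone"].to_numpy(dtype=float)
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    df_den = int(res.df_resid)
    return df, res, names, females, tps, df_den


def anova_time(panel: pd.DataFrame) -> AnovaResult:
    """Timepoint effect on testosterone, blocking on female.

    Fits the additive fixed-effects model ``testosterone ~ female +
    timepoint`` on the available records and tests the timepoint factor with
    its partial sum of squares. Error df = N - 1 - (n_females - 1) -
    (n_timepoints - 1).
    """
    df, res, names, females, tps, df_den = _fit_hormone_model(panel)
    tp_cols = [j for j, nm in enumerate(names) if nm.startswith("timepoint[")]
    # partial SS: compare against the model without the timepoint columns
    keep = [j for j in range(len(names)) if j not in tp_cols]
    X_red = res.model.exog[:, keep]
    res_red = sm.OLS(res.model.endog, X_red).fit()
    q = len(tp_cols)
    ss_tp = max(res_red.ssr - res.ssr, 0.0)
    ss_total = float(np.sum((res.model.endog - res.model.endog.mean()) ** 2))
    if res.ssr <= 1e-12 * max(ss_total, 1.0):
        # perfect fit: no residual variance left to test against
        if ss_tp <= 1e-12 * max(ss_total, 1.0):
            f_stat, p = 0.0, 1.0
        else:
            raise ValueError(
                "zero residual variance with a nonzero timepoint effect; "
                "the F statistic is unbounded (degenerate input)"
            )
    else:
        f_stat = (ss_tp / q) / (res.ssr / df_den)
        p = float(sps.f.sf(f_stat, q, df_den))

    lsmeans = _hormone_lsmeans(res, names, females, tps)
    return AnovaResult(
        f_statistic=float(f_stat),
        df_num=q,
        df_den=df_den,
        p_value=p,
        lsmeans=lsmeans,
        n_records=len(df),
        n_females=len(females),
    )


def _hormone_lsmeans(res, names, females, tps):
    """Least-squares timepoint means: predictions averaged over female levels."""
    k = len(names)
    nf = len(females)
    lsmeans = {}
    for t in tps:
        c = np.zeros(k)
        c[0] = 1.0
        for j, nm in enumerate(names):
            if nm.startswith("female["):
                c[j] = 1.0 / nf
        if t != tps[0]:
            c[names.index(f"timepoint[{t}]")] = 1.0
        est = float(c @ res.params.to_numpy())
        se = float(np.sqrt(c @ res.cov_params().to_numpy() @ c))
        lsmeans[t] = (est, se)
    return lsmeans


def pairwise_adjusted(panel: pd.DataFrame) -> list[PairwiseResult]:
    """Tukey–Kramer-adjusted pairwise timepoint contrasts of the hormone model.

    Contrasts are differences of timepoint least-squares means tested on the
    ANOVA error df; adjusted p values use the studentized range with
    k = number of timepoints.
    """
    df, res, names, females, tps, df_den = _fit_hormone_model(panel)
    k = len(names)
    cov = res.cov_params().to_numpy()
    params = res.params.to_numpy()
    out = []
    for t1, t2 in itertools.combinations(tps, 2):
        c = np.zeros(k)
        if t1 != tps[0]:
            c[names.index(f"timepoint[{t1}]")] += 1.0
        if t2 != tps[0]:
            c[names.index(f"timepoint[{t2}]")] -= 1.0
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        t_stat = est / se
        p_un = float(2 * sps.t.sf(abs(t_stat), df_den))
        p_adj = float(sps.studentized_range.sf(
            abs(t_stat) * math.sqrt(2.0), len(tps), df_den))
        out.append(PairwiseResult(
            pair=(t1, t2), estimate=est, t_statistic=float(t_stat),
            df=df_den, p_unadjusted=p_un, p_adjusted=min(1.0, p_adj),
        ))
    return out


# ---------------------------------------------------------------------------
# exact r x c test


def _log_table_prob(table, lr, lc, lN):
    """Log multivariate hypergeometric probability of a table given margins."""
    return lr + lc - lN - sum(math.lgamma(v + 1) for v in table)


def freeman_halton_exact(
    table,
    enumeration_bound: int = 200,
    monte_carlo: bool = False,
    n_samples: int = 100_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Exact test of independence for an r x c contingency table.

    Enumerates every nonnegative integer table with the observed margins and
    sums the (multivariate hypergeometric) probabilities of all tables no
    more probable than the observed one — the Freeman–Halton generalisation
    of the two-sided Fisher exact test. Probabilities within a relative
    1e-12 of the observed table's count as ties.

    Totals above ``enumeration_bound`` require ``monte_carlo=True`` (seeded
    Patefield sampling of the null table distribution).
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D nonnegative integer matrix")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all row and column margins must be positive")
    N = int(obs.sum())
    lr = sum(math.lgamma(v + 1) for v in rows)
    lc = sum(math.lgamma(v + 1) for v in cols)
    lN = math.lgamma(N + 1)
    logp_obs = _log_table_prob(obs.ravel(), lr, lc, lN)

    if N > enumeration_bound:
        if not monte_carlo:
            raise ValueError(
                f"table total {N} exceeds the enumeration bound "
                f"{enumeration_bound}; rerun with monte_carlo=True and a seed"
            )
        rng = np.random.default_rng(seed)
        sampler = sps.random_table(rows, cols)
        draws = sampler.rvs(size=n_samples, random_state=rng)
        lg = np.vectorize(math.lgamma)
        logp = lr + lc - lN - lg(draws + 1.0).sum(axis=(1, 2))
        hits = int(np.sum(logp <= logp_obs + 1e-12))
        return ExactTestResult(
            p_value=float((hits + 1) / (n_samples + 1)),
            n_tables=n_samples,
            row_margins=tuple(int(v) for v in rows),
            col_margins=tuple(int(v) for v in cols),
            method="monte_carlo",
        )

    r, c = obs.shape
    p_total = 0.0
    n_tables = 0
    cell = np.zeros((r, c), dtype=int)

    def fill_row(i, remaining_cols):
        nonlocal p_total, n_tables
        if i == r - 1:
            cell[i, :] = remaining_cols
            n_tables += 1
            lp = _log_table_prob(cell.ravel(), lr, lc, lN)
            if lp <= logp_obs + 1e-12:
                p_total += math.exp(lp)
            return
        _fill_cell(i, 0, int(rows[i]), remaining_cols)

    def _fill_cell(i, j, row_left, cols_left):
        if j == c - 1:
            if row_left <= cols_left[j]:
                cell[i, j] = row_left
                nxt = cols_left.copy()
                nxt[j] -= row_left
                fill_row(i + 1, nxt)
            return
        for v in range(min(row_left, cols_left[j]) + 1):
            cell[i, j] = v
            nxt = cols_left.copy()
            nxt[j] -= v
            _fill_cell(i, j + 1, row_left - v, nxt)

    fill_row(0, cols.copy())
    return ExactTestResult(
        p_value=min(1.0, float(p_total)),
        n_tables=n_tables,
        row_margins=tuple(int(v) for v in rows),
        col_margins=tuple(int(v) for v in cols),
        method="enumeration",
    )


# ---------------------------------------------------------------------------
# multiple testing


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("p-value list is empty")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


# ---------------------------------------------------------------------------
# colour time-course mixed models


def _validate_timecourse(data: pd.DataFrame, require_morph=True) -> pd.DataFrame:
    cols = TIMECOURSE_COLUMNS if require_morph else tuple(
        c for c in TIMECOURSE_COLUMNS if c != "morph")
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"time-course data is missing columns {missing}")
    df = data.dropna(subset=["value"]).copy()
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("response values must be finite")
    return df


def _term_f_tests(res, term_slices, n_obs, rank_x):
    """Wald F per fixed-effect term; denominator df = residual df."""
    fe = res.fe_params
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    df_den = n_obs - rank_x
    records = []
    for term, idx in term_slices.items():
        if term == "Intercept":
            continue
        L = np.zeros((len(idx), len(fe)))
        for r_i, j in enumerate(idx):
            L[r_i, j] = 1.0
        est = L @ np.asarray(fe)
        mid = L @ cov @ L.T
        try:
            stat = float(est @ np.linalg.solve(mid, est))
        except np.linalg.LinAlgError:
            records.append((term, np.nan, len(idx), df_den, np.nan))
            continue
        q = len(idx)
        f_val = stat / q
        records.append((term, f_val, q, df_den, float(sps.f.sf(f_val, q, df_den))))
    return pd.DataFrame(
        records, columns=["term", "F", "df_num", "df_den", "p_value"]
    ).set_index("term")


def _fit_mixed(df: pd.DataFrame, formula: str, term_map):
    df = df.copy()
    df["time"] = df["week"].astype(float)
    df["time2"] = df["time"] ** 2
    if df["value"].var() == 0:
        raise ValueError("response has zero variance; model is degenerate")
    model = smf.mixedlm(formula, data=df, groups=df["female_id"])
    res = model.fit(reml=True)
    if res.scale <= 0 or not np.isfinite(res.scale):
        raise ValueError("zero or undefined residual variance; degenerate fit")

    design_info = model.data.design_info
    name_order = list(res.fe_params.index)
    term_slices = {}
    for term_name, sl in design_info.term_name_slices.items():
        cols = design_info.column_names[sl]
        idx = [name_order.index(c) for c in cols]
        term_slices[term_map.get(term_name, term_name)] = idx

    n_obs = len(df)
    rank_x = np.linalg.matrix_rank(np.asarray(model.exog))
    ftab = _term_f_tests(res, term_slices, n_obs, rank_x)
    var_re = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    return res, ftab, var_re, n_obs


def fit_timecourse(data: pd.DataFrame, response: str = "value") -> LMMResult:
    """REML mixed model of one colour variable over the observation weeks.

    Fixed effects: time, time^2, morph, morph x time and morph x time^2;
    random intercept per female. F tests are Wald tests on the REML fit with
    a residual-df denominator.
    """
    df = _validate_timecourse(data)
    if response != "value":
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not found")
        df = df.rename(columns={"value": "_value_orig"}).rename(
            columns={response: "value"})
    if df["morph"].nunique() < 2:
        raise ValueError("at least 2 morphs are required; "
                         "use per_morph_trend for a single morph")
    if df["week"].nunique() < 3:
        raise ValueError("at least 3 distinct weeks are required")
    if (df.groupby("female_id").size() < 2).any():
        raise ValueError("every female needs at least 2 observations")
    # sum-to-zero morph coding: the time terms then test the slope averaged
    # over morphs rather than the reference morph's slope
    formula = ("value ~ time + time2 + C(morph, Sum) + C(morph, Sum):time "
               "+ C(morph, Sum):time2")
    term_map = {
        "time": "time",
        "time2": "time^2",
        "C(morph, Sum)": "morph",
        "C(morph, Sum):time": "morph:time",
        "C(morph, Sum):time2": "morph:time^2",
    }
    res, ftab, var_re, n_obs = _fit_mixed(df, formula, term_map)
    return LMMResult(
        response=response,
        fixed_effects=ftab,
        coefficients=res.fe_params,
        coefficient_se=res.bse_fe,
        intercept_variance=var_re,
        residual_variance=float(res.scale),
        n_obs=n_obs,
        n_females=df["female_id"].nunique(),
        converged=bool(res.converged),
    )


def per_morph_trend(data: pd.DataFrame, morph: str,
                    response: str = "value") -> LMMResult:
    """Linear and quadratic time trends within a single morph.

    Same mixed model as :func:`fit_timecourse` restricted to one morph and
    therefore without the morph terms.
    """
    df = _validate_timecourse(data)
    df = df[df["morph"] == morph]
    if df.empty:
        raise ValueError(f"no records for morph {morph!r}")
    if df["week"].nunique() < 3:
        raise ValueError(
            f"morph {morph!r} has data for fewer than 3 distinct weeks"
        )
    res, ftab, var_re, n_obs = _fit_mixed(
        df, "value ~ time + time2", {"time": "time", "time2": "time^2"})
    return LMMResult(
        response=response,
        fixed_effects=ftab,
        coefficients=res.fe_params,
        coefficient_se=res.bse_fe,
        intercept_variance=var_re,
        residual_variance=float(res.scale),
        n_obs=n_obs,
        n_females=df["female_id"].nunique(),
        converged=bool(res.converged),
    )
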