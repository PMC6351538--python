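"""Statistical layer: transforms, stratified ANOVAs, t-tests, regression.

Three designs are implemented with their classical expected-mean-square
F-tests written out explicitly rather than delegated to a mixed-model
fitter, so the error-term structure is visible and testable:

* split-plot ANOVA for cumulative emissions — blocks are locations, the
  main plot is pasture condition (tested against condition x location),
  the split plot is the nitrogen level (urine vs control, tested against
  the residual);
* randomized-complete-block one-way ANOVA for emission factors — blocks
  are locations, treatment is pasture condition;
* per-site two-sample t-tests on replicate EFs (pooled variance by
  default, Welch by flag).

Cumulative emissions are log-transformed with a recorded offset and EFs
square-root transformed with a recorded shift before ANOVA, since
controls can sit at or below zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """The data do not form the balanced design the test requires."""


class TransformError(ValueError):
    pass


class RegressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transforms


@dataclass(frozen=True)
class TransformedResponse:
    raw: float
    transformed: float
    transform: str  # log_offset | sqrt_shift | identity
    param: float  # offset delta or shift s (0 for identity)


def default_log_offset(values: Sequence[float]) -> float:
    """Half the smallest positive value; 0 if all values are positive anyway...

    The offset must make every value strictly positive, so it is applied
    unconditionally: delta = 0.5 * min(positive values).  Raises when no
    value is positive (nothing to anchor the scale).
    """
    arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise TransformError("log offset undefined: no positive values")
    return float(pos.min() / 2.0)


def default_sqrt_shift(values: Sequence[float]) -> float:
    """Shift making the minimum value 0: s = -min(0, min(values))."""
    arr = np.asarray(values, dtype=float)
    return float(-min(0.0, float(arr.min())))


def transform_response(
    values: Sequence[float], kind: str, param: Optional[float] = None
) -> list[TransformedResponse]:
    """Apply a recorded, invertible variance-stabilizing transform.

    kind 'log_offset': ln(x + delta), delta defaulting to half the
    smallest positive value; 'sqrt_shift': sqrt(x + s), s defaulting to
    the shift that zeroes the minimum; 'identity' passes through.
    """
    arr = np.asarray(values, dtype=float)
    if kind == "identity":
        return [TransformedResponse(float(x), float(x), "identity", 0.0) for x in arr]
    if kind == "log_offset":
        delta = default_log_offset(arr) if param is None else float(param)
        shifted = arr + delta
        bad = np.nonzero(shifted <= 0)[0]
        if bad.size:
            raise TransformError(
                f"log_offset: value at index {int(bad[0])} "
                f"({arr[bad[0]]!r}) non-positive after offset {delta}"
            )
        return [TransformedResponse(float(x), float(math.log(x + delta)), "log_offset", delta) for x in arr]
    if kind == "sqrt_shift":
        s = default_sqrt_shift(arr) if param is None else float(param)
        shifted = arr + s
        bad = np.nonzero(shifted < 0)[0]
        if bad.size:
            raise TransformError(
                f"sqrt_shift: value at index {int(bad[0])} negative after shift {s}"
            )
        return [TransformedResponse(float(x), float(math.sqrt(x + s)), "sqrt_shift", s) for x in arr]
    raise TransformError(f"unknown transform {kind!r}")


def transformed_values(values: Sequence[float], kind: str, param: Optional[float] = None) -> np.ndarray:
    return np.array([t.transformed for t in transform_response(values, kind, param)])


# ---------------------------------------------------------------------------
# ANOVA helpers


def _f_p(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float]:
    """(F, p) for a mean-square ratio; NaN when the denominator MS is 0."""
    if df_num <= 0 or df_den <= 0:
        return math.nan, math.nan
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    if ms_den == 0.0:
        return math.nan, math.nan
    f = ms_num / ms_den
    return f, float(stats.f.sf(f, df_num, df_den))


def _anova_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["source", "df", "sum_sq", "mean_sq", "F", "p", "error_stratum"])
    return df


def splitplot_anova(
    data: pd.DataFrame,
    response: str = "y",
    block: str = "location",
    mainplot: str = "condition",
    subplot: str = "nitrogen",
) -> pd.DataFrame:
    """Split-plot ANOVA with blocks, a main-plot and a split-plot factor.

    Sources and their tests::

        Location        (b-1)            — block, not tested
        Condition       (a-1)            — F against MainPlotError
        MainPlotError   (a-1)(b-1)       — condition x location
        Nitrogen        (n-1)            — F against Residual
        Condition:Nitrogen (a-1)(n-1)    — F against Residual
        Residual        remainder

    Requires a complete balanced design: every block x main x sub cell
    holds the same number of replicates (>= 1).  With replicates the
    residual pools the within-cell variation together with the remaining
    interaction strata, matching the classical analysis where whole plots
    are condition plots within each location.
    """
    for col in (response, block, mainplot, subplot):
        if col not in data.columns:
            raise DesignError(f"missing column {col!r}")
    d = data.dropna(subset=[response])
    blocks = sorted(d[block].unique())
    mains = sorted(d[mainplot].unique())
    subs = sorted(d[subplot].unique())
    b, a, n = len(blocks), len(mains), len(subs)
    if b < 2:
        raise DesignError("split-plot ANOVA needs >= 2 locations (block stratum)")
    if a < 2 or n < 2:
        raise DesignError("need >= 2 levels of both the main-plot and split-plot factor")
    sizes = d.groupby([block, mainplot, subplot], sort=False)[response].size()
    if len(sizes) != a * b * n:
        raise DesignError("incomplete design: at least one block x condition x nitrogen cell is empty")
    r = int(sizes.iloc[0])
    if not (sizes == r).all():
        raise DesignError(f"unbalanced design: cell sizes {sorted(set(sizes))}")

    # pivot to Y[b, a, n, r]
    y = np.empty((b, a, n, r), dtype=float)
    g = d.groupby([block, mainplot, subplot], sort=False)[response]
    for (bi, blv) in enumerate(blocks):
        for (ai, mlv) in enumerate(mains):
            for (ni, slv) in enumerate(subs):
                y[bi, ai, ni, :] = g.get_group((blv, mlv, slv)).to_numpy()

    grand = y.mean()
    m_b = y.mean(axis=(1, 2, 3))
    m_a = y.mean(axis=(0, 2, 3))
    m_n = y.mean(axis=(0, 1, 3))
    m_ba = y.mean(axis=(2, 3))
    m_an = y.mean(axis=(0, 3))

    ss_block = a * n * r * float(((m_b - grand) ** 2).sum())
    ss_main = b * n * r * float(((m_a - grand) ** 2).sum())
    ss_mpe = n * r * float(((m_ba - m_b[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_sub = a * b * r * float(((m_n - grand) ** 2).sum())
    ss_int = b * r * float(((m_an - m_a[:, None] - m_n[None, :] + grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())

    df_block, df_main, df_mpe = b - 1, a - 1, (a - 1) * (b - 1)
    df_sub, df_int = n - 1, (a - 1) * (n - 1)
    df_total = a * b * n * r - 1
    df_resid = df_total - df_block - df_main - df_mpe - df_sub - df_int
    ss_resid = ss_total - ss_block - ss_main - ss_mpe - ss_sub - ss_int
    ss_resid = max(ss_resid, 0.0)  # guard tiny negative round-off

    f_main, p_main = _f_p(ss_main, df_main, ss_mpe, df_mpe)
    f_sub, p_sub = _f_p(ss_sub, df_sub, ss_resid, df_resid)
    f_int, p_int = _f_p(ss_int, df_int, ss_resid, df_resid)

    def ms(ss, df):
        return ss / df if df > 0 else math.nan

    return _anova_table(
        [
            {"source": "Location", "df": df_block, "sum_sq": ss_block,
             "mean_sq": ms(ss_block, df_block), "F": math.nan, "p": math.nan,
             "error_stratum": ""},
            {"source": "Condition", "df": df_main, "sum_sq": ss_main,
             "mean_sq": ms(ss_main, df_main), "F": f_main, "p": p_main,
             "error_stratum": "MainPlotError"},
            {"source": "MainPlotError", "df": df_mpe, "sum_sq": ss_mpe,
             "mean_sq": ms(ss_mpe, df_mpe), "F": math.nan, "p": math.nan,
             "error_stratum": ""},
            {"source": "Nitrogen", "df": df_sub, "sum_sq": ss_sub,
             "mean_sq": ms(ss_sub, df_sub), "F": f_sub, "p": p_sub,
             "error_stratum": "Residual"},
            {"source": "Condition:Nitrogen", "df": df_int, "sum_sq": ss_int,
             "mean_sq": ms(ss_int, df_int), "F": f_int, "p": p_int,
             "error_stratum": "Residual"},
            {"source": "Residual", "df": df_resid, "sum_sq": ss_resid,
             "mean_sq": ms(ss_resid, df_resid), "F": math.nan, "p": math.nan,
             "error_stratum": ""},
        ]
    )


def blocked_oneway_anova(
    data: pd.DataFrame,
    response: str = "y",
    block: str = "location",
    treatment: str = "condition",
) -> pd.DataFrame:
    """Randomized-complete-block one-way ANOVA (Block, Treatment, Residual).

    Accepts one observation per block x treatment cell (the site-mean EF
    mode) or equal replication r per cell (replicate-EF mode); in either
    case F(Treatment) = MS_Treatment / MS_Residual with the block x
    treatment interaction and within-cell variation pooled as residual.
    """
    for col in (response, block, treatment):
        if col not in data.columns:
            raise DesignError(f"missing column {col!r}")
    d = data.dropna(subset=[response])
    blocks = sorted(d[block].unique())
    treats = sorted(d[treatment].unique())
    b, t = len(blocks), len(treats)
    if b < 2 or t < 2:
        raise DesignError("need >= 2 blocks and >= 2 treatments")
    sizes = d.groupby([block, treatment], sort=False)[response].size()
    if len(sizes) != b * t:
        raise DesignError("incomplete design: empty block x treatment cell")
    r = int(sizes.iloc[0])
    if not (sizes == r).all():
        raise DesignError(f"unbalanced design: cell sizes {sorted(set(sizes))}")

    y = np.empty((b, t, r), dtype=float)
    g = d.groupby([block, treatment], sort=False)[response]
    for bi, blv in enumerate(blocks):
        for ti, tlv in enumerate(treats):
            y[bi, ti, :] = g.get_group((blv, tlv)).to_numpy()

    grand = y.mean()
    ss_block = t * r * float(((y.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_treat = b * r * float(((y.mean(axis=(0, 2)) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_block - ss_treat, 0.0)
    df_block, df_treat = b - 1, t - 1
    df_total = b * t * r - 1
    df_resid = df_total - df_block - df_treat
    f_treat, p_treat = _f_p(ss_treat, df_treat, ss_resid, df_resid)

    def ms(ss, df):
        return ss / df if df > 0 else math.nan

    return _anova_table(
        [
            {"source": "Location", "df": df_block, "sum_sq": ss_block,
             "mean_sq": ms(ss_block, df_block), "F": math.nan, "p": math.nan,
             "error_stratum": ""},
            {"source": "Condition", "df": df_treat, "sum_sq": ss_treat,
             "mean_sq": ms(ss_treat, df_treat), "F": f_treat, "p": p_treat,
             "error_stratum": "Residual"},
            {"source": "Residual", "df": df_resid, "sum_sq": ss_resid,
             "mean_sq": ms(ss_resid, df_resid), "F": math.nan, "p": math.nan,
             "error_stratum": ""},
        ]
    )


# ---------------------------------------------------------------------------
# Per-site tests


@dataclass(frozen=True)
class SiteTest:
    site_id: str
    statistic: float
    df: float
    p: float
    mean_lvc: float
    sem_lvc: float
    mean_avc: float
    sem_avc: float
    letters: tuple[str, str]  # (LVC, AVC); same letter <=> p >= alpha
    alpha: float


def site_ttest(
    values_lvc: Sequence[float],
    values_avc: Sequence[float],
    site_id: str = "",
    alpha: float = 0.05,
    welch: bool = False,
) -> SiteTest:
    """Two-sample t-test of LVC vs AVC replicate values at one site.

    Pooled-variance by default (``welch=True`` for unequal variances),
    two-sided p.  Degenerate zero-variance, equal-mean groups get t = 0,
    p = 1 by convention.  Significance letters: both 'a' when p >= alpha,
    'a'/'b' otherwise.
    """
    x = np.asarray(values_lvc, dtype=float)
    z = np.asarray(values_avc, dtype=float)
    if x.size < 2 or z.size < 2:
        raise DesignError(f"site {site_id}: need >= 2 replicates per group")
    if x.std() == 0.0 and z.std() == 0.0 and x.mean() == z.mean():
        t_stat, p, dof = 0.0, 1.0, float(x.size + z.size - 2)
    else:
        res = stats.ttest_ind(x, z, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    m_l, s_l, _ = _mean_sem(x)
    m_a, s_a, _ = _mean_sem(z)
    letters = ("a", "a") if p >= alpha else ("a", "b")
    return SiteTest(
        site_id=site_id, statistic=t_stat, df=dof, p=p,
        mean_lvc=m_l, sem_lvc=s_l, mean_avc=m_a, sem_avc=s_a,
        letters=letters, alpha=alpha,
    )


def _mean_sem(arr: np.ndarray) -> tuple[float, float, int]:
    n = arr.size
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return float(arr.mean()), sem, n


def site_tests_table(
    ef: pd.DataFrame, response: str = "ef_percent", alpha: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Run site_ttest per site on replicate values (column layout of ef_table)."""
    rows = []
    for site, grp in ef.groupby("site", sort=True):
        lvc = grp.loc[grp["condition"] == "LVC", response].dropna()
        avc = grp.loc[grp["condition"] == "AVC", response].dropna()
        if len(lvc) < 2 or len(avc) < 2:
            continue
        t = site_ttest(lvc, avc, site_id=str(site), alpha=alpha, welch=welch)
        rows.append(
            {
                "site": t.site_id, "t": t.statistic, "df": t.df, "p": t.p,
                "mean_LVC": t.mean_lvc, "sem_LVC": t.sem_lvc,
                "mean_AVC": t.mean_avc, "sem_AVC": t.sem_avc,
                "letter_LVC": t.letters[0], "letter_AVC": t.letters[1],
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EF ~ rainfall regression


@dataclass(frozen=True)
class RainfallRegression:
    condition: str
    slope: float  # EF % per mm
    intercept: float
    r_squared: float
    n: int


def regress_ef_on_rainfall(
    ef_by_site: Sequence[float], rainfall_by_site: Sequence[float], condition: str = ""
) -> RainfallRegression:
    """OLS of site EF on total campaign rainfall (one point per site).

    Rainfall totals conventionally include the week before monitoring
    started.  Requires >= 3 sites.  A flat response returns slope 0 and
    r^2 = 0.
    """
    y = np.asarray(ef_by_site, dtype=float)
    x = np.asarray(rainfall_by_site, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise RegressionError(f"condition {condition}: need >= 3 sites, got {x.size}")
    if np.all(y == y[0]):
        return RainfallRegression(condition, 0.0, float(y[0]), 0.0, int(x.size))
    res = stats.linregress(x, y)
    return RainfallRegression(
        condition=condition,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=int(x.size),
    )
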