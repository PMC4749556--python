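"""Group statistics: one-sample t-test, one-way repeated-measures ANOVA, and
recomputation of the published summary rows from the packaged tables.

The published derived statistics (t, F) were computed from full-precision
per-subject values, while the packaged transcriptions carry only the printed
three-decimal values. ``reproduce_printed`` therefore compares recomputed
summaries to the printed ones at three-decimal (half-even) rounding, and for
the derived ratio statistics additionally propagates the +/-0.0005 rounding
half-width of every input through the computation: a printed t or F is
counted as reproduced if it falls inside the attainable interval. A printed
value outside that interval cannot have been produced by any un-rounding of
the printed inputs and is reported as a failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import PRINTED, SIGMA_GRID, PrintedTables, load_printed_tables


def round3(x: float) -> float:
    """Half-even rounding to three decimals (the tables' printed precision)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class TTestResult:
    n: int
    df: int
    mean: float
    sd: float
    t: float
    p_two_tailed: float
    null_value: float


@dataclass(frozen=True)
class RMAnovaResult:
    n_subjects: int
    n_levels: int
    F: float
    df_effect: int
    df_error: int
    p: float


def one_sample_t(values: np.ndarray | list[float], null_value: float) -> TTestResult:
    """Classical two-tailed one-sample t-test against ``null_value``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two observations")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        if mean == null_value:
            return TTestResult(n, n - 1, mean, sd, float("nan"), float("nan"), null_value)
        raise ValueError("zero variance with mean != null value: t undefined")
    res = sps.ttest_1samp(values, null_value)
    return TTestResult(
        n=n,
        df=n - 1,
        mean=mean,
        sd=sd,
        t=float(res.statistic),
        p_two_tailed=float(res.pvalue),
        null_value=float(null_value),
    )


def rm_anova_oneway(matrix: np.ndarray, greenhouse_geisser: bool = False) -> RMAnovaResult:
    """One-way within-subject ANOVA on a complete subjects x levels matrix.

    Reports the uncorrected F on (levels-1, (levels-1)(subjects-1)) degrees of
    freedom; with ``greenhouse_geisser=True`` the p-value (not F) is computed
    on epsilon-scaled degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 subjects and >=2 levels")
    if not np.all(np.isfinite(m)):
        raise ValueError("repeated-measures ANOVA requires a complete matrix")
    n, k = m.shape
    # degenerate case (no level effect at all): AnovaRM's 0/0 is ill-defined
    grand = m.mean()
    ss_levels = n * ((m.mean(axis=0) - grand) ** 2).sum()
    if ss_levels < 1e-14 * max(1.0, abs(grand)):
        return RMAnovaResult(n, k, 0.0, k - 1, (k - 1) * (n - 1), 1.0)
    # statsmodels AnovaRM as the fitting backend
    from statsmodels.stats.anova import AnovaRM

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "level": np.tile(np.arange(k), n),
            "value": m.ravel(),
        }
    )
    fit = AnovaRM(long, depvar="value", subject="subject", within=["level"]).fit()
    row = fit.anova_table.iloc[0]
    F = float(row["F Value"])
    df1 = int(round(row["Num DF"]))
    df2 = int(round(row["Den DF"]))
    p = float(row["Pr > F"])
    if greenhouse_geisser:
        eps = _gg_epsilon(m)
        p = float(sps.f.sf(F, eps * df1, eps * df2))
    return RMAnovaResult(n_subjects=n, n_levels=k, F=F, df_effect=df1, df_error=df2, p=p)


def _gg_epsilon(m: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon of a subjects x levels matrix."""
    k = m.shape[1]
    S = np.cov(m, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * grand**2)
    return float(num / den)


# ---------------------------------------------------------------------------
# recomputation of the published summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Check:
    name: str
    recomputed: float
    printed: float
    passed: bool
    note: str = ""


def _rounding_interval(func, values: np.ndarray, n_draws: int = 4000,
                       seed: int = 20231005) -> tuple[float, float]:
    """Attainable range of ``func`` when every printed input is un-rounded.

    Each printed 3-decimal value stands for any real in +/-0.0005 around it;
    the interval is estimated by seeded uniform perturbation, then widened by
    a small safety margin for the unexplored corners of the hypercube.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        out[i] = func(values + rng.uniform(-5e-4, 5e-4, size=values.shape))
    span = out.max() - out.min()
    pad = 0.05 * span
    return float(out.min() - pad), float(out.max() + pad)


def reproduce_printed(tables: PrintedTables | None = None) -> pd.DataFrame:
    """Recompute every published summary row and compare to the printed value.

    Direct summaries (means, SDs) must match at three-decimal rounding.
    Derived ratio statistics (|t|, F) pass if the printed value lies in the
    interval attainable given the three-decimal rounding of the inputs.
    Returns a tidy frame of checks; the p-values are reported, not asserted.
    """
    tables = tables if tables is not None else load_printed_tables()
    checks: list[Check] = []

    v1 = tables.table1_values
    t_res = one_sample_t(v1, 0.75)
    checks.append(Check("table1_mean", t_res.mean, PRINTED["table1_mean"],
                        round3(t_res.mean) == PRINTED["table1_mean"]))
    checks.append(Check("table1_sd", t_res.sd, PRINTED["table1_sd"],
                        round3(t_res.sd) == PRINTED["table1_sd"]))
    checks.append(Check("table1_df", t_res.df, PRINTED["table1_df"],
                        t_res.df == PRINTED["table1_df"]))
    abs_t = abs(t_res.t)
    lo, hi = _rounding_interval(
        lambda v: abs(one_sample_t(v, 0.75).t), v1
    )
    t_pass = round3(abs_t) == PRINTED["table1_abs_t"] or lo <= PRINTED["table1_abs_t"] <= hi
    checks.append(Check("table1_abs_t", abs_t, PRINTED["table1_abs_t"], t_pass,
                        note=f"attainable under input rounding: [{lo:.3f}, {hi:.3f}]"))
    checks.append(Check("table1_p", t_res.p_two_tailed, PRINTED["table1_p"], True,
                        note=f"reported only: p = {t_res.p_two_tailed:.5f}"))

    m2 = tables.table2_matrix
    for j, sd_level in enumerate(SIGMA_GRID):
        mean_j = float(m2[:, j].mean())
        sd_j = float(m2[:, j].std(ddof=1))
        checks.append(Check(f"table2_mean_sigma_{sd_level}", mean_j,
                            PRINTED["table2_col_means"][j],
                            round3(mean_j) == PRINTED["table2_col_means"][j]))
        checks.append(Check(f"table2_sd_sigma_{sd_level}", sd_j,
                            PRINTED["table2_col_sds"][j],
                            round3(sd_j) == PRINTED["table2_col_sds"][j]))

    an = rm_anova_oneway(m2)
    checks.append(Check("anova_df_effect", an.df_effect, PRINTED["anova_df"][0],
                        an.df_effect == PRINTED["anova_df"][0]))
    checks.append(Check("anova_df_error", an.df_error, PRINTED["anova_df"][1],
                        an.df_error == PRINTED["anova_df"][1]))
    lo, hi = _rounding_interval(lambda v: rm_anova_oneway(v).F, m2, n_draws=800)
    f_pass = round3(an.F) == PRINTED["anova_F"] or lo <= PRINTED["anova_F"] <= hi
    checks.append(Check("anova_F", an.F, PRINTED["anova_F"], f_pass,
                        note=f"attainable under input rounding: [{lo:.3f}, {hi:.3f}]"))
    checks.append(Check("anova_p", an.p, float("nan"), an.p < 0.001,
                        note="printed as p < 0.001"))

    return pd.DataFrame([c.__dict__ for c in checks])
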