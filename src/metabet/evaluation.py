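"""Model evaluation: Monte-Carlo model predictions over the contrast grid,
goodness of fit against subject curves, and the decisional-noise grid.

Predictions are Monte-Carlo over evidence draws, but the decisional noise on
the interval-comparison variable D is integrated out analytically (the bet
probability given the drawn evidence is Phi(D0 / sigma_d)). This
Rao-Blackwellisation removes one layer of simulation variance and lets the
whole sigma_d grid share a single set of evidence draws, so differences
between grid values reflect the noise level alone rather than Monte-Carlo
chatter.

Two goodness-of-fit scores are computed. ``r_squared`` is the proportion of
variance accounted for across the concatenated per-contrast curve statistics
(betting rate, Type-2 hit/false-alarm rates, both conditional accuracies),
with the total sum of squares taken around the subject's own mean of each
statistic. ``multinomial_loglik`` treats each trial's (bet x correctness)
outcome as one draw from the model's predicted four-category distribution at
that contrast. Both are reconstructions of standard signal-detection fit
scores rather than transcriptions of any particular toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import SubjectCurve
from .observer import ObserverConfig, bet_tp_probability, simulate_trials, with_sigma_d

#: statistics entering the variance-accounted-for score (the curve panels)
FIT_STATS = [
    "p_bet_tp",
    "type2_hr",
    "type2_far",
    "p_correct_given_bet_tp",
    "p_correct_given_bet_ta",
]

CATEGORY_COLS = ["p_tp_correct", "p_tp_error", "p_ta_correct", "p_ta_error"]
COUNT_COLS = ["n_tp_correct", "n_tp_error", "n_ta_correct", "n_ta_error"]

PROB_CLAMP = 1e-6

DEFAULT_SIGMA_GRID = (0.0, 0.1, 0.2, 0.3)


@dataclass
class ModelPrediction:
    """Per-contrast predicted statistics for one observer configuration."""

    config: ObserverConfig
    n_sim: int
    table: pd.DataFrame  # indexed rows per contrast: evidence, CURVE stats, categories


@dataclass(frozen=True)
class FitResult:
    subject_id: str
    sigma_d: float
    r_squared: float
    multinomial_loglik: float


def _prediction_table(evidence: np.ndarray, correct: np.ndarray,
                      p_bet: np.ndarray, levels: np.ndarray) -> pd.DataFrame:
    """Collapse per-trial (correct, P(bet TP)) into per-contrast statistics."""
    rows = []
    for lev in levels:
        m = evidence == lev
        c = correct[m].astype(float)
        b = p_bet[m]
        n = c.size
        p_cc = float((b * c).mean())          # bet TP & correct
        p_ce = float((b * (1 - c)).mean())    # bet TP & error
        p_ac = float(((1 - b) * c).mean())    # bet TA & correct
        p_ae = float(((1 - b) * (1 - c)).mean())
        p_correct = float(c.mean())
        p_bet_tp = float(b.mean())
        rows.append(
            {
                "evidence": float(lev),
                "n_sim": n,
                "p_correct": p_correct,
                "p_bet_tp": p_bet_tp,
                "type2_hr": p_cc / p_correct if p_correct > 0 else np.nan,
                "type2_far": p_ce / (1 - p_correct) if p_correct < 1 else np.nan,
                "p_correct_given_bet_tp": p_cc / p_bet_tp if p_bet_tp > 0 else np.nan,
                "p_correct_given_bet_ta": p_ac / (1 - p_bet_tp) if p_bet_tp < 1 else np.nan,
                "p_tp_correct": p_cc,
                "p_tp_error": p_ce,
                "p_ta_correct": p_ac,
                "p_ta_error": p_ae,
            }
        )
    return pd.DataFrame(rows)


def predict_curves(
    config: ObserverConfig,
    contrasts: np.ndarray | list[float],
    n_sim: int = 10_000,
    seed: int | None = None,
) -> ModelPrediction:
    """Monte-Carlo model prediction at each contrast (n_sim trials each)."""
    return predict_grid(config, contrasts, [config.sigma_d], n_sim, seed)[config.sigma_d]


def predict_grid(
    config: ObserverConfig,
    contrasts: np.ndarray | list[float],
    sigma_grid: list[float] | tuple[float, ...] = DEFAULT_SIGMA_GRID,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> dict[float, ModelPrediction]:
    """Predictions for every decisional-noise level, sharing evidence draws.

    The evidence simulation (and hence the noiseless decision variable D0 and
    the discrimination outcomes) is identical across the grid; only the
    analytic bet probability differs.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000 for stable curve estimates")
    levels = np.asarray(contrasts, dtype=float)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    evidence = np.repeat(levels, n_sim)
    orientations = np.where(rng.random(evidence.size) < 0.5, "left", "right")
    base = with_sigma_d(config, 0.0)
    sim = simulate_trials(base, orientations, evidence, rng)
    D0 = sim["D"]  # sigma_d = 0, so this is the noiseless decision variable
    out = {}
    for sd in sigma_grid:
        p_bet = bet_tp_probability(D0, float(sd))
        table = _prediction_table(evidence, sim["correct_tp"], p_bet, levels)
        out[float(sd)] = ModelPrediction(
            config=with_sigma_d(config, sd), n_sim=n_sim, table=table
        )
    return out


def _align(pred: ModelPrediction, summary: pd.DataFrame) -> pd.DataFrame:
    """Join subject per-contrast rows to model rows on the evidence level."""
    p = pred.table
    idx = []
    for ev in summary["evidence"]:
        j = np.flatnonzero(np.isclose(p["evidence"], ev, rtol=0, atol=1e-9))
        if j.size != 1:
            raise ValueError(
                f"model prediction has no (unique) contrast matching evidence {ev}; "
                "evaluate the model on the subject's evidence grid"
            )
        idx.append(int(j[0]))
    aligned = p.iloc[idx].reset_index(drop=True)
    aligned.index = summary.index
    return aligned


def goodness_of_fit(pred: ModelPrediction, curve: SubjectCurve) -> FitResult:
    """Variance accounted for and multinomial log-likelihood of one subject."""
    s = curve.summary
    m = _align(pred, s)
    ss_res = 0.0
    ss_tot = 0.0
    for stat in FIT_STATS:
        y = s[stat].to_numpy(dtype=float)
        yhat = m[stat].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(yhat)
        if ok.sum() < 2:
            continue
        ss_res += float(((y[ok] - yhat[ok]) ** 2).sum())
        ss_tot += float(((y[ok] - y[ok].mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("degenerate subject curve: zero variance in every statistic")
    r2 = 1.0 - ss_res / ss_tot

    counts = s[COUNT_COLS].to_numpy(dtype=float)
    probs = np.clip(m[CATEGORY_COLS].to_numpy(dtype=float), PROB_CLAMP, 1 - PROB_CLAMP)
    loglik = float((counts * np.log(probs)).sum())
    return FitResult(
        subject_id=curve.subject_id,
        sigma_d=pred.config.sigma_d,
        r_squared=r2,
        multinomial_loglik=loglik,
    )


def noise_grid_eval(
    curves: list[SubjectCurve],
    config: ObserverConfig,
    contrasts: np.ndarray | list[float],
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit every subject at every decisional-noise level.

    Returns a long-format frame (subject_id, sigma_d, r_squared,
    multinomial_loglik); pivot on (subject_id x sigma_d) for the familiar
    subjects-by-noise R^2 matrix.
    """
    if 0.0 not in {float(s) for s in sigma_grid}:
        raise ValueError("sigma_grid must include the noiseless observer (0.0)")
    preds = predict_grid(config, contrasts, sigma_grid, n_sim=n_sim, seed=seed)
    rows = []
    for curve in curves:
        for sd in sigma_grid:
            fit = goodness_of_fit(preds[float(sd)], curve)
            rows.append(
                {
                    "subject_id": fit.subject_id,
                    "sigma_d": fit.sigma_d,
                    "r_squared": fit.r_squared,
                    "multinomial_loglik": fit.multinomial_loglik,
                }
            )
    return pd.DataFrame(rows)


def r2_matrix(grid_eval: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long grid-evaluation frame into subjects x sigma_d R^2."""
    return grid_eval.pivot(index="subject_id", columns="sigma_d", values="r_squared")


def recovery_experiment(
    base_config: ObserverConfig,
    design,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    n_subjects: int = 12,
    n_replicates: int = 20,
    n_sim: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate cohorts at each decisional-noise level and refit the grid.

    For every replicate and every generating sigma_d, a cohort of
    ``n_subjects`` simulated participants runs the full design; each subject
    is scored against the model at every grid value and the cohort-mean R^2
    decides the best-fitting noise level. Model predictions are computed once
    (shared evidence draws across the grid) and reused for all cohorts.

    Returns a long frame: replicate, gen_sigma, fit_sigma, mean_r_squared,
    mean_loglik, best (bool: fit_sigma maximises the cohort-mean R^2).
    """
    from .analysis import subject_curve
    from .experiment import simulate_dataset

    contrasts = design.evidence_levels()
    rng = np.random.default_rng(seed)
    preds = predict_grid(base_config, contrasts, sigma_grid, n_sim=n_sim,
                         seed=int(rng.integers(2**31)))
    rows = []
    for rep in range(n_replicates):
        for gen_sd in sigma_grid:
            agent = with_sigma_d(base_config, gen_sd)
            fits = {float(sd): ([], []) for sd in sigma_grid}
            for s in range(n_subjects):
                ds = simulate_dataset(design, agent, seed=int(rng.integers(2**31)),
                                      subject_id=f"r{rep}s{s}")
                curve = subject_curve(ds)
                for sd in sigma_grid:
                    fit = goodness_of_fit(preds[float(sd)], curve)
                    fits[float(sd)][0].append(fit.r_squared)
                    fits[float(sd)][1].append(fit.multinomial_loglik)
            means = {sd: float(np.mean(v[0])) for sd, v in fits.items()}
            best_sd = max(means, key=means.get)
            for sd in sigma_grid:
                rows.append(
                    {
                        "replicate": rep,
                        "gen_sigma": float(gen_sd),
                        "fit_sigma": float(sd),
                        "mean_r_squared": means[float(sd)],
                        "mean_loglik": float(np.mean(fits[float(sd)][1])),
                        "best": float(sd) == best_sd,
                    }
                )
    return pd.DataFrame(rows)
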