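"""Behavioral analysis: per-contrast summaries, Type-2 SDT rates, accuracy
binning across subjects, and kernel-regression interpolation of the betting
rate at 75% discrimination accuracy.

Trials are collapsed across tilt, interval order and session within each
contrast level. Per contrast the pipeline computes (a) orientation
discrimination accuracy in the target-present interval, (b) the fraction of
trials betting on the target-present interval, (c) Type-2 hit and false-alarm
rates (betting on the target-present interval given a correct / incorrect
discrimination), and (d) accuracy conditional on the bet. Group curves are
formed by binning each subject's per-contrast points into ten equal accuracy
bins over [0.5, 1]; per-subject betting rate at 75% accuracy is interpolated
with Nadaraya-Watson kernel regression with a Gaussian kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import BehavioralDataset

#: statistics carried through binning and goodness-of-fit, in display order
CURVE_STATS = [
    "p_correct",
    "p_bet_tp",
    "type2_hr",
    "type2_far",
    "p_correct_given_bet_tp",
    "p_correct_given_bet_ta",
]

BIN_EDGES = np.linspace(0.5, 1.0, 11)


def summarize_by_contrast(dataset: BehavioralDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-contrast trial counts and the summary statistics (a)-(d).

    Rates with an empty denominator (e.g. the Type-2 false-alarm rate when
    every discrimination was correct) are returned as NaN, never as zero.
    Contrasts with zero trials simply do not appear; an all-empty input is an
    error.
    """
    df = dataset.records if isinstance(dataset, BehavioralDataset) else dataset
    if len(df) == 0:
        raise ValueError("empty dataset")
    rows = []
    for (pct, ev), grp in df.groupby(["contrast_pct", "evidence"], sort=True):
        n = len(grp)
        correct = grp["correct_tp"].to_numpy(dtype=bool)
        bet_tp = (grp["bet_interval"] == "TP").to_numpy()
        n_correct = int(correct.sum())
        n_error = n - n_correct
        n_bet = int(bet_tp.sum())
        rows.append(
            {
                "contrast_pct": pct,
                "evidence": ev,
                "n_trials": n,
                # raw category counts (bet x correctness), kept for the
                # multinomial goodness-of-fit downstream
                "n_tp_correct": int((bet_tp & correct).sum()),
                "n_tp_error": int((bet_tp & ~correct).sum()),
                "n_ta_correct": int((~bet_tp & correct).sum()),
                "n_ta_error": int((~bet_tp & ~correct).sum()),
                "p_correct": n_correct / n,
                "p_bet_tp": n_bet / n,
                "type2_hr": (bet_tp & correct).sum() / n_correct if n_correct else np.nan,
                "type2_far": (bet_tp & ~correct).sum() / n_error if n_error else np.nan,
                "p_correct_given_bet_tp": (bet_tp & correct).sum() / n_bet if n_bet else np.nan,
                "p_correct_given_bet_ta": (~bet_tp & correct).sum() / (n - n_bet)
                if n - n_bet
                else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("evidence").reset_index(drop=True)


@dataclass
class SubjectCurve:
    """One subject's per-contrast summary plus the interpolated betting rate
    at 75% correct."""

    subject_id: str
    experiment_id: str
    summary: pd.DataFrame
    bet_tp_at_75: float | None = None
    bandwidth: float | None = None
    extrapolated: bool = False


def subject_curve(
    dataset: BehavioralDataset,
    bandwidth: float | None = None,
) -> SubjectCurve:
    """Summarise one subject's dataset and interpolate p(bet TP) at 75%."""
    df = dataset.records
    subject = str(df["subject_id"].iloc[0])
    experiment = str(df["experiment_id"].iloc[0])
    summary = summarize_by_contrast(dataset)
    curve = SubjectCurve(subject_id=subject, experiment_id=experiment, summary=summary)
    interpolate_at_75(curve, h=bandwidth)
    return curve


# ---------------------------------------------------------------------------
# kernel regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelRegressionSpec:
    """Gaussian-kernel Nadaraya-Watson regression through (x_i, y_i)."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) == 0:
            raise ValueError("need equally many x and y, at least one point")
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth on the regressor axis."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return 0.05  # degenerate support: fall back to a tenth of the accuracy range
    return 1.06 * sd * n ** (-1 / 5)


def kernel_regress(spec: KernelRegressionSpec, x: float | np.ndarray) -> float | np.ndarray:
    """Kernel-weighted local average; invariant to kernel normalisation.

    If every weight underflows to zero (query far outside the support), the
    nearest training point's value is returned with a warning.
    """
    xi = np.asarray(spec.x, dtype=float)
    yi = np.asarray(spec.y, dtype=float)
    xq = np.atleast_1d(np.asarray(x, dtype=float))
    # max-subtracted log weights avoid underflow for distant queries
    logw = -0.5 * ((xq[:, None] - xi[None, :]) / spec.bandwidth) ** 2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    tot = w.sum(axis=1)
    out = np.empty(xq.shape)
    ok = tot > 0
    out[ok] = (w[ok] * yi).sum(axis=1) / tot[ok]
    if not ok.all():  # pragma: no cover - max-subtraction makes this unreachable
        warnings.warn("kernel weights underflowed; using nearest neighbour")
        for i in np.flatnonzero(~ok):
            out[i] = yi[np.argmin(np.abs(xi - xq[i]))]
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def interpolate_at_75(
    curve: SubjectCurve,
    h: float | None = None,
    target: float = 0.75,
) -> float:
    """Betting rate at 75% discrimination accuracy via kernel regression.

    The regression is fitted on the per-contrast summary points (accuracy ->
    betting rate), not per-trial. A target outside the observed accuracy span
    is flagged as extrapolation on the curve.
    """
    s = curve.summary
    if len(s) < 2:
        raise ValueError("need at least two contrast levels to interpolate")
    acc = s["p_correct"].to_numpy()
    bet = s["p_bet_tp"].to_numpy()
    if h is None:
        h = silverman_bandwidth(acc)
    spec = KernelRegressionSpec(x=tuple(acc), y=tuple(bet), bandwidth=float(h))
    value = float(kernel_regress(spec, target))
    curve.bet_tp_at_75 = value
    curve.bandwidth = float(h)
    curve.extrapolated = not (acc.min() <= target <= acc.max())
    if curve.extrapolated:
        warnings.warn(
            f"accuracy span [{acc.min():.3f}, {acc.max():.3f}] does not cover "
            f"{target}; interpolated value is an extrapolation"
        )
    return value


# ---------------------------------------------------------------------------
# group-level binning
# ---------------------------------------------------------------------------

def bin_across_subjects(curves: list[SubjectCurve]) -> pd.DataFrame:
    """Mean and SEM of each summary statistic in ten equal accuracy bins.

    Each subject contributes at most one value per bin (the mean of their
    per-contrast points falling in it); the SEM is across the subjects with
    data in that bin. Empty bins are kept as rows of NaN.
    """
    if not curves:
        raise ValueError("need at least one subject curve")
    stats = [c for c in CURVE_STATS if all(c in curve.summary.columns for curve in curves)]
    per_subject = []
    for curve in curves:
        s = curve.summary.copy()
        # final bin closed at 1.0
        idx = np.clip(np.digitize(s["p_correct"], BIN_EDGES[1:-1], right=False), 0, 9)
        s["bin"] = idx
        agg = s.groupby("bin")[stats].mean()
        per_subject.append(agg)
    stacked = pd.concat(per_subject, keys=range(len(per_subject)), names=["subject", "bin"])
    grouped = stacked.groupby("bin")
    mean = grouped.mean()
    sem = grouped.sem(ddof=1)
    n_subj = grouped.size()
    out = pd.DataFrame(
        {
            "bin": np.arange(10),
            "bin_lo": BIN_EDGES[:-1],
            "bin_hi": BIN_EDGES[1:],
        }
    ).set_index("bin")
    for stat in stats:
        out[f"{stat}_mean"] = mean[stat]
        out[f"{stat}_sem"] = sem[stat]
    out["n_subjects"] = n_subj
    out["n_subjects"] = out["n_subjects"].fillna(0).astype(int)
    return out.reset_index()
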