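"""Bayesian ideal observer for a two-interval forced-choice confidence task.

The observer lives in a two-dimensional signal-detection space. Evidence for a
left-tilted target of contrast ``c`` is a bivariate Gaussian sample centred at
``c * u_left``, evidence for a right-tilted target is centred at ``c * u_right``,
and a blank (target-absent) interval yields a sample from the noise
distribution at the origin. By default the two source axes are orthogonal
(``u_left = (1, 0)``, ``u_right = (0, 1)``) and the covariance is the identity.

On each trial the observer sees one sample from a source distribution (the
target-present interval) and one from the noise distribution (the
target-absent interval), but does not know which is which, nor the generating
contrast. It infers the tilt of each interval by marginalising the nuisance
contrast out of the joint posterior, takes the posterior probability of the
chosen tilt as its confidence ``p(correct)``, and bets on the interval whose
log-confidence ratio

    D = log p(S_chosen,1 | d_1) - log p(S_chosen,2 | d_2)

favours it. An optional additive Gaussian "decisional noise" term with
standard deviation ``sigma_d`` corrupts D before the bet, degrading the
metacognitive comparison without touching the tilt discriminations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

Orientation = Literal["left", "right", "none"]

DECISION_RULES = ("ideal_marginal", "hierarchical_map", "likelihood_only")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObserverConfig:
    """Generative and decisional parameters of a simulated observer.

    Parameters
    ----------
    contrast_grid
        Evidence levels (in units of the baseline noise SD) used both to
        generate target-present samples and as the support of the observer's
        discrete-uniform marginalisation prior over contrast. Zero is not on
        the grid by default: the observer is told every interval contains a
        target.
    orientation_prior
        Prior probability of the left-tilt source.
    sigma_d
        SD of the additive Gaussian decisional noise applied to the
        interval-comparison variable D.
    decision_rule
        ``ideal_marginal`` (marginalise contrast out), ``hierarchical_map``
        (first pick the MAP contrast, then discriminate conditional on it) or
        ``likelihood_only`` (compare contrast-maximised likelihoods instead of
        posteriors).
    sigma_add, sigma_mult, rho
        Covariance model Sigma(c) = s(c)^2 [[1, rho], [rho, 1]] with
        s(c)^2 = sigma_add^2 + (sigma_mult * c)^2. Defaults recover the basic
        identity-covariance observer.
    axis_angle_deg
        Angle between the left- and right-tilt source axes; 90 deg means
        orthogonal axes with means (c, 0) and (0, c).
    tie_rule
        Resolution of exact ties (D == 0, equal posteriors): ``random``
        (seeded uniform choice) or ``first`` (deterministic: left / the
        first interval).
    seed
        Root seed for the observer's own randomness (sample draws, decisional
        noise, tie breaks).
    """

    contrast_grid: tuple[float, ...] = (1.0,)
    orientation_prior: float = 0.5
    sigma_d: float = 0.0
    decision_rule: str = "ideal_marginal"
    sigma_add: float = 1.0
    sigma_mult: float = 0.0
    rho: float = 0.0
    axis_angle_deg: float = 90.0
    tie_rule: str = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.contrast_grid)
        object.__setattr__(self, "contrast_grid", grid)
        if len(grid) == 0:
            raise ValueError("contrast_grid must contain at least one level")
        arr = np.asarray(grid)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("contrast_grid values must be finite and non-negative")
        if not 0.0 < self.orientation_prior < 1.0:
            raise ValueError("orientation_prior must lie in (0, 1)")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be non-negative")
        if self.decision_rule not in DECISION_RULES:
            raise ValueError(f"decision_rule must be one of {DECISION_RULES}")
        if self.tie_rule not in ("random", "first"):
            raise ValueError("tie_rule must be 'random' or 'first'")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1) for a positive-definite covariance")
        if self.sigma_add <= 0 and self.sigma_mult == 0:
            raise ValueError("covariance is degenerate: sigma_add <= 0 with sigma_mult == 0")

    # -- geometry -----------------------------------------------------------
    @property
    def axis_left(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    @property
    def axis_right(self) -> np.ndarray:
        theta = math.radians(self.axis_angle_deg)
        return np.array([math.cos(theta), math.sin(theta)])

    def mean(self, orientation: Orientation, contrast: float) -> np.ndarray:
        """Centre of the evidence distribution for one source."""
        if orientation == "none":
            return np.zeros(2)
        axis = self.axis_left if orientation == "left" else self.axis_right
        return float(contrast) * axis

    def scale2(self, contrast: float | np.ndarray) -> float | np.ndarray:
        """Per-axis variance s(c)^2 of the (possibly contrast-dependent) covariance."""
        c = np.asarray(contrast, dtype=float)
        s2 = self.sigma_add**2 + (self.sigma_mult * c) ** 2
        if np.any(s2 <= 0):
            raise ValueError("covariance scale must be positive")
        return s2 if s2.ndim else float(s2)

    def covariance(self, contrast: float = 0.0) -> np.ndarray:
        s2 = self.scale2(contrast)
        return np.array([[s2, self.rho * s2], [self.rho * s2, s2]])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class EvidenceSample:
    """One interval's evidence pair d = (d_left, d_right) plus ground truth."""

    d_left: float
    d_right: float
    interval_role: Literal["TP", "TA"]
    true_contrast: float
    true_orientation: Orientation

    def __post_init__(self) -> None:
        if self.interval_role == "TA" and (
            self.true_contrast != 0 or self.true_orientation != "none"
        ):
            raise ValueError("target-absent samples have contrast 0 and no orientation")
        if (self.true_orientation == "none") != (self.true_contrast == 0):
            raise ValueError("orientation is 'none' iff contrast is 0")

    @property
    def d(self) -> np.ndarray:
        return np.array([self.d_left, self.d_right])


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior tilt probabilities for one interval and the induced choice."""

    p_left: float
    p_right: float
    chosen: Orientation
    confidence: float
    #: decision-rule-specific confidence score actually compared across
    #: intervals; equals ``confidence`` except under ``likelihood_only``,
    #: where it is the contrast-maximised likelihood of the chosen tilt.
    score: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.score):
            object.__setattr__(self, "score", self.confidence)


@dataclass(frozen=True)
class TrialDecision:
    """Outcome of one simulated two-interval trial."""

    D: float
    bet_interval: Literal["TP", "TA"]
    orientation_choice_tp: Orientation
    orientation_choice_ta: Orientation
    confidence_tp: float
    confidence_ta: float


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def draw_evidence(
    config: ObserverConfig,
    orientation: Orientation,
    contrast: float,
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> EvidenceSample | np.ndarray:
    """Draw evidence from the source (or noise) distribution.

    With ``size=None`` returns a single :class:`EvidenceSample`; with an
    integer ``size`` returns a ``(size, 2)`` array of draws (for Monte-Carlo
    use).
    """
    if (orientation == "none") != (contrast == 0):
        raise ValueError("orientation must be 'none' exactly when contrast is 0")
    rng = config.rng() if rng is None else rng
    mean = config.mean(orientation, contrast)
    cov = config.covariance(contrast)
    # covariance() already validates positive scale; |rho|<1 enforced in config
    if size is None:
        d = rng.multivariate_normal(mean, cov)
        role = "TA" if contrast == 0 else "TP"
        return EvidenceSample(float(d[0]), float(d[1]), role, float(contrast), orientation)
    return rng.multivariate_normal(mean, cov, size=size)


def _draws(config: ObserverConfig, means: np.ndarray, contrasts: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Vectorised correlated bivariate normal draws around per-row means."""
    n = means.shape[0]
    z = rng.standard_normal((n, 2))
    # Cholesky of [[1, rho], [rho, 1]]
    r = config.rho
    eps = np.empty_like(z)
    eps[:, 0] = z[:, 0]
    eps[:, 1] = r * z[:, 0] + math.sqrt(1.0 - r * r) * z[:, 1]
    s = np.sqrt(np.asarray(config.scale2(contrasts)))
    return means + s[:, None] * eps


# ---------------------------------------------------------------------------
# inference (vectorised core)
# ---------------------------------------------------------------------------

def _component_logliks(d: np.ndarray, config: ObserverConfig) -> np.ndarray:
    """Log p(d | S, c) for every tilt and grid contrast.

    Parameters
    ----------
    d : (n, 2) evidence array.

    Returns
    -------
    (n, 2, m) array: axis 1 indexes (left, right), axis 2 the contrast grid.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    grid = np.asarray(config.contrast_grid)
    means = np.stack(
        [np.outer(grid, config.axis_left), np.outer(grid, config.axis_right)]
    )  # (2, m, 2)
    s2 = np.asarray(config.scale2(grid))  # (m,)
    r = config.rho
    det = s2**2 * (1.0 - r * r)
    dx = d[:, None, None, 0] - means[None, :, :, 0]  # (n, 2, m)
    dy = d[:, None, None, 1] - means[None, :, :, 1]
    quad = (dx * dx - 2.0 * r * dx * dy + dy * dy) / (s2 * (1.0 - r * r))
    return -0.5 * (quad + np.log(det)) - _LOG2PI


def posterior_arrays(d: np.ndarray, config: ObserverConfig) -> dict[str, np.ndarray]:
    """Vectorised inference for n evidence pairs under the configured rule.

    Returns per-trial arrays: ``log_p_left``/``log_p_right`` (normalised
    marginal posteriors), ``choose_left`` (bool, ties unresolved -> exact
    0.5 handled by the caller's tie rule), ``log_confidence`` and
    ``log_score`` (the quantity entering the interval comparison).
    """
    ll = _component_logliks(d, config)  # (n, 2, m)
    m = ll.shape[2]
    log_prior_orient = np.log(
        np.array([config.orientation_prior, 1.0 - config.orientation_prior])
    )
    # uniform prior over the contrast grid; constant -log m cancels in the
    # normalisation but is kept so joint log-posteriors are proper
    log_joint = ll + log_prior_orient[None, :, None] - math.log(m)
    log_by_orient = logsumexp(log_joint, axis=2)  # (n, 2)
    log_norm = logsumexp(log_by_orient, axis=1)
    log_post = log_by_orient - log_norm[:, None]

    rule = config.decision_rule
    if rule == "ideal_marginal":
        choose_left = log_post[:, 0] > log_post[:, 1]
        tied = log_post[:, 0] == log_post[:, 1]
        log_conf = np.where(choose_left, log_post[:, 0], log_post[:, 1])
        log_score = log_conf
    elif rule == "hierarchical_map":
        # posterior over contrast with tilt summed out, then discriminate
        # conditional on the MAP contrast
        log_c_post = logsumexp(log_joint, axis=1)  # (n, m)
        c_hat = np.argmax(log_c_post, axis=1)
        idx = np.arange(ll.shape[0])
        cond = ll[idx, :, c_hat] + log_prior_orient[None, :]  # (n, 2)
        cond = cond - logsumexp(cond, axis=1)[:, None]
        choose_left = cond[:, 0] > cond[:, 1]
        tied = cond[:, 0] == cond[:, 1]
        log_conf = np.where(choose_left, cond[:, 0], cond[:, 1])
        log_score = log_conf
        log_post = cond
    elif rule == "likelihood_only":
        # heuristic: compare contrast-maximised likelihoods, ignoring priors
        best = ll.max(axis=2)  # (n, 2)
        choose_left = best[:, 0] > best[:, 1]
        tied = best[:, 0] == best[:, 1]
        log_score = np.where(choose_left, best[:, 0], best[:, 1])
        log_conf = np.where(choose_left, log_post[:, 0], log_post[:, 1])
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(rule)
    return {
        "log_p_left": log_post[:, 0],
        "log_p_right": log_post[:, 1],
        "choose_left": choose_left,
        "tied": tied,
        "log_confidence": log_conf,
        "log_score": log_score,
    }


def posterior_orientation(
    d: EvidenceSample | np.ndarray,
    config: ObserverConfig,
    rng: np.random.Generator | None = None,
) -> PosteriorResult:
    """Posterior tilt probabilities for one interval's evidence pair.

    The observer sees only the evidence pair, never the interval's role,
    generating contrast or true orientation.
    """
    vec = d.d if isinstance(d, EvidenceSample) else np.asarray(d, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("evidence must be finite")
    out = posterior_arrays(vec[None, :], config)
    p_left = float(np.exp(out["log_p_left"][0]))
    p_right = float(np.exp(out["log_p_right"][0]))
    if out["tied"][0]:
        rng = config.rng() if rng is None else rng
        chosen = _break_tie(("left", "right"), config, rng)
    else:
        chosen = "left" if out["choose_left"][0] else "right"
    return PosteriorResult(
        p_left=p_left,
        p_right=p_right,
        chosen=chosen,
        confidence=float(np.exp(out["log_confidence"][0])),
        score=float(np.exp(out["log_score"][0])),
    )


def decide_orientation(post: PosteriorResult) -> Orientation:
    """The tilt decision is the posterior argmax recorded in the result."""
    return post.chosen


def _break_tie(options: Sequence[str], config: ObserverConfig,
               rng: np.random.Generator) -> str:
    if config.tie_rule == "first":
        return options[0]
    return options[int(rng.integers(len(options)))]


def compare_confidence(
    post_tp: PosteriorResult,
    post_ta: PosteriorResult,
    config: ObserverConfig,
    rng: np.random.Generator | None = None,
) -> TrialDecision:
    """Bet on the interval with the higher confidence score.

    Computes D = log(score_1 / score_2) for the two intervals, adds decisional
    noise of SD ``sigma_d``, and bets on the first ("TP" slot) interval iff the
    noisy D exceeds zero. The comparison itself never consults which interval
    actually contained the target; the TP/TA labels are bookkeeping only.
    """
    for post in (post_tp, post_ta):
        if not math.isfinite(post.score) or post.score <= 0:
            raise ValueError("confidence score must be finite and positive")
    rng = config.rng() if rng is None else rng
    D = math.log(post_tp.score) - math.log(post_ta.score)
    if config.sigma_d > 0:
        D += config.sigma_d * float(rng.standard_normal())
    if D > 0:
        bet = "TP"
    elif D < 0:
        bet = "TA"
    else:
        bet = _break_tie(("TP", "TA"), config, rng)
    return TrialDecision(
        D=D,
        bet_interval=bet,
        orientation_choice_tp=post_tp.chosen,
        orientation_choice_ta=post_ta.chosen,
        confidence_tp=post_tp.confidence,
        confidence_ta=post_ta.confidence,
    )


def alternative_decision(
    post_tp: PosteriorResult,
    post_ta: PosteriorResult,
    config: ObserverConfig,
    rng: np.random.Generator | None = None,
) -> TrialDecision:
    """Interval comparison under a non-default decision rule.

    The rule is already baked into the posterior results' ``score`` fields by
    :func:`posterior_orientation` (MAP-contrast posteriors for
    ``hierarchical_map``, maximised likelihoods for ``likelihood_only``), so
    the comparison is the same noisy log-ratio test.
    """
    if config.decision_rule == "ideal_marginal":
        raise ValueError("alternative_decision requires a non-default decision_rule")
    return compare_confidence(post_tp, post_ta, config, rng)


def run_observer_trial(
    config: ObserverConfig,
    orientation: Orientation,
    contrast: float,
    rng: np.random.Generator | None = None,
) -> TrialDecision:
    """Simulate one full two-interval trial.

    Draws a target-present sample at (orientation, contrast) and a
    target-absent sample from the noise distribution, infers the tilt of each,
    and bets on the interval with higher confidence.
    """
    if contrast <= 0:
        raise ValueError("target-present contrast must be positive")
    rng = config.rng() if rng is None else rng
    d_tp = draw_evidence(config, orientation, contrast, rng)
    d_ta = draw_evidence(config, "none", 0.0, rng)
    post_tp = posterior_orientation(d_tp, config, rng)
    post_ta = posterior_orientation(d_ta, config, rng)
    return compare_confidence(post_tp, post_ta, config, rng)


# ---------------------------------------------------------------------------
# batch simulation (the workhorse for the experiment generator and model fits)
# ---------------------------------------------------------------------------

def simulate_trials(
    config: ObserverConfig,
    orientations: np.ndarray,
    contrasts: np.ndarray,
    rng: np.random.Generator,
    bet_probability: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorised simulation of many two-interval trials.

    Parameters
    ----------
    orientations : array of "left"/"right" per trial (target-present interval).
    contrasts : positive evidence level per trial.
    bet_probability
        If True, additionally return ``p_bet_tp``: the exact probability of
        betting on the target-present interval given the drawn evidence, i.e.
        the decisional noise (and tie rule) integrated out analytically. The
        sampled ``bet_tp`` draws are still returned.

    Returns
    -------
    dict with per-trial arrays: ``choice_tp``/``choice_ta`` (+1 left, -1
    right), ``correct_tp`` (bool), ``bet_tp`` (bool), ``D`` (noisy decision
    variable) and optionally ``p_bet_tp``.
    """
    orientations = np.asarray(orientations)
    contrasts = np.asarray(contrasts, dtype=float)
    n = contrasts.shape[0]
    if np.any(contrasts <= 0):
        raise ValueError("target-present contrasts must be positive")
    is_left = orientations == "left"
    means_tp = np.where(
        is_left[:, None], config.axis_left[None, :], config.axis_right[None, :]
    ) * contrasts[:, None]
    d_tp = _draws(config, means_tp, contrasts, rng)
    d_ta = _draws(config, np.zeros((n, 2)), np.zeros(n), rng)

    post_tp = posterior_arrays(d_tp, config)
    post_ta = posterior_arrays(d_ta, config)

    def _choices(post: dict[str, np.ndarray]) -> np.ndarray:
        choose_left = post["choose_left"].copy()
        tied = post["tied"]
        if tied.any():
            if config.tie_rule == "first":
                choose_left[tied] = True
            else:
                choose_left[tied] = rng.random(int(tied.sum())) < 0.5
        return np.where(choose_left, 1, -1)

    choice_tp = _choices(post_tp)
    choice_ta = _choices(post_ta)
    correct_tp = choice_tp == np.where(is_left, 1, -1)

    D0 = post_tp["log_score"] - post_ta["log_score"]
    D = D0.copy()
    if config.sigma_d > 0:
        D = D + config.sigma_d * rng.standard_normal(n)
    bet_tp = D > 0
    zero = D == 0
    if zero.any():
        if config.tie_rule == "first":
            bet_tp[zero] = True
        else:
            bet_tp[zero] = rng.random(int(zero.sum())) < 0.5

    out = {
        "d_tp": d_tp,
        "d_ta": d_ta,
        "choice_tp": choice_tp,
        "choice_ta": choice_ta,
        "correct_tp": correct_tp,
        "bet_tp": bet_tp,
        "D": D,
    }
    if bet_probability:
        out["p_bet_tp"] = bet_tp_probability(D0, config.sigma_d)
    return out


def bet_tp_probability(D0: np.ndarray, sigma_d: float) -> np.ndarray:
    """P(bet on interval 1 | noiseless D0), decisional noise integrated out.

    For sigma_d = 0 this is the indicator of D0 > 0 with exact ties at 0.5;
    for sigma_d > 0 it is the Gaussian tail probability Phi(D0 / sigma_d).
    """
    from scipy.stats import norm

    D0 = np.asarray(D0, dtype=float)
    if sigma_d == 0:
        return np.where(D0 > 0, 1.0, np.where(D0 < 0, 0.0, 0.5))
    return norm.cdf(D0 / sigma_d)


def with_sigma_d(config: ObserverConfig, sigma_d: float) -> ObserverConfig:
    """Copy of ``config`` with a different decisional noise level."""
    return replace(config, sigma_d=float(sigma_d))
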