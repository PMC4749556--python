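# Methods

## The question and the model

In near-threshold psychophysics, a classic claim is "performance without
awareness": discrimination accuracy above chance while the observer's own
confidence judgments carry no information. A bias-free way to probe this is a
two-interval forced-choice (2IFC) confidence design: each trial presents two
intervals, only one of which contains a tilted target (±45°) embedded in
masks; the participant discriminates the tilt of *both* intervals and then
bets on the discrimination they are more confident in. If betting on the
target-present (TP) interval stays at 50% while tilt discrimination is above
chance, awareness genuinely lags performance; no report criterion can fake
this.

`metabet` implements a Bayesian ideal observer of that task in a
two-dimensional signal-detection space. Evidence for an interval is a pair
d = (d_left, d_right). A left-tilted target at contrast c generates
d ~ N((c, 0), Σ); a right-tilted target, d ~ N((0, c), Σ); a blank interval,
d ~ N((0, 0), Σ). In the basic formulation Σ = I and the two source axes are
orthogonal.

The observer knows the tilt prior p(S) (0.5/0.5 by default) but not the
generating contrast, which is a nuisance variable. It forms the joint
posterior p(S, c | d) by Bayes' rule and marginalises c out over a discrete
uniform prior on its contrast grid:

    p(S | d) ∝ Σ_c p(d | S, c) p(S) / m        (m grid points)

picks the tilt with the larger posterior (Ŝ = argmax p(S | d)), and takes the
posterior of the chosen tilt as its confidence, p(correct) = p(Ŝ | d). The bet
compares the two intervals' confidences through

    D = log p(Ŝ₁ | d₁) − log p(Ŝ₂ | d₂) + ε,   ε ~ N(0, σ_d²)

betting on interval 1 iff D > 0. σ_d = 0 is the ideal observer; σ_d > 0
("decisional noise") degrades only the metacognitive comparison, leaving tilt
discrimination untouched, and drives the betting rate toward chance — the
experimental signature of performance without awareness. The comparison never
consults which interval actually held the target.

Two alternative decision rules are provided. `hierarchical_map` first picks
the maximum-a-posteriori contrast per interval (summing the tilt out of the
joint posterior) and then discriminates conditional on that estimate; it
behaves almost identically to the marginalising observer. `likelihood_only`
replaces the posterior confidences with contrast-maximised likelihoods; it is
a deliberately heuristic foil whose betting pattern deviates from the ideal
one at high contrast.

Why the ideal observer still bets below its accuracy ("performance >
awareness"): the tilt decision in the target-present interval is corrupted by
one noise source, but the interval comparison is corrupted by both intervals'
noise. On some trials the blank interval's sample happens to look more
decisive, so even a perfectly calibrated observer bets TP at, e.g., only
~0.66–0.69 when discriminating at 75% correct. This is the package's central
reproducible effect.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `contrast_grid` | evidence levels used for generation and for the observer's marginalisation prior | baseline-noise SDs | the design's 13 levels |
| `orientation_prior` | prior probability of the left tilt | — | 0.5 |
| `sigma_d` | SD of additive Gaussian noise on D | log-posterior-ratio units | 0 |
| `sigma_add`, `sigma_mult`, `rho` | covariance model Σ(c) = s(c)²·[[1, ρ], [ρ, 1]], s(c)² = σ_add² + (σ_mult·c)² | — | 1, 0, 0 (identity) |
| `axis_angle_deg` | angle between the two source axes | degrees | 90 (orthogonal) |
| `tie_rule` | resolution of D = 0 / equal posteriors | — | seeded uniform choice |

The contrast-dependent covariance is a standard additive/multiplicative
decomposition chosen here to parameterise the named model variants
(correlated noise, non-orthogonal axes, signal-dependent noise); the defaults
recover the basic identity-covariance observer exactly. Zero is deliberately
not on the observer's marginalisation grid by default: the simulated
participant, like the human one, is told every interval contains a target.
Including 0 only adds a tilt-symmetric component that rescales both
posteriors.

## The synthetic experiment

The generator emulates the reference design: 13 stimulus contrasts spanning
15–90%, two tilts, two interval orders, 10 trials per cell per session, five
sessions — 2600 trials per subject, 200 per contrast, counterbalanced exactly
and shuffled within session. Stimulus contrast is mapped linearly onto
evidence units (15% → 0.2, 90% → 4.2 noise-SD units), chosen once so that
discrimination accuracy spans roughly evenly from chance to ~100% across the
grid, which is what the original titration procedure achieved; no
psychophysical transfer function beyond this induced accuracy range matters
downstream. Blank-interval "discriminations" have no right answer and are
coded correct with probability 0.5, reproducing the task's scoring rule.

What the generator does *not* emulate: session-to-session contrast titration
(final contrast sets are taken as given), learning or feedback effects (the
second experiment's feedback, question order and blank-interval knowledge are
carried as metadata only, since observed behavior was essentially unchanged),
lapses, and reaction times. Passing tests therefore show that the analysis
pipeline recovers the properties of this stationary, lapse-free observer; they
do not certify behavior under non-stationarity.

## Analysis pipeline

Per contrast (collapsing tilt, order and session) the pipeline computes
discrimination accuracy, the TP-betting rate, Type-2 hit and false-alarm
rates (betting TP given a correct / incorrect discrimination), and accuracy
conditional on the bet. Rates with empty denominators are reported missing,
never zero. Group curves bin each subject's per-contrast points into ten
equal accuracy bins on [0.5, 1] (half-open bins, final bin closed; SEM across
subjects with data in the bin).

The betting rate at 75% correct is interpolated per subject by
Nadaraya–Watson regression with a Gaussian kernel fitted on the per-contrast
summary points. The bandwidth is not dictated by any published value; the
default is Silverman's rule-of-thumb on the accuracy axis (reported in every
output), overridable. Points are unweighted by trial count (per-contrast
counts are equal by design); count-weighting is a one-line extension left to
the caller. A 75% target outside the observed accuracy span is flagged as
extrapolation rather than silently returned.

## Model evaluation

Model predictions are Monte-Carlo over evidence draws (default 10⁴–2×10⁴
trials per contrast), but the decisional noise is integrated out analytically:
given the drawn evidence, P(bet TP) = Φ(D₀/σ_d). All σ_d grid values share a
single set of evidence draws, so differences across the grid are exact in σ_d
rather than re-simulated — a deliberate variance-reduction choice. Simulated
*subjects*, by contrast, always draw actual noisy bets.

Two fit scores are computed, both labelled reconstructions of standard
signal-detection goodness-of-fit practice rather than transcriptions of any
specific toolbox. `r_squared` is 1 − SS_res/SS_tot over the concatenated
per-contrast curve statistics (betting rate, Type-2 HR/FAR, both conditional
accuracies), SS_tot around the subject's own mean of each statistic, missing
values dropped pairwise. `multinomial_loglik` scores each trial's
(bet × correctness) outcome against the model's predicted four-category
distribution at that contrast, with category probabilities clamped to
[10⁻⁶, 1−10⁻⁶] so zero-probability categories stay finite. The two scores
rank the noise grid concordantly on synthetic cohorts (a tested property).

The decisional-noise evaluation refits every subject at
σ_d ∈ {0, 0.1, 0.2, 0.3} (a fixed grid; no continuous optimisation, and no
penalty for the extra parameter). Parameter recovery — cohorts of 12
simulated subjects at each grid value, refit and classified by cohort-mean
R² — identifies the generating value in ≳95% of replicates at the default
problem sizes (20 replicates × 4 levels × 12 subjects × 2600 trials,
predictions at 2×10⁴ trials per contrast; the whole experiment runs in about
a minute on one CPU).

## Recomputing the published tables

The packaged fixtures transcribe the two published group tables (12 per-unit
betting rates at 75% accuracy; the 12×4 R² matrix over the noise grid) at
their printed three-decimal precision, checksum-guarded. `reproduce_printed`
recomputes every summary row: means and SDs must match at three-decimal
(half-even) rounding; for the derived ratio statistics (|t|, F) the ±0.0005
rounding half-width of each printed input is propagated through the
computation, and the printed statistic passes if it lies in the attainable
interval. The one-sample |t| (printed 6.718, recomputed 6.717) passes under
that propagation. The printed repeated-measures F (19.301) does **not**: the
printed matrix yields F(3,33) = 43.086, and no un-rounding of its entries can
reach 19.301 (attainable interval ≈ [40, 46]). The published F was evidently
computed from full-precision values that were not deposited. The recomputed
main effect is, if anything, stronger (p < 10⁻⁹), so the scientific
conclusion reproduces even though the printed statistic does not; the
package reports this mismatch rather than hiding it, and the corresponding
check is expected to fail.

The repeated-measures ANOVA reports the uncorrected F on
(levels−1, (levels−1)(subjects−1)) degrees of freedom, matching the printed
df; a Greenhouse–Geisser-corrected p is available as an option. The three
units who completed both experiments are kept as independent rows, as in the
original analysis.

## Numerical choices

* All likelihood sums are computed in log space with max-subtraction;
  contrasts up to ~4 noise-SD with unit variance would otherwise underflow
  double precision in the density products.
* Ties (D = 0, equal posteriors) are measure-zero under continuous evidence
  but reachable with degenerate grids; they are resolved by a seeded uniform
  choice (or deterministically with `tie_rule="first"`), keeping every
  simulation bit-reproducible under its seed.
* One root seed per simulation; all per-trial randomness derives from a
  single `numpy.random.Generator` stream.
* Kernel-regression weights are computed with max-subtracted log weights, so
  distant queries cannot underflow to an all-zero weight vector.

## Known limitations

* The Type-2 false-alarm rate of the noiseless observer is only
  approximately flat: across the default grid the test suite measures it
  drifting from ~0.49 at the lowest contrast to ~0.41–0.45 at mid/high
  contrasts, and at the highest contrasts its estimate is inherently noisy
  (errors become rare). A band of ±0.05 around 0.5 is too strict a reading of
  "flat", and the corresponding acceptance-level check is left failing by
  design.
* R² over curve statistics is bounded above by sampling noise in the subject
  data: even the generating model scores ~0.55–0.65 on a 2600-trial subject,
  which is the regime the published per-subject values occupy.
* The fixed σ_d grid cannot distinguish noise levels between grid points; the
  package deliberately mirrors the original grid evaluation rather than
  optimising σ_d continuously.
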