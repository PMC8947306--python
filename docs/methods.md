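# Methods

This note documents the statistical procedure implemented by `tdslink`, the
choices made where the design was genuinely open, and the limits of what the
synthetic experiments demonstrate.

## From button presses to dominance curves

A TDS trial is a sequence of timestamped attribute selections closed by a
stop event.  Trial time is normalized by the stop time, so every trial maps
onto [0, 1] and trials of different durations become comparable.  On a
uniform grid of `s` instants (`Δt = 1/(s−1)`, both endpoints included) the
binary dominance indicator of an attribute is 1 at instant `t` iff the most
recent press at or before `t` selected it: a press takes effect at its own
timestamp and holds until the next press; before the first press nothing is
dominant; the stop press ends the trial without being a dominance event, so
the last selection holds through `t = 1`.  Two presses with an identical
timestamp collapse to the later one in file order (with a warning).
Averaging indicators over trials gives the dominance proportions; columns
of the unsmoothed matrix therefore sum to at most 1.

Smoothing uses a centered moving average with a window of fixed width in
normalized time (default 1/30).  The boundary rule is not standardized
anywhere, so the window simply shrinks at the curve ends rather than
inventing padding values.  Note that on the default 30-point grid a 1/30
window spans less than one grid step, so smoothing only becomes active on
finer grids or with wider windows; the default merely keeps the
configuration faithful to common practice.

Chance and significance levels for screening attributes use the standard
TDS binomial convention: `P0 = 1/k` and
`Ps = P0 + z_{1−α} √(P0(1−P0)/n)` (one-sided normal approximation), with an
exact binomial quantile available behind `exact=True`.  For tiny `n` the
normal threshold can exceed 1 and is capped just below it.  Screening is a
*report* (which attributes never exceed `Ps`); removal is left to the user.

## Bootstrap and stacking

One panel yields one curve set — only `s` instants per attribute, far too
few samples for a 14-variable CCA.  The trial set (the unit is always a
whole panel × repetition trial, never an instant) is therefore resampled
with replacement, `n` trials per draw, and the smoothed curves are
recomputed per resample; repeating this `n_sets` times gives the curve
ensemble.  Because every panelist contributes one trial per category to a
(panel, repetition) pair, the two categories are resampled **jointly**:
one index vector per bootstrap set is applied to both categories, so
cross-category dependence survives resampling.  Each set uses a
deterministic substream (set index mixed into the seed), so enlarging the
ensemble never reshuffles earlier sets.

For the trend variant each set contributes its `s` instants; the
differential variant first takes `x(t) − x(t−Δt)` (attached to `t`,
`s − 1` instants per set).  The first `n_excluded` instants of whichever
grid the variant produces are dropped per set, because almost nothing is
selected right after the start press.  With the default design — `s = 30`,
10 sets, 2 excluded, 51 trials — this yields 300/290 instants before
exclusion and 280/270 stacked rows for trend/differential.  Columns are
zero-centered **globally** across all sets (the alternative, per-set
centering, would remove real between-set level differences and make the
variates incomparable across sets); the pre-centering means are stored so
new curves can be projected consistently.

## The canonical correlation model

Given centered stacks `X` (N × p) and `Y` (N × q), the solver whitens the
within-set covariances by their inverse symmetric square roots
(eigendecomposition) and takes the SVD of the whitened cross-covariance;
singular values are the canonical correlations and the back-transformed
singular vectors the coefficients.  Contracts: `corr(u_j, v_j) = ρ_j` on
the training stack, variates of one set mutually uncorrelated, `ρ`
non-increasing, training variates unit-variance.  Signs are arbitrary in
CCA, so each pair is flipped to make the largest-magnitude `a_j`
coefficient positive.  A numerically rank-deficient within-set covariance
receives a documented ridge of `ε · trace/k` (default ε = 1e−8) with a
warning, and the fit fails if the matrix stays singular.  Coefficients are
reported both on the unit-variance-variate scale and rescaled so absolute
coefficients sum to 100 per dimension (patterns, not magnitudes, are
comparable across reports).

**Contributions.**  "Contribution of dimension j to a category" is the
variance-extracted convention: the mean over the category's variables of
the squared sample correlation between the variable and the category's own
variate `u_j` (or `v_j`).  For the full-rank smaller category the `r`
variates span its whole space, so contributions sum to exactly 1 — a useful
internal consistency check, asserted to 1e−8 in the tests.

**Dimension selection.**  Row `j` of the test table checks the null that
dimensions `j … r` all have zero population correlation, using the Pillai–
Bartlett trace `V_j = Σ_{i≥j} ρ_i²` with the standard asymptotic F
approximation on the residual problem (`p−j+1`, `q−j+1` variables,
`N−j+1` samples; `s = min`, `m = (|p−q|−1)/2`, `n = (N−p−q−2)/2` computed
on those residual sizes, `F = (df2/df1)·V/(s−V)` with `df1 = s(2m+s+1)`,
`df2 = s(2n+s+1)`).  The selected count is the number of leading
dimensions with `p < α`, stopping at the first failure.  The exact
F-approximation variant differs slightly between software packages; this
one is validated by simulation (type-I error 0.05 ± 0.03 at N = 300,
p = 8, q = 6) and against a row-shuffling permutation oracle on iid data.

**The independence caveat.**  Stacked bootstrap instants are *not*
independent: neighbouring instants of a smooth curve are strongly
autocorrelated and the same trials are redrawn across sets.  The
sequential tests treat rows as independent samples — the convention of the
analysis this package implements — which inflates significance; the
selected dimension count is best read as an upper bound.  For the related
question "are the two categories' sessions dependent at all?", the honest
null is provided by `pairing_permutation_null`, which permutes which
session of category 2 is paired with which session of category 1 and
reruns the entire bootstrap + CCA pipeline.  Row-shuffling the stacked
matrix is *not* a valid null here: two categories that share nothing but
smooth time structure would be declared dependent.

## The synthetic panel generator

`LatentPanelConfig.create` builds a paired study mirroring a realistic
small panel: 17 panelists × 3 repetitions (51 trials per category),
log-normal task durations around 30 s (σ = 0.15, so normalization is
exercised nontrivially), 8 primary-sensory and 6 multi-sensory attributes,
and a minimum dwell of about 1 s between presses.

Latent sensory episodes are smooth Gaussian bumps on normalized time
(dominance episodes in real TDS curves are unimodal); by default three
shared episodes centered at 0.15/0.5/0.85 with width 0.12 and amplitude
2.5.  Each category also owns a private bump set, and a coupling knob
`c ∈ [0, 1]` interpolates the effective latents,
`z_eff = c·z_shared + (1−c)·z_private`: at `c = 1` both categories respond
to the same episodes, at `c = 0` their sessions are statistically
independent.  An attribute's momentary intensity is
`loadings · z_eff(t) + panel effect + Gumbel(temperature)`; at renewal
epochs (minimum dwell 1 s plus an exponential extra, first press after
≈1.5 s) the panelist presses the argmax attribute if it changed.  Gumbel
noise makes selection a softmax with the configured temperature
(default 1.0); panel effects (sd 0.8) give panelists stable idiosyncratic
favourites.

Loadings give every attribute a "home" episode (strong positive loading
U(1.5, 2.5), weak N(0, 0.4) elsewhere), because a real study would already
have screened out attributes that never reach significant dominance — every
synthetic attribute must actually win sometimes for the stacked columns to
be non-degenerate, as in post-screening real data.  Dominance competition
depends on loading *differences*, so in the single-latent configuration
(where every attribute would share the same home) loadings are instead
spread over U(−2.5, 2.5) and the lone bump is broadened to width 0.25;
otherwise the episode would raise all intensities in lockstep and never
change the argmax.

`reference_curves` gives the noise-free limit: the argmax of expected
intensities, one-hot per instant, zero before the expected first press.
Empirical curves from many panelists converge to it only where the winning
margin dominates the noise scale — near episode switches and argmax
near-ties the hard reference is not the large-sample limit of the soft
selection rule, and the convergence test masks those instants.

### What the synthetic experiments do and do not show

The generator produces curves whose *temporal structure is shared across
trials* (all trials respond to the same latent episodes).  Consequently the
stacked matrices of two categories are correlated through time even at
`c = 0`, and the leading fitted canonical correlation has a high baseline
(≈0.9 at the default design) that reflects curve smoothness and the small
number of distinct instants, not session-level coupling.  The validation
experiments are designed around this: coupling recovery uses the planted
single-latent design (mean fitted `ρ_1 ≥ 0.8` across 20 seeds at ≈2000
stacked instants), the `c = 0` case is compared against the
pairing-permutation null band (exact by exchangeability), and the response
to coupling is assessed on the mean of `ρ_1` over 20 seeds.  Passing these
says the pipeline recovers planted coupling and does not invent
session-level dependence; it does not certify dimension-count calibration
on autocorrelated data (see the caveat above), and real panels add
behaviours the generator omits (learning and order effects, attribute-
button layout bias, panelist dropout, non-stationary dwell times).

## Numerical conventions

* Covariances use the `1/(N−1)` denominator throughout.
* Grid instants and event times compare with a 1e−9 absolute tolerance, so
  a press at exactly a grid instant is dominant there.
* Canonical correlations are clipped to [0, 1]; `V_j ≥ s` (all remaining
  correlations 1) maps to `F = ∞`, `p = 0`.
* `fit_cca` warns when `N ≤ p + q` (overfit regime) and on any ridge.
* Reported significance thresholds are capped at `1 − 1e−12`.
* All randomness flows from named integer seeds through
  `numpy.random.default_rng`; per-bootstrap-set and per-trial substreams
  mix indices into the seed material so results are reproducible and
  stable under enlargement.

## Problem sizes used in the validation suite

Acceptance-scale experiments run the reference design (51 trials, 10 sets,
280/270 rows), 500 replicates for the type-I calibration at N = 300, a
1000-permutation oracle at N = 60, 72 bootstrap sets (≈2000 rows) for the
recovery experiment, 20 seeds for the coupling-response means and 60
pipeline permutations per null band — sizes at which every check is stable
yet the whole suite completes in well under a minute on a laptop-class
machine.
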