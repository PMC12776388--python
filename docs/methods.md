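# Methods

## The detection problem

A cell exposed to an extracellular stimulus (here TNF, in ng/mL) must in
effect decide whether the stimulus is low (hypothesis H0) or high (H1) from a
noisy intracellular readout — the nuclear concentration of the transcription
factor NF-κB measured in single cells at one or more time points after
exposure. `cellnp` scores how well that decision can be made, in the
Neyman–Pearson (NP) sense: among all decision rules with false-alarm
probability P_FA ≤ α, the likelihood-ratio test maximizes the detection
probability P_D. No prior probabilities over hypotheses are needed; the
output is the (P_FA, P_D) operating point, the full ROC curve, or the
inverse problem (smallest P_FA reaching a target P_D).

## Statistical model

Single-cell fluorescence responses are modeled as lognormal: `y = ln(response)`
is Gaussian under each condition. For an N-dimensional readout (e.g. the
pair of time points 30 min and 4 h),

    Y ~ N(mu, Sigma)   under H0,
    Y ~ N(eta, Theta)  under H1,

with means and covariances fitted from data by the sample mean and the
unbiased (n−1) sample covariance. The estimator choice is immaterial at the
sample sizes involved (hundreds to thousands of cells per condition) and is
recorded in the fitted model's metadata.

## Canonical coordinates and the quadratic statistic

The pair is canonicalized in two steps: with `Sigma = U D U^T`, the whitening
map `D^{-1/2} U^T` sends H0 to N(0, I); the transformed H1 covariance
`C = D^{-1/2} U^T Theta U D^{-1/2}` is then rotated onto its eigenbasis
`C = V Lam V^T`. In coordinates `x = V^T D^{-1/2} U^T (y − mu)` the
hypotheses are H0: N(0, I) and H1: N(m, diag(lam)) with independent
components (`m = V^T D^{-1/2} U^T (eta − mu)`). For N = 1 this reduces to
`m = (mu1 − mu0)/sigma0` and `lam = sigma1²/sigma0²`. The log-likelihood
ratio is monotone in the quadratic statistic

    Z = sum_i [ x_i² − (x_i − m_i)² / lam_i ],

so NP decisions reduce to a single threshold z_th on Z, even though the
x-space critical region for unequal variances is quadratic (two disjoint rays
or a bounded interval in 1-D; `decision_region_1d` exposes that geometry as a
diagnostic). Eigenvalues are sorted descending and eigenvector signs fixed by
making the largest-magnitude component positive; all reported probabilities
are invariant to these conventions (tested). A coordinate is flagged
degenerate (carrying no information) only when both |lam−1| ≤ 1e−12 and
|m| ≤ 1e−12; the lam = 1, m ≠ 0 case needs no special handling because the
characteristic functions are continuous there (Gaussian limit).

## Distribution of Z: characteristic functions and Gil-Pelaez inversion

Under either hypothesis each coordinate of Z is a quadratic `a V² + b V + c`
in a standard normal V, so Z has a closed-form characteristic function: a
product over coordinates of `(1 − 2jω a_i)^{-1/2}` factors and exponential
factors (the per-coordinate radicands have real part exactly 1, so the
principal square-root branch is continuous in ω). The CDF follows from the
Gil-Pelaez formula

    F_Z(z) = 1/2 − (1/π) ∫₀^∞ Im[e^{−jωz} φ_Z(ω)] / ω dω.

Numerically the integrand is rewritten in magnitude/phase form
`ρ(ω) sin θ(ω) / ω` with closed-form ρ and θ (the canonical representation of
Z as `gamma0 + Σ w_j·ncx2(1, δ_j²) + s·N(0,1)`), and handled as follows:

- The ω → 0 limit of the integrand is the finite value E[Z; H] − z and is
  used analytically near zero.
- If a Gaussian component is present (any coordinate with lam = 1, m ≠ 0),
  ρ decays like exp(−s²ω²/2); the integral is truncated where that factor
  reaches ~e⁻⁷⁷ and evaluated by composite Gauss–Legendre with an
  oscillation-aware segment count.
- Otherwise ρ decays only polynomially (ω^{−N/2}); the integral is summed
  lobe by lobe between successive zeros of sin θ (found by bracketed
  root-finding on the monotone tail phase), with Wynn-epsilon acceleration of
  the alternating lobe series. Slow oscillation (thresholds near the phase-
  stationary point) makes individual lobes span decades of the algebraic
  envelope, so lobes are subdivided geometrically before fixed-order Gauss.
- Support bounds of one-sided quadratic forms and a Chernoff bound on the
  closed-form MGF clamp far-tail evaluations to 0/1.

Verified accuracy is ~1e−8 or better against the closed-form special cases
(Gaussian when all lam = 1; scaled central chi-square when all m = 0; scipy's
noncentral chi-square for general 1-D pairs) — far inside the 1e−4 CDF
contract — and Kolmogorov distance ≤ 0.002 against million-sample empirical
CDFs across a randomized battery.

Thresholds for target α solve `1 − F_Z(z_th; H0) = α` by Brent bisection on
the monotone CDF, bracketed by geometric expansion from the H0 mean ± 10 SD;
`pfa_at_pd` inverts the monotone ROC the same way. P_D is 1 − F_Z(z_th; H1),
consistent with the detection-region definition of the error probabilities.

## Mixed populations

For a population in which a fraction β of cells carries the A20 knockout,
each hypothesis is a two-component Gaussian mixture with the same composition
under H0 and H1 (same cells, different doses); mixing is at the cell level —
a cell is either WT or KO at both time points. The mixture likelihood ratio
has no scalar sufficient statistic, so the log-likelihood ratio itself
(computed with log-sum-exp stability) is thresholded. Error probabilities are
deterministic quadratures of the mixture densities over {LLR > log γ} on a
bounded tensor grid covering every component mean ± 8 marginal SDs (< 1e−6
Gaussian mass per tail outside; reported as `tail_bound`), with 4001 points
for N = 1 and 801 per axis for N = 2:

- N = 1: the region is resolved exactly against the piecewise-linear
  interpolant of the LLR, splitting every boundary-crossing cell
  analytically. This matters because a mixture LLR need not be monotone, so
  the boundary can cut several cells; whole-node inclusion leaves an
  O(node-mass) staircase.
- N = 2: node masses are sorted by LLR and accumulated, with fractional
  inclusion of the straddling node; the many boundary cells of a 2-D region
  have roughly canceling sub-cell errors. Agreement with million-sample
  Monte Carlo is within 3 binomial SEs, and doubling the grid changes
  results by < 5e−4 (both tested).

Thresholds are solved by bisection on the monotone map log γ → P_FA (or
P_D). When the LLR has an atom at the threshold (e.g. identical mixtures)
the target cannot be matched exactly; the conservative smaller-region point
is reported with a `conservative` flag — classical randomized NP tests are
deliberately out of scope. Dimensions above 2 are not quadrature-supported;
the Monte-Carlo estimators cover them.

## Monte-Carlo oracle

Every analytic probability has a simulation-based counterpart
(`montecarlo`): plain Monte Carlo with binomial standard errors, used in the
test suite as an independent oracle at n = 10⁶ with a 3·SE acceptance band
(~99.7% coverage), and available as the fallback for unsupported dimensions.
All draws come from numpy's PCG64; each operation derives its stream from
(seed, crc32 of an operation tag) so results are bit-reproducible and seeds
portable.

## Synthetic data generator

The paper-grade dataset this package targets (immunocytochemistry of WT and
A20⁻/⁻ mouse fibroblasts across a TNF dose panel) is not publicly deposited,
so `simulate` generates tables with the same statistical structure:

- lognormal responses; per-condition log-mean following a saturating Hill
  curve in dose, `b + A·d^h/(K^h + d^h)`. The functional form is the
  package's choice — the minimal monotone, saturating shape; real dose
  response curves are only known to be monotone with a plateau.
- dose-independent log-SD (default 0.5 everywhere), reflecting the
  observation that response SDs vary little across doses.
- defaults: doses {0.0021, 0.0052, 0.013, 0.2, 0.51, 1.3, 50} ng/mL, times
  {30, 240} min, K = 0.05 ng/mL, h = 1, n = 1000 cells/condition, seed
  20250101. WT: b = 4.0 with A = 1.5 (30 min) and A = 0.8 (4 h) — late-time
  attenuation by negative feedback. KO: b = 4.4 (upward shift from feedback
  loss) with A = 1.1 (30 min) and A = 0.6 (4 h).
- cross-time correlation of log responses rho = 0.3 by default. How paired
  per-cell two-time measurements arise from fixed-cell immunostaining is not
  something this model can resolve; the generator simply makes the
  correlation explicit and configurable (rho = 0 emulates independence), and
  the fitting layer offers an opt-in independence mode
  (`fit_gaussian_independent`) that builds a diagonal covariance from two
  unpaired selections.

All numeric defaults are calibrations chosen to encode the qualitative
orderings of interest, not measured values. The KO amplitudes in particular
were set so that the knockout's discrimination is strictly worse than WT at
*both* time points and mixture P_D decreases monotonically in β — with
KO amplitudes too close to WT, intermediate mixtures can paradoxically
discriminate worse than pure KO (the bimodal class-conditionals overlap
more), breaking the monotone β-sweep that the headline analysis displays.
A4 = 0.6 leaves a clear margin for that monotonicity.

What passing tests on synthetic data do show: the pipeline's probability
calculus is correct (closed forms, simulation cross-checks), its qualitative
orderings follow from the encoded dose-response geometry, and parameter
recovery works at realistic sample sizes. What they do not show: anything
about real NF-κB data values — real data have image-segmentation artifacts,
background subtraction noise, possible non-lognormal tails, and unknown
cross-time dependence, none of which the generator emulates.

## Numerical choices and degenerate inputs

- Covariances must be symmetric within 1e−10 and positive-definite; sample
  covariances with condition number > 1e10 raise a degeneracy error.
- Identical hypotheses (all coordinates degenerate) raise
  `DegenerateStatisticError`: Z ≡ 0 and no test exists.
- Nonpositive responses under `log_transform` follow a configurable policy:
  `drop` (default, with a mandatory logged count — immunostaining backgrounds
  can produce zeros) or `error`.
- Threshold solving: |achieved P_FA − α| ≤ 1e−5; ROC grids must be strictly
  increasing inside (0, 1); mixture thresholds meet |P_FA − α| ≤ 1e−4 unless
  flagged conservative.
- Doses are matched with relative tolerance 1e−9 (exact decimal values
  round-trip through CSV).

## Known limitations

- Gaussian (lognormal) class-conditionals only; no kernel or empirical fits.
- Mixture quadrature covers N ≤ 2; higher dimensions fall back to Monte
  Carlo estimates with sampling error.
- No Bayes/minimum-error framework with priors, no sequential or multi-class
  tests, and no randomized NP tests for atom-bearing likelihood ratios.
- The CLI's joint analysis requires wide-layout (per-cell paired) input; it
  does not estimate cross-time correlation from unpaired data.
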