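# Methods

This note records the models, estimators and design choices behind
`oifnet`, the assumptions they rest on, and what the synthetic benchmarks
do and do not demonstrate about real data.

## Inference model

The package treats causality as *predictability*: a directed interaction
score i→j measures how much species i's past improves the prediction of
species j beyond j's own past. Four estimators share one interface:

* **Transfer entropy** (`method="te"`): the directed, time-asymmetric
  information transfer, estimated plug-in on discretized series. With
  Markov orders k = l = 1 the community is assumed memoryless beyond one
  (delayed) step — the next state depends on the conditioned states only.
  The source–target delay u is applied to both the target's own
  conditioned past and the source's past (the printed form of the
  definition); `lag_target_history=False` switches to the alternative
  reading that lags only the source, with the target's past at lag 1.
* **Mutual information** (`method="mi"`): symmetric shared information,
  used both as a comparator and as the objective of the delay search.
* **Linear correlation** (`method="corr"`): the zero-lag Pearson
  coefficient; the linear baseline.
* **CCM cross-map skill** (`method="ccm_rho"`): state-space evidence via
  Takens reconstruction; the caused variable's shadow manifold encodes
  the causer, so the skill of estimating i from j's manifold scores i→j.

## Discretization and bias

Series are z-scored and partitioned into fixed bins of width r = 0.25
standard deviations anchored at zero (a box-kernel variant with max-norm
radius r is available; the histogram is the default because it admits an
exact brute-force oracle, `plugin_te_oracle`, against which the
production estimator agrees to 1e-12). Standardizing first makes the
0.25 width meaningful across abundance scales.

Plug-in information estimates on continuous data are biased upward —
severely so for the sparse 3-dimensional histograms of transfer entropy
(an independent pair at n = 10⁴ scores ≈ 0.5 bits uncorrected). Two
corrections are used, chosen to preserve the exact algebraic properties
each quantity needs:

* **TE — effective transfer entropy**: subtract the mean plug-in TE over
  source-shuffled surrogates (default 10, drawn from a dedicated seeded
  RNG so results are bitwise reproducible), clamp at zero. Shuffling the
  source destroys the directed coupling while keeping both marginals and
  the target's own dynamics, so the surrogate mean is precisely the
  no-coupling bias at the observed sample size and occupancy. This is a
  bias correction, not a significance test; no p-values are produced.
* **MI — Miller–Madow**: add the analytic (K−1)/2N occupancy correction
  per entropy term, clamp at zero. The correction is symmetric in the
  two arguments, so MI(X;Y) = MI(Y;X) continues to hold exactly at u = 0.

Both corrections can be disabled (`te_correction="none"`,
`mi_correction="none"`), which recovers the textbook plug-in values; the
oracle-equivalence and entropy-identity tests run in that mode. All
quantities are accumulated in nats and converted once at the end, so
bits = nats / ln 2 holds to the last ulp. Zero-probability cells
contribute 0 (the 0·log 0 convention).

Minimum data: estimators refuse fewer than 30 points — for MI, 30
overlapping pairs after the shift; for TE, a 30-point input window, the
same floor that defines the network resolution g below.

## Delay selection

The delay search computes MI(X(t−u); Y(t)) for each candidate u ≥ 1 and
returns the smallest u attaining the maximum (deterministic tie-break
toward parsimony), along with the information-distance profile
d = e^(−MI) with MI in nats. On explicit-lag pairs with an i.i.d. driver
the planted lag is recovered exactly; with a *deterministic chaotic*
driver the notion of "the" lag blurs, because the driver's past values
are functions of each other — the shipped lagged-pair generator
documents a case where the quadratic read-out composes with the driver's
own map and shifts the information-optimal lag by one. This is a
property of deterministic systems, not an estimator defect.

## CCM

Time-delay embedding uses E coordinates at lag tau (defaults E = 2 for
one-dimensional map benchmarks, or E chosen by univariate simplex
self-prediction over 1..10; tau = 1). Simplex projection takes the E+1
nearest library neighbors by Euclidean distance with exponential weights
w ∝ exp(−d/d₁); zero nearest distance falls back to equal weights over
the zero-distance neighbors. The predictee's own time index is always
excluded from the neighbor pool — a zero-distance self-match would make
any in-library cross-map trivially perfect — and a Theiler window
(default 0) excludes further temporal neighbors. Libraries are the first
L embedded points, so every CCM quantity is deterministic.

## Networks and diversity

Interaction matrices fill every ordered pair; pairs involving a
zero-variance (e.g. all-absent) species score 0 with a warning rather
than failing, since such species carry too little uncertainty to
transfer information. Delay policies: one fixed u (default, u = 1), a
per-pair optimum, or a single community-wide u maximizing the mean MI
profile across pairs. Normalization floors negatives at zero (CCM ρ can
be negative; interaction magnitudes are presented on a [0, 1] scale) and
min–max rescales the off-diagonal.

Dynamical networks re-estimate the matrix per time window at resolution
g = 30 points (60 weeks at biweekly sampling): expanding windows [0, t)
by default, or sliding fixed-length windows. Taxonomic α of a window is
the count of species with any strictly positive abundance; effective α
at threshold θ counts species with at least one incident directed link
(in or out — the "either" rule, configurable) of normalized strength
≥ θ, zero-valued entries never counting as links. The threshold search
scores the effective-α series against the taxonomic series at zero lag
(correlation, or plug-in MI on the integer counts) over a grid that must
include the reference operating points 0.2 and 0.3, and returns the
smallest maximizing θ.

Two structural facts about this machinery are worth knowing. Under
expanding windows the taxonomic series is a non-decreasing step function
(a species once seen stays counted), which typically renders it constant
and the agreement criterion degenerate — threshold optimization is
therefore best run on sliding windows, and the shipped evaluation does
so. And at θ = 0 the effective count equals the number of species with
any nonzero link, which on noisy estimates tracks the number of species
with any data — so a θ* of zero legitimately means "no thresholding
needed to track richness" for that system.

## The synthetic community

`maizuru_like_params` emulates the statistical structure of a biweekly
multi-species coastal census: 15 species, 285 time points, a minority of
strongly interacting dominant species, a majority of weak interactors,
zero-inflated rare taxa, and a shared annual environmental cycle.
Concretely: a multiplicative logistic map generalized to S species
(latent states clipped to [1e-6, 1]), a directed ring of strong
couplings (β ~ U(0.45, 0.6)) through a six-species core, a weak chain
(β ~ U(0.08, 0.15)) through most of the periphery leaving two species
truly uncoupled, growth rates U(3.6, 3.9) (chaotic regime), seasonality
as a shared sinusoidal modulation of the growth rates (amplitude 0.03,
period 26 samples = one year), lognormal observation noise (sd 0.01),
and three rare species whose occupancy follows a persistent two-state
chain (mean run 20 samples) with additional within-run dropout.

These choices were calibrated to the benchmark's purpose and fixed
before the evaluation suite was written, and several of them encode
genuine findings about the method's operating envelope:

* **Sparse strong coupling.** Densely reciprocally coupled cores entrain
  onto near-period-2 orbits (lag-1 autocorrelation ≈ −0.9), destroying
  the chaotic variability that carries detectable information flow. Real
  strong interactions that stabilize dynamics would be equally invisible
  to any predictability-based method.
* **Seasonality in the dynamics, not on the observations.** A shared
  multiplicative seasonal factor applied to the *observations* both
  scrambles the fine symbolic structure the binned estimator relies on
  and induces spurious common-driver dependence between non-interacting
  species; at 285 samples this overwhelms the planted signal at any
  amplitude ≥ 0.05. Growth-rate modulation is the more mechanistic
  reading of environmental forcing and keeps the map exact.
* **Low observation noise.** One-step chaotic-map couplings at 285
  samples are undetectable by binned TE beyond roughly 2–3%
  multiplicative observation error — chaos amplifies measurement noise
  into the conditioning variables. Real censuses are noisier but also
  have smoother (autocorrelated) dynamics, which are more noise-robust;
  passing benchmarks here therefore demonstrates correctness of the
  machinery, not noise robustness on field data.

## Evaluation problem sizes

The shipped evaluation uses 1000-step map runs (800 for coupling-grid
scans), n = 5·10⁴ for the Gaussian VAR comparison (10⁶ for the
regression cross-check of the closed form), 20 seeded replicates for the
noisy delay-recovery and direction-sensitivity rates, and sliding
windows with step 5 (52 windows) and 5 shuffle surrogates per TE for the
dynamical-network benchmark — enough windows for stable agreement
statistics while keeping the 15-species × 52-window × 210-pair
computation modest.

## Known limitations

* Bivariate scores only: no conditioning on third species, so indirect
  links are reported as inferred (no redundancy removal by design), and
  common forcing can masquerade as interaction.
* The plug-in-with-surrogate estimator targets bias, not variance; on
  30-point windows individual pair scores remain noisy and only
  aggregate quantities (α counts, threshold curves) are stable.
* The Gaussian closed form assumes a correctly specified VAR(1); it is
  an oracle for testing, not a general-purpose estimator.
* Kraskov-style nearest-neighbor estimators, surrogate-based
  significance testing, and β-diversity are out of scope.
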