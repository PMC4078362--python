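# Methods

This note records the model, the numerical choices, and the judgement calls
behind `zoomfit`, in the order the pipeline uses them.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Experimental design

Designs are plain Latin hypercubes: each parameter's current range is cut
into *n* equal-width strata, one uniform draw is taken per stratum, and the
per-parameter columns are permuted independently.  No space-filling
optimisation (maximin, Sobol) is applied — the loop resamples every
iteration, so design optimality buys little, and plain LHD keeps the
stratification property exactly testable.  A single integer seed governs a
run; per-iteration and per-purpose seeds are derived from it
deterministically, so a `(config, seed, simulator)` triple fixes every
artifact.

Degenerate ranges (lower = upper) are legal: the column is constant and a
warning is emitted.  A range that *collapses* during zooming is re-opened
by ε = 10⁻⁹·max(1, |value|).

## Output metrics

A simulation is reduced to 33 numbers: five twitch descriptors and six
force–pCa descriptors at each of λ = 0.9, 1.0, 1.1 (cell length relative
to resting length).

Twitch conventions, where the literature leaves latitude:

* **TTP** is measured from the first sample of the record; the stimulus is
  assumed at t = 0.  (Onset detection on noise-free simulated transients
  would add a threshold parameter for no benefit.)
* **RTx** is the first time after the peak at which tension falls to
  `Peak − x/100·(Peak − Min)`, with `Peak` and `Min` taken from the same
  record; crossings are located by linear interpolation between samples.
  An RTx never reached within the record is NaN and flags the row as
  incomplete.
* A flat record (amplitude ≤ 10⁻⁹ kPa) has no defined twitch metrics and
  fails the row.

Force–pCa conventions:

* pCa = −log₁₀([Ca] in mol/L).  The Hill linearization is
  y = log₁₀(F/(1−F)) with F normalized by the maximal simulated tension
  over the full concentration series (including the saturating 10 µM
  point), so |Slope| of the OLS line is an apparent Hill coefficient.  The
  log base is a convention; it scales Slope/Intercept and nothing else.
* Rows with (1−F) < 10⁻³ or F ≤ 0 are removed before the fit (log
  blow-up at saturation); fewer than 4 surviving rows is an error.
* **RMSDforce** is the RMS difference between the max-normalized simulated
  and target force curves in *standardized* variables: each pCa grid point
  is a variable, standardized by mean/SD over the **first iteration's
  batch**, and that scaler is frozen for all later iterations.  Freezing
  matters: standardizing by the *current* batch makes the success
  threshold self-normalizing (the batch contracts around the target, its
  SD shrinks, and the bar tightens in proportion — the criterion can then
  never be met).  Grid points with no batch spread contribute raw
  differences.

## Metamodels

All regressions standardize both blocks column-wise (sample SD, n−1; that
convention is what reproduces the bundled tables' printed SD columns).
Zero-variance columns — judged against a relative floor of
10⁻¹²·max(1, |mean|), since a constant column's floating-point SD is not
exactly zero — are dropped from modelling and restored to their mean on
inverse transform.

**PLSR** is sequential NIPALS with X-deflation; with as many components as
the rank of X it coincides with ordinary least squares (asserted against a
`lstsq` oracle, and cross-checked against scikit-learn's PLSRegression).
Component count:

* `ncomp="max"` (the pipeline default): min(p, n−2), the maximal
  supportable complexity.  The responses of a deterministic simulator are
  noise-free, so the classical overfitting argument for truncation does
  not apply; held-out accuracy on the bundled system increases
  monotonically up to full rank, while cross-validated PRESS — whose folds
  must fit on fewer rows than the final model — is biased toward far too
  few components and materially degrades the identifiability readout.
* `ncomp=None`: 10-fold CV, minimum PRESS with a one-standard-error
  parsimony rule, capped at min(n/3, p, n−2) — the right default when the
  responses carry measurement noise.

**Classical (sensitivity) metamodel**: standardized parameters are
expanded with squares and pairwise cross-terms (p → 2p + p(p−1)/2) and
regressed against standardized metrics; the standardized coefficient
magnitudes are the sensitivity measures, complemented by the Pearson
matrix over [parameters, metrics].

**Inverse metamodel (HC-PLSR)**: expanded standardized *metrics* predict
parameters.  A global PLSR is fitted; fuzzy C-means (Euclidean, fuzzifier
m = 2, tolerance 10⁻⁸, ≤ 500 iterations, deterministic per seed) clusters
its X-scores; one local PLSR is fitted per cluster on the hard-assigned
(dominant-membership) rows; prediction combines local predictions weighted
by the new point's fuzzy memberships (hard-max routing is a config
option).  Membership weighting at prediction with hard assignment at
fitting keeps small local fits well-posed.  Clusters below the minimum
size (default 10 rows) are merged into their nearest neighbour.  With
c = 1 the global model *is* the single local model, so HC-PLSR reduces to
PLSR exactly.

The cluster count is auto-selected by default: each candidate
(1, 2, 4, 8) is scored by mean test-set r² and the smallest count within
1% of the maximum wins.  This is the procedure a practitioner would run
anyway; at small design sizes it correctly refuses clusterings whose local
models would have to interpolate hundreds of regressors from a dozen rows.
A fixed count remains one config assignment away.

**Identifiability** is the squared Pearson correlation between simulated
and predicted parameter values on a random held-out third of the runs
(degenerate predictions score 0).  The screen is strict: r² must *exceed*
0.70 for a parameter's metamodel prediction to be used.

## Look-up and zooming

Distances to the target are measured in PCA score space: simulations and
target are stacked (the target participates in the standardization and the
PCA by default; simulations-only scaling is an option), and the RMSD over
the minimal set of components explaining 99% of the variance is divided by
that component count.  Ties in the ranking break by ascending row index.

The guideline set is the 20 nearest simulations' parameter vectors, plus —
first iteration only — the inverse-metamodel prediction at the target,
with unscreened entries filled by the mean of the 20 nearest rows and the
whole row clamped to the hard constraints.  Twenty is a deliberate balance:
enough zoom to make progress, enough spread to keep alternative feasible
regions alive.

New ranges extend the guideline hull by |column mean| / stepsize on each
side.  The division (not multiplication) is what makes a growing stepsize
*strengthen* the zoom, and the absolute value keeps the extension outward
for negative-valued parameters.  The stepsize schedule: start 4; +2 after
an iteration whose minimum RMSD beat the previous iteration's (strict
decrease), capped at 20; at the cap, a non-improving iteration backs off
by 2; below the cap, a non-improving iteration leaves it unchanged.

Success criteria are declarative clauses on named metrics: printed
intervals ("a–b", "between a and b") are closed, "less than" caps are
strict, and a missing referenced metric fails the clause with a flag.  The
loop stops as soon as one simulation passes everything (all passers are
collected) or at the iteration cap (default 25), returning the full audit
trail either way.  Rows whose simulation failed are dropped, not imputed;
an iteration with more than 50% failures aborts with per-row diagnostics.

## The bundled synthetic system

The synthetic module exists so the whole pipeline is testable with known
ground truth; it emulates the *shape* of the real problem, not its
biophysics.

* **Calcium transient**: C(t) = diastolic + A·(e^(−t/τd) − e^(−t/τr)),
  normalized so the grid maximum equals the configured peak.  Defaults —
  diastolic 0.1 µM, peak 1.0 µM, τ_rise 5 ms, τ_decay 20 ms, 160 ms at
  0.5 ms — give the fast, high-peak transient of mouse myocardium at
  body temperature.
* **Twitch model**: two linear relaxation stages,
  db/dt = k_off·(H(Ca(t)) − b) and dF/dt = α_r·(Fmax(λ)·b − F), with
  H a Hill function with coefficient nH and half-activation
  Ca50(λ) = Ca50ref·(1 + β₁(λ−1)), and Fmax(λ) = Tref·(1 + β₀(λ−1)).
  Both stages are integrated with an exact exponential step under
  piecewise-linear forcing (machine-precision for the sampled transient,
  no stiffness issues, vectorizable over whole designs).  The steady-state
  force–pCa curve is exactly Hill in closed form, which makes the metrics
  path verifiable to closed form: |Slope| recovers nH to 10⁻² (the
  residual distortion is the max-normalization at the 10 µM point).
* **Ground truth**: Ca50ref 0.5 µM, nH 5, k_off 0.15 ms⁻¹, α_r 0.08 ms⁻¹,
  Tref 120 kPa, β₀ 1.65, β₁ −1.5 — mouse-plausible demo values producing
  TTP ≈ 32 ms, RT50 ≈ 21 ms, Peak ≈ 85 kPa at resting length.  A
  **vestigial** parameter is carried in the parameter vector but never
  read by the equations: it is the built-in negative control for the
  identifiability machinery.
* **Initial ranges / constraints**: ranges bracket the truth generously
  (e.g. nH ∈ [2, 9], Tref ∈ [100, 140]); hard bounds encode the model's
  validity domain and a-priori physiology (nH ∈ [1, 15], Tref ∈ [90, 140],
  β₀ ∈ [0, 6], β₁ ∈ [−8, 0]).  The β bounds are not cosmetic: outside
  them the length-adjusted Ca50 or Fmax can turn non-positive, and an
  unconstrained zoom can walk there; rows that do fail individually.
* **Success bands** mirror the relative widths of published mouse twitch
  error bars: ±25% on RT50/RT90/TTP/Peak at λ = 1.0, ±10% on Peak at
  λ = 1.1, ±20% on Peak at λ = 0.9, an absolute Min < 1 kPa at λ = 1.1,
  and RMSDforce < 0.15 at each length.

What passing on this system does and does not show: the toy model is
smooth, noise-free, low-dimensional and exactly Hill at steady state, so
recovery there demonstrates the *machinery* (design, metrics, metamodels,
zooming, screening) — not robustness to measurement noise, stiff dynamics,
simulation failures at scale, or metric extraction from raw experimental
recordings, all of which belong to the user's simulator and data pipeline.

## Scaled problem sizes

The documented experiments use 200-run designs, ≤ 10 iterations and five
seeds — sizes chosen so the full recovery and reduction studies run in
about two minutes on a single core while leaving every mechanism
(screening, zooming, stepsize adaptation, variant comparison) exercised.
A production fit of a real contraction model would typically use 500-run
designs and a fixed 8-cluster inverse metamodel; both are single config
fields (`design_size`, `n_clusters`).

## Known limitations

* NIPALS with missing data is not implemented; rows with missing metrics
  are excluded from metamodel fits and from the distance ranking.
* The FCM fuzzifier is fixed (m = 2) rather than selected.
* Parallel simulation execution is left to the simulator's own batch hook;
  the pipeline itself is serial.
* The distance is a plain RMSD in PCA scores; the config hook for
  alternative weightings exists (the criteria are declarative), but no
  bespoke clinical weighting ships.
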