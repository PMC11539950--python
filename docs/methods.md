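# Methods

## Model and procedure

The package works with the standard IV skeleton.  Data are n i.i.d. rows of
covariates X, proposed instruments Z (q ≥ 1 columns), a treatment t and an
outcome y.  Unobserved confounders may affect both t and y (here through
correlated errors); an unobserved *mediator* of Z in y is what disqualifies
an instrument.

Both stages are general additive models: a linear coefficient vector over a
declared list of (possibly nonlinear) features.  The three designs are

* `X_t` — stage one, features of (X, Z), fitted to t by least squares;
* `X_y` — stage two, features of (X, t̂) only; a raw Z column is rejected at
  construction time, since a direct instrument term in the outcome model
  contradicts the definition of a valid instrument;
* `X_r` — the remainder model, features of (X, Z), used by the validity
  check.

The constrained two-stage estimator solves

    min_β ‖y − X_y β‖²  s.t.  rᵀ H r ≤ ε′,  r = y − X_y β,
    H = X_r (X_rᵀ X_r)⁻¹ X_rᵀ,

whose constraint says: the best least-squares prediction of the remainder
from the declared (X, Z) features may undercut the zero model's loss by at
most ε′.  Because rᵀHr is the squared norm of r's projection, the problem is
a convex QCQP.  The solver is exact, in three steps: (1) if the
unconstrained OLS solution satisfies the constraint, return it (status
`inactive`); (2) otherwise minimize the constraint itself — a reduced
least-squares problem in the orthonormal basis of col(X_r); if even that
minimum exceeds ε′, no model is feasible (status `infeasible`, the
instrument is flagged); (3) otherwise the optimum is on the boundary
(status `active`) and solves (A + λB)β = a + λc for the unique λ ≥ 0 at
which the constraint equals ε′; the constraint value is monotone along this
path, so the multiplier is found by bracketing (decade expansion) plus
Brent root-finding.  Convexity makes the KKT point the global optimum, so
no tie-breaking among stationary points arises.

The one-stage estimator minimizes the same outcome loss jointly over
(ω, β), replacing the fixed first stage with a Rashomon-set constraint
‖t − X_t ω‖² ≤ baseline − ε, where the baseline is the best covariates-only
stage-one loss (the same anchor the relevance check uses) and ε defaults to
5% of it.  It is solved by block-coordinate descent: the β-step is the
exact QCQP above; the ω-step is projected (exact-gradient where t̂ enters
linearly, finite-difference otherwise) descent, with projection onto the
Rashomon ellipsoid done by the same secular-equation machinery.  Multi-start
always includes the two-stage solution; every reported point is re-verified
against both constraints independently of the solver.  Note the joint
optimum generally *improves* on the sequential two-stage objective — the
Rashomon set gives stage one freedom to trade a little treatment fit for
outcome fit — so one-stage and two-stage coefficients coincide only when
the Rashomon set collapses onto the stage-one optimum (ε at its maximum).
The block scheme guarantees a non-increasing objective but not global
optimality of the joint nonconvex problem; restarts are the mitigation.

## Tolerances and calibration

* γ (default 0.01 at n = 1000): relative validity tolerance.
  ε′ = γ · ‖r̃‖², with r̃ the remainder of the *traditional unconstrained*
  two-stage fit with the same designs.  γ is a pure number; ε′ carries the
  squared units of y.  No automatic scaling of γ with n is attempted — how
  the tolerance should shrink with sample size is an open modelling
  question, so the value is always explicit.
* Relevance ε (default 5% of the covariates-only loss): the instrument must
  cut the stage-one loss by at least this much.  A failed relevance check is
  reported, not raised.
* Feasibility is decided with slack `cv ≤ ε′(1 + 1e-8) + 1e-12`; `active`
  means the constraint holds with equality inside that band.  The
  feasibility taxonomy distinguishes active from inactive exactly; floating
  point needs the band.
* Least squares is always solved through SVD/QR factorizations, never by
  inverting normal matrices; rank is decided at 1e-10 of the leading
  singular value because polynomial designs (z, z², z³) are strongly
  correlated.  Hat matrices are kept in factored form (an orthonormal basis)
  and materialized densely only for n ≤ 5000.

## Intercept conventions

Where intercepts live is not a cosmetic choice here:

* The **stage-one** fit is affine (intercept on by default).  With a
  misspecified first stage the omitted nonlinearity has a nonzero mean
  (E[z²] = 1), and an intercept-free stage one would fold that mean into
  the remainder in a way that overstates the check's signal.
* The **stage-two** design is exactly (features(X), t̂), with no free
  constant.  t̂ carries stage one's intercept through, so no location fit is
  lost — but a *free* stage-two constant would add one dimension to X_y,
  and whenever dim(X_y) reaches rank(H) the constraint minimum becomes
  identically zero: the validity check would be blind by construction.
* The **remainder model** is the exact span of the declared X_r features,
  no intercept: the null model of the check is the zero function, and the
  comparison is meaningful only if the competing class consists of the
  stated instrument/covariate features alone.  (A free constant would let
  the class beat the zero model whenever the remainder has nonzero mean,
  regardless of the instrument.)

Feature normalization (z-scoring) is available (`standardize`,
`normalize=` in the design builder) and makes the relative quantities
scale-free; the simulation studies run on the raw feature scale, where the
loss ratios are already scale-invariant for linear classes.

## Synthetic designs

All generators share x ~ N(0,1), z ~ N(0,1), (e1, e2) bivariate normal with
unit variances and correlation ρ = 0.8 — the correlated errors are the
unmeasured confounding.  Substreams of one seed drive x, z and the errors
separately, so signal parameters (φ, π) can change without changing the
noise; conditions are pairwise comparable draw by draw.

* valid: t = x + z + z² + e1, y = x + t + e2.
* non-instrument: y gains φ·m(z) with mediator m(z) ∝ z³.  By default the
  mediator is scaled to unit variance (m = z³/√15), so φ is the mediator's
  contribution to y in standard-deviation units and is comparable with the
  unit-variance error e2; `mediator_scale="raw"` uses z³ unscaled.  The
  mediator column is never exposed in the dataset — it is unknown to the
  analyst by construction.
* robustness: t = x + π·f(z) + e1, y = x + β·t + e2, with β = 1 and f one
  of z², z³, exp(z), log|z|, √|z|, logistic(z).  The estimating designs are
  polynomial regardless of f, which is the point: the estimator must be
  robust to not knowing the true nonlinearity.

What these designs do *not* emulate: heteroskedastic or heavy-tailed
errors, multi-dimensional observed confounders, weak-overlap regimes, or
mediators that also affect the treatment.  Passing the simulation studies
therefore says the machinery is correct under clean Gaussian conditions,
not that detection power generalizes to arbitrary real data.

## Study problem sizes

The identification studies run 1000 replicates per condition at n = 1000
per replicate (γ = 1% with the strong mediator φ = 1; γ = 0.1% with the
weak mediator φ = 0.1).  The misspecification ratios are reported as
medians over 11 independent n = 1000 datasets: the single-draw "true
percentage" moves by ±3 points from seed to seed, and the median pins the
center of that distribution without touching the per-dataset procedure.
The robustness study uses 200 replicates per (f, π) cell, π on a grid from
0.1 to 1 in steps of 0.05; the constrained estimator's summaries are over
the replicates it accepts (infeasible replicates are excluded and counted).
The feasibility-taxonomy suite draws 500 instances per model-class cell at
n = 160 with γ log-uniform in [1e-4, 10^-1.5], alternating valid and
non-instrument draws, with X_r = X_t and no intercepts so the taxonomy's
standing setting holds exactly.

## Design choices that were genuinely open

* The Rashomon baseline compares stage one against the best covariates-only
  model, mirroring the relevance check's anchor.
* When the two-stage problem is infeasible there is no constrained
  remainder; the validity report is then computed post hoc on the
  traditional remainder r̃, which is also what the misspecification tables
  show.
* The robustness study's constrained estimates use the constrained variant
  per replicate (not a post-hoc accept/reject of the traditional fit); a
  replicate that is infeasible contributes to the exclusion count instead.
* The unit-variance default for the mediator makes φ interpretable against
  the unit-variance structural errors and keeps the weak-mediator regime
  (φ = 0.1) genuinely borderline rather than trivially detectable; the raw
  z³ variant (variance 15) is retained for moment-level checks.

## Known limitations

* The validity check is necessary, not sufficient: a mediator orthogonal to
  the declared remainder features (e.g. a pure Hermite H₃ component when
  X_r stops at z²) is invisible to it.
* Squared loss only; binary treatments are handled by the same least-squares
  machinery, which is a linear-probability approximation, and no
  general-loss (e.g. logistic) variant of the constraint is provided.
* No standard errors or confidence intervals for β are computed; the
  robustness study's bands are empirical quantiles across simulation
  replicates.
* The one-stage solver certifies feasibility and monotone descent, not
  global optimality.
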