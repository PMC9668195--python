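# Methods

This note records the modelling choices, numerical conventions and known
limitations of `barknarx`, in the order the data flows through the package.

## Data model and units

One row of input is one stem section: tree id, species, total height `H`
(m), section height `Hb` (m), outside-bark diameter `DOB` (cm; the mean of
two perpendicular caliper readings when both are supplied) and two
perpendicular bark-gauge readings `k1, k2` (cm). Units are fixed — no
auto-detection — because silent unit coercion is the classic failure mode
with mixed cm/m forestry tables. Hard invariants (non-negative readings,
`k1 + k2 < DOB`, strictly ascending `Hb`) reject a file; soft checks
(per-species plausibility ranges, `Hb > H`) only flag. Sections above the
nominal total height are kept with a warning: tape-measured section heights
and the independently measured total height can legitimately disagree by a
few decimetres, and dropping such rows would change the sample counts.

## The flattened series

Sections are ordered tree-by-tree, trees in dataset order and sections from
the stump upward, giving indices `k = 1..K`. The distance to the top
`DTT = H − Hb` strictly decreases within a tree, so the series is a train
of descending ramps restarting at every tree boundary. By default the
recurrent model's delay window runs straight across tree boundaries,
treating the data as one continuous record; a `boundary_reset` option drops
windows that straddle two trees. Boundary samples are genuinely
unpredictable — the window then holds the previous tree's tip while the
target is a new tree's stump, whose diameter the inputs do not contain —
and this is the dominant term in the network's whole-series error on
synthetic data (see "What the tests show" below).

Scaling is linear Min–Max to [0, 1] per variable (`avg_d`, `DTT`, `DBT`),
fitted by default on the pooled train+validation portion; fitting on the
training split alone is available for leakage-free workflows. A constant
variable is an error, not a silent divide-by-zero. Out-of-range values at
prediction time extrapolate linearly.

The 70/15/15 split assigns *samples*, not trees, to partitions, because the
reference per-sample counts are only consistent with sample-wise
assignment; a tree-wise split is provided for statistically cleaner
workflows. Split sizes are deterministic: validation and test each get
`floor(0.15 K)` samples and training the remainder. This rounding
reproduces the reference counts for both species exactly — 1288/276/276 at
K = 1840 and 8258/1769/1769 at K = 11796 — whereas flooring the training
fraction would give 8257 in the second case.

## The NARX network

Architecture `2(d)-h-1`: the hidden layer sees `3d` scaled regressors
(two exogenous variables and one delayed target per delay step, `N = M =
d`), logistic sigmoid hidden units (a tanh option exists; logistic pairs
naturally with [0, 1] scaling), linear output. Training and default
evaluation are open-loop (series–parallel): delayed targets come from
measurements. Closed-loop prediction — feeding the model its own past
outputs after priming the first `d` positions — is available and labelled
in reports, since recursive evaluation degrades differently and the
reference evaluation mode is not documented.

Initialization is Nguyen–Widrow: each hidden unit's input-weight row is a
random direction scaled to norm `0.7 h^(1/n)`, biases spread evenly over
`[−β, β]`, output layer small-uniform, all determined by the seed.

Optimizers (all operating on scaled-space training error, all
deterministic given seed/data/config):

- **LM** — damped Gauss–Newton on the full residual Jacobian. Initial
  damping 1e−3, ×10 on a rejected step, ×0.1 on an accepted one, stop at
  damping 1e10 or gradient ∞-norm below 1e−10. Early stop after `patience`
  (default 6) consecutive validation failures; the best-validation weights
  are returned.
- **BR** — Bayesian regularization: LM steps on `β E_D + α E_W` with
  MacKay's evidence updates after every accepted step, using the
  Gauss–Newton Hessian approximation for the effective parameter count
  `γ = P − α · tr(H⁻¹)`. BR trains on the pooled train+validation samples
  with no early stop, and its validation cells are *reported as zero* — a
  reporting convention of the reference tables that the package reproduces
  deliberately, not a measured error.
- **SCG** — Møller's scaled conjugate gradient (σ = 5e−5, initial
  λ = 5e−7, no line search, conjugacy restart every P iterations), with the
  same validation early stop as LM.

Reported per-split MSE and Pearson R are computed in original units (cm)
after inverse scaling, from open-loop prediction over the whole series;
the first `d` priming positions are excluded from every metric.

The protocol of training many restarts and reporting one chosen uniformly
at random is kept (default 10 restarts in tests and examples, 100 behind
the CLI's `--full` switch); restart mean/sd of the training error are
reported alongside.

## Polynomial baselines

`STAT1` and `STAT2` as in the README; the quadratic term is `(Hb/H)²` in
both models, and the `STAT2` quotient `ρ` is the inside/outside-bark
diameter ratio at breast height, taken from the 1.3 m section (exact match
within 1e−6 m; linear interpolation between flanking sections only behind
an explicit flag, because the protocol guarantees a 1.3 m measurement).
Negative predictions are returned as-is — clamping would silently distort
RMSE comparisons — with clamping available as explicit post-processing.
Refits are ordinary least squares (the models are linear in coefficients),
with standard errors from `(XᵀX)⁻¹ s²`; a rank-deficient design raises.

## Comparison statistics

`ME = Σ(obs − pred)/K` fixes the sign convention: positive means the model
underestimates. EF defaults to the conventional observed-mean denominator
(bounded by 1, zero for the constant predictor at the observed mean); the
variant normalizing by the *predicted* series' spread is kept selectable
because both conventions circulate, and reports carry both values so either
can be matched. RMSE² equals the trainers' MSE by construction.

## Synthetic generator

The generator emulates the measurement protocol, not any particular forest:
section heights {0.0, 0.5, 1.3, 2.0, 4.0, …} ∩ [0, H); per-tree total
height and breast-height diameter drawn uniformly inside the published
per-species ranges (pine H ∈ [18.3, 32.7] m, DBH ∈ [15, 52] cm; oak
H ∈ [13.9, 35.9] m, DBH ∈ [12, 85] cm); a strictly decreasing power-law
stem profile anchored at breast height with per-tree exponent U(0.6, 1.0).
Sections whose diameter falls below the species' smallest published
diameter (pine 0.60 cm, oak 0.25 cm) are not measured.

Bark truth comes from a declared mechanism: a polynomial taper (printed or
user coefficients; the `STAT2` breast-height quotient is resolved by a
closed-form fixed point, since the model is linear in the breast-height
bark), or a known NARX network run closed-loop along the flattened series.
The default truth network is constructed, not trained: each hidden unit
reads mainly one input channel with positive gain, and positive output
weights keep the scaled output inside (0.1, 0.65), so generated bark is
always positive, below the diameter, and genuinely responsive to diameter,
height and its own past. For the network truth the minimum measured
diameter defaults to 4 cm so the bark-inside-stem invariant holds by
construction.

Observations: `k1,2 = DBT/2 · (1 ± a) + N(0, σ)`, with directional
asymmetry `a` = 10% of DBT by default (bark is systematically thicker on
one side of a stem), then quantized to the gauge resolution and floored at
the species' smallest recorded reading. The gauge quantum defaults to
0.01 cm rather than the instrument's nominal 0.1 cm because the published
bark minima (0.05 cm) are finer than a 1 mm gauge; both are selectable.
Sections violating `k1 + k2 < DOB` redraw their noise (up to 100 times)
and an unsatisfiable profile raises. Default noise σ = 0.1 cm per reading,
i.e. a √2·0.1 ≈ 0.14 cm noise floor on DBT.

Recovery studies use a raised diameter floor (8–10 cm) so the generated
bark stays far from the gauge floor: censoring at the floor would otherwise
bias the refit intercept by a fraction of a standard error. The noiseless
variant (`noiseless(profile)`) switches off noise, asymmetry, quantization
and flooring together.

## Problem sizes and determinism

Tests and the acceptance script run at reduced sizes chosen to keep the
statistical conclusions stable: 30–170 trees (≈ 400–2500 sections),
10 hidden units for recovery studies, 2–10 restarts, and 20 replicates for
the noisy-refit study. The acceptance script's quantities are reproducible
from its `--seed` alone; every random draw in the package flows from an
explicit `numpy` generator seed, and identical (seed, data, config) give
bit-identical training reports.

## What passing tests do and do not show

Synthetic data is smooth by construction: real bark is rough, irregular and
autocorrelated in ways no low-dimensional truth mechanism reproduces, so
recovery results demonstrate the *correctness of the machinery* (the
optimizers find the generating model; the refits are unbiased at the
declared noise), not field accuracy. On polynomial-truth data the
polynomial refit necessarily reaches the noise floor and the network
cannot beat it; the network's advantage claimed for real stems (local,
non-smooth bark variation) is exactly what the generator does not emulate.
The accuracy tables published for the original pine/oak measurements can
only be checked against the deposited field tables themselves
(`data/field/`, see README); the evaluation subset behind those tables is
ambiguous, so the reproduction path evaluates under both the whole-series
and test-split scopes and reports both.

## Known limitations

- The delay window carries no tree-identity information, so cross-boundary
  predictions are structurally poor; `boundary_reset` mitigates this in
  training but whole-series metrics still include boundary samples unless
  the caller masks them.
- BR's evidence updates use the Gauss–Newton Hessian; for very small
  residuals β grows without bound and training stops on a converged flag
  rather than refining hyperparameters further.
- The generator draws heights and diameters independently (no explicit
  H–DBH allometry beyond the shared taper anchor) and models no site, age
  or climate covariates.
- LM restarts can settle in different local minima on noisy data (the
  regularized trainer is the stability reference); the restart-selection
  protocol reports one draw plus across-restart spread rather than the best.
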