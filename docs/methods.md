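# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot show.  Units: capacitance is in farads inside
the physical dielectric model and in picofarads on the sensor/calibration
scale; moisture is a fraction internally and percent at every I/O boundary;
temperature in degC.

## Dielectric-mixture model

The detection cell is treated as a parallel-plate capacitor filled with a
three-phase bed: dry cereal matter, water, and inter-grain air.  The
effective relative permittivity is the volume-weighted mean of the phase
permittivities, and the water/cereal volume ratio follows from the
wet-basis moisture definition `W = rho_w V_w / (rho_c V_c + rho_w V_w)`.
Eliminating the volumes yields

    C(W) = A / (W/(1-W) + B) + D + F,

with `A = k rho_w (1-e)(eps_c - eps_w)/rho_c`, `B = rho_w/rho_c`,
`D = k (1-e) eps_w`, `F = k e eps_a`, and `k = S eps0 / d`.  The model
assumes the pore ratio `e` does not change with moisture (swelling is
ignored), phases mix linearly (no interfacial polarization), and the
permittivities are temperature-independent.  A sympy identity test and a
brute-force volume-fraction oracle confirm the closed form and its exact
inverse to better than 1e-10 relative error.

Two geometry parameters are not physically measured values: plate spacing
`d = 0.10 m` and pore ratio `e = 0.40` are documented placeholders, because
the closed form only fixes `S = 0.015 m^2` (150 mm x 100 mm plates).  They
scale the farad-level constants but cancel in the moisture round trip.

The separate empirical calibration `C = 0.30744 W + 17.28085` (pF) is valid
only at 22 degC and duty cycle 1/3 and is never combined with the
farad-scale closed form in one computation.

## Sparrow search and the chaos-initialized variant

The optimizer is the canonical three-role sparrow search (see the module
docstring for the exact update rules).  Choices that the literature leaves
open, fixed here once:

* finder contraction exponent `exp(-i/(alpha*T))` (the often-printed
  `exp(-i*alpha*T)` underflows for any realistic `i*T`; it remains
  available as `exp_form="printed"` for auditing);
* far-joiner step `Q * exp((X_worst - X)/i^2)`;
* roles re-sorted every iteration; fitness ties broken by lower index;
* finder fraction 0.2, safety value ST = 0.8, scout fraction 0.2 (top of
  the conventional 10-20% band; 0 is allowed to express the no-scout
  degenerate walk), denominator guard 1e-50;
* draw order fixed (alarm value; finder draws in rank order; joiner draws
  in rank order; scout draws in selection order) so seeded runs are
  bit-reproducible — the tests exploit this to compare every vectorized
  phase against a scalar-loop oracle sharing the random stream;
* non-finite objective values are treated as +inf with a warning;
* the reported best is an elitist archive over every evaluated position,
  so the convergence trace is non-increasing by construction.

Logistic-chaos initialization: each dimension is one orbit of
`y' = 4 y (1-y)` started from a uniform draw in (0.01, 0.99) resampled away
from the short periodic points {0.25, 0.5, 0.75}, affinely mapped onto the
box.  The orbit's invariant density is the arcsine law Beta(1/2, 1/2),
which the init test verifies by Kolmogorov-Smirnov distance.

**Known limitation (measured, not assumed).**  Under the short benchmark
protocol (population 30, 20 iterations, d = 30), the finder contraction
dominates the dynamics and the final best scales with the initial flock's
coordinate magnitudes.  Because the arcsine density concentrates mass near
the box edges, chaotic init starts *farther* from the origin-centred optima
than uniform init, and over paired seeds LCSSA's median final best is
slightly worse than SSA's on five of the six benchmarks (they tie on the
step function's integer plateau).  The often-claimed superiority of chaotic
initialization does not emerge here; the corresponding acceptance check is
deliberately left failing rather than weakened.

## Regressors

`ELMRegressor`: hidden input weights and biases uniform on [-1, 1] (or
supplied), sigmoid activation, output weights by `numpy.linalg.lstsq`
(minimum-norm).  With 100 hidden units and a few hundred training rows the
hidden matrix is numerically rank-deficient; the minimum-norm solution is
returned, with a warning if the activations are entirely constant (which
the tuner routinely produces when the search contracts all weights to 0).

`BPRegressor`: one hidden layer (default 5 sigmoid units from the sizing
rule `h = round(sqrt(m+n)) + a` with m=3 inputs, n=1 output, a=3), linear
output, full-batch gradient descent on the MSE.  Learning rate 0.01
(unstated in the source; configurable), at most 10^4 epochs, halting early
at MSE <= 0.01.  Gradients are verified against central finite differences.
The target stays in percent; only the features are standardized (training
statistics frozen at fit time — the leakage guard is tested).

`SSATunedRegressor`: what the optimizer tunes is standard practice for each
family — the ELM's 400-dimensional hidden-parameter vector (output weights
re-solved per candidate), or the BP net's 26-dimensional initial weight
vector evaluated untrained, with gradient descent fine-tuning from the
optimum.  Fitness is training-set RMSE: the campaign is deliberately split
only 3:1 into training/prediction sets (no validation split), so no
held-out fitness is available.  Population 20, 20 iterations, box [-1, 1].

**Known limitation (measured, not assumed).**  440 fitness evaluations
cannot meaningfully search a 400-dimensional box: the tuned ELM's training
RMSE improves by about 0.1% over a single random draw, and because the
fitness is training error, whatever selection does occur is selection
toward noise.  On the default synthetic campaign the paired-seed median
prediction-set R of the tuned variants is therefore statistically
indistinguishable from — and in the measured configuration slightly below —
the plain ELM's.  The published ordering (chaos-tuned >= SSA-tuned >=
plain) is a within-noise effect that does not reproduce; the acceptance
check encoding it is left failing rather than loosened.  In the noiseless
regime all six variants recover the generating surface (prediction
R > 0.99), confirming the pipeline itself is sound.

## Synthetic campaign

The generator emulates the factorial sensor campaign: 16 moisture levels
(5.64-23.52%, including the as-harvested 14.42%), 3 replicate samples per
level, 3 temperatures, 5 duty cycles — 720 records.  The noiseless surface
for duty `v > 0`,

    C(W,T,v) = (0.30744 W + 17.28085) * [1 + k_T (T-22)(1 + lambda W)] * [1 + k_v (v - 1/3)],

is anchored so the (22 degC, 1/3) slice is *exactly* the empirical
calibration line, and rises monotonically in all three variables, more
steeply in temperature for wet grain.  No measured equation exists for the
temperature and duty-cycle axes; the multiplicative form and the
coefficients `k_T = 0.004 /degC`, `lambda = 0.05 /%`, `k_v = 0.6`,
`sigma = 0.4 pF`, `baseline_air = 10 pF` are this package's own choices,
exposed in `NoiseModel` and chosen once to give a prediction-set R regime
broadly comparable to field calibrations.  Records at duty 0 are
empty-plate air baselines: they carry no moisture information, so the
pipeline excludes them from the model-fitting stage by default
(`include_empty_cell=True` restores them) while the campaign and its 3:1
split keep all 720 records.  The split uses a floor policy for the test
size (720 -> 540/180 exactly).

What the generator does **not** emulate: sensor drift, electrode fouling,
conductive contaminants, humidity coupling, replicate-level biases, or any
non-Gaussian noise.  Passing tests therefore demonstrate correctness of the
algorithms and pipeline on a clean, smooth response surface — not field
performance.  In particular the synthetic surface is far more learnable
than real differenced sensor data: all models score R_P ~ 0.94-0.98 here
versus ~0.5-0.7 on field data.

## Metrics

`RPD = 1/sqrt(1 - R^2)`: the reciprocal form without the square root
contradicts every published (R, RPD) pairing, while the square-root form
reproduces all twelve to within 0.001; the acceptance suite asserts exactly
that.  This definition is a monotone transform of R, not the classical
chemometrics SD/RMSE ratio, which is provided separately as
`classical_rpd`.  Band boundaries (1.4, 2.0) are assigned to the lower
band.  A numerically perfect fit (|R| = 1 to float precision, which the
noiseless campaign produces) is reported as RPD = inf in model reports,
while `rpd_from_r` itself keeps the strict |R| < 1 domain.  Dataset
summaries use the sample (N-1) standard deviation.

## Problem sizes and determinism

Default experiment: 720 records, 540/180 split (576 grain-present records
reach the regressors), six variants sharing one split and one model seed;
the paired comparisons in the tests use 11 model seeds.  The benchmark
comparison uses d = 30, population 30, 20 iterations, 11 paired seeds.
Every stage seed is recorded in the provenance block and one global seed
fans out deterministically (`ExperimentConfig.from_global_seed`), so two
runs of the same configuration produce byte-identical report CSVs.
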