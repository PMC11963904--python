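# Methods

## The mechanistic model

The dissociation curve is represented in Hill coordinates x = ln(p/p₀),
y = ln(s/(1−s)) as y − y₀ = (x − x₀) + h·tanh(k₀(x − x₀)) with constants
k₀ = 0.5343, s₀ = 0.867, p₀ = 7 kPa, h₀ = 3.5; y₀ is always derived from
s₀ rather than stored. The displacement at 37 °C decomposes as
a = a₁ + a₂ + a₃ + a₄ + a₅ with

    a₁ = −0.88 (pH − 7.40)        a₂ = 0.048 ln(PCO₂/5.33)
    a₃ = −0.7 FMetHb              a₄ = (0.3 − 0.1 FHbF)(cDPG/5 − 1)
    a₅ = −0.25 FHbF

and temperature shift b = 0.055(T − 37); x₀ = a + b and h = h₀ + a. The
"unknown knowns" term a₆ is fixed at zero throughout: fitting it jointly
with a₄ is not identifiable, and a₄ is instead the slot through which the
discrepancy models act (`a4_override` replaces the cDPG formula). All
saturations are fractions internally; percentage points appear only in
reporting. Pressures are kPa, temperatures °C; no mmHg support.

The combined coordinates are p = pO₂ + (pO₂/SO₂)·FCOHb/(1−FCOHb−FMetHb)
and s = (SO₂(1−FCOHb−FMetHb)+FCOHb)/(1−FMetHb); the training target is s.
The inverse map to SO₂ is provided for reporting and round-trips to 1e−12.

ds/da has the closed form s(1−s)·(−1 + tanh(k₀u) − h·k₀(1−tanh²(k₀u))),
u = x − x₀, which is negative for h > 0: the curve moves right (saturation
falls) as a increases. This derivative carries the training gradient of
the grey box through the mechanistic layer.

The model's validity range is taken as p ∈ [0.5, 45] kPa for curve sweeps
and monotonicity checks; this is an implementation choice, not a claim
about the physiology outside that range.

## Synthetic study generator

The generator is the study definition, not a convenience: the mechanistic
model with hidden term a₄(p) = 0.25·cos(2π ln p) − 0.55 produces noiseless
targets; observation noise is Gaussian with σ equal to a stated fraction
(2, 5, 10 or 15%) of the standard deviation of the noiseless s over the
generated set; 200 training and 50 validation points.

Input sampling (the literature gives no sampling law; these are this
package's choices, recorded in `SyntheticStudyConfig`):

- pH ~ U(7.0, 7.6), PCO₂ ~ U(3, 9) kPa, FMetHb ~ U(0, 0.02),
  T ~ U(35, 39) °C — plausible adult ICU arterial ranges;
- ln p ~ U(ln 2, ln 15): log-uniform combined pressure. The upper end
  matters: a₄ influences s only through the curve, and above s ≈ 0.99
  (p ≳ 10 kPa under the hidden term) the sensitivity ds/da₄ is so small
  that a₄ is unidentifiable there. With an upper bound of 15 kPa about 12%
  of points sit in that saturated tail — enough to represent
  oxygen-supplemented patients, few enough that the inverse problem stays
  well posed. Much wider ranges leave the embedded network unconstrained
  on a large fraction of the data and recovery of the hidden term degrades
  for every method.
- Rejection resampling removes draws whose noiseless s falls below 0.35,
  mimicking the clinical rarity of low-saturation records.
- Noisy observations are clipped into [1e−3, 1−1e−3] so logit transforms
  stay finite; clipping touches only extreme draws at the highest noise
  level.

Noise is defined on the combined-saturation scale (the training target).
The generator is a pure function of (config, noise level, seed).

What the generator does not emulate: correlated covariates (real pH and
PCO₂ are strongly anticorrelated), measurement error in the inputs,
repeated measurements per patient, and any cohort structure. Passing the
synthetic study therefore demonstrates that each method can recover a
hidden, smooth, p-dependent displacement under additive noise — not that
it will do so on clinical data with structured errors.

## Black box: constrained GP discrepancy

Observations are z = f(x) + δ(x) + e with f the a₄ = 0 model,
δ ~ GP(0, k) with the separable squared-exponential kernel exactly as
printed (no ½ factor, squared per-coordinate ratio), and e ~ N(0, σe²).
Inputs are standardized per coordinate (training mean/SD) before kernel
evaluation; the length-scale priors are interpreted on that scale, where
they are dimension-free.

Prior knowledge that the discrepancy vanishes flatly where the curve
saturates enters as noise-free observations δ = 0 and ∂δ/∂p = 0 at
p = 0.5 and 45 kPa (other inputs at reference values) — two value and two
derivative constraints. Derivative conditioning uses the closed-form
kernel derivatives ∂k/∂x′ⱼ = 2(xⱼ−x′ⱼ)/γⱼ²·k and
∂²k/∂xᵢ∂x′ⱼ = (2δᵢⱼ/γⱼ² − 4dᵢdⱼ/(γᵢ²γⱼ²))·k; both are unit-tested against
central finite differences, and the full conditioning against an
independent dense joint-Gaussian solve.

MAP priors: σ² ~ Inverse-Gamma with mean 0.3², mode 0.2² (shape 2.6,
scale 0.144, solved from the mean/mode equations and asserted);
σe² ~ Inverse-Gamma with mean 0.016², mode 0.015²; correlation lengths
γ₁..₄ ~ Gamma(42, 9) (shape–rate; long, smooth) and γ₅ ~ Gamma(4, 4) along
p, where the discrepancy oscillates. Optimization runs on
log-hyperparameters with L-BFGS-B from 8 prior-drawn starts (fixed seed);
the jitter ladder on the joint covariance diagonal is 0→1e−10→…→1e−6
relative to σ². A clinical mode pins σe² (records treated as exact).

Fitted on the synthetic study the ARD structure is recovered: γ₅ shrinks
to ~0.3 standardized units while the four nuisance lengths grow, and the
updated model f + δ cuts the baseline validation RMSE by an order of
magnitude at every noise level. Posterior SD at the constraint points is
at the jitter scale (~1e−9), i.e. the constraints hold essentially
exactly.

## Grey box: embedded network

Architecture: 5 inputs → 20 → 20 → 1, simplified-RBF activation
φ(x) = e^(−x²) for the synthetic study (64-wide ELU variant available for
clinical use). Glorot-uniform initialization, zero biases.

Two design choices differ from the obvious defaults, both forced by the
geometry of the problem and verified empirically during development:

1. **Inputs are fed in natural units, not standardized.** After
   per-coordinate standardization all five inputs look alike, and the
   hidden term — an oscillation along one of them — must be found inside
   an isotropic 5-D function class given only 200 points. Every smooth
   learner tried (this network, an independent MLP implementation, a
   CV-tuned RBF kernel ridge) then interpolates the training set through
   the four nuisance coordinates and generalizes at chance. In natural
   units p spans ~13 kPa while pH spans 0.6, so oscillations along p are
   cheap in weight norm and dependence on the narrow inputs is expensive —
   the anisotropy the problem needs, and consistent with the displacement
   formulas, which also act on natural units.
2. **Best-of-8 restarts with an Occam tie-break.** Full training
   (Adam: 5000 steps at 1e−2, full batch; then L-BFGS, history 50, up to
   1000 iterations, gradient tolerance 1e−9) is repeated from 8 seeded
   initializations. Among restarts whose final loss is within 1.25× of
   the best, the smallest weight norm wins: equal-loss minima with large
   weights reach the noise floor by interpolating sharply and drift freely
   in the high-saturation tail where a₄ is unidentified, which poisons the
   later distillation step. Restarts that fail to reach the noise floor
   (typically by a factor of 4 or more in loss) are excluded by the
   window automatically.

No explicit weight decay is used; restart selection plays that role. The
loss is plain MSE on s. Training is deterministic given the seed.

## Symbolic distillation

The regression set is the trained network's inputs and outputs on the
training inputs. The engine is a compact tree-based genetic program:

- operators: unary {sin, cos, ln, exp}, binary {+, −, ÷, ×}; ln and ÷ are
  protected (|argument| bounded away from zero) rather than fitness-penalized;
- population 160, 24 generations, max 30 nodes, tournament size 3,
  elitism 2; crossover 0.45, subtree/point/constant/insert/delete
  mutations 0.15/0.1/0.1/0.1/0.05; multiplicative parsimony 1e−3;
- generation 0 is seeded with a systematic library of unary-chain
  templates C·u₁(C·u₂(v)) + C over every ordered operator pair and every
  variable. This matters: a bare ln(p) subtree fits the data worse than a
  constant and dies out before mutation can wrap it in a trig function,
  so purely random initialization rarely assembles trig-of-log structures;
- constants are refitted by local least squares with random restarts
  (more restarts and more rounds for small structures — the frequency of
  an oscillatory term has many local optima);
- the final Pareto front over (MSE, node count) is polished: thorough
  constant refits, constant folding, pruning of negligible constants with
  identity simplification, and a unary-operator neighborhood search
  (swap each sin/cos/ln/exp for each alternative and refit), which
  rescues structures whose constants were trapped in a wrong basin;
- model selection is the score rule: the front entry with the largest
  drop in log-MSE per unit of added complexity. The raw-MSE minimum is
  systematically a large expression reproducing the network's
  idiosyncrasies; the elbow is the distilled law.

`match_canonical_form` normalizes a selected expression algebraically
(sympy): sin folded into cos, negative frequencies reflected, phases of 0
or π folded into the amplitude sign, and returns (α, β, γ) of
α·cos(β·ln p + φ) + γ, or nothing for expressions outside the family —
e.g. a cosine of p rather than of ln p, or any dependence on the other
inputs. The search itself is deterministic given the seed.

## Evaluation

Validation RMSE is computed on the combined-saturation scale against the
noiseless truth; clinical-style reports convert to SO₂ and summarize
absolute errors in percentage points with median, quartiles and Tukey
whiskers. k-fold splits are shuffled, near-equal and deterministic per
seed. Per-patient curve bundles sweep p over 200 log-spaced points in
[0.5, 45] kPa with the record's other inputs held fixed; the GP bundle
carries a ±2 SD band, and predictive-SD colouring is min–max normalized
per panel. Showcase patients are ranked by |baseline error| − |model
error| in SO₂ points.

## Problem sizes and tolerances

The shipped defaults run the full study — four noise levels with all
three fits — in a few minutes on one CPU; the mid/high-noise repetitions
in the test suite use a reduced search budget (population 128, 16
generations), which recovers structure but with slightly looser
coefficients. Numerical tolerances: combined-coordinate round trips and
fixed points at 1e−12; GP oracle equivalence at 1e−8; kernel-derivative
finite differences at 1e−6 (h = 1e−5); grey-box gradient checks at
relative 1e−5.

## Known limitations

- The a₆ Newton–Raphson fit and cDPG nomograms are out of scope.
- The grey box carries no predictive uncertainty; only the GP does.
- Symbolic recovery assumes the hidden law lies in the operator span; at
  15% noise the engine may return a structurally different expression
  (e.g. a cosine of p), matching the known behaviour of this pipeline.
- Restart selection by weight norm is a heuristic; a rare seed can still
  land every restart in a drifting basin, in which case the distilled
  expression carries junk correction terms.
- The GP's constraint placement (p = 0.5 and 45 kPa) is a modelling
  choice; the construction supports arbitrary constraint sets.
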