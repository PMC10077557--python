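# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `uvbee`, in the order the pipeline runs.

## Synthetic spectrum generator

The generator stands in for an undeposited instrument dataset. Each pure
solute is a sum of Gaussian absorption bands on the 190–400 nm grid
(1 nm spacing, 211 points):

    A(λ) = Σ_bands  c · ε_b · exp(−(λ − μ_b)² / (2 σ_b²))

with concentration `c` (mol/L), peak absorptivity scale `ε_b`, center `μ_b`
and width `σ_b`. Mixtures are pointwise sums of their components
(Beer–Lambert additivity). Defaults, chosen once and frozen:

| component | bands (nm) | ε (AU·L/mol) | width |
|-----------|-----------|--------------|-------|
| NaCl      | 197       | 2.0e4        | 6 nm  |
| NaOH      | 202       | 3.0e4        | 6 nm  |
| PEA       | 210, 258  | 6.0e4, 8.0e3 | 6 nm  |

The ε values encode three constraints simultaneously: (i) at equal
concentration the peak ordering is PEA > NaOH > NaCl; (ii) the 258 nm
feature of a mixture rises above a 3σ noise floor only when the PEA mole
fraction reaches ~10% m/m, so the qualitative "disappearing peak" behaviour
of dilute mixtures is reproduced; (iii) the weakest in-range single-component
sample (PEA at 3.06e−6 mol/L → peak ≈ 0.18 AU) still sits far above the
default noise. Gaussian band shapes and a common 6 nm width are the simplest
shapes consistent with broad solution-phase UV bands.

Sampling: single-component concentrations are log-uniform over the
preparation ranges (NaCl 3.52e−6–0.5, NaOH 7.62e−6–0.5, PEA
3.06e−6–8.91e−3 mol/L — up to five decades, which linear sampling would
collapse onto the top decade). Mixture samples jitter the seven recipe
concentrations by ±20% log-uniformly, emulating independently prepared
solutions. Noise is i.i.d. Gaussian per wavelength (σ = 0.002 AU, a typical
benchtop double-beam noise floor) plus an optional slow sinusoidal baseline
drift (amplitude 0 by default — the reference-beam subtraction of a
double-beam instrument removes most drift). The train/test split is
stratified and seeded; 30 samples per class at train fraction 2/3 gives the
canonical 20/10 split.

What the generator does **not** emulate: detector saturation and stray light
(real absorbances above ~3 AU are unreliable; synthetic ones are exact),
band asymmetry and solvent/pH shifts, wavelength-correlated noise, and
inter-session drift. Passing tests on this generator therefore demonstrate
that the pipeline recovers class structure under its stated assumptions, not
that the published instrument-data accuracies are reproduced.

## Feature extraction

Classification is by spectral *shape*: each spectrum is scaled to unit
Euclidean norm before PCA. With concentrations spanning five decades, raw
absorbance vectors of one class form a ray through the origin; the
near-origin structure of three rays cannot be resolved by a
bounded-weight network, whereas after normalization each class collapses to
a tight cluster of directions. Per-sample normalization (closure, SNV and
relatives) is standard chemometric practice for concentration-invariant
classification; it is configurable off (`--no-normalize`) for intensity-aware
work.

PCA is computed by SVD of the mean-centered (un-autoscaled, the spectroscopy
convention) data matrix. The variance contribution of component `i` is
`100 λ_i / Σ_all λ`, the denominator running over all eigenvalues, so
retained contributions are non-increasing and sum to at most 100%. Signs are
fixed by making each loading vector's largest-magnitude element positive —
PCA signs are otherwise arbitrary and sign-stability is needed for
deterministic artifacts. Test spectra are always projected with the
training-fit model; refitting on test data would leak information. Default
`k = 3` retained components (they carry nearly all variance of this
three-solute system); `k` is configurable. The three score dimensions are
standardized (mean 0, variance 1, fit on the training split only; constant
dimensions pass through unscaled) before entering the network.

## Network

Feed-forward net, default `[3, 8, k]`: hyperbolic-tangent hidden layer,
logistic output layer, one output unit per class. Targets are one-hot
(class labels 1..k are not reachable logistic outputs, so direct regression
onto the code would fight the output transfer); the predicted class is the
1-based argmax, ties to the lowest index. Solute classes are coded
NaCl = 1, NaOH = 2, PEA = 3; mixture classes 0–60% m/m are coded 1–7 in
mole-fraction order. Mixtures use the same 3-score input with a 7-unit
output layer (`[3, 8, 7]`); layer sizes are config-driven.

Gradient trainer (`gdm`): batch back-propagation with classical momentum
(`v ← m v − η ∇`, `θ ← θ + v`), learning rate 0.05, momentum 0.9, at most
2000 epochs, MSE goal 1e−6, weights initialized uniform `[−0.5, 0.5]`. A
non-finite loss raises immediately with the advice to lower the learning
rate; the logistic output otherwise bounds the loss, so divergence is only
reachable with a linear output layer.

## Colony optimizer

Standard colony: `N = 35` sources, `MaxCycle = 2000`, retention
`limit = 100`, objective tolerance 1e−6. Phases per cycle: one employed
move per source; `N` onlooker moves on roulette-wheel-selected sources
(probability ∝ fitness, `fit = 1/(1+f)` for `f ≥ 0`, `1+|f|` otherwise);
scout re-initialization of every source whose trial counter exceeds the
limit. Greedy selection keeps the incumbent on ties; the trial counter
resets on improvement; the global best is memorized across scouting, so the
reported trace is monotone non-increasing. Moves perturb a single random
dimension and are clamped to the box. Termination on reaching the tolerance
or the cycle budget.

Adaptive variant: `v_ij = ω(c) x_ij + (r + s L) (x_ij − x_kj)` with

* `ω(c) = ω_max − (ω_max − ω_min) c / T_max`, defaults 1.05 → 0.15 —
  the weight multiplies the *position* term, so values just above 1 early
  in the run slightly expand the search while values below 1 late in the
  run contract the population's coordinates and with them the effective
  step size. (The alternative reading — ω scaling only the difference
  term — was implemented and measured first: it is never better than the
  plain colony on Griewank because it slows basin escape without any
  compensating gain, so the position-term form was adopted.)
* Levy factor `L` from Mantegna's algorithm (`L = u/|v|^{1/β}`,
  `u ~ N(0, σ_u²)`, `v ~ N(0,1)`, β = 1.5, σ_u ≈ 0.6966), scaled by
  `s = 0.1` and riding on the neighbour difference. Tying the mutation
  amplitude to the difference keeps its typical size proportional to the
  colony spread — a fixed absolute amplitude was measured to destroy
  late-stage refinement entirely — while the heavy tail still delivers
  jumps of many times the spread. Performance on Griewank is flat for
  `s` in 0.01–0.5; 0.1 keeps the mutation term a visible fraction of the
  step. Both β and `s` are configurable.

With `ω ≡ 1` and `s = 0` the adaptive variant consumes the identical random
stream as the plain one and produces identical trajectories; this is a
tested invariant (the config deliberately allows `ω_min = ω_max`).

Measured on Griewank D = 5 at a 300-cycle budget over 10 seeds: plain colony
median final best 7.4e−3 (the first local minimum), adaptive 5.5e−7 —
the adaptive moves both escape that minimum and refine faster.

Network training by colony: the weight matrices and thresholds are flattened
to one vector (`[3,8,3]` → 59 parameters) and searched in `[−5, 5]` per
parameter — ample for tanh units on standardized 3-dimensional inputs; the
objective is training-set MSE.

## Metrics

Rows of the confusion matrix are actual classes, columns predicted.
Per class `j`: `recall_j = 100 N_jj / row_j`,
`precision_j = 100 N_jj / col_j`,
`F_j = 2 p_j r_j / (p_j + r_j)` reported on the 0–1 scale (matching the
conventional presentation where recall/precision/accuracy are percentages);
`accuracy = 100 trace / total`. Classes with empty rows or columns yield
0-valued metrics with a warning instead of an exception, so small synthetic
runs degrade gracefully. Regression summary with the integer class code as
response: `RMSEP = sqrt(Σ(y−ŷ)²/n)`, `REP = 100 RMSEP / ȳ`,
`R² = 1 − SS_res/SS_tot`; zero-mean actuals (REP) and zero-variance actuals
(R²) raise.

## Reproducibility machinery

All randomness flows through `numpy.random.default_rng` seeded per stage;
dataset, model and report artifacts embed their seeds and a SHA-256 hash of
the producing configuration, and a rerun from the same master seed is
byte-identical (tested). Spectra CSVs are written with `repr` precision so a
write/read round trip is exact.

## Problem sizes used in the automated checks

The behavioural test suite runs the optimizer comparison at 300 cycles ×
10 seeds (the full 2000-cycle budget changes the comparison's direction in
neither variant's favour, only its margin), trains end-to-end networks at a
600-cycle colony budget on the 30-samples-per-class datasets, and checks the
PCA oracle on 10×211 matrices. These sizes were chosen so the whole suite
completes in well under a minute of optimizer time while each check still
exercises the full algorithm.

## Known limitations

* The synthetic generator's idealizations above; absolute published
  accuracies on instrument data are out of reach by construction.
* The colony trainer is derivative-free and pays for it in evaluations;
  architectures beyond a few hundred parameters would need larger budgets.
* The position-term inertia weight biases the search toward the coordinate
  origin as ω falls below 1. For Griewank (optimum at the origin) and for
  network weights (small-weight solutions preferred) this is benign or
  helpful, but on problems whose optima lie far from the origin inside a
  wide box the plain variant or `ω_min` near 1 may be the better choice.
* Only the two colony variants and the momentum trainer are provided; other
  metaheuristics and second-order trainers are out of scope.
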