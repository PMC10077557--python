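# uvbee

Classification of UV-Vis spectra — dilute aqueous NaCl, NaOH,
β-phenylethylamine (PEA) and their seven-mole-fraction mixtures — with a
back-propagation neural network whose weights and thresholds are optimized by
an **improved adaptive artificial bee colony** (IAABC) algorithm.

During PEA synthesis the product stream contains PEA together with NaOH
(reactant) and NaCl (by-product). UV spectrophotometry is a fast, reagent-free
way to identify which species a sample contains, but the absorption bands of
NaCl (197 nm) and NaOH (202 nm) overlap, and the 258 nm PEA band vanishes at
low mole fraction — so raw peak-picking misjudges dilute samples. `uvbee`
implements the full chemometric pipeline for this problem: principal-component
score vectors of the spectra are the inputs of a small feed-forward net
(tansig hidden layer, logsig output layer), and a bee-colony metaheuristic
searches the network's parameter space instead of (or in addition to)
gradient descent.

## The optimizer

The artificial bee colony holds `N` candidate solutions ("honey sources")
`x_i` in a bounded `D`-dimensional box and repeats employed-bee, onlooker-bee
and scout-bee phases. The plain neighbourhood move perturbs one random
dimension `j` against a random other source `k`:

    v_ij = x_ij + r (x_ij − x_kj),          r ~ U[−1, 1]

Selection is greedy (a source is replaced only by a fitter candidate, with
fitness `1/(1+f)` for objective `f ≥ 0`), onlookers sample sources with
probability proportional to fitness, and a source that fails to improve more
than `limit` times is re-initialized uniformly at random.

The adaptive variant modifies the move in two ways:

    v_ij = ω(c) x_ij + (r + s L) (x_ij − x_kj)

* **adaptive inertia weight** `ω(c) = ω_max − (ω_max − ω_min) · c / T_max`,
  decaying linearly from 1.05 to 0.15 over the run: early cycles explore with
  near-unit weight, late cycles contract the population step size for fine
  local search;
* **Levy mutation** `L`, a heavy-tailed random factor (Mantegna's algorithm,
  stability exponent β = 1.5, scale `s = 0.1`) riding on the neighbour
  difference: most draws are small, but occasional draws are tens to hundreds
  of times the colony spread, letting the colony jump out of local optima.

With `ω ≡ 1` and `s = 0` the variant is step-for-step identical to the plain
colony. On the Griewank test function
`f(x) = 1 + Σ x_i²/4000 − Π cos(x_i/√i)` (global minimum `f(0) = 0`,
domain `[−600, 600]^D`) the adaptive variant escapes the characteristic
`f ≈ 7.4e−3` local minimum that traps the plain colony at short budgets (see
the worked example below).

## The classifier

Spectra (190–400 nm, 1 nm steps, 211 points) are L2-normalized per sample,
mean-centered, and decomposed by PCA; the first three score vectors are
standardized and fed to a `[3, 8, k]` network (`k` = number of classes,
one-hot targets, predicted class = argmax + 1). Trainers:

* `gdm` — batch gradient descent with momentum (learning rate 0.05,
  momentum 0.9, MSE goal 1e−6);
* `abc` / `iaabc` — the bee colony minimizing training-set MSE over the
  flattened parameter vector in `[−5, 5]` per parameter.

Evaluation reports the confusion matrix (rows = actual, columns = predicted),
per-class recall %, precision %, F-score (0–1), overall accuracy %, and — with
the integer class code as response — RMSEP, REP % and R².

Because no instrument dataset is publicly deposited, the package ships a
synthetic generator (`uvbee.synthgen`) emulating the system with Gaussian
absorption bands and Beer–Lambert additivity: PEA bands at 210/258 nm, NaOH
at 202 nm, NaCl at 197 nm, the seven mixture recipes at their published
concentrations, log-uniform concentration sampling, and additive instrument
noise (default σ = 0.002 AU).

## Worked example

Simulate the seven mixture classes (30 samples each, 20/10 split), train the
IAABC-optimized network, and evaluate on the held-out spectra:

```sh
uvbee simulate --classes mixtures --n-per-class 30 --seed 1 --out demo/data
uvbee train    --train demo/data/train.csv --trainer iaabc --seed 1 --out demo/model.json
uvbee evaluate --model demo/model.json --test demo/data/test.csv --out demo/metrics.json
```

prints

```
   class  Recall %  Precision %  F-Score
       0     100.0        100.0    1.000
      10     100.0        100.0    1.000
      20     100.0        100.0    1.000
      30     100.0        100.0    1.000
      40     100.0        100.0    1.000
      50      90.0        100.0    0.947
      60     100.0         90.9    0.952
Accuracy %: 98.6
RMSEP: 0.1195  REP %: 2.9881  R^2: 0.9964
```

69 of the 70 held-out mixture spectra (10 per class) are classified
correctly; the single error confuses adjacent mole fractions (one 50% sample
predicted as 60%), which is exactly the failure mode expected where
neighbouring recipes overlap spectrally. The regression row summarizes the same predictions with the class
code 1–7 as response: an RMSEP of 0.12 class units is a 3% relative error.

The optimizer comparison on Griewank (D = 5, N = 35, limit = 100, 300 cycles,
10 seeded runs):

```sh
uvbee benchmark --variant abc   --dim 5 --cycles 300 --runs 10 --seed 100 --out demo/bench
uvbee benchmark --variant iaabc --dim 5 --cycles 300 --runs 10 --seed 100 --out demo/bench
```

reports `median_final_best` 7.4e−3 for the plain colony (trapped in the
first local minimum) versus 5.5e−7 for the adaptive one (escaped and
refined), four orders of magnitude better at the same evaluation budget.

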