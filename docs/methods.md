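# Methods

## The model

`conncrit` analyses weighted functional connectomes: symmetric N×N
matrices `w_ij` of signed correlation weights between brain regions,
with `|w_ij| <= 1` and zero diagonal.

**Thresholding.** For each matrix the cut-off is
`w_t = <|w|> + n·σ_|w|`, with mean and *population* standard deviation
taken over the N(N−1)/2 upper-triangle magnitudes (the population/sample
choice is not canonical; population is fixed here so thresholds are
reproducible to the last bit). Edges with `|w_ij| > w_t` (strict) are
kept, preserving the weight's sign — anti-correlated regions carry
signal exactly as correlated ones do. When `n` is negative enough that
`w_t < 0` the effective threshold is clamped to 0 for binarization and
propagation; the literal rule would map a zero drive to the +1 state,
which is plainly a degenerate reading. Sweeping `n` (default −2.0 to 4.0
in steps of 0.1) traces the network from near-complete to empty.

**Signal transfer.** A stimulus `S ∈ {−1, 0, +1}^N` activates each
region independently: +1 with probability `p`, −1 with probability `p`,
0 otherwise. The response is a single synchronous step,

    drive_j = Σ_i a_ij · w_ij · s_i,
    r_j = +1 if drive_j > w_t;  −1 if drive_j < −w_t;  0 otherwise,

with no recurrent iteration (the response is a function of the stimulus,
not a dynamical trajectory). A drive exactly at the threshold falls in
the closed inactive band.

**Information readout.** For every ordered pair (i, j), i ≠ j, the
plug-in mutual information in nats,
`m(i,j) = H(s_i) + H(r_j) − H(s_i, r_j)`, is computed from the 3×3 joint
distribution of `(s_i, r_j)` — empirical counts over `n_trials = 1000`
stimulus draws per (matrix, n, p) cell, or exact enumeration of all 3^N
configurations for N ≤ 10. Marginals always come from the same joint, so
the estimate is internally consistent and nonnegative. Averaging is
`<m(j)> = Σ_i m(i,j)/(N−1)` and `m = Σ_j <m(j)>/N`, over **all** ordered
pairs: the N−1 divisor forces that reading, and because one propagation
step only couples adjacent pairs, non-adjacent pairs contribute
(asymptotically) zero. No entropy bias correction is applied; the
plug-in bias (~2/n_trials per fully supported pair) is common to all
cells, and every scientific statement here compares cells.

**Topology.** Largest-connected-component fraction (isolated nodes stay
in the normalization) via `scipy.sparse.csgraph`; global transitivity
`C = 3·triangles / connected triples = trace(A³) / Σ_v d_v(d_v−1)`
(0 when no triples). Both are cross-checked against networkx and igraph
in the test suite. The clustering drop `ΔC(i) = C(i) − C(i+1)` is
indexed from the smallest threshold and telescopes to
`C(first) − C(last)`.

**Weight statistics.** Surviving magnitudes on `(w_t, 1]` are fitted by
two models:

* the *boundary-power law* `p(x) = (γ+1)(1−x)^γ`, a power law in the
  reflected variable `1 − x` adapted to the bounded correlation range.
  Renormalized to the surviving domain its conditional density is
  `(γ+1)(1−x)^γ / (1−w_t)^{γ+1}`, and the MLE is closed-form:
  `γ̂ = −n / Σ ln((1−x_k)/(1−w_t)) − 1`.
* the *exponentially truncated power law* `p(x) ∝ x^{α−1} e^{−x/x_c}`,
  the conventional comparator for upper-bounded weight distributions,
  fitted by bounded L-BFGS-B from several starts with
  `α ∈ (−10, 10)`, `x_c ∈ (10⁻³, 10³)`. The exponential is implemented
  as decaying; a growing exponential is not a truncation. The
  normalization on `(w_t, 1]` uses an upper incomplete gamma function
  extended below `a = 0` by the integration-by-parts recurrence — exact
  and fast, with no quadrature near the `x^{α−1}` endpoint singularity.

Both fits are scored by the Kolmogorov–Smirnov distance
`D = max_x |F_e(x) − P(x)|`, evaluated on both sides of every empirical
step (the supremum of a step-function difference sits at a step edge);
this matches `scipy.stats.kstest` exactly for continuous model CDFs.
Model selection is by distance comparison only — no p-values, no
bootstrap. Values exactly equal to 1 are nudged to `1 − 10⁻¹²` (with a
warning) rather than dropped, keeping `n_values` comparable across
models.

**Critical-point localization.** On ensemble-mean curves at one
activation density: the argmax of `m`, the argmax of `ΔC`, and the
argmin of the boundary-power KS distance, ties broken toward smaller
`n`, with pairwise distances reported in grid steps and a flag when an
argmax sits on the grid boundary (a monotone curve has no interior
peak).

## The synthetic ensemble

Real connectome matrices are not bundled; the generator produces
ensembles with the statistical structure the analysis assumes, as an
explicit signal-plus-noise model:

* **Modular core.** Nodes are split into `n_modules = 2` equal blocks.
  Within-module magnitudes are the upper tail (the top ~49.5% by rank)
  of the boundary-power law with `γ = 10`.
* **Noise floor.** Between-module magnitudes are uniform on `(0, b)` — a
  featureless, maximum-entropy noise band. The width `b` is not free: it
  solves `E[−ln(1−|w|)] = 1/(γ+1)` for the pooled mixture, which pins
  the whole-matrix boundary-power MLE at the nominal exponent (the
  closed-form MLE depends on the sample only through that moment). For
  the default geometry, `b ≈ 0.055`.
* **Hub ordering.** Within modules, larger magnitudes are biased toward
  a nested core (`core_order_strength = 0.4`: a blend of depth rank and
  random rank). Floor values are strictly nested on the hub cores
  (`bridge_order_strength = 1.0`), i.e. inter-module connectivity
  concentrates on rich-club-like bridge hubs; cross edges then close
  triangles through the module interiors, so stripping the floor removes
  bridges node-by-node without collapsing transitivity.
* **Subjects.** One base matrix per ensemble; each subject adds
  independent N(0, 0.005²) noise to every weight (clamped to [−1, 1],
  re-symmetrized, diagonal zeroed). With `noise_sd = 0` subjects are
  identical. Signs are independent and symmetric — with i.i.d. symmetric
  stimuli the transfer statistics are invariant to edge-sign structure,
  so nothing more elaborate is warranted.

All randomness derives from one integer seed through
`numpy.random.SeedSequence(seed, spawn_key=...)` with fixed spawn keys
per stage (magnitudes, signs, placement, subject noise), and each
(subject, n, p) simulation cell derives its stimulus seed the same way
from the sweep's master seed — two runs with one master seed produce
byte-identical tables.

Under the default geometry the sweep exhibits, in order: a complete
graph while `w_t ≤ 0`; gradual removal of the noise floor (LCC stays 1,
transitivity high — bridges are hub-nested); a sharp percolation drop to
LCC ≈ 1/n_modules when the floor dies (near `n ≈ −0.2`); the
transitivity drop and the boundary-power KS minimum in the same grid
neighborhood; and module dissolution at high `n`. The mean mutual
information at `p = 0.01` peaks in that neighborhood, and its peak
exceeds the `p = 0.001` (sub-critical, too few activations) and
`p = 0.1` (super-critical, interference-saturated) peaks.

### Why the generator looks like this

In this transfer model the network-mean information is governed by the
degree distribution: a node of degree k relays one sender cleanly with
probability `(1−2p)^{k−1}`, so the mean-degree optimum sits near
`1/(2p)` (~35–50 at `p = 0.01` empirically). For the information peak to
coincide with the percolation transition, the graph must *fragment at
that degree* — which only module-scale structure does (a ring-lattice
backbone fragments at residual degree ~ln N and cannot co-locate the
transitions; brain networks fragment into modules under thresholding,
which is also the more faithful emulation). The hub nesting of the
strong core suppresses the homogeneous sparse regime in which the
`p = 0.1` curve would otherwise peak as high as the `p = 0.01` curve.

### What the generator does not emulate

Genuine BOLD time series and their correlation estimation noise;
inter-subject topological variability (subjects share one base matrix);
more than two hierarchy levels; spatial embedding and distance-dependent
connectivity; global signal and preprocessing artifacts. Passing tests
on this ensemble shows the *pipeline* detects coincident transitions
where they exist by construction — it is not evidence about real brains.

### Known divergences of the synthetic ensemble from the target figures

* The truncated-power-law KS curve rises steeply above the transition
  (matching the reported near-monotone growth) but also shows a shallow
  minimum near it, because the synthetic surviving tail is *exactly*
  boundary-power and a 2-parameter comparator can mimic it locally; real
  data show no such dip. The pipeline's claims therefore rest on the
  boundary-power dip location, not on the comparator lacking one.
* Model discrimination by KS is only meaningful where the families
  differ: the boundary-power law's signature is its vanishing density at
  `|w| = 1`, so discrimination experiments draw data with mass near that
  boundary (γ = 2, low truncation). At γ = 10 with truncation 0.3 the
  two families coincide to within sampling error.

## Problem sizes and numerical choices

* Headline sweep: 20 subjects × N = 100 × 61 thresholds × 3 densities ×
  1000 trials (~2 minutes on one core); exact-enumeration oracles at
  N ≤ 8 (3^N ≤ 6561 configurations, limit 10).
* Matrix validation tolerance 1e−9 (asymmetry, range); matrices are
  exactly symmetrized and clipped after validation so downstream
  invariants hold bitwise. Nonzero diagonals are zeroed with a warning,
  not rejected.
* Distribution fits need ≥ 10 values; sweeps record insufficient cells
  as missing (logged) rather than aborting.
* Probability tables are validated to 1e−9 mass; `0·ln 0 = 0`.
* Ensemble averaging is the arithmetic mean per (n, p) over subjects,
  each metric independently; missing cells are skipped in the mean.

## Limitations

* The mutual-information peak is intrinsically flat (±0.0005 nats over
  ~5 grid steps), so its argmax carries ±1–2 grid steps of Monte-Carlo
  wander at 1000 trials; co-location statements are made in grid steps,
  not absolute `n`.
* Plug-in entropies are biased upward at finite trials; comparisons are
  made only between cells estimated identically.
* The one-step transfer model has no dynamics: avalanches, refractory
  states, and asynchronous updates are out of scope by design.
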