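# Methods

This note documents the models and procedures implemented in `cytocycle`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical edge cases each stage handles.

## Volume correction

Raw ion counts scale with cell volume. With volume-proxy channels
*v = 1..l* (total-protein stain isotopes), the correction is

    y_norm[i,v] = y[i,v] / mean_i(y[i,v])
    y_corr[i,j] = y[i,j] / ((1/l) Σ_v y_norm[i,v])   for all m channels j.

The divisor is a pure per-cell factor, so multiplying a cell's entire row
by any constant cancels exactly — corrected values are concentrations
relative to the population mean cell. Consequences worth knowing:

* Correction recovers concentrations only up to the population constant;
  two datasets with different mean cell sizes remain on different absolute
  scales.
* Volume channels themselves are corrected too (not dropped): their
  post-correction collapse toward a constant is a useful diagnostic.
* Zeros are substituted with the channel mean (computed over **all** cells,
  zeros included) **in the volume channels only**, since only there can a
  zero break the divisor. Mean-substituting zeros in ordinary marker
  channels would teleport genuinely negative/zero cells to the middle of
  the distribution — for a bimodal marker like IdU this demonstrably
  manufactures false S-phase cells — so marker zeros are left as measured.
  `substitute_zeros` accepts an explicit channel list for other policies.
* An identically-zero channel has no meaningful mean and raises an error
  rather than silently producing NaNs.

The asinh transform `asinh(y/c)` uses cofactor `c = 5` (CyTOF convention):
linear below roughly `c`, logarithmic above, exact at `asinh(0) = 0`. By
default all non-volume channels are transformed; the volume channels have
served their purpose once the correction is applied. Pipeline order is
fixed: substitute zeros → normalize volume channels → correct → transform.

## Phase classification

The four cell-cycle markers are standardized to zero mean / unit sample
variance (ddof = 1) per sample; the (mean, sd) pairs are stored so held-out
cells or later batches can be projected into the identical space.

**Decision tree.** CART with Gini impurity, depth ≤ 6, cost-complexity
pruning strength chosen by 5-fold cross-validation over the pruning path.
Manual cell-cycle gating is itself a short cascade of single-marker
thresholds, so a shallow tree suffices and its exported if–else rules stay
human-readable. On the synthetic reference population the first split is on
IdU, matching the order of manual gating.

**Gaussian mixture.** Four components, full covariances, moment-matched to
the tree's predicted phases (mean, covariance, weight per phase). This
pins each component to a phase *before* EM, eliminating the label-switching
and rare-class-swallowing failure modes of unsupervised mixtures — relevant
because phase prevalences span an order of magnitude (G0/G1 ~40–60%, M
~3–5%). The mapping is never re-matched afterwards. EM runs with relative
log-likelihood tolerance 1e-6 and at most 500 iterations; every covariance
update adds a ridge of `1e-6 · trace/4` to the diagonal, and the
log-likelihood trace is recorded and asserted non-decreasing. A component
collapsing below 5 supporting cells at initialization degrades the model to
tree-only assignment with a warning rather than fitting an unsupported
covariance. Cells are assigned to the maximal-posterior component; the full
posterior matrix is retained for uncertainty inspection.

A default model trained on the synthetic reference population ships with
the package (trained lazily, cached) for users without manual gates;
training on user gates via `fit_phase_model` is preferred whenever gates
exist. Serialization stores the mixture parameters and standardization
statistics (which fully restore classification behaviour) plus the tree
rules as provenance text.

## Pseudotime

The embedding is `f_α(y) = Σ_j α_j y_j` over the standardized four-marker
space with `α ≥ 0`. For every cell pair across each adjacent phase pair
(G0/G1,S), (S,G2), (G2,M) the constraint `α·(y_q − y_p) ≥ ε − ξ` is added
with slack `ξ ≥ 0`, and `Σ w·ξ` is minimized subject to `Σ α = 1`.
Choices the LP formulation needs that a verbal description leaves open:

* **Margin ε = 0.01** (standardized units) encodes the strict inequality;
  together with the simplex constraint it fixes the scale (otherwise
  shrinking α trivializes the slack).
* **Slack weights** default to *balanced*: each pair weighted by the
  reciprocal of its class pair's pair count, so each of the three phase
  boundaries contributes equally despite M providing ~100× fewer pairs
  than G0/G1–S. *Uniform* weighting is available.
* **Subsampling**: the LP is solved on a per-phase stratified sample of
  fraction 0.1 (floor 50 cells per phase, all if fewer), seed-controlled,
  since the pair count grows quadratically. α is then applied to all
  cells. On the reference population, pseudotime from two independent 10%
  subsamples agrees with Spearman ρ > 0.99.
* Pseudotime is min–max rescaled to [0, 1] (all-equal projections map to
  0); the ordering breaks ties by ascending cell id, making output
  deterministic and independent of input row order.
* The trajectory is linear G0/G1 → M; the M → G1 wrap-around of real cycles
  is not modelled.
* Functional markers never influence α; two held-out validation shapes
  (cyclin E-like and p-CDK1(Tyr15)-like) are reserved to check the
  ordering: their smoothed-trajectory peaks must fall at the G1/S and G2/M
  boundaries respectively.

Mean trajectories use a sliding-window mean along the ordering; the window
shrinks symmetrically at the edges. Default width `max(51, n/100)`, forced
odd. The LP solver is HiGHS via `scipy.optimize.linprog` on a sparse
constraint matrix; slack variables make every instance feasible, so solver
failure is surfaced as a numerical error rather than handled. On small
instances the solution is verified in tests against an exact
vertex-enumeration oracle (the objective is convex piecewise-linear, so the
minimum lies at an intersection of constraint hyperplanes with the
simplex), and a 0.01-step lattice scan provides an independent upper bound.

## Alignment and cycle correction

**Alignment** equalizes phase proportions across samples by stratified
subsampling without replacement (with-replacement would duplicate cell
ids). The target is the mean of per-sample proportion vectors or a
reference sample's vector. Per sample, total kept size is
`N = min_p floor(count_p / target_p)` and per-phase counts are apportioned
by largest remainder, so achieved proportions match the target within one
cell per phase and no cell is ever fabricated. A sample missing a phase is
aligned as well as possible with that phase at zero, with a warning. In
multi-sample runs the order is: align first, then recompute trajectories on
the aligned subsets, then correct.

**Cycle correction** divides each selected marker by its rescaled mean
trajectory: `corrected(k,j) = y(k,j) / max(τ, m_j(k)/mean_j)` at order
position *k*. Rescaling by the grand mean keeps the marker's overall level;
the floor τ = 0.05 prevents blow-ups where a trajectory approaches zero
(e.g. IdU outside S phase), and binding events are counted and reported.
Correction is applied on the asinh-transformed scale, the scale on which
trajectories are computed; the four cell-cycle markers are excluded by
default since flattening them would destroy the information phases are
derived from. A marker with a flat trajectory passes through (nearly)
unchanged; a strongly modulated one keeps its mean but loses its
pseudotime dependence.

## Diagnostics

* Coefficients of variation (`sd/mean`, sample sd) per channel — volume
  correction must shrink the CV of constant-concentration markers.
* Pearson/Spearman associations for chosen channel pairs.
* PCA confounding: principal components of the centred, unit-scaled
  functional submatrix are regressed on the phase index (coded 1–4 as a
  single numeric regressor by default; a one-hot group-means fit is
  available and, nesting the linear fit, can only give larger R²) and on
  the condition indicator. Before correction the phase index should
  dominate PC1; after correction that R² should collapse while condition
  structure becomes visible on its own component.
* `variance_explained_by_pseudotime`: R² of a marker against its own
  sliding-window mean trajectory — a nonparametric regression on
  pseudotime used to quantify how much modulation the correction removed.

## Synthetic data generator

Each cell has a latent position `u ∈ [0,1]`; the phase label is the
segment of `u` under cumulative phase proportions (default 55/25/15/5%,
inside the typical ranges for cultured lines). Marker concentrations are
piecewise-linear shapes of `u` on the asinh scale plus Gaussian noise
(cell-cycle markers sd 0.2, functional sd 0.15), mapped back to the linear
scale; raw counts multiply every channel by a per-cell lognormal volume
factor (σ = 0.3), normalized to unit sample mean so "concentration" is
well defined and volume correction is exactly invertible on noiseless
draws. Negative linear values arising from noise are clipped at zero and
counted. Shapes: IdU has a high S plateau with entry/exit ramps covering 4%
of the phase (IdU uptake switches on/off fast relative to S duration),
cyclin B1 ramps through G2 and peaks in early M before a sharp drop, p-HH3
spikes in M after a slight late-G2 rise, p-RB increases monotonically from
mid-G1. Two holdout shapes peak exactly at the G1/S and G2/M boundaries.
Functional markers are configurable (baseline, modulation amplitude and
shape, multiplicative condition effect, noise); defaults include ramp,
half-sine and full-sine modulations at amplitudes 0.35–0.5, one
condition-responsive marker and one flat control.

What the generator does **not** emulate — and hence what passing tests do
not certify about instrument data: Poisson ion-count statistics and
zero-inflation beyond clipping, doublets, debris, bead/barcode artifacts,
batch drift, non-lognormal size distributions, apoptotic or quiescent
sub-states, and conditions where protein mass decouples from volume
(e.g. osmotic shifts), where volume-proxy correction is invalid by
construction.

## Problem sizes and determinism

The reference population is 10 000 cells (5 000 for the volume checks,
3 000 per condition for the two-condition PCA check); the ordering LP runs
on 10% stratified subsamples. All stochastic steps take explicit seeds; the
CLI derives per-stage, per-sample seeds from one global seed via CRC32, so
a rerun with the same config is byte-identical. CLI exit codes follow the
click convention: 0 success, 2 usage errors, 1 data/runtime errors.

## Known limitations

* Pseudotime is linear in the markers; cycles where no monotone linear
  combination separates phases would need the (out-of-scope) nonlinear
  embedding.
* With a zero-slack optimum the LP can be degenerate (a face of optima);
  real measurement noise makes this rare, but on sanitized synthetic data
  different subsamples may return different vertices of the optimal set.
* Phase-proportion alignment discards cells (up to the binding-phase
  ratio); severely imbalanced samples can lose most of their cells.
* The mean-substitution rule for volume-channel zeros biases those cells'
  divisors toward 1; with several volume channels the effect is diluted.
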