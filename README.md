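# cytocycle

Cell-volume and cell-cycle confounder correction for mass cytometry (CyTOF)
single-cell data.

Mass cytometry measures ~50 proteins per cell as metal-isotope ion counts,
but two latent per-cell factors confound every channel: **cell volume**
(bigger cells contain more of everything) and **cell-cycle state** (many
"functional" readouts rise and fall with cycle progression). Left
uncorrected, both masquerade as biological heterogeneity, inflate
marker–marker correlations and dominate the leading principal components of
any downstream analysis. `cytocycle` removes them in five composable steps:

1. **Volume correction.** Given total-protein stain channels
   *v = 1..l* (e.g. the Ru isotope channels of an amine-reactive ruthenium
   stain), each channel is normalized to unit population mean,
   `y_norm[i,v] = y[i,v] / mean_i y[i,v]`, and every channel *j* of every
   cell *i* becomes a relative concentration
   `y_corr[i,j] = y[i,j] / ((1/l) Σ_v y_norm[i,v])`.
   Zeros in the volume channels are first replaced by the channel mean so
   the divisor stays positive.
2. **asinh transform.** `y_trans = asinh(y_corr / c)` with cofactor
   `c = 5`, the community-standard variance-stabilizing scale.
3. **Phase classification.** The four canonical cell-cycle markers — IdU
   (S), cyclin B1 (G2/early M), p-HH3 (M), p-RB (late G1→M) — are
   standardized and fed to a hybrid classifier: a CART decision tree
   trained on gated cells provides labelled starting clusters, a
   4-component full-covariance Gaussian mixture is moment-matched to the
   tree's predictions and refined by EM, and each cell is assigned to the
   maximal-posterior component. The component↔phase correspondence is
   frozen at initialization, so labels never switch.
4. **Pseudotime.** A non-negative linear embedding
   `f_α(y_i) = Σ_j α_j y_ij` of the standardized markers is fitted so the
   known phase order G0/G1 < S < G2 < M is preserved: every pair of cells
   from adjacent phases contributes an ordering constraint with a
   non-negative slack variable, and the LP minimizes the weighted slack sum
   subject to `Σ α_j = 1, α ≥ 0`. The LP is solved on a per-phase
   stratified subsample; α then embeds every cell. Per-marker trajectories
   are smoothed with a sliding-window mean along the ordering.
5. **Cycle correction (and alignment).** Each marker's mean trajectory is
   rescaled around 1 by its grand mean, and single-cell values are divided
   by it, flattening cell-cycle modulation while preserving the marker's
   overall level. Across samples, phase proportions are first equalized by
   stratified subsampling toward the mean (or a reference sample's)
   proportion vector.

A synthetic-data generator with full ground truth (phase labels, latent
cycle position, volume factors, planted condition effects) makes every
stage testable without instrument data, and `cytocycle.diagnostics`
quantifies what each correction removed (CVs, marker associations, PCA
variance explained by phase/condition).

## Worked example

```sh
cytocycle simulate --out demo/fix --n-cells 5000 --seed 1
cytocycle correct-volume --fcs demo/fix/sample.fcs --channel-map demo/fix/channel_map.yaml --out demo/transformed.fcs
cytocycle classify      --fcs demo/transformed.fcs --channel-map demo/fix/channel_map.yaml --out demo/classified.fcs
cytocycle pseudotime    --fcs demo/classified.fcs  --channel-map demo/fix/channel_map.yaml --out demo/pseudotime.fcs --trajectories demo/traj.tsv
cytocycle correct-cycle --fcs demo/pseudotime.fcs  --channel-map demo/fix/channel_map.yaml --out demo/corrected.fcs
```

prints

```
wrote demo/fix/sample.fcs (5000 cells, 14 channels)
wrote demo/transformed.fcs; zero substitutions: none
wrote demo/classified.fcs; phase proportions: G0/G1=0.558, S=0.239, G2=0.156, M=0.047
wrote demo/pseudotime.fcs; alpha=(0.0457, 0.3102, 0.2662, 0.3780), total slack 0.00364917 over 46740 constraints
wrote demo/corrected.fcs; divisor floor binding at: no positions
```

Reading the output: the recovered phase proportions match the generator's
(55/25/15/5%) within sampling error; the embedding weights α show
pseudotime is driven mostly by cyclin B1, p-HH3 and p-RB with a small IdU
contribution; the near-zero total slack means the phase ordering is almost
perfectly preserved by the 1-D embedding; and the division floor never
bound, so no marker's mean trajectory approached zero. Each stage writes a
standard FCS file — phase labels as an integer parameter (1=G0/G1 … 4=M)
and pseudotime as a real parameter — so any cytometry tool can consume the
intermediate results. `cytocycle run --config cfg.yaml --outdir out` runs
all stages (plus multi-sample alignment) from a single YAML config; see
`docs/channel_map.example.yaml` for the channel-map schema.

The same pipeline is available as a library:

```python
import cytocycle as cc

sample = cc.generate(cc.GeneratorConfig(n_cells=10_000, seed=1))
transformed, _ = cc.volume_pipeline(sample.matrix, sample.channel_map)
standardized, stats = cc.standardize(transformed, sample.channel_map)
X = standardized.values[:, standardized.column_index(sample.channel_map.cellcycle_in_order)]
model = cc.fit_phase_model(X, sample.truth["phase"].to_numpy(), seed=0)
assignment = cc.assign_phases(model, X, standardized.cell_ids)
weights = cc.solve_ordering_lp(X, assignment, subsample_fraction=0.1, seed=11)
trajectory = cc.embed(weights, X, standardized.cell_ids)
corrected, _ = cc.correct_cycle(standardized, trajectory,
                                list(sample.channel_map.functional_channels))
```

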