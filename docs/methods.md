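# Methods

`pepmaps` implements a minimum-analog-peptide-set (MAPS) workflow for
studying and designing peptide inhibitors of dipeptidyl peptidase IV
(DPP-IV), the serine protease that inactivates the incretins GLP-1 and
GIP.  The pipeline has four statistical stages — descriptor encoding with
a QSAR of inhibitory potency, a response-surface design over side-chain
hydrophobicity, combinatorial candidate ranking, and enzyme-kinetics
analysis — plus a synthetic-data layer that emulates the statistical
structure each stage assumes.

## Descriptor scale and encoding

Each residue carries the three-component structural v-scale: `v1`
(van der Waals volume), `v2` (net charge index of the side chain) and
`v3` (side-chain hydrophobicity).  Raw columns are shipped as a bundled
TSV (`pepmaps/data/v_scale.tsv`).

**Normalization ("z-centering").**  Every column is brought to a common
dimensionless scale by a single affine map per column.  For `v3` the map
is calibrated by least squares against seven published anchor values
(I 0.725, P 0.059, A −0.194, F 0.716, R −1.000, K −0.991, W 1.000); the
fitted map reproduces every anchor to within 0.0025 and is numerically
indistinguishable from min–max scaling onto [−1, 1] (Trp at the top, Arg
at the bottom), which identifies the convention behind the published
values.  `v1` and `v2`, for which no anchors exist, are min–max scaled to
[−1, 1] with the same transform family.  The fitted `(slope, offset)`
pairs are stored in the scale metadata, and a calibration whose anchor
residuals exceed 0.005 raises a "normalization convention mismatch"
rather than silently shipping a different scale.

**Terminal encoding.**  A peptide of length 2–9 is represented by the 12
normalized descriptors of its two N-terminal and two C-terminal residues
(order `N1_v1 … N2_v3, C1_v1 … C2_v3`, with C1 the last residue).
Interior residues are deliberately ignored: the encoding is
length-stable, so peptides of different lengths share one design space.
For dipeptides the two blocks reuse the same residue pair, keeping all 12
model terms defined.  Reversing a sequence exactly swaps the N and C
blocks, a property the test suite checks by construction.

## QSAR of log IC50

The response is Y = log10(IC50/µM) and the model is linear in the 12
terminal descriptors with intercept `c`, N-side coefficients `a(i,j)` and
C-side coefficients `b(i,j)`.  Fitting is partial least squares (NIPALS,
mean-centered; no unit-variance scaling, because the descriptors are
already on one normalized scale).  With the latent-variable count equal
to the rank of the centered descriptor matrix the PLSR coincides with
ordinary least squares, a property enforced to 1e-8 in the tests via an
independent `lstsq` oracle.

**Latent-variable count.**  `n_latent="auto"` sweeps 1..rank and keeps
the count minimizing the leave-one-out root-mean-square prediction error
(ties toward fewer components); the whole sweep is retained on the model
object.  On the bundled 33-peptide panel the sweep is minimized at full
rank (12), where the fit gives R² = 0.659, residual standard error 0.451
log units, F = 3.22 and p ≈ 0.01.

**Fit statistics.**  `rmse` is the degrees-of-freedom-corrected residual
standard error sqrt(SSres/(n − k − 1)) with k the latent-variable count;
the uncorrected sqrt(SSres/n) is exposed as `rmse_raw`.  The overall F
test uses df = (k, n − k − 1).  Treating k as the model degrees of
freedom is an approximation — effective degrees of freedom for PLSR are a
contested quantity — and is recorded here as the package's convention.
The lack-of-fit test compares the retained-component model against the
full-rank OLS reference (no replicate measurements exist for a pure-error
term); a full-rank model is its own reference and returns p = 1.

**Cross-validation.**  `repeated_split_cv` repeats (default 100×) a
uniform random partition into 28 training and 5 test peptides, refits,
and pools the held-out predictions; R²cv = 1 − SSres/SStot over the
pooled held-out set.  This strictly held-out convention is deliberately
conservative: scoring each refit model on the *full* panel (training
rows included) would report roughly 0.58–0.60 on the bundled panel,
whereas the held-out statistic is ≈ 0.15 — collinear descriptors on 28
records extrapolate poorly to the 5 held-out peptides.  The package
reports the held-out value only; conventions that mix training rows into
the score are not offered because they overstate predictive ability.

**Coefficient significance.**  The default is a residual (fixed-design)
bootstrap: residuals are rescaled by sqrt(n/(n − k − 1)) so resampled
errors carry the unbiased variance estimate, resampled with replacement
around the fitted values, and the refit coefficient distributions give
two-sided sign-crossing p-values.  The design matrix is held fixed
because the peptide panel *is* fixed — resampling whole records
(available as `method="case"`) frequently produces near-singular
33-record designs at full rank, inflating coefficient variance and
masking real effects.  On the bundled panel the residual bootstrap flags
exactly the intercept, `N1_v3` and `C2_v3` — the hydrophobicity of the
N-terminal and next-to-C-terminal residues — in agreement with
parametric OLS t-tests on the same full-rank model (p = 0.0009 and 0.044
for the two hydrophobicity terms).

## Hydrophobicity design and response surface

`generate_design` emits the 15-point face-centered central composite
design in three factors: 8 factorial corners, 6 face centers and 1
center point, the smallest standard layout identifying all 10
coefficients of the full quadratic.  Each factor is the normalized `v3`
of one tripeptide position; `assign_residues` maps a coded level to the
pool residue with the nearest `v3` (ties alphabetical).  The published
analog panel itself ships as a fixture (`table2_analogs.tsv`) because
the historical residue choices deviate from pure nearest-neighbor
assignment.

`fit_quadratic` is OLS on the 10-term expansion with per-coefficient
t-tests at α = 0.05 and no multiplicity correction (single pre-specified
model); the expanded 15-point matrix has condition number < 10³.  A
corners-only design raises a rank-deficiency error since the three
squared terms are then confounded with the intercept.  Predictions are
reported clipped to [0, 100] % with the raw polynomial value retained —
near the design boundary the quadratic routinely extrapolates past 100 %.
`enumerate_and_rank` scores the 20×20 library with a fixed position 2
(the Xaa1-Pro-Xaa3 space of interest, 400 sequences) or the full 20³
space (8000), sorted by predicted inhibition.

## Enzyme kinetics

**IC50.**  Dose-response curves (% inhibition vs µM, triplicate) are fit
with a logistic fixed at bottom 0 / top 100 and free Hill slope; the
central estimate pools all replicate points and the reported SD is the
spread of per-replicate fits.  The curve must bracket 50 % inhibition
and the estimate must lie inside the tested range; otherwise the routine
refuses rather than extrapolating.

**Mode of inhibition.**  Initial rates v over a substrate × inhibitor
grid are fit globally with the general mixed-inhibition law
v = Vmax·S / (Km(1 + I/Kic) + S(1 + I/Kiu)) and its nested special cases
(competitive Kiu→∞, uncompetitive Kic→∞, non-competitive Kic = Kiu),
each by log-parameterized least squares multi-started from Hanes–Woolf
estimates.  The winner is the model with the lowest small-sample Akaike
criterion (AICc).  No additional evidence margin is stacked on top of
AICc: at the assay's 96-point grid the criterion already charges the
fourth parameter ≈ 4 log-units of fit improvement, and requiring a
further ΔAICc ≥ 2 was found to cut the power to detect genuine
mixed-type inhibition under the assay's own inhibitor levels (IC50/4 and
below) from ~88 % to ~68 %, defeating the analysis's purpose; the margin
remains available as a parameter for users who prefer a stricter
parsimony rule.  A winning full model whose Kic and Kiu agree within 20 %
is reported as non-competitive.  Lineweaver-Burk lines (1/v vs 1/S per
inhibitor level) are computed for display parity with the classical
plots; double-reciprocal regression distorts the error structure and is
never used for inference here.

## Synthetic data

One global seed fans out to fixed, named sub-streams (`qsar`, `design`,
`dose`, `rates`), so adding a generator never perturbs another's output
and identical configurations are bit-identical.  The generators emulate:
log-linear descriptor activity with Gaussian noise in log10 units
(default n = 40, sd 0.2, signal concentrated on the two terminal
hydrophobicity terms as observed for this enzyme); quadratic design
responses with percentage-point noise, truncated to [0, 100] and flagged
in a `saturated` column; logistic dose-response on a 3-fold serial
dilution 0.69–500 µM; and mixed-law rates on the 0.1–0.6 mM substrate
grid with inhibitor levels at IC50/{16, 8, 4} (IC50 derived from the rate
law at the 0.2 mM assay substrate concentration), four replicates,
multiplicative Gaussian noise (default 3 %).  Kinetic magnitudes default
to Vmax = 1 signal/min, Km = 0.2 mM (typical for the chromogenic
substrate Gly-Pro-pNA), Kic = 10 µM.

What the generators do *not* emulate: inter-assay drift, saturation
artifacts of plate readers, peptide degradation during the assay, or
correlated replicate errors.  Tests passing on these generators
therefore certify the estimators' statistical behavior under the assumed
error model, not robustness to real-assay systematics.

## Numerical choices and degenerate inputs

- Anchor calibration tolerance 0.005 absolute; anchors that cannot be
  met raise instead of refitting a different convention.
- Non-standard residue codes (B, J, O, U, X, Z) are rejected, never
  imputed; input is uppercased, and dash-separated three-letter names
  are accepted.
- PLSR auto-selection breaks LOO ties toward fewer components after
  rounding RMSEP to 12 decimals.
- Noiseless kinetic fits are protected by a floor on SS in the AICc so
  the simpler of two perfectly fitting models always wins.
- Zero or negative rates make double-reciprocal lines undefined and
  raise; the global fits do not require positivity of observations, only
  of parameters (enforced by log-parameterization).
- Bootstrap resamples with a constant response are discarded and redrawn
  (with an attempt cap), since no model is identifiable on them.

## Reported problem sizes

The bundled activity panel has 33 peptides; cross-validation uses 100
random 28/5 splits; coefficient bootstraps use 1000 draws (300 in the
simulation-replicate tests); the dose-response recovery study uses 500
simulated triplicate curves; the mode-classification benchmark uses 500
simulations per inhibition mode at the assay grid with 3 % rate noise;
bootstrap-coverage checks use 25 replicates × 200 draws.

## Known limitations

- The QSAR's cross-validated R² is low in the strictly held-out
  convention (see above); the model ranks potency usefully but its
  absolute held-out predictive power on 33 collinear records is modest,
  and per-peptide IC50 predictions should be treated as order-of-
  magnitude guidance.
- The lack-of-fit test degenerates to p = 1 whenever auto-selection
  keeps all components, which it does on the bundled panel.
- PLSR p-values (model F and bootstrap) treat the latent-variable count
  as known; selection uncertainty is not propagated.
- The kinetics classifier assumes initial-rate conditions and no
  substrate depletion or tight binding; inhibitor depletion at IC50/16
  levels is ignored.
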