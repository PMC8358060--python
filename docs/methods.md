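# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `flnrmap`.

## The nitrogen–carboxylation identity

The package is organised around

    Vcmax25 = α25 · LNC · fNR · fLNR,

with fLNR expressed in percent everywhere a value is reported or stored.
`α25` (specific activity of RuBisCO) defaults to 47.34 µmol CO₂ g⁻¹ s⁻¹
and `fNR` (RuBisCO mass per gram of RuBisCO nitrogen) to 6.25 g g⁻¹;
their admissible ranges, [47.34, 60.0] and [6.11, 7.16], are both the
validation bounds for user overrides and the uniform sampling ranges of
the uncertainty bootstrap. Note that the α25 default is the *lower
endpoint* of its range: point estimates of fLNR are therefore at the high
end of what the constant uncertainty alone would allow, and single-source
uncertainty runs spread about a different mean than the all-sources run
(absolute single-source sds consequently do not add exactly in quadrature
to the total; they do in the centered-constants regime, which is how the
property is tested).

## Temperature standardization

The peaked Arrhenius factor uses Ha = 71513 J mol⁻¹, Hd = 200000 J mol⁻¹,
ΔS = 649.12 J mol⁻¹ K⁻¹, R = 8.314 J mol⁻¹ K⁻¹ and Tref = 298.15 K. The
factor is exactly 1 at 25 °C and has a single interior optimum (≈ 32.7 °C
numerically). Interfaces take °C and convert to Kelvin internally.
Temperature acclimation of the Arrhenius parameters is deliberately not
modelled. A 0.08 floor on the correction factor is available but opt-in,
since it belongs to the optimality-model evaluation context rather than to
the standardization of field observations.

## Synthetic globe

The generator's role is to provide a world in which every downstream stage
has a known answer. Continuous covariates are Gaussian white noise
convolved with a Gaussian kernel (correlation length in cells;
`smoothness=0` gives white noise) and affinely rescaled into documented
realistic ranges (LMA 20–250 g m⁻², LPC 0.05–0.25 g m⁻², VPD 0.2–3 kPa,
pH 4–8.5, PAR 200–1200 µmol m⁻² s⁻¹, sand 10–90 %, and so on). Plant
functional types and Köppen-like classes are contiguous latitudinal bands
with ~10 % categorical noise, which guarantees every class has cells for
per-PFT fits. Cell centers sit on half-degree offsets, latitude indexed
south → north; all gridded I/O records this convention.

Layers default to mutually independent fields. An optional
within-group-correlation knob builds each attribution group's layers from
a small number of shared latent fields plus independent jitter; this
mimics real covariate stacks, where a group's top principal components
carry most of its variance, and is the default for the end-to-end
pipeline configuration (rank 3, jitter 0.05).

Mass-based leaf nitrogen is defined as LNCm = LNC·SLA with SLA an
independent smooth field in 5–25 m² kg⁻¹, so the trait maps reproduce the
grid's LNC layer exactly through LNC = LNCm/SLA; per-cell trait sds
default to 10 % of the means, a typical relative uncertainty for upscaled
trait products.

The ground-truth field is

    fLNR = b0 + Σ c_v · x_v + PFT offset + N(0, noise_sd),

with the slopes c_v defaulting to the global empirical equation
(−0.19·LMA + 42.2·LPC + 4.76·VPD + 0.25·pH + 0.0026·PAR + 0.032·sand).
Two deliberate deviations from a literal reading of that equation:

* **Intercept.** On *independent* uniform covariates the literal
  intercept (2.4 %) yields a mostly negative field (mid-range value
  ≈ −4 %), an artefact of removing the covariate correlations that keep
  the real world positive. The pipeline's default world therefore raises
  the intercept (30 %), which shifts the field but leaves every slope —
  the quantities of interest — unchanged. `make_truth` itself keeps 2.4
  as its signature default.
* **Floor.** Cells still non-positive are floored at 1 % with a warning
  and a count in the truth bundle (conservative relative to the smallest
  plausible allocation of a few percent). Coefficient-recovery
  experiments evaluate the raw linear surface with no floor, since a
  floored response is no longer linear in the covariates.

Site observations scatter around cluster centres (uniform within a
radius, default 1.5°), with a configurable fraction (default 0.3) placed
uniformly as isolated sites. The clusters exercise the spatial
autocorrelation that spatial cross-validation must remove; the isolated
sites are the analogue of sparse single-site records and are, in
practice, what survives the exclusion radius — with purely clustered
sites on a desk-scale domain a 150 km exclusion removes *every*
validation point. Observed Vcmax is the cell's true Vcmax25 projected to
a uniformly drawn leaf temperature (default 10–35 °C) plus Gaussian noise
(default 3 µmol m⁻² s⁻¹), truncated positive.

What the generator does **not** emulate: true Earth geography, real PFT
maps, the actual spatial covariance of climate/soil products, and any
nonlinearity or interaction in the fLNR–covariate relationship. Passing
tests therefore demonstrate correctness of the machinery — recovery of
known structure under the stated noise — not predictive skill on real
maps.

## Upscaling ensemble

`VcmaxForest` fits bagged regression trees (scikit-learn forest with all
features per split, i.e. pure bagging; 200 trees by default; remaining
tree hyperparameters are library defaults). Categorical predictors (PFT,
Köppen class) are one-hot encoded for the trees but treated as a single
unit in ranking and selection: permutation importance permutes all of a
unit's indicator columns with one shared row permutation and scores the
r² drop (5 repeats, averaged); constant predictors score 0.

Forward selection adds predictors in importance order and refits the full
ensemble at each step, stopping at the first step where out-of-bag r²
does not increase *and* out-of-bag MSE does not decrease, both read
strictly with a 1e−6 epsilon to absorb float jitter; the selected set is
the one before the failed step. Out-of-bag metrics are recomputed from a
full refit per step rather than incrementally.

Cross-validation repeats a random holdout (20 % by default). In spatial
mode, holdout rows within the exclusion radius (150 km great-circle,
haversine with Earth radius 6371 km — kilometres rather than degrees
because a degree of longitude shrinks poleward) of *any* training row are
dropped, independently in each repetition; a repetition with no survivors
is skipped with a warning, and the run errors only if all repetitions are
skipped. No species-abundance weighting is applied anywhere.

Gridded prediction reports the per-tree mean and the per-tree standard
deviation per cell; the latter is the map's uncertainty layer. The sd
across trees estimates the (fixed) bootstrap spread — it stabilises with
ensemble size rather than shrinking, which is how the suite tests it.

## Uncertainty bootstrap

Per draw: α25 ~ U[47.34, 60.0] and fNR ~ U[6.11, 7.16] — one value per
iteration shared across all cells, since a physical constant is a single
quantity, not a field; Vcmax25 ~ N(mean, sd) per cell; LNC from paired
positive-truncated Gaussian draws of (LNCm, SLA). Non-positive draws are
redrawn and counted. Per-cell draws are independent across cells (no
spatial coherence is imposed on the map perturbations); the total sd and
four single-source sds (others held at defaults/means) are reported per
cell. Distribution choices follow the information available: uniform
where only ranges are known, Gaussian where sds are mapped.

## Attribution

Groups: leaf traits {LPC, LMA}, climate {Tair, PP, PAR, VPD, SWC}, soil
{soilC, soilN, C:N, pH, sand, silt, bulkD, CEC}. LNC is excluded because
it sits in fLNR's denominator; chlorophyll is excluded from the leaf
group as a remote-sensing quantity rather than a structural trait.
Variables are z-scored; each group's correlation matrix is
eigendecomposed with a deterministic sign convention (largest-magnitude
loading positive). The additive model is

    fLNR ~ Σ_groups Σ_{k≤n_pcs} s(PC_k) + PFT dummies + intercept,

with penalized cubic B-splines (basis dimension 10 per smooth) and
`n_pcs=3` by default. The fit is solved in closed form as Gaussian
penalized least squares, (XᵀX + P)β = Xᵀy with P the block
second-derivative penalty scaled by a fixed weight (α = 1 by default)
— iterative GLM fitting fails outright on noiseless worlds (zero
residual), and because linear functions lie in the penalty null space the
recovery of linear structure is penalty-independent, so a data-driven
penalty search buys little here. Parameter covariance is the sandwich
σ²(XᵀX+P)⁻¹XᵀX(XᵀX+P)⁻¹ with σ² taken at the effective degrees of
freedom.

Partial curves are tabulated on a 100-point lattice spanning each score's
observed range, centered so their mean over cells is zero (the centering
offsets are carried so the additive reconstruction of fitted values is
exact). Group effects are the per-cell sums of a group's centered
smooths; the dominance label is the argmax of |effect| shares, and area
fractions count cells whose share meets each group's threshold (0.50 /
0.30 / 0.15 for leaf traits / climate / soil), cells equally weighted.
PFT levels with fewer than 20 cells are merged into the modal level.

Sensitivities come in two flavours, both reported:

* **Composed path** — per group, OLS of the group's total effect on the
  group's raw (unnormalized) variables; coefficients merge into one
  equation per scope, the intercept being the sum of group-fit intercepts
  plus the scope mean of the model's linear part and centering offsets.
  Per-PFT equations refit on that PFT's cells (minimum 200, else
  skipped). This path is exact only when the retained PCs span the
  signal: with `n_pcs=3` and more than three variables in a group, the
  truncation both discards part of the signal and, on strongly
  rank-deficient covariate worlds, leaves the per-variable attribution
  non-identifiable. Recovery checks therefore use independent covariates
  with the PC count covering full group rank.
* **Direct path** — one multivariate OLS of fLNR on the raw variables,
  the composition the final empirical equation represents; on a noiseless
  linear world it is exact to numerical precision. This is the path the
  acceptance script exercises.

95 % confidence intervals come from the OLS fits; collinear designs
(condition number > 1e8) proceed with the condition number logged.

## Model zoo

The power-form models carry their printed constants
(`e^3.712·LNC^0.65`; `e^3.946·LNC^(0.921+0.282 ln LPC)·LPC^0.121`) and
accept no overrides; note the second form's LPC trend changes sign at
LNC = e^(−0.121/0.282) ≈ 0.65 g m⁻². The PFT-linear and climate-linear
forms require a coefficient file; the shipped
`data/em_coefficients_synthetic.yaml` contains clearly-labelled synthetic
placeholders, not published values. CO₂, absent from the gridded stack,
enters the climate form as a scalar mixing ratio in the coefficient file.
Optimality-model maps are accepted only as external fields for
comparison. Map comparisons (Pearson r, per-PFT distribution summaries,
forest {DBF, EBF, ENF, MF} vs non-forest Welch t-test) use co-valid cells
only, unweighted by area (a cosine-latitude weighting would be the
natural extension; the desk-scale domains here make little difference).

## Determinism and problem sizes

One master seed expands through hashed per-stage seed sequences, so any
stage reruns in isolation bit-identically; the pipeline's JSON report is
byte-identical across reruns under a fixed seed. Default sizes are a
40×80 half-degree window (~2900 vegetated cells), 600 sites, 200 trees,
1000 bootstrap draws; the test suite runs reduced worlds (50–100 trees,
150–400 bootstrap draws, 120–300 sites) chosen so each property remains
comfortably detectable at the reduced size.

## Known limitations

* fLNR here is a multi-year, top-of-canopy quantity: no leaf-age,
  within-canopy, or seasonal variation.
* No variability of the RuBisCO kinetic constant (k25) with species,
  temperature or leaf traits; α25 is a global constant within its range.
* The attribution is associational — additive group structure, no
  interactions, no causal claims.
* The spatial exclusion radius interacts strongly with domain size and
  site clustering; on small domains with dense networks the spatial mode
  legitimately reports that no validation rows survive.
* NetCDF I/O uses the classic (NetCDF3) format via the scipy backend;
  GeoTIFF inputs are not supported.
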