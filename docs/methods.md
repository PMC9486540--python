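# Methods

## The assay being modelled

The stratification assay asks, per patient, whether anti-AChR autoantibodies
in plasma activate complement on AChR-bearing cells.  Complement-regulator-
deficient epithelial cells are transiently transfected with the four AChR
subunits (α1β1δε) plus Rapsyn; Rapsyn scaffolds the receptor into membrane
microclusters, so assembled AChR appears as compact fluorescent spots under
α-bungarotoxin staining, while without Rapsyn the stain is spatially
homogeneous.  Wells are treated under six arms: medium only, Ig-depleted NHS
only (complement source), patient plasma + NHS, plasma + NHS + anti-C7
antibody, plasma + NHS + isotype control, and pooled control plasma + NHS.
Readouts per well are the % AChR-positive cells, the % MAC-positive cells
within the AChR-positive population, and (from a parallel binding assay with
heat-inactivated plasma, i.e. no active complement) the % immunoglobulin-
positive cells with its AChR-negative background.

## Image analysis

**Nuclei** — Gaussian smoothing (σ = 2 px) of the nuclear channel, Otsu
threshold, Euclidean distance transform, peak seeds at ≥ 7 px spacing,
watershed split, minimum-area filter (30 px²).  A constant channel yields
zero nuclei rather than an error.

**Cells** — seeded watershed on the inverted smoothed actin channel, with
foreground = Otsu on smoothed actin OR the nuclei dilated by 2 px.  Exactly
one cell region per nucleus; border-touching cells are kept by default
(configurable).  Coordinates are 0-based row/col pixel indices; label 0 is
background.  The commercial software used for the original assay is
closed-source, so equivalence is asserted against synthetic ground truth
only, not against its outputs.

**Spots** — Laplacian-of-Gaussian blob detection (σ ∈ [1.2, 3.5] px over
3 scales; response threshold 60 intensity units at the generator's default
scales, which sits well above camera noise and the diffuse Rapsyn-free
signal and well below a matched cluster's response).  Each spot is assigned
to the cell containing its centroid (deterministic tie-break for straddling
spots), and its fluorescence is integrated over a 2.5σ disk after
subtracting the median of a 3-px surrounding annulus.  Per-cell readout =
sum of integrated spot fluorescence; positivity = sum > threshold, where the
threshold is either a fixed value or an Otsu split of log1p(sum) computed on
negative-control cells when supplied (a plate-level threshold against
controls) and on the well's own cells otherwise.

## Classification

Fold changes divide each treatment readout by the same-plate NHS-only value;
per-patient values are means over replicate experiments, computed before
classification.  The ordinal bands share printed endpoints, so intervals are
half-open with each shared boundary assigned to the milder class (fold 0.8
→ `-`, 1.3 → `-`) and percentage bands lower-bound inclusive (15% → `+`).
Values beyond the printed scale saturate: AChR fold > 1 → `-`, < 0.3 → `++`
(that scale's maximum); MAC fold < 1 → `-`, > 3.5 → `+++`.  Background-
corrected Ig binding is floored at 0 (a negative percentage is a subtraction
artefact).  No reference-cohort class assignment depends on an exact
boundary value, so the boundary convention is free.

Anti-C7 blockade is formalized as a class-step rule, since the source labels
("yes", "yes (partially)") carry no numeric criterion: not applicable when
the plasma arm shows no loss; *yes* when the anti-C7 arm reverts to `-`
while the isotype arm matches the plasma arm; *partial* when the anti-C7 arm
improves by ≥ 1 class step without reaching `-`; otherwise *no*.

Category assignment follows the reference cohort's structure exactly:
AChR-loss `++` → category 1, `+` → 2, otherwise IgG binding ≥ `++` → 3,
else 4.  This reproduces all 19 published patient rows; the blockade column
is reported but is not needed to discriminate any observed combination.

Which population supplies the uncorrected minuend of the Ig background
correction (% Ig-positive among all cells vs among AChR-positive cells) is
ambiguous in the source protocol; the default is all cells, with an
`ig_population` switch throughout.  The imaging pipeline is typically run
with `achr_pos`, which makes the corrected percentage independent of
transfection efficiency and puts archetype cohorts on the same scale as the
tabular generator.

**Known discrepancy.** The published per-patient table lists 6 category-4
patients (9 + 3 + 1 + 6 = 19 = the stated cohort size) while the cohort
figure legend says 7 (summing to 20).  The package reports the computed
count and flags the inconsistency in its documentation rather than
resolving it.

## Spearman correlation

`spearman_correlation` returns two-tailed rho/p via rank correlation plus a
confidence interval from the Fisher transform, `tanh(atanh ρ ± z·(n−3)^-½)`.
This large-sample interval is approximate for the small cohorts involved
(n ≈ 19); perfect monotone inputs return a degenerate interval at ±1, and
constant inputs an undefined (NaN) rho.

## Dose-response

The 4PL model is `y = bottom + (top − bottom)/(1 + (x/x_half)^hill)`; with
top > bottom the response decreases with x for hill > 0 and increases for
hill < 0, and `x_half` is reported as EC50 or IC50 depending on assay
direction.  Fitting is nonlinear least squares (trust-region, tolerances
1e-14) with the inflection parameterized on a log scale so it stays
positive; initial values are bottom = min(y), top = max(y), x_half = the
geometric median of x, hill = ±1 by response direction.  Optional 1/y²
weighting (immunoassay standard curves) enters as 1/|y| residual scaling
with a floor at 1% of the response span to guard near-zero responses; an
optional fixed top supports inhibition curves known to reach 100%.
A constant response or fewer than 5 points is rejected.  Back-interpolation
inverts the fitted curve and multiplies by the dilution factor; responses at
or beyond the asymptotes are flagged below/above the detection range, never
extrapolated.

## Synthetic data generator

The generator emulates the assay, not the optics: cells are placed on a
jittered grid (dense, non-overlapping, deterministic), nuclei and cell
bodies are rendered as 2-D Gaussians, and clustered signal as Gaussian spots
with Poisson counts (mean 4/cell) and lognormal amplitudes (σ = 0.25).
Within a cell, spots keep a minimum separation of ~3 spot radii — receptor
microclusters are discrete objects — which keeps the per-cell spot count a
well-posed ground truth for detector validation.  Camera noise is Poisson
shot noise plus Gaussian read noise (sd 4), both optional so tests can run
noiseless.  Defaults emulate a 10X field: 1024×1024 px at 0.65 µm/px with
500 cells, half transfected.

Treatment-arm effects are multiplicative factors on the phenotype's
complement activation `ca ∈ [0, 1]`: under complement-active arms (plasma,
plasma+isotype) the retained fraction of cluster-bearing cells is
`1 − 0.55·ca` (complement strips the receptor clusters from whole cells, so
the mean AChR spot sum is attenuated by exactly that loss factor and the
%-positive readout tracks it), and the MAC spot rate per AChR-bearing cell
is `0.15·(1 + 2·max(0, ca − 0.45))`.  The anti-C7 arm reverts both factors
to the NHS-only baseline; medium-only has no complement source and no MAC.
These slopes were chosen once so that the four archetype phenotypes
(cat1: binding 0.60 / ca 1.0; cat2: 0.35 / 0.5; cat3: 0.50 / 0.0;
cat4: 0.06 / 0.0) land in the middle of the published class bands —
archetype cat1 gives AChR fold ≈ 0.45 (`++`) with MAC fold ≈ 2 (`++`),
cat2 ≈ 0.72 (`+`) with MAC `-`, cat3 binds without loss, cat4 neither — and
they are the study conditions for all round-trip tests.

Randomness is structured for reproducibility and couplings: identical
config + seed is bitwise identical; each cell draws from its own seeded
streams, with ablation driven by a shared uniform and MAC counts by
inverse-CDF Poisson on a shared uniform, so increasing `ca` can only ablate
more cells and only add MAC spots (the monotonicity the tests assert).

The tabular fast path emits well-level percentages directly (baselines 42%
AChR-positive, 14% MAC-within-AChR-positive, 5% multiplicative fold noise,
1.5% additive percentage noise, 3 replicate plates per patient, per-patient
phenotype jitter sd 0.05) for cohort-scale tests without imaging.

What the generator does *not* model: illumination fields, PSF/optical
aberrations, cell-shape variation, debris, focus drift, plate edge effects,
or correlations between binding strength and titre.  Passing tests
therefore demonstrate the correctness of the analysis chain on data obeying
the assay's idealized structure, not robustness to real-microscopy
artefacts.

## Problem sizes and numerical choices

The shipped tests validate segmentation and spot recovery on 256–512 px
fields with 30–120 cells (noiseless for exact ground-truth checks, default
noise for robustness checks), run the image pipeline end-to-end at 256 px,
and run cohort round-trips on 20 tabular patients; these desk-scale sizes
are the package's chosen test conditions.  The full-scale imaging run
(20 patients × 5 arms at 1024², ~500 cells/field) is exercised via
`mgstrat run` with the default field settings.  Noisy 4PL recovery is
assessed on triplicate 11-point titrations (as the hemolysis assays are
run), summarizing the inflection's relative error by its median over 100
noise realizations.

## Known limitations

- Segmentation is classical (threshold + watershed); confluent monolayers
  with weak actin contrast or strongly overlapping nuclei will undersegment.
- The LoG response threshold is expressed in raw intensity units and must be
  rescaled if the intensity scales change by more than ~an order of
  magnitude.
- The Fisher-z Spearman interval and the class-step blockade rule are
  pragmatic formalizations; neither has a published numeric specification.
- The generator's arm effects are population-level multiplicative factors;
  it does not model per-cell heterogeneity in complement susceptibility.
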