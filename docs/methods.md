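# Methods

This note records the models, numerical conventions and design choices
behind `spectroinflame`, and what the synthetic validation does and does
not demonstrate.

## Data model

The atomic unit is a `Spectrum`: absorbance on a strictly descending,
uniformly spaced wavenumber axis (cm⁻¹). Descending storage matches the
FTIR plotting convention, and every window argument in the package is
`(high, low)` cm⁻¹ with closed ends — a point at exactly 1600 cm⁻¹ belongs
to the 1700–1600 amide-I window. Uniform spacing is enforced at axis
construction (relative tolerance 1e-6) because the derivative filter
assumes an equidistant grid. The default axis spans 1900–700 cm⁻¹ at
4 cm⁻¹ point spacing — half the nominal 8 cm⁻¹ spectral resolution of the
emulated acquisition, a typical zero-filled digitization; the spacing is a
configuration parameter, not a claim about any instrument.

`HyperspectralImage` adds a rows × cols pixel grid with `int8` labels
(−1 background, 0 MC, 1 SubMC, 2 MP, 3 unassigned tissue).
`SampleRecord` holds the averaged representative spectra of one
(animal, section, layer); `CohortSet` is a list of records on one axis.
Records — not pixels and not animals — are the statistical unit for group
tests and train/test stratification: pixels of one section are strongly
correlated (pseudo-replicates), while animal-level grouping is available
but not the default.

## Synthetic cohort generator

Each spectrum is a sum of Gaussian bands plus nuisance terms:

    A(ν) = Σ_b amp_b · m_layer(b) · m_sev(b) · (1 + ε_b) + baseline(ν) + noise(ν)

* **Band table.** Thirteen bands at the canonical tissue positions:
  amide I α-helix 1650 and β-sheet 1635, amide II 1545, protein 1481,
  lipid ester 1739, the collagen triplet 1280/1230/1200, glycogen
  1151/1076/1028, RNA 1115 and DNA 960 cm⁻¹. Widths (σ 8–16 cm⁻¹) and
  base amplitudes (0.07–1.0 AU) are generator choices. Two amplitudes are
  deliberately balanced: the glycogen 1076 band is kept at 0.12 AU and RNA
  1115 raised to 0.12 AU so that the RNA quantification window
  (1120–1080 cm⁻¹), which the 1076 tail overlaps, gains area with
  severity as inflamed tissue does; with a dominant 1076 band the falling
  glycogen signal would swamp the rising RNA signal inside that window.
* **Layer chemistry.** Multipliers encode the layer contrasts: β-sheet
  amide I strongest in SubMC, collagen ~3× higher in SubMC than MC/MP,
  glycogen highest in MC, amide bands strongest in MP, DNA depleted in MP.
  Config validation requires every layer pair to differ by ≥20 % in at
  least one band, so layers stay machine-distinguishable.
* **Severity effects.** Grade multipliers (control/mild/moderate/severe):
  protein 1.00/1.15/1.30/1.50, collagen 1.00/1.10/1.20/1.35, DNA & RNA
  1.00/1.20/1.45/1.80, glycogen 1.00/0.90/0.75/0.60. Directions follow the
  quantified biology (protein, collagen, nucleic acids up; glycogen down);
  the magnitudes are working defaults, monotonicity is validated.
* **Grading-noise overlap.** Inflammation is modelled as a continuous
  latent intensity on the grade scale (control = 0 … severe = 3). Each
  animal draws its intensity around the assigned grade
  (sd 0.35 grade units, scaled per grade by 0.4/0.6/1.8/0.5), and each
  section adds a further scaled draw (sd 0.35). Band multipliers are
  linearly interpolated along the severity curve at that intensity,
  floored at 0 ("healthier than control" does not exist) and extended by
  linear extrapolation half a grade above severe (inflammation does not
  stop at the grading cutoff). The large moderate scale encodes the
  well-known fact that inter-observer agreement of histological scoring is
  poorest for intermediate grades; it is what makes adjacent grades
  overlap and the moderate class consistently the hardest to classify.
* **Nuisance terms.** Per-band relative amplitude jitter (cv 0.05 per
  spectrum) and a shared per-band per-animal effect (cv 0.04) — per-band
  rather than a global scale factor, because SNV would cancel a pure scale
  change; a random per-pixel quadratic baseline (offset U(0, 0.05), tilt
  and curvature U(−0.02, 0.02) over the normalized axis), which makes
  rubber-band correction non-trivial; iid Gaussian pixel noise
  (sd 0.005 AU against an amide-I amplitude of ~1 AU).
* **Reproducibility.** All draws come from a hierarchical seed tree
  (cohort → animal → section → spectrum, via `SeedSequence` spawn keys), so
  adding spectra to one animal never changes another animal's draws, and a
  fixed seed reproduces the cohort bit-for-bit.

What the generator does **not** emulate: Mie and resonant-Mie scattering,
paraffin residues, atmospheric water-vapour/CO₂ lines, detector drift,
instrument line-shape convolution, and spatial correlation between
neighbouring pixels. Passing tests therefore demonstrate the correctness
and calibration of the analysis chain under a controlled band model — not
performance on real tissue spectra, whose artefacts the out-of-scope EMSC
family of corrections would have to handle first.

## Preprocessing

Two fixed stage orders:

* quantification: crop → background removal → rubber band → averaging;
* classification: crop → background removal → SG second derivative → SNV
  → averaging → SNV.

Choices worth recording:

* **Crop** keeps axis points inside the closed 1801–798 cm⁻¹ window
  (first/last retained points 1800 and 800 on the default axis).
* **Rubber band** is the lower convex hull (Andrew monotone chain, O(n)),
  interpolated between vertices; the corrected spectrum is ≥0 and exactly
  0 at hull vertices including both endpoints. It is invariant to added
  affine baselines and annihilates convex spectra; tests verify
  equivalence with an O(n³) pairwise-chord oracle.
* **Savitzky–Golay** uses a 9-point, 3rd-order, 2nd-derivative filter.
  The derivative is scaled by the signed axis step to the −deriv power, so
  the result is d²A/dν² in AU·cm², independent of spacing and storage
  direction. Edges are fitted with their own least-squares polynomials
  (`mode="interp"`) rather than reflect-padded: reflection breaks the
  filter's polynomial exactness at the boundary, while edge fitting keeps
  SG(9,3,2) exact (2a) at *every* point of a sampled quadratic. The filter
  attenuates genuine peak curvature (≈22 % for σ = 16 cm⁻¹ bands at
  4 cm⁻¹ spacing) — acceptable because downstream models only need
  consistent band sharpening, not absolute curvature.
* **SNV** divides the centered spectrum by its n−1 standard deviation and
  raises on constant input. Because bin means of unit-variance spectra are
  not unit variance, classification mode reapplies (idempotent) SNV to
  each averaged representative, so pipeline outputs are exactly mean-0 /
  sd-1. SNV is per spectrum over the whole cropped region — no pooling
  across spectra.
* **Background removal**: a pixel is background when its rubber-band
  corrected amide-I area falls below 10 % of the image maximum; amide I is
  used because it is the dominant tissue band. The criterion precedes both
  branches, so quantification and classification see the same pixel set.
* **Averaging**: pixels are shuffled with a fixed seed and split into
  exactly `n_avg` (default 25) near-equal bins (sizes differ by ≤1), each
  replaced by its pointwise mean; with fewer pixels than bins, pixels pass
  through unchanged. A seeded random partition is unbiased and
  reproducible.

## Band quantification

Band areas are trapezoidal integrals over closed windows of rubber-band
corrected absorbance (derivative spectra are never integrated). Default
windows: amide I 1700–1600, amide II 1580–1510, collagen 1300–1200,
glycogen 1250–1000, RNA 1120–1080, DNA 979–948 cm⁻¹. Group comparisons
take one mean area per record and apply Welch's unequal-variance t-test
(Welch–Satterthwaite df, two-sided p). No multiple-testing correction is
applied by default; a Holm step-down helper is provided. Calibration is
tested two ways: the p-value of a fixed 4+4 example matches a 10⁶-draw
permutation oracle within 0.01 (mid-p convention, which is the appropriate
comparison for a heavily tied discrete permutation null), and the type-I
error over 1000 null cohort simulations stays within 0.05 ± 0.02.
Note that with multiple sections per animal the record-level test ignores
animal-level correlation; the null simulations use one section per animal.

## PLS-DA and VIP

NIPALS PLS1 on mean-centered X and ±1-coded classes, deflating X and y per
component; the regression vector is B = W(PᵀW)⁻¹q and prediction is a sign
threshold at 0. The positive class defaults to the lexicographically
larger label ("severe" against "control"). With all min(n−1, p) components
the coefficient equals the least-squares solution (verified against the
normal-equations oracle), and an independent cross-check against a
reference PLS implementation agrees to 1e-8.

VIP uses the x-weight convention, VIP_j = √(p·Σ_a SSY_a w_aj² / Σ_a SSY_a)
with unit-norm weight vectors and SSY_a = q_a²‖t_a‖²; mean VIP² = 1 is an
algebraic identity asserted for every fitted model. Venetian-blind CV
sorts samples by class then index and assigns fold f every n_blinds-th
sample (default 10 blinds), keeping folds class-balanced; the LV count is
the smallest one achieving the global minimum CV misclassification
(parsimony tie-break). Follow-up Welch tests merge contiguous
VIP-significant (>1) wavenumbers into bands (integrated area per record)
and treat isolated points at peak intensity.

## Severity models

PCA (full SVD) keeps the fewest components reaching 95 % cumulative
variance, fitted on the training partition only. Base learners and their
defaults — ANN: one hidden layer of 100 logistic units, ≤300 epochs;
SVM: RBF kernel, C = 1, pairwise-coupling probabilities; RF: 500 trees,
√p features per split; kNN: k = 5 Euclidean on the reduced scores. All are
seeded and config-overridable. Per-class winners on an inner validation
split (by one-vs-rest AUROC, deduplicated, minimum two bases) are stacked:
out-of-fold class probabilities from an inner stratified 5-fold generate
the training matrix for a multinomial-logistic meta-learner, then the
bases are refitted on all training data.

Evaluation repeats a record-level stratified 70/30 shuffle split (all
spectra of a section stay on one side; every class keeps at least one
record on each side) ten times, reporting per-class one-vs-rest AUROC
(rank statistic, midrank ties) and per-class one-vs-rest classification
accuracy, per repeat and averaged. Under the default study conditions the
moderate grade attains the lowest mean AUROC in ≥7 of 10 independent
re-runs — the expected signature of the grading-noise overlap model, since
moderate is squeezed by both neighbours and carries the widest grading
noise.

The layer segmenter preprocesses pixels in classification mode, trains a
15-hidden-unit logistic MLP on exactly 10 pixel spectra per layer for 100
epochs, and labels tissue pixels by argmax probability; background pixels
pass through. On independent synthetic images at default noise it reaches
≥0.9 pixel accuracy (typically ≈1.0).

## Orchestration and reproducibility

`run_all` executes synthesize → preprocess → quantify → PLS-DA → severity
→ segment from one config, deriving per-stage seeds by hashing the stage
name with the global seed (stages are independently reproducible). Every
artifact's logical content (arrays + metadata, not raw file bytes, so
hashes are independent of HDF5 library details) is SHA-256 hashed into a
manifest; identical config + seed reproduces identical manifests, and
resumption verifies stored hashes before trusting intermediates.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
binary discrimination uses 3 animals per class × 2 sections × 3 layers ×
25 representative spectra; the severity ensemble uses 4 animals per class
× 2 sections × 10 spectra of the submucosa with 5–10 hold-out repeats;
segmentation images are 17 × 10 pixels with 5-row stripes. These sizes
exercise every code path with stable statistics on a single CPU; all
counts are configuration parameters.

## Known limitations

* Binary PLS-DA only; the four-grade problem is handled by the ensemble,
  not by multi-class PLS.
* No EMSC/Mie correction, atmospheric compensation or vendor file formats
  (HDF5, long CSV and JCAMP-DX XYDATA only).
* The Welch record-level tests treat sections of one animal as
  independent.
* Synthetic severe-vs-control separation is stronger than in real tissue;
  absolute sensitivities/specificities on synthetic cohorts should not be
  read as instrument performance estimates — the informative outputs are
  the calibration properties and the relative class ordering.
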