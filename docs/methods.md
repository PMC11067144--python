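# Methods

## The measurements

### Locus coeruleus signal intensity

Neuromelanin-sensitive turbo-spin-echo T1 images show the LC as a small
bilateral hyperintensity in the dorsal pons.  The pipeline quantifies it with
three rectangular template boxes: a rostral pontomesencephalic reference
region of 6200 mm³ and one 700 mm³ box per coeruleus–subcoeruleus complex,
placed so that no other bright structure (e.g. substantia nigra) falls inside
the LC boxes — distractors are handled by box placement, not by the search.

**Box construction.**  Boxes are built in voxels at the requested spacing.
The voxel count is chosen so count × voxel-volume is as close as possible to
the target (always within one voxel volume).  At 0.4 × 0.4 × 3 mm the
required counts (12 916/12 917 for the reference box) have no usable cuboid
factorisation, so a box is a stack of full rectangular slices plus a partial
final slice filled in deterministic linear order.  The left/right LC boxes
are exact mirror images about the grid's mid-sagittal plane.  Boxes are
resampled to native space by nearest-neighbour labelling: a native voxel
joins a box iff its template pre-image rounds into that box.

**Brightest-connected search.**  "The k brightest connected voxels" is
formalised as greedy seeded growth: seed at the box's maximum-intensity
voxel, then repeatedly add the highest-intensity voxel adjacent to the grown
set (26-connectivity by default; 6/18 available) and still inside the box,
stopping at k = 10 or when the frontier empties (a short set is a QC flag,
not an error).  All ties break on the smallest linearised voxel index
(x fastest, then y, then z), making the output bit-reproducible.  The exact
maximum-sum connected k-subset problem is NP-hard; an exhaustive enumerator
(k ≤ 6, small boxes) is provided as a slow cross-check, and an independently
coded re-derivation of the greedy rule serves as the test oracle.  k is
interpreted per side — one search per 700 mm³ box — because the geometry
defines one box per LC.

**Normalisation.**  LC-I defaults to the ratio m/r (selected-voxel mean over
reference-region mean); the contrast form (m − r)/r is available since both
appear in the neuromelanin literature.  Both are invariant under global
intensity rescaling.  Automated QC (selected set connected, inside its box,
of full size, centroid inside the box) replaces visual checking; voxels are
never edited.  A side failing QC is dropped from the bilateral average and
flagged; the other side is reported alone.

### NBM volumetry

A template-space binary NBM mask is pulled onto the native grid through the
subject's template→native map (the inverse of the spatial normalisation;
computing the registration is out of scope).  Values are trilinearly
interpolated and thresholded at 0.5 — smoother volume estimates under small
deformations than nearest-neighbour, which remains available by flag.  Volume
is voxel count × voxel volume per side; the side average is normalised to
ICV with a per-mil convention (raw mm³ always reported alongside, since the
units of published normalised volumes are rarely stated).  ICV is a required
cohort input.  Bilateral masks are split at the grid mid-sagittal plane when
side-labelled masks are not supplied.

Transforms are φ(p) = A(p + u(p)) with A affine and u a displacement field
sampled on the template grid.  Inverses are evaluated by fixed-point
iteration; constructors enforce 2πa/λ < 1 for the sinusoidal test fields
(amplitude a, period λ), which makes u a contraction and the map injective.

### Composite VOIs

Regional tables in the whitespace/`#`-comment stats dialect (per-hemisphere
cortical tables with volume/thickness/area; a segmentation table for
subcortical volumes) are parsed into a tidy per-subject frame.  Thickness
composites are surface-area-weighted means of member parcels per hemisphere
(the standard meta-ROI convention; a plain mean is a flag away, since
published tables rarely say which was used), volume composites are sums;
both are then left/right averaged.  Member parcel lists ship as an editable
YAML config; medial-temporal volumes get the same per-mil ICV normalisation
as the NBM for internal consistency.

### Statistics

Pairwise group differences use ANCOVA: OLS of the measure on a group
indicator plus age and sex, reporting the group coefficient (two-sided;
F = t² for the single-df contrast).  Partial correlations residualise both
variables on [1, covariates] and correlate the residuals; p comes from
t = r√(df/(1−r²)) with df = n − 2 − q, q counting encoded covariate columns
(group enters as reference-coded dummies in pooled-patient analyses).
Missing cells are deleted listwise per test and the n used is always
reported.  Bonferroni correction is applied within declared families:

* A — LC-I and NBM, each patient group vs controls: 2 × 3 = 6 tests;
* B — eight other imaging measures × all six pairwise contrasts = 48;
* C — five cognitive measures × six contrasts = 30;
* D — {LC-I, NBM} × eight imaging measures × four analysis sets
  (pooled patients + three patient groups) = 64 partial correlations;
* E — the cognitive-correlation family: 2 × 5 × 4 = 40 tests computed, with
  a configurable declared size defaulting to 48.  The published family size
  for this analysis does not factor into the computed test count, so it is
  exposed as a parameter rather than guessed; a family may legitimately be
  declared larger than the tests actually run (Bonferroni stays valid, just
  conservative).

Family A is patient-vs-control only because 2 × 3 reproduces the declared
six tests, while families B/C need all pairwise contrasts (8 × 6, 5 × 6) to
reproduce 48 and 30.  All tests are two-sided.

## The phantom

The generator emulates the measurement context, not anatomy:

* **TSE slab** — 256 × 256 × 20 grid at 0.4 × 0.4 × 3 mm (the slab's field
  of view is configurable; no published value exists), uniform background
  b = 100, one compact connected cluster of exactly `lc_cluster_voxels`
  (default 20) voxels of intensity b × contrast grown around each native LC
  box centre, optional 8-voxel distractors (1.5 × b) strictly outside all
  boxes, and additive Gaussian noise (σ = 2, i.e. 2% of background, as
  single-precision draws).  Rician magnitude noise is available; Gaussian is
  the default because it keeps closed-form checks simple, while real MR
  magnitude noise is Rician.  Ground-truth voxel sets are recorded before
  noise.  The template→native transform is a small per-subject in-plane
  translation (≤ 1.5 mm).
* **NBM** — a synthetic two-blob template (mirror ellipsoids, semi-axes
  3.55 × 8.15 × 3.45 mm ≈ 420 mm³ per side) on a 0.5 mm grid; the
  half-millimetre sampling and off-lattice semi-axes keep the discretisation
  error of so small a structure near one percent, which 1 mm voxels cannot.
  A real atlas mask can be supplied by path (the actual atlas is copyrighted
  and is not shipped).  The deformation is isotropic scaling by the group
  factor about the mask centroid composed with a sinusoidal displacement
  (a = 0.5 mm, λ = 20 mm, random phase), invertible by construction.
* **Cohort table** — group sizes default to 15/23/17/17
  (Control/AD/LATE/FTD); ages, sex ratios and the means/SDs of the cognitive
  and imaging measures default to values representative of such clinical
  cohorts (LATE ~7 years older; the cohort's LC-I missingness pattern of
  1 LATE + 5 FTD subjects is injected by default and is configurable).
  Group effects on LC contrast (1.30 control, 1.18 AD/LATE, 1.22 FTD) and
  NBM scale (1.00 / 0.85 / 0.88 / 0.88) are free parameters chosen to
  produce a clear AD-type deficit and a milder FTD one.  Measures and scores
  are a joint Gaussian around the group/covariate structure whose residual
  correlation matrix realises any requested conditional correlations
  (non-positive-definite requests error); the default is uncorrelated
  residuals.  Cognitive scores are generated unbounded (no ceiling at the
  scale maximum) to keep correlation calibration simple; truncation would be
  a one-line post-processing option.
* **Regional stats files** are generated as numbers, not from images:
  parcel thicknesses are the minimum-norm solution reproducing the drawn
  composite values exactly (parcels shared between composites receive
  intermediate values), all parcels carry equal surface area, and per-side
  volumes are written as value × ICV/1000 so the parsed, normalised
  composites recover the drawn measures.

What passing phantom tests do **not** show about real data: anatomy-induced
intensity gradients, partial-volume and motion effects, registration error
(transforms here are known exactly), atlas-mask validity, or the behaviour
of FreeSurfer itself — only the downstream arithmetic, search, resampling
and inference are validated.

## Numerical choices

* Tie-breaks everywhere by smallest linear voxel index; identical
  (design, seed) inputs give bit-identical images, tables and CSVs (per
  (seed, stage, subject) RNG streams; CSVs written with fixed float format).
* Warped-mask threshold 0.5; fixed-point inverse tolerance 1e-6 mm.
* Partial correlations clip |r| to 1 and error on (near-)zero residual
  variance (tolerance 1e-10 relative).
* ANCOVA refuses singular designs (e.g. a single-sex group with a sex
  covariate) and groups with fewer than three complete cases.
* Degenerate inputs error early and name the offending box/side/region.

## Problem sizes used in the validation suite

Simulation-based checks use: 1000 random 8 × 8 × 4 grids for greedy/oracle
equivalence; 100 noisy subjects for the extraction-vs-truth comparison;
n = 5000 for partial-correlation recovery (3 Fisher-z SE tolerance); 2000
null cohorts of 50/50 for ANCOVA type-I calibration and 500 replicates of
20/20 for power; a 40-subject image cohort for end-to-end determinism.
These sizes give the stated statistical tolerances while keeping the suite
runnable on one CPU in minutes.

## Known limitations

* The greedy rule is a formalisation of an unpublished in-house procedure;
  other formalisations (e.g. exact search, joint bilateral search) could
  select different voxels on adversarial intensity patterns.
* Volume estimates inherit grid discretisation error (~1–2% for the bundled
  template); very coarse grids or very small masks degrade further.
* The statistics layer implements the fixed published-style plan; it is not
  a general modelling framework (no mixed models, no FDR alternatives).
* Phantom realism is deliberately minimal (see above).
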