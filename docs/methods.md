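# Methods

## The optimization problem

A 4D-CT study sorts a free-breathing acquisition into ten 3D volumes, one
per 10%-wide bin of the respiratory cycle (phase 0 near maximal
inspiration by convention, but not by construction — the reference is
detected, not assumed).  Given delineated binary masks for the gross tumor
volume (GTV), the left and right lungs and the spinal cord on every phase,
the pipeline reduces each phase to two scalars:

- **T/L ratio** `= 100 · V(GTV) / V(ipsilateral lung)`, dimensionless on
  the percent scale.  A small ratio means the target occupies a small
  fraction of the lung that must be partially irradiated, favoring lung
  sparing.  Lower is better.
- **T–C distance** (mm): clearance between tumor and spinal cord, the
  organ at risk with the highest-priority dose constraint.  Higher is
  better.

The ipsilateral lung volume curve across the ten phases serves as the
inspiration surrogate: the **reference phase** is the phase of maximal
ipsilateral lung volume (ties break to the lowest phase index).  It can be
overridden per patient.

For each parameter the optimal phase is the argmin (T/L) or argmax (T–C),
ties to the lowest index; the worst phase is the opposite extreme.  Gains
are relative improvements over the value being improved upon:

    gain_vs_ref   = 100 · |v_ref  − v_opt| / v_ref
    gain_vs_worst = 100 · |v_worst − v_opt| / v_worst

Both are always computed.  This denominator convention, population-SD
(divisor N) cohort statistics, and display rounding half away from zero
are the unique combination that reproduces every derived cell of the
bundled reference cohort from its per-phase values; they are therefore
fixed, not configurable.

### Classification

With cutoff c (default 20%):

- **no_benefit** — none of the four gains exceeds c;
- otherwise the **driving parameter** is the one exceeding c, T/L taking
  precedence when both do (the volumetric parameter is the primary
  criterion; the distance acts as a safety check);
- **max_inspiration_optimal** if the driving parameter's optimum is the
  reference phase, **other_phase_optimal** otherwise;
- **inconclusive** under the optional `strict_concordance` rule when both
  parameters exceed the cutoff but point at optima more than one phase
  apart, neither being the reference.  This branch is deliberately
  conservative and off by default: the underlying clinical rule is the
  least standardized part of the procedure.

## Distance conventions

The T–C distance default is the minimum voxel-center-to-voxel-center
Euclidean distance between GTV and cord, with anisotropic spacing
respected; it is computed with an exact Euclidean distance transform of
the cord mask sampled at the GTV voxels and is contract-tested to equal
the brute-force all-pairs minimum.  Because published distance values are
sometimes reported under other conventions (and per-patient magnitudes
such as 165 mm are hard to reconcile with a minimum gap), three
alternatives are exposed via `distance_mode`: `min_surface`
(boundary-voxel restricted), `centroid_to_surface` and
`centroid_to_centroid`.  All modes agree on the phantom's geometry up to
the analytically expected offsets; the default is the only one that is a
true lower bound on the tumor–cord gap.

Surface areas use the exposed-voxel-face convention (faces bordering
background or the grid boundary), which is deterministic and mesh-free.
Masks are strictly binary; any float or label input is thresholded at
> 0.5.  World coordinates are voxel centers, `origin + index · spacing`.

## The bundled reference cohort

`data/cohort_*.csv` transcribe a published 14-patient lung-cancer 4D-CT
cohort: ten per-phase values per patient for both parameters, the derived
gain columns, and an "optimal phase equals reference" flag.  The tables do
not print the per-patient reference phase, so it is inferred by constraint
propagation: a candidate phase must reproduce the printed
gain-vs-reference in both tables after display rounding; a printed flag
constrains the candidate only when it is internally consistent with its
own printed gain (one patient's "yes" flag sits next to a 67% gain and is
dropped as self-contradictory).  The inference is unique for all fourteen
patients (phase 0 for eleven, phase 1 for two, phase 4 for one).

One patient's *declared* reference (phase 6, carried in
`cohort_meta.csv`) contradicts the phase 4 inferred from the printed
gains; no single baseline explains that patient's published row.  Gains
are computed against the inferred reference — the only baseline consistent
with the printed numbers — and the patient is classified **inconclusive**,
since a benefit judgment against an ambiguous baseline is not defensible.
Under this rule set the cohort splits 4 / 7 / 2 / 1
(maximal-inspiration-optimal / other-phase-optimal / no-benefit /
inconclusive), and the two no-benefit patients are exactly the ones with
all four gains at or below 20%.

Cohort summary statistics are reported two ways: `summarize()` on the
full-precision gains, and `rounded_gain_summary()` on the display-rounded
columns.  The latter is what a published integer-valued table implies and
is the form used for cross-checks against printed summary statistics.

## The synthetic phantom

The phantom emulates the study conditions at desk scale:

| component | model | default |
|---|---|---|
| lungs | two ellipsoids, mirrored; semi-axes scale as (volume scale)^(1/3) | semi-axes (45, 60, 85) mm ≈ 0.96 L each |
| inspiration | raised-cosine volume scale, max at `inspiration_phase` | +15% at phase 0 |
| cord | vertical cylinder spanning the grid | radius 6 mm, posterior midline |
| tumor | ellipsoid with equal transverse semi-axes | (10, 10, 14) mm ≈ 5.9 cm³, right lower lobe |
| motion | raised-cosine displacement, rest at cycle ends | 12 mm cranio-caudal (reported lower-lobe average); optional antero-posterior component toward the cord |
| noise | Gaussian HU noise on intensities only, seeded | σ = 15 HU |
| grid | 128³ at 2 mm (default); 256³ at 1 mm for recovery runs | |

Masks are exact voxelizations (voxel center inside the analytic shape) and
noise-free — segmentation is taken as given, matching the intended input
contract.  The equal-transverse-axes constraint on the tumor makes the
cord clearance closed-form (`axis distance − transverse semi-axis − cord
radius`), so every pipeline output has an analytic counterpart
(`expected_table`).  The generator validates that the tumor stays inside
the grid and the ipsilateral lung on every phase and names offending
phases.  Full ellipsoids rather than diaphragm-truncated ones keep the
volume closed form trivial; none of the validated quantities depends on
the lung's caudal shape.

What the phantom does *not* emulate: CT texture, deformable motion and
hysteresis, irregular breathing, segmentation error.  Passing recovery
tests therefore demonstrates the correctness of the morphometric and
decision machinery on known geometry, not robustness to clinical
delineation variability.

### Parameter recovery (measured by the acceptance script)

At 1 mm spacing on the 256³ grid, the image pipeline recovers the analytic
T/L ratio within 0.5% per phase (tolerance 3%), the cord clearance within
0.6 mm (tolerance: one voxel diagonal, 1.73 mm), and the reference and
TC-optimal phases exactly.  At the 2 mm default the same errors are
discretization-dominated (a few percent on ~150-voxel tumors), which is
why unit tests at that scale use proportionally wider bands; this is a
property of voxel counting, not of the algorithms.

## Numerical and design choices

- Exact Euclidean distance transform (`scipy.ndimage.distance_transform_edt`)
  rather than KD-trees: exact, O(n), and independent of mask sparsity.
- Inertia axes from the eigendecomposition of the biased covariance of
  foreground voxel centers; eigenvalues sorted descending; a single-voxel
  mask yields a zero matrix rather than NaNs.
- Empty masks produce explicit sentinels (`RoiMetrics.defined = False`,
  typed errors naming the ROI), never silent NaN propagation.
- Laterality is detected as the lung whose left-right centroid is nearest
  the GTV centroid — orientation-agnostic; an exact tie raises and demands
  explicit configuration.
- All randomness (phantom noise) flows from a single integer seed; runs
  are byte-reproducible, and report JSON is sorted-key serialized so
  repeated runs are byte-identical.
- Problem sizes: the default test suite voxel work runs on 64³ half-scale
  phantoms; the acceptance path runs one 128³ study at 2 mm and one 256³
  study at 1 mm.

## Known limitations

- DICOM / DICOM-RT ingestion is out of scope; NIfTI is the interchange
  format and masks must be pre-voxelized.
- The inconclusive branch encodes one defensible rule, not a validated
  clinical criterion.
- No dosimetric quantities (V20, mean lung dose, PTV margins) are
  computed; the parameters are purely morphological surrogates.
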