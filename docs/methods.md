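# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic cohort does and does not establish.

## Coordinate and volume conventions

All volumes of one analysis live on a single template grid; shapes must
match and affines must agree within 1e-4, otherwise a `GridMismatchError`
is raised. Voxel indices are 0-based; world coordinates are millimetres
via the 4×4 voxel-to-world affine. World→voxel snapping rounds halves
*away from zero*, a convention chosen (over banker's rounding) so that
visitation maps are bit-reproducible across platforms and independent of
index parity. Masks are resampled nearest-neighbour only, never
interpolated, so binarity is preserved by construction; whether a mask is
binarized before or after resampling therefore never arises. Masks are
stored as unsigned 8-bit NIfTI, probability and statistic maps as 32-bit
float.

## Visitation and disconnection maps

Streamlines are polylines in world mm; TRK's voxel-space coordinates are
normalized to world mm at read time (via nibabel), so no internal code
ever sees format-specific coordinates. Lesion–streamline intersection and
visitation mapping use dense arc-length resampling followed by
nearest-voxel snapping rather than exact segment–box clipping: it is
simpler, bit-reproducible, and a step of half the smallest voxel edge
(the default) cannot skip a voxel in which the fiber dwells for at least
one step length. The residual step-dependence is a boundary effect —
oblique segments can clip voxel corners with chords shorter than any
finite step — measured at roughly 1% of visited voxels between steps of a
half and a quarter voxel edge on smooth bundles; the test suite asserts a
≤2% symmetric-difference bound rather than exact step-invariance, which
does not hold in continuous geometry.

The disconnectome value at a voxel is the fraction of the N normative
controls whose lesion-intersecting streamlines visit it; every value is
an exact multiple of 1/N, stored as a proportion in [0, 1] and converted
to percent only for reporting. Lesion voxels receive whatever visitation
streamlines give them — they are not forced to 1. A lesion intersecting
no streamline in any control yields a valid all-zero map plus a
warning-level log message: on a whole-brain tractogram this is
pathological, on the sparse two-bundle phantom it is routine. Batch
computation resamples each control streamline once and reuses the voxel
sets across subjects; this is an exact optimization (selection and
visitation are pure functions of those sets), verified bit-for-bit
against subject-by-subject computation.

One deliberate deviation from the procedure the pipeline emulates:
normative tractograms are required to be pre-normalized to the common
template space, rather than registering each lesion into every control's
native space and back. The composition of transforms is equivalent, and
template-space tractograms are the only option for synthetic phantoms.

## Behavioral PLS

Both blocks are column z-scored (sample SD, denominator n−1), i.e.
correlation-scale behavioral PLS. The toolbox convention this mirrors is
not fully recoverable from published descriptions (centering-only is a
possible alternative); z-scoring was chosen because it makes the
identity-contrast oracle exact — each salience map equals the
mass-univariate Pearson correlation map, testable to 1e-10 — and makes
all outputs invariant to positive rescaling of any behavioral column.

Contrasts are applied exactly as given after unit-normalization; no
Gram–Schmidt orthogonalization is performed. This is a documented
limitation for non-orthogonal contrast sets; the identity set used
throughout is orthogonal and unaffected. With fixed contrasts there is no
axis-rotation or sign ambiguity across resamples, so no Procrustes
alignment is needed in the bootstrap — the usual alignment step of
rotated PLS is deliberately omitted.

Permutation inference permutes rows of the behavioral block jointly,
re-z-scores, and recomputes LV strengths; p-values use add-one smoothing,
(1 + exceedances)/(1 + n_perm), so p is never 0 and is exact under the
null. Bootstrap inference resamples subjects with replacement, applying
the same resample to both blocks. A resample with fewer than 3 distinct
subjects or a constant behavioral column is redrawn (and counted); a
*brain* column constant within a resample is instead given a z-scored
column of zeros — i.e. zero correlation contribution in that resample.
Redrawing on brain-column degeneracy is not viable: a voxel nonzero in a
single subject is missing from about 37% of bootstrap resamples, so
redraw-until-valid would almost never terminate at realistic mask sizes.
Bootstrap SEs at or below 1e-12 are treated as zero (the resampled
salience never actually varied); those voxels get a bootstrap ratio of 0
and are counted in the result. Default resample counts are 1000 for both
permutation and bootstrap, with independent streams spawned from one
master seed.

The analysis mask keeps voxels that are nonzero in at least one subject
*and* vary across subjects; constant columns are thereby excluded before
any z-scoring. Subjects with missing behavioral values are dropped from
both blocks and logged. Sex is coded as an indicator named `female`
(female = 1).

## Clusters and battery correlations

Suprathreshold means strictly greater than the threshold (a voxel at
exactly pseudo-z = 3 is excluded, reading "pseudo-z > 3" literally).
Default connectivity is 26 and the default minimum cluster size is 1
voxel — permissive defaults chosen because small (few-voxel) clusters are
meaningful at this threshold; both are configurable. Peak-position ties
break toward the lowest C-order voxel index. The negative tail is handled
explicitly: clusters of strongly negative bootstrap ratios are extracted
separately, and their table reports the signed peak value. With a
cognitive score *negatively* coupled to disconnection, the planted effect
lives in the negative tail; isolated opposite-tail voxels at |z| > 3 are
the expected false-positive rate of the threshold, not signal.

Cluster disconnectivity is the mean disconnection proportion over the
cluster's voxels, per subject (linear in the maps). Battery correlations
are Pearson, pairwise-complete per cell because the battery exists only
in a subsample; each cell carries its own n, and cells with fewer than 3
complete pairs or a constant column are set missing with a recorded
reason.

## Cohort statistics

All models are OLS (statsmodels). The phase-group model regresses the
cognitive score on the three-level stroke-phase factor (acute < 7 days,
subacute 7–180, chronic > 180; reference level acute) — with no
covariates its F equals the one-way ANOVA F. Age/sex adjustment is off by
default and available behind a flag. The lesion-load model uses total
lesion volume and number of lesions jointly. Degenerate fits are flagged
rather than reported as noise: zero explained variance reports F = 0,
zero residual variance sets a `degenerate` flag (t and F diverge), and
near-singular designs set a `collinear` flag.

The outlier-sensitivity refit needs an explicit rule where the emulated
analysis removed "one extreme case" without stating one: subjects whose
log lesion volume lies more than 4 SD from the cohort mean are flagged
(log scale to match the heavy right tail of lesion-size distributions;
threshold-based, so ties are all flagged), flagging more than 10% of the
cohort is an error, and both fits are always reported. The impairment
rate counts scores strictly below the cutoff (default 26; a score of
exactly 26 is not impaired — the standard MoCA convention).

## Synthetic cohort

The generator emulates the *shape* of a ~100-subject stroke cohort at
desk scale, not its anatomy:

| parameter | default | rationale |
| --- | --- | --- |
| grid | 32³ voxels, 2 mm | desk-scale stand-in for a 2 mm template grid |
| bundles | 2 tubes, radius 3 mm, 60 streamlines | one target, one distractor |
| controls | 20 | enough for 1/N granularity without whole-cohort cost |
| jitter | 0.5 mm bundle-level + 0.25 mm streamline-level SD | inter-individual anatomical variability at sub-voxel scale |
| subjects | 102, 1–3 spheres each, radii log-uniform 2–8 mm | heavy-tailed lesion sizes |
| on-target fraction | 0.3 | ~40% impairment incidence downstream |
| score model | clip(round(28.5 − 10·d + ε), 0, 30), ε ~ N(0, 2) | d = mean target-footprint disconnection; integer 0–30 scale exercised |
| age, sex | N(66.3, 12.3), P(female) = 0.255 | elderly stroke-cohort marginals |
| battery | 8 subtests, loading·(−d) + N(0, 1), 80% subsample | planted negative sign pattern |

Sphere lesions, whole-streamline jitter offsets and piecewise-linear
bundles are deliberate simplifications: they exercise every operator
(intersection, visitation, probability aggregation, masking, inference)
while making ground truth exact. Consequences for interpretation: passing
recovery tests shows the *pipeline* recovers a planted effect under
realistic sample sizes and noise, not that the method is robust to
registration error, anatomically realistic lesion shapes, distance
effects along fibers, or whole-brain fiber geometry — none of which the
phantom contains. The target "footprint" used as ground truth is the
visitation map of the noise-free streamline fan; the suprathreshold
recovery region is naturally somewhat larger (it includes the jitter
halo), which bounds attainable Dice below 1 by design.

Everything derives deterministically from one master seed through
hierarchical sub-seeds (controls / lesions / behavior). `write_cohort`
emits uncompressed NIfTI deliberately: gzip embeds metadata that breaks
byte-identical regeneration, and the manifest's SHA-256 hashes are used
both for tamper detection and pipeline cache keys.

## Pipeline

Stages (simulate → disconnectome → PLS → clusters → correlate → stats →
recovery) each write their outputs plus a hash of their parameters and
the SHA-256 of every input file. A rerun with unchanged inputs loads
cached outputs; since the report is assembled only from on-disk stage
outputs and contains no paths or timestamps, cached and cold runs are
byte-identical — a property under test. Any stage failure halts the run
naming the stage and the implicated subjects.

Default problem sizes in the test suite and acceptance script (32³ grid,
20 controls, 102 subjects, 500 permutations/bootstrap resamples, 20
master seeds for the recovery study) were chosen as the package's
standing desk-scale configuration: large enough for calibrated inference
bands — type-I error of the permutation test within its binomial band,
recovery in ≥ 90% of seeds — and small enough to run routinely.

## Known limitations

- Nonrotated PLS only; rotated (SVD) task PLS, mean-centered group
  contrasts and split-half stability are out of scope.
- No Gram–Schmidt for non-orthogonal contrast sets (documented above).
- Cluster-extent inference (permutation-based cluster p-values) and
  anatomical labeling of clusters are not implemented; cluster tables
  carry coordinates only.
- The intersection test is point-sampling-based; sub-step corner
  clipping is quantified, not eliminated.
- Registration estimation is out of scope: all inputs are assumed
  already in the common template space.
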