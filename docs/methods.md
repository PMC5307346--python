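# Methods

## Scope and data model

`tractprint` operates entirely on *streamline endpoint counts*: for each
seed voxel, the number of the `S` probabilistic-tractography samples that
terminate in each labelled target region, plus an explicit "unreached"
remainder for samples that hit no labelled region. Everything upstream of
those counts — diffusion modelling, fibre-orientation estimation,
streamline propagation, registration — is out of scope; all volumes in a
run must already share one voxel grid, and grid identity is enforced with
a strict shape check. Voxels are atomic: a voxel belongs to exactly one
region (nearest-neighbour labelling, no partial-volume fractions).

Five objects carry the pipeline: a `LabelVolume` (3-D integer labels plus
a table of region name / hemisphere / tissue class), a `SeedTemplate`
(boolean mask with provenance `functional`, `structural`, `merged` or
`cleansed`), `StreamlineSamples` (seed-voxel × target-region counts for
one subject), a `FingerprintMatrix` (seed-entity × region values with a
`raw` / `thresholded` / `normalised` stage tag), and a `SubParcellation`
(per-voxel hard assignment to a connectivity target).

## The connectivity estimator

For a seed entity *i* with *n* voxels,

    P_ij = Σ_{v ∈ i} c_vj / (S · n),

where `c_vj` is voxel *v*'s endpoint count in region *j*. This equals the
unweighted mean of the per-voxel proportions `c_vj / S`, and under the
simulator's sampling model the summed count is marginally
Binomial(S·n, p_ij), so the estimator is unbiased with standard error
`sqrt(p(1−p)/(S·n))` — the quantity the consistency checks use.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `S` | 5000 | streamline samples per seed voxel |
| `row_threshold_frac` | 0.01 | per-seed-row cutoff, as a fraction of the row's maximum streamline count |
| `voxel_class_frac` | 0.25 | fraction of `S` required to classify a voxel as connected to a target template (1250 of 5000) |
| `group_frac` | 0.50 | fraction of subjects in which a connection/assignment must be present to be retained |

All three fractions use a ≥ comparison, so boundary cases (a count exactly
at the cutoff, presence in exactly half the subjects) are kept. Threshold
comparisons are made on integer streamline counts, not on floating-point
probabilities, so the boundary is exact; when `voxel_class_frac · S` is
fractional the cutoff is rounded up (a voxel must reach *at least* the
stated fraction) and the rounding is logged.

## Design choices where the procedure was open

* **Row-wise threshold reference.** The 1 % threshold is taken relative to
  each seed row's own maximum streamline count, not a global maximum: each
  seed's strongest connection defines its scale, which matches per-seed
  fingerprint displays. A different reference can be obtained by
  thresholding externally before `consistency`.
* **Normalisation divisor.** Regional normalisation divides by the
  *target* region's voxel count; the seed side is already accounted for by
  the `1/(S·n)` in `P_ij`, and dividing by seed size again would
  double-count. Normalisation is applied after thresholding.
* **Directionality.** Connectivity is kept directed seed → target as
  computed; no symmetrisation is applied. Diffusion data carry no fibre
  directionality, so users who want symmetric measures can average the two
  directions themselves.
* **Presence.** A connection counts as "present" in a subject when it
  survives that subject's row threshold, not merely when its raw count is
  nonzero — group consistency is defined downstream of the thresholded
  analysis.
* **Tie-breaks.** Winner-take-all assignment breaks exact count ties by
  the lowest region label; the group consensus qualifies every target
  reaching `group_frac`, then picks the most frequent, then the lowest
  label. Both rules are deterministic and documented rather than random.
* **Consensus on hard labels.** The group sub-parcellation aggregates
  per-subject hard assignments (binarise, then threshold across subjects)
  rather than averaging fibre fractions, matching the
  classify-then-combine order of the per-subject stage.
* **Unlabelled grey voxels in the merge.** Functional-template voxels
  outside every atlas region are dropped from the merged template by
  default; callers holding an independent grey-tissue mask can keep them
  via `keep_unlabelled_grey`.
* **Overlap report rows.** Grey regions get one row each; white-matter and
  CSF regions are pooled into aggregate rows; fractions are exact counts,
  rounded only for display (half-up to integer percent, with `< 1%` for
  nonzero fractions rounding to zero).

## The synthetic phantom

The generator exists to give every pipeline rule a known ground truth, not
to imitate anatomy. Its default (`default_phantom_spec`) is a 24³ grid
holding 90 grey regions (45 per hemisphere; 16 named pairs of 64 voxels —
olfactory, piriform, amygdala, hippocampus, parahippocampal, putamen,
pallidum, thalamus, orbitofrontal, anterior cingulate, insula, caudate,
rectus, temporal pole, fusiform, lingual — plus 29 generic 8-voxel filler
pairs per hemisphere), a 1200-voxel white-matter compartment and a
300-voxel CSF compartment. Two left-hemisphere seed templates are built
in:

* a **structural** seed coinciding exactly with the olfactory region
  (64 voxels, split into an anterior and a posterior voxel class), and
* a **functional** seed of 100 voxels whose composition mimics a
  functionally-defined ROI: 37 % amygdala, 8 % piriform, 9 % putamen,
  7 % parahippocampal, 6 % hippocampus, 15 % white matter, 3 % CSF and
  15 % unlabelled voxels.

Each voxel class carries a planted vector of region-connection
probabilities. The anterior structural class is orbitofrontal/anterior-
cingulate dominated and the posterior class hippocampus/amygdala
dominated (dominant p = 0.40); the functional seed's primary-area classes
point at secondary olfactory areas (dominant p = 0.35); the white-matter
contamination alone connects to pallidum and thalamus, and the unlabelled
voxels alone to fusiform and lingual — so grey-matter cleansing removes
exactly those connections. Dominant probabilities sit above
`voxel_class_frac` by construction: sub-parcellation targets are, by
definition, the seed's dominant connections. Remaining probability mass is
"unreached", so row sums of raw fingerprints stay below 1.

Per subject, each class's probability vector is drawn from a Dirichlet
distribution with concentration `kappa · p` restricted to the planted
support (planted zeros stay exactly zero), then each voxel draws `S`
multinomial endpoints. `kappa` (default 300) sets between-subject
variability — the per-target standard deviation is roughly
`sqrt(p(1−p)/(kappa+1))`; `kappa=None` disables variability for estimator
calibration. Subjects use independent RNG substreams spawned from
`rng_seed`, so a subject's data never change when the cohort grows, and
identical spec + seed reproduce outputs bit for bit.

What the phantom does **not** emulate: spatial streamline trajectories
(only endpoint counts are generated, because every downstream formula
consumes counts), anatomical region shapes (regions are flat-order runs of
voxels; the pipeline never uses shape), registration error, distortion, or
count correlations between neighbouring voxels beyond the shared
class-level probability vector. Passing tests therefore certify the
count-based arithmetic, thresholding, aggregation and assignment logic —
not robustness to registration or tracking artefacts in real data.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the default phantom (307
seed voxels, 92 labelled targets) with 16-subject cohorts, 500
single-subject replicates for estimator calibration, 20 independent
cohorts for planted-network recovery, and a 6³ mini-phantom for the
brute-force enumeration oracles and calibration loops — sizes chosen so
the complete pipeline, including every acceptance experiment, runs in
seconds on one CPU.

## Known limitations

* Counts are assumed exchangeable within a voxel class; real tractography
  shows spatial gradients within a region that the simulator collapses.
* The threshold rules are exactly as stated (relative row maximum, fixed
  fractions); no data-driven threshold selection is provided.
* Sub-parcellation is hard (winner-take-all) with no spatial
  regularisation; soft or clustered alternatives are out of scope.
* No statistical inference across groups is implemented — the group stage
  describes consistency, it does not test hypotheses.
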