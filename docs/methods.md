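# Methods

## Model and pipeline

The pipeline estimates lesion-affected brain networks from two ingredients:
per-patient binary lesion masks co-registered to a common grid, and a
normative connectome — resting-state fMRI from healthy controls on the same
grid. Nothing is estimated from patient fMRI; all connectivity is read off
the normative data, which is what makes the method applicable to clinical
cohorts scanned only structurally.

Stages, in order:

1. **Brain mask.** A voxel is in-brain iff its time series has nonzero
   variance and is finite in every session of every control; the cohort
   mask is the intersection. All matrices index voxels in a fixed
   x-fastest (Fortran) raveling of the grid, so columns are reproducible.
2. **Cleaning.** Per control: least-squares removal of an intercept, any
   supplied motion regressors, the global mean over the brain mask, and
   optional mask-averaged nuisance series; then a zero-phase 4th-order
   Butterworth band-pass, 0.01–0.08 Hz by default. Tissue segmentation is
   out of scope — ventricular/white-matter regressors are accepted as
   user-supplied masks.
3. **Lesion-seeded connectivity.** The mean series over lesion∩brain voxels
   is correlated with every in-brain voxel; r is clamped to ±(1−1e−7)
   before arctanh so duplicated series stay finite. Multi-session controls
   are averaged within subject first, then across subjects (equal subject
   weights). Lesioned entries are exact zeros.
4. **Union matrix and standardization.** Averaged vectors are stacked into
   X (patients × voxels). By default X is z-scored *globally* over its
   non-lesioned cells; the alternative per-row scope is available as
   `zscore_scope="row"`. We default to global scope because per-row scaling
   inflates rows from patients whose lesions couple weakly to any network —
   such rows are mostly shared sampling noise, and giving them unit
   variance injects that noise into the signal subspace. Global scaling
   preserves each patient's relative coupling strength; in ground-truth
   simulations it recovers the planted network visibly more reliably.
   Zeros are restored after scaling either way.
5. **Order selection.** SVD of X; cumulative explained variance from
   squared singular values. The subspace order is the knee of that curve:
   the curve is prepended with the origin (zero components explain zero
   variance), the chord is drawn from the origin to the final point, and
   the order with the maximum distance above the chord is taken (ties to
   the smallest order; a flat curve returns 1 with a warning). Prepending
   the origin makes the rule well-behaved when the first component already
   explains much of the variance. An explicit `order` override exists.
6. **ICA.** Natural-gradient Infomax with the logistic nonlinearity,
   appropriate for super-Gaussian (sparse, positive) spatial sources:
   ΔW = lr·(I + (1 − 2g(U))Uᵀ/b)·W over randomized mini-batches
   (b = min(V, 256)), initial lr = 0.01/ln(q·e). The learning rate is
   multiplied by 0.9 whenever the aggregate per-pass update turns by more
   than 60° (oscillation near an optimum) and halved with a weight reset if
   an update blows up; convergence is a Frobenius weight change below 1e−6
   between passes, with up to 1024 passes. Thirty restarts are run from
   seeds master+i; the restart minimizing the mean pairwise Amari
   inter-symbol interference, ISI(W_i·W_j⁻¹), against the other converged
   restarts is selected. ISI is zero iff two solutions agree up to
   permutation and scaling, so the selected run is the one the ensemble
   keeps re-finding.
7. **Maps.** Selected sources are z-scored over brain voxels and
   sign-oriented to positive skewness (the network side of a spatial
   component is its sparse positive tail). Thresholding at |Z| > 1 (0.5 and
   1.5 as robustness alternates) yields positive/negative masks.
8. **Identification.** Per component and reference: Dice between the
   positive mask and the binarized reference (continuous references are
   z-scored over brain and thresholded at the same z as the components),
   and Pearson correlation over brain voxels between the *positive part* of
   the component map and the reference. The component with the best mean
   rank over all (reference, metric) pairs wins; the trace records whether
   the winner was unanimous.
9. **Damage and behavior.** Damage score = max component Z inside
   positive-mask∩lesion (0 with a warning when disjoint — the patient is
   retained, since silently dropping patients would change n invisibly).
   For binary references the z-scored intersection count is used instead
   (sample sd, n−1 — the convention for every z-score across patients).
   Lesion size is regressed out of the scores (OLS with intercept) before
   Pearson correlation with behavior; two-sided p from the t distribution
   with n−2 df. Correlation strengths between maps are compared with the
   independent-samples Fisher r-to-z test; when the two correlations share
   the behavior vector this is approximate (a dependent-correlations test
   would be stricter), which we note rather than hide.

## Baselines

- **Overlap analysis**: voxelwise lesion counts; a sharing curve (fraction
  of ever-lesioned voxels lesioned in ≥ k patients); pairwise overlap
  |A∩B|/min(|A|,|B|) by default (Dice and union-normalized switchable).
- **VLSM**: voxels lesioned in 25–75% of patients; pooled-variance
  two-sample t on behavior between lesioned and spared (Welch switchable);
  Benjamini–Hochberg at α = 0.05 across eligible voxels.
- **Overlay LNM**: per patient, a one-sample t across controls of the
  Fisher-Z values per voxel, Bonferroni-corrected over tested voxels;
  positive voxels with corrected p < 1e−6 form the patient map; common maps
  keep voxels present in ≥ ceil(f·n) patients, f ∈ {0.7, 0.8, 0.9}.

## Synthetic cohorts

The generator emulates the study design with known ground truth. Defaults
(all configurable in `SimCohortConfig`):

- **Grid**: 18³ voxels of 4 mm; a spherical "brain" of radius 0.45·18
  voxels (≈ 2270 in-brain voxels). Chosen so the full pipeline runs in
  seconds per cohort on one CPU.
- **Networks**: K = 4 isotropic Gaussian blobs (σ = 1.8 voxels, truncated
  at 2σ) at well-separated random centres; supports barely overlap, so maps
  are near-orthogonal — the identifiability premise of the spatial-ICA
  model.
- **Control fMRI**: 20 subjects × 1 session × 150 timepoints at TR = 2 s.
  Voxel series = Σ_k map_k·s_k(t) + global(t) + white noise. Network
  sources s_k are fresh per subject and band-limited to 0.01–0.08 Hz
  (hemodynamic fluctuations are slow; with white sources the band-pass
  would discard most signal degrees of freedom, which real data do not do).
  The shared global fluctuation (amplitude 0.5 at every brain voxel) gives
  global-signal regression something real to remove; without it GSR on a
  few equal-sized networks induces exaggerated anti-network artifacts.
  snr — sd(signal)/sd(noise) at a network's peak voxel — defaults to 2.0,
  which after band-pass filtering yields peak seed correlations around
  0.9, i.e. realistic Fisher-Z magnitudes rather than saturated ones.
- **Lesions**: 24 patients; each lesion is a sphere of 20–80 voxels centred
  near one network (uniform over networks by default), jittered by ±1σ, so
  patients damaging the same network still overlap little (mean pairwise
  overlap ≈ 0.1 — strong location heterogeneity by construction).
- **Behavior**: each WAB-style score = intercept + slope·(max target-map
  value inside the lesion) + Gaussian noise, clipped to its WAB range. AQ
  slope −60 on the [0, 1] damage scale with noise sd 8: patients missing
  the target network score near ceiling, direct hits lose tens of points —
  a strong but not deterministic brain–behavior link. Generating slopes are
  stored in `DataFrame.attrs` for recovery tests.

What the generator deliberately does **not** emulate: hemodynamic response
shapes, head motion, physiological noise spectra, multi-site effects,
white-matter disconnection, and non-spherical lesion geometry. Passing
tests therefore show that the pipeline recovers planted structure under its
own model assumptions at desk scale — they do not certify performance on
real cohorts, where preprocessing quality and violations of spatial
independence matter.

## Numerical choices

- Grid compatibility: dims equal and affines within 1e−4 mm entrywise; no
  silent resampling (an explicit nearest-neighbour resampler exists for
  reference maps, keeping binary masks binary).
- Non-finite input voxels are an error, never imputed.
- r-clamp 1−1e−7 before arctanh; zero-variance target voxels are excluded
  by the brain mask upstream.
- Cross-ISI selection excludes non-converged restarts from candidacy but
  reports them in the pairwise matrix; ties go to the smallest index.
- The whitened subspace has unit-variance rows; mixing = W⁻¹ exactly, so
  mixing·sources reconstructs the subspace to machine precision.
- Sample sd (n−1) for z-scores across patients; population sd for map
  standardization over voxels.

## Validation harnesses and their scale

Split-half (default 10 repeats; one random patient dropped first when the
count is odd), subgroup reruns (each labelled group ≥ 3 patients), and a
robustness scan over healthy-control subset sizes and component thresholds.
Acceptance checks run the full pipeline over 10 master seeds at the default
cohort scale (minutes on one CPU): the identified component matches the
planted network (spatial r ≥ 0.8 on the positive part, the same similarity
measure identification uses) in most seeds, damage–behavior correlations
are negative and significant with the target component strongest, the
zero-slope null keeps the false-positive rate near α (slight inflation is
expected: the damage-score distribution is a zero-inflated mixture at
n = 24), the 90% overlay-LNM common map is empty while the ICA route still
finds the network, and reruns with the same master seed are bit-identical.

## Known limitations

- The Fisher independent-samples test for comparing correlations ignores
  their dependence through the shared behavior vector.
- The knee rule occasionally selects K+1 components on noisy cohorts; the
  surplus component absorbs shared sampling noise and slightly blurs the
  others. The `order` override exists for exactly this case.
- Only spatial (not temporal) ICA is implemented; FastICA/JADE variants,
  ICASSO clustering and automatic artifact classification are out of scope.
- White-matter tract anatomy is ignored: damage is scored on voxel
  intersections, not disconnection.
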