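# Methods

## The reconstruction model

Optical motion capture represents a trial as a measurement matrix **M** of
shape *n* × 3*m*: *n* time frames, *m* markers, three coordinates (mm) per
marker.  Occlusion and marker detachment leave *gaps* — runs of frames in
which a marker's position is unknown.  Because human movement is highly
coordinated, the coordinates of different markers are strongly
intercorrelated and **M** is approximately low-rank; a missing marker can
therefore be estimated from the markers that remain visible.

The estimator is a pair of weighted principal-component bases.  Let **N**
(*k* × 3*m*) collect the *complete* frames of **M** (no missing marker) and
let **N**_zeros be **N** with the corrupted markers' columns replaced by
zeros.  Both matrices are centered with the column means of **N**, scaled
column-wise by a weight vector (below), and decomposed by SVD.  Each basis
is truncated at the smallest *k* whose cumulative sum of normalized singular
values (normalized by their plain sum, not by their squares) reaches
θ_λ.  A transition matrix **T** is the least-squares map from the truncated
scores of **N**_zeros to the truncated scores of **N** over the same frames.
The reconstruction is

```
R = M_zeros · PC_zeros,trunc · T · PC_truncᵀ
```

where **M**_zeros is the centered, weighted measurement matrix with gap
entries zero-filled.  **R** is un-weighted (element-wise division),
un-centered, and only the gap entries of **M** are replaced; observed
samples are returned bit-identical.

Weighting: for a reconstruction target *i*, every other marker *j* receives
w_j = exp(−d̄_ij² / 2σ²), with d̄_ij the mean Euclidean distance over the
frames where both markers are observed.  The target's own columns get the
small constant w_mm.  With several simultaneous targets a marker takes the
largest weight over all targets.  Markers sharing no observed frame with
any target receive 10⁻⁶ (positive to keep the matrices well-formed,
small enough to be effectively excluded); the same floor catches Gaussian
underflow for very distant markers.

### Multi-gap strategies

* **R1 (simultaneous)**: one pass of the reconstruction with every
  corrupted marker zeroed in **N**_zeros and the max-rule weights.
* **R2 (consecutive)**: each corrupted marker *i* is reconstructed on its
  own.  Another corrupted marker *h* is **omitted** (its columns removed)
  when d̄_ih > θ_D·D_i, where D_i is the unweighted mean of d̄_ij over all
  other markers, or when *h*'s gaps overlap the target's in time (≥ 1
  shared gap frame); otherwise *h* is kept and its gap frames are removed
  from the analysis.  Complete markers always participate.  The training
  matrix for marker *i* is therefore complete over the *included* markers
  only, which recovers rows R1 discards.

R2 never feeds reconstructed values of one marker into the reconstruction
of another: every marker works from the original corrupted data.  This
removes any dependence on processing order (verified by a permutation
test) at the cost of ignoring information a filled neighbour might add.
A marker whose every neighbour is omitted is reported unfilled — a partial
success, not a failure.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| w_mm | weight on the missing marker's own columns | 0.02 | must be > 0: at 0 the two bases coincide and gaps cannot be recovered |
| σ | Gaussian weighting length scale | 200 mm | assumes mm units |
| θ_λ | singular-value-sum truncation threshold | 0.99 | value sum, not variance sum |
| θ_D | relative distance cutoff in R2 | 0.5 | 0 drops every corrupted neighbour; 2 keeps virtually all |
| min_complete_frames | floor on usable training rows | 10 | configurable for very short trials |

### Numerical choices

* Centering uses the complete-frame column means for every matrix and the
  means are restored after reconstruction; this makes the reconstruction
  exactly equivariant under rigid translation.
* The inverse of an orthonormal truncated basis is its transpose.
* **T** comes from `lstsq` on the score matrices; a rank-deficient score
  matrix falls back to the pseudoinverse solution with a logged
  condition-number warning.
* The two bases are truncated independently with the same θ_λ; singular
  values below `max(k) · eps · s₁` count as zero, so θ_λ = 1 keeps exactly
  the numerically nonzero spectrum.
* Weights cancel exactly on gap-free data; a gap-free input is returned
  unchanged without fitting anything.

## Baselines

Per-coordinate natural cubic spline and straight-line interpolation through
the observed samples.  Boundary gaps (no support on one side) are filled
with the nearest observed value; a coordinate with a single observed sample
is filled constant with a warning.  These use no inter-marker information
and serve as the conventional reference.

## Synthetic gait generator

The generator produces the study conditions for all self-contained tests.
Markers are grouped into body-segment clusters (≈ 4 markers per segment,
60 mm spread) whose centres span a standing body volume and are ordered
along the body axis into a chain.  Movement is `latent_rank` unit-RMS
latent trajectories — sinusoids at harmonics of the stride frequency plus
one slow drift — mapped to coordinates by loadings that are shared within a
segment up to a 2% marker-specific wobble.  The first component is
whole-body sway (common mode); intermediate components load on contiguous
windows of the segment chain, like limb-specific movement.  Amplitudes
decay as 1/(l+1) from `amplitude_scale` (default 300 mm RMS for the
dominant component).  White noise of `noise_sd` (default 0.5 mm) emulates
sensor noise.  With `noise_sd = 0` and the remaining defaults the matrix
has numerical rank exactly `latent_rank + 1` (the mean offset adds one).

Three optional features reproduce what makes real data hard:

* `irregularity` (rad): slow random phase modulation, independent per
  component, so stride timing and inter-limb phase relations drift.
* `articulation` (fraction): a tail of ~2·rank weak second-order
  interaction components (products of latent pairs) with their own random
  segment windows.  Real marker data is only approximately low-rank
  because joints rotate; this term supplies that singular-value tail.  It
  is what makes the choice of weights and training rows matter: with the
  tail present, the θ_λ truncation is a real capacity limit, and focusing
  the basis on the target's neighbourhood (R2) beats the broad compromise
  weighting of R1, as it does on real recordings.  Without it the data is
  exactly a noisy subspace, any sufficient marker subset is equally
  informative, and the simultaneous strategy trivially saturates — an
  unrealistically easy regime.
* `soft_tissue_sd` (mm): smooth (low-pass filtered) marker-specific
  artifact motion that no other marker can predict, emulating skin
  movement relative to bone.  It sets the accuracy floor: with it, typical
  reconstruction errors land in the few-mm range reported for real gait
  rather than at the sensor-noise floor.

Presets bundle these into three named conditions: `walkl_like` (4300
frames, 37 markers, 240 Hz, mild irregularity 0.3, articulation 0.1,
soft-tissue 1 mm), `cp_gait_like` (600 frames, 35 markers, 200 Hz,
irregularity 0.6, articulation 0.15, soft-tissue 2 mm) and `walkrun_like`
(400 frames, 30 markers, 120 Hz, a mid-trial regime switch to 1.5× stride
frequency with new loadings).  The corruption protocols draw a uniform
number of gaps (5–15 of 20–480 frames for the long walk; 2–6 of 20–120
frames for the short trials), each on a uniform random marker at a uniform
onset; gaps on one marker may overlap (union taken), and a configuration
leaving fewer than 5% of frames complete is redrawn so the subspace methods
always have training rows.

What passing tests on this generator do **not** show: the generator has no
musculoskeletal constraints, no genuine rotational kinematics (only their
second-order statistical signature), no marker relabeling/swap artifacts,
and its noise is Gaussian.  Accuracy figures on synthetic data therefore
characterize the algorithm's behaviour, not expected clinical accuracy on
any particular real dataset.

## Evaluation harness

Accuracy is the mean Euclidean distance (mm) between filled and true
positions pooled over every gap marker-frame (not averaged per marker
first), plus per-axis mean absolute errors and a per-marker breakdown.
The replicate experiment corrupts a gap-free trial 50 times (seeds derived
from one master seed by a counter), fills each copy and reports the median
accuracy; method failures count as missing values.  The one-at-a-time
sensitivity sweep evaluates one parameter over its standard grid
(w_mm: 15 log steps over 10⁻⁵–1; σ: 15 linear steps over 100–1500 mm;
θ_λ: 15 linear steps over 0.86–1.0; θ_D: 11 linear steps over 0–2) on 20
corrupted copies, subtracts each copy's across-grid mean, and averages the
centered curves with their standard error.

Problem sizes in the shipped tests and in `scripts/acceptance.py` follow
the preset trial lengths above (the long-walk condition is run at its full
4300 frames, 50 replicates); the exact-subspace checks use small instances
(≤ 12 markers) so they can be verified against a brute-force least-squares
completion oracle.

## Known limitations

* The transition matrix is a purely linear map between score spaces; no
  musculoskeletal or rigid-body constraints are enforced, so anatomically
  impossible fills are possible and should be reviewed.
* C3D support covers the common Intel/float subset of the standard (plus
  scaled-integer reads); analog channels are skipped and other processor
  types are rejected.
* Accuracy degrades when the training frames do not cover the movement
  regime inside the gap (e.g. reconstructing running from walking-only
  data); the harness makes this easy to quantify per dataset by corrupting
  a complete trial.
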