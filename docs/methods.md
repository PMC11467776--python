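# Methods

## Problem and approach

Online adaptive radiotherapy replans a patient while they lie on the couch,
so the safety check on the new plan — a secondary, independent dose
calculation — must run in well under a minute. `geodose` implements a
geometry-encoded deep-learning approach to this check for VMAT
(volumetric modulated arc therapy) plans:

1. **Fluence reconstruction.** For each sampled gantry angle the MLC/jaw
   aperture of every control point is rasterized on the isocenter plane as a
   fractional-area matrix and weighted by the control point's monitor-unit
   (MU) share — the increment of cumulative meterset weight times the beam
   MU. Contributions are binned to the nearest sampled angle and summed
   across arcs, giving one fluence map (FM) per angle.
2. **Geometry encoding.** Each FM is back-projected from the isocenter plane
   toward the point source onto a plane 300 mm from the isocenter
   (magnification (SAD − 300)/SAD = 0.7 at SAD = 1000 mm) and painted
   additively into the CT-derived relative-electron-density (RED) volume by
   nearest-voxel deposition. The painted voxels form a ring in air around
   the patient, so one single-channel volume carries both anatomy and the
   exact delivery geometry.
3. **Dose regression.** A 3D U-Net variant maps the integrated volume to
   dose. Supervision (and evaluation) use only the central axial slice of a
   sub-volume centred at the isocenter.
4. **Verification metrics.** Agreement between estimated and reference dose
   is quantified by global-normalization γ analysis (default 3%/2 mm and
   2%/2 mm, 10% low-dose threshold) and by structure metrics (D98, D95,
   Dmax, Dmin, Dmean) with errors expressed in % of prescription.

## Coordinate and data conventions

DICOM patient coordinates (LPS), millimetres, throughout. Grid metadata
(`origin`, `spacing`, `dims`) is ordered (x, y, z); arrays are indexed
[z, y, x]; voxel indices are 0-based; `origin` is the centre of voxel
(0, 0, 0). Gantry angles follow IEC 61217 for head-first supine: 0° is
anterior (−y), 90° patient-left (+x), rotation about the
superior–inferior (z) axis. MLC bank A is the −x bank; leaf and jaw
positions are stated at the isocenter plane.

## The network

Architecture (per level width `f`, starting at `base_features` and doubling
per downsampling):

* block: conv3×3×3 → Convolved CReLU (concatenated ±ReLU, which doubles
  channels, followed by a 3×3×3 convolution restoring `f`) → conv3×3×3 →
  Convolved CReLU → group normalization;
* downsampling: 2×2×2 max-pool and average-pool concatenated (doubles
  channels; the next block's first convolution absorbs the doubling), with
  DropBlock (rate 0.1, block edge drawn uniformly from 1..5, spatial mask
  shared across channels) applied to each downsampling output in training
  mode only;
* upsampling: nearest-neighbour and trilinear factor-2 interpolation
  concatenated, then the same-level encoder output joined by a skip
  connection;
* head: 1×1×1 convolution to one dose channel.

Same-padding keeps spatial dims constant within a level; input dims must be
divisible by 2^(levels−1). Group-norm groups default to 6 when 6 divides the
base width (the clinical-scale base of 24), else the largest divisor ≤ 8;
narrow desk-scale nets may set the group count explicitly so that more than
one channel shares statistics. The head convolution is zero-initialized so
early training starts from a zero dose estimate.

The stack is implemented directly on numpy arrays with hand-written
backward passes (float32 or float64); gradient correctness is pinned by
finite-difference tests. Training uses AdamW (decoupled weight decay 1e-2),
MSE on the central axial slice only, batch shuffling, and a convergence
rule of no validation-loss decrease within `patience` epochs; the
parameters with the lowest validation loss are restored. The default
learning rate is 5e-4 and constant; an optional cosine annealing schedule
(to lr/10) exists for short desk-scale runs, where the stochastic
augmentations otherwise set a loss floor at a constant rate. Two
augmentations are applied per training sample: a factor drawn uniformly
from [0, 5] multiplying the painted fluence and the dose target together
(RED untouched — this forces the model to read the fluence rather than
memorize anatomy→dose), and optionally a random rotation of input and
target about the superior–inferior axis.

## Synthetic cases and the analytic dose oracle

Clinical CT/plan/dose triples are not shippable, so the package generates
cases with the statistical structure the learning task needs:

* **Phantom**: an elliptic-cylinder body of soft tissue (RED ≈ 1 with a
  smooth Gaussian-filtered texture field, amplitude 0.04), a spherical
  target (PTV) at the isocenter, pelvic organs (bladder, rectum, femoral
  heads) with class-specific RED draws, and a uniform couch slab posterior
  to the body. Per-case anatomy is jittered (body axes ±10%, target radius
  ±20%, organ centres ±5 mm, sizes ±15%).
* **Plan**: one control point per sampled gantry angle per arc; apertures
  follow the target's beam's-eye-view extent per leaf row with ±3 mm
  Gaussian dilation/erosion noise (conformal-plus-noise, so dose correlates
  with target shape as optimized plans do); meterset increments are random
  positive draws normalized to sum to the arc MU.
* **Oracle dose**: dose(v) = fluence term × exp(−μ_eff × radiological
  depth) × (SAD/d_sv)², summed over angles. The fluence term is the FM
  convolved with a Gaussian scatter kernel (width stated at the isocenter
  plane) sampled at the voxel's divergent projection; radiological depth is
  the cumulative RED path in a parallel-ray approximation (volume rotated
  to beam coordinates, cumulative sum, rotated back), which is exact for an
  axis-aligned slab and keeps the whole oracle exactly linear in fluence.
  Defaults μ_eff = 0.005/mm and lateral σ = 5 mm are order-of-magnitude
  6 MV values. This oracle is a ground-truth *generator* for the learning
  task — deliberately simple, not a clinical dose engine, and no claim of
  dosimetric realism is made. Plan MU is normalized per case so the mean
  PTV dose equals the 45 Gy prescription.

What passing tests on these cases do **not** show: accuracy on real
anatomy (no heterogeneity detail, no realistic HU texture, no couch
transmission), realistic penumbra or scatter physics, or clinical γ rates.
They do show that every stage of the pipeline — fluence bookkeeping,
geometric encoding, learning, evaluation — behaves as specified and that
the network genuinely reads the encoded fluence (null-fluence check).

## Desk-scale study configuration

The pipeline defaults define a study small enough to regenerate and retrain
from scratch in minutes on one CPU core while preserving the method's
geometry exactly:

| quantity | value | why |
|---|---|---|
| grid | 32×32×8 voxels at 20×20×10 mm | same 640 mm transverse extent as a clinical grid, so the 300 mm encoding ring lies inside the volume in air |
| gantry sampling | 10° (36 FMs/arc) | desk-scale stand-in for the 2°/180-FM clinical sampling (which the fluence module supports and tests cover) |
| FM grid | 25 mm pixels, 200 mm field of view | FM resolution matched to the voxel pitch, mirroring the clinical regime (2.5 mm FMs on a 2.7 mm grid); a finer FM lattice makes the reference dose depend on sub-voxel aperture detail that voxelized encoding cannot carry |
| oracle | μ_eff 0.005/mm, lateral σ 20 mm, beamlets on the 25 mm FM lattice | σ is matched to the coarse voxel pitch so dose is resolved on the grid |
| cases | 40 (26 train / 4 val / 10 test, hash-split) | smallest set where held-out evaluation is meaningful |
| network | 3 levels, base 8, groups 2, DropBlock 0.1 | reduced analogue of the 4-level/base-24 clinical net |
| training | AdamW, lr 2.5e-3 cosine-annealed, batch 2, ≤150 epochs, float32 | small batches buy more optimizer steps per FLOP at fixed compute; annealing pushes below the augmentation noise floor |
| encoding scale | fixed 2.0/850 per archive | one archive-wide gain keeps dose exactly proportional to painted intensity across cases; per-case auto-scaling (the encoder default for single volumes) would vary the input→dose gain by ±20% and cap achievable accuracy |

At this scale the trained network reproduces the oracle dose only
approximately: held-out central-slice γ(3%/2 mm, 10% threshold) pass rates
land in the 50–70% range, far below clinical-scale performance. Two causes
are structural: the architecture needs orders of magnitude more optimizer
steps than a minutes-long CPU run provides (the clinical-scale training in
this family of models runs for days on a GPU), and on a 20 mm grid the 2 mm
distance-to-agreement term of γ is inert, so body-surface buildup voxels —
where regression errors concentrate — cannot pass via spatial agreement.
The desk-scale study therefore demonstrates the pipeline end to end and the
direction of learning, not clinical agreement rates.

## Numerical choices

* Aperture rasterization is exact fractional area (interval overlaps per
  leaf row), clipped to [0, 1]; verified against a supersampling oracle.
* Angle binning: nearest sampled angle, circular; exact midpoints round to
  the lower bin.
* MU share uses the later control point of each delivery segment (no
  intra-segment interpolation).
* Painting: nearest-voxel deposition, additive across maps and overlaps;
  points outside the grid are dropped; painted voxels may warn or error if
  they intersect the body/couch mask.
* γ search: candidate displacements on a step lattice (0.2 mm in 2D, 1 mm
  in 3D) containing the zero offset exactly, radius capped at 3×DTA,
  evaluated dose interpolated linearly; voxels below the threshold are
  excluded (NaN in the map). γ is computed on the central axial slice by
  default, with a 3D mode.
* Dx% is the minimum dose of the hottest ⌈x%·n⌉ voxels (voxel-count
  percentile; equivalent to volume percentiles on uniform grids).
* Resampling is trilinear and idempotent at matched spacing; sub-volume
  extraction zero-pads out-of-grid regions.
* DVH curves are cumulative with ≥-threshold semantics, so the curve is
  100% at 0 Gy and Dx% inverse lookup agrees with the percentile within
  one bin width.

## Known limitations

* The oracle's parallel-depth approximation slightly misstates off-axis
  radiological paths for divergent rays; on-axis behaviour is exact.
* The couch is a uniform slab; leaf transmission, tongue-and-groove and
  output factors are not modelled (the fluence map is a binary-aperture,
  MU-weighted intensity by design).
* Only coplanar, single-isocenter arcs are supported.
* The default HU→RED curve is a 4-anchor placeholder; sites should load a
  measured curve from YAML.
* The desk-scale γ pass rates are a property check on synthetic physics,
  not a clinical accuracy claim.
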