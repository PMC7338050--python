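# Methods

This note documents the quantification procedure implemented by `ciliaq`,
its numerical choices, and what the synthetic-data tests do and do not
demonstrate about real microscopy data.

## The measurement problem

Primary cilia are solitary, antenna-like membrane protrusions, roughly
2–10 µm long and 0.2–0.3 µm in diameter. In fixed-cell experiments they
are visualized by immunostaining a cilium-enriched protein (Arl13B or
acetylated tubulin) and recording confocal z-stacks (lateral pixel size
≈ 0.2 µm, axial step 0.4–0.5 µm). The quantities of interest per cilium
are its volume, its mean fluorescence in each channel (e.g. how much of
a cargo protein localizes to the cilium), and above all its length in
µm. In live-cell biosensor experiments, the same segmentation applied
per frame yields per-cilium fluorescence traces whose ratios report
second-messenger dynamics (cAMP, Ca²⁺).

## Segmentation

The marker channel is binarized with a single global threshold computed
on its maximum-intensity projection:

1. 256-bin histogram over the projection's own `[min, max]` range. The
   procedure therefore depends only on the histogram *shape*; affine
   intensity rescaling (gain, offset, bit-depth conversion) does not
   change the mask.
2. Renyi-entropy threshold selection (Sahoo, Wilkins & Yeager 1997), in
   the exact formulation of the ImageJ `Auto_Threshold` plugin: three
   candidate levels maximize the Renyi entropy of the
   background/foreground partition at orders ρ→1 (the Kapur/Shannon
   limit), ρ = 1/2 and ρ = 2; the sorted candidates are combined with
   the plugin's weighting rule, whose weights depend on whether the
   candidates fall within 5 gray levels of each other. Ties within an
   order resolve to the lowest level.
3. The selected bin index is mapped to an intensity: the *upper edge*
   of the optimal bin. A voxel is foreground iff its intensity is
   strictly greater than this threshold, applied to every z-slice. For
   8-bit integer data this reproduces the reference "value > level"
   semantics bit-for-bit; for other ranges the 256-level re-binning is
   a documented convention and the one plausible source of divergence
   from the original plugin on >8-bit data.

An exhaustive plain-loop scan over all candidate levels at each order
serves as the test oracle for step 2.

## Object detection and intensity measurement

Foreground voxels are partitioned into maximal 3D connected components
at 26-connectivity (face+edge+corner; thin diagonal cilia fragment
under 6-connectivity). Components smaller than **10 voxels** are
discarded as noise — *below* the threshold, so a 10-voxel object is
kept. Each surviving component is one cilium. Per channel, its mean
intensity is the arithmetic mean over exactly the member voxels;
objects touching the stack border are kept but flagged. Labeling is
verified against a breadth-first-search oracle on seeded random masks.

## Length measurement

The length of a cilium is measured on a smoothed, upsampled
reconstruction of its binary 3D region:

1. **Upsample ×3** per axis by voxel replication (no interpolation —
   the subsequent blur provides the smoothing). Calibration scales
   accordingly (0.21 µm lateral pixels become 0.07 µm).
2. **Gaussian blur, σ = 3 upscaled lateral pixels** (0.21 µm at the
   default pixel size). The blur is physically isotropic: the axial
   sigma is the same 0.21 µm expressed in upscaled z-pixels
   (σ_z = 3·dx/dz pixels). For strongly anisotropic voxels this is the
   only self-consistent reading of a single stated sigma.
3. **Rebinarize at half amplitude**, where the amplitude is the
   blurred mask's *peak value*: 1 for objects much larger than the
   kernel, lower for sub-resolution tubes whose ridge never reaches 1.
   An absolute 0.5 cut would erase every cilium thinner than the blur
   kernel — at 0.21 µm pixels that is the entire biological radius
   range. The half-amplitude core is then extended along the ridge
   down to half that level (hysteresis, by morphological
   reconstruction): where a connected cilium's ridge dips locally (thin
   or diagonally-stepping stretches), the cut must not sever it,
   because the thinning step is contractually topology-preserving.
   `SkelParams.ridge_follow_fraction` (default 0.5 of the rebinarize
   level; 1.0 disables) controls the extension.
4. **3D thinning** to a curve skeleton: border voxels are deleted one
   at a time, in six directional subiterations (two-phase: the
   candidate layer is frozen at the start of each pass, then each
   candidate is re-checked at deletion time), whenever deletion
   preserves both foreground 26-connectivity and background
   6-connectivity of the 3×3×3 neighborhood — the classical (26, 6)
   simple-point characterization — and the voxel is not a curve
   endpoint. Component count and cycles are preserved exactly. The
   inner loops are numba-compiled.
5. **Length.** Two numbers are reported. The *total skeleton length*
   is the minimum-spanning-forest weight of the calibrated 26-neighbor
   skeleton graph (summing raw neighbor edges would double-count where
   three mutually adjacent voxels meet). The *cilium length*
   (`length_um`) starts from the longest geodesic — the largest
   shortest-path distance between skeleton endpoints (degree ≤ 1
   nodes), tie-broken by deterministic node order — and reports the
   length of the **taut tip-to-tip path**: the shortest calibrated
   26-path through the smoothed cilium volume connecting the two
   skeleton tips that realize that geodesic. Summing steps along the
   voxel-jagged skeleton chain itself systematically overestimates
   oblique and curved lengths by 8–20% (digital chain-length bias plus
   thinning jitter); the taut path is the minimal representative of
   the same tip-to-tip course — same endpoints, same homotopy class —
   and removes the jitter. For an unbranched axis-aligned cilium all
   these numbers coincide, and on analytic chains the geodesic is
   exact: a collinear N-node chain at spacing d measures (N−1)·d, a
   body-diagonal chain (N−1)·√(dx²+dy²+dz²).

Lengths shorter than the blur width (0.21 µm) are below the method's
resolution and reported as undefined (e.g. a 1-voxel object); the
object itself is retained. The measurement is deterministic:
re-running on the same object is bit-identical. It is exactly linear
in the calibration, and invariant under 90° axis permutation up to a
few percent (the directional thinning order shifts tip voxels by about
a voxel; exact invariance holds for the geodesic on a fixed node set).

## Trace corrections

Per-ROI fluorescence traces (frames every few seconds; stimulus added
after a baseline period) support:

* per-channel background subtraction;
* FRET spectral correction
  `FRET_corrected = FRET − α·cerulean − β·citrine`, defaults
  **α = 0.75** (donor emission bleeding into the acceptor filter) and
  **β = 0.02** (direct acceptor excitation). A helper estimates α or β
  from single-fluorophore control recordings as the least-squares
  slope through the origin of acceptor-channel on donor-channel
  signal — a reproducible stand-in for interactive
  colocalization-based estimation;
* framewise ratios (cerulean/FRET_corrected for the FRET sensor,
  cerulean/citrine for confocal ratio imaging, mCherry/cpGFP for the
  cADDis sensor). Zero-denominator frames become NaN and are excluded
  from summaries, never interpolated;
* baseline normalization: division by the per-channel mean over the
  baseline window (default: all frames strictly before the stimulus
  frame). The normalized baseline mean is 1 to machine precision and
  the operation is idempotent;
* plate-reader Ca²⁺ normalization
  `(F − F_baseline)/(F_ionomycin − F_baseline)`, divided by the
  fraction of reporter-positive cells when given (population
  recordings in which only transfected cells respond).

## Expression gating and length analysis

Ectopic expression of a cilium-targeted construct lengthens cilia at
high ciliary levels. Length comparisons are therefore restricted to a
low-expression regime: the mean ciliary fluorescence of
non-transfected control cilia (arithmetic mean of per-cilium means) is
subtracted, cilia with gated-channel intensity **≥ 7.5 a.u.** are
excluded (strict `<` keeps only values below the gate), and treated
lengths are expressed as percent of the control mean. An OLS fit of
length on intensity with the standard zero-slope t-test quantifies the
expression–length correlation that motivates the gate. The gate can be
applied per experiment (after per-experiment background subtraction)
or globally; both are supported via `GateParams`.

Time-lapse recordings are linked frame-to-frame by greedy
nearest-centroid assignment (closest pairs first, maximum displacement
2 µm by default; unlinked detections start new tracks), which suffices
for stationary-to-slowly-drifting cilia. Statistical tests beyond the
zero-slope test are out of scope; outputs are plain tables.

## Synthetic data: what it emulates, what it does not

The generator plants curved tubes with known centerline, radius and
per-channel amplitude into a calibrated volume:

* centerlines are arc-length-parameterized random walks with bounded
  per-step direction change (default ≤ 0.3 rad/µm), total arc length
  exact by construction; lengths uniform in 2–8 µm, radii in
  0.1–0.3 µm — the biological range;
* a voxel belongs to a tube when its center lies within the radius of
  the centerline; sub-voxel tubes always leave at least the
  nearest-voxel trace, so thin cilia stay connected;
* the marker channel carries the tubes at amplitude 150 a.u. on a
  10 a.u. background; cargo channels share the footprint with a
  per-cilium amplitude drawn uniformly from 2–15 a.u. *added* to the
  background, so control-background subtraction recovers the planted
  amplitude and the 7.5 a.u. gate can be exercised with planted
  positives and negatives;
* optional optics and noise: Gaussian PSF (0.1 µm in the recovery
  study — confocal-like), Poisson shot noise on the blurred signal,
  Gaussian read noise (sd 5 a.u. in the study). At amplitude 150 the
  combined noise is ≈ 13 a.u., i.e. SNR ≈ 11.
* ground truth is recorded before blur and noise, so recovery
  tolerances absorb optics and algorithm bias together, as with a real
  microscope.

Default geometry: 16×128×128 voxels at 0.21/0.21/0.4 µm; defaults for
noise and blur are *off* (the clean baseline used by the exactness
tests); the recovery study passes the imaging conditions explicitly.

What passing these tests shows: the pipeline recovers tube-shaped
objects of the stated geometry under blur and mixed noise, with exact
detection in all 50 study fields and ≥ 90% of lengths within
2·radius + 10% of truth. What they do not show: robustness to touching
cilia (no watershed splitting), cell-body autofluorescence, uneven
staining along the axoneme, or depth-dependent PSF aberration — none
of which the generator models.

## Numerical choices and degenerate inputs

* Histograms: 256 bins over `[min, max]`; single-occupied-bin
  histograms (e.g. an all-zero stack) raise a degenerate-input error
  rather than returning an arbitrary threshold.
* Strict inequalities at every boundary: threshold (`>`), size filter
  (keep `≥ 10`), expression gate (keep `< 7.5`).
* Tie-breaks: lowest histogram level; first-found geodesic pair in
  deterministic (z, y, x) node order.
* Bounding-box crops for length measurement are padded by the blur
  support (⌈4σ/3⌉+1 original voxels) so the kernel is never clipped.
* Zero-denominator trace frames → NaN; zero baseline mean → error.
* Objects at the stack border are measured but flagged.
* Every output table embeds a config hash and the package version.

## Known limitations

* Lengths carry the residual digital-path bias of the taut 26-path
  (median ≈ +6% on the recovery study) — an upper-bias, since a taut
  digital path can only match or exceed the true arc length inside the
  tube, minus endpoint erosion by the blur.
* Axis-permutation invariance of the full chain is approximate (few
  percent), a property of any direction-ordered thinning.
* The Renyi threshold on >8-bit data follows the 256-level re-binning
  convention; other tools may bin differently.
* Touching cilia merge into one object; the tracker is greedy and
  frame-local, with no gap bridging across empty frames.
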