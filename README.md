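# ciliaq

Automated 3D quantification of primary cilia in multi-channel
fluorescence z-stacks — a Python library and command-line tool
implementing the CiliaQ quantification scheme, plus the ratiometric
biosensor trace corrections used alongside it.

Primary cilia are antenna-like membrane protrusions (length 2–10 µm,
diameter ≈ 0.2–0.3 µm) that compartmentalize signaling — notably cAMP
signaling, which controls ciliary length. Experiments on ciliary
signaling need unbiased per-cilium measurements from confocal stacks:
how many cilia, how long each one is, and how much fluorescence each
channel (marker, cargo, biosensor) carries inside the cilium. This
package provides that measurement chain for cell biologists working
with stained (Arl13B, acetylated tubulin) or biosensor-expressing
cilia, together with a synthetic-stack generator so the whole pipeline
is testable with known ground truth.

## The method

Given a calibrated stack *I(c, z, y, x)* with a designated ciliary
marker channel:

1. **Threshold** — compute the maximum-intensity projection
   *P(y,x) = max_z I(marker, z, y, x)*, build its 256-level histogram
   {p_i}, and select the threshold with the Renyi-entropy rule
   (maximum-entropy partitions at orders ρ→1, ρ=1/2, ρ=2, combined by
   the standard weighting rule). Binarize the full 3D channel with
   strict `intensity > threshold`.
2. **Detect** — 3D connected components at 26-connectivity; discard
   objects below **10 voxels** (noise); each remaining object is a
   cilium. Per channel, the cilium's intensity is the mean over its
   member voxels.
3. **Measure length** — upsample the object's binary region ×3,
   Gaussian-blur with σ = 3 upscaled pixels (0.21 µm), re-binarize at
   half amplitude, thin to a 3D curve skeleton (topology-preserving
   simple-point deletion), and report the calibrated length of the
   taut tip-to-tip path between the skeleton's farthest endpoints,
   along with the total skeleton length.
4. **Traces** (biosensor mode) — per-frame segmentation + tracking
   yields per-cilium traces; corrections include background
   subtraction, FRET bleed-through removal
   `FRET_corr = FRET − 0.75·cerulean − 0.02·citrine`, channel ratios
   (cerulean/FRET_corr, mCherry/cpGFP), baseline normalization, and
   plate-reader normalization
   `(F − F_bl)/(F_iono − F_bl)/fraction_positive`.
5. **Expression gating** — subtract the mean ciliary fluorescence of
   non-transfected controls, keep cilia expressing **< 7.5 a.u.**, and
   normalize lengths to the control mean; an OLS length-vs-intensity
   fit with zero-slope test documents why the gate is needed.

Details, numerical conventions and limitations: `docs/methods.md`.

## Worked example

Simulate a field of three cilia under confocal-like conditions and
quantify it:

```python
from ciliaq import SyntheticSpec, generate_cilium_field, run_pipeline

spec = SyntheticSpec(n_cilia=3, seed=11, psf_sigma_um=0.1,
                     noise_gaussian_sd=5.0, noise_poisson=True)
stack, truth = generate_cilium_field(spec)
result = run_pipeline(stack)
print(result.table[["id", "volume_voxels", "length_um",
                    "mean_intensity_0", "mean_intensity_1"]].round(3))
```

prints

```
 id  volume_voxels  length_um  mean_intensity_0  mean_intensity_1
  9             27      2.957           108.676            18.259
 12             53      8.592           111.193            13.585
 13            125      7.531           132.142            14.786
```

against planted arc lengths of 2.771, 7.824 and 6.910 µm — each
recovered within the expected 2·radius + 10% tolerance (blur and noise
erode sub-resolution tubes; the marker means sit below the planted
150 a.u. for the same reason). Column `mean_intensity_1` is the cargo
channel: subtracting the 10 a.u. background recovers the planted
per-cilium expression levels used for gating.

The same run from the shell:

```bash
ciliaq simulate --n-cilia 3 --seed 11 --out field.ome.tif --truth truth.csv
ciliaq quantify field.ome.tif --table objects.csv
# INFO ciliaq.pipeline: threshold=32.66 on channel 0; 225 foreground voxels
# INFO ciliaq.pipeline: objects: 23 detected, 3 after 10-voxel size filter
```

(`ciliaq simulate` defaults to noise-free output; the INFO lines above
are from the noisy Python example.) Other subcommands: `segment`
(mask only), `analyze` (gating + control normalization on object
tables), `traces` (FRET/cADDis trace correction), `run` (full pipeline
from a YAML config).

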