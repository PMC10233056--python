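# Methods

`lirads-auto` implements a fully automatic LI-RADS pipeline for multi-phase
contrast-enhanced liver imaging: lesion segmentation, per-lesion major-feature
characterization (APHE, washout, enhancing capsule), deterministic rule-based
category inference (LR-3 / LR-4 / LR-5), and a multi-level evaluation suite.
A synthetic phantom generator supplies multi-phase studies with known feature
dynamics so every stage is testable without clinical data. This note records
the models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Pipeline model

Given co-registered arterial, portal-venous (PV), and delayed phase volumes,
the stages run in order:

1. **Preprocessing.** Each volume is normalized by the piecewise map
   `n = 0` if `o < 80`, `n = (o − 80)/(P99 − 80)` if `80 ≤ o ≤ P99`, `n = 1`
   if `o > P99`, where `P99` is the volume's 99th intensity percentile, then
   standardized to zero mean / unit variance per volume. The floor of 80
   reflects that in T1-weighted liver MR the lowest intensities are air and
   background; the percentile cap absorbs the unbounded bright tail MR lacks
   a Hounsfield-style calibration for. Inputs to the segmentation network are
   2.5D windows — three neighbouring axial slices stacked as channels,
   labelled by the centre slice's mask — so an S-slice volume yields S − 2
   windows.
2. **Segmentation** runs on the delayed phase (the ROI-extraction phase; a
   config switch widens it). The network is a nested encoder–decoder
   (UNet++-style): a residual encoder with optional CBAM channel+spatial
   attention per block, 2×2 max-pool downsampling, and the dense grid of
   decoder nodes X[i][j], each fusing all same-level predecessors with the
   upsampled node below; a 1×1 convolution and sigmoid give the centre-slice
   foreground probability map. The final top-level node is the sole output
   (no deep-supervision averaging).
3. **Characterization.** Per detected 3-D component, the slice with the
   largest segmented area is selected (ties → lowest index), cropped square
   around the component's bounding box with a 25% margin, resized, and
   standardized. One crop per phase feeds a shared convolutional backbone
   with three parameter-disjoint sigmoid heads. At inference, `p_aphe` comes
   from the arterial crop and `p_washout`/`p_capsule` are the **maximum** of
   the PV and delayed head outputs ("present in either phase"); boolean calls
   use `p ≥ 0.5` (configurable).
4. **Scoring.** Lesion size is the maximum in-plane Feret diameter (largest
   centre-to-centre pixel distance within any axial slice, scaled by in-plane
   spacing) **plus one in-plane spacing unit**, so a single voxel measures one
   pixel width and a straight run of k voxels at 1 mm measures k mm. The rule
   engine is a total lookup over (B1, B2+B3, size bin) with half-open bins
   [0,10), [10,20), [20,∞) mm. The one ambiguous cell (B1=1, 10–19 mm, one
   minor feature) resolves by policy; the default `prefer_washout_rule` maps
   it to LR-5 when the minor feature is washout and LR-4 when it is capsule
   alone, mirroring the v2018 distinction the collapsed table loses.
   `report_both` keeps the ambiguity.

## Losses

Segmentation trains on a hybrid loss: `(1 − soft dice) + focal`. The soft
dice term is aggregated per class over the batch,
`(2Σyp + ε)/(Σy² + Σp² + ε)` with ε = 1, rather than evaluated per pixel
(the per-pixel ratio is 0/0 on background). Writing the hybrid as
`(1 − dice) + focal` instead of `−(dice − focal)` shifts it by a constant so
it is nonnegative with identical gradients. Targets are one-hot {0,1}. The
focal term is `−(1/N) Σ α_c (1−p)^γ y log p` with α on the foreground class
and 1−α on background; defaults α = 0.25, γ = 2 (the originating focal-loss
convention). Probabilities are clipped at 1e−7 before logarithms.

Once the running training loss (mean of the last 10 steps) first falls below
`lovasz_trigger` (default 0.3), a Lovász–Softmax term is **added** and stays
on (latched): per class, the error vector `m = |y − p|` is sorted descending
and dotted with the discrete gradient of the Lovász extension of the Jaccard
loss, averaged over classes present in target or prediction. For hard
predictions this equals 1 − IoU exactly; the analytic training gradient
treats the sorting permutation as locally constant (the standard
almost-everywhere subgradient).

The characterizer trains with the phase-adaptive multi-task loss
`L = (1 − x)·L_aphe + x·(L_washout + L_capsule)`, x ∈ {0,1} the phase
indicator (0 arterial, 1 PV/delayed), each head loss a binary cross-entropy.
Routing is exact: an arterial-only optimizer step leaves the washout and
capsule head weights bit-identical (Adam applied to a zero gradient with zero
state performs a zero update), while the shared backbone learns from every
sample. The non-adaptive comparison arm trains every head on every sample,
which forces washout/capsule supervision onto arterial crops that do not
carry the signal.

All networks are implemented in a compact numpy layer library
(`lirads_auto.nn`) with hand-written backward passes — stride-1 convolutions
via sliding windows, explicit 2×2 pooling/upsampling, residual blocks, CBAM,
dense heads, Adam — verified against central finite differences in the test
suite (worst-case error ~1e−9 in float64).

## Phantom generator

Each patient is an ellipsoidal uniform "liver" (intensity 150) on a dark
background (intensity 40, below the normalization floor) with 0–3
non-overlapping spherical lesions placed inside the liver; additive Gaussian
noise is applied last. A lesion is isointense to parenchyma except through
its feature flags: APHE adds +60 over the whole lesion in the arterial phase;
washout subtracts 45 from the lesion core in PV and delayed; capsule renders
a ~1.6-voxel bright shell (+50) just inside the lesion boundary in PV and
delayed. Offsets are configurable so "easy" (high-contrast, low-noise) and
"hard" datasets can be generated. Every lesion's label is produced by the
scoring rule engine from its flags and sampled diameter, so labels are
rule-consistent by construction. All randomness derives from
(dataset seed, patient index, lesion index) seed sequences: identical specs
are bit-reproducible and patients are mutually independent.

Default composition emulates the clinical cohort structure this pipeline is
modelled on: 512×512 slices, diameters 4–164 mm with ~45% under 20 mm, and
HCC-typical prevalences (APHE 0.80, washout 0.70, capsule 0.50).

Because feature contrast is the *only* lesion signal, a lesion with neither
washout nor capsule is invisible in the delayed phase that the default
pipeline segments — undetectable by construction — so end-to-end category
accuracy is evaluated over detected lesions matched to ground truth. The
phantoms deliberately omit anatomy: no texture, vessels, motion, partial
volume, or MR physics (noise is Gaussian, not Rician — the pipeline never
exploits the noise distribution). Passing tests therefore demonstrate that
the machinery is correct and that the networks learn the intended contrast
dynamics; they say nothing about performance on clinical images.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| normalization floor | 80 | scanner units | background cutoff |
| normalization percentile | 0.99 | — | bright-tail cap, per volume |
| focal α / γ | 0.25 / 2 | — | class weight / focusing |
| dice ε | 1.0 | — | smoothing, avoids 0/0 |
| lovasz_trigger | 0.3 | loss units | latch threshold for the IoU surrogate |
| probability clip | 1e−7 | — | before logs |
| augmentation | ±15°, ±10% shift, p=0.5 flips | — | zero-padded to input size |
| folds | 9 | — | patient-level split; sizes differ by ≤1 |
| binarization threshold | 0.5 | — | swept 0.2–0.8 in evaluation |
| min component size | 5 | voxels | speckle suppression (1 = strict) |
| crop margin | 0.25 | box fraction | context kept around the lesion |
| feature call threshold | 0.5 | — | `p ≥ t` convention, boundary inclusive |
| Adam learning rate | 1e−3 (seg 2e−3 desk-scale) | — | optimizer |

## Numerical and convention choices

- Fold splitting is by patient, never by window, so neighbouring slices of
  one patient cannot straddle the train/test boundary; stratification is
  optional and off by default.
- Per-patient DICE: empty-vs-empty (no lesion, none predicted) is 1 in the
  pipeline report and configurable in `local_dice_mean` (default 0);
  truth-nonempty vs empty prediction is 0.
- Precision with zero predictions is reported as 1 with an explicit
  `degenerate_precision` flag, keeping threshold sweeps total.
- Lesion-level detection: ≥1 shared voxel by default, optional IoU ≥ τ; true
  negatives are undefined at lesion and patient level and never reported.
  (A detected lesion is a true *positive*; detection counts cannot produce
  lesion-level true negatives.)
- Boundary slices of a predicted volume copy the nearest interior window's
  map, so S slices in → S maps out.
- Representative-slice ties break to the lowest index; the same slice index
  (from the segmentation mask) is used for all three phases, since phases are
  co-registered and segmented once.
- Training batches oversample lesion-bearing windows (half of each batch)
  because window stacks are overwhelmingly lesion-free.

## Desk-scale problem sizes

The shipped tests and the easy end-to-end check run, as the package's own
test conditions: 40 patients of 24×64×64 voxels (2.0×1.25×1.25 mm), 0–2
lesions of 8–22 mm each, contrast (+90/−70/+80), noise σ = 2; a 2-stage
nested network with base width 8 and CBAM trained 500 steps at batch 8; a
(8,16)-width characterizer on 32×32 crops trained 400 steps. One quarter of
patients are held out. Full-scale defaults (4-stage network, 512×512, 9
folds) are configured but not exercised in the test suite.

## Limitations

- The numpy networks are CPU-bound and sized for phantoms; clinical-scale
  512×512 training would require a GPU framework behind the same interfaces.
- No inter-phase registration is implemented (phantom phases are co-registered
  by construction).
- Only LR-3/4/5 are modelled; LR-1/2/M/TIV and the threshold-growth feature
  (which needs longitudinal studies) are out of scope.
- The ambiguous LR-4/5 cell has no ground-truth resolution; both the policy
  and the size-bin boundary conventions are explicit configuration, not
  recovered facts.
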