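# spineseg

Two-phase semantic and instance segmentation of whole-spine sagittal MR
label maps.

Whole-spine analysis needs two complementary masks: a **semantic** mask that
labels each voxel with its anatomical structure (vertebral body, posterior
elements, intervertebral disc, endplate, spinal canal, cord, sacrum — 14
structures in all) and an **instance** mask that separates the individual
vertebrae and discs (vertebra 1 vs vertebra 2, …).  Networks trained
directly on instance labels confuse neighboring vertebrae, because all
vertebrae look alike.  This package implements the alternative: segment
semantically first, then convert the semantic mask into instances with a
sliding-window procedure that only ever reasons about *relative* positions
(the vertebra at the center of a window, the one above, the one below).

It is aimed at researchers building or evaluating spine-segmentation
pipelines: the per-voxel semantic classifier and the per-cutout instance
predictor are pluggable contracts (trained networks in production; exact
and noisy phantom-backed oracles here), and every downstream step —
cutout extraction, consistency-ordered fusion, post-processing, panoptic
evaluation — is importable, tested code.

## Method

Phase 1 produces a semantic mask with the 14 structure codes.  Phase 2:

1. **Corpus centers.** Connected-component analysis (26-connectivity) on the
   vertebral-body label yields one center of mass per vertebra, ordered top
   to bottom.
2. **Cutouts.** Around each center a fixed-geometry window — 248 × 304 × 64
   voxels at (0.75, 0.75, 1.65) mm in posterior–inferior–right orientation —
   is sampled from the semantic mask.
3. **Relative prediction.** A per-cutout predictor labels each cutout voxel
   *center*, *above*, *below* or background.  Inner vertebrae are therefore
   predicted three times (once per adjacent cutout), outer ones twice.
4. **Consistency-ordered fusion.** For each vertebra the mean pairwise Dice
   across its appearances is computed; vertebrae are written into the
   instance mask from the highest to the lowest score, each voxel decided by
   a weighted per-voxel majority, and a claimed voxel is never overwritten —
   so the least consistent predictions are addressed last and an error in
   one cutout stays local.
5. **Discs and endplates** from the semantic mask receive instance ids from
   the nearest vertebra above (center-of-mass comparison in mm).
6. **Post-processing** reconciles the masks: unsupported instance voxels are
   removed, orphaned semantic components are rescued into the neighboring
   instance, isolated elements are deleted by a bounding-box analysis, and
   articular-process components are relabeled by majority vote.

Evaluation follows standard practice: Dice similarity coefficient (DSC),
average symmetric surface distance (ASSD, mm), and the panoptic family —
recognition quality RQ = TP/(TP + FP/2 + FN/2) with true positives at
IoU ≥ 0.5, segmentation quality SQ = mean matched IoU, and PQ = RQ · SQ —
plus a paired Wilcoxon signed-rank test for cohort comparisons.

Everything is testable without data downloads: the `phantom` module
generates deterministic synthetic whole-spine label maps (3–24 vertebrae,
nine posterior substructures, discs/endplates, canal/cord, sacrum,
anisotropic thick-slice spacing, optional fused vertebrae and missing outer
slices) with consistent ground-truth semantic and instance masks.

## Worked example

```python
from spineseg.phantom import PhantomSpec, generate_phantom
from spineseg.instance_stage import (
    NoisyInstancePredictor, OracleInstancePredictor, semantic_to_instances,
)
from spineseg.postprocess import MaskPair, apply_postprocessing
from spineseg.metrics import evaluate_subject

phantom = generate_phantom(PhantomSpec(n_vertebrae=7, seed=3))
predictor = NoisyInstancePredictor(       # emulates instance-model errors
    OracleInstancePredictor(phantom.instances),
    flip_rate=0.06, drop_rate=0.03, seed=3,
)
result = semantic_to_instances(phantom.semantic, predictor)
pair = apply_postprocessing(MaskPair(phantom.semantic, result.instances))
report = evaluate_subject(pair, MaskPair(phantom.semantic, phantom.instances))
print(report.instances.to_string(index=False))
```

prints

```
   group      dsc  rq       sq       pq     assd  tp  fp  fn
vertebra 0.994913 1.0 0.989934 0.989934 0.090698   7   0   0
     ivd 1.000000 1.0 1.000000 1.000000 0.000000   6   0   0
endplate 1.000000 1.0 1.000000 1.000000 0.000000   6   0   0
```

All seven vertebrae are recognized (RQ 1.0, no false positives/negatives)
despite 6 % label-swap and 3 % dropout noise in every cutout prediction;
the surviving boundary errors cost half a percent of Dice and 0.09 mm of
surface distance.  With the exact oracle predictor instead, the recovered
instance mask equals the ground truth voxel for voxel and every score is
1.0 (ASSD 0.0).

The same pipeline is available from the shell:

```bash
spineseg phantom --out-dir ph --n-vertebrae 7 --seed 3
spineseg pipeline --image ph/phantom_image.nii.gz --out-dir out \
    --truth-semantic ph/phantom_semantic.nii.gz \
    --truth-instances ph/phantom_instances.nii.gz \
    --ref-semantic ph/phantom_semantic.nii.gz \
    --ref-instances ph/phantom_instances.nii.gz
```

Subcommands: `phantom`, `semantic`, `instance`, `postprocess`,
`merge-annotations`, `evaluate`, `pipeline`.

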