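# Methods

## Model and assumptions

The package converts a 14-class semantic spine mask into a per-vertebra /
per-disc instance mask.  The central assumption is that instance identity
is a *local, relative* property: given a window centered on one vertebral
body, deciding which voxels belong to that vertebra versus its immediate
neighbors above and below is easy, whereas assigning global indices
("third vertebra from the top") is brittle.  The pipeline therefore:

1. finds one center of mass per 26-connected vertebral-body (corpus)
   component of the semantic mask, ordered top to bottom;
2. samples a fixed-geometry cutout around each center and asks a pluggable
   predictor for a relative label map over the cutout
   (center / above / below / background);
3. fuses the overlapping predictions: each vertebra's appearances (up to
   three — the cutout centered on it plus both neighbors) are mapped back
   to the canonical grid, scored by their mean pairwise Dice, and written
   into the instance mask in descending score order with a strict
   no-overwrite rule;
4. assigns each disc and endplate component the instance id derived from
   the nearest vertebra above;
5. reconciles the two masks with four idempotent post-processing rules.

Working orientation is PIR throughout (axis 0 posterior, axis 1 inferior,
axis 2 right); "superior" means decreasing axis-1 index.  Inputs in any
orthogonal orientation are reoriented on entry; affines with shear beyond
1e-4 are rejected rather than silently resampled.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| cutout size | (248, 304, 64) | voxels | window large enough to hold a vertebra and both neighbors at any spine level |
| cutout spacing | (0.75, 0.75, 1.65) | mm | finer than typical sagittal acquisitions on every axis, so the nearest-neighbor round trip cutout↔canonical grid is exact |
| instance-match IoU threshold | 0.5 | — | inclusive (IoU = 0.5 is a true positive); at this threshold one-to-one matches are unique, so greedy matching is order-independent |
| center-role vote weight | 1.5 | — | the cutout centered on a vertebra is its primary prediction; the extra weight breaks exact voting ties in its favor |
| single-appearance score | 0.0 | — | an uncorroborated vertebra integrates last and cannot claim contested voxels |
| isolation margin | 5 | voxels | dilation of the main component's bounding box before the isolation test |
| corpus–IVD fill band | ≤ 2 | voxels | widest hole relabeled as endplate; unbounded filling would bridge unrelated structures |
| connectivity | 26 | — | thick-slice anisotropy fragments structures under 6-connectivity |

Vertebra instance ids are 1..N top to bottom; disc and endplate instances
use disjoint +100 and +200 blocks keyed by the owning vertebra, so the
three families never collide in one file.

## Resampling exactness

Cutouts are extracted and mapped back with nearest-neighbor sampling under
a diagonal index map `p = scale·c + offset`.  When the cutout spacing is
strictly finer than the volume spacing on every axis (`scale < 1`), each
canonical voxel's nearest cutout voxel lies within half a canonical voxel
of it, so the canonical→cutout→canonical round trip is the identity — this
is what makes voxel-exact recovery with oracle predictors possible.  With
coarser cutout spacing the round trip is only approximate; the default
geometry keeps it exact for common sagittal spacings.

## Fusion details

The per-voxel decision for one vertebra is a weighted vote over its
appearances: a voxel is included when the weight of appearances marking it
exceeds half the weight of appearances whose windows cover it.  The vote is
computed in the canonical grid after back-mapping each appearance, not in
the cutout grid; with the exact round trip above the two formulations
agree, and the canonical-grid vote needs a single pass.  Score ties between
vertebrae break toward the more superior one; voxel-vote ties break toward
the center-role appearance via its 1.5 weight.  A vertebra whose every
appearance is empty is skipped with a warning and the remaining ids are
renumbered consecutively.

The consistency score is the mean *pairwise* Dice over appearances (not
Dice against a consensus); with at most three appearances the two readings
are close, and the pairwise form needs no auxiliary consensus mask.

## Disc/endplate ownership

Each 26-connected IVD or endplate component takes the id of the vertebra
whose corpus center of mass is nearest in mm among those strictly superior
to the component's center of mass.  Both endplate slabs flanking one disc
therefore belong to the vertebra above the disc.  A component with no
vertebra above (e.g. a disc above the topmost vertebra) falls back to the
globally nearest vertebra with a logged warning.

## Post-processing

Rules run in a fixed order, each toggleable and idempotent:

1. **remove_unsupported** — instance voxels that are semantic background
   are cleared.
2. **rescue_components** — connected components of vertebra-group semantic
   foreground that carry no instance id receive the id with the plurality
   of their 26-neighborhood shell (ties toward the more superior id).  The
   rule operates on the components of the *uncovered* foreground, so
   partially covered structures are healed too and rules 1+2 together make
   the vertebra-range instance foreground exactly equal the vertebra-group
   semantic foreground.
3. **remove_isolated** — components whose bounding boxes miss the 5-voxel-
   dilated bounding box of the largest component are deleted; the largest
   component always survives.  In the chained application the rule is
   evaluated on the semantic mask — whose foreground is one connected spine
   — and deletions are mirrored onto the instance mask; judging isolation
   on the instance mask alone would delete the posterior elements, which
   are separated from the corpus column by the semantic-only canal/cord.
4. **relabel_articular** — each articular-process component takes its
   majority instance id (ties toward the more superior id), cleaning the
   few-voxel instance mixing typical at facet joints.

## Annotation merging

Training-label fusion combines three sources on one grid under a strict
no-overwrite priority (base corpus/IVD/canal/sacrum model, then
translation-derived vertebra substructures, then the cord tool).  Holes of
at most two voxels between corpus and IVD along the inferior axis are then
filled and relabeled as endplate — endplate labels are created only by this
relabeling.  Only axial (inferior-axis) gaps are considered; diagonal gaps
are out of scope.

## Evaluation conventions

* Dice of two empty masks is 1.0, of one empty mask 0.0.
* ASSD uses surface voxels (foreground with a 6-connected background
  neighbor, volume borders counting as background) and exact Euclidean
  nearest-surface distances in mm; it is undefined (NaN) for empty masks.
* Instance DSC and ASSD average over matched pairs only; unmatched
  instances are reflected in RQ, not in the overlap averages.
* Missing structures yield NaN and are excluded from cohort averages.
* The paired Wilcoxon signed-rank test reports p = 1 for all-zero
  differences and flags significance at 0.05.

## What the phantom emulates — and what it does not

The synthetic generator produces a column of 3–24 box-shaped vertebrae with
nine posterior substructures each, interleaved discs and endplate slabs, a
continuous canal/cord channel, a sacrum block, per-vertebra size jitter,
optional fused pairs and optional missing outer slices, at a default
spacing of (0.8, 0.8, 3.3) mm emulating thick-slice sagittal acquisitions.
Ground-truth semantic and instance masks are mutually consistent by
construction.

Shapes are axis-aligned boxes, not anatomical meshes: the phantom
exercises connectivity, ordering, windowing, fusion, ownership and
consistency logic, but nothing about curved anatomy, partial-volume
boundaries, pathology beyond fusion, or MR intensity statistics.  The
noisy predictor corrupts relative labels only *within* the cutout's
labeled foreground (swaps among above/center/below plus dropout), modeling
instance confusion at boundaries rather than hallucination outside the
semantic mask.  Passing tests therefore demonstrate the correctness of the
conversion and evaluation machinery under controlled error models — not
clinical segmentation accuracy, which depends on the trained backends that
plug into the two predictor contracts.

## Problem sizes

The test suite and the acceptance script run phantom cohorts of 3–24
vertebrae (volumes around 52 × 500 × 14 voxels at the largest), 20-phantom
recovery sweeps, 200 random mask pairs for the metric cross-checks and 100
random match tables for the panoptic identities — sizes chosen so the full
default suite completes in a couple of minutes on one CPU while still
covering every code path.

## Known limitations

* No anatomical naming (C2…L5): instance ids are positional, counted from
  the top of the field of view.
* The sacrum stays semantic-only; it receives no instance id.
* The semantic stage is a contract, not a model: no network training or
  inference ships with the package.
* Sheared affines and DICOM inputs are rejected; NIfTI-1 only.
* The bounding-box isolation rule assumes the spine is the largest
  foreground component, which can fail on extreme fields of view.
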