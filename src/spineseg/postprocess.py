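"""Optional post-processing rules reconciling the semantic and instance masks.

Four rules, applied in a fixed order and each independently toggleable:

1. instance voxels that are background in the semantic mask are removed;
2. vertebra-group semantic foreground still missing from the instance mask
   is rescued into the instance with the most neighboring voxels;
3. a bounding-box analysis removes elements isolated from the largest
   connected component (the target spine);
4. articular-process components are relabeled to their majority instance id
   (the instance model mixes neighboring vertebrae there by a few voxels).

Rules 1+2 make the foreground voxel sets of the two masks consistent.  In
the chained application, rule 3 is evaluated on the semantic mask — whose
foreground is one connected spine component — and deletions are mirrored
onto the instance mask; the instance foreground alone is multi-component by
design (canal and cord separate the posterior elements from the corpus
column and carry no instance ids), so judging isolation there would delete
healthy structures.  Every rule is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .label_scheme import BACKGROUND, CODES, VERTEBRA_CODES
from .volume_io import AnatomicalVolume

__all__ = [
    "MaskPair",
    "RULE_NAMES",
    "remove_unsupported_instance_voxels",
    "rescue_missing_components",
    "remove_isolated_elements",
    "relabel_articular_processes",
    "apply_postprocessing",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Dilation margin (voxels) of the main component's bounding box in the
#: isolation test.
ISOLATION_MARGIN = 5

RULE_NAMES = (
    "remove_unsupported",
    "rescue_components",
    "remove_isolated",
    "relabel_articular",
)

_ARTICULAR_CODES = (
    CODES["articular_inferior_left"],
    CODES["articular_inferior_right"],
    CODES["articular_superior_left"],
    CODES["articular_superior_right"],
)


@dataclass(frozen=True)
class MaskPair:
    """A semantic mask and an instance mask on the same grid."""

    semantic: AnatomicalVolume
    instances: AnatomicalVolume

    def __post_init__(self) -> None:
        if not self.semantic.same_grid(self.instances):
            raise ValueError("semantic and instance masks must share one grid")


def remove_unsupported_instance_voxels(pair: MaskPair) -> MaskPair:
    """Clear instance voxels that are background in the semantic mask."""
    inst = pair.instances.data.copy()
    inst[pair.semantic.data == BACKGROUND] = 0
    return MaskPair(pair.semantic, pair.instances.with_data(inst))


def _vertebra_group_mask(semantic: np.ndarray) -> np.ndarray:
    out = np.zeros(semantic.shape, dtype=bool)
    for code in VERTEBRA_CODES:
        out |= semantic == code
    return out


def rescue_missing_components(pair: MaskPair) -> MaskPair:
    """Assign orphaned vertebra-group semantic foreground to neighboring instances.

    Connected components (26-connectivity) of vertebra-group semantic voxels
    that carry no instance id receive the instance id holding the plurality
    of their 26-neighborhood shell; ties resolve toward the more superior
    (smaller) id.  Components with zero instance neighbors are left
    unassigned with a warning.
    """
    inst = pair.instances.data.copy()
    orphan = _vertebra_group_mask(pair.semantic.data) & (inst == 0)
    if not orphan.any():
        return MaskPair(pair.semantic, pair.instances.with_data(inst))
    labels, n = ndimage.label(orphan, structure=_CONN26)
    objects = ndimage.find_objects(labels)
    for comp in range(1, n + 1):
        sl = objects[comp - 1]
        grown = tuple(
            slice(max(0, s.start - 1), min(dim, s.stop + 1))
            for s, dim in zip(sl, inst.shape)
        )
        comp_mask = labels[grown] == comp
        shell = ndimage.binary_dilation(comp_mask, structure=_CONN26) & ~comp_mask
        neighbor_ids = inst[grown][shell]
        neighbor_ids = neighbor_ids[neighbor_ids > 0]
        if neighbor_ids.size == 0:
            log.warning("orphan component %d has no instance neighbors; left unassigned", comp)
            continue
        ids, counts = np.unique(neighbor_ids, return_counts=True)
        best = ids[counts == counts.max()].min()  # tie -> more superior id
        region = inst[grown]
        region[comp_mask] = best
        inst[grown] = region
    return MaskPair(pair.semantic, pair.instances.with_data(inst))


def remove_isolated_elements(
    mask: AnatomicalVolume, margin: int = ISOLATION_MARGIN
) -> AnatomicalVolume:
    """Delete components whose bounding boxes miss the main component's dilated box.

    The largest foreground component always survives; an empty mask is
    returned unchanged with a warning.
    """
    fg = mask.data != BACKGROUND
    if not fg.any():
        log.warning("remove_isolated_elements called on an empty mask")
        return mask.with_data(mask.data.copy())
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n == 1:
        return mask.with_data(mask.data.copy())
    sizes = ndimage.sum_labels(fg, labels, range(1, n + 1))
    main = int(np.argmax(sizes)) + 1
    objects = ndimage.find_objects(labels)
    main_box = tuple(
        (max(0, s.start - margin), min(dim, s.stop + margin))
        for s, dim in zip(objects[main - 1], mask.data.shape)
    )
    out = mask.data.copy()
    for comp in range(1, n + 1):
        if comp == main:
            continue
        box = objects[comp - 1]
        intersects = all(
            s.start < hi and s.stop > lo for s, (lo, hi) in zip(box, main_box)
        )
        if not intersects:
            out[labels == comp] = BACKGROUND
    return mask.with_data(out)


def relabel_articular_processes(pair: MaskPair) -> MaskPair:
    """Majority-vote the instance id within each articular-process component.

    For every 26-connected component of the four articular semantic labels,
    all its voxels take the component's majority instance id (ties toward
    the more superior id); components without any instance voxels are left
    untouched.
    """
    inst = pair.instances.data.copy()
    for code in _ARTICULAR_CODES:
        structure_mask = pair.semantic.data == code
        if not structure_mask.any():
            continue
        labels, n = ndimage.label(structure_mask, structure=_CONN26)
        objects = ndimage.find_objects(labels)
        for comp in range(1, n + 1):
            sl = objects[comp - 1]
            comp_mask = labels[sl] == comp
            ids = inst[sl][comp_mask]
            ids = ids[ids > 0]
            if ids.size == 0:
                continue
            uniq, counts = np.unique(ids, return_counts=True)
            best = uniq[counts == counts.max()].min()
            region = inst[sl]
            region[comp_mask] = best
            inst[sl] = region
    return MaskPair(pair.semantic, pair.instances.with_data(inst))


def apply_postprocessing(
    pair: MaskPair, skip: tuple[str, ...] = (), margin: int = ISOLATION_MARGIN
) -> MaskPair:
    """Apply the full rule chain in the fixed order, honoring ``skip``."""
    unknown = set(skip) - set(RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown post-processing rule(s): {sorted(unknown)}")
    if "remove_unsupported" not in skip:
        pair = remove_unsupported_instance_voxels(pair)
    if "rescue_components" not in skip:
        pair = rescue_missing_components(pair)
    if "remove_isolated" not in skip:
        semantic = remove_isolated_elements(pair.semantic, margin=margin)
        inst = pair.instances.data.copy()
        inst[semantic.data == BACKGROUND] = 0  # mirror deletions onto the instance mask
        pair = MaskPair(semantic, pair.instances.with_data(inst))
    if "relabel_articular" not in skip:
        pair = relabel_articular_processes(pair)
    return pair
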