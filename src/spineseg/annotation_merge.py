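"""Multi-source reference-annotation fusion used to build training labels.

Three automated annotation sources are combined on one grid with a strict
no-overwrite priority — base (corpus/IVD/canal/sacrum model) over
translation-derived substructures over the cord tool: when adding a source,
voxels already segmented as a different structure are excluded.  Afterwards
small gaps between corpus and IVD regions along the inferior axis are
filled and relabeled as endplates; endplate labels arise only here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_scheme import BACKGROUND, CODES
from .semantic_stage import validate_semantic_mask
from .volume_io import AnatomicalVolume

__all__ = ["AnnotationSource", "merge_annotations", "fill_corpus_ivd_gaps", "MAX_GAP"]

#: Widest corpus–IVD hole (voxels along the inferior axis) that is filled as
#: endplate; unbounded filling would bridge unrelated structures.
MAX_GAP = 2


@dataclass(frozen=True)
class AnnotationSource:
    """A semantic mask with its priority rank and provenance tag."""

    mask: AnatomicalVolume
    priority: int
    provenance: str  # "base" | "translated" | "cord"


def merge_annotations(
    base: AnatomicalVolume, translated: AnatomicalVolume, cord: AnatomicalVolume
) -> AnatomicalVolume:
    """Merge three congruent sources with priority base > translated > cord.

    A voxel labeled by a higher-priority source is never altered by a
    lower-priority one; lower sources write only onto accumulated
    background.
    """
    for src in (translated, cord):
        if not base.same_grid(src):
            raise ValueError("annotation sources must be congruent (resample to the base grid first)")
    for src in (base, translated, cord):
        validate_semantic_mask(src)
    out = base.data.copy()
    for src in (translated, cord):
        free = out == BACKGROUND
        out[free] = src.data[free]
    return base.with_data(out)


def fill_corpus_ivd_gaps(mask: AnatomicalVolume, max_gap: int = MAX_GAP) -> AnatomicalVolume:
    """Fill small corpus–IVD holes along the inferior axis as endplate.

    For every anterior-posterior x lateral column, any run of at most
    ``max_gap`` voxels strictly between a corpus voxel and an IVD voxel
    (containing neither label) is relabeled endplate, whether it is
    background or some other transition label.  Wider holes and columns
    without corpus–IVD adjacency are untouched; diagonal gaps are not
    considered.
    """
    corpus, ivd, endplate = CODES["corpus"], CODES["ivd"], CODES["endplate"]
    data = mask.data.copy()
    anchors = (data == corpus) | (data == ivd)
    if not anchors.any():
        return mask.with_data(data)
    xs, zs = np.nonzero(anchors.any(axis=1))
    for x, z in zip(xs, zs):
        column = data[x, :, z]
        pos = np.nonzero((column == corpus) | (column == ivd))[0]
        if pos.size < 2:
            continue
        for p, q in zip(pos[:-1], pos[1:]):
            gap = q - p - 1
            if 0 < gap <= max_gap and column[p] != column[q]:
                column[p + 1 : q] = endplate
    return mask.with_data(data)
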