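"""Phase 2: semantic mask → vertebra/disc instance mask.

Around the center of mass of every vertebral-body (corpus) connected
component, a fixed-geometry cutout is extracted from the semantic mask and
passed to a per-cutout predictor that labels the cutout's *center* vertebra
plus the one *above* and *below* it.  Each vertebra therefore appears in up
to three cutouts; the mean pairwise Dice across these appearances is its
consistency score, and vertebrae are written into the final mask from the
highest to the lowest score so the least consistent predictions are
addressed last and can never overwrite an established instance.  Discs and
endplates from the semantic mask are then given instance ids from the
nearest vertebra above.

All operations assume the canonical PIR orientation; connected components
use 26-connectivity throughout (thick-slice anisotropy makes 6-connectivity
fragment structures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .label_scheme import (
    BACKGROUND,
    CODES,
    DISC_OFFSET,
    ENDPLATE_OFFSET,
    MAX_VERTEBRAE,
    SCHEME,
)
from .volume_io import AnatomicalVolume

__all__ = [
    "REL_BACKGROUND",
    "REL_ABOVE",
    "REL_CENTER",
    "REL_BELOW",
    "CutoutConfig",
    "CorpusCenter",
    "Cutout",
    "CutoutPrediction",
    "Appearance",
    "AppearanceSet",
    "PredictorContractError",
    "InstancePredictor",
    "OracleInstancePredictor",
    "NoisyInstancePredictor",
    "find_corpus_centers",
    "extract_cutout",
    "predict_cutout",
    "collect_appearances",
    "consistency_score",
    "fuse_instances",
    "assign_disc_endplate_instances",
    "semantic_to_instances",
]

log = logging.getLogger(__name__)

# relative-label codes of a cutout prediction
REL_BACKGROUND = 0
REL_ABOVE = 1
REL_CENTER = 2
REL_BELOW = 3

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Vote weight of the center-role appearance; >1 so exact ties between the
#: cutout centered on a vertebra and a neighboring cutout resolve toward the
#: center prediction.
CENTER_ROLE_WEIGHT = 1.5


class PredictorContractError(ValueError):
    """A per-cutout predictor violated its input/output contract."""


@dataclass(frozen=True)
class CutoutConfig:
    """Fixed cutout geometry (defaults: 248 x 304 x 64 voxels at 0.75/0.75/1.65 mm, PIR)."""

    size: tuple[int, int, int] = (248, 304, 64)
    spacing: tuple[float, float, float] = (0.75, 0.75, 1.65)
    orientation: str = "PIR"

    def __post_init__(self) -> None:
        if len(self.size) != 3 or any(int(s) <= 0 for s in self.size):
            raise ValueError("cutout size must be three positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("cutout spacing must be three positive values")
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class CorpusCenter:
    """Center of mass of one corpus connected component, ranked top to bottom."""

    index: int
    voxel: tuple[int, int, int]
    component_id: int


@dataclass(frozen=True)
class Placement:
    """Diagonal map cutout index -> canonical continuous index: ``p = scale*c + offset``."""

    scale: tuple[float, float, float]
    offset: tuple[float, float, float]
    size: tuple[int, int, int]
    canonical_shape: tuple[int, int, int]

    def cutout_to_canonical(self, cutout_idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.scale) * np.asarray(cutout_idx, dtype=float) + np.asarray(self.offset)

    def canonical_to_cutout(self, canonical_idx: np.ndarray) -> np.ndarray:
        return (np.asarray(canonical_idx, dtype=float) - np.asarray(self.offset)) / np.asarray(self.scale)

    def sample_from_canonical(self, volume: np.ndarray, fill: int = 0) -> np.ndarray:
        """Nearest-neighbor sample of a canonical grid onto the cutout grid."""
        out = None
        idx, valid = [], []
        for a in range(3):
            pos = np.rint(self.scale[a] * np.arange(self.size[a]) + self.offset[a]).astype(int)
            ok = (pos >= 0) & (pos < volume.shape[a])
            idx.append(np.clip(pos, 0, volume.shape[a] - 1))
            valid.append(ok)
        out = volume[np.ix_(*idx)].copy()
        for a, ok in enumerate(valid):
            if not ok.all():
                sl = [slice(None)] * 3
                sl[a] = ~ok
                out[tuple(sl)] = fill
        return out

    def canonical_region(self) -> tuple[tuple[slice, slice, slice], list[np.ndarray]]:
        """Canonical voxel region covered by the cutout, with nearest cutout indices.

        A canonical voxel is covered when its nearest cutout grid position
        falls inside the window.
        """
        slices, cidx = [], []
        for a in range(3):
            lo = int(np.ceil(self.offset[a] - 0.5 * self.scale[a]))
            hi = int(np.floor(self.offset[a] + (self.size[a] - 0.5) * self.scale[a] - 1e-9)) + 1
            lo = max(lo, 0)
            hi = min(hi, self.canonical_shape[a])
            slices.append(slice(lo, max(lo, hi)))
            pos = np.rint((np.arange(lo, max(lo, hi)) - self.offset[a]) / self.scale[a]).astype(int)
            cidx.append(np.clip(pos, 0, self.size[a] - 1))
        return tuple(slices), cidx

    def backmap(self, relmap: np.ndarray, code: int) -> tuple[tuple[slice, slice, slice], np.ndarray]:
        """Map ``relmap == code`` back to the canonical grid (region slices + bool block)."""
        slices, cidx = self.canonical_region()
        block = relmap[np.ix_(*cidx)] == code
        return slices, block


@dataclass(frozen=True)
class Cutout:
    """A semantic cutout tied to one corpus center."""

    data: np.ndarray
    placement: Placement
    center: CorpusCenter


@dataclass(frozen=True)
class CutoutPrediction:
    """Relative-label map (above/center/below/background) for one cutout."""

    center_index: int
    relative: np.ndarray
    placement: Placement


@dataclass(frozen=True)
class Appearance:
    """One vertebra's mask contributed by one cutout, in the canonical grid."""

    cutout_index: int
    role: str  # "above" | "center" | "below"
    region: tuple[slice, slice, slice]
    block: np.ndarray  # bool, shaped like the region

    @property
    def weight(self) -> float:
        return CENTER_ROLE_WEIGHT if self.role == "center" else 1.0

    def voxel_count(self) -> int:
        return int(self.block.sum())


@dataclass
class AppearanceSet:
    """All appearances of one vertebra plus their mutual consistency score."""

    vertebra_index: int
    appearances: list[Appearance] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.appearances)


@runtime_checkable
class InstancePredictor(Protocol):
    """Per-cutout contract: semantic cutout in, relative-label map out."""

    def predict(self, cutout: Cutout) -> np.ndarray: ...


# --- operations --------------------------------------------------------------------


def find_corpus_centers(semantic: AnatomicalVolume) -> list[CorpusCenter]:
    """One center per 26-connected corpus component, sorted top to bottom."""
    corpus = semantic.data == CODES["corpus"]
    if not corpus.any():
        return []
    labels, n = ndimage.label(corpus, structure=_CONN26)
    coms = ndimage.center_of_mass(corpus, labels, range(1, n + 1))
    order = np.argsort([c[1] for c in coms], kind="stable")  # ascending inferior axis
    centers = []
    for rank, i in enumerate(order):
        voxel = tuple(int(round(c)) for c in coms[i])
        centers.append(CorpusCenter(index=rank, voxel=voxel, component_id=int(i) + 1))
    return centers


def extract_cutout(
    semantic: AnatomicalVolume, center: CorpusCenter, config: CutoutConfig
) -> Cutout:
    """Fixed-size, fixed-spacing cutout around a corpus center (background-padded)."""
    shape = semantic.shape
    if any(not (0 <= center.voxel[a] < shape[a]) for a in range(3)):
        raise ValueError(f"center {center.voxel} lies outside the volume {shape}")
    if semantic.orientation != config.orientation:
        raise ValueError(
            f"semantic mask orientation {semantic.orientation} does not match "
            f"cutout orientation {config.orientation}; reorient first"
        )
    scale = tuple(config.spacing[a] / semantic.spacing[a] for a in range(3))
    offset = tuple(center.voxel[a] - scale[a] * (config.size[a] - 1) / 2.0 for a in range(3))
    placement = Placement(scale=scale, offset=offset, size=config.size, canonical_shape=shape)
    data = placement.sample_from_canonical(semantic.data, fill=BACKGROUND)
    return Cutout(data=data, placement=placement, center=center)


def predict_cutout(cutout: Cutout, predictor: InstancePredictor) -> CutoutPrediction:
    """Run the predictor on one cutout and validate its output contract.

    The predictor consumes only the semantic cutout; handing it image data
    (non-integer or non-scheme values) is rejected up front.
    """
    if not np.issubdtype(cutout.data.dtype, np.integer):
        raise PredictorContractError(
            "predictor input must be a semantic (integer-coded) cutout, not image data"
        )
    values = set(int(v) for v in np.unique(cutout.data))
    if not values <= (SCHEME.all_codes | {BACKGROUND}):
        raise PredictorContractError("cutout contains values outside the semantic scheme")
    rel = np.asarray(predictor.predict(cutout))
    if rel.shape != tuple(cutout.placement.size):
        raise PredictorContractError(
            f"relative map shape {rel.shape} != cutout size {cutout.placement.size}"
        )
    out_values = set(int(v) for v in np.unique(rel))
    if not out_values <= {REL_BACKGROUND, REL_ABOVE, REL_CENTER, REL_BELOW}:
        raise PredictorContractError(
            f"predictor emitted labels outside {{background, above, center, below}}: "
            f"{sorted(out_values)}"
        )
    return CutoutPrediction(
        center_index=cutout.center.index, relative=rel, placement=cutout.placement
    )


def collect_appearances(
    predictions: Sequence[CutoutPrediction], centers: Sequence[CorpusCenter]
) -> list[AppearanceSet]:
    """Gather vertebra *k*'s appearances from cutouts k-1 (below), k (center), k+1 (above).

    Inner vertebrae collect three appearances and the outer ones two; empty
    roles simply reduce the count.
    """
    if len(predictions) != len(centers):
        raise ValueError("need exactly one prediction per corpus center")
    by_index = {p.center_index: p for p in predictions}
    n = len(centers)
    sets = []
    for k in range(n):
        aset = AppearanceSet(vertebra_index=k)
        for cutout_index, code, role in (
            (k - 1, REL_BELOW, "below"),
            (k, REL_CENTER, "center"),
            (k + 1, REL_ABOVE, "above"),
        ):
            pred = by_index.get(cutout_index)
            if pred is None:
                continue
            region, block = pred.placement.backmap(pred.relative, code)
            if not block.any():
                continue
            aset.appearances.append(
                Appearance(cutout_index=cutout_index, role=role, region=region, block=block)
            )
        sets.append(aset)
    return sets


def _pair_dice(a: Appearance, b: Appearance, shape: tuple[int, int, int]) -> float:
    # Dice over full canonical masks; blocks live on (possibly different) regions.
    na, nb = a.voxel_count(), b.voxel_count()
    if na + nb == 0:
        return 1.0
    lo = [max(a.region[i].start, b.region[i].start) for i in range(3)]
    hi = [min(a.region[i].stop, b.region[i].stop) for i in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        inter = 0
    else:
        sa = tuple(slice(lo[i] - a.region[i].start, hi[i] - a.region[i].start) for i in range(3))
        sb = tuple(slice(lo[i] - b.region[i].start, hi[i] - b.region[i].start) for i in range(3))
        inter = int((a.block[sa] & b.block[sb]).sum())
    return 2.0 * inter / (na + nb)


def consistency_score(aset: AppearanceSet, shape: tuple[int, int, int] | None = None) -> float:
    """Mean pairwise Dice over all unordered appearance pairs.

    A single appearance has no pair to corroborate it and scores 0.0 so that
    uncorroborated vertebrae integrate last.
    """
    if aset.count == 0:
        raise ValueError("empty appearance set has no consistency score")
    if aset.count == 1:
        return 0.0
    scores = []
    apps = aset.appearances
    for i in range(len(apps)):
        for j in range(i + 1, len(apps)):
            scores.append(_pair_dice(apps[i], apps[j], shape or ()))
    return float(np.mean(scores))


def fuse_instances(
    appearance_sets: Sequence[AppearanceSet], semantic: AnatomicalVolume
) -> AnatomicalVolume:
    """Integrate vertebrae into one instance mask from highest to lowest score.

    Each vertebra's voxels are the weighted per-voxel majority across its
    appearances (ties favor the center-role appearance, which carries weight
    :data:`CENTER_ROLE_WEIGHT`); a voxel once assigned is never overwritten
    by a later, lower-score instance.  Score ties break toward the more
    superior vertebra.  Output ids are renumbered 1..N top to bottom.
    """
    shape = semantic.shape
    out = np.zeros(shape, dtype=np.uint16)
    claimed = np.zeros(shape, dtype=bool)

    scored = []
    for aset in appearance_sets:
        if aset.count == 0:
            log.warning("vertebra %d has no non-empty appearances; skipped", aset.vertebra_index)
            continue
        scored.append((consistency_score(aset), aset))
    order = sorted(scored, key=lambda t: (-t[0], t[1].vertebra_index))

    written: list[int] = []
    for score, aset in order:
        votes = np.zeros(shape, dtype=np.float32)
        cover = np.zeros(shape, dtype=np.float32)
        for app in aset.appearances:
            votes[app.region] += app.weight * app.block
            cover[app.region] += app.weight
        sel = (votes > cover / 2.0) & ~claimed
        if not sel.any():
            log.warning("vertebra %d lost all voxels to higher-score instances", aset.vertebra_index)
            continue
        out[sel] = aset.vertebra_index + 1  # provisional id = rank + 1
        claimed |= sel
        written.append(aset.vertebra_index)

    # renumber to consecutive 1..N in top-to-bottom order
    remap = np.zeros(max(written, default=0) + 2, dtype=np.uint16)
    for new_id, rank in enumerate(sorted(written), start=1):
        remap[rank + 1] = new_id
    return semantic.with_data(remap[out])


def assign_disc_endplate_instances(
    semantic: AnatomicalVolume, instances: AnatomicalVolume
) -> AnatomicalVolume:
    """Give each IVD/endplate component the id derived from the nearest vertebra above.

    "Above" means the candidate corpus center of mass lies strictly superior
    (smaller inferior-axis coordinate) to the component's center of mass;
    distances compare in mm.  A component with no vertebra above falls back
    to the globally nearest vertebra with a logged warning.
    """
    if not semantic.same_grid(instances):
        raise ValueError("semantic and instance masks must share one grid")
    out = instances.data.copy()
    spacing = np.asarray(semantic.spacing)

    vids = [int(v) for v in np.unique(instances.data) if 0 < v <= MAX_VERTEBRAE]
    if not vids:
        if (semantic.data == CODES["ivd"]).any() or (semantic.data == CODES["endplate"]).any():
            log.warning("no vertebra instances; discs/endplates left unassigned")
        return instances.with_data(out)
    corpus = semantic.data == CODES["corpus"]
    centers = {}
    for v in vids:
        sel = (instances.data == v) & corpus
        if not sel.any():
            sel = instances.data == v
        centers[v] = np.asarray(ndimage.center_of_mass(sel)) * spacing

    for code, offset in ((CODES["ivd"], DISC_OFFSET), (CODES["endplate"], ENDPLATE_OFFSET)):
        structure_mask = semantic.data == code
        if not structure_mask.any():
            continue
        labels, n = ndimage.label(structure_mask, structure=_CONN26)
        coms = ndimage.center_of_mass(structure_mask, labels, range(1, n + 1))
        for comp, com in enumerate(coms, start=1):
            com_mm = np.asarray(com) * spacing
            above = [v for v in vids if centers[v][1] < com_mm[1]]
            if above:
                owner = min(above, key=lambda v: float(np.linalg.norm(centers[v] - com_mm)))
            else:
                owner = min(vids, key=lambda v: float(np.linalg.norm(centers[v] - com_mm)))
                log.warning(
                    "component of code %d has no vertebra above; assigned to nearest (id %d)",
                    code,
                    owner,
                )
            out[labels == comp] = owner + offset
    return instances.with_data(out)


@dataclass(frozen=True)
class InstanceResult:
    """Full phase-2 result with intermediates for inspection."""

    instances: AnatomicalVolume
    centers: list[CorpusCenter]
    appearance_sets: list[AppearanceSet]


def semantic_to_instances(
    semantic: AnatomicalVolume,
    predictor: InstancePredictor,
    config: CutoutConfig | None = None,
) -> InstanceResult:
    """Run the complete phase-2 conversion on a canonical-orientation semantic mask."""
    config = config or CutoutConfig()
    centers = find_corpus_centers(semantic)
    if not centers:
        log.warning("no corpus voxels found; reporting zero vertebrae")
        empty = semantic.with_data(np.zeros(semantic.shape, dtype=np.uint16))
        return InstanceResult(instances=empty, centers=[], appearance_sets=[])
    predictions = [
        predict_cutout(extract_cutout(semantic, c, config), predictor) for c in centers
    ]
    sets = collect_appearances(predictions, centers)
    vertebrae = fuse_instances(sets, semantic)
    full = assign_disc_endplate_instances(semantic, vertebrae)
    return InstanceResult(instances=full, centers=centers, appearance_sets=sets)


# --- phantom-backed predictors ------------------------------------------------------


class OracleInstancePredictor:
    """Perfect per-cutout predictor backed by a phantom's ground-truth instances.

    Emulates a trained relative-label network: for the cutout's center
    vertebra (identified from the ground truth at the corpus center) it
    emits the center/above/below classes exactly as the ground truth
    dictates, restricted to the cutout window.
    """

    def __init__(self, truth_instances: AnatomicalVolume):
        self.truth = truth_instances
        data = truth_instances.data
        vids = [int(v) for v in np.unique(data) if 0 < v <= MAX_VERTEBRAE]
        coms = {v: ndimage.center_of_mass(data == v) for v in vids}
        self.ordered = sorted(vids, key=lambda v: coms[v][1])

    def predict(self, cutout: Cutout) -> np.ndarray:
        gt = cutout.placement.sample_from_canonical(self.truth.data, fill=0)
        center_id = int(self.truth.data[cutout.center.voxel])
        if center_id not in self.ordered:
            # center voxel off the corpus (e.g. corrupted input): fall back to
            # the dominant vertebra id inside the window
            counts = [(int((gt == v).sum()), v) for v in self.ordered]
            counts.sort()
            if not counts or counts[-1][0] == 0:
                return np.zeros(cutout.placement.size, dtype=np.uint8)
            center_id = counts[-1][1]
        pos = self.ordered.index(center_id)
        rel = np.zeros(gt.shape, dtype=np.uint8)
        rel[gt == center_id] = REL_CENTER
        if pos > 0:
            rel[gt == self.ordered[pos - 1]] = REL_ABOVE
        if pos < len(self.ordered) - 1:
            rel[gt == self.ordered[pos + 1]] = REL_BELOW
        return rel


class NoisyInstancePredictor:
    """Oracle predictor plus deterministic relative-label noise.

    Noise stays within the cutout's labeled foreground — label swaps among
    above/center/below plus dropout to background — mirroring how a real
    instance model confuses neighboring vertebrae at their boundaries rather
    than hallucinating outside the semantic mask.  ``cutout_indices``
    optionally restricts corruption to specific cutouts.
    """

    def __init__(
        self,
        base: InstancePredictor,
        flip_rate: float = 0.05,
        drop_rate: float = 0.02,
        seed: int = 0,
        cutout_indices: set[int] | None = None,
    ):
        if not (0 <= flip_rate <= 1 and 0 <= drop_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        self.base = base
        self.flip_rate = flip_rate
        self.drop_rate = drop_rate
        self.seed = seed
        self.cutout_indices = cutout_indices

    def predict(self, cutout: Cutout) -> np.ndarray:
        rel = np.asarray(self.base.predict(cutout)).copy()
        if self.cutout_indices is not None and cutout.center.index not in self.cutout_indices:
            return rel
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, cutout.center.index])
        fg = rel != REL_BACKGROUND
        if self.flip_rate > 0:
            flip = fg & (rng.random(rel.shape) < self.flip_rate)
            shift = rng.integers(1, 3, size=rel.shape)  # +1 or +2 mod 3 among {1,2,3}
            rel[flip] = (rel[flip] - 1 + shift[flip]) % 3 + 1
        if self.drop_rate > 0:
            drop = fg & (rng.random(rel.shape) < self.drop_rate)
            rel[drop] = REL_BACKGROUND
        return rel
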