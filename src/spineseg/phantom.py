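"""Synthetic whole-spine phantoms with ground-truth semantic and instance masks.

The phantom emulates a sagittal whole-spine label map: a column of
vertebra-like bodies stacked along the inferior axis, each with a corpus and
eight posterior-element substructures, interleaved discs and endplates, a
continuous spinal canal/cord channel posterior to the corpus column, and a
sacrum block at the bottom.  Shapes are axis-aligned boxes — sufficient to
exercise connectivity, ordering and fusion logic while staying fully
deterministic.  The default spacing (0.8, 0.8, 3.3) mm mimics thick-slice
sagittal acquisitions (in-plane resolution much finer than slice thickness).

Conventions
-----------
* Grid orientation is canonical PIR: axis 0 posterior, axis 1 inferior
  (so the topmost vertebra has the smallest axis-1 index), axis 2 right.
* Vertebra instance ids run 1..N top to bottom; a fused pair shares one id
  and ids stay consecutive.  The disc below vertebra *k* gets the disc id
  derived from *k*; both endplate slabs flanking that disc belong to *k*
  (the nearest vertebra above their centers).
* ``fused_pairs`` uses 1-based vertebra indices, e.g. ``(2, 3)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .label_scheme import (
    BACKGROUND,
    CODES,
    SCHEME,
    disc_id,
    endplate_id,
)
from .volume_io import AnatomicalVolume, canonical_affine

__all__ = ["PhantomSpec", "Phantom", "CorruptionSpec", "generate_phantom", "corrupt_mask"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and randomness of one synthetic spine.

    All physical sizes are in mm and converted to voxels with the given
    spacing; the inferior-axis layout per vertebra is
    ``corpus | endplate | disc | endplate | next corpus``.
    """

    n_vertebrae: int = 8
    spacing: tuple[float, float, float] = (0.8, 0.8, 3.3)
    corpus_depth_mm: float = 17.6
    corpus_height_mm: float = 11.2
    disc_thickness_mm: float = 3.2
    endplate_thickness_mm: float = 0.8
    n_slices: int = 14
    fused_pairs: tuple[tuple[int, int], ...] = ()
    missing_outer_slices: int = 0
    size_jitter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if self.disc_thickness_mm <= 0 or self.endplate_thickness_mm <= 0:
            raise ValueError("disc and endplate thickness must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.n_slices < 8:
            raise ValueError("phantom needs at least 8 lateral slices")
        if self.missing_outer_slices < 0 or 2 * self.missing_outer_slices >= self.n_slices:
            raise ValueError("missing_outer_slices would remove the whole volume")
        for a, b in self.fused_pairs:
            if not (1 <= a < b <= self.n_vertebrae and b == a + 1):
                raise ValueError(f"fused pair {(a, b)} must reference valid adjacent vertebrae")


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: pseudo-image plus ground-truth mask pair."""

    image: AnatomicalVolume
    semantic: AnatomicalVolume
    instances: AnatomicalVolume
    spec: PhantomSpec
    #: final instance id for each original vertebra index (1-based, after fusion)
    vertebra_ids: tuple[int, ...] = ()

    @property
    def n_instances(self) -> int:
        return max(self.vertebra_ids) if self.vertebra_ids else 0


def _final_ids(spec: PhantomSpec) -> list[int]:
    """Map original 1-based vertebra index -> final instance id after fusion."""
    parent = list(range(spec.n_vertebrae + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in spec.fused_pairs:
        ra, rb = find(a), find(b)
        parent[max(ra, rb)] = min(ra, rb)
    roots = [find(i) for i in range(1, spec.n_vertebrae + 1)]
    order = sorted(set(roots))
    rank = {r: i + 1 for i, r in enumerate(order)}
    return [rank[r] for r in roots]


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build (image, semantic mask, instance mask) for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    dx, dy, dz = spec.spacing

    h_c = max(6, round(spec.corpus_height_mm / dy))
    h_d = max(1, round(spec.disc_thickness_mm / dy))
    e = max(1, round(spec.endplate_thickness_mm / dy))
    d_c = max(8, round(spec.corpus_depth_mm / dx))

    n = spec.n_vertebrae
    jit = rng.integers(-1, 2, size=n) if spec.size_jitter else np.zeros(n, dtype=int)
    heights = np.maximum(6, h_c + jit)
    depth_jit = rng.integers(-2, 1, size=n) if spec.size_jitter else np.zeros(n, dtype=int)
    depths = np.maximum(8, d_c + depth_jit)

    fused_after = {a for a, _ in spec.fused_pairs}  # no disc below vertebra a

    margin = 4
    sacrum_gap, sacrum_h = 2, 12
    # vertical layout
    corpus_rows: list[tuple[int, int]] = []
    disc_rows: list[tuple[int, int, int]] = []  # (y0, y1, owner original index)
    plate_rows: list[tuple[int, int, int]] = []
    y = margin
    for k in range(1, n + 1):
        y1 = y + int(heights[k - 1])
        corpus_rows.append((y, y1))
        y = y1
        if k < n:
            if k in fused_after:
                continue  # corpora fused: next corpus continues directly
            plate_rows.append((y, y + e, k))
            y += e
            disc_rows.append((y, y + h_d, k))
            y += h_d
            plate_rows.append((y, y + e, k))
            y += e
    column_end = y
    sac0 = column_end + sacrum_gap
    sac1 = sac0 + sacrum_h
    ny = sac1 + margin

    # anterior-posterior layout (axis 0): canal face fixed so the foreground
    # stays one connected component regardless of per-vertebra depth jitter
    canal0, canal1 = 25, 31
    cord0, cord1 = 27, 29
    arcus0, arcus1 = 31, 37
    spin0, spin1 = 37, 49
    nx = spin1 + 3

    # lateral layout (axis 2)
    nz = spec.n_slices
    w_c = min(nz - 4, max(5, round(30.0 / dz)))
    s0 = (nz - w_c) // 2
    s1 = s0 + w_c
    canal_s0, canal_s1 = s0 + (w_c - 4) // 2, s0 + (w_c - 4) // 2 + 4
    cord_s0, cord_s1 = canal_s0 + 1, canal_s1 - 1
    art_left = (canal_s0 - 2, canal_s0)
    art_right = (canal_s1, canal_s1 + 2)
    cost_left = (max(0, s0 - 2), s0)
    cost_right = (s1, min(nz, s1 + 2))

    sem = np.zeros((nx, ny, nz), dtype=np.uint8)
    inst = np.zeros((nx, ny, nz), dtype=np.uint16)
    ids = _final_ids(spec)

    # canal + cord channel, continuous from first corpus to sacrum end
    sem[canal0:canal1, margin:sac1, canal_s0:canal_s1] = CODES["spinal_canal"]
    sem[cord0:cord1, margin:sac1, cord_s0:cord_s1] = CODES["spinal_cord"]

    for k in range(1, n + 1):
        y0, y1 = corpus_rows[k - 1]
        d = int(depths[k - 1])
        vid = ids[k - 1]
        sem[canal0 - d : canal0, y0:y1, s0:s1] = CODES["corpus"]
        inst[canal0 - d : canal0, y0:y1, s0:s1] = vid
        # arcus behind the canal over the corpus rows
        sem[arcus0:arcus1, y0:y1, canal_s0:canal_s1] = CODES["arcus"]
        inst[arcus0:arcus1, y0:y1, canal_s0:canal_s1] = vid
        # spinous process, central band of the vertebra
        sy0, sy1 = y0 + 4, max(y0 + 5, y1 - 4)
        sem[spin0:spin1, sy0:sy1, cord_s0:cord_s1] = CODES["spinous_process"]
        inst[spin0:spin1, sy0:sy1, cord_s0:cord_s1] = vid
        # articular processes: superior at the top rows, inferior at the bottom
        for code, (z0, z1), (ay0, ay1) in (
            (CODES["articular_superior_left"], art_left, (y0, y0 + 3)),
            (CODES["articular_superior_right"], art_right, (y0, y0 + 3)),
            (CODES["articular_inferior_left"], art_left, (y1 - 3, y1)),
            (CODES["articular_inferior_right"], art_right, (y1 - 3, y1)),
        ):
            sem[arcus0:arcus1, ay0:ay1, z0:z1] = code
            inst[arcus0:arcus1, ay0:ay1, z0:z1] = vid
        # costal processes: lateral wings beside the corpus
        cy0, cy1 = y0 + 3, max(y0 + 4, y1 - 3)
        for code, (z0, z1) in (
            (CODES["costal_process_left"], cost_left),
            (CODES["costal_process_right"], cost_right),
        ):
            sem[canal0 - d : canal0 - d + 8, cy0:cy1, z0:z1] = code
            inst[canal0 - d : canal0 - d + 8, cy0:cy1, z0:z1] = vid

    corpus_face = canal0 - int(np.min(depths))
    for y0, y1, owner in disc_rows:
        sem[corpus_face:canal0, y0:y1, s0:s1] = CODES["ivd"]
        inst[corpus_face:canal0, y0:y1, s0:s1] = disc_id(ids[owner - 1])
    for y0, y1, owner in plate_rows:
        sem[corpus_face:canal0, y0:y1, s0:s1] = CODES["endplate"]
        inst[corpus_face:canal0, y0:y1, s0:s1] = endplate_id(ids[owner - 1])

    sem[canal0 - d_c : canal0, sac0:sac1, s0:s1] = CODES["sacrum"]

    if spec.missing_outer_slices:
        m = spec.missing_outer_slices
        sem[:, :, :m] = BACKGROUND
        sem[:, :, nz - m :] = BACKGROUND
        inst[:, :, :m] = 0
        inst[:, :, nz - m :] = 0

    # pseudo-image: structure-dependent intensity plus smoothed noise
    intensity = np.array([20.0] + [60.0 + 12.0 * c for c in range(1, 15)], dtype=np.float32)
    img = intensity[sem] + rng.normal(0.0, 8.0, size=sem.shape).astype(np.float32)
    img = ndimage.gaussian_filter(img, sigma=(0.7, 0.7, 0.3))

    affine = canonical_affine(spec.spacing)
    return Phantom(
        image=AnatomicalVolume(img, affine),
        semantic=AnatomicalVolume(sem, affine),
        instances=AnatomicalVolume(inst, affine),
        spec=spec,
        vertebra_ids=tuple(ids),
    )


# --- mask corruption ---------------------------------------------------------------


@dataclass(frozen=True)
class CorruptionSpec:
    """Noise model emulating segmentation-model errors.

    flip_rate
        Per-voxel probability that a foreground voxel is dropped to
        background (emulates missed voxels, e.g. at outermost slices).
    boundary_jitter
        Per-voxel probability that a surface voxel takes the value of a
        random 6-neighbor (emulates ragged label boundaries).
    drop_components
        Label values removed entirely from the mask.
    """

    flip_rate: float = 0.0
    boundary_jitter: float = 0.0
    drop_components: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for r in (self.flip_rate, self.boundary_jitter):
            if not 0.0 <= r <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")


def _as_corruption(noise: CorruptionSpec | Mapping) -> CorruptionSpec:
    if isinstance(noise, CorruptionSpec):
        return noise
    return CorruptionSpec(
        flip_rate=float(noise.get("flip_rate", 0.0)),
        boundary_jitter=float(noise.get("boundary_jitter", 0.0)),
        drop_components=tuple(noise.get("drop_components", ())),
    )


_FACE_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def corrupt_mask(
    mask: AnatomicalVolume, noise: CorruptionSpec | Mapping, seed: int
) -> AnatomicalVolume:
    """Deterministically corrupt a label map; all rates zero is the identity."""
    spec = _as_corruption(noise)
    rng = np.random.default_rng(seed)
    data = mask.data.copy()

    for label in spec.drop_components:
        data[data == label] = BACKGROUND

    if spec.boundary_jitter > 0:
        fg = data != BACKGROUND
        eroded = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(3, 1))
        surface = fg & ~eroded
        coords = np.argwhere(surface)
        if coords.size:
            hit = rng.random(len(coords)) < spec.boundary_jitter
            pick = rng.integers(0, 6, size=len(coords))
            src = data.copy()
            for i in np.nonzero(hit)[0]:
                x, y, z = coords[i]
                sx, sy, sz = _FACE_SHIFTS[pick[i]]
                nx_, ny_, nz_ = x + sx, y + sy, z + sz
                if 0 <= nx_ < data.shape[0] and 0 <= ny_ < data.shape[1] and 0 <= nz_ < data.shape[2]:
                    data[x, y, z] = src[nx_, ny_, nz_]

    if spec.flip_rate > 0:
        fg = data != BACKGROUND
        drop = fg & (rng.random(data.shape) < spec.flip_rate)
        data[drop] = BACKGROUND

    return mask.with_data(data)


def write_phantom(phantom: Phantom, out_dir: str | Path, stem: str = "phantom") -> dict[str, Path]:
    """Write image/semantic/instance NIfTI triplet plus the spec as JSON."""
    from .volume_io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": write_volume(phantom.image, out / f"{stem}_image.nii.gz"),
        "semantic": write_volume(phantom.semantic, out / f"{stem}_semantic.nii.gz"),
        "instances": write_volume(phantom.instances, out / f"{stem}_instances.nii.gz"),
    }
    spec_dict = asdict(phantom.spec)
    spec_dict["fused_pairs"] = [list(p) for p in phantom.spec.fused_pairs]
    (out / f"{stem}_spec.json").write_text(json.dumps(spec_dict, indent=2) + "\n")
    paths["spec"] = out / f"{stem}_spec.json"
    return paths
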