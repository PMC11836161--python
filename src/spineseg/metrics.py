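"""Evaluation suite: overlap and surface metrics, instance matching, panoptic scores.

Conventions
-----------
* Dice of two empty masks is 1.0; of one empty mask 0.0.
* ASSD requires two nonempty masks; otherwise it is a missing value (NaN).
  Surface voxels are foreground voxels with at least one 6-connected
  background neighbor (volume borders count as background).
* Instance matching is greedy one-to-one by descending IoU among pairs with
  IoU >= 0.5 (inclusive); at that threshold matches are provably unique, so
  the greedy order cannot change the result.
* RQ = TP / (TP + FP/2 + FN/2); SQ = mean IoU over matched pairs; PQ = RQ*SQ.
* Missing structures yield NaN and are excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy import stats

from .label_scheme import (
    BACKGROUND,
    DISC_OFFSET,
    ENDPLATE_OFFSET,
    GROUP_CODES,
    MAX_VERTEBRAE,
    SCHEME,
    is_disc_id,
    is_endplate_id,
    is_vertebra_id,
)
from .postprocess import MaskPair
from .volume_io import AnatomicalVolume

__all__ = [
    "dice",
    "iou",
    "assd",
    "surface_voxels",
    "MatchTable",
    "match_instances",
    "panoptic_scores",
    "derive_semantic_from_instances",
    "semantic_to_groups",
    "EvaluationReport",
    "evaluate_subject",
    "SignedRankResult",
    "paired_signed_rank",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)

_INSTANCE_GROUPS = {
    "vertebra": is_vertebra_id,
    "ivd": is_disc_id,
    "endplate": is_endplate_id,
}


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, AnatomicalVolume) else np.asarray(mask)
    return data.astype(bool)


def _check_congruent(a, b) -> None:
    if isinstance(a, AnatomicalVolume) and isinstance(b, AnatomicalVolume):
        if not a.same_grid(b):
            raise ValueError("masks must be congruent (same shape and affine)")
    else:
        da = a.data if isinstance(a, AnatomicalVolume) else np.asarray(a)
        db = b.data if isinstance(b, AnatomicalVolume) else np.asarray(b)
        if da.shape != db.shape:
            raise ValueError(f"mask shapes differ: {da.shape} vs {db.shape}")


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 when both empty."""
    _check_congruent(a, b)
    a, b = _as_bool(a), _as_bool(b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def iou(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    _check_congruent(a, b)
    a, b = _as_bool(a), _as_bool(b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def surface_voxels(mask) -> np.ndarray:
    """Foreground voxels with >= 1 six-connected background neighbor (bool array)."""
    fg = _as_bool(mask)
    eroded = ndimage.binary_erosion(fg, structure=_CONN6, border_value=0)
    return fg & ~eroded


def assd(a, b, spacing=None) -> float:
    """Average symmetric surface distance in mm (spacing-aware).

    Mean over both surface voxel sets of each surface voxel's Euclidean
    distance to the other surface; 0 for identical masks.  Undefined (NaN)
    when either mask is empty.
    """
    _check_congruent(a, b)
    if spacing is None:
        if isinstance(a, AnatomicalVolume):
            spacing = a.spacing
        else:
            spacing = (1.0, 1.0, 1.0)
    spacing = np.asarray(spacing, dtype=float)
    fa, fb = _as_bool(a), _as_bool(b)
    if not fa.any() or not fb.any():
        return float("nan")
    sa = np.argwhere(surface_voxels(fa)) * spacing
    sb = np.argwhere(surface_voxels(fb)) * spacing
    d_ab, _ = cKDTree(sb).query(sa, k=1)
    d_ba, _ = cKDTree(sa).query(sb, k=1)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


@dataclass(frozen=True)
class MatchTable:
    """Greedy one-to-one instance matching result at a fixed IoU threshold."""

    pairs: tuple[tuple[int, int, float], ...]  # (pred id, ref id, IoU)
    unmatched_pred: tuple[int, ...]
    unmatched_ref: tuple[int, ...]
    iou_threshold: float = 0.5

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_ref)

    @property
    def matched_ious(self) -> tuple[float, ...]:
        return tuple(p[2] for p in self.pairs)


def match_instances(pred, ref, iou_threshold: float = 0.5) -> MatchTable:
    """Match predicted to reference instances greedily by descending IoU.

    Pairs with IoU >= ``iou_threshold`` (inclusive, default 0.5) are
    candidate true positives; leftovers become FP (pred) / FN (ref).  The
    result is invariant under relabeling of the instance ids.
    """
    _check_congruent(pred, ref)
    p = (pred.data if isinstance(pred, AnatomicalVolume) else np.asarray(pred)).astype(np.int64)
    r = (ref.data if isinstance(ref, AnatomicalVolume) else np.asarray(ref)).astype(np.int64)
    pred_ids, pred_sizes = np.unique(p[p > 0], return_counts=True)
    ref_ids, ref_sizes = np.unique(r[r > 0], return_counts=True)
    size_p = dict(zip(pred_ids.tolist(), pred_sizes.tolist()))
    size_r = dict(zip(ref_ids.tolist(), ref_sizes.tolist()))

    both = (p > 0) & (r > 0)
    candidates = []
    if both.any():
        combo = p[both] * (r.max() + 1) + r[both]
        combo_ids, inter = np.unique(combo, return_counts=True)
        for cid, ov in zip(combo_ids.tolist(), inter.tolist()):
            pi, ri = divmod(cid, int(r.max() + 1))
            union = size_p[pi] + size_r[ri] - ov
            score = ov / union
            if score >= iou_threshold:
                candidates.append((score, pi, ri))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_p: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for score, pi, ri in candidates:
        if pi in used_p or ri in used_r:
            continue
        pairs.append((pi, ri, score))
        used_p.add(pi)
        used_r.add(ri)
    return MatchTable(
        pairs=tuple(pairs),
        unmatched_pred=tuple(int(i) for i in pred_ids if int(i) not in used_p),
        unmatched_ref=tuple(int(i) for i in ref_ids if int(i) not in used_r),
        iou_threshold=iou_threshold,
    )


def panoptic_scores(table: MatchTable) -> tuple[float, float, float]:
    """(RQ, SQ, PQ); all NaN when the table holds no instances at all."""
    tp, fp, fn = table.tp, table.fp, table.fn
    if tp + fp + fn == 0:
        return (float("nan"),) * 3
    rq = tp / (tp + fp / 2.0 + fn / 2.0)
    sq = float(np.mean(table.matched_ious)) if tp else 0.0
    return rq, sq, rq * sq


def derive_semantic_from_instances(instances: AnatomicalVolume) -> AnatomicalVolume:
    """Collapse instance ids to anatomic-group codes (all vertebrae one label)."""
    data = instances.data
    out = np.zeros(data.shape, dtype=np.uint8)
    for i in (int(v) for v in np.unique(data) if v != 0):
        if is_vertebra_id(i):
            out[data == i] = GROUP_CODES["vertebra"]
        elif is_disc_id(i):
            out[data == i] = GROUP_CODES["ivd"]
        elif is_endplate_id(i):
            out[data == i] = GROUP_CODES["endplate"]
        else:
            raise ValueError(f"instance id {i} outside all known ranges")
    return instances.with_data(out)


def semantic_to_groups(semantic: AnatomicalVolume) -> AnatomicalVolume:
    """Map semantic structure codes to anatomic-group codes."""
    lut = np.zeros(max(SCHEME.all_codes) + 1, dtype=np.uint8)
    for name, code in SCHEME.codes.items():
        lut[code] = GROUP_CODES[SCHEME.groups[name]]
    data = semantic.data
    if data.max(initial=0) >= len(lut) or data.min(initial=0) < 0:
        raise ValueError("semantic mask contains codes outside the scheme")
    return semantic.with_data(lut[data.astype(np.int64)])


def _group_instance_submask(instances: np.ndarray, group: str) -> np.ndarray:
    pred = _INSTANCE_GROUPS[group]
    out = np.zeros_like(instances)
    for i in (int(v) for v in np.unique(instances) if v != 0):
        if pred(i):
            out[instances == i] = i
    return out


@dataclass
class EvaluationReport:
    """Per-structure and per-instance-group metric tables for one subject."""

    structures: pd.DataFrame  # columns: group, dsc, assd
    instances: pd.DataFrame  # columns: group, dsc, rq, sq, pq, assd, tp, fp, fn

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("dsc", "assd"):
            vals = self.structures[name].dropna()
            out[f"structure_{name}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        for name in ("dsc", "rq", "sq", "pq", "assd"):
            vals = self.instances[name].dropna()
            out[f"instance_{name}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        return out


def evaluate_subject(pred: MaskPair, ref: MaskPair) -> EvaluationReport:
    """Structure-wise DSC/ASSD per anatomic group plus instance-wise panoptic metrics.

    Structure rows cover each anatomic group present in either mask (groups
    absent from both are missing and excluded).  Instance rows cover the
    vertebra, IVD and endplate id ranges: DSC and ASSD average over matched
    pairs only; RQ/SQ/PQ come from greedy matching at IoU >= 0.5.
    """
    if not pred.semantic.same_grid(ref.semantic):
        raise ValueError("prediction and reference must be congruent")
    spacing = ref.semantic.spacing

    pg = semantic_to_groups(pred.semantic).data
    rg = semantic_to_groups(ref.semantic).data
    rows = []
    for group, code in GROUP_CODES.items():
        a, b = pg == code, rg == code
        if not a.any() and not b.any():
            continue
        rows.append(
            {"group": group, "dsc": dice(a, b), "assd": assd(a, b, spacing)}
        )
    structures = pd.DataFrame(rows, columns=["group", "dsc", "assd"])

    inst_rows = []
    p_inst = pred.instances.data
    r_inst = ref.instances.data
    for group in _INSTANCE_GROUPS:
        sub_p = _group_instance_submask(p_inst, group)
        sub_r = _group_instance_submask(r_inst, group)
        if not sub_p.any() and not sub_r.any():
            continue
        table = match_instances(sub_p, sub_r)
        rq, sq, pq = panoptic_scores(table)
        pair_dscs = [dice(sub_p == pi, sub_r == ri) for pi, ri, _ in table.pairs]
        pair_assds = [assd(sub_p == pi, sub_r == ri, spacing) for pi, ri, _ in table.pairs]
        inst_rows.append(
            {
                "group": group,
                "dsc": float(np.mean(pair_dscs)) if pair_dscs else float("nan"),
                "rq": rq,
                "sq": sq,
                "pq": pq,
                "assd": float(np.mean(pair_assds)) if pair_assds else float("nan"),
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
            }
        )
    instances = pd.DataFrame(
        inst_rows, columns=["group", "dsc", "rq", "sq", "pq", "assd", "tp", "fp", "fn"]
    )
    return EvaluationReport(structures=structures, instances=instances)


@dataclass(frozen=True)
class SignedRankResult:
    p_value: float
    significant: bool
    alpha: float = 0.05


def paired_signed_rank(scores_a, scores_b, alpha: float = 0.05) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired per-subject scores.

    All-zero differences are degenerate and reported as p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(a == b):
        return SignedRankResult(p_value=1.0, significant=False, alpha=alpha)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return SignedRankResult(p_value=p, significant=p < alpha, alpha=alpha)
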