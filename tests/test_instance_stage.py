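import numpy as np
import pytest
from scipy import ndimage

from spineseg import instance_stage as inst
from spineseg.instance_stage import (
    Appearance,
    AppearanceSet,
    CorpusCenter,
    CutoutConfig,
    NoisyInstancePredictor,
    OracleInstancePredictor,
    PredictorContractError,
    assign_disc_endplate_instances,
    collect_appearances,
    consistency_score,
    extract_cutout,
    find_corpus_centers,
    fuse_instances,
    predict_cutout,
    semantic_to_instances,
)
from spineseg.label_scheme import CODES, disc_id, endplate_id
from spineseg.phantom import PhantomSpec, generate_phantom
from spineseg.volume_io import AnatomicalVolume, canonical_affine


class TestFindCorpusCenters:
    def test_counts_and_top_to_bottom_order(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        assert len(centers) == 5
        rows = [c.voxel[1] for c in centers]
        assert rows == sorted(rows)
        # ranks match the ground-truth instance centroid order
        gt_rows = [
            ndimage.center_of_mass(phantom5.instances.data == v)[1] for v in (1, 2, 3, 4, 5)
        ]
        for c, gt in zip(centers, gt_rows):
            assert phantom5.instances.data[c.voxel] == centers.index(c) + 1
            assert abs(c.voxel[1] - gt) < 12

    def test_empty_semantic_yields_empty_list(self, phantom5):
        empty = phantom5.semantic.with_data(np.zeros_like(phantom5.semantic.data))
        assert find_corpus_centers(empty) == []

    def test_fused_pair_yields_one_fewer_center(self):
        ph = generate_phantom(PhantomSpec(n_vertebrae=5, fused_pairs=((2, 3),), seed=0))
        assert len(find_corpus_centers(ph.semantic)) == 4


class TestExtractCutout:
    def test_fixed_output_shape(self, phantom5):
        center = find_corpus_centers(phantom5.semantic)[0]
        cut = extract_cutout(phantom5.semantic, center, CutoutConfig())
        assert cut.data.shape == (248, 304, 64)

    def test_border_region_padded_with_background(self, phantom5):
        # topmost center: the window extends far above the volume
        center = find_corpus_centers(phantom5.semantic)[0]
        cut = extract_cutout(phantom5.semantic, center, CutoutConfig())
        assert not cut.data[:, :40, :].any()

    def test_placement_round_trip_within_one_voxel(self, phantom5):
        center = find_corpus_centers(phantom5.semantic)[2]
        cut = extract_cutout(phantom5.semantic, center, CutoutConfig())
        marker = np.array(center.voxel)
        c = np.rint(cut.placement.canonical_to_cutout(marker))
        back = np.rint(cut.placement.cutout_to_canonical(c))
        assert np.all(np.abs(back - marker) <= 1)

    def test_center_outside_volume_rejected(self, phantom5):
        bad = CorpusCenter(index=0, voxel=(0, 10_000, 0), component_id=1)
        with pytest.raises(ValueError):
            extract_cutout(phantom5.semantic, bad, CutoutConfig())


class TestPredictCutout:
    def test_oracle_matches_windowed_ground_truth(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        predictor = OracleInstancePredictor(phantom5.instances)
        k = 2
        cut = extract_cutout(phantom5.semantic, centers[k], CutoutConfig())
        pred = predict_cutout(cut, predictor)
        gt_window = cut.placement.sample_from_canonical(phantom5.instances.data, fill=0)
        expected = np.zeros_like(gt_window, dtype=np.uint8)
        expected[gt_window == k] = inst.REL_ABOVE
        expected[gt_window == k + 1] = inst.REL_CENTER
        expected[gt_window == k + 2] = inst.REL_BELOW
        assert np.array_equal(pred.relative, expected)

    def test_topmost_cutout_has_empty_above_class(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        predictor = OracleInstancePredictor(phantom5.instances)
        cut = extract_cutout(phantom5.semantic, centers[0], CutoutConfig())
        pred = predict_cutout(cut, predictor)
        assert not (pred.relative == inst.REL_ABOVE).any()
        assert (pred.relative == inst.REL_CENTER).any()

    def test_image_cutout_rejected_by_contract(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        cut = extract_cutout(phantom5.semantic, centers[0], CutoutConfig())
        image_cut = inst.Cutout(
            data=cut.placement.sample_from_canonical(phantom5.image.data.astype(np.float32)),
            placement=cut.placement,
            center=cut.center,
        )
        with pytest.raises(PredictorContractError):
            predict_cutout(image_cut, OracleInstancePredictor(phantom5.instances))

    def test_predictor_emitting_other_labels_rejected(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        cut = extract_cutout(phantom5.semantic, centers[0], CutoutConfig())

        class BadPredictor:
            def predict(self, cutout):
                return np.full(cutout.placement.size, 7, dtype=np.uint8)

        with pytest.raises(PredictorContractError):
            predict_cutout(cut, BadPredictor())


class TestCollectAppearances:
    def test_inner_three_outer_two(self, phantom5_result):
        assert [s.count for s in phantom5_result.appearance_sets] == [2, 3, 3, 3, 2]

    def test_single_vertebra_single_appearance(self):
        ph = generate_phantom(PhantomSpec(n_vertebrae=1, seed=2))
        res = semantic_to_instances(ph.semantic, OracleInstancePredictor(ph.instances))
        assert [s.count for s in res.appearance_sets] == [1]

    def test_empty_role_reduces_count(self, phantom5):
        centers = find_corpus_centers(phantom5.semantic)
        predictor = OracleInstancePredictor(phantom5.instances)
        preds = [
            predict_cutout(extract_cutout(phantom5.semantic, c, CutoutConfig()), predictor)
            for c in centers
        ]
        # blank the "below" class of cutout 1: vertebra 2 (index 2) loses one appearance
        rel = preds[1].relative.copy()
        rel[rel == inst.REL_BELOW] = 0
        preds[1] = inst.CutoutPrediction(1, rel, preds[1].placement)
        sets = collect_appearances(preds, centers)
        assert [s.count for s in sets] == [2, 3, 2, 3, 2]


def _appearance(shape, coords, role="center", cutout_index=0):
    block = np.zeros(shape, dtype=bool)
    for c in coords:
        block[c] = True
    region = tuple(slice(0, s) for s in shape)
    return Appearance(cutout_index=cutout_index, role=role, region=region, block=block)


class TestConsistencyScore:
    def test_identical_appearances_score_one(self):
        shape = (4, 4, 4)
        coords = [(1, 1, 1), (2, 2, 2)]
        aset = AppearanceSet(0, [_appearance(shape, coords, r, i) for i, r in enumerate(["below", "center", "above"])])
        assert consistency_score(aset) == 1.0

    def test_half_overlap_scores_half(self):
        # 8 voxels each, overlapping in 4: Dice = 2*4/16 = 0.5
        shape = (4, 4, 4)
        a = [(0, 0, z) for z in range(4)] + [(1, 0, z) for z in range(4)]
        b = [(1, 0, z) for z in range(4)] + [(2, 0, z) for z in range(4)]
        aset = AppearanceSet(
            0, [_appearance(shape, a, "center", 0), _appearance(shape, b, "below", 1)]
        )
        assert consistency_score(aset) == pytest.approx(0.5)

    def test_single_appearance_scores_zero(self):
        aset = AppearanceSet(0, [_appearance((3, 3, 3), [(1, 1, 1)])])
        assert consistency_score(aset) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            consistency_score(AppearanceSet(0, []))


class TestFuseInstances:
    def test_oracle_recovery_is_exact(self, phantom5, phantom5_result):
        assert np.array_equal(phantom5_result.instances.data, phantom5.instances.data)

    def test_low_score_appearance_cannot_steal_claimed_voxels(self):
        shape = (3, 30, 3)
        sem = AnatomicalVolume(np.zeros(shape, dtype=np.uint8), canonical_affine((1, 1, 1)))
        top = [(x, y, z) for x in range(3) for y in range(2, 12) for z in range(3)]
        overlap = [(x, y, z) for x in range(3) for y in range(10, 12) for z in range(3)][:10]
        lower_only = [(x, y, z) for x in range(3) for y in range(12, 20) for z in range(3)]
        set_a = AppearanceSet(
            0,
            [
                _appearance(shape, top, "center", 0),
                _appearance(shape, top, "above", 1),
            ],
        )  # score 1.0
        set_b = AppearanceSet(
            1,
            [
                _appearance(shape, lower_only + overlap, "center", 1),
                _appearance(shape, lower_only, "below", 0),
            ],
        )  # score < 1.0
        out = fuse_instances([set_a, set_b], sem).data
        for c in overlap:
            assert out[c] == 1  # high-score instance keeps contested voxels
        for c in lower_only:
            assert out[c] == 2

    def test_single_vertebra_gets_id_one(self):
        shape = (3, 8, 3)
        sem = AnatomicalVolume(np.zeros(shape, dtype=np.uint8), canonical_affine((1, 1, 1)))
        aset = AppearanceSet(0, [_appearance(shape, [(1, 2, 1), (1, 3, 1)])])
        out = fuse_instances([aset], sem).data
        assert set(np.unique(out)) == {0, 1}


class TestDiscEndplateAssignment:
    def test_phantom_owners_recovered(self, phantom5, phantom5_result):
        # disc between vertebrae 2 and 3 carries vertebra 2's disc id
        gt = phantom5.instances.data
        out = phantom5_result.instances.data
        assert (out[gt == disc_id(2)] == disc_id(2)).all()
        assert (out[gt == endplate_id(4)] == endplate_id(4)).all()

    def test_disc_above_topmost_vertebra_falls_back_with_warning(self, caplog):
        shape = (3, 20, 3)
        sem = np.zeros(shape, dtype=np.uint8)
        sem[1, 2:4, 1] = CODES["ivd"]  # disc above every vertebra
        sem[0:3, 8:14, 0:3] = CODES["corpus"]
        vol = AnatomicalVolume(sem, canonical_affine((1, 1, 1)))
        inst_mask = np.zeros(shape, dtype=np.uint16)
        inst_mask[0:3, 8:14, 0:3] = 1
        instances = AnatomicalVolume(inst_mask, canonical_affine((1, 1, 1)))
        import logging

        with caplog.at_level(logging.WARNING, logger="spineseg.instance_stage"):
            out = assign_disc_endplate_instances(vol, instances)
        assert (out.data[sem == CODES["ivd"]] == disc_id(1)).all()
        assert any("no vertebra above" in r.message for r in caplog.records)


class TestPipelineProperties:
    def test_determinism(self, phantom5):
        predictor = NoisyInstancePredictor(
            OracleInstancePredictor(phantom5.instances), flip_rate=0.1, drop_rate=0.05, seed=3
        )
        a = semantic_to_instances(phantom5.semantic, predictor)
        b = semantic_to_instances(phantom5.semantic, predictor)
        assert np.array_equal(a.instances.data, b.instances.data)

    def test_vertebra_and_disc_id_ranges_disjoint_and_consecutive(self, phantom5_result):
        ids = set(int(v) for v in np.unique(phantom5_result.instances.data) if v)
        verts = sorted(i for i in ids if i < 100)
        assert verts == list(range(1, len(verts) + 1))
        assert all(100 < i < 300 for i in ids - set(verts))

    def test_no_corpus_yields_empty_instance_mask(self, phantom5):
        empty = phantom5.semantic.with_data(np.zeros_like(phantom5.semantic.data))
        res = semantic_to_instances(empty, OracleInstancePredictor(phantom5.instances))
        assert not res.instances.data.any()
        assert res.centers == []
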