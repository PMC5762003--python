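import numpy as np
import pandas as pd
import pytest

from conftest import random_blob_mask
from echoseg.agreement import (
    AgreementTable,
    AreaRecord,
    area_agreement,
    area_cm2,
    paired_metric_test,
    pairwise_table,
    williams_index,
)


def _masks(rng, n_images, n_ops, shape=(20, 20)):
    autos, ops = {}, {}
    for i in range(n_images):
        iid = f"im{i:03d}"
        autos[iid] = random_blob_mask(shape, rng)
        ops[iid] = [random_blob_mask(shape, rng) for _ in range(n_ops)]
    return autos, ops


def _table_from_values(values_per_image, metric="dice", mode="COD"):
    rows = []
    for iid, vals in values_per_image.items():
        for j, v in enumerate(vals):
            row = {"image_id": iid, "rater_a": "a", "rater_b": f"b{j}", metric: v}
            rows.append(row)
    return AgreementTable(pd.DataFrame(rows), mode)


class TestPairwiseTable:
    def test_cod_row_count(self, rng):
        autos, ops = _masks(rng, 10, 3)
        t = pairwise_table(autos, ops, "COD")
        assert len(t.rows) == 30
        assert set(t.rows["rater_a"]) == {"auto"}

    def test_iod_row_count(self, rng):
        _, ops = _masks(rng, 10, 3)
        t = pairwise_table(None, ops, "IOD")
        assert len(t.rows) == 30  # C(3,2)=3 pairs per image

    def test_91_images_gives_273_cod_rows(self, rng):
        autos, ops = _masks(rng, 91, 3, shape=(12, 12))
        assert len(pairwise_table(autos, ops, "COD").rows) == 273

    def test_iod_identical_operators(self, rng):
        m = random_blob_mask((20, 20), rng)
        t = pairwise_table(None, {"im0": [m, m, m]}, "IOD")
        assert (t.rows["dice"] == 1.0).all()
        assert (t.rows["hausdorff_mm"] == 0.0).all()

    def test_missing_auto_mask_names_image(self, rng):
        _, ops = _masks(rng, 2, 3)
        with pytest.raises(ValueError, match="im001"):
            pairwise_table({"im000": ops["im000"][0]}, ops, "COD")

    def test_missing_operator_masks_named(self, rng):
        autos, ops = _masks(rng, 1, 3)
        ops["im000"] = []
        with pytest.raises(ValueError, match="im000"):
            pairwise_table(autos, ops, "COD")


class TestWilliamsIndex:
    def test_equal_tables_give_unit_index_degenerate_ci(self):
        vals = {f"im{i}": [0.8, 0.8, 0.8] for i in range(5)}
        cod = _table_from_values(vals)
        iod = _table_from_values(vals, mode="IOD")
        res = williams_index(cod, iod, "dice")
        assert res.wi == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_single_image_dice_example(self):
        cod = _table_from_values({"im0": [0.8, 0.8, 0.8]})
        iod = _table_from_values({"im0": [0.9, 0.9, 0.9]}, mode="IOD")
        assert williams_index(cod, iod, "dice").wi == pytest.approx(1.125)

    def test_single_image_hausdorff_example(self):
        cod = _table_from_values({"im0": [4.0, 4.0, 4.0]}, metric="hausdorff_mm")
        iod = _table_from_values({"im0": [2.0, 2.0, 2.0]}, metric="hausdorff_mm", mode="IOD")
        assert williams_index(cod, iod, "hausdorff_mm").wi == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        vals_c = {f"im{i}": list(rng.uniform(0.5, 1, 3)) for i in range(6)}
        vals_i = {f"im{i}": list(rng.uniform(0.5, 1, 3)) for i in range(6)}
        w1 = williams_index(_table_from_values(vals_c), _table_from_values(vals_i, mode="IOD"), "dice").wi
        sc = {k: [7.3 * v for v in vs] for k, vs in vals_c.items()}
        si = {k: [7.3 * v for v in vs] for k, vs in vals_i.items()}
        w2 = williams_index(_table_from_values(sc), _table_from_values(si, mode="IOD"), "dice").wi
        assert w1 == pytest.approx(w2, rel=1e-12)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (5, 20, 80):
            vals_c = {f"im{i}": list(rng.uniform(0.6, 0.9, 3)) for i in range(n)}
            vals_i = {f"im{i}": list(rng.uniform(0.6, 0.9, 3)) for i in range(n)}
            res = williams_index(_table_from_values(vals_c), _table_from_values(vals_i, mode="IOD"), "dice")
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_swap_moves_to_reciprocal_regime(self):
        cod = _table_from_values({"im0": [0.8] * 3})
        iod = _table_from_values({"im0": [0.9] * 3}, mode="IOD")
        w = williams_index(cod, iod, "dice").wi
        w_swapped = williams_index(iod, cod, "dice").wi
        assert w_swapped == pytest.approx(1.0 / w)

    def test_mismatched_image_sets_rejected(self):
        cod = _table_from_values({"im0": [0.8] * 3})
        iod = _table_from_values({"im1": [0.9] * 3}, mode="IOD")
        with pytest.raises(ValueError):
            williams_index(cod, iod, "dice")

    def test_ci_ordering_invariant(self, rng):
        vals_c = {f"im{i}": list(rng.uniform(0.5, 1, 3)) for i in range(8)}
        vals_i = {f"im{i}": list(rng.uniform(0.5, 1, 3)) for i in range(8)}
        res = williams_index(_table_from_values(vals_c), _table_from_values(vals_i, mode="IOD"), "dice")
        assert res.ci_low <= res.wi <= res.ci_high


class TestPairedMetricTest:
    def test_identical_tables_convention(self):
        vals = {f"im{i}": [0.8, 0.85, 0.9] for i in range(5)}
        t, p = paired_metric_test(_table_from_values(vals), _table_from_values(vals), "dice")
        assert t == 0.0 and p == 1.0

    def test_constant_shift_highly_significant(self, rng):
        base = {f"im{i:02d}": list(rng.uniform(0.6, 0.9, 3)) for i in range(30)}
        shifted = {k: [v + 0.1 for v in vs] for k, vs in base.items()}
        _, p = paired_metric_test(_table_from_values(base), _table_from_values(shifted), "dice")
        assert p < 1e-6

    def test_too_few_images_rejected(self):
        a = _table_from_values({"im0": [0.8] * 3})
        with pytest.raises(ValueError):
            paired_metric_test(a, a, "dice")

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            mu = rng.uniform(0.7, 0.8, 12)
            a = {f"im{i}": list(mu[i] + rng.normal(0, 0.05, 3)) for i in range(12)}
            b = {f"im{i}": list(mu[i] + rng.normal(0, 0.05, 3)) for i in range(12)}
            _, p = paired_metric_test(_table_from_values(a), _table_from_values(b), "dice")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestArea:
    def test_thousand_pixels_at_mean_spacing(self):
        m = np.zeros((40, 40), bool)
        m.flat[:1000] = True
        assert area_cm2(m, spacing=0.54) == pytest.approx(2.916)

    def test_empty_mask(self):
        assert area_cm2(np.zeros((5, 5), bool), spacing=0.54) == 0.0

    def test_doubling_spacing_quadruples_area(self, rng):
        m = random_blob_mask((20, 20), rng)
        assert area_cm2(m, 2.0) == pytest.approx(4 * area_cm2(m, 1.0))

    def test_segmentation_mask_spacing_used(self):
        from echoseg.postprocess import SegmentationMask

        m = SegmentationMask(np.ones((10, 10), bool), spacing=1.0)
        assert area_cm2(m) == pytest.approx(1.0)


class TestAreaAgreement:
    def test_perfect_agreement(self):
        recs = [AreaRecord(f"im{i}", "rest", 10.0, [10.0, 10.0, 10.0]) for i in range(3)]
        tab = area_agreement(recs)
        assert len(tab) == 1
        assert tab.iloc[0]["cod_mean"] == 0.0

    def test_two_image_hand_fixture(self):
        recs = [
            AreaRecord("im0", "rest", 10.0, [11.0, 12.0, 10.0]),
            AreaRecord("im1", "rest", 8.0, [8.0, 9.0, 10.0]),
        ]
        tab = area_agreement(recs)
        # im0 COD: |10-11|,|10-12|,|10-10| -> mean 1.0; im1: 0,1,2 -> mean 1.0
        assert tab.iloc[0]["cod_mean"] == pytest.approx(1.0)
        # im0 IOD: |11-12|,|11-10|,|12-10| -> 4/3; im1: |8-9|,|8-10|,|9-10| -> 4/3
        assert tab.iloc[0]["iod_mean"] == pytest.approx(4 / 3)

    def test_three_stages_present(self):
        recs = []
        for stage in ("rest", "valsalva", "contraction"):
            recs += [AreaRecord(f"{stage}{i}", stage, 10.0, [10.5, 9.5, 10.2]) for i in range(2)]
        tab = area_agreement(recs)
        assert list(tab["stage"]) == ["contraction", "valsalva", "rest"]

    def test_missing_stage_omitted_with_warning(self, caplog):
        import logging

        recs = [AreaRecord("im0", "rest", 10.0, [10.0, 11.0, 12.0]) for _ in range(2)]
        with caplog.at_level(logging.WARNING, logger="echoseg.agreement"):
            tab = area_agreement(recs)
        assert len(tab) == 1
        assert any("omitted" in r.message for r in caplog.records)
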