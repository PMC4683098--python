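"""Tests of per-cell morphometry and activation quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from optofurrow.core import ImageStack, LabelMask, PhotoactivationProtocol, Rect
from optofurrow.quantify import (
    QuantificationParams,
    activation_level,
    ap_anisotropy,
    build_feature_table,
    cell_area,
    depletion_ratio,
    derive_region_masks,
)
from optofurrow.synthetic import (
    NoiseModel,
    SyntheticParams,
    make_tissue,
    render_frame,
    simulate_movie,
    simulate_recruitment,
)

from conftest import interior_labels


def _mask(arr: np.ndarray, px: float = 0.5) -> LabelMask:
    return LabelMask(np.asarray(arr, dtype=np.int32), px)


class TestCellArea:
    def test_square_area(self):
        arr = np.zeros((20, 20), dtype=np.int32)
        arr[5:15, 5:15] = 1
        assert cell_area(_mask(arr), 1) == pytest.approx(25.0)

    def test_absent_label_raises(self):
        with pytest.raises(KeyError):
            cell_area(_mask(np.ones((4, 4))), 7)

    def test_partition_accounting(self, tissue):
        total = sum(cell_area(tissue.labels, int(l)) for l in tissue.labels.label_ids)
        n_px = (tissue.labels.labels > 0).sum()
        assert total == pytest.approx(n_px * tissue.labels.pixel_size_um**2)


class TestApAnisotropy:
    def test_disk_is_isotropic(self):
        yy, xx = np.mgrid[0:50, 0:50]
        arr = ((xx - 25) ** 2 + (yy - 25) ** 2 <= 20**2).astype(np.int32)
        assert ap_anisotropy(_mask(arr), 1) == pytest.approx(1.0, abs=0.02)

    def test_rectangle_matches_side_ratio(self):
        # second moments of a w x h rectangle are w^2/12 and h^2/12, so
        # the moment-ratio anisotropy equals the side ratio
        arr = np.zeros((30, 60), dtype=np.int32)
        arr[10:20, 10:50] = 1  # 40 x 10 (x by y)
        assert ap_anisotropy(_mask(arr), 1) == pytest.approx(4.0, rel=0.02)

    def test_dv_convention_is_reciprocal(self):
        arr = np.zeros((30, 60), dtype=np.int32)
        arr[10:20, 10:50] = 1
        a = ap_anisotropy(_mask(arr), 1, axis="ap")
        d = ap_anisotropy(_mask(arr), 1, axis="dv")
        assert d == pytest.approx(1 / a, rel=1e-12)

    def test_rotation_reciprocity_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            # random blobby cell: threshold a smoothed random field
            from scipy.ndimage import gaussian_filter

            field = gaussian_filter(rng.normal(size=(40, 40)), 4.0)
            arr = (field > np.quantile(field, 0.75)).astype(np.int32)
            # keep the largest component only
            from skimage.measure import label as sklabel

            lab = sklabel(arr, connectivity=1)
            if lab.max() == 0:
                continue
            big = np.argmax(np.bincount(lab.ravel())[1:]) + 1
            arr = (lab == big).astype(np.int32)
            if arr.sum() < 16:
                continue
            a = ap_anisotropy(_mask(arr), 1)
            a_rot = ap_anisotropy(_mask(np.rot90(arr).copy()), 1)
            assert a_rot == pytest.approx(1 / a, rel=0.02)

    def test_degenerate_raises(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[5, 2:8] = 1  # 1 px tall
        with pytest.raises(ValueError):
            ap_anisotropy(_mask(arr), 1)
        arr2 = np.zeros((10, 10), dtype=np.int32)
        arr2[5, 5] = 1
        with pytest.raises(ValueError):
            ap_anisotropy(_mask(arr2), 1)


class TestRegionMasks:
    def test_square_cell_ring_count(self):
        arr = np.zeros((15, 15), dtype=np.int32)
        arr[2:13, 2:13] = 1  # 11x11 cell surrounded by background
        regs = derive_region_masks(
            _mask(arr), np.ones((15, 15)), QuantificationParams(membrane_halfwidth_px=1)
        )
        # boundary layer of an 11x11 square: 4*11 - 4 = 40 px
        assert regs[1].membrane.sum() == 40

    def test_masks_disjoint_and_inside_cell(self, tissue, noiseless_params):
        fr = render_frame(tissue, noiseless_params)
        regs = derive_region_masks(tissue.labels, fr.data[0, 0, 1])
        for lab, r in regs.items():
            assert not np.logical_and(r.membrane, r.cytosol).any()
            cell = tissue.labels.labels == lab
            assert (cell | ~r.membrane).all() and (cell | ~r.cytosol).all()

    def test_nucleus_mostly_excluded(self, noiseless_params):
        p = noiseless_params
        tis = make_tissue(p)
        fr = render_frame(tis, p)
        yy, xx = np.mgrid[0 : p.field_shape_px[0], 0 : p.field_shape_px[1]]
        regs = derive_region_masks(tis.labels, fr.data[0, 0, 1])
        checked = 0
        for lab in interior_labels(tis.labels.labels):
            s = tis.cell_state[lab]
            nx, ny = s.nucleus_center
            disk = (xx - nx) ** 2 + (yy - ny) ** 2 <= s.nucleus_radius**2
            interior_disk = disk & (tis.labels.labels == lab)
            excluded = interior_disk & ~regs[lab].cytosol & ~regs[lab].membrane
            if interior_disk.sum() >= 10:
                assert excluded.sum() >= 0.9 * interior_disk.sum()
                checked += 1
        assert checked > 10


class TestActivationLevel:
    def _regions(self):
        mem = np.zeros((10, 10), dtype=bool)
        cyt = np.zeros((10, 10), dtype=bool)
        mem[0, :] = True
        cyt[5:8, :] = True
        from optofurrow.quantify import RegionMasks

        return RegionMasks(1, mem, cyt)

    def test_equal_means_zero(self):
        img = np.full((10, 10), 7.0)
        assert activation_level(img, self._regions()) == 0.0

    def test_double_membrane_is_one(self):
        img = np.full((10, 10), 2.0)
        img[0, :] = 4.0
        assert activation_level(img, self._regions()) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(gain=st.floats(0.01, 100.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 10, (10, 10))
        r = self._regions()
        assert activation_level(img * gain, r) == pytest.approx(activation_level(img, r), abs=1e-9)

    def test_zero_cytosol_mean_raises(self):
        img = np.zeros((10, 10))
        img[0, :] = 1.0
        with pytest.raises(ZeroDivisionError):
            activation_level(img, self._regions())


class TestDepletionRatio:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).uniform(1, 5, (8, 8))
        m = np.ones((8, 8), dtype=bool)
        assert depletion_ratio(img, img, m) == 0.0

    def test_half_intensity_is_minus_one(self):
        img = np.random.default_rng(0).uniform(1, 5, (8, 8))
        m = np.ones((8, 8), dtype=bool)
        assert depletion_ratio(img / 2, img, m) == pytest.approx(-1.0)

    def test_imposed_factor_recovered(self):
        rng = np.random.default_rng(2)
        img0 = rng.uniform(1, 5, (12, 12))
        m = np.zeros((12, 12), dtype=bool)
        m[3:9, 3:9] = True
        img1 = img0.copy()
        img1[m] *= 0.3
        assert depletion_ratio(img1, img0, m) == pytest.approx(np.log2(0.3), abs=1e-6)


class TestFeatureTable:
    def test_single_cell_single_record(self):
        arr = np.zeros((1, 1, 1, 20, 20))
        arr[0, 0, 0] = 1.0
        stack = ImageStack(arr, 0.5, 30.0, channel_roles=("membrane",))
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:15, 5:15] = 1
        df = build_feature_table(stack, [[_mask(lab)]], None)
        assert len(df) == 1
        assert df.area_um2.iloc[0] == pytest.approx(25.0)

    def test_record_accounting_and_region_flags(self, noiseless_params):
        proto = PhotoactivationProtocol(regions=(Rect(120, 180, 60, 150),))
        stack, truths = simulate_movie(noiseless_params, proto, 2)
        masks = [[t.labels] for t in truths]
        df = build_feature_table(stack, masks, proto)
        n_expected = sum(t.n_cells for t in truths) - df.attrs["n_dropped"]
        assert len(df) == n_expected
        # centroid-in-rectangle oracle
        for _, row in df.iterrows():
            inside = 120 <= row.centroid_x_px < 180 and 60 <= row.centroid_y_px < 150
            assert row.in_activation_region == inside

    def test_dimension_mismatch_raises(self, noiseless_params, tissue):
        stack, truths = simulate_movie(noiseless_params, PhotoactivationProtocol(), 2)
        with pytest.raises(ValueError):
            build_feature_table(stack, [[t.labels] for t in truths[:1]], None)

    def test_constriction_recovered_from_ground_truth_masks(self, noiseless_params):
        proto = PhotoactivationProtocol()
        stack, truths = simulate_movie(noiseless_params, proto, 12)
        masks = [[t.labels] for t in truths]
        df = build_feature_table(stack, masks, proto)
        keep = [
            l
            for l in interior_labels(truths[0].labels.labels)
            if truths[0].cell_state[l].contractile
        ]
        sel = df[df.cell_label.isin(keep)]
        med = sel.groupby("t_index").area_um2.median()
        shrink_measured = 1 - med.iloc[-1] / med.iloc[0]
        t_end = truths[-1].time_s
        con = noiseless_params.constriction
        shrink_programmed = con.shrink_fraction * (1 - np.exp(-t_end / con.tau_s))
        assert shrink_measured == pytest.approx(shrink_programmed, rel=0.05)
        a_med = sel.groupby("t_index").ap_anisotropy.median()
        a_programmed = 1 + con.anisotropy_gain * (1 - np.exp(-t_end / con.tau_s))
        assert a_med.iloc[-1] == pytest.approx(a_programmed, rel=0.10)

    def test_recruitment_trajectory_recovered_at_5pct_noise(self):
        p = SyntheticParams(noise=NoiseModel(gaussian_sd=0.05 * 200.0), n_z=1, seed=17)
        proto = PhotoactivationProtocol(regions=(Rect(120, 180, 60, 150),))
        stack, truths = simulate_movie(p, proto, 10)
        masks = [[t.labels] for t in truths]
        df = build_feature_table(stack, masks, proto)
        act_labels = {l for l, s in truths[-1].cell_state.items() if s.activated}
        sel = df[df.cell_label.isin(act_labels) & df.activation_log2_ratio.notna()]
        measured = sel.groupby("t_index").activation_log2_ratio.mean()
        programmed = simulate_recruitment(
            proto, p.recruitment, measured.index.to_numpy() * p.frame_interval_s
        )
        assert np.max(np.abs(measured.to_numpy() - programmed)) < 0.1
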