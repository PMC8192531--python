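"""Circularity, N/C intensity ratio and multicellularity on labeled masks."""

import math

import numpy as np
import pytest
from skimage import draw

from gatekmc import (
    LabeledMask,
    PhantomSpec,
    circularity,
    gen_masks,
    gen_two_channel_image,
    multicellularity,
    nuclear_cyto_ratio,
)


def _disk_mask(radius=60, size=200, label=1):
    grid = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw.disk((size / 2, size / 2), radius, shape=grid.shape)
    grid[rr, cc] = label
    return grid


class TestCircularity:
    def test_rasterized_disk_is_circular(self):
        df = circularity(LabeledMask(_disk_mask(radius=60)))
        assert df["circularity"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_axis_aligned_square(self):
        grid = np.zeros((120, 120), dtype=np.int32)
        grid[10:90, 10:90] = 1
        df = circularity(LabeledMask(grid))
        assert df["circularity"].iloc[0] == pytest.approx(math.pi / 4, rel=0.05)

    def test_star_less_circular_than_hull(self):
        star = gen_masks(PhantomSpec(shape="star", radius=100, size=256))
        hull = gen_masks(PhantomSpec(shape="disk", radius=100, size=256))
        assert star.truth["circularity"] < 0.5
        c_star = circularity(star.mask)["circularity"].iloc[0]
        c_hull = circularity(hull.mask)["circularity"].iloc[0]
        assert c_star < c_hull

    @pytest.mark.parametrize("aspect", [1, 2, 4])
    def test_ellipse_matches_ramanujan_analytic(self, aspect):
        ph = gen_masks(PhantomSpec(shape="ellipse", radius=80, aspect=aspect, size=220))
        measured = circularity(ph.mask)["circularity"].iloc[0]
        assert measured == pytest.approx(ph.truth["circularity"], rel=0.05)

    def test_ellipse_series_strictly_decreasing(self):
        values = [
            circularity(gen_masks(PhantomSpec(shape="ellipse", radius=80, aspect=a, size=220)).mask)[
                "circularity"
            ].iloc[0]
            for a in (1, 2, 4)
        ]
        assert values[0] > values[1] > values[2]

    def test_invariance_under_translation_rotation_upsampling(self):
        base = np.zeros((200, 200), dtype=np.int32)
        rr, cc = draw.ellipse(90, 100, 30, 55)
        base[rr, cc] = 1
        c0 = circularity(LabeledMask(base))["circularity"].iloc[0]
        shifted = circularity(LabeledMask(np.roll(base, (13, -7), axis=(0, 1))))["circularity"].iloc[0]
        rotated = circularity(LabeledMask(np.rot90(base)))["circularity"].iloc[0]
        upsampled = circularity(LabeledMask(np.kron(base, np.ones((2, 2), dtype=np.int32))))[
            "circularity"
        ].iloc[0]
        assert shifted == pytest.approx(c0, rel=1e-9)
        assert rotated == pytest.approx(c0, rel=1e-9)
        assert upsampled == pytest.approx(c0, rel=0.02)

    def test_pixel_size_scales_dimensions_but_not_circularity(self):
        grid = _disk_mask(radius=40)
        df1 = circularity(LabeledMask(grid, pixel_size=1.0))
        df2 = circularity(LabeledMask(grid, pixel_size=0.5))
        assert df2["area_um2"].iloc[0] == pytest.approx(df1["area_um2"].iloc[0] / 4)
        assert df2["circularity"].iloc[0] == df1["circularity"].iloc[0]

    def test_edge_touching_object_flagged_but_measured(self):
        grid = np.zeros((80, 80), dtype=np.int32)
        rr, cc = draw.disk((0, 40), 25, shape=grid.shape)
        grid[rr, cc] = 1
        df = circularity(LabeledMask(grid))
        assert bool(df["touches_edge"].iloc[0])
        assert np.isfinite(df["circularity"].iloc[0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no labeled objects"):
            circularity(LabeledMask(np.zeros((10, 10), dtype=np.int32)))


class TestNuclearCytoRatio:
    def test_uniform_image_gives_unit_ratio(self):
        tc = gen_two_channel_image(PhantomSpec(nucleus_mean=100.0, cytoplasm_mean=100.0))
        df = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)
        assert df["ratio"].iloc[0] == pytest.approx(1.0)

    def test_noise_free_ratio_exact(self):
        tc = gen_two_channel_image(PhantomSpec(nucleus_mean=200.0, cytoplasm_mean=100.0))
        df = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)
        assert df["ratio"].iloc[0] == pytest.approx(2.0)

    def test_recovery_at_snr10_over_fifty_cells(self):
        # noise SD = cytoplasm mean / 10
        tc = gen_two_channel_image(
            PhantomSpec(nucleus_mean=200.0, cytoplasm_mean=100.0, noise_sd=10.0, n_cells=50, seed=4)
        )
        df = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)
        assert df["error"].eq("").all()
        assert df["ratio"].mean() == pytest.approx(2.0, rel=0.05)

    def test_invariant_under_intensity_rescaling(self):
        tc = gen_two_channel_image(PhantomSpec(noise_sd=5.0, seed=1))
        a = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)["ratio"].iloc[0]
        b = nuclear_cyto_ratio(3.7 * tc.intensity, tc.nucleus_mask, tc.cell_mask)["ratio"].iloc[0]
        assert b == pytest.approx(a, rel=1e-12)

    def test_background_noise_does_not_affect_ratio(self):
        tc = gen_two_channel_image(PhantomSpec(seed=2))
        noisy = tc.intensity.copy()
        outside = tc.cell_mask.labels == 0
        noisy[outside] += np.random.default_rng(0).uniform(0, 50, outside.sum())
        a = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)["ratio"].iloc[0]
        b = nuclear_cyto_ratio(noisy, tc.nucleus_mask, tc.cell_mask)["ratio"].iloc[0]
        assert a == b

    def test_zero_cytoplasm_intensity_yields_error_record(self):
        tc = gen_two_channel_image(PhantomSpec(nucleus_mean=100.0, cytoplasm_mean=50.0))
        img = tc.intensity.copy()
        img[(tc.cell_mask.labels > 0) & (tc.nucleus_mask.labels == 0)] = 0.0
        df = nuclear_cyto_ratio(img, tc.nucleus_mask, tc.cell_mask)
        assert df["error"].iloc[0] == "zero cytoplasmic intensity"
        assert math.isnan(df["ratio"].iloc[0])

    def test_integrated_intensity_option(self):
        tc = gen_two_channel_image(PhantomSpec(nucleus_mean=200.0, cytoplasm_mean=100.0))
        mean_df = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask, statistic="mean")
        sum_df = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask, statistic="sum")
        n_nuc = (tc.nucleus_mask.labels > 0).sum()
        n_cyt = ((tc.cell_mask.labels > 0) & (tc.nucleus_mask.labels == 0)).sum()
        assert sum_df["ratio"].iloc[0] == pytest.approx(
            mean_df["ratio"].iloc[0] * n_nuc / n_cyt
        )


class TestMulticellularity:
    def _cluster_with_nuclei(self, n_nuclei, size=200):
        clusters = LabeledMask(_disk_mask(radius=80, size=size))
        nuclei = np.zeros((size, size), dtype=np.int32)
        for k in range(n_nuclei):
            cy = size / 2 + 30 * math.sin(2 * math.pi * k / max(n_nuclei, 1))
            cx = size / 2 + 30 * math.cos(2 * math.pi * k / max(n_nuclei, 1))
            rr, cc = draw.disk((cy, cx), 8, shape=nuclei.shape)
            nuclei[rr, cc] = k + 1
        return clusters, LabeledMask(nuclei)

    @pytest.mark.parametrize("n,expected", [(1, False), (2, False), (3, True), (5, True)])
    def test_strictly_more_than_two_nuclei(self, n, expected):
        clusters, nuclei = self._cluster_with_nuclei(n)
        df = multicellularity(clusters, nuclei)
        assert df["n_nuclei"].iloc[0] == n
        assert bool(df["multicellular"].iloc[0]) is expected

    def test_unassigned_nucleus_reported(self):
        clusters, _ = self._cluster_with_nuclei(0)
        nuclei = np.zeros((200, 200), dtype=np.int32)
        rr, cc = draw.disk((5, 5), 3)  # far outside the cluster
        nuclei[rr, cc] = 1
        df = multicellularity(clusters, LabeledMask(nuclei))
        assert df["n_nuclei"].iloc[0] == 0
        assert df.attrs["unassigned_nuclei"] == [1]
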