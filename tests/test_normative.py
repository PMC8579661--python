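"""Single-case normative comparison and ROI binarization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connfp import (
    build_feature_table,
    crawford_map,
    crawford_t,
    make_toy_atlas,
    resolve_rois,
    summarize_roi,
    tabulate_cohort,
)


class TestCrawfordT:
    def test_case_at_control_mean(self, rng):
        controls = rng.standard_normal(18)
        t, p, df = crawford_t(controls.mean(), controls)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)
        assert df == 17

    def test_two_sd_case_closed_form(self, rng):
        controls = rng.standard_normal(18)
        case = controls.mean() + 2 * controls.std(ddof=1)
        t, p, df = crawford_t(case, controls)
        assert t == pytest.approx(2 / np.sqrt(19 / 18), abs=1e-10)
        # independent oracle: numerical integration of the t density
        from scipy.integrate import quad
        from scipy.special import gammaln

        dfv = 17
        dens = lambda x: (
            np.exp(gammaln((dfv + 1) / 2) - gammaln(dfv / 2))
            / np.sqrt(dfv * np.pi) * (1 + x * x / dfv) ** (-(dfv + 1) / 2)
        )
        tail, _ = quad(dens, abs(t), np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-8)

    def test_converges_to_z_test_for_large_n(self, rng):
        controls = rng.standard_normal(100_000)
        case = controls.mean() + 2 * controls.std(ddof=1)
        _, p, _ = crawford_t(case, controls)
        assert abs(p - 2 * stats.norm.sf(2.0)) < 1e-3

    def test_scale_and_shift_invariance(self, rng):
        controls = rng.standard_normal(18)
        case = 1.3
        t1, _, _ = crawford_t(case, controls)
        t2, _, _ = crawford_t(5.0 * case + 2.0, 5.0 * controls + 2.0)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            crawford_t(1.0, np.ones(10))

    def test_single_control_raises(self):
        with pytest.raises(ValueError):
            crawford_t(1.0, np.array([1.0]))


class TestCrawfordMap:
    def test_case_equal_to_mean_map_gives_zero_t(self, rng):
        controls = rng.standard_normal((10, 4, 4, 3))
        mask = np.ones((4, 4, 3), dtype=bool)
        cmap = crawford_map(controls.mean(axis=0), controls, mask)
        assert np.allclose(cmap.t, 0.0, atol=1e-10)
        assert cmap.df == 9

    def test_inflated_voxel_attains_map_max(self, rng):
        controls = rng.standard_normal((12, 5, 5, 2))
        mask = np.ones((5, 5, 2), dtype=bool)
        case = controls.mean(axis=0).copy()
        case[2, 3, 1] += 10 * controls.std(axis=0, ddof=1)[2, 3, 1]
        cmap = crawford_map(case, controls, mask)
        assert np.unravel_index(np.argmax(cmap.t), cmap.t.shape) == (2, 3, 1)

    def test_matches_scalar_loop_oracle(self, rng):
        controls = rng.standard_normal((8, 50, 1, 1))
        case = rng.standard_normal((50, 1, 1))
        mask = np.ones((50, 1, 1), dtype=bool)
        cmap = crawford_map(case, controls, mask)
        n = 8
        for i in range(50):
            c = controls[:, i, 0, 0]
            t_expected = (case[i, 0, 0] - c.mean()) / (
                c.std(ddof=1) * np.sqrt((n + 1) / n)
            )
            assert cmap.t[i, 0, 0] == pytest.approx(t_expected, abs=1e-12)
            assert cmap.p[i, 0, 0] == pytest.approx(
                2 * stats.t.sf(abs(t_expected), n - 1), abs=1e-12
            )

    def test_grid_mismatch_raises(self, rng):
        controls = rng.standard_normal((5, 4, 4, 3))
        with pytest.raises(ValueError, match="grid mismatch"):
            crawford_map(rng.standard_normal((4, 4, 4)), controls,
                         np.ones((4, 4, 3), dtype=bool))

    def test_out_of_mask_p_is_one(self, rng):
        controls = rng.standard_normal((6, 3, 3, 2))
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        cmap = crawford_map(rng.standard_normal((3, 3, 2)), controls, mask)
        assert np.all(cmap.p[~mask] == 1.0)


@pytest.fixture(scope="module")
def roi_setup():
    atlas = make_toy_atlas((16, 16, 12))
    rois = resolve_rois(atlas, "left")
    mesial = rois[("mesial", "ipsilateral")]
    return atlas, mesial


def _cmap_from(t_map, atlas):
    from connfp.normative import CrawfordMap

    df = 17
    p = 2 * stats.t.sf(np.abs(t_map), df)
    return CrawfordMap(t=t_map, p=p, df=df, mask=atlas.brain_mask,
                       affine=atlas.affine)


class TestSummarizeROI:
    def test_null_map_gives_zero(self, roi_setup):
        atlas, mesial = roi_setup
        cmap = _cmap_from(np.zeros(atlas.data.shape), atlas)
        s = summarize_roi(cmap, mesial, atlas)
        assert s.indicator == 0 and s.n_sig == 0
        assert s.n_roi == int(mesial.mask(atlas).sum())

    def test_single_significant_voxel_flips_indicator(self, roi_setup):
        atlas, mesial = roi_setup
        t = np.zeros(atlas.data.shape)
        vox = tuple(np.argwhere(mesial.mask(atlas))[0])
        t[vox] = 5.0  # p ~ 1e-4 < 0.005 at df 17
        s = summarize_roi(_cmap_from(t, atlas), mesial, atlas)
        assert s.indicator == 1 and s.n_sig == 1

    def test_significant_decreases_do_not_count(self, roi_setup, rng):
        atlas, mesial = roi_setup
        t = np.zeros(atlas.data.shape)
        roi_vox = np.argwhere(mesial.mask(atlas))
        # mix of strong decreases and mild increases
        for v in roi_vox[:5]:
            t[tuple(v)] = -6.0
        for v in roi_vox[5:8]:
            t[tuple(v)] = 1.0
        cmap = _cmap_from(t, atlas)
        s = summarize_roi(cmap, mesial, atlas)
        # brute-force filter oracle
        sig = (cmap.p < 0.005) & (cmap.t > 0) & mesial.mask(atlas)
        assert s.n_sig == int(sig.sum()) == 0
        assert s.indicator == 0
        assert s.n_sig_decrease == 5

    def test_indicator_monotone_in_case_inflation(self, roi_setup):
        atlas, mesial = roi_setup
        t = np.zeros(atlas.data.shape)
        roi_vox = np.argwhere(mesial.mask(atlas))
        t[tuple(roi_vox[0])] = 4.0
        before = summarize_roi(_cmap_from(t, atlas), mesial, atlas).indicator
        t[tuple(roi_vox[1])] = 8.0  # inflate another voxel
        after = summarize_roi(_cmap_from(t, atlas), mesial, atlas).indicator
        assert after >= before == 1

    def test_empty_roi_raises(self, roi_setup):
        from connfp.wdc import ROIDefinition

        atlas, _ = roi_setup
        ghost = ROIDefinition("mesial", "ipsilateral", labels=(99,))
        cmap = _cmap_from(np.zeros(atlas.data.shape), atlas)
        with pytest.raises(ValueError, match="empty"):
            summarize_roi(cmap, ghost, atlas)

    def test_bad_alpha_raises(self, roi_setup):
        atlas, mesial = roi_setup
        cmap = _cmap_from(np.zeros(atlas.data.shape), atlas)
        with pytest.raises(ValueError):
            summarize_roi(cmap, mesial, atlas, alpha=1.5)


def _fake_features(rng, n=30, p_one=0.3):
    from connfp.normative import ROI_ORDER

    rows = []
    for i in range(n):
        row = {"id": f"p{i:03d}"}
        for roi, side in ROI_ORDER:
            ind = int(rng.random() < p_one)
            row[f"{roi}_{side}_ind"] = ind
            row[f"{roi}_{side}_nsig"] = ind * int(rng.integers(1, 10))
        row["outcome"] = int(rng.random() < 0.5)
        rows.append(row)
    return pd.DataFrame(rows)


class TestTabulate:
    def test_all_zero_indicators(self, rng):
        feat = _fake_features(rng, n=10, p_one=0.0)
        tab = tabulate_cohort(feat)
        assert (tab["all_increased"] == 0).all()
        assert (tab["all_increased_pct"] == 0.0).all()

    def test_seven_of_thirty_percentage(self, rng):
        feat = _fake_features(rng, n=30, p_one=0.0)
        feat.loc[:6, "mesial_ipsilateral_ind"] = 1
        tab = tabulate_cohort(feat).set_index("roi")
        row = tab.loc["mesial - ipsilateral"]
        assert row["all_increased"] == 7
        assert row["all_increased_pct"] == 23.3  # 100*7/30 to 1 decimal

    def test_matches_counting_oracle(self, rng):
        feat = _fake_features(rng, n=25, p_one=0.4)
        tab = tabulate_cohort(feat).set_index("roi")
        for col_roi in ["pole_ipsilateral", "lateral_contralateral"]:
            roi, side = col_roi.split("_")
            sf = feat[feat["outcome"] == 1]
            expected = int(sf[f"{col_roi}_ind"].sum())
            assert tab.loc[f"{roi} - {side}", "SF_increased"] == expected

    def test_subset_filter(self, rng):
        feat = _fake_features(rng, n=20, p_one=0.5)
        keep = feat["id"].iloc[:8]
        tab = tabulate_cohort(feat, subset=keep)
        assert (tab["all_n"] == 8).all()


class TestFeatureTable:
    def test_id_mismatch_raises(self, rng):
        from connfp.normative import ROISummary

        summaries = {"pX": [ROISummary("mesial", "ipsilateral", 0, 0, 5)]}
        patients = pd.DataFrame({"id": ["pY"], "side": ["left"],
                                 "outcome": ["SF"]})
        with pytest.raises(ValueError, match="mismatch"):
            build_feature_table(summaries, patients)
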