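"""Lesion aggregation, median-split grouping and finding cross-tabs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rotadebulk.frames import AblationMetrics
from rotadebulk.lesion import (
    GROUP_LABELS,
    crosstab_findings,
    integrate_volumes,
    median_split_groups,
)


def fake_metric(z, p=0.5, a=0.5, o=0.25, excluded=False, mode="catheter"):
    return AblationMetrics(
        mode=mode, frame_index=int(z), z_mm=z, p_area=p, a_area=a, o_area=o,
        p_angle=90.0, a_angle=80.0, o_angle=40.0,
        pct_correct_area=None if excluded else 100 * o / p,
        pct_error_area=None if excluded else 100 * (a - o) / a,
        pct_correct_angle=None if excluded else 44.4,
        pct_error_angle=None if excluded else 50.0,
        d_catheter_intima=0.0, d_wire_intima=0.2, d_catheter_wire=0.0,
        contact=True, min_lumen_diam=1.5, mean_lumen_diam=1.9,
        lumen_area_pre=2.9, lumen_area_post=3.6, burr_lumen_ratio=0.9,
        calc_arc_deg=238.0, calc_min_depth_um=430.0, calc_type="eccentric",
        lumen_loss_area=0.0, deep_injury=False, flap_outside_p=False,
        excluded=excluded, exclusion_reason="x" if excluded else None)


class TestIntegrateVolumes:
    def test_rectangle_rule(self):
        frames = [fake_metric(z, p=p) for z, p in zip((0, 1, 2), (0.5, 0.5, 1.0))]
        lm = integrate_volumes(frames, spacing=1.0)
        assert lm.p_volume == pytest.approx(2.0)

    def test_all_perfect_frames_give_perfect_volume(self):
        frames = [fake_metric(z, p=0.4, a=0.4, o=0.4) for z in range(4)]
        lm = integrate_volumes(frames, spacing=1.0)
        assert lm.pct_correct_volume == pytest.approx(100.0)
        assert lm.pct_error_volume == pytest.approx(0.0)

    def test_linearity_under_area_scaling(self):
        rng = np.random.default_rng(2)
        frames = [fake_metric(z, p=rng.uniform(0.2, 1), a=rng.uniform(0.2, 1),
                              o=rng.uniform(0.0, 0.2)) for z in range(6)]
        lm1 = integrate_volumes(frames, spacing=1.0)
        scaled = [fake_metric(f.z_mm, p=3 * f.p_area, a=3 * f.a_area,
                              o=3 * f.o_area) for f in frames]
        lm3 = integrate_volumes(scaled, spacing=1.0)
        assert lm3.p_volume == pytest.approx(3 * lm1.p_volume)
        assert lm3.a_volume == pytest.approx(3 * lm1.a_volume)
        assert lm3.pct_correct_volume == pytest.approx(lm1.pct_correct_volume)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(9)
        areas = rng.uniform(0.1, 1.0, (5, 3))
        frames = [fake_metric(z, p=pa, a=aa, o=min(pa, aa) * 0.5)
                  for z, (pa, aa, _) in enumerate(areas)]
        lm = integrate_volumes(frames, spacing=0.5)
        assert lm.p_volume == pytest.approx(areas[:, 0].sum() * 0.5)
        assert lm.a_volume == pytest.approx(areas[:, 1].sum() * 0.5)

    def test_excluded_frames_do_not_contribute_to_means(self):
        frames = [fake_metric(0), fake_metric(1, excluded=True)]
        lm = integrate_volumes(frames, spacing=1.0)
        assert lm.mean_pct_correct_angle == pytest.approx(44.4)

    def test_errors(self):
        with pytest.raises(ValueError):
            integrate_volumes([], spacing=1.0)
        frames = [fake_metric(0), fake_metric(1), fake_metric(3)]
        with pytest.raises(ValueError, match="spacing"):
            integrate_volumes(frames, spacing=1.0)
        with pytest.raises(ValueError, match="modes"):
            integrate_volumes([fake_metric(0), fake_metric(1, mode="wire")])


class TestMedianSplit:
    def test_quadrant_assignment_at_reference_medians(self):
        # cohort medians engineered to 47.8 / 41.6
        table = pd.DataFrame({
            "pct_correct_area": [60.0, 30.0, 47.8, 35.6],
            "pct_error_area": [20.0, 70.0, 41.6, 13.2],
        })
        labels, med_c, med_e = median_split_groups(table)
        assert labels[0] == "good_prediction"      # high C, low E
        assert labels[1] == "irrelevant_ablation"  # low C, high E

    def test_labels_partition_frames(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({
            "pct_correct_area": rng.uniform(0, 100, 101),
            "pct_error_area": rng.uniform(0, 100, 101),
        })
        labels, _, _ = median_split_groups(table)
        counts = labels.value_counts()
        assert counts.sum() == 101
        assert set(counts.index) <= set(GROUP_LABELS)

    def test_independent_metrics_give_quarter_quadrants(self):
        rng = np.random.default_rng(8)
        n = 1000
        table = pd.DataFrame({
            "pct_correct_area": rng.uniform(0, 100, n),
            "pct_error_area": rng.uniform(0, 100, n),
        })
        labels, _, _ = median_split_groups(table)
        frac = labels.value_counts() / n
        assert ((frac - 0.25).abs() <= 0.05).all()

    def test_ties_at_median_go_high(self):
        table = pd.DataFrame({
            "pct_correct_area": [50.0, 50.0, 10.0],
            "pct_error_area": [10.0, 90.0, 50.0],
        })
        labels, med_c, med_e = median_split_groups(table)
        assert labels[0] == "good_prediction"   # C == median counts as high
        assert labels[2] == "irrelevant_ablation"


class TestCrosstab:
    def test_all_false_degenerate(self):
        labels = pd.Series(["good_prediction"] * 5 + ["over_ablation"] * 5)
        findings = pd.Series([False] * 10)
        _, chi2, p, test = crosstab_findings(labels, findings)
        assert test == "degenerate" and p == 1.0

    def test_proportional_findings_independent(self):
        labels = pd.Series((["good_prediction"] * 10 + ["over_ablation"] * 10
                            + ["insufficient_ablation"] * 10
                            + ["irrelevant_ablation"] * 10))
        findings = pd.Series(([True] * 5 + [False] * 5) * 4)
        _, chi2, p, _ = crosstab_findings(labels, findings)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_concentrated_findings_significant(self):
        # injuries concentrated in over + irrelevant ablation frames
        counts = {"good_prediction": (40, 1), "over_ablation": (25, 12),
                  "insufficient_ablation": (38, 2), "irrelevant_ablation": (24, 14)}
        labels, findings = [], []
        for g, (neg, pos) in counts.items():
            labels += [g] * (neg + pos)
            findings += [False] * neg + [True] * pos
        tab, chi2, p, test = crosstab_findings(pd.Series(labels), pd.Series(findings))
        expected_chi2, expected_p, _, _ = sps.chi2_contingency(
            np.array([v for v in counts.values()]))
        assert chi2 == pytest.approx(expected_chi2)
        assert p == pytest.approx(expected_p)
        assert p < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            crosstab_findings(pd.Series(dtype=object), pd.Series(dtype=bool))
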