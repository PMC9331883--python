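"""Peak integration, LiP selection, fold changes, protection calls, region maps."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dartslip import (
    AnnotationInterval,
    AnnotationKind,
    ChromTrace,
    FoldChange,
    LiPSelection,
    PeakArea,
    ProteinRecord,
    call_protected,
    fold_change,
    fold_changes,
    integrate_peak,
    map_regions,
    merge_intervals,
    render_chromatogram,
    rollup_peptide,
    rollup_table,
    select_lip_peptides,
)
from dartslip.tlip_mrm import (
    AREA_COLUMNS,
    DD_DOSE,
    DD_VEHICLE,
    TRYPSIN_ONLY,
    region_report_markdown,
)


def trace(time, intensity, **kw):
    defaults = dict(peptide_id="p", transition_id="t", condition=TRYPSIN_ONLY,
                    replicate_id="r1")
    defaults.update(kw)
    return ChromTrace(time=np.asarray(time, float), intensity=np.asarray(intensity, float),
                      **defaults)


class TestIntegratePeak:
    def test_rectangular_pulse(self):
        t = np.linspace(0, 10, 1001)
        y = np.where((t >= 2) & (t <= 6), 5.0, 0.0)
        area = integrate_peak(trace(t, y), (2.0, 6.0)).area
        assert area == pytest.approx(20.0, rel=1e-6)

    def test_linear_trace_zero_after_baseline(self):
        t = np.linspace(0, 10, 101)
        y = 3.0 + 0.7 * t
        area = integrate_peak(trace(t, y), (1.0, 9.0), baseline="linear_endpoints").area
        assert area == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("true_area", [10.0, 1234.5, 1e6])
    def test_gaussian_area_within_one_percent(self, true_area):
        tr = render_chromatogram(true_area, rt=5.0, width=0.1)
        got = integrate_peak(tr, (float(tr.time[0]), float(tr.time[-1]))).area
        assert got == pytest.approx(true_area, rel=0.01)

    def test_window_outside_trace_errors(self):
        with pytest.raises(ValueError, match="outside"):
            integrate_peak(trace([0, 1, 2], [0, 1, 0]), (1.0, 5.0))

    def test_negative_excursions_floored(self):
        t = np.linspace(0, 4, 401)
        y = np.where((t >= 1) & (t <= 2), 2.0, 0.0)  # baseline chord dips below tail
        area = integrate_peak(trace(t, y), (0.0, 4.0), baseline="linear_endpoints").area
        assert area >= 0.0


class TestRollup:
    def _areas(self, values):
        return [PeakArea("p", f"t{i}", TRYPSIN_ONLY, "r1", v) for i, v in enumerate(values)]

    def test_sum_and_identity(self):
        assert rollup_peptide(self._areas([100, 200, 300])).area == 600
        assert rollup_peptide(self._areas([42.0])).area == 42.0

    def test_permutation_invariance(self):
        a = rollup_peptide(self._areas([1.0, 2.5, 7.0]))
        b = rollup_peptide(self._areas([7.0, 1.0, 2.5]))
        assert a.area == b.area

    def test_mixed_groups_rejected(self):
        areas = self._areas([1.0]) + [PeakArea("q", "t9", TRYPSIN_ONLY, "r1", 1.0)]
        with pytest.raises(ValueError):
            rollup_peptide(areas)

    def test_table_rollup_matches_list_rollup(self):
        df = pd.DataFrame(
            [
                ("p", "t1", TRYPSIN_ONLY, float("nan"), "r1", 100.0),
                ("p", "t2", TRYPSIN_ONLY, float("nan"), "r1", 200.0),
            ],
            columns=AREA_COLUMNS,
        )
        assert rollup_table(df)["area"].tolist() == [300.0]


def area_df(tryp, veh, dosed=None, dose=1.0, peptide="p"):
    rows = []
    for r, v in enumerate(tryp):
        rows.append((peptide, "peptide", TRYPSIN_ONLY, float("nan"), f"r{r}", v))
    for r, v in enumerate(veh):
        rows.append((peptide, "peptide", DD_VEHICLE, float("nan"), f"r{r}", v))
    for r, v in enumerate(dosed or []):
        rows.append((peptide, "peptide", DD_DOSE, dose, f"r{r}", v))
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


class TestLiPSelection:
    def test_identical_areas_not_lip(self):
        sel = select_lip_peptides(area_df([100, 110, 90], [100, 110, 90]))
        assert not sel[0].is_lip
        assert sel[0].mean_ratio_dd_vs_tryp == pytest.approx(1.0)

    def test_strong_suppression_detected(self, rng):
        tryp = 1000.0 * (1 + 0.05 * rng.standard_normal(3))
        veh = 0.2 * 1000.0 * (1 + 0.05 * rng.standard_normal(3))
        sel = select_lip_peptides(area_df(tryp, veh))
        assert sel[0].is_lip
        assert sel[0].p_value <= 0.05

    def test_increased_area_never_lip(self):
        sel = select_lip_peptides(area_df([100, 100, 100], [500, 490, 510]))
        assert not sel[0].is_lip

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            select_lip_peptides(area_df([100, 100], [100]))

    def test_zero_areas_floored(self):
        df = area_df([100, 100, 100], [0.0, 4.0, 4.0])
        sel = select_lip_peptides(df)
        assert math.isfinite(sel[0].p_value)


class TestFoldChange:
    def test_identical_gives_unity(self):
        df = area_df([1, 1, 1], [500, 500, 500], [500, 500, 500])
        assert fold_change(df, "p", 1.0).fc == pytest.approx(1.0)

    def test_doubling(self):
        df = area_df([1, 1], [1000, 1000], [2000, 2000])
        assert fold_change(df, "p", 1.0).fc == pytest.approx(2.0)

    def test_reciprocal_identity(self):
        df_fwd = area_df([1, 1], [1000, 900], [2100, 1900])
        df_rev = area_df([1, 1], [2100, 1900], [1000, 900])
        assert fold_change(df_fwd, "p", 1.0).fc * fold_change(df_rev, "p", 1.0).fc == (
            pytest.approx(1.0)
        )

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        base = area_df([800, 900, 1000], [400, 380, 420], [700, 820, 760])
        scaled = base.copy()
        scaled["area"] *= scale
        assert fold_change(scaled, "p", 1.0).fc == pytest.approx(
            fold_change(base, "p", 1.0).fc, rel=1e-9
        )


class TestCallProtected:
    def _lip(self, pid, is_lip=True):
        return LiPSelection(pid, is_lip, 0.01 if is_lip else 0.9, 0.2 if is_lip else 1.0)

    def test_unity_fold_changes_give_empty_set(self):
        lips = [self._lip("a"), self._lip("b")]
        fcs = [FoldChange("a", 1.0, 1.0, 0.9), FoldChange("b", 1.0, 1.0, 0.8)]
        assert call_protected(lips, fcs) == set()

    def test_non_lip_never_called(self):
        lips = [self._lip("a", is_lip=False)]
        fcs = [FoldChange("a", 1.0, 3.0, 0.001)]
        assert call_protected(lips, fcs) == set()

    def test_called_at_any_single_dose(self):
        lips = [self._lip("a")]
        fcs = [FoldChange("a", 1.0, 1.1, 0.5), FoldChange("a", 10.0, 2.2, 0.01)]
        assert call_protected(lips, fcs) == {"a"}

    def test_monotone_in_thresholds(self):
        lips = [self._lip(p) for p in "abc"]
        fcs = [
            FoldChange("a", 1.0, 1.6, 0.01),
            FoldChange("b", 1.0, 2.5, 0.04),
            FoldChange("c", 1.0, 3.0, 0.2),
        ]
        loose = call_protected(lips, fcs, fc_min=1.5, alpha=0.05)
        tight_fc = call_protected(lips, fcs, fc_min=2.0, alpha=0.05)
        tight_alpha = call_protected(lips, fcs, fc_min=1.5, alpha=0.02)
        assert tight_fc <= loose and tight_alpha <= loose


class TestMapRegions:
    def _protein(self):
        seq = "A" * 900
        anns = (
            AnnotationInterval("helix_2", 49, 77, AnnotationKind.HELIX),
            AnnotationInterval("gate_loop", 279, 289, AnnotationKind.LOOP),
            AnnotationInterval("Tyr75", 75, 75, AnnotationKind.RESIDUE),
        )
        return ProteinRecord("PYGB-like", seq, anns)

    def test_helix_overlap_and_residue_hit(self):
        report = map_regions([(71, 78)], self._protein())
        assert ((71, 78), "helix_2", 7) in report.overlaps
        assert "Tyr75" in report.residue_hits

    def test_gate_loop_overlap(self):
        report = map_regions([(279, 290)], self._protein())
        assert ((279, 290), "gate_loop", 11) in report.overlaps

    def test_bookended_peptides_merge(self):
        report = map_regions([(10, 20), (21, 30)], self._protein())
        assert report.protected_intervals == ((10, 30),)

    def test_out_of_range_peptide_errors(self):
        with pytest.raises(ValueError, match="outside"):
            map_regions([(890, 905)], self._protein())

    @given(
        intervals=st.lists(
            st.tuples(st.integers(1, 880), st.integers(1, 20)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_merged_cover_exactly_the_union(self, intervals):
        merged = merge_intervals(intervals)
        union = set()
        for s, e in intervals:
            union.update(range(s, e + 1))
        covered = set()
        for s, e in merged:
            assert s <= e
            covered.update(range(s, e + 1))
        assert covered == union
        # pairwise disjoint and not bookended
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert s2 > e1 + 1

    def test_markdown_report_lists_overlaps(self):
        report = map_regions([(71, 78)], self._protein())
        text = region_report_markdown(report, [FoldChange("71-78", 1.0, 2.0, 0.01)])
        assert "helix_2" in text and "71-78" in text
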