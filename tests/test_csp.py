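"""CSP arithmetic, grouping, group statistics and mover classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silbind import (
    Assignment,
    CSPConfig,
    MoverClass,
    Peak2D,
    PeakList,
    SignalGroup,
    TitrationSeries,
    classify_movers,
    compute_csp_table,
    csp_analysis,
    csp_hsqc,
    csp_tocsy,
    group_stats,
)
from silbind.core_io import ValidationError
from silbind.csp import CSPRecord, classify_group

A_NH = Assignment(1, "A", "H", "HA")
A_CA = Assignment(1, "A", "CA", "HA")


def _tocsy_peak(f1, f2, present=True):
    return Peak2D(A_NH, f1, f2, present)


def _hsqc_peak(f1, f2, present=True):
    return Peak2D(A_CA, f1, f2, present)


class TestCSPTocsy:
    def test_zero_displacement(self):
        assert csp_tocsy(_tocsy_peak(8.0, 4.2), _tocsy_peak(8.0, 4.2)) == 0.0

    def test_three_four_five_triangle(self):
        start, end = _tocsy_peak(8.00, 4.20), _tocsy_peak(8.03, 4.24)
        assert csp_tocsy(start, end) == pytest.approx(0.05, abs=1e-12)

    def test_symmetric_in_start_end(self):
        start, end = _tocsy_peak(8.01, 4.23), _tocsy_peak(8.07, 4.19)
        assert csp_tocsy(start, end) == csp_tocsy(end, start)

    def test_missing_peak_gives_nan(self):
        assert math.isnan(csp_tocsy(_tocsy_peak(0, 0, present=False), _tocsy_peak(8, 4.2)))


class TestCSPHsqc:
    def test_weighted_displacement(self):
        # sqrt(0.1^2 + 0.3 * 0.2^2) = 0.148324...
        start, end = _hsqc_peak(52.0, 4.20), _hsqc_peak(52.2, 4.30)
        assert csp_hsqc(start, end, alpha=0.3) == pytest.approx(
            math.sqrt(0.01 + 0.3 * 0.04), abs=1e-12
        )
        assert csp_hsqc(start, end, alpha=0.3) == pytest.approx(0.148324, abs=1e-6)

    def test_alpha_one_reduces_to_euclidean(self):
        start, end = _hsqc_peak(52.0, 4.2), _hsqc_peak(52.5, 4.3)
        t_start, t_end = _tocsy_peak(8.0 - 8.0 + 2.0, 4.2), _tocsy_peak(2.5, 4.3)
        assert csp_hsqc(start, end, alpha=1.0) == pytest.approx(
            csp_tocsy(t_start, t_end), abs=1e-12
        )

    def test_zero_carbon_displacement_gives_proton_magnitude(self):
        start, end = _hsqc_peak(52.0, 4.2), _hsqc_peak(52.0, 4.35)
        assert csp_hsqc(start, end) == pytest.approx(0.15, abs=1e-12)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValidationError):
            csp_hsqc(_hsqc_peak(52, 4.2), _hsqc_peak(52, 4.3), alpha=0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        dh=st.floats(0, 1), dc=st.floats(0, 5),
        scale_h=st.floats(1, 2), scale_c=st.floats(1, 2),
        alpha=st.floats(0.05, 1.0), alpha_boost=st.floats(1, 3),
    )
    def test_monotone_in_displacements_and_alpha(self, dh, dc, scale_h, scale_c, alpha, alpha_boost):
        """csp_hsqc never decreases when |dH|, |dC| or alpha grows."""
        base = _hsqc_peak(52.0, 4.2)
        v = csp_hsqc(base, _hsqc_peak(52.0 + dc, 4.2 + dh), alpha)
        assert csp_hsqc(base, _hsqc_peak(52.0 + dc * scale_c, 4.2 + dh), alpha) >= v - 1e-15
        assert csp_hsqc(base, _hsqc_peak(52.0 + dc, 4.2 + dh * scale_h), alpha) >= v - 1e-15
        assert csp_hsqc(base, _hsqc_peak(52.0 + dc, 4.2 + dh), alpha * alpha_boost) >= v - 1e-15


class TestGrouping:
    @pytest.mark.parametrize(
        "atoms, spectrum, expected",
        [
            (("CA", "HA"), "HSQC", SignalGroup.CA_HA),
            (("CB", "HB"), "HSQC", SignalGroup.CB_HB),
            (("CG", "HG"), "HSQC", SignalGroup.CG_HG),
            (("CE", "HE"), "HSQC", SignalGroup.CH3),
            (("H", "HA"), "TOCSY", SignalGroup.TOCSY_NH_HA),
            (("HA", "HB"), "TOCSY", SignalGroup.TOCSY_OTHER),
        ],
    )
    def test_atom_names_determine_group(self, atoms, spectrum, expected):
        from silbind.core_io import SpectrumType

        a = Assignment(7, "M", *atoms)
        assert classify_group(a, SpectrumType.coerce(spectrum)) is expected


def _two_point_series(sequence, displacements):
    """Series with given per-residue (d_f1, d_f2) between ratio 0 and 10."""
    start, end = [], []
    for local, (d1, d2) in displacements.items():
        a = Assignment(local, sequence.residue_type(local), "H", "HA")
        start.append(Peak2D(a, 8.0, 4.2))
        end.append(Peak2D(a, 8.0 + d1, 4.2 + d2))
    return TitrationSeries(
        sequence,
        [PeakList("TOCSY", 0.0, start), PeakList("TOCSY", 10.0, end)],
    )


class TestComputeCSPTable:
    def test_matches_hand_computed_displacements(self, sp2_sequence):
        displacements = {1: (0.03, 0.04), 2: (0.0, 0.1), 3: (0.0, 0.0)}
        series = _two_point_series(sp2_sequence, displacements)
        records = compute_csp_table(series, CSPConfig())
        by_res = {r.assignment.residue_index: r.csp for r in records}
        assert by_res[1] == pytest.approx(0.05, abs=1e-12)
        assert by_res[2] == pytest.approx(0.1, abs=1e-12)
        assert by_res[3] == 0.0

    def test_identical_endpoint_gives_all_zero(self, sp2_sequence):
        series = _two_point_series(sp2_sequence, {1: (0, 0), 2: (0, 0)})
        assert all(r.csp == 0.0 for r in compute_csp_table(series))

    def test_missing_endpoint_marks_record_missing(self, sp2_sequence):
        a1 = Assignment(1, "A", "H", "HA")
        a2 = Assignment(2, "D", "H", "HA")
        series = TitrationSeries(
            sp2_sequence,
            [
                PeakList("TOCSY", 0.0, [Peak2D(a1, 8.0, 4.2), Peak2D(a2, 8.3, 4.4)]),
                PeakList("TOCSY", 10.0, [Peak2D(a1, 8.1, 4.3)]),
            ],
        )
        records = compute_csp_table(series)
        by_res = {r.assignment.residue_index: r for r in records}
        assert by_res[2].mover_class is MoverClass.MISSING
        assert math.isnan(by_res[2].csp)
        assert by_res[1].mover_class is None

    def test_absent_ratio_reports_available(self, sp2_sequence):
        series = _two_point_series(sp2_sequence, {1: (0.1, 0.1)})
        with pytest.raises(ValidationError, match=r"available.*0\.0.*10\.0"):
            compute_csp_table(series, CSPConfig(endpoint_ratio=3.0))


class TestGroupStats:
    def _records(self, values, group=SignalGroup.TOCSY_NH_HA):
        return [
            CSPRecord(Assignment(i + 1, "A", "H", "HA"), v, group)
            for i, v in enumerate(values)
        ]

    def test_equal_values_have_zero_sigma(self):
        (s,) = group_stats(self._records([0.1, 0.1]))
        assert (s.mean, s.sigma, s.n) == (pytest.approx(0.1), 0.0, 2)

    def test_population_sigma_hand_value(self):
        (s,) = group_stats(self._records([0.0, 0.2]))
        assert s.mean == pytest.approx(0.1)
        assert s.sigma == pytest.approx(0.1)  # population convention

    def test_sample_sigma_option(self):
        (s,) = group_stats(self._records([0.0, 0.2]), population_sigma=False)
        assert s.sigma == pytest.approx(0.2 / math.sqrt(2))

    def test_all_missing_group_omitted(self):
        records = [
            CSPRecord(A_NH, math.nan, SignalGroup.TOCSY_NH_HA, MoverClass.MISSING)
        ]
        assert group_stats(records) == []


class TestClassifyMovers:
    def _classified(self, values):
        records = [
            CSPRecord(Assignment(i + 1, "A", "H", "HA"), v, SignalGroup.TOCSY_NH_HA)
            for i, v in enumerate(values)
        ]
        stats = group_stats(records)
        return classify_movers(records, stats)

    def test_two_sigma_above_mean_is_strong(self):
        values = [0.0, 0.1, 0.1, 0.1, 0.5]  # last sits far above mean + sigma
        out = self._classified(values)
        mu = sum(values) / len(values)
        sigma = (sum((v - mu) ** 2 for v in values) / len(values)) ** 0.5
        assert values[-1] >= mu + sigma
        assert out[-1].mover_class is MoverClass.STRONG

    def test_zero_in_positive_group_is_weak(self):
        out = self._classified([0.0, 0.1, 0.2])
        assert out[0].mover_class is MoverClass.WEAK

    def test_degenerate_group_all_at_mean_is_medium(self):
        out = self._classified([0.1, 0.1, 0.1])
        assert all(r.mover_class is MoverClass.MEDIUM for r in out)

    def test_classes_partition_each_group(self, sp2_sequence):
        displacements = {i: (0.01 * i, 0.005 * i) for i in range(1, 11)}
        series = _two_point_series(sp2_sequence, displacements)
        records, stats = csp_analysis(series)
        for s in stats:
            classed = [r for r in records if r.group is s.group
                       and r.mover_class is not MoverClass.MISSING]
            assert len(classed) == s.n
            assert all(
                r.mover_class in (MoverClass.WEAK, MoverClass.MEDIUM, MoverClass.STRONG)
                for r in classed
            )

    def test_single_perturbed_residue_is_unique_strong_mover(self, sp2_sequence):
        displacements = {i: (0.0, 0.0) for i in range(1, 11)}
        displacements[7] = (0.08, 0.06)  # only the methionine moves
        series = _two_point_series(sp2_sequence, displacements)
        records, _ = csp_analysis(series)
        strong = [r for r in records if r.mover_class is MoverClass.STRONG]
        assert [r.assignment.residue_index for r in strong] == [7]
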