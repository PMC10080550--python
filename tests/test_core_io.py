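"""Peak-list and centroid-list I/O: parsing, validation, round trips."""

import math

import pytest

from silbind import (
    Assignment,
    MSSpectrum,
    Peak2D,
    PeakList,
    PeptideSequence,
    SpectrumType,
    TitrationSeries,
    read_ms_spectrum,
    read_peaklist,
    read_series,
    write_peaklist,
)
from silbind.core_io import ParseError, ValidationError

PEAKLIST_TEXT = """residue_index\tresidue_type\tatom_f1\tatom_f2\tf1_ppm\tf2_ppm
1\tA\tH\tHA\t8.123456\t4.251234
4\tH\tH\tHA\t8.501000\t4.432100
7\tM\tH\tHG\t8.020000\t2.110000
"""


@pytest.fixture
def peaklist_file(tmp_path):
    path = tmp_path / "peaks.tsv"
    path.write_text(PEAKLIST_TEXT)
    return path


class TestPeptideSequence:
    def test_rejects_empty_and_unknown_letters(self):
        with pytest.raises(ValidationError):
            PeptideSequence("")
        with pytest.raises(ValidationError):
            PeptideSequence("ADXB")

    def test_protein_numbering_and_labels(self, sp2_sequence):
        # residue 11 of the peptide is His87 of the parent protein
        assert sp2_sequence.protein_index(11) == 87
        assert sp2_sequence.label(11) == "87His"
        assert sp2_sequence.local_index(87) == 11
        assert sp2_sequence.residue_type(11) == "H"


class TestReadPeaklist:
    def test_well_formed_file(self, peaklist_file):
        pl = read_peaklist(peaklist_file, "TOCSY", 0.0)
        assert len(pl.peaks) == 3
        assert pl.peaks[0].f1_ppm == pytest.approx(8.123456)
        assert all(p.present for p in pl.peaks)

    def test_blank_shift_becomes_absent_peak(self, tmp_path):
        path = tmp_path / "gap.tsv"
        path.write_text(
            "residue_index\tresidue_type\tatom_f1\tatom_f2\tf1_ppm\tf2_ppm\n"
            "1\tA\tH\tHA\t\t4.25\n"
            "2\tD\tH\tHA\t8.3\t4.4\n"
        )
        pl = read_peaklist(path, "TOCSY", 0.0)
        assert not pl.peaks[0].present
        assert pl.peaks[1].present

    def test_duplicate_assignment_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "residue_index\tresidue_type\tatom_f1\tatom_f2\tf1_ppm\tf2_ppm\n"
            "1\tA\tH\tHA\t8.1\t4.2\n"
            "1\tA\tH\tHA\t8.2\t4.3\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_peaklist(path, "TOCSY", 0.0)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "residue_index\tresidue_type\tatom_f1\tatom_f2\tf1_ppm\tf2_ppm\n"
            "1\tA\tH\tHA\t8.1\t4.2\n"
            "oops\tA\tH\tHA\t8.1\t4.2\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_peaklist(path, "TOCSY", 0.0)

    def test_round_trip_preserves_values(self, peaklist_file, tmp_path):
        pl = read_peaklist(peaklist_file, "TOCSY", 0.5)
        out = tmp_path / "out.tsv"
        write_peaklist(pl, out)
        again = read_peaklist(out, "TOCSY", 0.5)
        for a, b in zip(pl.peaks, again.peaks):
            assert a.assignment == b.assignment
            assert a.f1_ppm == pytest.approx(b.f1_ppm, abs=1e-6)
            assert a.f2_ppm == pytest.approx(b.f2_ppm, abs=1e-6)

    def test_round_trip_keeps_missing_peaks(self, tmp_path):
        a = Assignment(1, "A", "H", "HA")
        pl = PeakList("TOCSY", 0.0, [Peak2D(a, present=False)])
        out = tmp_path / "missing.tsv"
        write_peaklist(pl, out)
        again = read_peaklist(out, "TOCSY", 0.0)
        assert not again.peaks[0].present


class TestValidation:
    def test_present_peak_needs_finite_shifts(self):
        a = Assignment(1, "A", "H", "HA")
        with pytest.raises(ValidationError):
            Peak2D(a, math.nan, 4.2, present=True)

    def test_shift_windows_depend_on_spectrum_type(self):
        a = Assignment(1, "A", "CA", "HA")
        # 52 ppm is fine on a carbon F1 axis but absurd for a proton
        PeakList("HSQC", 0.0, [Peak2D(a, 52.0, 4.2)])
        b = Assignment(1, "A", "H", "HA")
        with pytest.raises(ValidationError, match="window"):
            PeakList("TOCSY", 0.0, [Peak2D(b, 52.0, 4.2)])

    def test_atom_vocabulary(self):
        with pytest.raises(ValidationError, match="vocabulary"):
            Assignment(1, "A", "H", "QX7")


class TestSeries:
    def _lists(self, ratios):
        a = Assignment(1, "A", "H", "HA")
        return [PeakList("TOCSY", r, [Peak2D(a, 8.0 + r / 100, 4.2)]) for r in ratios]

    def test_points_sorted_by_ratio(self, sp2_sequence):
        series = TitrationSeries(sp2_sequence, self._lists([0.5, 0.0]))
        assert series.ratios == [0.0, 0.5]

    def test_ordering_stable_under_permutation(self, sp2_sequence):
        s1 = TitrationSeries(sp2_sequence, self._lists([0.0, 0.1, 0.5]))
        s2 = TitrationSeries(sp2_sequence, self._lists([0.5, 0.0, 0.1]))
        assert s1.ratios == s2.ratios
        for p1, p2 in zip(s1.points, s2.points):
            assert [pk.f1_ppm for pk in p1.peaks] == [pk.f1_ppm for pk in p2.peaks]

    def test_five_point_study_design(self, sp2_sequence):
        series = TitrationSeries(sp2_sequence, self._lists([0.0, 0.1, 0.5, 3.0, 10.0]))
        assert series.ratios == [0.0, 0.1, 0.5, 3.0, 10.0]

    def test_mixed_spectrum_types_rejected(self, sp2_sequence):
        a = Assignment(1, "A", "H", "HA")
        b = Assignment(1, "A", "CA", "HA")
        lists = [
            PeakList("TOCSY", 0.0, [Peak2D(a, 8.0, 4.2)]),
            PeakList("HSQC", 1.0, [Peak2D(b, 52.0, 4.2)]),
        ]
        with pytest.raises(ValidationError, match="mixed"):
            TitrationSeries(sp2_sequence, lists)

    def test_duplicate_ratios_rejected(self, sp2_sequence):
        with pytest.raises(ValidationError, match="non-unique"):
            TitrationSeries(sp2_sequence, self._lists([0.0, 0.0]))

    def test_union_reconciliation_flags_missing(self, sp2_sequence):
        a = Assignment(1, "A", "H", "HA")
        b = Assignment(4, "H", "H", "HA")
        lists = [
            PeakList("TOCSY", 0.0, [Peak2D(a, 8.0, 4.2), Peak2D(b, 8.4, 4.5)]),
            PeakList("TOCSY", 1.0, [Peak2D(a, 8.1, 4.3)]),  # b disappears
        ]
        series = TitrationSeries(sp2_sequence, lists)
        peak = series.points[1].peak(b)
        assert peak is not None and not peak.present

    def test_read_series_sorts_files(self, peaklist_file, tmp_path, sp2_sequence):
        second = tmp_path / "p2.tsv"
        second.write_text(PEAKLIST_TEXT)
        series = read_series([second, peaklist_file], [10.0, 0.0], "TOCSY", sp2_sequence)
        assert series.ratios == [0.0, 10.0]


class TestMSSpectrumIO:
    def test_reads_two_column_centroids(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("mz,area\n" + "\n".join(f"{500 + i},{10 * i + 1}" for i in range(10)))
        spectrum = read_ms_spectrum(path, 100.0, 50.0)
        assert len(spectrum.peaks) == 10
        assert spectrum.ratio == pytest.approx(0.5)

    def test_empty_file_gives_empty_spectrum(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_ms_spectrum(path, 100.0, 0.0).peaks == []

    def test_negative_area_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("500.0,-5\n")
        with pytest.raises(ValidationError, match="area"):
            read_ms_spectrum(path, 100.0, 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            MSSpectrum(-1.0, 0.0, [])
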