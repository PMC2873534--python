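import numpy as np
import pandas as pd
import pytest

from cnapeel import (
    ArmTable,
    MarkerGrid,
    PeakRegion,
    assign_arms,
    project_segments,
    read_marker_matrix,
    read_peak_report,
    read_seg,
    segments_from_matrix,
    write_igv_tracks,
    write_marker_matrix,
    write_peak_report,
)
from cnapeel.genome_io import (
    DuplicateMarkerError,
    ArmAssignmentError,
    OverlappingSegmentError,
    SegmentSet,
    UnsortedMarkerError,
)
from conftest import make_matrix


def _write(path, text):
    path.write_text(text)
    return path


MATRIX_3x2 = (
    "marker\tchrom\tpos\tS1\tS2\n"
    "m1\tchr1\t100\t0.5\t-0.2\n"
    "m2\tchr1\t200\tNA\t0.1\n"
    "m3\tchr2\t50\t0.0\t0.3\n"
)


class TestMarkerMatrix:
    def test_well_formed_round_trip(self, tmp_path):
        m = read_marker_matrix(_write(tmp_path / "m.tsv", MATRIX_3x2))
        assert m.values.shape == (3, 2)
        assert m.samples == ("S1", "S2")
        assert list(m.grid.chrom) == ["1", "1", "2"]  # chr prefix stripped
        write_marker_matrix(m, tmp_path / "rt.tsv")
        m2 = read_marker_matrix(tmp_path / "rt.tsv")
        np.testing.assert_array_equal(m.values, m2.values)
        np.testing.assert_array_equal(m.grid.pos, m2.grid.pos)

    def test_na_cell_becomes_missing(self, tmp_path):
        m = read_marker_matrix(_write(tmp_path / "m.tsv", MATRIX_3x2))
        assert np.isnan(m.values[1, 0]) and not np.isnan(m.values[1, 1])

    def test_duplicate_marker_rejected_by_name(self, tmp_path):
        text = MATRIX_3x2.replace("m3", "m1")
        with pytest.raises(DuplicateMarkerError, match="m1"):
            read_marker_matrix(_write(tmp_path / "m.tsv", text))

    def test_unsorted_positions_sorted_or_rejected(self, tmp_path):
        lines = MATRIX_3x2.splitlines()
        swapped = "\n".join([lines[0], lines[2], lines[1], lines[3]]) + "\n"
        path = _write(tmp_path / "m.tsv", swapped)
        m = read_marker_matrix(path, on_unsorted="sort")
        assert list(m.grid.pos[:2]) == [100, 200]
        with pytest.raises(UnsortedMarkerError):
            read_marker_matrix(path, on_unsorted="error")


SEG = (
    "sample\tchrom\tstart\tend\tvalue\n"
    "S1\tchr1\t100\t200\t0.5\n"
    "S1\tchr1\t201\t300\t-0.1\n"
)


class TestSeg:
    def test_projection_containment_and_missing(self, tmp_path):
        segs = read_seg(_write(tmp_path / "s.seg", SEG))
        grid = MarkerGrid(
            names=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([150, 400], dtype=np.int64),
        )
        m = project_segments(segs, grid)
        assert m.values[0, 0] == 0.5
        assert np.isnan(m.values[1, 0])

    def test_abutting_boundary_convention(self, tmp_path):
        segs = read_seg(_write(tmp_path / "s.seg", SEG))
        grid = MarkerGrid(
            names=np.array(["a", "b"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([200, 201], dtype=np.int64),
        )
        m = project_segments(segs, grid)
        assert m.values[0, 0] == 0.5 and m.values[1, 0] == -0.1

    def test_overlapping_segments_rejected(self, tmp_path):
        text = SEG.replace("201\t300", "150\t250")
        with pytest.raises(OverlappingSegmentError, match="S1"):
            read_seg(_write(tmp_path / "s.seg", text))

    def test_headerless_six_column_dialect(self, tmp_path):
        text = "S1\t1\t100\t200\t11\t0.5\n"
        segs = read_seg(_write(tmp_path / "s.seg", text))
        assert segs.records.loc[0, "num_markers"] == 11

    def test_projection_inverts_segmentation(self, small_grid):
        rng = np.random.default_rng(0)
        values = rng.choice([0.0, 0.5, -0.3], size=(10, 3))
        m = make_matrix(values, small_grid)
        back = project_segments(segments_from_matrix(m), small_grid)
        np.testing.assert_allclose(back.values, m.values)


class TestArms:
    def test_gap_markers_dropped(self, small_grid):
        arms = ArmTable(records=pd.DataFrame(
            [("1", "p", 1, 3500), ("1", "q", 5500, 10_000)],
            columns=["chrom", "arm", "start", "end"],
        ))
        m = make_matrix(np.zeros((10, 2)), small_grid)
        out = assign_arms(m, arms)
        # markers at 4001 and 5001 fall in the centromere gap
        assert out.n_markers == 8
        assert set(out.grid.arm) == {"p", "q"}

    def test_chromosome_without_arms_rejected(self, two_chrom_grid):
        arms = ArmTable(records=pd.DataFrame(
            [("1", "p", 1, 4500), ("1", "q", 4501, 10_000)],
            columns=["chrom", "arm", "start", "end"],
        ))
        m = make_matrix(np.zeros((20, 2)), two_chrom_grid)
        with pytest.raises(ArmAssignmentError, match="2"):
            assign_arms(m, arms)

    def test_unordered_arm_intervals_rejected(self):
        with pytest.raises(Exception, match="disjoint"):
            ArmTable(records=pd.DataFrame(
                [("1", "p", 1, 6000), ("1", "q", 4501, 10_000)],
                columns=["chrom", "arm", "start", "end"],
            ))


def _peak(first=2, last=5, start=2001, end=5001, chrom="1", order=1):
    return PeakRegion(
        direction="amp", chrom=chrom, first=first, last=last, start=start,
        end=end, peak_marker=first, q_value=0.01, order=order, variant="standard",
    )


class TestReports:
    def test_peak_report_round_trip(self, tmp_path, small_grid, gene_table):
        peaks = [_peak(), _peak(first=6, last=6, start=6001, end=6001, order=2)]
        write_peak_report(peaks, gene_table, tmp_path / "p.tsv", grid=small_grid)
        df = read_peak_report(tmp_path / "p.tsv")
        assert len(df) == 2
        assert df.loc[0, "genes"] == "GENE_A"  # 2000-3000 inside 2001-5001
        assert df.loc[1, "genes"] == ""  # no gene at 6001, row still present
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (2001, 5001)

    def test_igv_and_bed_tracks(self, tmp_path, small_grid):
        scores = np.arange(10, dtype=float)
        peak = _peak(start=100, end=200)
        igv, bed = write_igv_tracks(scores, [peak], small_grid, tmp_path / "out")
        igv_rows = igv.read_text().strip().splitlines()
        assert len(igv_rows) == 11  # header + one row per marker
        bed_rows = bed.read_text().strip().splitlines()
        assert bed_rows[1].split("\t")[1:3] == ["99", "200"]  # 0-based half-open

    def test_empty_peak_list_gives_header_only_bed(self, tmp_path, small_grid):
        _, bed = write_igv_tracks(np.zeros(10), [], small_grid, tmp_path / "out")
        lines = bed.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")


def test_segmentset_rejects_inverted_interval():
    df = pd.DataFrame(
        [("S1", "1", 300, 200, 0.5)],
        columns=["sample", "chrom", "start", "end", "value"],
    )
    with pytest.raises(Exception, match="start > end"):
        SegmentSet(records=df)
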