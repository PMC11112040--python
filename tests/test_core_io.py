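"""Container invariants, parsers, coverage conversion."""

import numpy as np
import pytest

from cutrunkit import core_io
from cutrunkit.core_io import (CoverageTrack, FormatError, GenomicInterval,
                               fragments_to_coverage, parse_bedgraph,
                               parse_fragments, parse_peaks,
                               parse_sample_sheet, write_bedgraph,
                               write_fragments, write_narrowpeak)

from conftest import make_frags, make_peaks


class TestGenomicInterval:
    @pytest.mark.parametrize("chrom,start,end", [
        ("chr1", 100, 100), ("chr1", 300, 200), ("chr1", -1, 50), ("", 0, 10)])
    def test_rejects_invalid(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_length_and_overlap_are_half_open(self):
        a = GenomicInterval("chr1", 100, 250)
        assert len(a) == 150
        assert a.overlap(GenomicInterval("chr1", 250, 300)) == 0  # touching
        assert a.overlap(GenomicInterval("chr1", 200, 300)) == 50
        assert a.overlap(GenomicInterval("chr2", 100, 250)) == 0


class TestFragmentParsing:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chr1\t100\t250\n")
        fs = parse_fragments(p, "s1")
        assert len(fs) == 1
        f = fs.fragments[0]
        assert (f.chrom, f.start, f.end, len(f)) == ("chr1", 100, 250, 150)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("")
        assert len(parse_fragments(p, "s1")) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("# header\nchr1\t300\t200\n")
        with pytest.raises(FormatError) as exc:
            parse_fragments(p, "s1")
        assert exc.value.line == 2

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("track name=x\nbrowser pos\n# c\nchr1\t0\t10\n")
        assert len(parse_fragments(p, "s1")) == 1

    def test_round_trip_identity(self, tmp_path, rng):
        frags = make_frags([("chr1", int(s), int(s) + int(l))
                            for s, l in zip(rng.integers(0, 10_000, 50),
                                            rng.integers(1, 500, 50))])
        path = tmp_path / "rt.bed"
        write_fragments(frags, path)
        back = parse_fragments(path, "s")
        assert [(f.chrom, f.start, f.end) for f in back.fragments] == \
            [(f.chrom, f.start, f.end) for f in frags.fragments]


class TestPeakParsing:
    def test_narrowpeak_summit_and_score(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t300\tpk\t0\t.\t7.5\t-1\t-1\t50\n")
        ps = parse_peaks(p)
        assert ps.peaks[0].summit == 50 and ps.peaks[0].score == 7.5

    def test_bed3_defaults(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t300\n")
        pk = parse_peaks(p).peaks[0]
        assert pk.score == 0.0 and pk.summit is None

    def test_summit_outside_interval_rejected(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t300\tpk\t0\t.\t1\t-1\t-1\t250\n")
        with pytest.raises(FormatError):
            parse_peaks(p)

    def test_round_trip_identity(self, tmp_path, rng):
        peaks = make_peaks([("chr1", 100, 300), ("chr1", 500, 900)],
                           scores=[1.25, 1 / 3])
        peaks.peaks[0].summit = 42
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path, header="# test")
        back = parse_peaks(path)
        for a, b in zip(peaks, back):
            assert (a.interval, a.score, a.summit, a.name) == \
                (b.interval, b.score, b.summit, b.name)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t0\t10\tsame\nchr1\t20\t30\tsame\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_peaks(p)


class TestBedGraph:
    def test_constant_segment(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = parse_bedgraph(p, bin_size=50)
        assert track.values["chr1"].tolist() == [2.0, 2.0]

    def test_length_weighted_mean(self, tmp_path):
        p = tmp_path / "m.bedgraph"
        p.write_text("chr1\t0\t50\t1.0\nchr1\t50\t100\t3.0\n")
        track = parse_bedgraph(p, bin_size=100)
        assert track.values["chr1"].tolist() == [2.0]

    def test_overlapping_segments_rejected(self, tmp_path):
        p = tmp_path / "o.bedgraph"
        p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(FormatError, match="overlap"):
            parse_bedgraph(p)

    def test_random_segments_match_per_base_oracle(self, tmp_path, rng):
        size, bin_size = 5_000, 25
        edges = np.sort(rng.choice(np.arange(1, size), size=400, replace=False))
        edges = np.concatenate([[0], edges, [size]])
        segs = []
        for s, e in zip(edges[:-1], edges[1:]):
            if rng.random() < 0.5:  # leave gaps
                segs.append((int(s), int(e), float(rng.integers(1, 10))))
        lines = "".join(f"chr1\t{s}\t{e}\t{v}\n" for s, e, v in segs)
        p = tmp_path / "r.bedgraph"
        p.write_text(lines)
        track = parse_bedgraph(p, bin_size=bin_size, chrom_sizes={"chr1": size})
        base = np.zeros(size)
        for s, e, v in segs:
            base[s:e] = v
        oracle = base.reshape(-1, bin_size).mean(axis=1)
        np.testing.assert_allclose(track.values["chr1"], oracle, rtol=0, atol=1e-12)

    def test_round_trip_preserves_binned_values(self, tmp_path, rng):
        size, bin_size = 2_000, 10
        vals = rng.random(size // bin_size) * rng.integers(0, 2, size // bin_size)
        track = CoverageTrack(chrom_sizes={"chr1": size}, bin_size=bin_size,
                              values={"chr1": vals})
        path = tmp_path / "rt.bedgraph"
        write_bedgraph(track, path, header="# test")
        back = parse_bedgraph(path, bin_size=bin_size, chrom_sizes={"chr1": size})
        np.testing.assert_array_equal(back.values["chr1"], track.values["chr1"])


class TestSampleSheet:
    HEADER = "sample_id\trole\treplicate_group\ttarget_bed\tspikein_bed\tcontrol\n"

    def test_experiment_control_link(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text(self.HEADER +
                     "e1\texperiment\tA\te1.bed\te1s.bed\tc1\n"
                     "c1\tcontrol\tctrl\tc1.bed\tc1s.bed\t\n")
        sheet = parse_sample_sheet(p)
        assert sheet.control_of("e1").sample_id == "c1"

    @pytest.mark.parametrize("rows,msg", [
        ("e1\texperiment\tA\ta\tb\t\ne1\texperiment\tA\tc\td\t\n", "duplicate"),
        ("e1\texperiment\tA\ta\tb\tmissing\n", "not in sheet"),
        ("e1\tbogus\tA\ta\tb\t\n", "unknown role"),
    ])
    def test_invalid_sheets_rejected(self, tmp_path, rows, msg):
        p = tmp_path / "sheet.tsv"
        p.write_text(self.HEADER + rows)
        with pytest.raises(FormatError, match=msg):
            parse_sample_sheet(p)


class TestFragmentsToCoverage:
    def test_full_and_split_overlap(self):
        frags = make_frags([("chr1", 0, 100)])
        t = fragments_to_coverage(frags, {"chr1": 100}, bin_size=100)
        assert t.values["chr1"].tolist() == [1.0]
        frags = make_frags([("chr1", 50, 150)])
        t = fragments_to_coverage(frags, {"chr1": 200}, bin_size=100)
        assert t.values["chr1"].tolist() == [0.5, 0.5]

    def test_fragment_beyond_chrom_end_rejected(self):
        with pytest.raises(ValueError, match="beyond chrom end"):
            fragments_to_coverage(make_frags([("chr1", 50, 150)]),
                                  {"chr1": 120}, 10)

    def test_matches_per_base_oracle_and_conserves_mass(self, rng):
        size, bin_size, n = 100_000, 10, 1000
        ivs = []
        for _ in range(n):
            length = int(rng.integers(30, 400))
            start = int(rng.integers(0, size - length))
            ivs.append(("chr1", start, start + length))
        frags = make_frags(ivs)
        track = fragments_to_coverage(frags, {"chr1": size}, bin_size)
        base = np.zeros(size)
        for _, s, e in ivs:
            base[s:e] += 1
        oracle = base.reshape(-1, bin_size).mean(axis=1)
        np.testing.assert_allclose(track.values["chr1"], oracle, atol=1e-9)
        total_bp = sum(e - s for _, s, e in ivs)
        assert track.values["chr1"].sum() * bin_size == pytest.approx(total_bp)
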