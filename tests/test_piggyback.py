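"""PWM scanning, background regions, motif enrichment, candidate ranking."""

import numpy as np
import pytest
from scipy.special import comb

from cutrunkit.piggyback import (PWM, attach_proteins, base_frequencies,
                                 extract_peak_sequences,
                                 generate_background_regions, motif_enrichment,
                                 parse_ms_table, parse_motif_protein_map,
                                 parse_pwms, piggyback_candidates, scan_pwm,
                                 write_pwms)
from cutrunkit.simulate import consensus_pwm

from conftest import make_peaks

UNIFORM = np.full(4, 0.25)


def single_base_pwm(base="A", major=0.97):
    row = np.full(4, (1 - major) / 3)
    row["ACGT".index(base)] = major
    return PWM("m1", row.reshape(1, 4))


class TestScanning:
    def test_length_one_pwm_forward_hits_only(self):
        hits = scan_pwm({"s": "AAAA"}, single_base_pwm("A"), UNIFORM,
                        threshold=0.0)
        assert len(hits) == 4
        assert all(h.strand == "+" for h in hits)

    def test_hand_computed_log_odds(self):
        matrix = np.array([[0.7, 0.1, 0.1, 0.1],
                           [0.1, 0.6, 0.2, 0.1],
                           [0.2, 0.1, 0.6, 0.1],
                           [0.1, 0.1, 0.1, 0.7]])
        pwm = PWM("toy", matrix)
        hits = scan_pwm({"s": "ACGT"}, pwm, UNIFORM, threshold=-100.0)
        fwd = [h for h in hits if h.strand == "+"][0]
        expected = sum(np.log2(v / 0.25) for v in (0.7, 0.6, 0.6, 0.7))
        assert fwd.score == pytest.approx(expected, abs=1e-12)

    def test_palindrome_scores_both_strands_equally(self):
        pwm = PWM("pal", consensus_pwm("ACGT", 0.85))  # revcomp(ACGT)=ACGT
        hits = scan_pwm({"s": "TTACGTTT"}, pwm, UNIFORM, threshold=-100.0)
        by_strand = {s: sorted((h.offset, round(h.score, 9)) for h in hits
                               if h.strand == s) for s in "+-"}
        assert by_strand["+"] == by_strand["-"]

    def test_n_windows_skipped(self):
        hits = scan_pwm({"s": "AANA"}, single_base_pwm("A"), UNIFORM,
                        threshold=0.0)
        assert sorted(h.offset for h in hits) == [0, 1, 3]

    def test_pwm_longer_than_sequence_no_hits(self):
        pwm = PWM("long", consensus_pwm("ACGTACGT"))
        assert scan_pwm({"s": "ACG"}, pwm, UNIFORM, threshold=-100.0) == []

    def test_matches_brute_force_on_short_sequences(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        pwm = PWM("m", consensus_pwm("ACGTT", 0.7))
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 50))))
            hits = scan_pwm({"s": seq}, pwm, UNIFORM, threshold=-1e9)
            got = {(h.offset, h.strand): h.score for h in hits}
            L = len(pwm)
            for off in range(len(seq) - L + 1):
                fwd = sum(np.log2(pwm.matrix[j, "ACGT".index(seq[off + j])]
                                  / 0.25) for j in range(L))
                window_rc = "".join(comp[c] for c in seq[off:off + L][::-1])
                rev = sum(np.log2(pwm.matrix[j, "ACGT".index(window_rc[j])]
                                  / 0.25) for j in range(L))
                assert got[(off, "+")] == pytest.approx(fwd, abs=1e-9)
                assert got[(off, "-")] == pytest.approx(rev, abs=1e-9)

    def test_reverse_complemented_input_preserves_region_hits(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        pwm = PWM("m", consensus_pwm("ACGTAC", 0.8))
        seqs = {f"r{i}": "".join(rng.choice(list("ACGT"), size=60))
                for i in range(20)}
        rc = {k: "".join(comp[c] for c in v[::-1]) for k, v in seqs.items()}
        thr = 0.8 * pwm.max_score(UNIFORM)
        regions_fwd = {h.region for h in scan_pwm(seqs, pwm, UNIFORM, thr)}
        regions_rc = {h.region for h in scan_pwm(rc, pwm, UNIFORM, thr)}
        assert regions_fwd == regions_rc


class TestPWMIO:
    def test_round_trip(self, tmp_path):
        pwms = [PWM("m1", consensus_pwm("ACGTA")),
                PWM("m2", consensus_pwm("TTTTGGGG"))]
        path = tmp_path / "motifs.txt"
        write_pwms(pwms, path)
        back = parse_pwms(path)
        assert [p.motif_id for p in back] == ["m1", "m2"]
        np.testing.assert_allclose(back[0].matrix, pwms[0].matrix, atol=1e-6)

    def test_invalid_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("MOTIF m1\n0.5 0.5 0.5 0.5\n" * 4)
        with pytest.raises(ValueError):
            parse_pwms(path)

    def test_maps_parse(self, tmp_path):
        mp = tmp_path / "map.tsv"
        mp.write_text("motif_id\tprotein_id\nm1\tP1\nm1\tP2\n")
        assert parse_motif_protein_map(mp) == {"m1": ["P1", "P2"]}
        ms = tmp_path / "ms.tsv"
        ms.write_text("protein_id\tabundance\nP1\t12.5\n")
        assert parse_ms_table(ms) == {"P1": 12.5}


class TestBackgroundRegions:
    def test_length_matched_and_disjoint(self, rng):
        peaks = make_peaks([("chr1", int(s), int(s) + 200)
                            for s in np.arange(100) * 10_000 + 4000])
        bg = generate_background_regions(peaks, {"chr1": 1_000_000}, seed=3)
        assert len(bg) == len(peaks)
        for b in bg:
            assert len(b.interval) == 200
            for p in peaks:
                assert b.interval.overlap(p.interval) == 0

    def test_deterministic_given_seed(self):
        peaks = make_peaks([("chr1", 1000, 1200)])
        a = generate_background_regions(peaks, {"chr1": 100_000}, seed=5)
        b = generate_background_regions(peaks, {"chr1": 100_000}, seed=5)
        assert a.peaks[0].interval == b.peaks[0].interval

    def test_impossible_placement_errors(self):
        peaks = make_peaks([("chr1", 0, 900)])
        with pytest.raises(RuntimeError, match="attempts"):
            generate_background_regions(peaks, {"chr1": 1000}, seed=1)


def hypergeom_tail_oracle(k, n, k_bg, n_bg):
    """P(X >= k) for X ~ Hypergeom(N=n+n_bg, K=k+k_bg, draws=n), by direct
    combinatorial summation."""
    N, K = n + n_bg, k + k_bg
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i, exact=True) * comb(N - K, n - i, exact=True)
    return total / comb(N, n, exact=True)


class TestEnrichment:
    def hits(self, motif, regions):
        from cutrunkit.piggyback import MotifHit
        return [MotifHit(motif, r, 0, "+", 5.0) for r in regions]

    def test_no_enrichment_when_rates_equal(self):
        df = motif_enrichment(self.hits("m", [f"p{i}" for i in range(10)]),
                              self.hits("m", [f"b{i}" for i in range(10)]),
                              100, 100)
        assert df["p"][0] > 0.5
        assert df["odds_ratio"][0] == pytest.approx(1.0)

    def test_matches_exact_hypergeometric_oracle(self):
        df = motif_enrichment(self.hits("m", [f"p{i}" for i in range(30)]),
                              self.hits("m", [f"b{i}" for i in range(5)]),
                              100, 100)
        assert df["p"][0] == pytest.approx(hypergeom_tail_oracle(30, 100, 5, 100),
                                           abs=1e-10)

    def test_zero_hits_p_is_one(self):
        df = motif_enrichment([], self.hits("m", ["b1"]), 50, 50,
                              motif_ids=["m"])
        assert df["p"][0] == pytest.approx(1.0)

    def test_region_level_counting(self):
        # many hits in one region still count once
        hits = self.hits("m", ["p1"] * 5)
        df = motif_enrichment(hits, [], 10, 10, motif_ids=["m"])
        assert df["k"][0] == 1


class TestCandidates:
    def enr(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["motif_id", "q"])

    def pwms(self):
        out = [PWM("m1", consensus_pwm("ACGTA"), proteins=["X"]),
               PWM("m2", consensus_pwm("TGCAT"), proteins=["Y"])]
        return out

    def test_empty_ms_table_no_candidates(self):
        cands, _ = piggyback_candidates(
            self.enr([("m1", 0.001)]), self.pwms(), {}, 0.05)
        assert cands.empty

    def test_enriched_motif_protein_ranked_first(self):
        cands, no_motif = piggyback_candidates(
            self.enr([("m1", 0.001), ("m2", 0.5)]), self.pwms(),
            {"X": 10.0, "Z": 3.0}, 0.05)
        assert cands["protein_id"].tolist() == ["X"]
        assert cands["rank"].tolist() == [1]
        assert no_motif == ["Z"]

    def test_bait_motif_excluded(self):
        cands, _ = piggyback_candidates(
            self.enr([("m1", 0.001), ("m2", 0.002)]), self.pwms(),
            {"X": 10.0, "Y": 5.0}, 0.05, bait_motif_id="m1")
        assert cands["protein_id"].tolist() == ["Y"]

    def test_order_invariant_to_motif_permutation(self):
        enr = self.enr([("m2", 0.002), ("m1", 0.001)])
        a, _ = piggyback_candidates(enr, self.pwms(),
                                    {"X": 1.0, "Y": 2.0}, 0.05)
        b, _ = piggyback_candidates(enr.iloc[::-1], self.pwms()[::-1],
                                    {"Y": 2.0, "X": 1.0}, 0.05)
        assert a["protein_id"].tolist() == b["protein_id"].tolist()


class TestGroundTruthRecovery:
    def test_planted_motif_protein_is_the_only_candidate(self, fixture_dir):
        """End-to-end on the synthetic study: peaks were seeded with the
        partner motif; the MS table holds the partner and a motif-less
        decoy. Exactly the partner protein must come out."""
        from cutrunkit import core_io, pipeline, simulate
        pipeline.stage_norm(fixture_dir, seed=7)
        pipeline.stage_callpeaks(fixture_dir, seed=7)
        pipeline.stage_piggyback(fixture_dir, seed=7)
        cands = pipeline.read_tsv(fixture_dir / "candidates.tsv")
        assert cands["protein_id"].tolist() == ["PROT_PARTNER"]
        no_motif = pipeline.read_tsv(fixture_dir / "no_motif_proteins.tsv")
        assert no_motif["protein_id"].tolist() == ["PROT_NOMOTIF"]


class TestSequenceUtilities:
    def test_base_frequencies(self):
        freqs = base_frequencies({"a": "AACC", "b": "GGNN"})
        np.testing.assert_allclose(freqs, [2 / 6, 2 / 6, 2 / 6, 0.0])

    def test_extract_peak_sequences(self):
        genome = {"chr1": "ACGTACGTAC"}
        peaks = make_peaks([("chr1", 2, 6)])
        assert extract_peak_sequences(genome, peaks) == {"p1": "GTAC"}
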