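"""Length-based Bulky test, background ceilings, unique-peak rule."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from cutrunkit.classify import (BackgroundModel, bulky_classification,
                                call_unique_peaks, mannwhitney_exact_p,
                                max_window_count, place_fragments_uniform,
                                simulate_background)
from cutrunkit.core_io import fragments_to_coverage
from cutrunkit.spikein import normalize_coverage

from conftest import make_frags, make_peaks


def enumeration_oracle_p(a, b):
    """Fully independent exact two-sided p: enumerate every assignment."""
    combined = np.concatenate([a, b]).astype(float)
    ranks = sps.rankdata(combined)
    n_a = len(a)
    r_obs = ranks[:n_a].sum()
    sums = np.array([ranks[list(idx)].sum()
                     for idx in combinations(range(len(combined)), n_a)])
    lo = (sums <= r_obs + 1e-9).mean()
    hi = (sums >= r_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lo, hi))


class TestExactMannWhitney:
    def test_printed_small_example(self):
        # U = 0; one-tail 1/20 -> two-sided 0.1
        p = mannwhitney_exact_p([100, 110, 120], [300, 310, 320])
        assert p == pytest.approx(0.1)

    def test_fully_separated_ten_vs_ten(self):
        a = np.arange(10) + 100.0
        b = np.arange(10) + 500.0
        # one-tail 1/C(20,10) = 1/184756
        assert mannwhitney_exact_p(a, b) == pytest.approx(2 / 184756, rel=1e-9)

    def test_equals_full_enumeration_with_ties(self, rng):
        for _ in range(30):
            n_a = int(rng.integers(3, 7))
            n_b = int(rng.integers(3, 13 - n_a))
            a = rng.integers(100, 108, n_a)  # narrow range forces ties
            b = rng.integers(100, 110, n_b)
            assert mannwhitney_exact_p(a, b) == pytest.approx(
                enumeration_oracle_p(a, b), abs=1e-12)


def frags_for_peaks(peaks, lengths_per_peak, rng, jitter=50):
    ivs = []
    for p, lengths in zip(peaks, lengths_per_peak):
        mid = p.interval.midpoint
        for ln in lengths:
            c = mid + int(rng.integers(-jitter, jitter))
            ivs.append((p.interval.chrom, c - int(ln) // 2,
                        c - int(ln) // 2 + int(ln)))
    return make_frags(ivs)


class TestBulkyClassification:
    def test_shifted_lengths_called_bulky(self, rng):
        peaks = make_peaks([("chr1", i * 10_000 + 2000, i * 10_000 + 3000)
                            for i in range(6)])
        lens_a = [np.maximum(rng.normal(150, 25, 60).round(), 30)
                  for _ in range(6)]
        lens_b = [np.maximum(rng.normal(230 if i < 2 else 150, 25, 60).round(), 30)
                  for i in range(6)]
        fa = frags_for_peaks(peaks, lens_a, rng)
        fb = frags_for_peaks(peaks, lens_b, rng)
        df = bulky_classification(fa, fb, peaks, alpha=0.05)
        assert df["class"].tolist()[:2] == ["Bulky", "Bulky"]
        assert (df["class"].tolist()[2:] == ["NonBulky"] * 4)

    def test_below_min_n_untestable(self, rng):
        peaks = make_peaks([("chr1", 1000, 2000)])
        fa = frags_for_peaks(peaks, [[150, 160, 170]], rng)
        fb = frags_for_peaks(peaks, [np.full(20, 150.0)], rng)
        df = bulky_classification(fa, fb, peaks, min_n=5)
        assert df["class"][0] == "untestable" and np.isnan(df["p"][0])

    def test_empty_peak_set(self):
        df = bulky_classification(make_frags([]), make_frags([]),
                                  make_peaks([]))
        assert df.empty


class TestBackgroundSimulation:
    def test_zero_and_single_fragment_ceilings(self):
        sizes = {"chr1": 10_000}
        empty = simulate_background(make_frags([]), sizes, 500, 5, seed=1)
        assert empty.ceiling == 0.0
        one = simulate_background(make_frags([("chr1", 0, 100)]), sizes,
                                  500, 5, seed=1)
        assert one.ceiling == 1.0

    def test_matches_event_sweep_oracle(self, rng):
        """Same seeded placement stream, independent window-max algorithm."""
        sizes = {"chr1": 100_000}
        ivs = []
        for _ in range(500):
            s = int(rng.integers(0, 99_900))
            ivs.append(("chr1", s, s + 100))
        frags = make_frags(ivs)
        w, n_sims, seed = 500, 20, 123
        model = simulate_background(frags, sizes, w, n_sims, seed)
        lengths = frags.lengths()
        oracle_rng = np.random.default_rng(seed)
        oracle_max = []
        for _ in range(n_sims):
            _, starts = place_fragments_uniform(oracle_rng, lengths, sizes)
            ends = starts + lengths
            # oracle: evaluate the count at every candidate window start
            n_pos = sizes["chr1"] - w + 1
            cand = np.unique(np.clip(np.concatenate(
                [[0], np.maximum(starts - w + 1, 0), ends]), 0, n_pos - 1))
            best = max(int(((starts < x + w) & (ends > x)).sum()) for x in cand)
            oracle_max.append(best)
        np.testing.assert_array_equal(model.per_sim_max, oracle_max)

    def test_ceiling_monotone_in_n_sims_and_fragments(self, rng):
        sizes = {"chr1": 50_000}
        ivs = [("chr1", int(s), int(s) + 80)
               for s in rng.integers(0, 49_000, 300)]
        small = simulate_background(make_frags(ivs[:150]), sizes, 400, 10, 7)
        big = simulate_background(make_frags(ivs), sizes, 400, 10, 7)
        assert big.ceiling >= small.ceiling
        few = simulate_background(make_frags(ivs), sizes, 400, 5, 7)
        many = simulate_background(make_frags(ivs), sizes, 400, 15, 7)
        assert many.ceiling >= few.ceiling

    def test_fragment_longer_than_genome_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            simulate_background(make_frags([("chr1", 0, 900)]), {"chr1": 500},
                                100, 2, 0)

    def test_max_window_count_fragment_at_chrom_end(self):
        assert max_window_count(1000, 1000, np.array([900]),
                                np.array([1000])) == 1


def track_with_peak(peak_value, size=20_000, bin_size=10, span=(5000, 6000),
                    base=0.0, normalized=True):
    nb = size // bin_size
    vals = np.full(nb, base)
    vals[span[0] // bin_size: span[1] // bin_size] = peak_value
    t = fragments_to_coverage(make_frags([]), {"chr1": size}, bin_size)
    t.values["chr1"] = vals
    if normalized:
        t = normalize_coverage(t, 1.0)
    return t


def bg_model(ceiling, window=500):
    return BackgroundModel(sample_id="b", window=window, n_sims=1, seed=0,
                           per_sim_max=np.array([ceiling]))


class TestUniquePeaks:
    PEAK = [("chr1", 5000, 6000)]

    def call(self, cov_a, cov_b, ceiling, **kw):
        return call_unique_peaks(make_peaks(self.PEAK),
                                 track_with_peak(cov_a),
                                 track_with_peak(cov_b),
                                 bg_model(ceiling), **kw)

    def test_direct_rule_application(self):
        df = self.call(40.0, 2.0, 8)
        assert bool(df["unique"][0])  # 40 >= 32 and 2 <= 8

    def test_below_four_fold_boundary(self):
        assert not bool(self.call(31.9, 2.0, 8)["unique"][0])

    def test_smallest_unique_multiple_is_four(self):
        flagged = [m for m in range(1, 9)
                   if bool(self.call(float(m * 8), 2.0, 8)["unique"][0])]
        assert flagged and min(flagged) == 4

    def test_b_above_ceiling_blocks_uniqueness(self):
        assert not bool(self.call(100.0, 9.0, 8)["unique"][0])

    def test_monotone_in_cov_a(self):
        flags = [bool(self.call(c, 2.0, 8)["unique"][0])
                 for c in np.linspace(0, 100, 41)]
        assert flags == sorted(flags)  # once unique, stays unique

    def test_observed_mode(self):
        df = self.call(40.0, 9.0, 8, mode="observed")
        assert bool(df["unique"][0])  # 40 >= 4 * 9

    def test_mixed_normalization_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            call_unique_peaks(make_peaks(self.PEAK),
                              track_with_peak(10.0, normalized=True),
                              track_with_peak(1.0, normalized=False),
                              bg_model(8))


class TestNullCalibration:
    def test_type_one_error_controlled(self):
        """Identical length distributions in both samples: the fraction of
        peaks at p < 0.05 stays near the nominal level."""
        rng = np.random.default_rng(42)
        n_peaks, n_frag = 400, 40
        pvals = []
        for _ in range(n_peaks):
            a = np.maximum(rng.normal(150, 25, n_frag).round(), 30)
            b = np.maximum(rng.normal(150, 25, n_frag).round(), 30)
            pvals.append(sps.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic").pvalue)
        frac = (np.array(pvals) < 0.05).mean()
        assert 0.03 <= frac <= 0.07
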