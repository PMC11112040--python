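"""Fragment-length peak classification and unique ("black and white") peaks.

Two classifications beyond plain coverage comparison:

**Bulky / NonBulky.** A peak whose between-sample difference is carried by
the *lengths* of the released fragments rather than by coverage points to a
different protein complex protecting more or less DNA at that locus. Per
peak, the fragment-length distributions of the two samples are compared
with a two-sided Mann-Whitney U test — exact (full enumeration of the
rank-sum distribution, ties handled through midranks) when the combined
count is small, tie-corrected normal approximation otherwise — and BH
correction across peaks. Peaks with q < alpha are Bulky.

**Unique peaks.** To decide whether a locus bound in experiment A is
genuinely absent in experiment B, the maximum window coverage B could show
*by chance* is estimated by Monte-Carlo: all of B's fragments are re-placed
uniformly at random over the genome (lengths preserved) and the maximum
fragment count over every sliding window is recorded; the ceiling is the
maximum over simulations. A peak of A is unique iff B's observed coverage
stays at or below its background ceiling while A's coverage reaches at
least ``ratio`` (default 4) times that ceiling. An alternative mode
compares A directly against ``ratio`` times B's observed coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CoverageTrack, FragmentSet, PeakSet
from .peakops import bh_qvalues

EXACT_MAX_N = 20  # combined sample size at or below which the exact test runs


def mannwhitney_exact_p(lengths_a: np.ndarray, lengths_b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of the rank-sum
    null (all C(n_a+n_b, n_a) assignments equally likely), with midranks for
    ties. p = min(1, 2 * min(P(R <= r_obs), P(R >= r_obs)))."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)  # midranks
    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled ranks are integers
    r_obs = int(np.rint(2 * ranks[:len(a)].sum()))
    n_a = len(a)
    total = r2.sum()
    # dp[k, s] = number of size-k subsets with doubled-rank-sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        # materialize RHS before assigning: each item may be used once
        dp[1:, r:] = dp[1:, r:] + dp[:-1, :total + 1 - r]
    dist = dp[n_a]
    n_subsets = dist.sum()
    lo = dist[:r_obs + 1].sum() / n_subsets
    hi = dist[r_obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class BackgroundModel:
    """Simulated maximum background window coverage for one sample."""

    sample_id: str
    window: int  # bp
    n_sims: int
    seed: int
    per_sim_max: np.ndarray  # max window fragment count per simulation

    @property
    def ceiling(self) -> float:
        return float(self.per_sim_max.max()) if len(self.per_sim_max) else 0.0


def bulky_classification(frags_a: FragmentSet, frags_b: FragmentSet,
                         peaks: PeakSet, alpha: float = 0.05,
                         min_n: int = 5) -> pd.DataFrame:
    """Per-peak fragment-length comparison between two samples.

    Fragments are assigned to peaks by midpoint. Peaks with fewer than
    ``min_n`` fragments in either sample are flagged untestable and excluded
    from the BH correction. Returns one row per peak with counts, median
    lengths, U, p, q and the Bulky/NonBulky class.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    lens_by_peak_a = _peak_lengths(frags_a, peaks)
    lens_by_peak_b = _peak_lengths(frags_b, peaks)
    rows = []
    for i, p in enumerate(peaks):
        la, lb = lens_by_peak_a[i], lens_by_peak_b[i]
        row = {"name": p.name, "n_A": len(la), "n_B": len(lb),
               "median_len_A": float(np.median(la)) if len(la) else np.nan,
               "median_len_B": float(np.median(lb)) if len(lb) else np.nan,
               "U": np.nan, "p": np.nan, "q": np.nan, "class": "untestable"}
        if len(la) >= min_n and len(lb) >= min_n:
            row["U"] = float(sps.mannwhitneyu(la, lb,
                                              alternative="two-sided",
                                              method="asymptotic").statistic)
            if len(la) + len(lb) <= EXACT_MAX_N:
                row["p"] = mannwhitney_exact_p(la, lb)
            else:
                row["p"] = float(sps.mannwhitneyu(
                    la, lb, alternative="two-sided", method="asymptotic").pvalue)
            row["class"] = "pending"
        rows.append(row)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["name", "n_A", "n_B", "median_len_A", "median_len_B",
                 "U", "p", "q", "class"])
    testable = df["class"] == "pending" if len(df) else pd.Series(dtype=bool)
    if len(df) and testable.any():
        q = bh_qvalues(df.loc[testable, "p"].to_numpy())
        df.loc[testable, "q"] = q
        df.loc[testable, "class"] = np.where(q < alpha, "Bulky", "NonBulky")
    return df


def _peak_lengths(frags: FragmentSet, peaks: PeakSet) -> list[np.ndarray]:
    mids_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in frags.fragments:
        mids_by_chrom.setdefault(f.chrom, []).append((f.midpoint, len(f)))
    sorted_by_chrom = {}
    for chrom, pairs in mids_by_chrom.items():
        arr = np.array(pairs, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        sorted_by_chrom[chrom] = arr[order]
    out = []
    for p in peaks:
        arr = sorted_by_chrom.get(p.interval.chrom)
        if arr is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        lo = np.searchsorted(arr[:, 0], p.interval.start, side="left")
        hi = np.searchsorted(arr[:, 0], p.interval.end, side="left")
        out.append(arr[lo:hi, 1].copy())
    return out


def place_fragments_uniform(rng: np.random.Generator, lengths: np.ndarray,
                            chrom_sizes: dict[str, int]) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """One background placement: for each fragment a chromosome is drawn with
    probability proportional to its length, then a start uniformly from
    [0, L - len]. Returns (chrom_index, start) arrays. This placement rule
    is part of the background-model definition."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if lengths.size and lengths.max() > sizes.max():
        raise ValueError("fragment longer than every chromosome")
    idx = rng.choice(len(chroms), size=len(lengths), p=sizes / sizes.sum())
    highs = sizes[idx].astype(np.int64) - np.asarray(lengths, dtype=np.int64)
    if len(lengths) and highs.min() < 0:
        i = int(np.argmin(highs))
        raise ValueError(f"fragment longer than chromosome {chroms[idx[i]]} "
                         f"({lengths[i]} > {int(sizes[idx[i]])})")
    starts = rng.integers(0, highs + 1) if len(lengths) else \
        np.empty(0, dtype=np.int64)
    return idx, starts.astype(np.int64)


def max_window_count(chrom_len: int, window: int, starts: np.ndarray,
                     ends: np.ndarray) -> int:
    """Maximum number of fragments overlapping any w-bp window on one
    chromosome (window starts range over [0, L - w])."""
    n_pos = max(chrom_len - window, 0) + 1
    diff = np.zeros(n_pos + 1, dtype=np.int64)
    lo = np.clip(starts - window + 1, 0, n_pos)
    hi = np.clip(ends, 0, n_pos)
    keep = lo < hi
    np.add.at(diff, lo[keep], 1)
    np.add.at(diff, hi[keep], -1)
    counts = np.cumsum(diff[:-1])
    return int(counts.max()) if len(counts) else 0


def simulate_background(frags: FragmentSet, chrom_sizes: dict[str, int],
                        window: int = 500, n_sims: int = 100,
                        seed: int = 0) -> BackgroundModel:
    """Monte-Carlo ceiling on background window coverage.

    Each simulation re-places every fragment uniformly at random over the
    genome (lengths preserved, see :func:`place_fragments_uniform`) and
    records the maximum fragment count over all w-bp sliding windows; the
    ceiling is the maximum across simulations. Deterministic given the seed.
    """
    if n_sims < 1 or window <= 0:
        raise ValueError("need n_sims >= 1 and window > 0")
    lengths = frags.lengths()
    chroms = list(chrom_sizes)
    rng = np.random.default_rng(seed)
    per_sim = np.zeros(n_sims, dtype=np.int64)
    for s in range(n_sims):
        idx, starts = place_fragments_uniform(rng, lengths, chrom_sizes)
        best = 0
        for ci, chrom in enumerate(chroms):
            mask = idx == ci
            if not mask.any():
                continue
            st = starts[mask]
            best = max(best, max_window_count(chrom_sizes[chrom], window,
                                              st, st + lengths[mask]))
        per_sim[s] = best
    return BackgroundModel(sample_id=frags.sample_id, window=window,
                           n_sims=n_sims, seed=seed, per_sim_max=per_sim)


def call_unique_peaks(peaks_a: PeakSet, cov_a: CoverageTrack,
                      cov_b: CoverageTrack, bg_b: BackgroundModel,
                      ratio: float = 4.0, mode: str = "ceiling",
                      ceiling: float | None = None) -> pd.DataFrame:
    """Unique-peak calls for experiment A against experiment B.

    In ``ceiling`` mode a peak is unique iff B's mean coverage over the peak
    stays at or below B's simulated background ceiling while A's reaches at
    least ``ratio`` times that ceiling. In ``observed`` mode A is compared
    against ``ratio`` times B's observed coverage instead. ``ceiling``
    overrides the raw window-count ceiling of ``bg_b`` with a value already
    converted to the coverage tracks' units (per-base depth, possibly
    spike-in scaled); without it the raw count ceiling is used and the
    caller is responsible for unit consistency.
    """
    if cov_a.normalized != cov_b.normalized:
        raise ValueError("cannot mix normalized and un-normalized tracks")
    if mode not in ("ceiling", "observed"):
        raise ValueError(f"unknown mode {mode!r}")
    c = bg_b.ceiling if ceiling is None else float(ceiling)
    rows = []
    for p in peaks_a:
        iv = p.interval
        ca = cov_a.region_mean(iv.chrom, iv.start, iv.end)
        cb = cov_b.region_mean(iv.chrom, iv.start, iv.end)
        if mode == "ceiling":
            unique = (cb <= c) and (ca >= ratio * c) and c > 0
        else:
            unique = ca >= ratio * cb and ca > 0
        rows.append({"name": p.name, "chrom": iv.chrom, "start": iv.start,
                     "end": iv.end, "cov_A": ca, "cov_B": cb,
                     "ceiling_B": c, "ratio": ratio, "mode": mode,
                     "unique": unique})
    return pd.DataFrame(rows)
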