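"""Spike-in-aware enrichment peak calling and differential peak testing.

The caller slides fixed windows over spike-in-scaled coverage, converts the
windowed coverage to approximate fragment counts (coverage bp / typical
fragment length), and tests each window against Poisson(lambda) where
lambda is the larger of the scaled local control level (10 kb around the
window) and the scaled genome-wide mean — the usual local-background guard
against calling peaks inside broad enriched domains. Windows passing a BH
q-value cutoff and a minimum fold over lambda are merged into peaks.

Differential occupancy between two conditions is assessed per union peak
with an exact conditional binomial test: conditional on the total count
n = k_A + k_B, under the null of equal spike-in-normalized occupancy k_A is
Binomial(n, w) with w = (1/f_A) / (1/f_A + 1/f_B), the share of raw reads
condition A is expected to contribute given the scale factors. This is
assumption-light (no dispersion model) and exactly computable, at the cost
of ignoring biological replicate variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CoverageTrack, FragmentSet, GenomicInterval, Peak, PeakSet

LOCAL_BG_WINDOW = 10_000  # bp around a test window for the local lambda


@dataclass
class PeakCallParams:
    window: int = 500  # bp
    step: int = 100  # bp
    q_threshold: float = 0.05
    min_fold: float = 2.0
    merge_gap: int = 200  # bp
    frag_len: float = 150.0  # bp; converts coverage bp to fragment counts

    def __post_init__(self):
        if not (self.window >= self.step > 0):
            raise ValueError("need window >= step > 0")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.merge_gap < 0 or self.min_fold < 1 or self.frag_len <= 0:
            raise ValueError("invalid merge_gap/min_fold/frag_len")


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return sps.false_discovery_control(p, method="bh")


def scan_windows(exp: CoverageTrack, ctrl: CoverageTrack | None,
                 factors: tuple[float, float | None],
                 params: PeakCallParams) -> pd.DataFrame:
    """Windowed Poisson scan; returns one row per window with the observed
    pseudo-count k, background lambda, fold, p and BH q."""
    f_exp, f_ctrl = factors
    if ctrl is not None:
        if ctrl.bin_size != exp.bin_size or ctrl.chrom_sizes != exp.chrom_sizes:
            raise ValueError("experiment and control tracks are on different grids")
        if f_ctrl is None:
            raise ValueError("control track supplied without a control factor")
    if params.window % exp.bin_size or params.step % exp.bin_size:
        raise ValueError("window and step must be multiples of the track bin size")

    to_count = exp.bin_size / params.frag_len  # coverage-sum -> fragment count
    bg = ctrl if ctrl is not None else exp
    f_bg = f_ctrl if ctrl is not None else f_exp
    # genome-wide mean fragment count per window
    lam_global = f_bg * bg.mean() * params.window / params.frag_len

    rows = []
    wbins = params.window // exp.bin_size
    sbins = params.step // exp.bin_size
    lbins = max(LOCAL_BG_WINDOW // exp.bin_size, wbins)
    for chrom, size in exp.chrom_sizes.items():
        v_exp = exp.values[chrom] * f_exp
        cs_exp = np.concatenate([[0.0], np.cumsum(v_exp)])
        if ctrl is not None:
            v_bg = bg.values[chrom] * f_bg
            cs_bg = np.concatenate([[0.0], np.cumsum(v_bg)])
        nb = len(v_exp)
        for b0 in range(0, max(nb - wbins, 0) + 1, sbins):
            b1 = b0 + wbins
            k = (cs_exp[b1] - cs_exp[b0]) * to_count
            lam = lam_global
            if ctrl is not None:
                lo = max(0, (b0 + b1) // 2 - lbins // 2)
                hi = min(nb, lo + lbins)
                local = (cs_bg[hi] - cs_bg[lo]) / (hi - lo) * wbins * to_count
                lam = max(lam, local)
            rows.append((chrom, b0 * exp.bin_size, b1 * exp.bin_size, k, lam))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "k", "lam"])
    k_int = np.rint(df["k"]).astype(np.int64)
    lam = np.maximum(df["lam"].to_numpy(), 1e-12)
    df["p"] = sps.poisson.sf(k_int - 1, lam)  # P(X >= k)
    df["fold"] = df["k"] / lam
    df["q"] = bh_qvalues(df["p"].to_numpy()) if len(df) else []
    return df


def call_peaks(exp: CoverageTrack, ctrl: CoverageTrack | None,
               factors: tuple[float, float | None],
               params: PeakCallParams | None = None) -> PeakSet:
    """Call enriched peaks on spike-in-scaled coverage.

    Significant windows (BH q < q_threshold and fold >= min_fold) within
    ``merge_gap`` bp of each other are merged; each peak's summit is its
    highest-coverage bin and its score the best window fold enrichment over
    lambda (the conventional signalValue).
    """
    params = params or PeakCallParams()
    df = scan_windows(exp, ctrl, factors, params)
    sig = df[(df["q"] < params.q_threshold) & (df["fold"] >= params.min_fold)
             & (df["k"] > 0)]
    peaks: list[Peak] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        best_fold = 0.0
        for _, w in grp.iterrows():
            if cur_end is not None and w["start"] <= cur_end + params.merge_gap:
                cur_end = max(cur_end, int(w["end"]))
                best_fold = max(best_fold, w["fold"])
            else:
                if cur_start is not None:
                    peaks.append(_make_peak(exp, chrom, cur_start, cur_end,
                                            best_fold, len(peaks) + 1))
                cur_start, cur_end = int(w["start"]), int(w["end"])
                best_fold = w["fold"]
        if cur_start is not None:
            peaks.append(_make_peak(exp, chrom, cur_start, cur_end, best_fold,
                                    len(peaks) + 1))
    return PeakSet(peaks=peaks)


def _make_peak(exp: CoverageTrack, chrom: str, start: int, end: int,
               best_fold: float, idx: int) -> Peak:
    b0, b1 = start // exp.bin_size, -(-end // exp.bin_size)
    v = exp.values[chrom][b0:b1]
    summit_bin = int(np.argmax(v))
    summit = min(summit_bin * exp.bin_size + exp.bin_size // 2, end - start - 1)
    return Peak(GenomicInterval(chrom, start, min(end, exp.chrom_sizes[chrom])),
                score=float(best_fold), summit=summit, name=f"peak_{idx}")


def union_peaks(peak_sets: list[PeakSet],
                set_names: list[str] | None = None) -> PeakSet:
    """Merge overlapping peaks (half-open overlap; touching intervals stay
    separate) across sets, recording which input sets contributed to each
    merged peak in ``provenance``."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    if set_names is None:
        set_names = [f"set{i + 1}" for i in range(len(peak_sets))]
    items = []  # (chrom, start, end, set_name, score)
    for name, ps in zip(set_names, peak_sets):
        for p in ps:
            items.append((p.interval.chrom, p.interval.start, p.interval.end,
                          name, p.score))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[Peak] = []
    prov: list[tuple[str, ...]] = []
    cur = None  # [chrom, start, end, set names, max score]
    for chrom, start, end, name, score in items:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(name)
            cur[4] = max(cur[4], score)
        else:
            if cur is not None:
                merged.append(Peak(GenomicInterval(cur[0], cur[1], cur[2]),
                                   score=cur[4], name=f"union_{len(merged) + 1}"))
                prov.append(tuple(sorted(cur[3])))
            cur = [chrom, start, end, {name}, score]
    if cur is not None:
        merged.append(Peak(GenomicInterval(cur[0], cur[1], cur[2]),
                           score=cur[4], name=f"union_{len(merged) + 1}"))
        prov.append(tuple(sorted(cur[3])))
    return PeakSet(peaks=merged, provenance=prov)


def count_fragments_in_peaks(frags: FragmentSet, peaks: PeakSet) -> np.ndarray:
    """Fragment counts per peak; a fragment is assigned to a peak iff its
    midpoint lies inside the half-open peak interval."""
    by_chrom: dict[str, list[int]] = {}
    for f in frags.fragments:
        by_chrom.setdefault(f.chrom, []).append(f.midpoint)
    sorted_mids = {c: np.sort(np.array(m, dtype=np.int64))
                   for c, m in by_chrom.items()}
    counts = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        mids = sorted_mids.get(p.interval.chrom)
        if mids is None:
            continue
        counts[i] = (np.searchsorted(mids, p.interval.end, side="left")
                     - np.searchsorted(mids, p.interval.start, side="left"))
    return counts


def differential_peaks(counts_a: np.ndarray, counts_b: np.ndarray,
                       factor_a: float, factor_b: float,
                       alpha: float = 0.05,
                       peak_names: list[str] | None = None) -> pd.DataFrame:
    """Exact conditional binomial test for differential occupancy per peak.

    Under equal normalized occupancy, k_A | (k_A + k_B = n) is Binomial(n, w)
    with w = (1/f_A) / (1/f_A + 1/f_B). Two-sided exact p, BH q, and
    log2FC = log2((k_A f_A + 0.5) / (k_B f_B + 0.5)). Peaks with zero total
    count get p = 1, log2FC = 0 and are flagged untestable.
    """
    ka = np.asarray(counts_a, dtype=np.int64)
    kb = np.asarray(counts_b, dtype=np.int64)
    if ka.shape != kb.shape:
        raise ValueError("count vectors differ in length")
    if factor_a <= 0 or factor_b <= 0:
        raise ValueError("scale factors must be positive")
    w = (1.0 / factor_a) / (1.0 / factor_a + 1.0 / factor_b)
    n = ka + kb
    p = np.ones(len(ka))
    for i in range(len(ka)):
        if n[i] > 0:
            p[i] = sps.binomtest(int(ka[i]), int(n[i]), w,
                                 alternative="two-sided").pvalue
    lfc = np.log2((ka * factor_a + 0.5) / (kb * factor_b + 0.5))
    lfc[n == 0] = 0.0
    q = bh_qvalues(p) if len(p) else np.array([])
    direction = np.where(n == 0, "untestable",
                         np.where(q >= alpha, "ns",
                                  np.where(lfc > 0, "up_in_A", "down_in_A")))
    return pd.DataFrame({
        "name": peak_names if peak_names is not None
        else [f"peak_{i + 1}" for i in range(len(ka))],
        "count_A": ka, "count_B": kb,
        "scaled_A": ka * factor_a, "scaled_B": kb * factor_b,
        "log2FC": lfc, "p": p, "q": q, "direction": direction,
        "testable": n > 0,
    })
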