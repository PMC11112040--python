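"""Spike-in statistics, depth-adjusted scale factors, QC, and normalization.

Heterologous spike-in DNA (synthetic, yeast/fly chromatin, or carry-over
E. coli) is sequenced alongside the target genome at a proportion that is —
absent technical variation — constant across samples, so per-sample scale
factors can be derived from spike-in read counts. The classic factor is
f = S / N_spike for a user constant S. Because controls in CUT&RUN-style
experiments are commonly sequenced at a fraction (one-third to one-fourth)
of the experiment depth, the factor used here additionally adjusts for
sequencing depth:

    f_i = S / ( (N_spike,i / N_total,i) * T_bar ),    T_bar = mean_j N_total,j

where the mean runs over the jointly normalized sample set. When all
samples have identical depth (N_total,i = T_bar) this reduces exactly to
S / N_spike,i. The depth-adjusted form is one of several satisfying that
reduction; it is kept behind ``compute_scale_factors`` so the strategy can
be swapped without touching callers.

QC flags two conditions per experiment/control pair: spike-in proportion
higher in the control than in the experiment (inverted background, a sign
of a failed experiment), and control depth outside the recommended
one-fourth to one-third of the experiment depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CoverageTrack, FragmentSet, PeakSet, SampleSheet

DEFAULT_S = 10_000.0
DEPTH_BAND = (0.25, 1.0 / 3.0)  # recommended control/experiment depth ratio


@dataclass(frozen=True)
class SpikeInStats:
    sample_id: str
    n_total: int  # target-genome fragment count
    n_spike: int  # spike-in-genome fragment count

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError(f"{self.sample_id}: no target fragments "
                             "(cannot compute spike-in statistics)")
        if self.n_spike < 0:
            raise ValueError("negative spike-in count")

    @property
    def proportion(self) -> float:
        """Spike-in read proportion p = N_spike / (N_total + N_spike)."""
        return self.n_spike / (self.n_total + self.n_spike)

    @property
    def ratio(self) -> float:
        """Spike-in / target ratio used in the scale factor."""
        return self.n_spike / self.n_total


@dataclass(frozen=True)
class ScaleFactor:
    sample_id: str
    f: float
    s_constant: float
    t_bar: float  # mean target depth of the jointly normalized set

    def __post_init__(self):
        if not (np.isfinite(self.f) and self.f > 0):
            raise ValueError(f"{self.sample_id}: scale factor must be finite "
                             f"and positive, got {self.f}")


def spikein_stats(target: FragmentSet, spike: FragmentSet) -> SpikeInStats:
    """Count fragments on both genomes for one sample."""
    if target.sample_id != spike.sample_id:
        raise ValueError(f"sample_id mismatch: {target.sample_id!r} vs "
                         f"{spike.sample_id!r}")
    return SpikeInStats(sample_id=target.sample_id,
                        n_total=len(target), n_spike=len(spike))


def meers_factor(stats: SpikeInStats, s_constant: float = DEFAULT_S) -> float:
    """Classic spike-in factor S / N_spike (no depth adjustment)."""
    if stats.n_spike == 0:
        raise ValueError(
            f"{stats.sample_id}: no spike-in fragments; spike-in normalization "
            "is undefined — use a non-spike-in (e.g. depth-only) normalization")
    return s_constant / stats.n_spike


def compute_scale_factors(stats_list: list[SpikeInStats],
                          s_constant: float = DEFAULT_S) -> list[ScaleFactor]:
    """Depth-adjusted scale factors for a jointly normalized sample set.

    f_i = S / ((N_spike,i / N_total,i) * T_bar) with T_bar the arithmetic
    mean of target depths. Equal depths reduce this to S / N_spike,i
    exactly. Raises if any sample lacks spike-in fragments.
    """
    if not stats_list:
        raise ValueError("need at least one sample")
    for st in stats_list:
        if st.n_spike == 0:
            raise ValueError(f"{st.sample_id}: no spike-in fragments")
    t_bar = float(np.mean([st.n_total for st in stats_list]))
    return [ScaleFactor(sample_id=st.sample_id,
                        f=s_constant / (st.ratio * t_bar),
                        s_constant=s_constant, t_bar=t_bar)
            for st in stats_list]


def qc_spikein(sheet: SampleSheet,
               stats: dict[str, SpikeInStats]) -> pd.DataFrame:
    """Per experiment/control pair QC report (never raises on QC findings).

    ``warn_spike_inverted`` is set iff the control spike-in proportion
    exceeds the experiment's. ``advisory_depth`` is set iff the
    control/experiment depth ratio falls outside the closed band
    [1/4, 1/3]. Experiments without a control get NA flags.
    """
    rows = []
    for exp in sheet.experiments():
        st_exp = stats[exp.sample_id]
        ctrl = sheet.control_of(exp.sample_id)
        row = {
            "experiment": exp.sample_id,
            "control": ctrl.sample_id if ctrl else None,
            "p_experiment": st_exp.proportion,
            "p_control": np.nan,
            "depth_ratio": np.nan,
            "warn_spike_inverted": pd.NA,
            "advisory_depth": pd.NA,
            "message": "no control",
        }
        if ctrl is not None:
            st_ctrl = stats[ctrl.sample_id]
            ratio = st_ctrl.n_total / st_exp.n_total
            inverted = st_ctrl.proportion > st_exp.proportion
            depth_bad = not (DEPTH_BAND[0] <= ratio <= DEPTH_BAND[1])
            msgs = []
            if inverted:
                msgs.append("control spike-in proportion exceeds experiment "
                            f"({st_ctrl.proportion:.4g} > {st_exp.proportion:.4g})")
            if depth_bad:
                msgs.append(f"control/experiment depth ratio {ratio:.3g} outside "
                            "recommended [1/4, 1/3]")
            row.update(p_control=st_ctrl.proportion, depth_ratio=ratio,
                       warn_spike_inverted=inverted, advisory_depth=depth_bad,
                       message="; ".join(msgs) or "ok")
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_coverage(track: CoverageTrack, factor: ScaleFactor | float) -> CoverageTrack:
    """Return a new track with every bin multiplied by the scale factor."""
    if track.normalized:
        raise ValueError("track is already normalized "
                         f"(scale {track.scale_applied}); refusing to re-scale")
    f = factor.f if isinstance(factor, ScaleFactor) else float(factor)
    out = track.copy()
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] * f
    out.normalized = True
    out.scale_applied = f
    return out


def matrix_at_regions(track: CoverageTrack, peaks: PeakSet, flank: int = 1000,
                      num_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Signal matrix over peak-centered windows (for heatmap-style summaries).

    Row i covers [midpoint_i - flank, midpoint_i + flank) split into
    ``num_bins`` equal sub-windows; each cell is the mean track value over
    its sub-window, with bp outside the chromosome contributing zero.
    Returns (matrix, clipped) where ``clipped[i]`` marks rows whose window
    ran past a chromosome boundary. 2*flank must be divisible by num_bins.
    """
    if flank <= 0 or num_bins < 1:
        raise ValueError("flank must be positive and num_bins >= 1")
    if (2 * flank) % num_bins:
        raise ValueError("2*flank must be divisible by num_bins")
    sub = 2 * flank // num_bins
    mat = np.zeros((len(peaks), num_bins))
    clipped = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        mid = p.interval.midpoint
        w0 = mid - flank
        size = track.chrom_sizes.get(p.interval.chrom, 0)
        if w0 < 0 or w0 + 2 * flank > size:
            clipped[i] = True
        for j in range(num_bins):
            s, e = w0 + j * sub, w0 + (j + 1) * sub
            # region_mean zero-fills outside [0, chrom length)
            mat[i, j] = track.region_mean(p.interval.chrom, s, e) if e > 0 else 0.0
    return mat, clipped
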