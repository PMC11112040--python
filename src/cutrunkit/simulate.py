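"""Deterministic synthetic CUT&RUN data with known ground truth.

The generator emulates the essentials of an antibody-directed nuclease
experiment: a low uniform background of released fragments over the target
genome, focal enrichment at binding sites, a per-sample admixture of
heterologous spike-in DNA on a separate small genome, and per-condition
fragment-length distributions (peak-level length shifts model distinct
protein complexes protecting more or less DNA). It also fabricates the
side inputs needed downstream: a random genome sequence with motif
instances planted at peak summits, toy position weight matrices, an
affinity-MS abundance table, and annotation interval sets.

Everything is driven by one integer seed; per-sample substreams are derived
by stable hashing of the sample id, so outputs are bit-identical across
runs and independent across samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FragmentSet, GenomicInterval, Peak, PeakSet

MIN_FRAG_LEN = 30  # bp; sub-nucleosomal floor for truncating length draws

_BASES = np.array(list("ACGT"))


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Child generator for (seed, keys...), stable across runs/platforms."""
    digest = hashlib.sha256(("/".join(keys)).encode()).digest()
    return np.random.default_rng([seed & 0x7FFFFFFF,
                                  int.from_bytes(digest[:4], "big")])


@dataclass
class PeakSpec:
    """One true binding site: where it is, how enriched, and the fragment
    length distribution it produces, each optionally per condition."""

    chrom: str
    start: int
    end: int
    enrichment: float | dict[str, float] = 10.0  # fold over background
    frag_len: tuple[float, float] | dict[str, tuple[float, float]] | None = None

    def fold_for(self, condition: str) -> float:
        if isinstance(self.enrichment, dict):
            return float(self.enrichment.get(condition, 1.0))
        return float(self.enrichment)

    def frag_len_for(self, condition: str,
                     default: tuple[float, float]) -> tuple[float, float]:
        if self.frag_len is None:
            return default
        if isinstance(self.frag_len, dict):
            return self.frag_len.get(condition, default)
        return self.frag_len


@dataclass
class SimConfig:
    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_background_fragments: int = 100_000
    peaks: list[PeakSpec] = field(default_factory=list)
    spikein_fraction: float = 0.05
    conditions: list[str] = field(default_factory=lambda: ["expA", "expB"])
    background_frag_len: tuple[float, float] = (150.0, 25.0)
    spike_chrom_sizes: dict[str, int] = field(default_factory=lambda: {"spike1": 100_000})
    placement_sd_frac: float = 0.125  # peak fragment centers: sd = frac * width

    def __post_init__(self):
        if not (0 <= self.spikein_fraction < 1):
            raise ValueError("spikein_fraction must lie in [0, 1)")
        for spec in self.peaks:
            if spec.chrom not in self.chrom_sizes:
                raise ValueError(f"peak chrom {spec.chrom!r} not in genome")
            if not (0 <= spec.start < spec.end <= self.chrom_sizes[spec.chrom]):
                raise ValueError(
                    f"peak {spec.chrom}:{spec.start}-{spec.end} outside genome")
            for cond in self.conditions:
                if spec.fold_for(cond) < 1:
                    raise ValueError("enrichment fold must be >= 1")

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())


def _draw_lengths(rng, n: int, mean: float, sd: float) -> np.ndarray:
    lens = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(lens, MIN_FRAG_LEN)


def _uniform_fragments(rng, n: int, chrom_sizes: dict[str, int],
                       mean: float, sd: float) -> list[GenomicInterval]:
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    lens = _draw_lengths(rng, n, mean, sd)
    out = []
    for i, ln in zip(idx, lens):
        size = chrom_sizes[chroms[i]]
        ln = min(int(ln), size)
        start = int(rng.integers(0, size - ln + 1))
        out.append(GenomicInterval(chroms[i], start, start + ln))
    return out


def _peak_fragments(rng, spec: PeakSpec, condition: str, cfg: SimConfig,
                    n_extra: int) -> list[GenomicInterval]:
    mean, sd = spec.frag_len_for(condition, cfg.background_frag_len)
    width = spec.end - spec.start
    mid = (spec.start + spec.end) / 2
    centers = rng.normal(mid, cfg.placement_sd_frac * width, size=n_extra)
    lens = _draw_lengths(rng, n_extra, mean, sd)
    size = cfg.chrom_sizes[spec.chrom]
    out = []
    for c, ln in zip(centers, lens):
        ln = min(int(ln), size)
        start = int(np.clip(round(c - ln / 2), 0, size - ln))
        out.append(GenomicInterval(spec.chrom, start, start + ln))
    return out


def simulate_experiment(cfg: SimConfig) -> tuple[
        dict[str, FragmentSet], dict[str, FragmentSet], pd.DataFrame]:
    """Generate target and spike-in fragments for every condition.

    Background fragments land uniformly over the genome; each peak adds
    ``(fold - 1) * n_background * peak_width / genome_length`` expected extra
    fragments (Poisson-distributed), centered normally around the peak
    midpoint, so that total local density is ~fold x background. Spike-in
    fragment counts are chosen so the spike-in read fraction equals
    ``spikein_fraction``.

    Returns per-condition target fragments, per-condition spike-in fragments,
    and a truth table with one row per simulated peak (per-condition folds,
    fragment-length means, and for every ordered condition pair a
    length-shift flag and a >=4-fold uniqueness flag).
    """
    targets: dict[str, FragmentSet] = {}
    spikes: dict[str, FragmentSet] = {}
    glen = cfg.genome_length()
    for cond in cfg.conditions:
        rng = substream(cfg.seed, "target", cond)
        frags = _uniform_fragments(rng, cfg.n_background_fragments, cfg.chrom_sizes,
                                   *cfg.background_frag_len)
        for k, spec in enumerate(cfg.peaks):
            fold = spec.fold_for(cond)
            lam = (fold - 1.0) * cfg.n_background_fragments * (spec.end - spec.start) / glen
            n_extra = int(rng.poisson(lam)) if lam > 0 else 0
            frags.extend(_peak_fragments(rng, spec, cond, cfg, n_extra))
        targets[cond] = FragmentSet(sample_id=cond, genome_tag="target", fragments=frags)

        srng = substream(cfg.seed, "spikein", cond)
        n_spike = int(round(cfg.spikein_fraction / (1 - cfg.spikein_fraction)
                            * len(frags)))
        spikes[cond] = FragmentSet(
            sample_id=cond, genome_tag="spikein",
            fragments=_uniform_fragments(srng, n_spike, cfg.spike_chrom_sizes,
                                         *cfg.background_frag_len))
    return targets, spikes, truth_table(cfg)


def truth_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for k, spec in enumerate(cfg.peaks):
        row = {"name": f"true_peak_{k + 1}", "chrom": spec.chrom,
               "start": spec.start, "end": spec.end}
        for cond in cfg.conditions:
            row[f"fold.{cond}"] = spec.fold_for(cond)
            row[f"frag_len_mean.{cond}"] = spec.frag_len_for(
                cond, cfg.background_frag_len)[0]
        for a in cfg.conditions:
            for b in cfg.conditions:
                if a == b:
                    continue
                row[f"length_shift.{a}_vs_{b}"] = (
                    spec.frag_len_for(a, cfg.background_frag_len)[0]
                    != spec.frag_len_for(b, cfg.background_frag_len)[0])
                row[f"unique.{a}_vs_{b}"] = spec.fold_for(a) >= 4 * spec.fold_for(b)
        rows.append(row)
    return pd.DataFrame(rows)


def true_peakset(cfg: SimConfig) -> PeakSet:
    return PeakSet(peaks=[
        Peak(GenomicInterval(s.chrom, s.start, s.end), name=f"true_peak_{k + 1}")
        for k, s in enumerate(cfg.peaks)])


def simulate_replicate_scores(n: int, pi: float, mu: float, sigma: float,
                              rho: float, seed: int) -> tuple[np.ndarray, np.ndarray,
                                                              np.ndarray]:
    """Paired replicate scores from a two-component bivariate normal mixture.

    With probability ``pi`` a pair comes from the reproducible component
    N2((mu, mu), sigma^2 I with correlation rho); otherwise from the
    standard uncorrelated bivariate normal. Returns (scores1, scores2,
    labels) with labels True for the reproducible component.
    """
    if not (0 <= pi <= 1):
        raise ValueError("pi must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (-1 < rho < 1):
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < pi
    z = rng.standard_normal((n, 2))
    # correlate via Cholesky of [[1, rho], [rho, 1]]
    x = np.where(labels, mu + sigma * z[:, 0], z[:, 0])
    y_rep = mu + sigma * (rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1])
    y = np.where(labels, y_rep, z[:, 1])
    return x, y, labels


# ---------------------------------------------------------------------------
# sequence-level side inputs

def random_genome(chrom_sizes: dict[str, int], seed: int,
                  gc: float = 0.4) -> dict[str, str]:
    """IID random genome sequence with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom, size in chrom_sizes.items():
        rng = substream(seed, "genome", chrom)
        out[chrom] = "".join(_BASES[rng.choice(4, size=size, p=p)])
    return out


def plant_motif(genome: dict[str, str], chrom: str, position: int,
                site: str) -> None:
    """Overwrite genome[chrom] at ``position`` with ``site`` (in place on the
    dict)."""
    seq = genome[chrom]
    if position < 0 or position + len(site) > len(seq):
        raise ValueError("motif site outside chromosome")
    genome[chrom] = seq[:position] + site + seq[position + len(site):]


def consensus_pwm(consensus: str, major: float = 0.85) -> np.ndarray:
    """PWM matrix (L x 4, columns A,C,G,T) concentrated on a consensus."""
    minor = (1 - major) / 3
    m = np.full((len(consensus), 4), minor)
    for i, base in enumerate(consensus.upper()):
        m[i, "ACGT".index(base)] = major
    return m


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line.upper())
    return {k: "".join(v) for k, v in out.items()}
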