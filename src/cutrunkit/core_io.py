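"""Core genomic containers and text-format I/O.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; formats that use other conventions are converted at the boundary.
Paired-end fragments are treated as unstranded intervals, since a CUT&RUN
fragment spans both mates.

Formats handled here: BED3/BED6 fragment files, ENCODE 10-column narrowPeak,
4-column bedGraph, and the TSV sample sheet that pairs experiments with
their controls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_COMMENT_PREFIXES = ("#", "track", "browser")

SAMPLE_SHEET_COLUMNS = ["sample_id", "role", "replicate_group", "target_bed", "spikein_bed"]


class FormatError(ValueError):
    """A record in a text file violates the format contract."""

    def __init__(self, message: str, path: str | os.PathLike | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp under half-open arithmetic (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class FragmentSet:
    """Fragments of one sample aligned to one genome (target or spike-in)."""

    sample_id: str
    genome_tag: str  # "target" or "spikein"
    fragments: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.genome_tag not in ("target", "spikein"):
            raise ValueError(f"genome_tag must be target/spikein, got {self.genome_tag!r}")

    def __len__(self) -> int:
        return len(self.fragments)

    def lengths(self) -> np.ndarray:
        return np.array([len(f) for f in self.fragments], dtype=np.int64)

    def midpoints(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments], dtype=np.int64)


@dataclass
class Peak:
    interval: GenomicInterval
    score: float = 0.0
    summit: int | None = None  # offset from interval.start
    name: str = ""

    def __post_init__(self):
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit} outside peak {self.name!r} "
                f"of length {len(self.interval)}")


@dataclass
class PeakSet:
    """A named, scored collection of peaks; names unique within the set."""

    peaks: list[Peak] = field(default_factory=list)
    provenance: list[tuple[str, ...]] | None = None  # per-peak contributing sources

    def __post_init__(self):
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate peak names: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.peaks], dtype=float)


@dataclass
class CoverageTrack:
    """Binned genome coverage. Bins tile [0, chrom length) half-open.

    ``values[chrom][i]`` is (signal bp in bin i) / bin_size, i.e. the mean
    per-base value over the bin; a partial last bin is still normalized by
    the full bin_size so that ``sum(values) * bin_size`` equals total signal
    bp exactly.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    values: dict[str, np.ndarray]
    normalized: bool = False
    scale_applied: float | None = None

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            n = n_bins(size, self.bin_size)
            v = np.asarray(self.values.get(chrom, np.zeros(n)), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{chrom}: expected {n} bins, got {v.shape}")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative coverage values")
            self.values[chrom] = v

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def mean(self) -> float:
        """Genome-wide per-base mean value."""
        total = sum(float(v.sum()) for v in self.values.values()) * self.bin_size
        return total / self.genome_length()

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean value over [start, end); positions outside the
        chromosome count as zero."""
        if chrom not in self.chrom_sizes or end <= start:
            return 0.0
        size = self.chrom_sizes[chrom]
        lo, hi = max(0, start), min(end, size)
        if hi <= lo:
            return 0.0
        v = self.values[chrom]
        b0, b1 = lo // self.bin_size, (hi - 1) // self.bin_size
        total = 0.0
        for b in range(b0, b1 + 1):
            bs, be = b * self.bin_size, min((b + 1) * self.bin_size, size)
            total += v[b] * (min(be, hi) - max(bs, lo))
        return total / (end - start)

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            chrom_sizes=dict(self.chrom_sizes), bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            normalized=self.normalized, scale_applied=self.scale_applied)


@dataclass
class SampleRow:
    sample_id: str
    role: str  # "experiment" or "control"
    replicate_group: str
    target_bed: str
    spikein_bed: str
    control_id: str | None = None


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self):
        ids = [r.sample_id for r in self.rows]
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            raise ValueError(f"duplicate sample_id(s): {dups}")
        known = set(ids)
        for r in self.rows:
            if r.role not in ("experiment", "control"):
                raise ValueError(f"{r.sample_id}: unknown role {r.role!r}")
            if r.control_id:
                if r.control_id not in known:
                    raise ValueError(
                        f"{r.sample_id}: control {r.control_id!r} not in sheet")
                if self[r.control_id].role != "control":
                    raise ValueError(
                        f"{r.sample_id}: control {r.control_id!r} has role "
                        f"{self[r.control_id].role!r}")

    def __getitem__(self, sample_id: str) -> SampleRow:
        for r in self.rows:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def experiments(self) -> list[SampleRow]:
        return [r for r in self.rows if r.role == "experiment"]

    def control_of(self, sample_id: str) -> SampleRow | None:
        row = self[sample_id]
        return self[row.control_id] if row.control_id else None


# ---------------------------------------------------------------------------
# helpers

def n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)


def _is_comment(line: str) -> bool:
    s = line.lstrip()
    return (not s) or any(s.startswith(p) for p in _COMMENT_PREFIXES)


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _is_comment(raw):
                continue
            yield lineno, raw.rstrip("\n").split("\t")


def _parse_coords(fields, path, lineno) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise FormatError(f"expected >=3 tab-separated columns, got {len(fields)}",
                          path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"non-integer coordinate: {exc}", path, lineno) from None
    if not chrom or start < 0 or start >= end:
        raise FormatError(f"invalid interval {chrom}:{start}-{end}", path, lineno)
    return chrom, start, end


# ---------------------------------------------------------------------------
# parsers / writers

def parse_fragments(path, sample_id: str, genome_tag: str = "target") -> FragmentSet:
    """Read a BED3+ fragment file into a :class:`FragmentSet`.

    Columns beyond chrom/start/end are ignored except a strand in column 6.
    Raises :class:`FormatError` with the offending line number on malformed
    records (start >= end, non-integer coordinates).
    """
    frags = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, path, lineno)
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        frags.append(GenomicInterval(chrom, start, end, strand))
    return FragmentSet(sample_id=sample_id, genome_tag=genome_tag, fragments=frags)


def write_fragments(frags: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for f in frags.fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def parse_peaks(path) -> PeakSet:
    """Read BED3/BED6 or ENCODE narrowPeak into a :class:`PeakSet`.

    For narrowPeak the signalValue column (7) becomes the score and the
    point-source column (10) the summit offset; -1 means no summit. BED3
    records get score 0 and no summit; unnamed records are auto-named.
    """
    peaks = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, path, lineno)
        name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") \
            else f"peak_{len(peaks) + 1}"
        score, summit = 0.0, None
        if len(fields) >= 10:  # narrowPeak
            try:
                score = float(fields[6])
                s = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"bad narrowPeak fields: {exc}", path, lineno) from None
            if s != -1:
                if not (0 <= s < end - start):
                    raise FormatError(
                        f"summit offset {s} outside interval of length {end - start}",
                        path, lineno)
                summit = s
        elif len(fields) >= 5:
            try:
                score = float(fields[4])
            except ValueError:
                raise FormatError(f"non-numeric score {fields[4]!r}", path, lineno) \
                    from None
        try:
            peaks.append(Peak(GenomicInterval(chrom, start, end), score, summit, name))
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno) from None
    return PeakSet(peaks=peaks)


def write_narrowpeak(peaks: PeakSet, path, header: str | None = None) -> None:
    """Write a PeakSet as ENCODE narrowPeak (score in signalValue col 7)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit is None else p.summit
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t"
                     f"{p.score:.17g}\t-1\t-1\t{summit}\n")


def parse_bedgraph(path, bin_size: int = 10,
                   chrom_sizes: dict[str, int] | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph onto a regular bin grid.

    Each bin's value is the length-weighted mean of the overlapping segments,
    with uncovered bp counting as zero. Chromosome lengths default to the
    maximum segment end seen. Overlapping segments are an error.
    """
    segs: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(f"expected 4 columns, got {len(fields)}", path, lineno)
        chrom, start, end = _parse_coords(fields, path, lineno)
        try:
            value = float(fields[3])
        except ValueError:
            raise FormatError(f"non-numeric value {fields[3]!r}", path, lineno) from None
        if value < 0:
            raise FormatError(f"negative coverage {value}", path, lineno)
        segs.setdefault(chrom, []).append((start, end, value))

    if chrom_sizes is None:
        chrom_sizes = {c: max(e for _, e, _ in s) for c, s in segs.items()}
    values = {}
    for chrom, size in chrom_sizes.items():
        chrom_segs = sorted(segs.get(chrom, []))
        prev_end = -1
        acc = np.zeros(n_bins(size, bin_size))
        for start, end, value in chrom_segs:
            if start < prev_end:
                raise FormatError(f"overlapping bedGraph segments on {chrom} at {start}",
                                  path)
            prev_end = end
            if end > size:
                raise FormatError(f"segment end {end} beyond {chrom} length {size}", path)
            if value:
                _accumulate_weighted(acc, start, end, value, bin_size)
        values[chrom] = acc
    return CoverageTrack(chrom_sizes=chrom_sizes, bin_size=bin_size, values=values)


def _accumulate_weighted(acc: np.ndarray, start: int, end: int, value: float,
                         bin_size: int) -> None:
    """Add value * (overlap bp / bin_size) of segment [start, end) into the
    per-bin means; the weight is exactly 1.0 for fully covered bins so that
    whole-bin segments round-trip bit-exactly."""
    b0, b1 = start // bin_size, (end - 1) // bin_size
    if b0 == b1:
        acc[b0] += value * ((end - start) / bin_size)
        return
    acc[b0] += value * (((b0 + 1) * bin_size - start) / bin_size)
    acc[b1] += value * ((end - b1 * bin_size) / bin_size)
    if b1 > b0 + 1:
        acc[b0 + 1:b1] += value


def write_bedgraph(track: CoverageTrack, path, header: str | None = None) -> None:
    """Write a binned track as bedGraph, merging runs of equal-valued bins
    and omitting zero runs."""
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        for chrom in track.chrom_sizes:
            size = track.chrom_sizes[chrom]
            v = track.values[chrom]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[j + 1] == v[i]:
                    j += 1
                if v[i] != 0:
                    start = i * track.bin_size
                    end = min((j + 1) * track.bin_size, size)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v[i]:.17g}\n")
                i = j + 1


def parse_sample_sheet(path) -> SampleSheet:
    """Read the TSV sample sheet; the optional ``control`` column links an
    experiment row to its control row by sample_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s) {missing}", path)
    rows = []
    for _, rec in df.iterrows():
        rows.append(SampleRow(
            sample_id=rec["sample_id"], role=rec["role"],
            replicate_group=rec["replicate_group"],
            target_bed=rec["target_bed"], spikein_bed=rec["spikein_bed"],
            control_id=rec.get("control", "") or None))
    try:
        return SampleSheet(rows=rows)
    except ValueError as exc:
        raise FormatError(str(exc), path) from None


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLE_SHEET_COLUMNS + ["control"]) + "\n")
        for r in sheet.rows:
            fh.write("\t".join([r.sample_id, r.role, r.replicate_group,
                                r.target_bed, r.spikein_bed, r.control_id or ""]) + "\n")


def fragments_to_coverage(frags: FragmentSet, chrom_sizes: dict[str, int],
                          bin_size: int = 10) -> CoverageTrack:
    """Pile fragments into binned coverage.

    Bin value = (sum of fragment overlap bp with the bin) / bin width, so the
    track conserves mass: sum(value_i * width_i) == total fragment bp.
    """
    per_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for f in frags.fragments:
        if f.chrom not in chrom_sizes:
            raise ValueError(f"fragment chrom {f.chrom!r} not in chrom_sizes")
        if f.end > chrom_sizes[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} beyond chrom end "
                f"{chrom_sizes[f.chrom]}")
        per_chrom[f.chrom].append(f)
    values = {}
    for chrom, size in chrom_sizes.items():
        # per-base depth by difference array, then per-bin means
        diff = np.zeros(size + 1, dtype=np.int64)
        for f in per_chrom[chrom]:
            diff[f.start] += 1
            diff[f.end] -= 1
        depth = np.cumsum(diff[:-1])
        nb = n_bins(size, bin_size)
        sums = np.zeros(nb)
        full = size // bin_size
        if full:
            sums[:full] = depth[:full * bin_size].reshape(full, bin_size).sum(axis=1)
        if full < nb:
            sums[full] = depth[full * bin_size:].sum()
        values[chrom] = sums / bin_size
    return CoverageTrack(chrom_sizes=dict(chrom_sizes), bin_size=bin_size, values=values)
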