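"""Piggy-back binding candidates from motif enrichment plus affinity-MS.

A factor without (or beyond) its own DNA contact can be recruited to
chromatin by riding on a sequence-specific partner. Candidates for such
partners are found by (i) scanning peak sequences of the bait with a
collection of position weight matrices, (ii) testing each motif for
enrichment at peaks versus length-matched random background regions with a
one-sided hypergeometric (Fisher) test at region level, and (iii) keeping
enriched motifs whose associated proteins also co-purify in the bait's
affinity mass-spectrometry table. The inference is necessarily limited to
partners with a known DNA motif; MS proteins lacking any motif in the
collection are reported separately rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import FormatError, GenomicInterval, Peak, PeakSet
from .peakops import bh_qvalues

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_THRESHOLD_FRAC = 0.8  # of the PWM's maximum attainable log-odds


@dataclass
class PWM:
    """Position probability matrix (L x 4, columns A,C,G,T) with the
    proteins known to bind the motif."""

    motif_id: str
    matrix: np.ndarray
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2(p / bg) per position and base; zero probabilities floored."""
        return np.log2(np.maximum(self.matrix, 1e-12) / background)

    def max_score(self, background: np.ndarray) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(motif_id=self.motif_id, matrix=self.matrix[::-1, ::-1].copy(),
                   proteins=list(self.proteins))


def parse_pwms(path, min_length: int = 4) -> list[PWM]:
    """Read a plain-text motif file: ``MOTIF <id>`` lines each followed by
    L whitespace-separated rows of 4 base probabilities (a
    ``letter-probability matrix`` header line between them is tolerated)."""
    pwms: list[PWM] = []
    name, rows = None, []

    def flush(lineno):
        if name is None:
            return
        if len(rows) < min_length:
            raise FormatError(f"motif {name}: length {len(rows)} < {min_length}",
                              path, lineno)
        pwms.append(PWM(motif_id=name, matrix=np.array(rows)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("MOTIF"):
                flush(lineno)
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError("MOTIF line without an id", path, lineno)
                name, rows = parts[1], []
            elif line.lower().startswith("letter-probability"):
                continue
            else:
                vals = line.split()
                if len(vals) != 4:
                    raise FormatError(f"expected 4 probabilities, got {len(vals)}",
                                      path, lineno)
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise FormatError(f"non-numeric probability in {line!r}",
                                      path, lineno) from None
        flush(None)
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate motif ids", path)
    return pwms


def write_pwms(pwms: list[PWM], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def base_frequencies(sequences: dict[str, str]) -> np.ndarray:
    """A/C/G/T frequencies over all sequences (N ignored); uniform if empty."""
    counts = np.zeros(4)
    for seq in sequences.values():
        arr = _encode(seq)
        valid = arr >= 0
        if valid.any():
            counts += np.bincount(arr[valid], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr].astype(np.int64)


def _scan_one_strand(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; offsets whose window contains an
    ambiguous base score -inf."""
    L = lom.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        window = codes[j:j + n]
        ok = window >= 0
        bad |= ~ok
        scores += np.where(ok, lom[j, np.clip(window, 0, 3)], 0.0)
    scores[bad] = -np.inf
    return scores


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    region: str
    offset: int
    strand: str
    score: float


def scan_pwm(sequences: dict[str, str], pwm: PWM,
             background: np.ndarray | None = None,
             threshold: float | None = None) -> list[MotifHit]:
    """Scan named sequences with a PWM on both strands.

    The score at an offset is the summed log2(p/bg) over the motif window;
    windows containing N are skipped. ``threshold`` defaults to 80% of the
    motif's maximum attainable score. Reverse-strand hits are reported at
    their forward-coordinate offset.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background must be 4 frequencies summing to 1")
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRAC * pwm.max_score(bg)
    lom_fwd = pwm.log_odds(bg)
    lom_rev = pwm.reverse_complement().log_odds(bg)
    hits = []
    for region, seq in sequences.items():
        codes = _encode(seq)
        for strand, lom in (("+", lom_fwd), ("-", lom_rev)):
            scores = _scan_one_strand(codes, lom)
            for off in np.flatnonzero(scores >= threshold):
                hits.append(MotifHit(pwm.motif_id, region, int(off), strand,
                                     float(scores[off])))
    return hits


def extract_peak_sequences(genome: dict[str, str], peaks: PeakSet) -> dict[str, str]:
    out = {}
    for p in peaks:
        iv = p.interval
        if iv.chrom not in genome:
            raise KeyError(f"{p.name}: chrom {iv.chrom!r} not in genome")
        out[p.name] = genome[iv.chrom][iv.start:iv.end]
    return out


def generate_background_regions(peaks: PeakSet, chrom_sizes: dict[str, int],
                                seed: int, max_attempts: int = 1000) -> PeakSet:
    """Length-matched random regions placed uniformly outside the peaks
    (rejection sampling; deterministic given the seed)."""
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        occupied.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    out = []
    for p in peaks:
        length = len(p.interval)
        for _ in range(max_attempts):
            ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            size = chrom_sizes[chroms[ci]]
            if length > size:
                continue
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            if any(start < e and s < end
                   for s, e in occupied.get(chroms[ci], [])):
                continue
            out.append(Peak(GenomicInterval(chroms[ci], start, end),
                            name=f"bg_{p.name}"))
            break
        else:
            raise RuntimeError(
                f"could not place a background region for {p.name} after "
                f"{max_attempts} attempts; genome too crowded")
    return PeakSet(peaks=out)


def motif_enrichment(hits_peaks: list[MotifHit], hits_bg: list[MotifHit],
                     n_peaks: int, n_bg: int,
                     motif_ids: list[str] | None = None) -> pd.DataFrame:
    """Region-level motif enrichment, peaks vs background.

    k = peak regions with >=1 hit, k_bg likewise; one-sided p is the
    hypergeometric upper tail of k on the 2x2 table (at least k of the n
    peak regions among the k + k_bg hit-positive regions). Odds ratios are
    Haldane-corrected; BH across motifs.
    """
    if n_peaks < 1 or n_bg < 1:
        raise ValueError("need at least one peak and one background region")
    if motif_ids is None:
        motif_ids = sorted({h.motif_id for h in hits_peaks}
                           | {h.motif_id for h in hits_bg})
    rows = []
    for mid in motif_ids:
        k = len({h.region for h in hits_peaks if h.motif_id == mid})
        k_bg = len({h.region for h in hits_bg if h.motif_id == mid})
        p = float(sps.hypergeom.sf(k - 1, n_peaks + n_bg, k + k_bg, n_peaks))
        orr = ((k + 0.5) * (n_bg - k_bg + 0.5)) / ((n_peaks - k + 0.5) * (k_bg + 0.5))
        rows.append({"motif_id": mid, "k": k, "n": n_peaks,
                     "k_bg": k_bg, "n_bg": n_bg, "odds_ratio": orr, "p": p})
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["motif_id", "k", "n", "k_bg", "n_bg", "odds_ratio", "p"])
    df["q"] = bh_qvalues(df["p"].to_numpy()) if len(df) else []
    return df


def piggyback_candidates(enrichment: pd.DataFrame, pwms: list[PWM],
                         ms_table: dict[str, float], alpha: float = 0.05,
                         bait_motif_id: str | None = None
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Rank piggy-back partner candidates.

    A candidate is a protein mapped from a motif enriched at the bait's
    peaks (q < alpha, bait's own motif excluded) that also appears in the
    affinity-MS table; ranked by (q ascending, MS abundance descending).
    Also returns the MS proteins that lack any motif in the collection —
    the blind spot of motif-limited inference.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    protein_motifs: dict[str, list[str]] = {}
    for pwm in sorted(pwms, key=lambda m: m.motif_id):
        for prot in pwm.proteins:
            protein_motifs.setdefault(prot, []).append(pwm.motif_id)
    qmap = dict(zip(enrichment["motif_id"], enrichment["q"])) if len(enrichment) else {}
    rows = []
    for prot, motifs in protein_motifs.items():
        if prot not in ms_table:
            continue
        for mid in motifs:
            if bait_motif_id is not None and mid == bait_motif_id:
                continue
            q = qmap.get(mid)
            if q is not None and q < alpha:
                rows.append({"protein_id": prot, "motif_id": mid,
                             "enrichment_q": float(q),
                             "ms_abundance": float(ms_table[prot])})
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["protein_id", "motif_id", "enrichment_q", "ms_abundance"])
    if len(df):
        df = df.sort_values(["enrichment_q", "ms_abundance", "protein_id"],
                            ascending=[True, False, True], kind="stable")
        df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    no_motif = sorted(p for p in ms_table if p not in protein_motifs)
    return df, no_motif


def parse_motif_protein_map(path) -> dict[str, list[str]]:
    """TSV ``motif_id<TAB>protein_id`` (one pair per line) -> mapping."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("motif_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError("expected motif_id<TAB>protein_id", path, lineno)
            out.setdefault(parts[0], []).append(parts[1])
    return out


def attach_proteins(pwms: list[PWM], mapping: dict[str, list[str]]) -> None:
    for pwm in pwms:
        pwm.proteins = list(mapping.get(pwm.motif_id, []))


def parse_ms_table(path) -> dict[str, float]:
    """TSV ``protein_id<TAB>abundance`` -> mapping."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError("expected protein_id<TAB>abundance", path, lineno)
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                raise FormatError(f"non-numeric abundance {parts[1]!r}",
                                  path, lineno) from None
    return out
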