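"""Irreproducible discovery rate analysis for replicate peak calls.

Replicate peak scores are matched by reciprocal best overlap, converted to
normal pseudo-values through their ranks (z = Phi^-1((n - rank + 0.5)/n),
rank 1 = best score, average ranks for ties), and modeled as a two-component
bivariate Gaussian mixture: an uncorrelated standard-normal "irreproducible"
component and a correlated, shifted "reproducible" component

    (1 - pi) N2(0, 0, 1, 1, 0)  +  pi N2(mu, mu, sigma^2, sigma^2, rho).

The mixture is fitted by EM with closed-form M-steps under the exchangeable
constraint (equal means and variances in both replicates). The local idr of
a peak pair is the posterior probability of the irreproducible component;
the global IDR at rank i (pairs sorted by local idr) is the mean of the i
smallest local idrs — the expected irreproducible fraction among the top i
selected pairs. Selection keeps pairs with global IDR below a threshold.

This is the plug-in (parametric pseudo-value) variant of IDR: deterministic
and exactly reproducible, at the cost of ignoring the uncertainty of the
rank transform handled by the semi-parametric original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .core_io import GenomicInterval, Peak, PeakSet

MIN_PAIRS = 10  # below this the two-component mixture is unidentifiable


@dataclass
class IDRModel:
    pi: float = 0.5
    mu: float = 1.0
    sigma: float = 1.0
    rho: float = 0.5
    converged: bool = False
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def validate(self):
        if not (0 <= self.pi <= 1):
            raise ValueError("pi must lie in [0, 1]")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")


@dataclass
class MatchedPeaks:
    """Reciprocally matched replicate peaks with their scores."""

    peaks1: list[Peak]
    peaks2: list[Peak]
    n_unmatched1: int
    n_unmatched2: int

    def __len__(self) -> int:
        return len(self.peaks1)

    def scores(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([p.score for p in self.peaks1]),
                np.array([p.score for p in self.peaks2]))


def match_replicate_peaks(peaks1: PeakSet, peaks2: PeakSet) -> MatchedPeaks:
    """Pair peaks across replicates by reciprocal maximal overlap.

    Each peak is linked to the opposite-set peak with the largest bp overlap
    (ties: leftmost); only mutual best pairs are kept. Raises if the
    replicates share no overlapping peaks.
    """
    best12 = _best_overlap(peaks1, peaks2)
    best21 = _best_overlap(peaks2, peaks1)
    pairs = [(i, j) for i, j in enumerate(best12)
             if j is not None and best21[j] == i]
    if not pairs:
        raise ValueError("replicates share no overlapping peaks")
    return MatchedPeaks(
        peaks1=[peaks1.peaks[i] for i, _ in pairs],
        peaks2=[peaks2.peaks[j] for _, j in pairs],
        n_unmatched1=len(peaks1) - len(pairs),
        n_unmatched2=len(peaks2) - len(pairs))


def _best_overlap(a: PeakSet, b: PeakSet) -> list[int | None]:
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, p in enumerate(b):
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out: list[int | None] = []
    for p in a:
        cands = by_chrom.get(p.interval.chrom, [])
        best_j, best_ov = None, 0
        for start, end, j in cands:
            if start >= p.interval.end:
                break
            ov = min(end, p.interval.end) - max(start, p.interval.start)
            if ov > best_ov:
                best_ov, best_j = ov, j
        out.append(best_j)
    return out


def ranks_to_pseudovalues(scores, min_n: int = MIN_PAIRS) -> np.ndarray:
    """Normal pseudo-values z_i = Phi^-1((n - rank_i + 0.5)/n) with rank 1 =
    largest score and average ranks for ties."""
    s = np.asarray(scores, dtype=float)
    if len(s) < min_n:
        raise ValueError(f"need at least {min_n} scores for a stable mixture "
                         f"fit, got {len(s)}")
    rank = sps.rankdata(-s, method="average")
    return sps.norm.ppf((len(s) - rank + 0.5) / len(s))


def _log_densities(x: np.ndarray, y: np.ndarray,
                   model: IDRModel) -> tuple[np.ndarray, np.ndarray]:
    log_f0 = -np.log(2 * np.pi) - 0.5 * (x ** 2 + y ** 2)
    s2, rho = model.sigma ** 2, model.rho
    dx, dy = x - model.mu, y - model.mu
    quad = (dx ** 2 - 2 * rho * dx * dy + dy ** 2) / (s2 * (1 - rho ** 2))
    log_f1 = (-np.log(2 * np.pi) - np.log(s2) - 0.5 * np.log(1 - rho ** 2)
              - 0.5 * quad)
    return log_f0, log_f1


def mixture_loglik(x: np.ndarray, y: np.ndarray, model: IDRModel) -> float:
    log_f0, log_f1 = _log_densities(x, y, model)
    comp = np.stack([np.log1p(-model.pi) + log_f0
                     if model.pi < 1 else np.full_like(log_f0, -np.inf),
                     np.log(model.pi) + log_f1
                     if model.pi > 0 else np.full_like(log_f1, -np.inf)])
    return float(logsumexp(comp, axis=0).sum())


def fit_copula_mixture(x, y, init: IDRModel | None = None, tol: float = 1e-6,
                       max_iter: int = 500) -> IDRModel:
    """EM fit of the two-component exchangeable Gaussian mixture.

    E-step: posterior responsibility of the reproducible component per pair.
    M-step: closed-form weighted updates of pi, mu, sigma^2, rho. Stops when
    the log-likelihood gain drops below ``tol``. Parameters are clamped to
    their domains; convergence of pi to 0 or 1 is flagged ``degenerate``
    rather than raised, since it is the honest answer on single-component
    data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite pseudo-values")
    m = IDRModel() if init is None else IDRModel(
        pi=init.pi, mu=init.mu, sigma=init.sigma, rho=init.rho)
    m.validate()
    eps = 1e-6
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        log_f0, log_f1 = _log_densities(x, y, m)
        la = np.log(max(m.pi, 1e-300)) + log_f1
        lb = np.log(max(1 - m.pi, 1e-300)) + log_f0
        norm = np.logaddexp(la, lb)
        gamma = np.exp(la - norm)  # P(reproducible | pair)
        ll = float(norm.sum())
        m.loglik_trace.append(ll)
        m.n_iter = it
        if ll - prev_ll < tol and it > 1:
            m.converged = True
            break
        prev_ll = ll
        # M-step (exchangeable: pool both coordinates)
        g = gamma.sum()
        if g < eps or g > len(x) - eps:
            m.degenerate = True
        g = max(g, 1e-12)
        m.pi = float(np.clip(gamma.mean(), eps, 1 - eps))
        mu = float((gamma * (x + y)).sum() / (2 * g))
        m.mu = max(mu, 1e-8)
        dx, dy = x - m.mu, y - m.mu
        s2 = float((gamma * (dx ** 2 + dy ** 2)).sum() / (2 * g))
        m.sigma = float(np.sqrt(max(s2, 1e-8)))
        rho = float((gamma * dx * dy).sum() / (g * max(s2, 1e-12)))
        m.rho = float(np.clip(rho, 1e-8, 1 - 1e-6))
    if m.pi <= eps or m.pi >= 1 - eps:
        m.degenerate = True
    if m.mu <= 1e-3 and m.rho <= 0.05:
        # the "reproducible" component collapsed onto the noise component:
        # the likelihood is then flat in pi, so report pure noise explicitly
        m.degenerate = True
        m.pi = eps
    return m


def compute_idr(model: IDRModel, x, y) -> pd.DataFrame:
    """Local idr (posterior irreproducible probability) and global IDR
    (running mean of sorted local idrs) per pair, in input order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    log_f0, log_f1 = _log_densities(x, y, model)
    la = np.log(max(model.pi, 1e-300)) + log_f1
    lb = np.log(max(1 - model.pi, 1e-300)) + log_f0
    local = np.exp(lb - np.logaddexp(la, lb))
    order = np.argsort(local, kind="stable")
    cummean = np.cumsum(local[order]) / np.arange(1, len(local) + 1)
    global_idr = np.empty_like(local)
    global_idr[order] = cummean
    return pd.DataFrame({"score1": x, "score2": y,
                         "local_idr": local, "global_idr": global_idr})


def idr_select(result: pd.DataFrame, matched: MatchedPeaks,
               threshold: float = 0.05) -> PeakSet:
    """Reproducible peaks: pairs with global IDR < threshold, reported as
    the intersection interval of the pair with the mean of the two scores."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    keep = np.flatnonzero(result["global_idr"].to_numpy() < threshold)
    peaks = []
    for rank, i in enumerate(keep, start=1):
        p1, p2 = matched.peaks1[i], matched.peaks2[i]
        start = max(p1.interval.start, p2.interval.start)
        end = min(p1.interval.end, p2.interval.end)
        peaks.append(Peak(GenomicInterval(p1.interval.chrom, start, end),
                          score=(p1.score + p2.score) / 2.0,
                          name=f"idr_peak_{rank}"))
    return PeakSet(peaks=peaks)
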