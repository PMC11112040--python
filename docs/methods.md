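# Methods

This note records the models, conventions, numerical choices, and known
limitations behind cutrunkit, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, containers, and I/O

All coordinates are 0-based half-open (BED convention) throughout the
library; 1-based formats would be converted at the parsing boundary.
Fragments are unstranded intervals: a paired-end CUT&RUN fragment spans
both mates, so strand carries no information here. Coverage tracks are
binned; bin *i* of a chromosome holds (signal bp in bin)/bin_size, so
`sum(values) * bin_size` equals total signal bp exactly (a partial last bin
is still normalized by the full bin size — the track is mass-conserving by
construction, at the cost of a slight underestimate of per-base depth in a
trailing partial bin). Default bin size is 10 bp; no published convention
exists for this choice, and every window parameter must be a multiple of
it. bedGraph parsing resamples onto the bin grid by length-weighted means
with uncovered bp counting as zero; full-bin segments round-trip
bit-exactly. All parsers reject records violating the half-open invariants
with a line-numbered error, and skip `#`/`track`/`browser` lines.

## Spike-in model

Spike-in DNA (synthetic, heterologous chromatin, or carry-over *E. coli*)
is present at an amount per cell that is constant across samples, so the
spike-in read count is the yardstick for cross-sample scaling. Two
quantities are deliberately distinct:

- the **proportion** p = N_spike/(N_total+N_spike), used for QC
  comparisons (a control's proportion exceeding its experiment's signals
  an inverted signal-to-background relationship);
- the **ratio** N_spike/N_total, used inside the scale factor.

The depth-adjusted factor is f_i = S / ((N_spike,i/N_total,i) · T̄) with T̄
the arithmetic mean of target depths over the jointly normalized set and
S = 10 000 by default (a conventional constant; it only sets the overall
scale). The defining constraints are (a) the formula involves the total
read count and (b) at equal depths it reduces exactly to the classic
S/N_spike. The implementation treats the formula as a swappable strategy
behind `compute_scale_factors`, since other closed forms satisfy the same
constraints. The factor is permutation-equivariant in the sample list and
rejects samples without spike-in reads rather than silently falling back
to depth-only scaling.

QC uses a closed advisory band [1/4, 1/3] for the control/experiment depth
ratio ("one-third or one-fourth" read without strictness), and never
aborts: the report is data, not an exception.

## Window Poisson peak caller

The caller is a deliberately simple, fully specified stand-in for external
peak callers, so that every p-value it emits is oracle-checkable. Windowed
scaled coverage is converted to approximate fragment counts by dividing
coverage bp by a typical fragment length (default 150 bp, a parameter).
Each window's count k is tested against Poisson(λ),
λ = max(local control mean over 10 kb, genome-wide mean), the standard
local-background guard; p = P(X ≥ k) from the exact survival function,
BH-corrected over all windows. Windows with q below threshold and fold
k/λ ≥ min_fold merge when closer than `merge_gap`; the summit is the
highest-coverage bin, the score the best window fold (the usual
narrowPeak signalValue semantics). Because a fragment contributes at most
1 to a window's pseudo-count, the statistic is under- rather than
over-dispersed relative to Poisson, making the test conservative at the
margins. Limitations: no replicate dispersion model and no broad-domain
mode; those are out of scope.

Differential occupancy uses the exact conditional binomial test described
in the README, with w derived from the reciprocal scale factors (the share
of *raw* counts condition A should contribute when normalized occupancy is
equal). The two-sided p is the minlike sum, which makes the test exactly
anti-symmetric under swapping conditions. log₂ fold changes use a 0.5
pseudo-count so zero counts stay finite. The test conditions away library
size but ignores biological replicate variability — with replicates, a
dispersion-based tool is the right escalation; counts here use one
representative replicate per condition.

## Fragment-length classification (Bulky/NonBulky)

Fragments are assigned to peaks by midpoint (consistent with counting;
avoids double-assignment between adjacent peaks). The two samples' length
distributions per peak are compared by a two-sided Mann–Whitney U test.
For combined n ≤ 20 the p-value is exact: the doubled midranks are
integers, so the full rank-sum null distribution is computed by a
subset-sum dynamic program (ties handled exactly); p = min(1, 2·min(P(R ≤
r), P(R ≥ r))). Larger peaks use the tie-corrected normal approximation
with continuity correction. BH runs across testable peaks only; peaks with
fewer than `min_n` (default 5) fragments in either sample are flagged
untestable rather than silently dropped. The classifier reports coverage
alongside the length test but does not covariate-adjust for it; "Bulky"
means the *length* difference is significant, whatever the coverage does.

## Background ceilings and unique peaks

The null question "how high could this sample's coverage get anywhere in
the genome by chance?" is answered by Monte-Carlo: every fragment is
re-placed uniformly at random — chromosome drawn proportional to length,
start uniform on [0, L − len], fragment lengths preserved — and the
maximum fragment count over all w-bp sliding windows (default w = 500) is
recorded; the ceiling is the maximum over `n_sims` simulations (default
100 in the library, 50 in the pipeline stage for speed). The placement
rule is part of the model definition; the window maximum is computed by a
difference-array sweep and is checked in the tests against an independent
event-point algorithm on the same placements.

A peak of experiment A is **unique** versus experiment B iff B's mean
coverage over the peak stays at or below B's ceiling *and* A's reaches at
least `ratio` (default 4) times that ceiling. The ratio threshold is
applied to the simulated ceiling — tying the rule to the background model —
with `mode="observed"` available to compare against 4× B's observed
coverage instead. The ceiling is a window fragment *count* while tracks
hold per-base depth; the pipeline stage converts the ceiling to the
tracks' units by ceiling · L̄/(w + L̄) · f_B (a fragment of length L̄
overlaps a w-window over w + L̄ start positions) before comparing. Both
tracks must be on the same normalization status; mixing is an error.

## IDR

This is the plug-in (parametric pseudo-value) IDR variant: deterministic,
closed-form, and exactly testable, rather than the semi-parametric
pseudo-likelihood of the original method — a deliberate trade of marginal
flexibility for reproducibility. Replicate peaks are paired by reciprocal
best overlap (ties to the leftmost). Scores map to z = Φ⁻¹((n − rank +
½)/n) with average ranks for ties; fewer than 10 pairs is an error (the
mixture is unidentifiable). The EM fit of
(1−π)·N₂(0,I) + π·N₂(μ,μ,σ²,σ²,ρ) uses closed-form exchangeable M-steps,
initialization (π, μ, σ, ρ) = (0.5, 1, 1, 0.5), tolerance 1e−6 on the
log-likelihood, max 500 iterations, and clamps parameters to their
domains. Convergence of π to a boundary is flagged degenerate, not fatal.
When the fitted signal component collapses onto the noise component
(μ ≤ 1e−3 and ρ ≤ 0.05) the likelihood is flat in π, so the fit reports
π → 0 explicitly — pure noise is then the honest answer. Selection uses
the global IDR (cumulative mean of sorted local idrs) at threshold 0.05;
selected pairs are reported as the intersection interval with averaged
scores. Only two replicates are supported.

## Piggy-back inference

Scanning is log₂(p/background) summed over the motif window, both strands,
windows containing N skipped; the default threshold is 80 % of each PWM's
maximum attainable score and background base frequencies are estimated
from the supplied genome. Enrichment is counted at region level (a region
with ≥ 1 hit counts once — robust to hit clustering) against
length-matched background regions placed uniformly outside the peaks by
rejection sampling (1000 attempts per region, then an error). The
one-sided hypergeometric upper tail on the 2×2 region table gives p; BH
across motifs; odds ratios are Haldane-corrected. Candidates are proteins
of enriched motifs (q < α) that appear in the affinity-MS table, ranked by
(q ascending, abundance descending), with the bait's own motif excluded:
the inference direction is that the bait rides on sequence-specific
partners whose motifs mark its peaks and which co-purify with it. The
approach is blind to partners without a known motif; those MS proteins are
listed separately instead of being dropped silently. MS preprocessing
(normalization, imputation) is out of scope.

## Annotation and unified output

Overlap annotation uses ≥ 1 bp half-open overlap; the fraction is measured
against the peak (not the annotation), with each set's intervals unioned
first. Enhancer–gene links emit one row per overlapping (peak, enhancer)
pair; the unified table deduplicates per (peak, gene) keeping maximum
confidence. Nearest-feature distances are signed (negative upstream, ties
downstream, 0 on overlap). The unified output is a single left-join on
peak name — one row per peak always — with `block.field` column names and
explicit NA for analyses that did not cover a peak; coordinate conflicts
between tables are an error, not a silent overwrite. Annotation databases
are inputs, never bundled.

## Synthetic data generator

The generator emulates: uniform background fragment release over the
genome; focal sites adding Poisson((fold−1)·n_bg·width/genome) extra
fragments with centers normal around the site midpoint (sd = width/8);
per-condition fragment-length normals (default 150 ± 25 bp, floored at
30 bp — a sub-nucleosomal minimum); and spike-in fragments on a separate
100 kb toy genome at a count giving the configured spike-in read fraction.
One global seed drives everything; per-sample substreams come from SHA-256
hashing of the sample id, so outputs are bit-identical across runs and
independent across samples.

It does **not** emulate: sequence-composition bias, mappability, chromatin
accessibility structure in the background, MNase sequence preference,
PCR duplicates, or read-level errors (no FASTQ). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data artifacts.

The bundled study (`cutrunkit simulate`) uses a 200 kb genome, two
conditions × two replicates at 20 k background fragments (~15× depth), 5 %
spike-in, and 14 true 1 kb sites: eight shared at 10-fold (two with a
230 ± 30 bp fragment-length shift in condition B), three per condition at
16-fold — strong enough to clear the 4×-ceiling unique rule decisively,
since the ceiling is a maximum (not a mean) of the background null. The
control is generated at 30 % of the experiment depth with its spike-in
count solved so that its spike-normalized background depth equals the
experiments' — the relation a well-behaved experiment/control pair
satisfies, because both measure the same nonspecific background per unit
of spike-in material. The genome sequence is IID random (GC 0.4) with
10 bp consensus sites for a bait and a partner motif planted at every
condition-A peak; at the default 80 % scan threshold only exact 10-mers
score above threshold, so chance background hits are rare by construction.

Problem sizes in the test suite and acceptance script (1 Mb genome /
10⁵ fragments for caller recovery, 100 kb for the background-model oracle,
n = 10⁴ for IDR recovery, 1000 null peaks for calibration) were chosen as
the smallest sizes at which the checked quantities are statistically
stable.

## Command-line design

Configuration precedence is flags over defaults; all stages of one run
share a directory laid out by `simulate`. Resume-on-failure is reduced to:
a stage whose outputs exist is skipped unless `--force` — same user value,
simpler contract. Every output begins with a `# cutrunkit v… cmd=… seed=…`
provenance header, and identical inputs plus seed give byte-identical
outputs (no timestamps anywhere). The `all` subcommand invokes exactly the
same stage functions as the individual subcommands, which is what makes
end-to-end equal stepwise composition by construction.
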