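"""File-level pipeline stages and the synthetic study fixture.

Each stage reads and writes plain-text files inside one run directory laid
out by :func:`make_fixture` (the ``simulate`` subcommand), so the whole
analysis can run as ``cutrunkit all`` or as individual subcommands with
identical results. Every output starts with a provenance header recording
the version, the subcommand, its parameters, and the seed; a stage whose
outputs already exist is skipped unless forced.

The default fixture is a compact but complete study: a 200 kb single-chrom
target genome, two conditions x two replicates at 20k background fragments
each (~15x depth), a low-depth IgG-style control at 30% of the experiment
depth, 5% spike-in reads on a separate 100 kb spike genome, and 14 true
1 kb binding sites: eight shared between conditions (two with a fragment-
length shift in condition B), three specific to each condition at >=4-fold.
Bait and partner motif instances are planted at every condition-A site of
the accompanying random genome sequence, and the affinity-MS table carries
the bait, the partner, and a motif-less decoy protein.
"""

from __future__ import annotations

import hashlib
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, classify, core_io, idr, peakops, piggyback, \
    simulate, spikein

BAIT_MOTIF = "M_bait"
PARTNER_MOTIF = "M_partner"
DECOY_MOTIF = "M_decoy"
_MOTIF_CONSENSUS = {BAIT_MOTIF: "TTGACGTCAA", PARTNER_MOTIF: "CCAACGTTGG",
                    DECOY_MOTIF: "GATTACAGGT"}
_MOTIF_PROTEIN = {BAIT_MOTIF: "PROT_BAIT", PARTNER_MOTIF: "PROT_PARTNER",
                  DECOY_MOTIF: "PROT_ABSENT"}


def _derive_seed(seed: int, *keys: str) -> int:
    digest = hashlib.sha256((f"{seed}/" + "/".join(keys)).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def header(cmd: str, seed: int | None = None, **params) -> str:
    parts = [f"# cutrunkit v{__version__} cmd={cmd}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in sorted(params.items()))
    return " ".join(parts) + "\n"


def write_tsv(df: pd.DataFrame, path, head: str) -> None:
    with open(path, "w") as fh:
        fh.write(head)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            out[chrom] = int(size)
    return out


def _outputs_exist(paths) -> bool:
    return all(os.path.exists(p) for p in paths)


# ---------------------------------------------------------------------------
# fixture

def default_config(seed: int = 0, genome_size: int = 200_000,
                   n_background: int = 20_000,
                   spikein_fraction: float = 0.05) -> simulate.SimConfig:
    """The experiment-sample configuration of the bundled synthetic study."""
    conds = ["expA_r1", "expA_r2", "expB_r1", "expB_r2"]
    a_conds = ["expA_r1", "expA_r2"]
    b_conds = ["expB_r1", "expB_r2"]
    peaks = []
    width, spacing, first = 1000, 12_000, 10_000
    shifted_len = (230.0, 30.0)
    for i in range(14):
        start = first + i * spacing
        if start + width > genome_size:
            raise ValueError("genome too small for the default peak layout")
        if i < 8:  # shared sites
            enr = {c: 10.0 for c in conds}
            flen = {c: shifted_len for c in b_conds} if i in (1, 2) else None
        elif i < 11:  # condition-A specific, strong enough to clear the
            enr = {c: 16.0 for c in a_conds}  # 4x-background-ceiling rule
            flen = None
        else:  # condition-B specific
            enr = {c: 16.0 for c in b_conds}
            flen = None
        peaks.append(simulate.PeakSpec("chr1", start, start + width,
                                       enrichment=enr, frag_len=flen))
    return simulate.SimConfig(
        seed=seed, chrom_sizes={"chr1": genome_size},
        n_background_fragments=n_background, peaks=peaks,
        spikein_fraction=spikein_fraction, conditions=conds)


def make_fixture(outdir, seed: int = 0, genome_size: int = 200_000,
                 n_background: int = 20_000, spikein_fraction: float = 0.05,
                 ctrl_depth_ratio: float = 0.30) -> Path:
    """Write the complete synthetic study into ``outdir`` and return it.

    The control is generated at ``ctrl_depth_ratio`` of the expected
    experiment depth (the recommended one-third-ish regime) and its spike-in
    count is solved so that its spike-normalized background coverage matches
    the experiments' — the configuration a well-behaved experiment/control
    pair satisfies by construction, since both measure the same nonspecific
    background per unit of spike-in material.
    """
    out = Path(outdir)
    (out / "fragments").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    cfg = default_config(seed, genome_size, n_background, spikein_fraction)
    # expected experiment totals (peak extras on top of background)
    extra = sum((spec.fold_for(cfg.conditions[0]) - 1.0) * n_background
                * (spec.end - spec.start) / genome_size for spec in cfg.peaks)
    ntot_e = n_background + extra
    nspike_e = spikein_fraction / (1 - spikein_fraction) * ntot_e
    ntot_c = ctrl_depth_ratio * ntot_e
    # f_c * depth_c = f_e * background-depth_e under the depth-adjusted factor
    nspike_c = ntot_c ** 2 * nspike_e / (ntot_e * n_background)
    ctrl_spikein_fraction = nspike_c / (nspike_c + ntot_c)
    ctrl_background = int(round(ntot_c))
    targets, spikes, truth = simulate.simulate_experiment(cfg)
    ctrl_cfg = simulate.SimConfig(
        seed=seed, chrom_sizes=cfg.chrom_sizes,
        n_background_fragments=ctrl_background, peaks=[],
        spikein_fraction=ctrl_spikein_fraction, conditions=["ctrl"])
    ctrl_t, ctrl_s, _ = simulate.simulate_experiment(ctrl_cfg)
    targets.update(ctrl_t)
    spikes.update(ctrl_s)

    rows = []
    for cond in cfg.conditions + ["ctrl"]:
        tpath = out / "fragments" / f"{cond}.target.bed"
        spath = out / "fragments" / f"{cond}.spikein.bed"
        core_io.write_fragments(targets[cond], tpath)
        core_io.write_fragments(spikes[cond], spath)
        role = "control" if cond == "ctrl" else "experiment"
        group = "ctrl" if cond == "ctrl" else cond.split("_")[0][-1]  # A or B
        rows.append(core_io.SampleRow(
            sample_id=cond, role=role, replicate_group=group,
            target_bed=str(tpath.relative_to(out)),
            spikein_bed=str(spath.relative_to(out)),
            control_id=None if cond == "ctrl" else "ctrl"))
    core_io.write_sample_sheet(core_io.SampleSheet(rows=rows),
                               out / "sample_sheet.tsv")
    write_chrom_sizes(cfg.chrom_sizes, out / "chrom_sizes.tsv")
    write_chrom_sizes(cfg.spike_chrom_sizes, out / "spike_chrom_sizes.tsv")
    write_tsv(truth, out / "truth.tsv", header("simulate", seed))

    # genome sequence with bait + partner motif sites at condition-A peaks
    genome = simulate.random_genome(cfg.chrom_sizes, seed)
    a_bound = [s for s in cfg.peaks if s.fold_for("expA_r1") > 1]
    for spec in a_bound:
        mid = (spec.start + spec.end) // 2
        simulate.plant_motif(genome, spec.chrom, mid - 30,
                             _MOTIF_CONSENSUS[BAIT_MOTIF])
        simulate.plant_motif(genome, spec.chrom, mid + 15,
                             _MOTIF_CONSENSUS[PARTNER_MOTIF])
    simulate.write_fasta(genome, out / "genome.fa")

    pwms = [piggyback.PWM(mid, simulate.consensus_pwm(cons))
            for mid, cons in _MOTIF_CONSENSUS.items()]
    piggyback.write_pwms(pwms, out / "motifs.txt", header("simulate", seed))
    with open(out / "motif2protein.tsv", "w") as fh:
        fh.write(header("simulate", seed))
        fh.write("motif_id\tprotein_id\n")
        for mid, prot in _MOTIF_PROTEIN.items():
            fh.write(f"{mid}\t{prot}\n")
    with open(out / "ms_table.tsv", "w") as fh:
        fh.write(header("simulate", seed))
        fh.write("protein_id\tabundance\n")
        fh.write("PROT_BAIT\t1000.0\nPROT_PARTNER\t250.0\nPROT_NOMOTIF\t180.0\n")

    # annotation sets: "enhancers" around shared sites + decoys, "promoters"
    rng = np.random.default_rng(_derive_seed(seed, "annotations"))
    with open(out / "annotations" / "enhancers.bed", "w") as fh:
        fh.write(header("simulate", seed))
        for i, spec in enumerate(cfg.peaks[:8]):
            fh.write(f"{spec.chrom}\t{spec.start - 200}\t{spec.end + 200}\t"
                     f"enh_{i + 1}\n")
        for j in range(5):
            s = int(rng.integers(0, genome_size - 800))
            fh.write(f"chr1\t{s}\t{s + 800}\tenh_rand_{j + 1}\n")
    with open(out / "annotations" / "promoters.bed", "w") as fh:
        fh.write(header("simulate", seed))
        for j in range(10):
            s = int(rng.integers(0, genome_size - 1500))
            fh.write(f"chr1\t{s}\t{s + 1500}\tprom_{j + 1}\n")
    tissues = ["T_alpha", "T_beta"]
    with open(out / "egmap.tsv", "w") as fh:
        fh.write(header("simulate", seed))
        for i, spec in enumerate(cfg.peaks[:4]):
            conf = 0.6 + 0.1 * i
            fh.write(f"{spec.chrom}\t{spec.start - 200}\t{spec.end + 200}\t"
                     f"GENE{i + 1}\t{tissues[i % 2]}\t{conf:.2f}\n")
        spec = cfg.peaks[0]
        fh.write(f"{spec.chrom}\t{spec.start - 100}\t{spec.end + 100}\t"
                 f"GENE1\t{tissues[1]}\t0.55\n")
    return out


# ---------------------------------------------------------------------------
# shared loaders

def _load_sheet(dirpath: Path) -> core_io.SampleSheet:
    sheet = core_io.parse_sample_sheet(dirpath / "sample_sheet.tsv")
    for row in sheet.rows:  # paths are relative to the run directory
        row.target_bed = str(dirpath / row.target_bed)
        row.spikein_bed = str(dirpath / row.spikein_bed)
    return sheet


def _load_fragments(row: core_io.SampleRow) -> tuple[core_io.FragmentSet,
                                                     core_io.FragmentSet]:
    return (core_io.parse_fragments(row.target_bed, row.sample_id, "target"),
            core_io.parse_fragments(row.spikein_bed, row.sample_id, "spikein"))


def _load_factors(dirpath: Path) -> dict[str, float]:
    df = read_tsv(dirpath / "factors.tsv")
    return dict(zip(df["sample_id"], df["f"]))


def _group_reps(sheet: core_io.SampleSheet, group: str) -> list[core_io.SampleRow]:
    reps = [r for r in sheet.experiments() if r.replicate_group == group]
    if not reps:
        raise ValueError(f"no experiment samples in replicate group {group!r}")
    return reps


# ---------------------------------------------------------------------------
# stages

def stage_norm(dirpath, seed: int = 0, s_constant: float = spikein.DEFAULT_S,
               bin_size: int = 10, force: bool = False) -> None:
    dirpath = Path(dirpath)
    outs = [dirpath / "spikein_stats.tsv", dirpath / "factors.tsv",
            dirpath / "qc.tsv"]
    if _outputs_exist(outs) and not force:
        return
    sheet = _load_sheet(dirpath)
    sizes = read_chrom_sizes(dirpath / "chrom_sizes.tsv")
    stats = {}
    for row in sheet.rows:
        target, spike = _load_fragments(row)
        stats[row.sample_id] = spikein.spikein_stats(target, spike)
    stats_list = [stats[r.sample_id] for r in sheet.rows]
    factors = spikein.compute_scale_factors(stats_list, s_constant)
    head = header("norm", seed, S=s_constant, bin_size=bin_size)
    write_tsv(pd.DataFrame([{
        "sample_id": st.sample_id, "n_total": st.n_total, "n_spike": st.n_spike,
        "proportion": st.proportion} for st in stats_list]),
        dirpath / "spikein_stats.tsv", head)
    write_tsv(pd.DataFrame([{
        "sample_id": f.sample_id, "f": f.f, "S": f.s_constant, "t_bar": f.t_bar}
        for f in factors]), dirpath / "factors.tsv", head)
    write_tsv(spikein.qc_spikein(sheet, stats), dirpath / "qc.tsv", head)
    (dirpath / "coverage").mkdir(exist_ok=True)
    fmap = {f.sample_id: f for f in factors}
    for row in sheet.rows:
        target, _ = _load_fragments(row)
        track = core_io.fragments_to_coverage(target, sizes, bin_size)
        norm = spikein.normalize_coverage(track, fmap[row.sample_id])
        core_io.write_bedgraph(norm, dirpath / "coverage" /
                               f"{row.sample_id}.norm.bedgraph", head)


def stage_callpeaks(dirpath, seed: int = 0, bin_size: int = 10,
                    params: peakops.PeakCallParams | None = None,
                    force: bool = False) -> None:
    dirpath = Path(dirpath)
    params = params or peakops.PeakCallParams()
    sheet = _load_sheet(dirpath)
    sizes = read_chrom_sizes(dirpath / "chrom_sizes.tsv")
    factors = _load_factors(dirpath)
    (dirpath / "peaks").mkdir(exist_ok=True)
    head = header("callpeaks", seed, window=params.window, step=params.step,
                  q=params.q_threshold, min_fold=params.min_fold)
    for row in sheet.experiments():
        out = dirpath / "peaks" / f"{row.sample_id}.narrowPeak"
        if out.exists() and not force:
            continue
        target, _ = _load_fragments(row)
        exp_track = core_io.fragments_to_coverage(target, sizes, bin_size)
        ctrl_row = sheet.control_of(row.sample_id)
        ctrl_track, f_ctrl = None, None
        if ctrl_row is not None:
            ctrl_frags, _ = _load_fragments(ctrl_row)
            ctrl_track = core_io.fragments_to_coverage(ctrl_frags, sizes, bin_size)
            f_ctrl = factors[ctrl_row.sample_id]
        peaks = peakops.call_peaks(exp_track, ctrl_track,
                                   (factors[row.sample_id], f_ctrl), params)
        core_io.write_narrowpeak(peaks, out, head)


def stage_diffpeaks(dirpath, seed: int = 0, group_a: str = "A",
                    group_b: str = "B", alpha: float = 0.05,
                    force: bool = False) -> None:
    dirpath = Path(dirpath)
    outs = [dirpath / "union.narrowPeak", dirpath / "diff.tsv"]
    if _outputs_exist(outs) and not force:
        return
    sheet = _load_sheet(dirpath)
    factors = _load_factors(dirpath)
    reps_a, reps_b = _group_reps(sheet, group_a), _group_reps(sheet, group_b)
    sets, names = [], []
    for row in reps_a + reps_b:
        sets.append(core_io.parse_peaks(dirpath / "peaks" /
                                        f"{row.sample_id}.narrowPeak"))
        names.append(row.sample_id)
    union = peakops.union_peaks(sets, names)
    head = header("diffpeaks", seed, group_a=group_a, group_b=group_b, alpha=alpha)
    core_io.write_narrowpeak(union, dirpath / "union.narrowPeak", head)
    frags_a = core_io.parse_fragments(reps_a[0].target_bed, reps_a[0].sample_id)
    frags_b = core_io.parse_fragments(reps_b[0].target_bed, reps_b[0].sample_id)
    counts_a = peakops.count_fragments_in_peaks(frags_a, union)
    counts_b = peakops.count_fragments_in_peaks(frags_b, union)
    diff = peakops.differential_peaks(
        counts_a, counts_b, factors[reps_a[0].sample_id],
        factors[reps_b[0].sample_id], alpha,
        peak_names=[p.name for p in union])
    write_tsv(diff, dirpath / "diff.tsv", head)


def stage_classify(dirpath, seed: int = 0, bin_size: int = 10,
                   window: int = 500, n_sims: int = 50, alpha: float = 0.05,
                   ratio: float = 4.0, min_n: int = 5, frag_len: float = 150.0,
                   group_a: str = "A", group_b: str = "B",
                   force: bool = False) -> None:
    """Bulky/NonBulky over the union peaks plus unique-peak calls of
    condition A against condition B (first replicates)."""
    dirpath = Path(dirpath)
    outs = [dirpath / "bulky.tsv", dirpath / "unique.tsv",
            dirpath / "background.tsv"]
    if _outputs_exist(outs) and not force:
        return
    sheet = _load_sheet(dirpath)
    sizes = read_chrom_sizes(dirpath / "chrom_sizes.tsv")
    factors = _load_factors(dirpath)
    rep_a, rep_b = _group_reps(sheet, group_a)[0], _group_reps(sheet, group_b)[0]
    union = core_io.parse_peaks(dirpath / "union.narrowPeak")
    frags_a = core_io.parse_fragments(rep_a.target_bed, rep_a.sample_id)
    frags_b = core_io.parse_fragments(rep_b.target_bed, rep_b.sample_id)
    head = header("classify", seed, window=window, n_sims=n_sims, alpha=alpha,
                  ratio=ratio)
    bulky = classify.bulky_classification(frags_a, frags_b, union, alpha, min_n)
    write_tsv(bulky, dirpath / "bulky.tsv", head)

    bg_seed = _derive_seed(seed, "background", rep_b.sample_id)
    bg = classify.simulate_background(frags_b, sizes, window, n_sims, bg_seed)
    write_tsv(pd.DataFrame({"sim": np.arange(1, n_sims + 1),
                            "max_window_count": bg.per_sim_max}),
              dirpath / "background.tsv",
              head + f"# sample={rep_b.sample_id} ceiling={bg.ceiling}\n")
    f_a, f_b = factors[rep_a.sample_id], factors[rep_b.sample_id]
    cov_a = spikein.normalize_coverage(
        core_io.fragments_to_coverage(frags_a, sizes, bin_size), f_a)
    cov_b = spikein.normalize_coverage(
        core_io.fragments_to_coverage(frags_b, sizes, bin_size), f_b)
    # ceiling (a max window fragment count) -> normalized per-base depth units
    depth_ceiling = bg.ceiling * frag_len / (window + frag_len) * f_b
    uniq = classify.call_unique_peaks(union, cov_a, cov_b, bg, ratio,
                                      ceiling=depth_ceiling)
    write_tsv(uniq, dirpath / "unique.tsv", head)


def stage_idr(dirpath, seed: int = 0, threshold: float = 0.05,
              peaks1=None, peaks2=None, group: str = "A",
              force: bool = False) -> None:
    dirpath = Path(dirpath)
    outs = [dirpath / "idr.tsv", dirpath / "idr_selected.narrowPeak"]
    if _outputs_exist(outs) and not force:
        return
    if peaks1 is None or peaks2 is None:
        sheet = _load_sheet(dirpath)
        reps = _group_reps(sheet, group)
        if len(reps) < 2:
            raise ValueError(f"group {group!r} has fewer than two replicates")
        peaks1 = dirpath / "peaks" / f"{reps[0].sample_id}.narrowPeak"
        peaks2 = dirpath / "peaks" / f"{reps[1].sample_id}.narrowPeak"
    ps1, ps2 = core_io.parse_peaks(peaks1), core_io.parse_peaks(peaks2)
    matched = idr.match_replicate_peaks(ps1, ps2)
    s1, s2 = matched.scores()
    z1 = idr.ranks_to_pseudovalues(s1)
    z2 = idr.ranks_to_pseudovalues(s2)
    model = idr.fit_copula_mixture(z1, z2)
    result = idr.compute_idr(model, z1, z2)
    result.insert(0, "name", [p.name for p in matched.peaks1])
    head = header("idr", seed, threshold=threshold,
                  pi=f"{model.pi:.4f}", rho=f"{model.rho:.4f}",
                  converged=model.converged)
    write_tsv(result, dirpath / "idr.tsv", head)
    selected = idr.idr_select(result, matched, threshold)
    core_io.write_narrowpeak(selected, dirpath / "idr_selected.narrowPeak", head)


def stage_piggyback(dirpath, seed: int = 0, alpha: float = 0.05,
                    bait_motif: str | None = BAIT_MOTIF,
                    threshold_frac: float = piggyback.DEFAULT_THRESHOLD_FRAC,
                    group: str = "A", force: bool = False) -> None:
    dirpath = Path(dirpath)
    outs = [dirpath / "enrichment.tsv", dirpath / "candidates.tsv",
            dirpath / "no_motif_proteins.tsv"]
    if _outputs_exist(outs) and not force:
        return
    sheet = _load_sheet(dirpath)
    rep = _group_reps(sheet, group)[0]
    peaks = core_io.parse_peaks(dirpath / "peaks" / f"{rep.sample_id}.narrowPeak")
    genome = simulate.read_fasta(dirpath / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}
    pwms = piggyback.parse_pwms(dirpath / "motifs.txt")
    piggyback.attach_proteins(
        pwms, piggyback.parse_motif_protein_map(dirpath / "motif2protein.tsv"))
    ms = piggyback.parse_ms_table(dirpath / "ms_table.tsv")
    bg_regions = piggyback.generate_background_regions(
        peaks, sizes, _derive_seed(seed, "piggyback-bg"))
    bg_freqs = piggyback.base_frequencies(genome)
    seq_peaks = piggyback.extract_peak_sequences(genome, peaks)
    seq_bg = piggyback.extract_peak_sequences(genome, bg_regions)
    hits_p, hits_b = [], []
    for pwm in pwms:
        thr = threshold_frac * pwm.max_score(bg_freqs)
        hits_p += piggyback.scan_pwm(seq_peaks, pwm, bg_freqs, thr)
        hits_b += piggyback.scan_pwm(seq_bg, pwm, bg_freqs, thr)
    enr = piggyback.motif_enrichment(hits_p, hits_b, len(peaks), len(bg_regions),
                                     motif_ids=[p.motif_id for p in pwms])
    head = header("piggyback", seed, alpha=alpha, bait=bait_motif,
                  threshold_frac=threshold_frac)
    write_tsv(enr, dirpath / "enrichment.tsv", head)
    cands, no_motif = piggyback.piggyback_candidates(enr, pwms, ms, alpha,
                                                     bait_motif)
    write_tsv(cands, dirpath / "candidates.tsv", head)
    write_tsv(pd.DataFrame({"protein_id": no_motif}),
              dirpath / "no_motif_proteins.tsv", head)


def stage_annotate(dirpath, seed: int = 0, tissues: list[str] | None = None,
                   force: bool = False) -> None:
    dirpath = Path(dirpath)
    outs = [dirpath / "annotation.tsv", dirpath / "gene_links.tsv",
            dirpath / "unified.tsv"]
    if _outputs_exist(outs) and not force:
        return
    union = core_io.parse_peaks(dirpath / "union.narrowPeak")
    sets = []
    for bed in sorted((dirpath / "annotations").glob("*.bed")):
        sets.append(annotate.parse_annotation_set(bed, bed.stem))
    overlaps = annotate.overlap_annotate(union, sets)
    egmap = annotate.parse_enhancer_gene_map(dirpath / "egmap.tsv")
    links = annotate.enhancer_gene_annotate(union, egmap, tissues)
    head = header("annotate", seed,
                  tissues=",".join(tissues) if tissues else "all")
    write_tsv(overlaps, dirpath / "annotation.tsv", head)
    write_tsv(links, dirpath / "gene_links.tsv", head)

    tables: dict[str, pd.DataFrame] = {"annotation": overlaps, "genes": links}
    for block, fname in (("diff", "diff.tsv"), ("bulky", "bulky.tsv"),
                         ("unique", "unique.tsv")):
        path = dirpath / fname
        if path.exists():
            tables[block] = read_tsv(path)
    idr_path = dirpath / "idr_selected.narrowPeak"
    if idr_path.exists():
        selected = core_io.parse_peaks(idr_path)
        tables["idr"] = pd.DataFrame({
            "name": [p.name for p in union],
            "reproducible": [
                any(p.interval.overlap(s.interval) > 0 for s in selected)
                for p in union]})
    unified = annotate.unified_output(union, tables)
    write_tsv(unified, dirpath / "unified.tsv", head)


_ALL_STAGES = ["norm", "callpeaks", "diffpeaks", "classify", "idr",
               "piggyback", "annotate"]


def run_all(dirpath, seed: int = 0, force: bool = False) -> None:
    """norm -> callpeaks -> diffpeaks -> classify -> idr -> piggyback ->
    annotate, ending with the unified output table."""
    stage_norm(dirpath, seed, force=force)
    stage_callpeaks(dirpath, seed, force=force)
    stage_diffpeaks(dirpath, seed, force=force)
    stage_classify(dirpath, seed, force=force)
    stage_idr(dirpath, seed, force=force)
    stage_piggyback(dirpath, seed, force=force)
    stage_annotate(dirpath, seed, force=force)
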