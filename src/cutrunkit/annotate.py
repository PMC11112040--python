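"""Peak annotation against interval sets, enhancer-gene maps, and the
unified integrated output table.

Annotation sets are arbitrary labeled BED interval collections (enhancers,
DNase hypersensitive sites, factor binding compendia, ...). Enhancer-gene
maps link enhancer intervals to target genes per tissue/cell line. The
unified output left-joins every analysis table produced elsewhere in the
package onto the peak list, one row per peak, with namespaced
``block.field`` columns and explicit NA where an analysis did not cover a
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FormatError, GenomicInterval, PeakSet, _data_lines, _parse_coords


@dataclass
class AnnotationSet:
    set_id: str
    intervals: list[GenomicInterval]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.set_id:
            raise ValueError("set_id must be non-empty")
        if self.labels and len(self.labels) != len(self.intervals):
            raise ValueError("labels/intervals length mismatch")


def parse_annotation_set(path, set_id: str) -> AnnotationSet:
    """BED with an optional label in column 4."""
    ivs, labels = [], []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, path, lineno)
        ivs.append(GenomicInterval(chrom, start, end))
        labels.append(fields[3] if len(fields) >= 4 else "")
    return AnnotationSet(set_id=set_id, intervals=ivs, labels=labels)


def parse_enhancer_gene_map(path) -> pd.DataFrame:
    """TSV ``chrom start end gene tissue confidence`` -> validated frame."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "gene", "tissue", "confidence"],
                     header=None, dtype={"chrom": str, "gene": str, "tissue": str})
    if len(df) and df.iloc[0]["chrom"] == "chrom":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["confidence"] = df["confidence"].astype(float)
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"]) | (df["gene"] == "")]
    if len(bad):
        raise FormatError(f"invalid enhancer rows at index {bad.index.tolist()[:5]}",
                          path)
    return df


def _merged_intervals(intervals: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chrom merged (start, end) arrays for fast overlap queries."""
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in per.items():
        pairs.sort()
        merged = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _overlap_bp(merged: dict[str, np.ndarray], iv: GenomicInterval) -> int:
    arr = merged.get(iv.chrom)
    if arr is None:
        return 0
    total = 0
    for s, e in arr:
        if s >= iv.end:
            break
        total += max(0, min(int(e), iv.end) - max(int(s), iv.start))
    return total


def overlap_annotate(peaks: PeakSet, sets: list[AnnotationSet]) -> pd.DataFrame:
    """Per-peak overlap flag and fraction against each annotation set.

    flag = any overlap >= 1 bp (half-open); fraction = overlapped bp
    (against the union of the set's intervals) / peak length.
    """
    ids = [s.set_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate set_id among {ids}")
    merged_by_set = {s.set_id: _merged_intervals(s.intervals) for s in sets}
    rows = []
    for p in peaks:
        row = {"name": p.name}
        for s in sets:
            ov = _overlap_bp(merged_by_set[s.set_id], p.interval)
            row[f"{s.set_id}.overlaps"] = ov > 0
            row[f"{s.set_id}.fraction"] = ov / len(p.interval)
        rows.append(row)
    cols = ["name"] + [f"{i}.{f}" for i in ids for f in ("overlaps", "fraction")]
    return pd.DataFrame(rows, columns=cols)


def enhancer_gene_annotate(peaks: PeakSet, egmap: pd.DataFrame,
                           tissues: list[str] | None = None) -> pd.DataFrame:
    """Peak-to-gene links via enhancer overlap (one row per overlapping
    (peak, enhancer) pair). ``tissues`` filters the map before overlap and
    must name known tissues."""
    if tissues is not None:
        known = sorted(egmap["tissue"].unique())
        unknown = [t for t in tissues if t not in known]
        if unknown:
            raise ValueError(f"unknown tissue(s) {unknown}; available: {known}")
        egmap = egmap[egmap["tissue"].isin(tissues)]
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in egmap.groupby("chrom")}
    for p in peaks:
        grp = by_chrom.get(p.interval.chrom)
        if grp is None:
            continue
        for _, e in grp.iterrows():
            if e["start"] >= p.interval.end:
                break
            if e["end"] > p.interval.start:
                rows.append({"name": p.name, "gene": e["gene"],
                             "tissue": e["tissue"],
                             "confidence": e["confidence"]})
    return pd.DataFrame(rows, columns=["name", "gene", "tissue", "confidence"])


def nearest_feature(peaks: PeakSet,
                    features: list[GenomicInterval]) -> pd.DataFrame:
    """Signed distance from each peak to its nearest feature on the same
    chromosome: 0 if overlapping, else the gap in bp, negative when the
    nearest feature lies upstream (lower coordinates); ties go downstream.
    Peaks on chromosomes without features get NA (with a one-row warning
    marker in the ``note`` column).
    """
    if not features:
        raise ValueError("feature list is empty")
    per: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        per.setdefault(f.chrom, []).append((f.start, f.end))
    for chrom in per:
        per[chrom].sort()
    rows = []
    for p in peaks:
        feats = per.get(p.interval.chrom)
        if feats is None:
            rows.append({"name": p.name, "distance": np.nan,
                         "note": "no feature on chromosome"})
            continue
        best = None  # (abs distance, signed distance)
        for s, e in feats:
            if e > p.interval.start and s < p.interval.end:
                best = (0, 0)
                break
            if e <= p.interval.start:  # upstream
                d = p.interval.start - e
                cand = (d, -d)
            else:  # downstream
                d = s - p.interval.end
                cand = (d, d)
            # ties (equal gap) prefer downstream: positive sign sorts after
            # negative on the signed key, so compare (abs, -sign)
            if best is None or cand[0] < best[0] or (cand[0] == best[0]
                                                     and cand[1] > best[1]):
                best = cand
        rows.append({"name": p.name, "distance": best[1], "note": ""})
    return pd.DataFrame(rows, columns=["name", "distance", "note"])


def unified_output(peaks: PeakSet,
                   tables: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Left-join analysis tables onto the peak list.

    Every table must carry a ``name`` column keyed by peak name; its other
    columns appear as ``block.column``. Enhancer-gene link tables (with a
    ``gene`` column) are collapsed to one row per peak first: links
    deduplicated per gene keeping the maximum confidence, then joined into
    comma-separated ``genes``/``tissues`` fields. The result has exactly one
    row per input peak, NA where an analysis lacks the peak.
    """
    base = pd.DataFrame({
        "name": [p.name for p in peaks],
        "chrom": [p.interval.chrom for p in peaks],
        "start": [p.interval.start for p in peaks],
        "end": [p.interval.end for p in peaks],
        "score": [p.score for p in peaks],
    })
    for block in sorted(tables or {}):
        tbl = tables[block]
        if "name" not in tbl.columns:
            raise ValueError(f"table {block!r} lacks a 'name' column")
        if "gene" in tbl.columns and "confidence" in tbl.columns:
            tbl = _collapse_gene_links(tbl)
        dup = tbl["name"].duplicated()
        if dup.any():
            offenders = tbl.loc[dup, "name"].unique().tolist()[:5]
            raise ValueError(f"table {block!r} has duplicate peak rows: {offenders}")
        conflict = {"chrom", "start", "end"} & set(tbl.columns)
        if conflict:
            probe = base.merge(tbl[["name", *sorted(conflict)]], on="name",
                               how="inner", suffixes=("", "_other"))
            for c in sorted(conflict):
                if not (probe[c] == probe[f"{c}_other"]).all():
                    raise ValueError(
                        f"table {block!r} disagrees with peak coordinates ({c})")
            tbl = tbl.drop(columns=sorted(conflict))
        renamed = tbl.rename(columns={c: f"{block}.{c}" for c in tbl.columns
                                      if c != "name"})
        base = base.merge(renamed, on="name", how="left")
    return base


def _collapse_gene_links(links: pd.DataFrame) -> pd.DataFrame:
    if not len(links):
        return pd.DataFrame(columns=["name", "genes", "tissues", "max_confidence"])
    dedup = (links.sort_values("confidence", ascending=False, kind="stable")
             .drop_duplicates(["name", "gene"]))
    dedup = dedup.sort_values(["name", "gene"], kind="stable")
    agg = dedup.groupby("name", sort=True).agg(
        genes=("gene", lambda g: ",".join(g)),
        tissues=("tissue", lambda t: ",".join(t)),
        max_confidence=("confidence", "max")).reset_index()
    return agg
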