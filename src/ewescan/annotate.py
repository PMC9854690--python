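"""Candidate regions (+/-50 kb) and candidate-gene annotation.

A candidate SNP at position p yields the closed 1-based region
[max(1, p-50000), p+50000]; a candidate consensus haplotype is flanked from
its bp span.  Overlapping regions of the same (method, group) are merged by
default so one gene is not reported twice from adjacent candidate SNPs.  A
gene is reported when its interval overlaps a region by >= 1 bp
(closed-interval overlap; a minimum-overlap option is available), tagged
with the method (FST or ROH) and fecundity group.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneRecord
from .roh import CandidateHaplotype


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    source: str  # SNP id or haplotype tag (merged regions join sources with ,)
    group: str
    method: str  # "FST" or "ROH"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end}]")


def build_regions(fst_candidates: pd.DataFrame | None = None,
                  roh_candidates: list[CandidateHaplotype] | None = None,
                  flank: int = 50_000, merge: bool = True,
                  fst_group: str = "high") -> list[CandidateRegion]:
    """Flank candidates into regions, clip at position 1, and (by default)
    merge overlapping regions of the same (method, group).

    ``fst_candidates`` is the frame from :func:`ewescan.fst.select_candidates`
    (columns snp, chrom, bp); frequency-differential candidates are not
    group-specific, so they carry ``fst_group`` ("high" by default: the
    differential contrasts the groups and the reporting convention follows
    the published table, which lists FST hits under high fecundity).
    """
    regions: list[CandidateRegion] = []
    if fst_candidates is not None:
        for row in fst_candidates.itertuples(index=False):
            p = int(row.bp)
            regions.append(CandidateRegion(
                chrom=str(row.chrom), start=max(1, p - flank), end=p + flank,
                source=str(row.snp), group=fst_group, method="FST"))
    if roh_candidates:
        for c in roh_candidates:
            tag = f"{c.chrom}:{c.start_bp}-{c.end_bp}"
            regions.append(CandidateRegion(
                chrom=c.chrom, start=max(1, c.start_bp - flank),
                end=c.end_bp + flank, source=tag, group=c.group, method="ROH"))
    if not merge:
        return regions
    merged: list[CandidateRegion] = []
    key = lambda r: (r.method, r.group, r.chrom, r.start, r.end)
    for (method, group, chrom), bucket in _group_by(regions).items():
        bucket.sort(key=lambda r: (r.start, r.end))
        current = None
        for r in bucket:
            if current is not None and r.start <= current.end:  # closed overlap
                current.end = max(current.end, r.end)
                current.source += "," + r.source
            else:
                if current is not None:
                    merged.append(current)
                current = CandidateRegion(chrom=r.chrom, start=r.start, end=r.end,
                                          source=r.source, group=r.group,
                                          method=r.method)
        if current is not None:
            merged.append(current)
    merged.sort(key=lambda r: (r.method, r.group, r.chrom, r.start))
    return merged


def _group_by(regions: list[CandidateRegion]) -> dict:
    buckets: dict[tuple[str, str, str], list[CandidateRegion]] = {}
    for r in regions:
        buckets.setdefault((r.method, r.group, r.chrom), []).append(r)
    return buckets


def intersect_genes(regions: list[CandidateRegion], genes: list[GeneRecord],
                    min_overlap_bp: int = 1) -> pd.DataFrame:
    """Candidate-gene table: one row per unique (gene, method, group).

    A gene is reported iff its closed interval overlaps a region by at
    least ``min_overlap_bp``.  Raises when the region and gene chromosome
    label sets are disjoint (a naming-convention mismatch).
    """
    if regions and genes:
        rchroms = {r.chrom for r in regions}
        gchroms = {g.chrom for g in genes}
        if not rchroms & gchroms:
            raise ValueError(
                f"chromosome naming mismatch: regions use {sorted(rchroms)[:5]}, "
                f"genes use {sorted(gchroms)[:5]}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # closed 1-based interval -> half-open for the tree
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    rows = []
    seen = set()
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            g: GeneRecord = iv.data
            overlap = min(r.end, g.end) - max(r.start, g.start) + 1
            if overlap < min_overlap_bp:
                continue
            key = (g.name, r.method, r.group)
            if key in seen:
                continue
            seen.add(key)
            rows.append({
                "gene": g.name, "method": r.method, "group": r.group,
                "chrom": g.chrom, "position": g.start,
                "region": f"{r.chrom}:{r.start}-{r.end}", "source": r.source,
            })
    table = pd.DataFrame(rows, columns=["gene", "method", "group", "chrom",
                                        "position", "region", "source"])
    return table.sort_values(["group", "method", "chrom", "position"],
                             ignore_index=True)


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Row counts of the candidate-gene table by (method, group), plus
    per-group totals across methods (method = 'total')."""
    if table.empty:
        counts = pd.DataFrame(columns=["method", "group", "n_genes"])
    else:
        counts = (table.groupby(["method", "group"]).size()
                  .rename("n_genes").reset_index())
    totals = (table.groupby("group").size().rename("n_genes").reset_index()
              if not table.empty else pd.DataFrame(columns=["group", "n_genes"]))
    totals.insert(0, "method", "total")
    out = pd.concat([counts, totals], ignore_index=True)
    return out.sort_values(["method", "group"], ignore_index=True)


def count(summary: pd.DataFrame, method: str, group: str) -> int:
    """Convenience lookup into a summarize_counts frame (0 when absent)."""
    hit = summary[(summary["method"] == method) & (summary["group"] == group)]
    return int(hit["n_genes"].iloc[0]) if len(hit) else 0


def load_published_candidate_genes() -> pd.DataFrame:
    """The published Katahdin fecundity candidate-gene table bundled with
    the package (gene, method, group, chromosome, position): the reference
    shape this pipeline's report mirrors."""
    ref = importlib.resources.files("ewescan") / "data" / "katahdin_candidate_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
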