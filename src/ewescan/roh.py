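"""Runs of homozygosity: sliding-window detection, per-group in-run SNP
frequencies, and consensus candidate haplotypes.

Detection follows the sliding-window scheme of the classic SNP-array ROH
callers: every contiguous window of ``window_size`` SNPs on a chromosome is
classified homozygous iff it contains at most ``max_opp_window``
heterozygous and at most ``max_miss_window`` missing calls; each SNP is
scored by the fraction of windows covering it that are homozygous; SNPs
scoring strictly above ``threshold`` are in-state; maximal consecutive
in-state stretches with at least ``min_snp`` SNPs become runs, with bp
bounds read off the marker map (inclusive, length = end - start + 1).

A consensus candidate haplotype for a group is a maximal stretch of >= 3
consecutive SNPs each covered by a run in >= 75% of the group's ewes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RohParams:
    window_size: int = 15
    threshold: float = 0.05
    min_snp: int = 20
    max_opp_window: int = 1
    max_miss_window: int = 1
    # constraints present in SNP-array ROH callers but disabled by default
    min_length_bp: int | None = None
    max_gap_bp: int | None = None
    min_density_kb_per_snp: float | None = None

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.min_snp < 1:
            raise ValueError("window_size and min_snp must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0,1]")
        if self.max_opp_window < 0 or self.max_miss_window < 0:
            raise ValueError("max_opp_window/max_miss_window must be >= 0")


@dataclass
class ROHRun:
    individual_id: str
    chrom: str
    first_snp: str
    last_snp: str
    first_idx: int  # global row index into the marker map
    last_idx: int
    start_bp: int
    end_bp: int
    n_snp: int
    length_bp: int


@dataclass
class CandidateHaplotype:
    group: str
    chrom: str
    snp_ids: list[str]
    start_bp: int
    end_bp: int
    frequencies: list[float]

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums of every length-w contiguous window of x (len = len(x)-w+1)."""
    c = np.concatenate(([0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _snp_scores(het: np.ndarray, miss: np.ndarray, params: RohParams) -> np.ndarray:
    """Fraction of covering windows that are homozygous, per SNP (one
    chromosome, one individual)."""
    L = het.size
    w = params.window_size
    hom_win = (
        (_rolling_sum(het.astype(np.int32), w) <= params.max_opp_window)
        & (_rolling_sum(miss.astype(np.int32), w) <= params.max_miss_window)
    )
    n_win = L - w + 1
    # SNP i is covered by windows max(0, i-w+1) .. min(i, n_win-1)
    c = np.concatenate(([0], np.cumsum(hom_win)))
    idx = np.arange(L)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    covered = c[hi + 1] - c[lo]
    return covered / (hi - lo + 1)


def _true_stretches(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] (inclusive) index stretches where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_runs(matrix: GenotypeMatrix, marker_map: pd.DataFrame,
                params: RohParams | None = None) -> list[ROHRun]:
    """Sliding-window ROH detection per individual and chromosome."""
    params = params or RohParams()
    if list(matrix.marker_ids) != marker_map["snp"].tolist():
        raise ValueError("matrix markers do not match the marker map")
    runs: list[ROHRun] = []
    chrom_col = marker_map["chrom"].to_numpy()
    bp = marker_map["bp"].to_numpy()
    snp_ids = marker_map["snp"].to_numpy()
    # chromosome blocks in map order
    block_starts = [0] + (np.flatnonzero(chrom_col[1:] != chrom_col[:-1]) + 1).tolist()
    block_bounds = list(zip(block_starts, block_starts[1:] + [len(chrom_col)]))

    for b0, b1 in block_bounds:
        chrom = str(chrom_col[b0])
        L = b1 - b0
        if L < params.window_size:
            logger.warning("chromosome %s has %d SNPs < window size %d; skipped",
                           chrom, L, params.window_size)
            continue
        sub = matrix.codes[:, b0:b1]
        het = sub == 1
        miss = sub == MISSING
        for i, ind in enumerate(matrix.individual_ids):
            scores = _snp_scores(het[i], miss[i], params)
            in_state = scores > params.threshold
            for s, e in _true_stretches(in_state):
                n_snp = e - s + 1
                if n_snp < params.min_snp:
                    continue
                g0, g1 = b0 + s, b0 + e
                start_bp, end_bp = int(bp[g0]), int(bp[g1])
                length = end_bp - start_bp + 1
                if params.min_length_bp is not None and length < params.min_length_bp:
                    continue
                if params.min_density_kb_per_snp is not None:
                    if (length / 1000.0) / n_snp > params.min_density_kb_per_snp:
                        continue
                if params.max_gap_bp is not None:
                    gaps = np.diff(bp[g0:g1 + 1])
                    if gaps.size and gaps.max() > params.max_gap_bp:
                        continue
                runs.append(ROHRun(
                    individual_id=ind, chrom=chrom,
                    first_snp=str(snp_ids[g0]), last_snp=str(snp_ids[g1]),
                    first_idx=int(g0), last_idx=int(g1),
                    start_bp=start_bp, end_bp=end_bp,
                    n_snp=n_snp, length_bp=length,
                ))
    return runs


def runs_to_frame(runs: list[ROHRun]) -> pd.DataFrame:
    return pd.DataFrame([{
        "individual": r.individual_id, "chrom": r.chrom,
        "first_snp": r.first_snp, "last_snp": r.last_snp,
        "n_snp": r.n_snp, "from_bp": r.start_bp, "to_bp": r.end_bp,
        "length_bp": r.length_bp,
    } for r in runs])


def snp_run_frequency(runs: list[ROHRun], labels: pd.Series | dict[str, str],
                      marker_map: pd.DataFrame) -> pd.DataFrame:
    """Per group and SNP: fraction of the group's individuals with >= 1 run
    covering the SNP.  Returns columns snp, chrom, bp, freq_high, freq_low.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    n_markers = len(marker_map)
    out = marker_map[["snp", "chrom", "bp"]].copy()
    for group in ("high", "low"):
        members = labels.index[labels == group].tolist()
        if not members:
            raise ValueError(f"group {group!r} is empty")
        covered_any = np.zeros((len(members), n_markers), dtype=bool)
        member_pos = {m: i for i, m in enumerate(members)}
        for r in runs:
            i = member_pos.get(r.individual_id)
            if i is None:
                continue
            covered_any[i, r.first_idx:r.last_idx + 1] = True
        out[f"freq_{group}"] = covered_any.mean(axis=0)
    return out


def call_candidate_haplotypes(freqs: pd.DataFrame, marker_map: pd.DataFrame,
                              min_freq: float = 0.75,
                              min_snps: int = 3) -> list[CandidateHaplotype]:
    """Maximal stretches of consecutive SNPs with group frequency >= min_freq
    (inclusive boundary) and >= min_snps members, per group."""
    candidates: list[CandidateHaplotype] = []
    chrom_col = freqs["chrom"].to_numpy()
    boundary = np.concatenate(([True], chrom_col[1:] != chrom_col[:-1]))
    chrom_block = np.cumsum(boundary)  # same id within each chromosome block
    for group in ("high", "low"):
        col = f"freq_{group}"
        if col not in freqs.columns:
            continue
        above = freqs[col].to_numpy() >= min_freq
        # break stretches at chromosome boundaries by masking per block
        for block_id in np.unique(chrom_block):
            sel = chrom_block == block_id
            offset = np.flatnonzero(sel)[0]
            for s, e in _true_stretches(above[sel]):
                if e - s + 1 < min_snps:
                    continue
                g0, g1 = offset + s, offset + e
                sub = freqs.iloc[g0:g1 + 1]
                candidates.append(CandidateHaplotype(
                    group=group, chrom=str(sub["chrom"].iat[0]),
                    snp_ids=sub["snp"].tolist(),
                    start_bp=int(sub["bp"].iat[0]), end_bp=int(sub["bp"].iat[-1]),
                    frequencies=sub[col].tolist(),
                ))
    return candidates


def haplotypes_to_frame(candidates: list[CandidateHaplotype]) -> pd.DataFrame:
    """Table-shaped export: group, start/end SNP, chromosome, n SNP, bp span."""
    return pd.DataFrame([{
        "group": c.group, "start_snp": c.snp_ids[0], "end_snp": c.snp_ids[-1],
        "chrom": c.chrom, "n_snp": c.n_snp,
        "from_bp": c.start_bp, "to_bp": c.end_bp,
        "min_freq": min(c.frequencies),
    } for c in candidates])
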