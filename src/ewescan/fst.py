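"""Per-SNP fixation indices and between-group differentiation.

Two statistics per marker:

* within-group fixation index F = 1 - Ho/He per subpopulation (Ho observed
  heterozygote fraction, He = 2p(1-p) from the group allele frequency), and
  the differential delta = |F_high - F_low|;
* the two-population Weir-Cockerham per-locus theta from variance components
  a, b, c (theta = a / (a + b + c)), which responds directly to
  allele-frequency divergence.

Candidates are the markers at or above the top quantile of the chosen
ranking statistic (default theta: the within-group differential is ~0 for
any frequency gap when both groups are internally in HW proportions, so it
cannot rank frequency-differentiated loci).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-SNP statistics for the two phenotype-defined subpopulations."""

    table: pd.DataFrame  # snp, chrom, bp, f_high, f_low, delta, theta


def _group_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (n called, alt freq, observed het fraction) for one group."""
    called = codes != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, codes, 0).sum(axis=0) / (2 * n)
        ho = (codes == 1).sum(axis=0) / n
    p = np.where(n > 0, p, np.nan)
    ho = np.where(n > 0, ho, np.nan)
    return n, p, ho


def per_group_fixation(p: np.ndarray, ho: np.ndarray) -> np.ndarray:
    """F = 1 - Ho/He with He = 2p(1-p); F = 0 where the group is monomorphic."""
    he = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - ho / he
    return np.where(he == 0, 0.0, f)


def weir_cockerham_theta(n1, p1, h1, n2, p2, h2):
    """Two-population per-locus Weir-Cockerham theta.

    Arguments are per-group sample sizes (diploid individuals with calls),
    alt-allele frequencies and observed heterozygote fractions; arrays
    broadcast elementwise.  Markers monomorphic over both groups (or with a
    group entirely missing) return NaN.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    return np.where((a + b + c) == 0, np.nan, theta)


def fst_scan(matrix: GenotypeMatrix, marker_map: pd.DataFrame,
             labels: pd.Series | dict[str, str]) -> FstResult:
    """Compute per-SNP F_high, F_low, delta and Weir-Cockerham theta.

    ``labels`` maps individual id -> "high"/"low".  Markers where either
    group has no non-missing call are kept in the table with NaN statistics
    and logged.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    lab = labels.reindex(matrix.individual_ids)
    if lab.isna().any():
        missing = lab.index[lab.isna()].tolist()[:5]
        raise ValueError(f"no group label for individuals: {missing}")
    hi = (lab == "high").to_numpy()
    lo = (lab == "low").to_numpy()
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError("each group needs at least two individuals")

    n1, p1, ho1 = _group_stats(matrix.codes[hi])
    n2, p2, ho2 = _group_stats(matrix.codes[lo])
    f_high = per_group_fixation(p1, ho1)
    f_low = per_group_fixation(p2, ho2)
    theta = weir_cockerham_theta(n1, p1, ho1, n2, p2, ho2)
    undefined = (n1 == 0) | (n2 == 0)
    if undefined.any():
        logger.warning("%d markers skipped: one group entirely missing", undefined.sum())
    coords = marker_map.set_index("snp").loc[matrix.marker_ids]
    table = pd.DataFrame({
        "snp": matrix.marker_ids,
        "chrom": coords["chrom"].to_numpy(),
        "bp": coords["bp"].to_numpy(),
        "f_high": np.where(undefined, np.nan, f_high),
        "f_low": np.where(undefined, np.nan, f_low),
    })
    table["delta"] = np.abs(table["f_high"] - table["f_low"])
    table["theta"] = np.where(undefined, np.nan, theta)
    return FstResult(table=table)


def select_candidates(result: FstResult, fraction: float = 0.20,
                      stat: str = "theta") -> pd.DataFrame:
    """Markers at or above the (1 - fraction) empirical quantile of ``stat``.

    Ties at the threshold are all included.  Returns a frame with columns
    snp, chrom, bp, stat, method ("FST"), ordered by (chrom, bp).  Markers
    with undefined statistic are excluded from both the quantile and the
    selection; at least 5 defined markers are required.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if stat not in ("theta", "delta", "wc"):
        raise ValueError(f"unknown ranking statistic {stat!r}")
    col = "theta" if stat in ("theta", "wc") else "delta"
    table = result.table
    defined = table[col].notna()
    if defined.sum() < 5:
        raise ValueError("need at least 5 markers with a defined statistic")
    values = table.loc[defined, col].to_numpy()
    threshold = np.quantile(values, 1.0 - fraction)
    sel = table[defined & (table[col] >= threshold)].copy()
    sel = sel.rename(columns={col: "stat"})[["snp", "chrom", "bp", "stat"]]
    sel["method"] = "FST"
    order = sel["chrom"].astype(str).to_numpy()
    sel = sel.iloc[np.lexsort((sel["bp"].to_numpy(), order))].reset_index(drop=True)
    return sel
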