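"""Marker quality control: minor-allele frequency, exact Hardy-Weinberg
test, and call rate.

All three statistics are evaluated on the full input matrix and markers
failing any rule are removed as a union (not sequentially re-estimated), so
per-filter counts may overlap; the report records every reason per marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class QcError(ValueError):
    """Raised when QC leaves no usable markers; carries the report."""

    def __init__(self, message: str, report: "QcReport"):
        super().__init__(message)
        self.report = report


@dataclass
class QcReport:
    per_marker: pd.DataFrame  # snp, maf, hwe_p, call_rate, fail_maf/hwe/call_rate, removed
    removed_counts: dict[str, int]
    surviving_ids: list[str]

    @property
    def n_removed(self) -> int:
        return int(self.per_marker["removed"].sum())


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n_ref_hom, n_het, n_alt_hom) over non-missing calls at one marker."""
    codes = np.asarray(codes)
    return (int((codes == 0).sum()), int((codes == 1).sum()), int((codes == 2).sum()))


def minor_allele_frequency(codes: np.ndarray) -> float:
    """min(p, 1-p) of the alt allele over non-missing calls; NaN if all missing."""
    codes = np.asarray(codes)
    called = codes[codes != MISSING]
    if called.size == 0:
        return float("nan")
    p = called.sum() / (2 * called.size)
    return float(min(p, 1.0 - p))


def call_rate(codes: np.ndarray) -> float:
    codes = np.asarray(codes)
    if codes.size == 0:
        return float("nan")
    return float((codes != MISSING).sum() / codes.size)


@lru_cache(maxsize=None)
def _het_log_weights(n: int, n_a: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Feasible heterozygote counts and their log-probabilities.

    Conditional on n diploids and n_a copies of the rarer allele, the exact
    distribution of the heterozygote count h (same parity as n_a) is
    P(h) = n! / (nAA! h! naa!) * 2^h * n_a! n_b! / (2n)!   (up to the shared
    normalizer, which cancels in the test).
    """
    n_b = 2 * n - n_a
    hs, logs = [], []
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        logs.append(
            h * math.log(2.0)
            - math.lgamma(n_aa + 1) - math.lgamma(h + 1) - math.lgamma(n_bb + 1)
        )
        hs.append(h)
    return tuple(hs), tuple(logs)


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Sums the probabilities of all heterozygote configurations (conditional on
    the allele counts) that are no more probable than the observed one.  The
    "no more probable" comparison is decided in exact integer arithmetic
    (cross-multiplied factorial ratios), so ties are handled exactly; only the
    final summation is floating point.  Monomorphic markers return p = 1.
    """
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_ref_hom + n_het + n_alt_hom
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_alt = n_het + 2 * n_alt_hom
    n_a = min(n_alt, 2 * n - n_alt)  # rarer allele count
    if n_a == 0:
        return 1.0
    hs, logs = _het_log_weights(n, n_a)
    logs = np.asarray(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    # exact inclusion: P(h) <= P(obs)  <=>  2^h / (nAA! h! naa!) <= same for obs,
    # decided by integer cross-multiplication
    f = math.factorial
    def weight_num_den(h: int) -> tuple[int, int]:
        n_aa = (n_a - h) // 2
        n_bb = (2 * n - n_a - h) // 2
        return 2 ** h, f(n_aa) * f(h) * f(n_bb)
    num_o, den_o = weight_num_den(n_het)
    include = np.zeros(len(hs), dtype=bool)
    for k, h in enumerate(hs):
        num_h, den_h = weight_num_den(h)
        include[k] = num_h * den_o <= num_o * den_h
    return float(min(1.0, probs[include].sum()))


def apply_qc(matrix: GenotypeMatrix, maf_min: float = 0.05,
             hwe_p_min: float = 1e-6, call_rate_min: float = 0.90,
             hwe_exclude_above: bool = False) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers failing MAF < maf_min, HWE p < hwe_p_min, or call
    rate < call_rate_min (union of the three rules, evaluated on the input).

    ``hwe_exclude_above`` flips the HWE rule to exclude p > hwe_p_min (a
    nonstandard direction offered for auditing; the default excludes
    disequilibrium, i.e. small p).  An all-missing marker has undefined
    MAF/HWE and is removed by the call-rate rule.
    """
    codes = matrix.codes
    n_markers = matrix.n_markers
    called = codes != MISSING
    n_called = called.sum(axis=0)
    cr = np.divide(n_called, matrix.n_individuals, where=matrix.n_individuals > 0,
                   out=np.zeros(n_markers))

    alt_counts = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt_counts / (2 * n_called)
    maf = np.minimum(p_alt, 1 - p_alt)
    maf[n_called == 0] = np.nan

    hwe_p = np.ones(n_markers)
    for j in range(n_markers):
        if n_called[j] == 0:
            hwe_p[j] = np.nan
            continue
        col = codes[:, j]
        hwe_p[j] = hwe_exact_test(*genotype_counts(col[col != MISSING]))

    fail_maf = np.nan_to_num(maf, nan=1.0) < maf_min
    if hwe_exclude_above:
        fail_hwe = np.nan_to_num(hwe_p, nan=0.0) > hwe_p_min
    else:
        fail_hwe = np.nan_to_num(hwe_p, nan=1.0) < hwe_p_min
    fail_cr = cr < call_rate_min
    removed = fail_maf | fail_hwe | fail_cr

    per_marker = pd.DataFrame({
        "snp": matrix.marker_ids,
        "maf": maf,
        "hwe_p": hwe_p,
        "call_rate": cr,
        "fail_maf": fail_maf,
        "fail_hwe": fail_hwe,
        "fail_call_rate": fail_cr,
        "removed": removed,
    })
    report = QcReport(
        per_marker=per_marker,
        removed_counts={
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
            "call_rate": int(fail_cr.sum()),
            "total": int(removed.sum()),
        },
        surviving_ids=[m for m, r in zip(matrix.marker_ids, removed) if not r],
    )
    logger.info("QC: removed %d/%d markers (maf %d, hwe %d, call rate %d)",
                report.removed_counts["total"], n_markers,
                report.removed_counts["maf"], report.removed_counts["hwe"],
                report.removed_counts["call_rate"])
    if removed.all():
        raise QcError("no markers survive QC", report)
    keep_idx = np.flatnonzero(~removed)
    return matrix.subset_markers(keep_idx), report
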