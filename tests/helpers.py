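"""Shared test utilities: tiny-matrix builders and independent oracles.

The oracles deliberately re-derive each statistic by direct enumeration or
step-by-step scalar arithmetic, independent of the vectorized production
code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd

from ewescan.io import GenotypeMatrix
from ewescan.roh import RohParams


def make_map(n_snps: int, chrom: str = "1", spacing: int = 1000,
             start: int = 1000) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": chrom, "snp": [f"{chrom}_snp{j}" for j in range(n_snps)],
        "cm": 0.0, "bp": start + spacing * np.arange(n_snps),
        "allele_a": "A", "allele_b": "B",
    })


def make_matrix(codes, chrom: str = "1") -> tuple[GenotypeMatrix, pd.DataFrame]:
    codes = np.asarray(codes, dtype=np.int8)
    mm = make_map(codes.shape[1], chrom=chrom)
    matrix = GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(codes.shape[0])],
        marker_ids=mm["snp"].tolist(), codes=codes)
    return matrix, mm


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full enumeration in exact rational arithmetic
# ---------------------------------------------------------------------------

def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE p by summing, in exact Fractions, the conditional
    probabilities of all heterozygote configurations no more probable than
    the observed one."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if min(na, nb) == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        aa = (na - h) // 2
        bb = (nb - h) // 2
        return Fraction(
            factorial(n) * 2 ** h * factorial(na) * factorial(nb),
            factorial(aa) * factorial(h) * factorial(bb) * factorial(2 * n))

    feasible = range(min(na, nb) % 2, min(na, nb) + 1, 2)
    probs = {h: prob(h) for h in feasible}
    assert sum(probs.values()) == 1
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# Sliding-window ROH detection by direct per-window enumeration
# ---------------------------------------------------------------------------

def roh_bruteforce(codes: np.ndarray, params: RohParams) -> list[tuple[int, int]]:
    """Run index spans [(first, last)] for one individual on one chromosome,
    enumerating every window and every SNP score explicitly."""
    L = len(codes)
    w = params.window_size
    if L < w:
        return []
    windows = []
    for k in range(L - w + 1):
        win = codes[k:k + w]
        n_het = int(sum(1 for g in win if g == 1))
        n_mis = int(sum(1 for g in win if g == -1))
        windows.append(n_het <= params.max_opp_window
                       and n_mis <= params.max_miss_window)
    in_state = []
    for i in range(L):
        cover = [windows[k] for k in range(max(0, i - w + 1), min(i, L - w) + 1)]
        in_state.append(sum(cover) / len(cover) > params.threshold)
    runs = []
    i = 0
    while i < L:
        if in_state[i]:
            j = i
            while j + 1 < L and in_state[j + 1]:
                j += 1
            if j - i + 1 >= params.min_snp:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# Weir-Cockerham theta from genotype counts, scalar step-by-step
# ---------------------------------------------------------------------------

def wc_theta_oracle(counts1: tuple[int, int, int],
                    counts2: tuple[int, int, int]) -> float:
    """Per-locus two-population theta evaluated one variance component at a
    time from the genotype count triples (ref hom, het, alt hom)."""
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def counts_to_codes(counts: tuple[int, int, int]) -> np.ndarray:
    return np.array([0] * counts[0] + [1] * counts[1] + [2] * counts[2],
                    dtype=np.int8)
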