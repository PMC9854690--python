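"""Synthetic SNP-chip cohort with planted selection signals.

Emulates the study design the scan targets: two subpopulations of Katahdin
ewes (23 high- and 25 low-fecundity by default) genotyped on a ~50k-density
array laid out over 25 autosomes.  Per SNP, genotypes are drawn under
Hardy-Weinberg proportions from a base allele frequency shared by both
groups, except for

* planted differentiated loci (group-specific frequencies),
* planted shared ROH: a span of SNPs overwritten with a single homozygous
  haplotype in a fraction of one group's ewes (the footprint of a selected
  IBD segment),
* planted QC failures: loci with MAF < 0.05, loci with a hard excess of
  homozygotes (out of HWE), and loci with depressed call rate.

Phenotypes follow a liability y = b0 + b1*bc + group_offset + noise,
discretized to {0,1,2} lambs; the per-group body-condition distributions
differ (high-fecundity ewes are in better condition), because the pipeline
clusters the model-FITTED phenotypes and group structure must be visible
through the covariate the model keeps.  Group offsets are calibrated
numerically so the discretized group means hit the configured targets
(1.3 / 1.1 by default).

Identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .io import MISSING, GeneRecord, GenotypeMatrix, validate_marker_map

PlantedRoh = tuple[str, int, int, int, float]   # group, chrom, start_idx, n_snps, carrier_frac
PlantedDiff = tuple[int, int, float, float]     # chrom, snp_idx, freq_high, freq_low


@dataclass
class SimulationConfig:
    n_high: int = 23
    n_low: int = 25
    n_chrom: int = 25
    snps_per_chrom: int = 80
    chrom_length_bp: int = 4_000_000
    base_maf_range: tuple[float, float] = (0.10, 0.50)
    missing_rate: float = 0.02
    n_low_maf_snps: int = 40
    n_hwe_violating_snps: int = 25
    n_low_call_snps: int = 15
    planted_roh: list[PlantedRoh] = field(default_factory=lambda: [
        ("high", 3, 20, 30, 0.90),
        ("low", 7, 25, 30, 0.85),
    ])
    planted_diff_snps: list[PlantedDiff] = field(default_factory=lambda: [
        (1, 40, 0.80, 0.20),
        (5, 40, 0.80, 0.20),
        (10, 40, 0.20, 0.80),
        (15, 40, 0.80, 0.20),
        (20, 40, 0.20, 0.80),
    ])
    pheno_means: tuple[float, float] = (1.3, 1.1)  # (high, low)
    beta0: float = 0.65
    beta1: float = 0.15
    noise_sd: float = 0.35
    # body-condition (1..5) probabilities per group
    bc_probs_high: tuple[float, ...] = (0.0, 0.0, 0.05, 0.60, 0.35)
    bc_probs_low: tuple[float, ...] = (0.05, 0.55, 0.37, 0.03, 0.0)
    years: tuple[int, ...] = (2019, 2020, 2021)
    # calibrate group liability offsets so discretized means hit pheno_means;
    # False gives the bare model y = b0 + b1*bc + noise (no group offset)
    calibrate_means: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 2 or self.n_low < 2:
            raise ValueError("each group needs at least 2 ewes")
        lo, hi = self.base_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("base_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        roh_spans: dict[int, list[tuple[int, int]]] = {}
        for group, chrom, start, n_snps, frac in self.planted_roh:
            if group not in ("high", "low"):
                raise ValueError(f"planted ROH group must be high/low, got {group!r}")
            if not 0.0 < frac <= 1.0:
                raise ValueError("carrier_fraction must be in (0, 1]")
            if not (1 <= chrom <= self.n_chrom):
                raise ValueError(f"planted ROH chromosome {chrom} out of range")
            if start < 0 or start + n_snps > self.snps_per_chrom:
                raise ValueError(f"planted ROH span [{start}, {start + n_snps}) "
                                 f"exceeds chromosome {chrom}")
            roh_spans.setdefault(chrom, []).append((start, start + n_snps))
        for chrom, idx, fh, fl in self.planted_diff_snps:
            if not (0.0 <= fh <= 1.0 and 0.0 <= fl <= 1.0):
                raise ValueError("planted frequencies must lie in [0, 1]")
            if not (1 <= chrom <= self.n_chrom) or not (0 <= idx < self.snps_per_chrom):
                raise ValueError(f"planted diff SNP ({chrom}, {idx}) out of range")
            for s, e in roh_spans.get(chrom, []):
                if s <= idx < e:
                    raise ValueError(
                        f"planted diff SNP collides with planted ROH at "
                        f"chromosome {chrom}, SNP index {idx}")


@dataclass
class TruthTable:
    planted_roh_regions: list[tuple[str, str, int, int]]  # group, chrom, start_bp, end_bp
    planted_diff_snp_ids: list[str]
    qc_fail_snp_ids: list[tuple[str, str]]                # (marker id, reason)
    true_groups: dict[str, str]                           # ewe id -> high/low

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "planted_roh": pd.DataFrame(self.planted_roh_regions,
                                        columns=["group", "chrom", "start_bp", "end_bp"]),
            "planted_diff": pd.DataFrame({"snp": self.planted_diff_snp_ids}),
            "qc_fail": pd.DataFrame(self.qc_fail_snp_ids, columns=["snp", "reason"]),
            "groups": pd.DataFrame({"ewe_id": list(self.true_groups),
                                    "group": list(self.true_groups.values())}),
        }


def _group_offset(target: float, bc_probs: np.ndarray, beta0: float, beta1: float,
                  noise_sd: float) -> float:
    """Liability offset making E[discretized fecundity] equal the target,
    given the group's body-condition distribution."""
    bc = np.arange(1, 6)

    def expected(off: float) -> float:
        mu = beta0 + beta1 * bc + off
        e = norm.sf((0.5 - mu) / noise_sd) + norm.sf((1.5 - mu) / noise_sd)
        return float((bc_probs * e).sum()) - target

    return brentq(expected, -5.0, 5.0, xtol=1e-10)


def _make_marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    spacing = cfg.chrom_length_bp / (cfg.snps_per_chrom + 1)
    for c in range(1, cfg.n_chrom + 1):
        base = spacing * np.arange(1, cfg.snps_per_chrom + 1)
        jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=cfg.snps_per_chrom)
        bp = np.maximum.accumulate(np.round(base + jitter).astype(np.int64))
        bp += np.arange(cfg.snps_per_chrom)  # break any residual ties
        bp = np.maximum(bp, 1)
        for j, pos in enumerate(bp):
            rows.append((str(c), f"oar{c}_{j:04d}", 0.0, int(pos), "A", "B"))
    frame = pd.DataFrame(rows, columns=["chrom", "snp", "cm", "bp",
                                        "allele_a", "allele_b"])
    return validate_marker_map(frame)


def simulate_population(cfg: SimulationConfig
                        ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Draw genotypes, phenotypes and the ground-truth table.

    Returns (GenotypeMatrix, MarkerMap frame, PhenotypeTable frame with one
    row per ewe-year, TruthTable).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_high + cfg.n_low
    ids = [f"ewe{i + 1:03d}" for i in range(n)]
    group_of = {ids[i]: ("high" if i < cfg.n_high else "low") for i in range(n)}
    hi_idx = np.arange(cfg.n_high)
    lo_idx = np.arange(cfg.n_high, n)

    marker_map = _make_marker_map(cfg, rng)
    m = len(marker_map)

    def flat(chrom: int, idx: int) -> int:
        return (chrom - 1) * cfg.snps_per_chrom + idx

    roh_flat_spans = [(g, flat(c, s), flat(c, s) + ln, fr)
                      for g, c, s, ln, fr in cfg.planted_roh]
    diff_flat = {flat(c, i): (fh, fl) for c, i, fh, fl in cfg.planted_diff_snps}

    in_roh = np.zeros(m, dtype=bool)
    for _, s, e, _ in roh_flat_spans:
        in_roh[s:e] = True
    reserved = in_roh.copy()
    for j in diff_flat:
        reserved[j] = True

    free = np.flatnonzero(~reserved)
    n_special = cfg.n_low_maf_snps + cfg.n_hwe_violating_snps + cfg.n_low_call_snps
    if n_special > free.size:
        raise ValueError("not enough unreserved SNPs for the planted QC failures")
    special = rng.choice(free, size=n_special, replace=False)
    low_maf_idx = special[:cfg.n_low_maf_snps]
    hwe_idx = special[cfg.n_low_maf_snps:cfg.n_low_maf_snps + cfg.n_hwe_violating_snps]
    low_call_idx = special[cfg.n_low_maf_snps + cfg.n_hwe_violating_snps:]

    # --- base frequencies ------------------------------------------------
    maf = rng.uniform(cfg.base_maf_range[0], cfg.base_maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)          # alt-allele frequency
    freq[in_roh] = rng.uniform(0.4, 0.6, size=int(in_roh.sum()))

    freq_high = freq.copy()
    freq_low = freq.copy()
    for j, (fh, fl) in diff_flat.items():
        freq_high[j] = fh
        freq_low[j] = fl

    # --- genotypes under HW proportions ----------------------------------
    codes = np.empty((n, m), dtype=np.int8)
    codes[:cfg.n_high] = rng.binomial(2, freq_high, size=(cfg.n_high, m))
    codes[cfg.n_high:] = rng.binomial(2, freq_low, size=(cfg.n_low, m))

    # HWE-violating loci: every individual homozygous (hard het deficit)
    for j in hwe_idx:
        f = rng.uniform(0.25, 0.5)
        codes[:, j] = 2 * (rng.random(n) < f).astype(np.int8)

    # low-MAF loci: 1-3 alt alleles placed as heterozygotes
    for j in low_maf_idx:
        codes[:, j] = 0
        k = int(rng.integers(1, 4))
        carriers = rng.choice(n, size=k, replace=False)
        codes[carriers, j] = 1

    # planted shared ROH: one homozygous haplotype per region
    for group, s, e, frac in roh_flat_spans:
        pool = hi_idx if group == "high" else lo_idx
        n_carriers = max(1, int(round(frac * pool.size)))
        carriers = rng.choice(pool, size=n_carriers, replace=False)
        haplotype = 2 * rng.integers(0, 2, size=e - s).astype(np.int8)
        codes[np.ix_(carriers, np.arange(s, e))] = haplotype

    # --- missingness (last, so planted tracts are homozygous pre-masking) -
    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        codes[mask] = MISSING
    for j in low_call_idx:
        n_miss = int(np.ceil(0.15 * n))
        victims = rng.choice(n, size=n_miss, replace=False)
        codes[victims, j] = MISSING

    matrix = GenotypeMatrix(individual_ids=ids,
                            marker_ids=marker_map["snp"].tolist(), codes=codes)

    # --- phenotypes -------------------------------------------------------
    bc_probs = {"high": np.asarray(cfg.bc_probs_high, dtype=float),
                "low": np.asarray(cfg.bc_probs_low, dtype=float)}
    for g, p in bc_probs.items():
        if p.size != 5 or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"bc_probs_{g} must be 5 probabilities summing to 1")
    if cfg.calibrate_means:
        offsets = {
            "high": _group_offset(cfg.pheno_means[0], bc_probs["high"], cfg.beta0,
                                  cfg.beta1, cfg.noise_sd),
            "low": _group_offset(cfg.pheno_means[1], bc_probs["low"], cfg.beta0,
                                 cfg.beta1, cfg.noise_sd),
        }
    else:
        offsets = {"high": 0.0, "low": 0.0}
    bc = np.empty(n, dtype=int)
    for i, ind in enumerate(ids):
        bc[i] = rng.choice(np.arange(1, 6), p=bc_probs[group_of[ind]])
    final_age = np.clip(rng.normal(4.48, 1.28, size=n), 2.5, 9.0)
    final_births = np.clip(np.round(rng.normal(3.2, 1.31, size=n)), 1, 8).astype(int)

    rows = []
    n_years = len(cfg.years)
    for yi, year in enumerate(sorted(cfg.years)):
        back = n_years - 1 - yi
        hours = np.clip(rng.normal(24.0, 6.0, size=n), 4.0, 48.0)
        eps = rng.normal(0.0, cfg.noise_sd, size=n)
        for i, ind in enumerate(ids):
            liab = cfg.beta0 + cfg.beta1 * bc[i] + offsets[group_of[ind]] + eps[i]
            fec = int(np.clip(np.rint(liab), 0, 2))
            rows.append({
                "ewe_id": ind, "year": year,
                "age": round(float(final_age[i]) - back, 2),
                "body_condition": int(bc[i]),
                "hours_to_estrus": round(float(hours[i]), 1),
                "n_births": max(1, int(final_births[i]) - back),
                "fecundity": fec,
            })
    phenotypes = pd.DataFrame(rows)

    # --- truth table ------------------------------------------------------
    bp = marker_map["bp"].to_numpy()
    snp_ids = marker_map["snp"].to_numpy()
    chrom_col = marker_map["chrom"].to_numpy()
    truth = TruthTable(
        planted_roh_regions=[(g, str(chrom_col[s]), int(bp[s]), int(bp[e - 1]))
                             for g, s, e, _ in roh_flat_spans],
        planted_diff_snp_ids=[str(snp_ids[j]) for j in sorted(diff_flat)],
        qc_fail_snp_ids=(
            [(str(snp_ids[j]), "maf") for j in sorted(low_maf_idx)]
            + [(str(snp_ids[j]), "hwe") for j in sorted(hwe_idx)]
            + [(str(snp_ids[j]), "call_rate") for j in sorted(low_call_idx)]
        ),
        true_groups=group_of,
    )
    return matrix, marker_map, phenotypes, truth


def simulate_gene_annotation(marker_map: pd.DataFrame, n_genes: int, seed: int,
                             cover_regions: list[tuple[str, int, int]] | None = None
                             ) -> list[GeneRecord]:
    """Random gene annotation on the map's chromosomes.

    ``cover_regions`` are (chrom, start_bp, end_bp) intervals each of which
    is guaranteed at least one overlapping gene (used to plant recoverable
    genes over the simulated signals).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = np.random.default_rng(seed)
    chrom_max = marker_map.groupby("chrom", sort=False)["bp"].max()
    chroms = chrom_max.index.to_list()
    genes: list[GeneRecord] = []
    counter = 0

    def next_name() -> str:
        nonlocal counter
        counter += 1
        return f"GENE{counter:04d}"

    for region in cover_regions or []:
        chrom, r_start, r_end = str(region[0]), int(region[1]), int(region[2])
        anchor = int(rng.integers(r_start, r_end + 1))
        length = int(rng.integers(5_000, 60_000))
        start = max(1, anchor - length // 2)
        genes.append(GeneRecord(name=next_name(), chrom=chrom, start=start,
                                end=start + length,
                                strand="+" if rng.random() < 0.5 else "-"))
    for _ in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(5_000, 200_000))
        start = int(rng.integers(1, max(2, int(chrom_max[chrom]) - length)))
        genes.append(GeneRecord(name=next_name(), chrom=str(chrom), start=start,
                                end=start + length,
                                strand="+" if rng.random() < 0.5 else "-"))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
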