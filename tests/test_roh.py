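"""ROH sliding-window detection, per-group in-run frequencies, and
consensus candidate haplotypes."""

import numpy as np
import pandas as pd
import pytest

from ewescan.io import MISSING, GenotypeMatrix
from ewescan.roh import (
    RohParams,
    call_candidate_haplotypes,
    detect_runs,
    snp_run_frequency,
)
from helpers import make_map, make_matrix, roh_bruteforce


def single_ind(codes, params, chrom="1"):
    matrix, mm = make_matrix(np.asarray(codes, dtype=np.int8)[None, :], chrom=chrom)
    return detect_runs(matrix, mm, params)


class TestDetectRuns:
    def test_all_homozygous_is_one_full_run(self):
        runs = single_ind([0] * 100, RohParams())
        assert len(runs) == 1
        assert (runs[0].first_idx, runs[0].last_idx, runs[0].n_snp) == (0, 99, 100)

    def test_alternating_heterozygotes_yield_nothing(self):
        codes = [1 if j % 2 else 0 for j in range(100)]
        assert single_ind(codes, RohParams()) == []

    def test_planted_tract_matches_window_oracle(self):
        """30-SNP homozygous tract in dense heterozygosity: span equals the
        explicit per-window enumeration."""
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2], size=200, p=[0.25, 0.5, 0.25]).astype(np.int8)
        codes[85:115] = 2
        params = RohParams(min_snp=20)
        runs = single_ind(codes, params)
        expect = roh_bruteforce(codes, params)
        assert [(r.first_idx, r.last_idx) for r in runs] == expect
        assert len(expect) == 1
        s, e = expect[0]
        assert s <= 85 and e >= 114

    def test_short_chromosome_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ewescan.roh"):
            runs = single_ind([0] * 10, RohParams(window_size=15))
        assert runs == []
        assert "skipped" in caplog.text

    def test_runs_never_span_chromosomes(self):
        codes = np.zeros((1, 60), dtype=np.int8)
        mm = pd.concat([make_map(30, chrom="1"), make_map(30, chrom="2")],
                       ignore_index=True)
        matrix = GenotypeMatrix(["i0"], mm["snp"].tolist(), codes)
        runs = detect_runs(matrix, mm, RohParams())
        assert sorted(r.chrom for r in runs) == ["1", "2"]
        assert all(r.n_snp == 30 for r in runs)

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(9)
        codes = rng.choice([0, 1, 2, MISSING], size=(6, 120),
                           p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        codes[2, 40:80] = 0
        matrix, mm = make_matrix(codes)
        runs = detect_runs(matrix, mm, RohParams(min_snp=10))
        perm = [3, 1, 5, 0, 4, 2]
        shuffled = GenotypeMatrix([matrix.individual_ids[i] for i in perm],
                                  list(matrix.marker_ids), codes[perm])
        runs2 = detect_runs(shuffled, mm, RohParams(min_snp=10))
        key = lambda r: (r.individual_id, r.first_idx, r.last_idx)
        assert sorted(map(key, runs)) == sorted(map(key, runs2))

    def test_window_one_reduces_to_homozygous_stretches(self):
        """window=1, maxOpp=0, maxMiss=0, minSNP=1 and any sub-unit threshold
        make runs exactly the maximal homozygous stretches."""
        rng = np.random.default_rng(4)
        codes = rng.choice([0, 1, 2, MISSING], size=150,
                           p=[0.35, 0.2, 0.35, 0.1]).astype(np.int8)
        params = RohParams(window_size=1, threshold=0.5, min_snp=1,
                           max_opp_window=0, max_miss_window=0)
        runs = single_ind(codes, params)
        hom = (codes == 0) | (codes == 2)
        expected = []
        j = 0
        while j < 150:
            if hom[j]:
                k = j
                while k + 1 < 150 and hom[k + 1]:
                    k += 1
                expected.append((j, k))
                j = k + 1
            else:
                j += 1
        assert [(r.first_idx, r.last_idx) for r in runs] == expected

    def test_matches_bruteforce_on_random_instances(self):
        """Vectorized detection equals the window-enumeration oracle on
        randomized genotypes and parameters (subset; the exhaustive sweep
        lives in the acceptance suite)."""
        rng = np.random.default_rng(12)
        for trial in range(15):
            L = int(rng.integers(20, 200))
            codes = rng.choice([0, 1, 2, MISSING], size=L,
                               p=[0.35, 0.2, 0.35, 0.1]).astype(np.int8)
            params = RohParams(
                window_size=int(rng.integers(2, 16)),
                threshold=float(rng.choice([0.05, 0.2, 0.5])),
                min_snp=int(rng.integers(1, 20)),
                max_opp_window=int(rng.integers(0, 3)),
                max_miss_window=int(rng.integers(0, 3)))
            runs = single_ind(codes, params)
            assert [(r.first_idx, r.last_idx) for r in runs] == \
                roh_bruteforce(codes, params)


class TestRunFrequency:
    def make_runs(self, spans_by_ind, mm):
        from ewescan.roh import ROHRun

        runs = []
        bp = mm["bp"].to_numpy()
        for ind, spans in spans_by_ind.items():
            for s, e in spans:
                runs.append(ROHRun(ind, "1", mm["snp"][s], mm["snp"][e], s, e,
                                   int(bp[s]), int(bp[e]), e - s + 1,
                                   int(bp[e] - bp[s] + 1)))
        return runs

    def test_full_coverage_is_one(self):
        mm = make_map(10)
        labels = pd.Series({f"i{k}": "high" for k in range(4)} | {"j0": "low", "j1": "low"})
        runs = self.make_runs({f"i{k}": [(2, 7)] for k in range(4)}, mm)
        freqs = snp_run_frequency(runs, labels, mm)
        assert (freqs.loc[2:7, "freq_high"] == 1.0).all()
        assert (freqs["freq_low"] == 0.0).all()

    def test_no_runs_is_all_zero(self):
        mm = make_map(5)
        labels = pd.Series({"a": "high", "b": "high", "c": "low", "d": "low"})
        freqs = snp_run_frequency([], labels, mm)
        assert (freqs[["freq_high", "freq_low"]].to_numpy() == 0).all()

    def test_three_of_four_meets_candidate_threshold(self):
        mm = make_map(10)
        labels = pd.Series({f"i{k}": "high" for k in range(4)} | {"j0": "low", "j1": "low"})
        runs = self.make_runs({f"i{k}": [(0, 9)] for k in range(3)}, mm)
        freqs = snp_run_frequency(runs, labels, mm)
        assert (freqs["freq_high"] == 0.75).all()
        cands = call_candidate_haplotypes(freqs, mm)  # 0.75 inclusive
        assert len(cands) == 1 and cands[0].group == "high" and cands[0].n_snp == 10

    def test_empty_group_rejected(self):
        mm = make_map(5)
        labels = pd.Series({"a": "high", "b": "high"})
        with pytest.raises(ValueError, match="low"):
            snp_run_frequency([], labels, mm)


class TestCandidateHaplotypes:
    def freq_frame(self, high):
        mm = make_map(len(high))
        return pd.DataFrame({"snp": mm["snp"], "chrom": mm["chrom"],
                             "bp": mm["bp"], "freq_high": high,
                             "freq_low": 0.0}), mm

    def test_three_consecutive_qualify(self):
        freqs, mm = self.freq_frame([0.1, 0.8, 0.8, 0.8, 0.1])
        cands = call_candidate_haplotypes(freqs, mm)
        assert len(cands) == 1
        assert cands[0].snp_ids == mm["snp"][1:4].tolist()

    def test_two_consecutive_do_not(self):
        freqs, mm = self.freq_frame([0.8, 0.8, 0.1, 0.1, 0.1])
        assert call_candidate_haplotypes(freqs, mm) == []

    def test_stretch_broken_at_chromosome_boundary(self):
        mm = pd.concat([make_map(3, chrom="1"), make_map(3, chrom="2")],
                       ignore_index=True)
        freqs = pd.DataFrame({"snp": mm["snp"], "chrom": mm["chrom"],
                              "bp": mm["bp"], "freq_high": 0.9, "freq_low": 0.0})
        cands = call_candidate_haplotypes(freqs, mm)
        assert [(c.chrom, c.n_snp) for c in cands] == [("1", 3), ("2", 3)]

    def test_planted_regions_yield_overlapping_candidates(self, default_sim, default_cfg):
        """Every planted shared ROH (carrier fraction >= 0.8) surfaces as a
        consensus candidate haplotype overlapping the planted bp span, using
        the generator's true groups."""
        matrix, mm, _, truth = default_sim
        labels = pd.Series(truth.true_groups)
        runs = detect_runs(matrix, mm, RohParams())
        freqs = snp_run_frequency(runs, labels, mm)
        cands = call_candidate_haplotypes(freqs, mm)
        for group, chrom, start, end in truth.planted_roh_regions:
            hit = [c for c in cands if c.group == group and c.chrom == chrom
                   and c.start_bp <= end and c.end_bp >= start]
            assert hit, f"planted region {group} {chrom}:{start}-{end} not recovered"
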