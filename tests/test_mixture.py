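"""Pileup counting and the informative-SNP mixture estimator."""

import math

import numpy as np
import pytest

from helpers import pileup_oracle

from mitomixer.errors import NoInformativeSitesError, ReferenceMismatchError
from mitomixer.genomes import CircularGenome
from mitomixer.haplotyping import InformativeSNP
from mitomixer.mixture import (
    PileupColumn,
    build_pileup,
    compare_amplification_modes,
    estimate_exogenous_fraction,
    estimate_from_alignments,
    snp_frequencies,
)
from mitomixer.simulate import ReadSimConfig, simulate_reads


def expected_site_freq(f: float, e: float) -> float:
    """Expected donor-allele read frequency at a clean informative site.

    True-donor reads keep the donor base with probability 1-e; each
    non-donor read errs into the donor base with probability e/3.
    """
    return f * (1 - e) + (1 - f) * e / 3


class TestBuildPileup:
    def test_counts_match_brute_force_oracle(self, small_sim, small_pair):
        positions = small_pair.snp_positions() + [1, 500, 1500]
        cols = build_pileup(small_sim.sam_path, small_pair.recipient, positions)
        oracle = pileup_oracle(small_sim.sam_path, positions, 20, 20)
        for col in cols:
            assert col.counts == {
                b: oracle[col.position].get(b, 0) for b in "ACGT"
            }

    def test_depth_zero_when_no_coverage(self, small_pair, tmp_path):
        cfg = ReadSimConfig(coverage=30, mixture_fraction=0.0, seed=4)
        res = simulate_reads(small_pair, cfg, tmp_path / "x", emit_fastq=False)
        # min_baseq above the simulated Q30 removes every base
        cols = build_pileup(
            res.sam_path, small_pair.recipient, [10, 20], min_baseq=31
        )
        assert all(c.depth == 0 for c in cols)
        assert all(c.mean_baseq == 0.0 for c in cols)

    def test_reference_length_mismatch_rejected(self, small_sim):
        wrong = CircularGenome("other", "ACGT" * 100)
        with pytest.raises(ReferenceMismatchError):
            build_pileup(small_sim.sam_path, wrong, [1])


def _col(position, counts):
    full = dict.fromkeys("ACGT", 0)
    full.update(counts)
    return PileupColumn(position=position, counts=full, mean_baseq=30.0)


def _snp(position, donor, recipient, flags=()):
    return InformativeSNP(position, donor, recipient, frozenset(flags))


class TestSnpFrequencies:
    def test_basic_arithmetic(self):
        freqs = snp_frequencies(
            [_col(5, {"A": 90, "G": 10})], [_snp(5, "G", "A")], min_depth=50
        )
        assert freqs[0].donor_freq == pytest.approx(0.10)
        assert freqs[0].passed

    def test_low_depth_fails(self):
        freqs = snp_frequencies(
            [_col(5, {"A": 30, "G": 10})], [_snp(5, "G", "A")], min_depth=100
        )
        assert not freqs[0].passed
        assert freqs[0].fail_reason == "low_depth"

    def test_flagged_site_fails_unless_kept(self):
        cols = [_col(5, {"A": 90, "G": 110})]
        snps = [_snp(5, "G", "A", {"in_deletion"})]
        assert snp_frequencies(cols, snps, 100)[0].fail_reason == "flagged_site"
        assert snp_frequencies(cols, snps, 100, keep_flagged=True)[0].passed

    def test_site_frequencies_binomially_distributed(self, small_sim, small_pair):
        cfg_f = 0.2
        cols = build_pileup(
            small_sim.sam_path, small_pair.recipient, small_pair.snp_positions()
        )
        snps = [_snp(p, d, r) for p, d, r in small_pair.truth_snps]
        freqs = snp_frequencies(cols, snps, min_depth=100)
        for f in freqs:
            sd = math.sqrt(cfg_f * (1 - cfg_f) / f.depth)
            assert abs(f.donor_freq - cfg_f) <= 4 * sd


class TestEstimate:
    def test_mean_of_two_sites(self):
        freqs = snp_frequencies(
            [_col(5, {"A": 90, "G": 10}), _col(9, {"C": 80, "T": 20})],
            [_snp(5, "G", "A"), _snp(9, "T", "C")],
            min_depth=50,
        )
        est = estimate_exogenous_fraction(freqs)
        assert est.percent_exogenous == pytest.approx(15.0)
        assert est.n_snps_used == 2

    def test_all_zero_frequencies(self):
        freqs = snp_frequencies(
            [_col(5, {"A": 200}), _col(9, {"C": 200})],
            [_snp(5, "G", "A"), _snp(9, "T", "C")],
            min_depth=50,
        )
        est = estimate_exogenous_fraction(freqs)
        assert est.percent_exogenous == 0.0
        assert est.sem == 0.0

    def test_no_passed_sites_raises(self):
        freqs = snp_frequencies(
            [_col(5, {"A": 10})], [_snp(5, "G", "A")], min_depth=100
        )
        with pytest.raises(NoInformativeSitesError):
            estimate_exogenous_fraction(freqs)


class TestBoundaryExactness:
    def test_pure_recipient_estimate_at_error_floor(self, small_pair, tmp_path):
        cfg = ReadSimConfig(coverage=400, mixture_fraction=0.0, seed=21)
        res = simulate_reads(small_pair, cfg, tmp_path / "f0", emit_fastq=False)
        est = estimate_from_alignments(
            res.sam_path, small_pair.donor, small_pair.recipient
        )
        ceiling = 100 * cfg.error_rate / 3 + 4 * max(est.sem, 1e-3)
        assert est.percent_exogenous <= ceiling

    def test_pure_donor_estimate_near_hundred(self, small_pair, tmp_path):
        cfg = ReadSimConfig(coverage=400, mixture_fraction=1.0, seed=22)
        res = simulate_reads(small_pair, cfg, tmp_path / "f1", emit_fastq=False)
        est = estimate_from_alignments(
            res.sam_path, small_pair.donor, small_pair.recipient
        )
        floor = 100 - (100 * cfg.error_rate / 3 + 4 * max(est.sem, 1e-3))
        assert est.percent_exogenous >= floor


DOSE_FRACTIONS = (0.00625, 0.054, 0.145)


@pytest.fixture(scope="module")
def dose_means(small_pair, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("doses")
    means = {}
    for f in DOSE_FRACTIONS:
        vals = []
        for seed in range(20):
            cfg = ReadSimConfig(coverage=400, mixture_fraction=f, seed=1000 + seed)
            res = simulate_reads(
                small_pair, cfg, tmp / f"f{f}_{seed}", emit_fastq=False
            )
            est = estimate_from_alignments(
                res.sam_path, small_pair.donor, small_pair.recipient
            )
            vals.append(est.percent_exogenous)
        means[f] = (np.mean(vals), np.std(vals, ddof=1) / len(vals) ** 0.5)
    return means


@pytest.fixture(scope="module")
def mode_estimates(small_pair, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("modes")
    ests = {"rca_uniform": [], "pcr_two_amplicon": []}
    for mode in ests:
        for seed in range(20):
            cfg = ReadSimConfig(
                coverage=400,
                mixture_fraction=0.10,
                amplification_mode=mode,
                seed=300 + seed,
            )
            res = simulate_reads(
                small_pair, cfg, tmp / f"{mode}_{seed}", emit_fastq=False
            )
            ests[mode].append(
                estimate_from_alignments(
                    res.sam_path, small_pair.donor, small_pair.recipient
                )
            )
    return ests


class TestRecoveryAcrossDoses:
    def test_unbiased_within_monte_carlo_error(self, dose_means):
        for f, (mean, mc_se) in dose_means.items():
            expected = 100 * expected_site_freq(f, 0.001)
            assert abs(mean - expected) <= 2 * mc_se + 1e-9, (f, mean, expected)

    def test_dose_monotonicity(self, dose_means):
        ms = [dose_means[f][0] for f in DOSE_FRACTIONS]
        assert ms[0] < ms[1] < ms[2]


class TestAmplificationConcordance:
    def test_identical_estimates_have_zero_difference(self, small_sim, small_pair):
        est = estimate_from_alignments(
            small_sim.sam_path, small_pair.donor, small_pair.recipient
        )
        rec = compare_amplification_modes(est, est)
        assert rec.difference_pp == 0.0
        assert rec.ratio == pytest.approx(1.0)

    def test_modes_concordant_below_one_point(self, mode_estimates):
        mean_rca = np.mean(
            [e.percent_exogenous for e in mode_estimates["rca_uniform"]]
        )
        mean_pcr = np.mean(
            [e.percent_exogenous for e in mode_estimates["pcr_two_amplicon"]]
        )
        assert abs(mean_rca - mean_pcr) < 1.0

    def test_depth_imbalance_does_not_bias_mean(self, small_pair, tmp_path):
        vals = []
        for seed in range(10):
            cfg = ReadSimConfig(
                coverage=500,
                mixture_fraction=0.10,
                amplification_mode="pcr_two_amplicon",
                amplicon_depth_ratio=5.0,
                seed=600 + seed,
            )
            res = simulate_reads(
                small_pair, cfg, tmp_path / f"im{seed}", emit_fastq=False
            )
            est = estimate_from_alignments(
                res.sam_path, small_pair.donor, small_pair.recipient
            )
            vals.append(est.percent_exogenous)
        mc_se = np.std(vals, ddof=1) / len(vals) ** 0.5
        assert abs(np.mean(vals) - 10.0) <= max(3 * mc_se, 0.4)
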