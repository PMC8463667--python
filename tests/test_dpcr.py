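"""Digital-PCR Poisson statistics and the chip simulator."""

import math
import warnings

import numpy as np
import pytest

from mitomixer.dpcr import (
    AssayDef,
    PartitionCounts,
    copies_per_ng,
    deletion_heteroplasmy,
    dual_probe_fraction,
    poisson_lambda,
    quantify_chip,
    read_counts_tsv,
    write_counts_tsv,
)
from mitomixer.errors import (
    InvalidParameterError,
    SaturationError,
    UndefinedFractionError,
    UndefinedHeteroplasmyError,
)
from mitomixer.simulate import ChipSimConfig, simulate_dpcr, simulate_dpcr_heteroplasmy


def _counts(n_positive, n_valid=20_000, ng=float("nan"), name="a"):
    return PartitionCounts(name, n_valid, n_positive, ng)


class TestPoissonLambda:
    def test_closed_form_example(self):
        # p such that -ln(1-p) == 1 exactly: p = 1 - 1/e
        n_pos = round(20_000 * (1 - math.exp(-1)))  # 12642
        lam = poisson_lambda(n_pos, 20_000)
        assert lam == pytest.approx(1.0, abs=1e-4)

    def test_zero_positive_is_zero(self):
        assert poisson_lambda(0, 20_000) == 0.0

    def test_hand_computed_value(self):
        assert poisson_lambda(100, 20_000) == pytest.approx(
            -math.log(1 - 100 / 20_000)
        )

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            poisson_lambda(20_000, 20_000)

    @pytest.mark.parametrize("pos,valid", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, pos, valid):
        with pytest.raises(InvalidParameterError):
            poisson_lambda(pos, valid)


class TestCopiesPerNg:
    def test_arithmetic(self):
        # lambda * n_valid / ng with a hand-picked count
        c = _counts(119, 20_000, ng=2.0)
        res = copies_per_ng(c)
        lam = -math.log(1 - 119 / 20_000)
        assert res.lam == pytest.approx(lam)
        assert res.copies_per_chip == pytest.approx(lam * 20_000)
        assert res.copies_per_ng == pytest.approx(lam * 20_000 / 2.0)
        # ~59.6 copies/ng, matching the low-occupancy regime of a nuclear
        # single-copy gene assay loaded with 2 ng
        assert res.copies_per_ng == pytest.approx(59.68, abs=0.1)

    def test_ci_brackets_point_estimate(self):
        res = copies_per_ng(_counts(500, 20_000, ng=1.0))
        lo, hi = res.ci95_per_ng
        assert lo < res.copies_per_ng < hi
        assert res.ci95 == res.ci95_per_ng

    def test_per_ng_inverse_in_load(self):
        a = copies_per_ng(_counts(400, 20_000, ng=1.0))
        b = copies_per_ng(_counts(400, 20_000, ng=4.0))
        assert a.copies_per_ng == pytest.approx(4 * b.copies_per_ng)

    def test_zero_positive_gives_zero_copies(self):
        res = copies_per_ng(_counts(0, 20_000, ng=2.0))
        assert res.copies_per_chip == 0.0
        assert res.copies_per_ng == 0.0
        assert res.ci95_per_ng[0] == 0.0

    def test_missing_load_rejected(self):
        with pytest.raises(InvalidParameterError):
            copies_per_ng(_counts(100, 20_000))

    def test_quantify_chip_override(self):
        res = quantify_chip(_counts(100, 20_000), ng_loaded=2.5)
        assert res.copies_per_ng == pytest.approx(
            copies_per_ng(_counts(100, 20_000, ng=2.5)).copies_per_ng
        )


class TestDeletionHeteroplasmy:
    def _cn(self, per_ng, name="x"):
        lam = per_ng  # ng=1, n_valid irrelevant for the ratio
        return copies_per_ng(
            _counts(round(20_000 * (1 - math.exp(-per_ng / 20_000))), ng=1.0, name=name)
        )

    def test_arithmetic_example(self):
        # FL at 16.5% of total -> heteroplasmy 83.5%
        fl = self._cn(16_500 * 0.165, "full_length")
        tot = self._cn(16_500, "total")
        res = deletion_heteroplasmy(fl, tot)
        assert res.percent == pytest.approx(83.5, abs=0.2)
        assert not res.clamped

    def test_equal_assays_give_zero(self):
        c = self._cn(5000)
        assert deletion_heteroplasmy(c, c).percent == 0.0

    def test_zero_full_length_gives_hundred(self):
        fl = copies_per_ng(_counts(0, ng=1.0, name="full_length"))
        tot = self._cn(5000, "total")
        assert deletion_heteroplasmy(fl, tot).percent == 100.0

    def test_fl_above_total_clamped_with_warning(self):
        fl = self._cn(5200, "full_length")
        tot = self._cn(5000, "total")
        with pytest.warns(UserWarning, match="clamping"):
            res = deletion_heteroplasmy(fl, tot)
        assert res.percent == 0.0
        assert res.clamped

    def test_zero_total_undefined(self):
        fl = self._cn(100, "full_length")
        tot = copies_per_ng(_counts(0, ng=1.0, name="total"))
        with pytest.raises(UndefinedHeteroplasmyError):
            deletion_heteroplasmy(fl, tot)


class TestDualProbe:
    def test_equal_channels_give_half(self):
        a = _counts(800, name="a")
        b = _counts(800, name="b")
        assert dual_probe_fraction(a, b) == pytest.approx(0.5)

    def test_empty_b_gives_zero(self):
        assert dual_probe_fraction(_counts(800), _counts(0)) == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedFractionError):
            dual_probe_fraction(_counts(0), _counts(0))


class TestAssayDef:
    def test_target_inside_deletion_detects_full_length_only(self):
        a = AssayDef.from_deletion("nd4", 11_000, 8470, 13_447)
        assert a.detects == "full_length_only"

    def test_target_outside_deletion_detects_all(self):
        a = AssayDef.from_deletion("nd1", 3500, 8470, 13_447)
        assert a.detects == "all_molecules"


class TestChipSimulator:
    def test_determinism(self):
        cfg = ChipSimConfig(true_copies_per_ng=1000, ng_loaded=5.0, seed=3)
        assert simulate_dpcr(cfg) == simulate_dpcr(cfg)
        other = ChipSimConfig(true_copies_per_ng=1000, ng_loaded=5.0, seed=4)
        assert simulate_dpcr(other) != simulate_dpcr(cfg)

    def test_valid_fraction_shrinks_chip(self):
        cfg = ChipSimConfig(
            true_copies_per_ng=100, ng_loaded=1.0, valid_fraction=0.9, seed=0
        )
        assert simulate_dpcr(cfg).n_valid == 18_000

    def test_occupancy_matches_poisson_occupancy_law(self):
        # lambda* = 1 -> positive fraction 1 - 1/e over many chips
        fracs = []
        for seed in range(100):
            cfg = ChipSimConfig(
                true_copies_per_ng=20_000, ng_loaded=1.0, seed=seed
            )
            c = simulate_dpcr(cfg)
            fracs.append(c.n_positive / c.n_valid)
        assert np.mean(fracs) == pytest.approx(1 - math.exp(-1), abs=0.005)

    @pytest.mark.parametrize("lam_true", [0.01, 0.1, 0.5, 1.0, 3.0])
    def test_lambda_round_trip(self, lam_true):
        # simulate at a known occupancy, re-infer lambda; mean relative
        # error over replicate chips stays below 3%
        ests = []
        for seed in range(40):
            cfg = ChipSimConfig(
                true_copies_per_ng=lam_true * 20_000, ng_loaded=1.0, seed=10 + seed
            )
            c = simulate_dpcr(cfg)
            ests.append(poisson_lambda(c.n_positive, c.n_valid))
        assert abs(np.mean(ests) - lam_true) / lam_true < 0.03

    def test_estimator_consistency_in_partition_count(self):
        # spread of the recovered concentration shrinks as chips grow
        spreads = []
        for n in (2_000, 20_000, 200_000):
            vals = []
            for seed in range(30):
                cfg = ChipSimConfig(
                    true_copies_per_ng=0.5 * n,
                    ng_loaded=1.0,
                    n_partitions=n,
                    seed=seed,
                )
                c = simulate_dpcr(cfg)
                vals.append(poisson_lambda(c.n_positive, c.n_valid))
            spreads.append(np.std(vals))
        assert spreads[0] > spreads[1] > spreads[2]

    @pytest.mark.parametrize("h", [0.0, 0.5, 0.835, 1.0])
    def test_heteroplasmy_recovery(self, h):
        vals = []
        for seed in range(20):
            cfg = ChipSimConfig(
                true_copies_per_ng=1527.0, ng_loaded=6.55, seed=100 + seed
            )
            fl, tot = simulate_dpcr_heteroplasmy(1527.0, h, cfg)
            with warnings.catch_warnings():
                # at h=0 sampling noise triggers the clamp warning by design
                warnings.simplefilter("ignore", UserWarning)
                res = deletion_heteroplasmy(copies_per_ng(fl), copies_per_ng(tot))
            vals.append(res.percent)
        assert abs(np.mean(vals) - 100 * h) < 1.0

    def test_invalid_sim_configs_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChipSimConfig(true_copies_per_ng=-1, ng_loaded=1.0)
        with pytest.raises(InvalidParameterError):
            ChipSimConfig(true_copies_per_ng=1, ng_loaded=1.0, valid_fraction=0.0)
        with pytest.raises(InvalidParameterError):
            simulate_dpcr_heteroplasmy(
                100.0, 1.5, ChipSimConfig(true_copies_per_ng=100, ng_loaded=1.0)
            )


class TestCountsIO:
    def test_roundtrip(self, tmp_path):
        counts = [
            _counts(100, 20_000, ng=2.0, name="b2m"),
            _counts(5000, 18_000, ng=6.55, name="total"),
        ]
        path = tmp_path / "counts.tsv"
        write_counts_tsv(counts, path)
        loaded = read_counts_tsv(path)
        assert loaded == counts

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("assay\tn_valid\nx\t100\n")
        with pytest.raises(InvalidParameterError):
            read_counts_tsv(path)

    def test_invalid_partition_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            PartitionCounts("x", 10, 11)
        with pytest.raises(InvalidParameterError):
            PartitionCounts("x", 0, 0)
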