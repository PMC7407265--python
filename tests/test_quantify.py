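"""Poisson quantification: rate estimation, MAF, LoB/LoD, estimator recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropquant import (
    ClassifiedWell,
    SimulationConfig,
    concentration,
    detect_mutation,
    dropoff_maf,
    estimate_lambda,
    limit_of_blank,
    lod_from_dilution,
    simulate_partition,
)
from dropquant.errors import (
    InsufficientDataError,
    InvalidCountsError,
    SaturationError,
)


def _cw(n_total, n_negative, n_double_positive, n_fam_only, n_hex_only=0):
    return ClassifiedWell("w", n_total, n_negative, n_double_positive, n_fam_only, n_hex_only)


class TestEstimateLambda:
    def test_all_negative_is_zero(self):
        est = estimate_lambda(20000, 20000)
        assert est.lam == 0.0
        assert (est.ci_low, est.ci_high) == (0.0, 0.0)

    def test_half_negative_is_ln2(self):
        est = estimate_lambda(10000, 20000)
        assert est.lam == pytest.approx(math.log(2), abs=1e-9)
        # delta-method half-width 1.96*sqrt((e^lam - 1)/n) = 1.96*sqrt(1/20000)
        assert est.ci_low == pytest.approx(0.679, abs=5e-4)
        assert est.ci_high == pytest.approx(0.707, abs=5e-4)

    def test_ninety_percent_negative(self):
        assert estimate_lambda(18000, 20000).lam == pytest.approx(0.105361, abs=1e-6)

    def test_monte_carlo_partition_oracle(self):
        """lambda-hat from 500 multinomially partitioned wells recovers
        -ln(0.9) within 3 SE."""
        n_droplets, copies = 2000, int(round(0.105361 * 2000))
        rng = np.random.default_rng(8)
        estimates = []
        for _ in range(500):
            occ = simulate_partition(copies, 0, n_droplets, seed=rng)
            n_neg = int(np.sum(occ.sum(axis=1) == 0))
            estimates.append(estimate_lambda(n_neg, n_droplets).lam)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - copies / n_droplets) < 3 * se

    def test_saturation_and_invalid_counts(self):
        with pytest.raises(SaturationError):
            estimate_lambda(0, 20000)
        with pytest.raises(InvalidCountsError):
            estimate_lambda(30000, 20000)


@pytest.mark.parametrize(
    "lam,vol,expected",
    [(0.0, 0.85, 0.0), (0.693147, 0.85, 815.47), (1.0, 1.0, 1000.0)],
)
def test_concentration(lam, vol, expected):
    assert concentration(lam, vol) == pytest.approx(expected, rel=1e-4)


class TestDropoffMaf:
    def test_no_mutant_population(self):
        r = dropoff_maf(_cw(20000, 15700, 4300, 0))
        assert r.lam_mut == 0.0
        assert r.maf == 0.0

    def test_pure_mutant_is_100_percent(self):
        r = dropoff_maf(_cw(20000, 18000, 0, 2000))
        assert r.lam_wt == 0.0
        assert r.maf == pytest.approx(100.0)

    def test_mixed_well_closed_form(self):
        r = dropoff_maf(_cw(20000, 18000, 1900, 100))
        assert r.lam_total == pytest.approx(0.105361, abs=1e-6)
        assert r.lam_wt == pytest.approx(0.099820, abs=1e-6)
        assert r.lam_mut == pytest.approx(0.005540, abs=1e-6)
        assert r.maf == pytest.approx(5.26, abs=0.005)
        assert r.maf_ci_low < r.maf < r.maf_ci_high

    def test_hex_only_excess_attaches_warning(self):
        r = dropoff_maf(_cw(20000, 17800, 1900, 100, 200))
        assert r.warnings

    def test_saturated_well_raises(self):
        with pytest.raises(SaturationError):
            dropoff_maf(_cw(100, 0, 50, 50))

    @given(extra=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_maf_monotone_in_fam_only(self, extra):
        base = dropoff_maf(_cw(20100, 18000, 2000, 100))
        more = dropoff_maf(_cw(20100 + extra, 18000, 2000, 100 + extra))
        assert more.maf >= base.maf - 1e-12

    def test_small_lambda_limit_matches_naive_ratio(self):
        """At lambda <= 0.01 the Poisson-corrected MAF converges to the naive
        droplet-count ratio within 0.1 percentage point."""
        n_total = 1_000_000
        n_fam, n_dp = 20, 9980  # lambda_total ~ 0.01
        r = dropoff_maf(_cw(n_total, n_total - n_fam - n_dp, n_dp, n_fam))
        naive = 100.0 * n_fam / (n_fam + n_dp)
        assert abs(r.maf - naive) < 0.1


class TestMafRecovery:
    @pytest.mark.parametrize("maf_pct", [0.1, 1.0, 5.0, 20.0, 44.0])
    def test_mean_estimate_within_3se_of_truth(self, maf_pct):
        """200 simulated wells at 4848 copies: mean estimated MAF within 3 SE
        of the realised truth (range spans the reported patient burdens)."""
        total = 4848
        n_mut = int(round(maf_pct / 100.0 * total))
        n_wt = total - n_mut
        truth = 100.0 * n_mut / total
        rng = np.random.default_rng(int(maf_pct * 10))
        estimates = []
        for _ in range(200):
            occ = simulate_partition(n_wt, n_mut, 20000, seed=rng)
            wt, mut = occ[:, 0], occ[:, 1]
            cw = _cw(
                20000,
                int(np.sum((wt == 0) & (mut == 0))),
                int(np.sum(wt >= 1)),
                int(np.sum((wt == 0) & (mut >= 1))),
            )
            estimates.append(dropoff_maf(cw).maf)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - truth) < 3 * se


class TestDetectionAndLimits:
    def test_detect_rule(self):
        r0 = dropoff_maf(_cw(20000, 15700, 4300, 0))
        assert detect_mutation(r0) is False
        r5 = dropoff_maf(_cw(20000, 15700, 4295, 5))
        assert detect_mutation(r5, lob_droplets=0, min_droplets_rule=1) is True
        r2 = dropoff_maf(_cw(20000, 15700, 4298, 2))
        assert detect_mutation(r2, lob_droplets=2) is False  # must strictly exceed LoB

    def test_lob_nearest_rank(self):
        def blanks(counts):
            return [_cw(10000, 10000 - c, 0, c) for c in counts]

        assert limit_of_blank(blanks([0, 0, 0, 0])) == 0
        assert limit_of_blank(blanks([0, 0, 0, 1])) == 1
        # 20 blanks, 19 zeros and one 3: rank ceil(0.95*20)=19 -> 0
        assert limit_of_blank(blanks([0] * 19 + [3])) == 0
        with pytest.raises(InsufficientDataError):
            limit_of_blank([])

    def test_lod_single_level(self):
        lod = lod_from_dilution([(0.10, [True] * 10)])
        assert lod.lod_pct == pytest.approx(10.0)

    def test_lod_requires_monotone_qualification(self):
        levels = [(0.01, [True] * 100), (0.001, [True] * 99 + [False])]
        lod = lod_from_dilution(levels, required_rate=0.95)
        assert lod.lod_pct == pytest.approx(0.1)
        # a failing middle level blocks lower levels from qualifying
        levels = [(0.01, [True]), (0.005, [False]), (0.001, [True])]
        assert lod_from_dilution(levels).lod_pct == pytest.approx(1.0)

    def test_lod_excludes_blank_level_and_may_be_unreached(self):
        lod = lod_from_dilution([(0.0, [True] * 5), (0.01, [False] * 5)])
        assert lod.lod_pct is None
        assert 0.0 in lod.detection_rates
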