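import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from cltriage import (
    TwoByTwo,
    fisher_exact_two_sided,
    kruskal_wallis,
    mann_whitney,
    rate,
    relative_risk,
)
from cltriage.stats import format_rate


def fisher_oracle(a, b, c, d):
    """Exact-rational full enumeration of the conditional distribution."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def comb(n_, k_):
        return Fraction(math.comb(n_, k_))

    denom = comb(n, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: comb(c1, x) * comb(n - c1, r1 - x) / denom for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestRelativeRisk:
    def test_suture_term_direction_reproduces_published_interval(self):
        """Term birth, braided (23/38) vs monofilament (51/60): RR 0.71,
        Katz 95% CI (0.54, 0.94) at 2 dp."""
        res = relative_risk(TwoByTwo(23, 15, 51, 9))
        assert res.rr == pytest.approx(0.712, abs=5e-4)
        assert round(res.ci_low, 2) == 0.54
        assert round(res.ci_high, 2) == 0.94

    def test_equal_risks_give_unity(self):
        res = relative_risk(TwoByTwo(10, 10, 10, 10))
        assert res.rr == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_row_swap_reciprocity(self):
        t = TwoByTwo(9, 51, 15, 23)
        assert relative_risk(t.swap_rows()).rr == pytest.approx(
            1.0 / relative_risk(t).rr
        )

    def test_column_swap_is_complementary_outcome(self):
        t = TwoByTwo(9, 51, 15, 23)
        res = relative_risk(t.swap_columns())
        assert res.rr == pytest.approx((51 / 60) / (23 / 38))

    def test_zero_cell_needs_continuity(self):
        t = TwoByTwo(0, 10, 5, 5)
        res = relative_risk(t)
        assert math.isnan(res.ci_low)
        res_cc = relative_risk(t, continuity=True)
        assert res_cc.continuity_corrected
        assert res_cc.ci_low < res_cc.rr < res_cc.ci_high

    def test_katz_interval_coverage(self):
        """~95% of simulated binomial pairs produce an interval covering the
        true risk ratio (seeded, 10000 reps)."""
        rng = np.random.default_rng(123)
        n1, n2, p1, p2 = 60, 40, 0.4, 0.25
        true_rr = p1 / p2
        x1 = rng.binomial(n1, p1, size=10000)
        x2 = rng.binomial(n2, p2, size=10000)
        covered = total = 0
        for a, c in zip(x1, x2):
            if a == 0 or c == 0 or a == n1 or c == n2:
                continue
            res = relative_risk(TwoByTwo(int(a), n1 - int(a), int(c), n2 - int(c)))
            total += 1
            covered += res.ci_low <= true_rr <= res.ci_high
        assert covered / total == pytest.approx(0.95, abs=0.01)


class TestFisherExact:
    def test_two_by_two_identity_table(self):
        assert fisher_exact_two_sided(TwoByTwo(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_suture_preterm_table(self):
        """Preterm by suture (9/60 vs 15/38) gives p ~ 0.008."""
        p = fisher_exact_two_sided(TwoByTwo(9, 51, 15, 23))
        assert p == pytest.approx(fisher_oracle(9, 51, 15, 23), rel=1e-9)
        assert round(p, 3) == 0.008

    def test_zero_margin_gives_unity(self):
        assert fisher_exact_two_sided(TwoByTwo(0, 0, 3, 4)) == 1.0
        assert fisher_exact_two_sided(TwoByTwo(0, 3, 0, 4)) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        """Implementation equals the exact-rational oracle on every random
        table with total <= 40."""
        rng = np.random.default_rng(99)
        for _ in range(400):
            total = int(rng.integers(1, 41))
            cuts = sorted(rng.integers(0, total + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            cells = rng.integers(0, 30, size=4)
            if cells.sum() == 0:
                continue
            t = TwoByTwo(*map(int, cells))
            _, p_ref = sps.fisher_exact([[t.a, t.b], [t.c, t.d]])
            assert fisher_exact_two_sided(t) == pytest.approx(p_ref, abs=1e-9)

    def test_enumeration_bound(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(TwoByTwo(9000, 2000, 1, 1))


class TestMannWhitney:
    def test_identical_multisets_exact_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.method == "exact"
        assert res.p == 1.0

    def test_disjoint_small_samples(self):
        """Fully separated triples: U = 0 and exact two-sided p = 0.1
        (2 of the C(6,3) = 20 equally likely arrangements are as extreme)."""
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)

    def test_exact_matches_enumeration(self):
        """Six-per-side random data: implementation equals brute force."""
        rng = np.random.default_rng(21)
        x = rng.integers(0, 10, 6).astype(float)
        y = rng.integers(0, 10, 6).astype(float)
        res = mann_whitney(list(x), list(y))
        assert res.method == "exact"
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = 36 / 2
        obs = abs(res.u_x - mu)
        count = total = 0
        for combo in itertools.combinations(range(12), 6):
            u = ranks[list(combo)].sum() - 21
            count += abs(u - mu) >= obs - 1e-9
            total += 1
        assert res.p == pytest.approx(count / total)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_all_equal_gives_zero(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5], [5]])
        assert h == 0.0
        assert p == 1.0

    def test_two_groups_consistent_with_mann_whitney(self):
        """For 2 groups, chi2(H) equals the two-sided normal p of the
        (uncorrected) Mann-Whitney z."""
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.8, 1, 22)
        h, p_kw = kruskal_wallis([x, y])
        res = mann_whitney(x, y, continuity=False)
        assert p_kw == pytest.approx(res.p, rel=1e-9)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mu, 1, 70) for mu in (0.0, 0.8, 1.6)]
        _, p = kruskal_wallis(groups)
        assert p < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestRate:
    @pytest.mark.parametrize(
        "num,den,display",
        [(70, 725, "9.7%"), (24, 98, "24.5%"), (98, 725, "13.5%"), (0, 10, "0.0%")],
    )
    def test_printed_rates(self, num, den, display):
        assert format_rate(rate(num, den)) == display

    def test_braided_preterm_rate(self):
        # 15/38 = 39.47%; reported as 40% after rounding to whole percent
        assert rate(15, 38) == pytest.approx(39.4737, abs=1e-3)
        assert abs(rate(15, 38) - 40.0) < 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rate(1, 0)
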