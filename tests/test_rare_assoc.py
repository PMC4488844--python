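"""QC, relatedness, trend/inflation, SKAT-O and FDR statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lqtex.rare_assoc import (
    beta_maf_weights,
    bh_fdr,
    hwe_exact,
    ibd_pi_hat,
    pca_outliers,
    quadform_sf,
    skato,
    trend_lambda,
    trend_stat,
    variant_qc,
)
from lqtex.variant_model import FunctionalClass, GenotypeTable, VariantSite


def _table(gt, prefix="s"):
    gt = np.asarray(gt, dtype=np.int8)
    sites = [
        VariantSite("1", 1 + j, "A", "G", gene=f"G{j}",
                    functional_class=FunctionalClass.missense)
        for j in range(gt.shape[1])
    ]
    return GenotypeTable([f"{prefix}{i}" for i in range(gt.shape[0])], sites, gt)


def hwe_oracle(n0, n1, n2):
    """Full enumeration over het counts using exact rational-free arithmetic."""
    n = n0 + n1 + n2
    n_rare = 2 * min(n0, n2) + n1
    hets = range(n_rare % 2, n_rare + 1, 2)
    weights = []
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        w = (
            h * math.log(2)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(common_hom + 1)
        )
        weights.append(w)
    mx = max(weights)
    probs = [math.exp(w - mx) for w in weights]
    total = sum(probs)
    probs = [p / total for p in probs]
    obs = probs[list(hets).index(n1)]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(100, 0, 0) == 1.0

    def test_all_het_matches_enumeration(self):
        assert hwe_exact(0, 100, 0) == pytest.approx(hwe_oracle(0, 100, 0), rel=1e-12)

    def test_label_symmetry(self):
        for n0, n1, n2 in [(10, 5, 3), (40, 12, 1), (7, 0, 9)]:
            assert hwe_exact(n0, n1, n2) == pytest.approx(hwe_exact(n2, n1, n0))

    def test_matches_enumeration_oracle_over_grid(self):
        for n0, n1, n2 in itertools.product(range(0, 16, 3), repeat=3):
            if n0 + n1 + n2 == 0:
                continue
            assert hwe_exact(n0, n1, n2) == pytest.approx(
                hwe_oracle(n0, n1, n2), rel=1e-10
            ), (n0, n1, n2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 0)


class TestVariantQC:
    def test_low_call_rate_removed(self):
        col = np.array([[-1]] * 21 + [[0]] * 79, dtype=np.int8)  # 79% called
        retained, log = variant_qc(_table(col), maf_max=None)
        assert retained == [] and log.iloc[0]["rule"] == "call_rate"

    def test_hwe_violation_removed(self):
        # wildly het-deficient: all homs, half and half
        col = np.array([[0]] * 50 + [[2]] * 50, dtype=np.int8)
        retained, log = variant_qc(_table(col), maf_max=None)
        assert retained == [] and log.iloc[0]["rule"] == "hwe"

    def test_survivors_match_predicate_oracle_on_panel(self):
        rng = np.random.default_rng(2)
        n, m = 120, 200
        gt = np.zeros((n, m), dtype=np.int8)
        for j in range(m):
            q = rng.uniform(0.0, 0.15)
            gt[:, j] = rng.binomial(2, q, size=n)
            miss = rng.random(n) < rng.uniform(0, 0.3)
            gt[miss, j] = -1
        table = _table(gt)
        retained, _ = variant_qc(table, call_rate_min=0.8, hwe_min_p=1e-6,
                                 maf_max=0.05)
        oracle = []
        for j in range(m):
            col = gt[:, j]
            called = col[col >= 0]
            if len(called) / n < 0.8:
                continue
            n0 = int((called == 0).sum())
            n1 = int((called == 1).sum())
            n2 = int((called == 2).sum())
            if hwe_oracle(n0, n1, n2) < 1e-6:
                continue
            af = called.sum() / (2 * len(called))
            if min(af, 1 - af) >= 0.05:
                continue
            oracle.append(j)
        assert retained == oracle


class TestPiHat:
    @staticmethod
    def _cohort_with_pair(seed, relationship, n_sites=1000, n_extra=60):
        rng = np.random.default_rng(seed)
        q = rng.uniform(0.1, 0.5, n_sites)
        extras = rng.binomial(2, q, size=(n_extra, n_sites))
        a = rng.binomial(2, q, size=n_sites)
        if relationship == "self":
            b = a.copy()
        elif relationship == "unrelated":
            b = rng.binomial(2, q, size=n_sites)
        elif relationship == "parent_offspring":
            other = rng.binomial(2, q, size=n_sites)
            trans_a = np.where(a == 2, 1, np.where(a == 0, 0, rng.integers(0, 2, n_sites)))
            trans_o = np.where(other == 2, 1, np.where(other == 0, 0,
                                                       rng.integers(0, 2, n_sites)))
            b = trans_a + trans_o
        gt = np.vstack([a, b, extras]).astype(np.int8)
        return _table(gt)

    @pytest.mark.parametrize(
        "relationship,expected",
        [("self", 1.0), ("unrelated", 0.0), ("parent_offspring", 0.5)],
    )
    def test_known_relationships(self, relationship, expected):
        table = self._cohort_with_pair(31, relationship)
        pi = ibd_pi_hat(table, ("s0", "s1"))
        assert pi == pytest.approx(expected, abs=0.05)

    def test_few_sites_warns(self):
        table = self._cohort_with_pair(5, "unrelated", n_sites=30)
        with pytest.warns(UserWarning, match="informative"):
            ibd_pi_hat(table, ("s0", "s1"))


class TestPcaOutliers:
    def test_homogeneous_cohort_no_flags(self):
        rng = np.random.default_rng(8)
        q = rng.uniform(0.1, 0.5, 300)
        gt = rng.binomial(2, q, size=(80, 300)).astype(np.int8)
        assert pca_outliers(_table(gt), n_components=2, sigma=6.0) == []

    def test_planted_divergent_sample_flagged(self):
        rng = np.random.default_rng(9)
        q = rng.uniform(0.05, 0.2, 400)
        gt = rng.binomial(2, q, size=(60, 400))
        # one sample drawn from flipped allele frequencies
        gt[0, :] = rng.binomial(2, 1 - q, size=400)
        flagged = pca_outliers(_table(gt.astype(np.int8)), n_components=2, sigma=4.0)
        assert "s0" in flagged

    def test_zero_components_no_flags(self):
        gt = np.zeros((5, 10), dtype=np.int8)
        assert pca_outliers(_table(gt), n_components=0) == []

    def test_too_many_components_rejected(self):
        gt = np.zeros((3, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            pca_outliers(_table(gt), n_components=5)


class TestTrendLambda:
    def test_published_counts_match_closed_form(self):
        """Score test on the case/control genotype marginals of the
        published association hit's first variant: cases 157/4/0 and
        controls 585/1/0 (hom-ref/het/hom-alt)."""
        gt = np.array(
            [[1]] * 4 + [[0]] * 157 + [[1]] * 1 + [[0]] * 585, dtype=np.int8
        )
        labels = np.array([1] * 161 + [0] * 586)
        stat = trend_stat(gt[:, 0], labels)
        # independent closed-form evaluation of the trend score test
        n_g = np.array([742, 5, 0])
        r_g = np.array([157, 4, 0])
        s = np.array([0, 1, 2])
        N, R = n_g.sum(), 161
        u = (s * r_g).sum() - R * (s * n_g).sum() / N
        var = (R / N) * (1 - R / N) * ((s**2 * n_g).sum() - (s * n_g).sum() ** 2 / N)
        assert stat == pytest.approx(u**2 / var, rel=1e-12)

    def test_null_simulation_lambda_near_one(self):
        rng = np.random.default_rng(12)
        n, m = 600, 2000
        q = rng.uniform(0.05, 0.5, m)
        gt = rng.binomial(2, q, size=(n, m)).astype(np.int8)
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: n // 3]] = 1
        _, lam = trend_lambda(_table(gt), labels)
        assert lam == pytest.approx(1.0, abs=0.1)

    def test_single_class_labels_rejected(self):
        gt = np.array([[0], [1]], dtype=np.int8)
        with pytest.raises(ValueError):
            trend_lambda(_table(gt), np.array([1, 1]))

    def test_all_monomorphic_rejected(self):
        gt = np.zeros((10, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            trend_lambda(_table(gt), np.array([0, 1] * 5))


def _null_gene(rng, n, m):
    mafs = rng.uniform(0.002, 0.01, m)
    return rng.binomial(1, mafs, size=(n, m)) + rng.binomial(1, mafs, size=(n, m))


class TestSkato:
    def test_burden_reduction_matches_independent_score_test(self):
        """rho=1 equals the weighted burden score test computed from first
        principles (collapse, score, variance, 1-df chi-square)."""
        rng = np.random.default_rng(21)
        n, m = 400, 5
        G = _null_gene(rng, n, m)
        y = rng.binomial(1, 0.25, n)
        res = skato(G, y, rho_grid=[1.0])
        mafs = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        b = G @ beta_maf_weights(mafs)
        mu = y.mean()
        z2 = (b @ (y - mu)) ** 2 / (mu * (1 - mu) * ((b - b.mean()) ** 2).sum())
        assert res.p_value == pytest.approx(float(stats.chi2.sf(z2, 1)), abs=1e-6)

    def test_skat_reduction_matches_full_kernel_oracle(self):
        """rho=0 equals direct quadratic-form evaluation on the n x n
        kernel (eigenvalues computed from the projected kernel itself)."""
        rng = np.random.default_rng(22)
        n, m = 60, 4
        G = _null_gene(rng, n, m)
        y = rng.binomial(1, 0.4, n)
        res = skato(G, y, rho_grid=[0.0])
        mafs = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        w = beta_maf_weights(mafs)
        mu = y.mean()
        v = mu * (1 - mu)
        Z = G * w
        q = float(((Z.T @ (y - mu)) ** 2).sum())
        # full-rank route: eigenvalues of P^(1/2) Z Z' P^(1/2) with
        # P = v (I - 11'/n), built explicitly
        P = v * (np.eye(n) - np.ones((n, n)) / n)
        ev, U = np.linalg.eigh(P)
        P_half = U @ np.diag(np.sqrt(np.clip(ev, 0, None))) @ U.T
        K = P_half @ Z @ Z.T @ P_half
        lam = np.linalg.eigvalsh(K)
        lam = lam[lam > 1e-8]
        assert res.p_value == pytest.approx(quadform_sf(q, lam), abs=1e-6)

    def test_invariant_to_variant_and_sample_order(self):
        rng = np.random.default_rng(23)
        n, m = 200, 6
        G = _null_gene(rng, n, m)
        y = rng.binomial(1, 0.3, n)
        base = skato(G, y).p_value
        perm_v = rng.permutation(m)
        perm_s = rng.permutation(n)
        assert skato(G[:, perm_v], y).p_value == pytest.approx(base, rel=1e-8)
        assert skato(G[perm_s][:, :], y[perm_s]).p_value == pytest.approx(base, rel=1e-8)

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            skato(np.zeros((10, 1)), np.array([0, 1] * 5))

    def test_strong_signal_gives_small_p(self):
        rng = np.random.default_rng(24)
        n = 300
        y = np.zeros(n, dtype=int)
        y[:100] = 1
        G = _null_gene(rng, n, 4)
        G[:12, 0] = 1  # 12 case-exclusive carriers
        G[:10, 1] = 1
        assert skato(G, y).p_value < 1e-4


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_matches_stepup_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        got = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        q = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q, 1)
        assert got == pytest.approx(oracle)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_q_at_least_p_and_rank_monotone(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
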