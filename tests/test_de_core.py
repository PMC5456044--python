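import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as st

from smoketc import de_core
from smoketc.io_formats import CountMatrix, SampleRecord
from tests.conftest import two_group_matrix


def exact_oracle(s1: int, total: int, r1: float, r2: float) -> float:
    """Independent enumeration of the conditional two-sided p-value."""
    x = np.arange(total + 1)
    logp = st.nbinom.logpmf(x, r1, 0.5) + st.nbinom.logpmf(total - x, r2, 0.5)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    return float(prob[prob <= prob[s1] * (1 + 1e-8)].sum())


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal min-over-tail definition, O(m^2)."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank0, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank0, m)]
        q[idx] = min(1.0, min(tail))
    return q


class TestTMM:
    def test_identical_columns(self):
        counts = np.tile(np.array([[5], [10], [100]]), (1, 2))
        cm = CountMatrix(
            ["a", "b", "c"],
            [SampleRecord("s1", "AC", "1d"), SampleRecord("s2", "CS", "1d")],
            counts,
        )
        nf = de_core.tmm_factors(cm)
        np.testing.assert_allclose(nf.factors, [1.0, 1.0], atol=1e-12)

    def test_pure_depth_difference(self, rng):
        base = rng.integers(1, 500, size=(300, 1))
        counts = np.hstack([base, 2 * base])
        cm = CountMatrix(
            [f"g{i}" for i in range(300)],
            [SampleRecord("s1", "AC", "1d"), SampleRecord("s2", "CS", "1d")],
            counts,
        )
        nf = de_core.tmm_factors(cm)
        np.testing.assert_allclose(nf.factors, [1.0, 1.0], atol=1e-9)

    def test_geometric_mean_one(self, null_matrix):
        nf = de_core.tmm_factors(null_matrix)
        assert abs(np.exp(np.mean(np.log(nf.factors))) - 1.0) < 1e-8

    def test_inflated_top_genes_shrink_factor(self, rng):
        # one sample's top-5% genes inflated: its TMM factor must fall below
        # the untrimmed-mean-of-M oracle value (robustness of trimming) and
        # below 1
        cm = two_group_matrix(rng, n_genes=2000, n_per_group=2)
        counts = cm.counts.copy()
        top = np.argsort(counts[:, 0])[-100:]
        counts[top, 0] *= 8
        cm2 = CountMatrix(cm.gene_ids, cm.samples, counts)
        nf = de_core.tmm_factors(cm2, ref_index=1)
        lib = counts.sum(axis=0)
        both = (counts[:, 0] > 0) & (counts[:, 1] > 0)
        m = np.log2(
            (counts[both, 0] / lib[0]) / (counts[both, 1] / lib[1])
        )
        untrimmed = 2 ** m.mean()
        assert nf.factors[0] < 1.0
        assert nf.factors[0] / nf.factors[1] < untrimmed

    def test_no_shared_genes_error(self):
        counts = np.array([[5, 0], [0, 7]])
        cm = CountMatrix(
            ["a", "b"],
            [SampleRecord("s1", "AC", "1d"), SampleRecord("s2", "CS", "1d")],
            counts,
        )
        with pytest.raises(ValueError, match="shares no expressed"):
            de_core.tmm_factors(cm)


class TestDispersion:
    def test_poisson_limit(self, rng):
        cm = two_group_matrix(rng, n_genes=2000, phi=0.0)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf)
        assert disp.common_phi < 0.01

    def test_parameter_recovery(self, rng):
        cm = two_group_matrix(rng, n_genes=2000, phi=0.2)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf)
        assert 0.15 <= disp.common_phi <= 0.25

    def test_infinite_prior_df_gives_common(self, rng):
        cm = two_group_matrix(rng, n_genes=300)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf, prior_df=np.inf)
        np.testing.assert_allclose(disp.tagwise_phi, disp.common_phi)

    def test_tagwise_shrinks_toward_common(self, rng):
        cm = two_group_matrix(rng, n_genes=500, phi=0.15)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        weak = de_core.estimate_dispersion(cm, labels, nf, prior_df=2.0)
        strong = de_core.estimate_dispersion(cm, labels, nf, prior_df=100.0)
        spread_weak = np.std(np.log(weak.tagwise_phi))
        spread_strong = np.std(np.log(strong.tagwise_phi))
        assert spread_strong < spread_weak


class TestExactTest:
    def _single_gene_cm(self, row_a, row_b):
        counts = np.array([list(row_a) + list(row_b)])
        samples = [
            SampleRecord(f"a{i}", "AC", "9mo") for i in range(len(row_a))
        ] + [SampleRecord(f"b{i}", "CS", "9mo") for i in range(len(row_b))]
        return CountMatrix(["g"], samples, counts)

    def _unit_nf(self, cm):
        # equal library sizes, no renormalization: counts pass through
        return de_core.NormFactors(
            sample_ids=cm.sample_ids,
            factors=np.ones(len(cm.samples)),
            lib_sizes=np.ones(len(cm.samples)),
        )

    def test_balanced_gene(self):
        cm = self._single_gene_cm([10, 12, 8], [10, 12, 8])
        nf = self._unit_nf(cm)
        disp = de_core.DispersionEstimates(0.1, np.array([0.1]))
        res = de_core.exact_test(
            cm, [s.group for s in cm.samples], ("CS", "AC"), nf, disp
        )
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert res.loc[0, "log2_fc"] == 0.0

    def test_label_swap_antisymmetry(self):
        cm = self._single_gene_cm([10, 12, 8], [40, 38, 44])
        nf = self._unit_nf(cm)
        disp = de_core.DispersionEstimates(0.1, np.array([0.1]))
        labels = [s.group for s in cm.samples]
        r1 = de_core.exact_test(cm, labels, ("CS", "AC"), nf, disp)
        r2 = de_core.exact_test(cm, labels, ("AC", "CS"), nf, disp)
        assert r1.loc[0, "p_value"] == pytest.approx(r2.loc[0, "p_value"], abs=1e-12)
        assert r1.loc[0, "log2_fc"] == pytest.approx(-r2.loc[0, "log2_fc"], abs=1e-12)

    def test_brute_force_oracle_spec_case(self):
        # n=3+3, equalized totals (10,12,8) vs (40,38,44), phi=0.1
        phi = 0.1
        s_ac, s_cs = 10 + 12 + 8, 40 + 38 + 44
        total = s_ac + s_cs
        p_impl = de_core._exact_nb_pvalues(
            np.array([s_cs]), np.array([total]),
            np.array([3 / phi]), np.array([3 / phi]),
        )[0]
        p_orc = exact_oracle(s_cs, total, 3 / phi, 3 / phi)
        assert p_impl == pytest.approx(p_orc, abs=1e-10)

    def test_brute_force_oracle_randomized(self, rng):
        for _ in range(100):
            total = int(rng.integers(1, 201))
            s1 = int(rng.integers(0, total + 1))
            phi = float(rng.choice([0.01, 0.1, 0.5]))
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            p_impl = de_core._exact_nb_pvalues(
                np.array([s1]), np.array([total]),
                np.array([n1 / phi]), np.array([n2 / phi]),
            )[0]
            assert p_impl == pytest.approx(
                exact_oracle(s1, total, n1 / phi, n2 / phi), abs=1e-10
            )

    def test_zero_total_gene(self):
        cm = self._single_gene_cm([0, 0, 0], [0, 0, 0])
        nf = self._unit_nf(cm)
        disp = de_core.DispersionEstimates(0.1, np.array([0.1]))
        res = de_core.exact_test(
            cm, [s.group for s in cm.samples], ("CS", "AC"), nf, disp
        )
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2_fc"] == 0.0

    def test_significant_flag_definition(self, rng):
        cm = two_group_matrix(rng, n_genes=400)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf)
        res = de_core.exact_test(cm, labels, ("CS", "AC"), nf, disp)
        expected = (res["q_value"] <= 0.10) & (
            res["log2_fc"].abs() >= np.log2(1.5)
        )
        assert (res["significant"] == expected).all()


class TestBH:
    def test_closed_form(self):
        np.testing.assert_allclose(
            de_core.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        assert (de_core.bh_adjust([1.0] * 5) == 1.0).all()

    def test_against_literal_oracle(self, rng):
        p = rng.random(1000)
        np.testing.assert_allclose(de_core.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de_core.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_properties(self, pvals):
        q = de_core.bh_adjust(pvals)
        assert ((q >= 0) & (q <= 1)).all()
        # monotone in p-value rank
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestIndependentFilter:
    def _results(self, p):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(p))],
                "log2_fc": np.ones(len(p)),
                "p_value": p,
                "q_value": de_core.bh_adjust(p),
                "significant": False,
            }
        )

    def test_theta_zero_equals_plain_bh(self, rng):
        p = rng.random(500)
        res = self._results(p)
        stat = rng.random(500)
        out, theta = de_core.independent_filter(
            res, stat, fdr=0.10, thetas=np.array([0.0])
        )
        assert theta == 0.0
        np.testing.assert_allclose(out["q_value"], de_core.bh_adjust(p))

    def test_null_few_discoveries(self, rng):
        p = rng.random(2000)
        res = self._results(p)
        stat = rng.random(2000)
        out, _ = de_core.independent_filter(res, stat, fdr=0.10)
        assert (out["q_value"] <= 0.10).sum() <= 0.10 * 2000

    def test_filter_beats_unfiltered_with_planted_structure(self, rng):
        # strong signal among high-expression genes, half the genes near-zero
        n_hi, n_lo = 1000, 1000
        p_hi = np.concatenate([rng.uniform(0, 1e-5, 100), rng.random(n_hi - 100)])
        p_lo = rng.random(n_lo)
        p = np.concatenate([p_hi, p_lo])
        stat = np.concatenate([rng.uniform(10, 100, n_hi), rng.uniform(0, 0.5, n_lo)])
        res = self._results(p)
        plain = (de_core.bh_adjust(p) <= 0.10).sum()
        out, theta = de_core.independent_filter(res, stat, fdr=0.10)
        assert (out["q_value"] <= 0.10).sum() >= plain


class TestCalibrationSmall:
    def test_null_pvalue_fraction(self, rng):
        # small version of the type-I property; full scale in acceptance
        cm = two_group_matrix(rng, n_genes=3000, phi=0.1)
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf)
        res = de_core.exact_test(cm, labels, ("CS", "AC"), nf, disp)
        frac = (res["p_value"] <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_fold_change_recovery(self, rng):
        # planted log2FC = 1: mean estimate within +-0.1 over 500 genes
        n_genes, n = 5000, 5  # planted fraction kept inside the TMM trim window
        mu = np.exp(rng.normal(5, 0.7, n_genes))
        mu_cs = mu.copy()
        mu_cs[:500] *= 2.0
        r = 10.0
        ya = rng.negative_binomial(r, r / (r + mu[:, None]), (n_genes, n))
        yb = rng.negative_binomial(r, r / (r + mu_cs[:, None]), (n_genes, n))
        samples = [SampleRecord(f"a{i}", "AC", "9mo") for i in range(n)] + [
            SampleRecord(f"b{i}", "CS", "9mo") for i in range(n)
        ]
        cm = CountMatrix(
            [f"g{i}" for i in range(n_genes)], samples, np.hstack([ya, yb])
        )
        nf = de_core.tmm_factors(cm)
        labels = [s.group for s in cm.samples]
        disp = de_core.estimate_dispersion(cm, labels, nf)
        res = de_core.exact_test(cm, labels, ("CS", "AC"), nf, disp)
        assert abs(res["log2_fc"][:500].mean() - 1.0) < 0.1
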