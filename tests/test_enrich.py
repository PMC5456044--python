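import numpy as np
import pytest
from scipy import stats as st

from smoketc import de_core, enrich
from smoketc.io_formats import CountMatrix, GeneSetDB, SampleRecord
from tests.conftest import two_group_matrix


def make_cm(counts, n_treat, n_control):
    counts = np.asarray(counts)
    samples = [SampleRecord(f"a{i}", "AC", "9mo") for i in range(n_control)] + [
        SampleRecord(f"c{i}", "CS", "9mo") for i in range(n_treat)
    ]
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])], samples, counts
    )


def unit_nf(cm):
    return de_core.NormFactors(
        sample_ids=cm.sample_ids,
        factors=np.ones(len(cm.samples)),
        lib_sizes=cm.lib_sizes,
    )


class TestGeneLevelStats:
    def test_identical_samples_give_zero(self):
        col = np.array([[10], [20], [30]])
        cm = make_cm(np.hstack([col, col]), 1, 1)
        labels = [s.group for s in cm.samples]
        stats_m = enrich.gene_level_stats(cm, labels, ("CS", "AC"), unit_nf(cm))
        np.testing.assert_allclose(stats_m, 0.0, atol=1e-12)

    def test_depth_invariance(self):
        col = np.array([[10], [20], [30]])
        cm1 = make_cm(np.hstack([col, col]), 1, 1)
        cm2 = make_cm(np.hstack([col, 2 * col]), 1, 1)
        labels = [s.group for s in cm1.samples]
        # same moderation constant so only the depth scaling differs
        c = 8.0 / 60.0
        s1 = enrich.gene_level_stats(cm1, labels, ("CS", "AC"), unit_nf(cm1), c)
        s2 = enrich.gene_level_stats(cm2, labels, ("CS", "AC"), unit_nf(cm2), c)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_two_by_two_hand_computed(self):
        counts = np.array([[8, 12, 30, 50]])  # AC: 8,12; CS: 30,50
        cm = make_cm(counts, 2, 2)
        labels = [s.group for s in cm.samples]
        nf = unit_nf(cm)
        c = 0.001
        stats_m = enrich.gene_level_stats(cm, labels, ("CS", "AC"), nf, c)
        lib = counts[0]
        expect = []
        for i in (2, 3):  # treatment columns
            for j in (0, 1):
                expect.append(
                    np.log2((counts[0, i] / lib[i] + c) / (counts[0, j] / lib[j] + c))
                )
        assert stats_m.shape == (1, 4)
        np.testing.assert_allclose(stats_m[0], expect, atol=1e-12)


class TestSetTest:
    def test_whole_genome_set(self, rng):
        cm = two_group_matrix(rng, n_genes=300)
        labels = [s.group for s in cm.samples]
        stats_m = enrich.gene_level_stats(
            cm, labels, ("CS", "AC"), de_core.tmm_factors(cm)
        )
        stat, p = enrich.set_test(stats_m, np.arange(300), "up", 5, 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_null_calibration_small(self, rng):
        cm = two_group_matrix(rng, n_genes=1500)
        labels = [s.group for s in cm.samples]
        stats_m = enrich.gene_level_stats(
            cm, labels, ("CS", "AC"), de_core.tmm_factors(cm)
        )
        ps = [
            enrich.set_test(stats_m, rng.choice(1500, 20, replace=False), "up", 5, 5)[1]
            for _ in range(300)
        ]
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_monotone_in_planted_effect(self, rng):
        # increasing a planted set effect never increases its one-sided p
        seed_counts = two_group_matrix(rng, n_genes=800).counts
        labels = ["AC"] * 5 + ["CS"] * 5
        previous_p = 1.1
        for fold in (1.0, 1.5, 2.5, 4.0):
            counts = seed_counts.copy()
            counts[:20, 5:] = np.rint(counts[:20, 5:] * fold).astype(np.int64)
            cm = make_cm(counts, 5, 5)
            stats_m = enrich.gene_level_stats(
                cm, labels, ("CS", "AC"), unit_nf(cm)
            )
            _, p = enrich.set_test(stats_m, np.arange(20), "up", 5, 5)
            assert p <= previous_p + 1e-12
            previous_p = p

    def test_too_small_set_rejected(self, rng):
        stats_m = rng.normal(size=(100, 4))
        with pytest.raises(ValueError):
            enrich.set_test(stats_m, np.array([3]), "up")


class TestCoreGenes:
    def test_planted_strong_gene_recovered(self, rng):
        stats_m = rng.normal(0, 0.3, size=(500, 9))
        stats_m[7, :] += 3 * 0.3  # 3 SD effect
        genes = [f"g{i}" for i in range(500)]
        got = enrich.core_genes(stats_m, genes, np.array([7, 8, 9, 10]), "up")
        assert got == ["g7"]

    def test_null_set_nearly_empty(self, rng):
        stats_m = rng.normal(0, 1, size=(2000, 9))
        genes = [f"g{i}" for i in range(2000)]
        idx = rng.choice(2000, 30, replace=False)
        got = enrich.core_genes(stats_m, genes, idx, "up")
        # expected count = 30 * one-tail mass beyond 1 SD (~16%)
        assert len(got) <= 12

    def test_opposite_sign_never_core(self, rng):
        stats_m = rng.normal(0, 0.3, size=(200, 9))
        stats_m[5, :] = -5.0  # strong but wrong direction
        genes = [f"g{i}" for i in range(200)]
        got = enrich.core_genes(stats_m, genes, np.array([5, 6, 7, 8]), "up")
        assert "g5" not in got


class TestEnrichContrast:
    def _planted(self, rng, lfc=1.0):
        cm = two_group_matrix(rng, n_genes=1000)
        counts = cm.counts.copy()
        counts[:20, 5:] = np.rint(counts[:20, 5:] * 2.0**lfc).astype(np.int64)
        sets = {"planted": [f"g{i:04d}" for i in range(20)]}
        for k in range(20):
            idx = rng.choice(np.arange(20, 1000), 20, replace=False)
            sets[f"null{k}"] = [f"g{i:04d}" for i in idx]
        return CountMatrix(cm.gene_ids, cm.samples, counts), GeneSetDB(sets=sets)

    def test_q_values_are_bh_per_direction(self, rng):
        cm, db = self._planted(rng)
        tab = enrich.enrich_contrast(cm, db, "CS", "AC")
        for direction in ("up", "down"):
            sel = tab["direction"] == direction
            np.testing.assert_allclose(
                tab.loc[sel, "q_value"],
                de_core.bh_adjust(tab.loc[sel, "p_value"].to_numpy()),
            )

    def test_planted_set_detected_up(self, rng):
        cm, db = self._planted(rng)
        tab = enrich.enrich_contrast(cm, db, "CS", "AC")
        row = tab[(tab["set"] == "planted") & (tab["direction"] == "up")].iloc[0]
        assert row["significant"]
        assert row["set_stat"] > 0

    def test_direction_exclusivity_on_coherent_effect(self, rng):
        cm, db = self._planted(rng, lfc=1.5)
        tab = enrich.enrich_contrast(cm, db, "CS", "AC")
        planted = tab[tab["set"] == "planted"].set_index("direction")
        assert planted.loc["up", "significant"]
        assert not planted.loc["down", "significant"]

    def test_small_sets_skipped(self, rng):
        cm = two_group_matrix(rng, n_genes=100)
        db = GeneSetDB(sets={"tiny": ["g0000", "g0001"]})
        tab = enrich.enrich_contrast(cm, db, "CS", "AC")
        assert len(tab) == 0


class TestGrid:
    def test_direction_flip_recorded(self, rng):
        # planted up at one time point and down at another
        from smoketc.io_formats import SampleRecord

        n_genes = 600
        mu = np.exp(rng.normal(4, 1, n_genes))
        r = 10.0

        def draw(mu_vec, n=5):
            return rng.negative_binomial(
                r, r / (r + mu_vec[:, None]), (n_genes, n)
            )

        samples, blocks = [], []
        for t in ("1d", "7d"):
            for grp in ("AC", "CS"):
                m = mu.copy()
                if grp == "CS" and t == "1d":
                    m[:25] *= 4.0
                if grp == "CS" and t == "7d":
                    m[:25] /= 4.0
                blocks.append(draw(m))
                samples += [
                    SampleRecord(f"{grp}_{t}_{i}", grp, t) for i in range(5)
                ]
        cm = CountMatrix(
            [f"g{i:04d}" for i in range(n_genes)], samples, np.hstack(blocks)
        )
        sets = {"flip": [f"g{i:04d}" for i in range(25)]}
        for k in range(10):
            idx = rng.choice(np.arange(25, n_genes), 20, replace=False)
            sets[f"null{k}"] = [f"g{i:04d}" for i in idx]
        tables = enrich.enrich_timepoints(cm, GeneSetDB(sets=sets), ("1d", "7d"))
        grid = enrich.significance_grid(tables)
        assert grid.loc["flip", "1d"] == 1
        assert grid.loc["flip", "7d"] == -1
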