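"""Genotype QC: call-rate filters, HWE exact test, IBS, heterozygosity, PCA."""
import numpy as np
import pytest

from pgxvalidity.qc import (
    call_rate_filter,
    heterozygosity_check,
    hwe_exact_test,
    hwe_filter,
    pairwise_ibs,
    pca,
    sex_mismatch_filter,
)
from pgxvalidity.sim import SimConfig, StratumConfig, default_config, simulate_genotypes
from pgxvalidity.types import MISSING, GenotypeMatrix, SampleRecord, VariantRecord


def _matrix(calls, prefix="v"):
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    variants = [
        VariantRecord(f"{prefix}{j}", "1", 100 + j, "A", "G") for j in range(m)
    ]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, calls)


class TestCallRateFilter:
    def test_complete_matrix_removes_nothing(self):
        m = _matrix(np.ones((4, 5)))
        out, report = call_rate_filter(m, 0.95, 0.95)
        assert out.n_samples == 4 and out.n_variants == 5
        assert not report.removed_samples and not report.removed_variants

    def test_low_call_rate_sample_removed_with_reason(self):
        calls = np.ones((4, 10), dtype=np.int16)
        calls[0, :1] = MISSING  # 90% call rate
        out, report = call_rate_filter(_matrix(calls), 0.95, 0.5)
        assert report.removed_samples == [("s0", "call_rate")]
        assert out.n_samples == 3

    def test_matches_independent_recount(self):
        cfg = default_config(seed=21, missing_rate=0.03, n_background_snps=120)
        matrix, _ = simulate_genotypes(cfg)
        out, report = call_rate_filter(matrix, 0.95, 0.95)
        # brute-force iterative recount of row/column missingness
        miss = matrix.calls == MISSING
        rows = list(range(matrix.n_samples))
        cols = list(range(matrix.n_variants))
        bad_samples, bad_variants = set(), set()
        while True:
            drop_r = [i for i in rows if 1 - miss[i][cols].mean() < 0.95]
            rows = [i for i in rows if i not in drop_r]
            drop_c = [j for j in cols if 1 - miss[rows][:, j].mean() < 0.95]
            cols = [j for j in cols if j not in drop_c]
            bad_samples |= {matrix.sample_ids[i] for i in drop_r}
            bad_variants |= {matrix.variant_ids[j] for j in drop_c}
            if not drop_r and not drop_c:
                break
        assert report.removed_sample_ids() == bad_samples
        assert report.removed_variant_ids() == bad_variants
        assert set(out.sample_ids) == set(matrix.sample_ids) - bad_samples
        assert set(out.variant_ids) == set(matrix.variant_ids) - bad_variants

    def test_idempotent(self):
        cfg = default_config(seed=22, missing_rate=0.05, n_background_snps=60)
        matrix, _ = simulate_genotypes(cfg)
        once, _ = call_rate_filter(matrix, 0.95, 0.95)
        twice, rep2 = call_rate_filter(once, 0.95, 0.95)
        assert twice.sample_ids == once.sample_ids
        assert twice.variant_ids == once.variant_ids
        assert not rep2.removed_samples and not rep2.removed_variants

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_rate_filter(_matrix(np.empty((0, 0))), 0.95, 0.95)


class TestHweExactTest:
    def test_modal_small_table(self):
        # full enumeration over het in {0,2,4}: weights 6/70, 48/70, 16/70
        assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 25) == 1.0

    def test_against_enumeration_value(self):
        # independent rational-arithmetic enumeration for (57, 34, 9)
        from fractions import Fraction
        from math import comb

        n, het_obs = 100, 34
        r = 2 * 9 + 34
        weights = {}
        for h in range(r % 2, min(r, 2 * n - r) + 1, 2):
            n_rare = (r - h) // 2
            n_comm = n - h - n_rare
            if n_comm < 0:
                continue
            weights[h] = Fraction(comb(n, n_rare) * comb(n - n_rare, h) * 2**h)
        total = sum(weights.values())
        expected = float(
            sum(w for w in weights.values() if w <= weights[het_obs]) / total
        )
        assert hwe_exact_test(57, 34, 9) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestHweFilter:
    def _samples(self, matrix, ethnicity="Chinese"):
        return [
            SampleRecord(s, "M", ethnicity, "control", 0, 50.0)
            for s in matrix.sample_ids
        ]

    def test_hw_proportions_retained(self):
        # 25/50/25 at MAF 0.5 is the modal configuration
        calls = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        m = _matrix(calls[:, None])
        out, _ = hwe_filter(m, self._samples(m), "Chinese", alpha=1e-6)
        assert out.n_variants == 1

    def test_all_heterozygote_variant_removed(self):
        m = _matrix(np.ones((40, 1)))
        out, report = hwe_filter(m, self._samples(m), "Chinese", alpha=1e-6)
        assert out.n_variants == 0
        assert report.removed_variants == [("v0", "hwe")]

    def test_alpha_one_keeps_monomorphic(self):
        calls = np.column_stack([np.zeros(30), np.ones(30)])
        m = _matrix(calls)
        out, _ = hwe_filter(m, self._samples(m), "Chinese", alpha=1.0)
        assert out.variant_ids == ["v0"]  # p = 1 boundary retained

    def test_unknown_stratum_errors(self):
        m = _matrix(np.ones((5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            hwe_filter(m, self._samples(m, "Chinese"), "Klingon")


class TestPairwiseIbs:
    def test_duplicate_sample_flagged(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]])
        table, report = pairwise_ibs(_matrix(calls), threshold=0.9)
        row = table[(table.sample_i == "s0") & (table.sample_j == "s1")]
        assert row.ibs.iloc[0] == 1.0
        assert ("s0", "s1", 1.0) in report.flagged_pairs

    def test_opposite_homozygotes_score_zero(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]])
        table, _ = pairwise_ibs(_matrix(calls))
        assert table.ibs.iloc[0] == 0.0

    def test_matches_per_site_recount(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(2, 200)).astype(np.int16)
        calls[0, :10] = MISSING
        table, _ = pairwise_ibs(_matrix(calls))
        a, b = calls[0].astype(float), calls[1].astype(float)
        vals = [(2 - abs(x - y)) / 2 for x, y in zip(a, b)
                if x != MISSING and y != MISSING]
        assert table.ibs.iloc[0] == pytest.approx(np.mean(vals))
        assert table.n_shared.iloc[0] == len(vals)

    def test_no_shared_calls_is_undefined(self):
        calls = np.array([[0, MISSING], [MISSING, 1]])
        table, report = pairwise_ibs(_matrix(calls))
        assert np.isnan(table.ibs.iloc[0])
        assert not report.flagged_pairs


class TestHeterozygosity:
    def test_identical_samples_unflagged(self):
        rates, report = heterozygosity_check(_matrix(np.ones((5, 10))))
        assert not report.flagged_het_samples

    def test_all_het_outlier_flagged(self):
        calls = np.zeros((20, 30), dtype=np.int16)
        calls[:, 0] = 1          # everyone slightly heterozygous
        calls[0, :] = 1          # one fully heterozygous sample
        _, report = heterozygosity_check(_matrix(calls), sd_multiplier=3)
        assert report.flagged_het_samples == ["s0"]

    def test_matches_independent_mean_sd(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(30, 80)).astype(np.int16)
        rates, report = heterozygosity_check(_matrix(calls), sd_multiplier=2)
        het = [(row == 1).mean() for row in calls]
        mu = sum(het) / len(het)
        sd = (sum((h - mu) ** 2 for h in het) / (len(het) - 1)) ** 0.5
        expect = {f"s{i}" for i, h in enumerate(het) if abs(h - mu) > 2 * sd}
        assert set(report.flagged_het_samples) == expect


def test_sex_mismatch_filter_removes_injected_ids():
    m = _matrix(np.ones((4, 3)))
    out, report = sex_mismatch_filter(m, ["s2"])
    assert out.sample_ids == ["s0", "s1", "s3"]
    assert report.removed_samples == [("s2", "sex_mismatch")]


class TestPca:
    @staticmethod
    def _two_pop_matrix(seed=0, divergence=2.5, n=60, m=150):
        cfg = SimConfig(
            strata=(
                StratumConfig("A", 0, n, {"NAT2*4": 1.0},
                              background_divergence=divergence),
                StratumConfig("B", 0, n, {"NAT2*4": 1.0},
                              background_divergence=divergence),
            ),
            n_background_snps=m,
            seed=seed,
        )
        return simulate_genotypes(cfg)

    def test_pc1_separates_divergent_strata(self):
        matrix, truth = self._two_pop_matrix()
        res = pca(matrix, n_components=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        labels = truth.stratum == "A"
        # best threshold classifier on PC1
        acc = max(
            max(((pc1 > t) == labels).mean(), ((pc1 <= t) == labels).mean())
            for t in pc1
        )
        assert acc >= 0.95

    def test_spectrum_is_nonnegative_and_sorted(self):
        matrix, _ = self._two_pop_matrix(seed=3)
        res = pca(matrix, n_components=6)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_variant_order_permutation_invariance(self):
        matrix, _ = self._two_pop_matrix(seed=5, n=25, m=60)
        res1 = pca(matrix, n_components=3)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(matrix.variant_ids))
        res2 = pca(matrix.subset(variants=perm), n_components=3)
        for k in range(3):
            c1 = res1.coordinates.iloc[:, k]
            c2 = res2.coordinates.iloc[:, k]
            assert abs(np.corrcoef(c1, c2)[0, 1]) > 1 - 1e-9

    def test_sample_duplication_preserves_directions(self):
        matrix, _ = self._two_pop_matrix(seed=7, n=20, m=50)
        dup = GenotypeMatrix(
            matrix.sample_ids + [s + "_dup" for s in matrix.sample_ids],
            matrix.variants,
            np.vstack([matrix.calls, matrix.calls]),
        )
        r1 = pca(matrix, n_components=2)
        r2 = pca(dup, n_components=2)
        half = r2.coordinates.iloc[: matrix.n_samples]
        for k in range(2):
            corr = np.corrcoef(r1.coordinates.iloc[:, k], half.iloc[:, k])[0, 1]
            assert abs(corr) > 1 - 1e-6

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pca(_matrix(np.ones((5, 4))), n_components=2)
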