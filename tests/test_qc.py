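import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epilipid.qc import (
    apply_report,
    compute_pcs,
    estimate_ibd_pihat,
    hwe_exact_test,
    hwe_filter,
    maf_filter,
    remove_related,
    run_qc,
    sample_call_rate_filter,
    snp_call_rate_filter,
)
from epilipid.genotypes import GenotypeMatrix, snp_meta_frame
from .conftest import make_genotypes
from .oracles import hwe_exact_oracle, min_vertex_cover_size


def with_missing(d, rows, col):
    d = np.asarray(d, dtype=float).copy()
    d[rows, col] = np.nan
    return d


class TestCallRateFilters:
    def test_snp_boundaries(self, rng):
        d = rng.binomial(2, 0.3, (100, 3)).astype(float)
        d = with_missing(d, range(4), 1)   # 96/100 calls: retained
        d = with_missing(d, range(6), 2)   # 94/100 calls: removed
        G = make_genotypes(d)
        out, removed = snp_call_rate_filter(G, 0.95)
        assert removed == ["snp003"]
        assert list(out.snp_ids) == ["snp001", "snp002"]

    def test_complete_matrix_no_removals(self, small_genotypes):
        out, removed = snp_call_rate_filter(small_genotypes, 0.95)
        assert removed == [] and out.n_snps == small_genotypes.n_snps

    def test_sample_boundaries(self, rng):
        d = rng.binomial(2, 0.3, (3, 100)).astype(float)
        d[1, :11] = np.nan  # 89% calls: removed
        d[2, :9] = np.nan   # 91% calls: retained
        G = make_genotypes(d)
        out, removed = sample_call_rate_filter(G, 0.90)
        assert removed == ["S0002"]
        assert list(out.sample_ids) == ["S0001", "S0003"]

    def test_empty_matrix_raises(self):
        G = make_genotypes(np.empty((0, 0)))
        with pytest.raises(ValueError):
            snp_call_rate_filter(G)

    def test_idempotence(self, rng):
        d = rng.binomial(2, 0.3, (50, 10)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        G = make_genotypes(d)
        once, _ = snp_call_rate_filter(G, 0.95)
        twice, removed2 = snp_call_rate_filter(once, 0.95)
        assert removed2 == [] and twice.equals(once)


class TestMAFFilter:
    def test_boundary_inclusive(self):
        d = np.zeros((100, 1))
        d[:10, 0] = 1.0  # f = 0.05 exactly
        out, removed = maf_filter(make_genotypes(d), 0.05)
        assert removed == []

    def test_folding_high_frequency(self):
        d = np.full((100, 1), 2.0)
        d[:8, 0] = 1.0  # f = 0.96, MAF 0.04
        out, removed = maf_filter(make_genotypes(d), 0.05)
        assert removed == ["snp001"]

    def test_zero_threshold_keeps_all(self, small_genotypes):
        out, removed = maf_filter(small_genotypes, 0.0)
        assert removed == []

    def test_all_missing_snp_removed_with_warning(self, caplog):
        d = np.column_stack([np.full(20, np.nan), np.ones(20)])
        with caplog.at_level("WARNING"):
            out, removed = maf_filter(make_genotypes(d), 0.0)
        assert removed == ["snp001"] and "zero non-missing" in caplog.text


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 57) == 1.0

    def test_two_minor_alleles_enumeration(self):
        # 2 minor alleles in 2 individuals: het counts {0, 2} possible
        assert hwe_exact_test(0, 2, 0) == pytest.approx(
            hwe_exact_oracle(0, 2, 0), abs=1e-12
        )
        assert hwe_exact_test(1, 0, 1) == pytest.approx(
            hwe_exact_oracle(1, 0, 1), abs=1e-12
        )

    @given(
        counts=st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        ).filter(lambda c: 0 < sum(c) <= 50)
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), abs=1e-12
        )

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_filter_removes_extreme_disequilibrium(self, rng):
        hwe_ok = rng.binomial(2, 0.3, (500, 1)).astype(float)
        # all-heterozygote SNP: grossly out of equilibrium
        bad = np.ones((500, 1))
        G = make_genotypes(np.hstack([hwe_ok, bad]))
        out, removed = hwe_filter(G, 1e-7)
        assert removed == ["snp002"]


@pytest.fixture(scope="module")
def unrelated():
    rng = np.random.default_rng(99)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 1000), (40, 1000)).astype(float)
    return make_genotypes(d)


class TestPiHat:
    def test_duplicate_pair_near_one(self, unrelated):
        d = unrelated.dosages.copy()
        d[1] = d[0]
        G = make_genotypes(d)
        tab = estimate_ibd_pihat(G)
        dup = tab[(tab.sample_1 == "S0001") & (tab.sample_2 == "S0002")]
        assert float(dup.pihat.iloc[0]) >= 0.95

    def test_unrelated_mean_near_zero(self, unrelated):
        tab = estimate_ibd_pihat(unrelated)
        assert abs(tab.pihat_raw.mean()) < 0.02
        first = tab.iloc[0]
        assert -0.1 < first.pihat_raw < 0.1

    def test_clamped_to_unit_interval(self, unrelated):
        tab = estimate_ibd_pihat(unrelated)
        assert ((tab.pihat >= 0) & (tab.pihat <= 1)).all()

    def test_few_snps_warns(self, caplog, rng):
        d = rng.binomial(2, 0.3, (5, 10)).astype(float)
        with caplog.at_level("WARNING"):
            estimate_ibd_pihat(make_genotypes(d))
        assert "unstable" in caplog.text


class TestRemoveRelated:
    def make_table(self, pairs, ids):
        import pandas as pd

        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                p = 0.9 if (ids[i], ids[j]) in pairs else 0.0
                rows.append((ids[i], ids[j], p, p, 100))
        return pd.DataFrame(
            rows, columns=["sample_1", "sample_2", "pihat_raw", "pihat", "n_snps"]
        )

    def test_duplicate_pair_removes_exactly_one(self, rng):
        ids = ["S0001", "S0002", "S0003"]
        G = make_genotypes(rng.binomial(2, 0.3, (3, 20)).astype(float))
        tab = self.make_table({("S0001", "S0002")}, ids)
        out, removed = remove_related(G, tab, 0.3)
        assert len(removed) == 1 and out.n_samples == 2

    def test_no_pairs_no_removals(self, rng):
        G = make_genotypes(rng.binomial(2, 0.3, (3, 20)).astype(float))
        tab = self.make_table(set(), ["S0001", "S0002", "S0003"])
        out, removed = remove_related(G, tab, 0.3)
        assert removed == []

    def test_triangle_matches_minimal_vertex_cover(self, rng):
        ids = [f"S{i + 1:04d}" for i in range(4)]
        edges = {("S0001", "S0002"), ("S0001", "S0003"), ("S0002", "S0003")}
        G = make_genotypes(rng.binomial(2, 0.3, (4, 20)).astype(float))
        tab = self.make_table(edges, ids)
        out, removed = remove_related(G, tab, 0.3)
        assert len(removed) == min_vertex_cover_size(edges) == 2
        assert "S0004" not in removed


class TestPCA:
    def test_orthogonality_and_variance_order(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 60), (80, 60)).astype(float)
        pcs = compute_pcs(make_genotypes(d), k=5)
        S = pcs.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        var = S.var(axis=0)
        assert np.all(np.diff(var) <= 1e-10)

    def test_two_subpopulations_separate_on_pc1(self, rng):
        f1 = rng.uniform(0.1, 0.5, 150)
        f2 = np.clip(f1 + rng.choice([-1.0, 1.0], 150) * 0.25, 0.05, 0.95)
        pop1 = rng.binomial(2, f1, (100, 150)).astype(float)
        pop2 = rng.binomial(2, f2, (100, 150)).astype(float)
        pcs = compute_pcs(make_genotypes(np.vstack([pop1, pop2])), k=2)
        pc1 = pcs["PC1"].to_numpy()
        a, b = pc1[:100], pc1[100:]
        pooled = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 2 * pooled

    def test_k_too_large_raises(self, small_genotypes):
        with pytest.raises(ValueError):
            compute_pcs(small_genotypes, k=6)

    def test_deterministic_sign(self, rng):
        d = rng.binomial(2, 0.3, (50, 20)).astype(float)
        G = make_genotypes(d)
        p1 = compute_pcs(G, k=3)
        p2 = compute_pcs(G.copy(), k=3)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())


class TestPipeline:
    def test_report_replay_is_bit_exact(self, rng):
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 60), (60, 60)).astype(float)
        d[rng.random(d.shape) < 0.03] = np.nan
        d[1] = d[0]  # plant a duplicate pair
        G = make_genotypes(d)
        out, report = run_qc(G, maf=0.05)
        replayed = apply_report(G, report)
        assert replayed.equals(out)

    def test_pipeline_order_recorded(self, rng):
        d = rng.binomial(2, 0.3, (30, 60)).astype(float)
        _, report = run_qc(make_genotypes(d), maf=0.05)
        assert report.steps == [
            "snp_call_rate", "hwe", "sample_call_rate", "relatedness", "maf",
        ]
        assert report.thresholds["hwe_p"] == 1e-7

    def test_relatedness_skipped_on_sparse_panel(self, rng, caplog):
        d = rng.binomial(2, 0.3, (30, 10)).astype(float)
        with caplog.at_level("WARNING"):
            _, report = run_qc(make_genotypes(d))
        assert "relatedness_skipped" in report.steps
        assert "skipped" in caplog.text

    def test_duplicate_sample_removed_by_pipeline(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 200), (30, 200)).astype(float)
        d[1] = d[0]
        _, report = run_qc(make_genotypes(d))
        assert report.samples_removed_relatedness == 1
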