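import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dysreg.de import (
    NBDifferential,
    bh_adjust,
    compute_log_cpm,
    estimate_size_factors,
    estimate_surrogates,
    filter_low_expressed,
    stratum_contrast,
    summarize_deg,
)
from dysreg.io import CountMatrix, DataError, SampleTable
from dysreg.simulate import SimParams, simulate_experiment


def _cm(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows))
    genes = [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return CountMatrix(genes, samples, rows)


class TestFilterLowExpressed:
    def test_even_n_median_below_threshold_removed(self):
        cm = _cm([[0, 9, 9, 10, 11, 12], [20, 20, 20, 20, 20, 20]])
        kept = filter_low_expressed(cm, 10)
        assert kept.gene_ids == ["g1"]  # median 9.5 < 10 for g0

    def test_boundary_median_exactly_ten_kept(self):
        cm = _cm([[10] * 6])
        assert filter_low_expressed(cm, 10).n_genes == 1

    def test_all_zero_gene_removed(self):
        cm = _cm([[0, 0, 0], [15, 15, 15]])
        assert filter_low_expressed(cm, 10).gene_ids == ["g1"]

    def test_everything_filtered_raises(self):
        with pytest.raises(DataError, match="threshold"):
            filter_low_expressed(_cm([[1, 1, 1]]), 10)

    def test_matches_brute_force_median_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_genes = int(rng.integers(1, 8))
            n_samples = int(rng.integers(1, 9))
            counts = rng.integers(0, 25, size=(n_genes, n_samples))
            cm = _cm(counts)
            # brute force: sort each row, average the central order statistics
            expect = []
            for i, row in enumerate(counts):
                srt = sorted(row)
                m = len(srt)
                med = (
                    srt[m // 2]
                    if m % 2
                    else (srt[m // 2 - 1] + srt[m // 2]) / 2
                )
                if med >= 10:
                    expect.append(f"g{i}")
            if not expect:
                with pytest.raises(DataError):
                    filter_low_expressed(cm, 10)
            else:
                assert filter_low_expressed(cm, 10).gene_ids == expect


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        cm = _cm([[10, 20], [30, 60], [7, 14]])
        sf = estimate_size_factors(cm)["size_factor"].to_numpy()
        assert sf == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], abs=1e-12)

    def test_identical_samples_unit_factors(self):
        cm = _cm([[5, 5, 5], [9, 9, 9]])
        sf = estimate_size_factors(cm)["size_factor"].to_numpy()
        assert sf == pytest.approx([1, 1, 1], abs=1e-12)

    def test_single_sample_unit_factor(self):
        sf = estimate_size_factors(_cm([[4], [9]]))["size_factor"].to_numpy()
        assert sf == pytest.approx([1.0])

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        cm = _cm(rng.integers(1, 200, size=(50, 8)))
        sf = estimate_size_factors(cm)["size_factor"].to_numpy()
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 200, size=(60, 4))
        sf1 = estimate_size_factors(_cm(counts))["size_factor"].to_numpy()
        scaled = counts.copy()
        scaled[:, 2] *= 3
        sf2 = estimate_size_factors(_cm(scaled))["size_factor"].to_numpy()
        ratios = sf2 / sf1
        assert ratios[2] / ratios[0] == pytest.approx(3.0, rel=1e-9)

    def test_no_all_positive_gene_raises(self):
        with pytest.raises(DataError):
            estimate_size_factors(_cm([[0, 5], [5, 0]]))


class TestLogCpm:
    def test_arithmetic(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1000
        counts[1, 0] = 10**6 - 1000
        expr = compute_log_cpm(_cm(counts))
        assert expr.values[0, 0] == pytest.approx(np.log2(1001), abs=1e-9)

    def test_zero_count_is_zero_at_default_pseudocount(self):
        expr = compute_log_cpm(_cm([[0, 5], [10, 5]]))
        assert expr.values[0, 0] == 0.0

    def test_scale_invariance_per_sample(self):
        counts = np.array([[3, 7], [11, 2], [6, 6]])
        doubled = counts.copy()
        doubled[:, 1] *= 2
        e1 = compute_log_cpm(_cm(counts))
        e2 = compute_log_cpm(_cm(doubled))
        assert np.allclose(e1.values[:, 1], e2.values[:, 1])


class TestBHAdjust:
    def test_worked_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.3])) == pytest.approx([0.3])

    def test_matches_brute_force_on_random_vectors(self):
        def brute(p):
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            out = np.empty(m)
            for rank_pos, i in enumerate(order):
                # step-up: min over j >= rank of p_(j) * m / (j+1)
                out[i] = min(
                    min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
                )
            return out

        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = int(rng.integers(1, 13))
            p = np.round(rng.random(m), 2)  # coarse grid forces ties
            assert np.allclose(bh_adjust(p), brute(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_nan_excluded_from_denominator(self):
        p = np.array([0.01, np.nan, 0.02])
        out = bh_adjust(p)
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust(np.array([0.01, 0.02])))

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_rank_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= p - 1e-12)  # padj >= p
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.5]))


class TestSurrogates:
    def test_batch_recovery(self):
        params = SimParams(n_genes=1000, frac_de=0.0, n_batches=2, batch_sd=0.5, seed=2)
        counts, samples, truth = simulate_experiment(params)
        filtered = filter_low_expressed(counts)
        sv = estimate_surrogates(filtered, samples, ["genotype"], 1)
        r = np.corrcoef(sv["SV1"], truth.batch)[0, 1]
        assert abs(r) >= 0.9

    def test_no_batch_sv_barely_moves_estimates(self):
        params = SimParams(n_genes=800, frac_de=0.1, seed=3)
        counts, samples, _ = simulate_experiment(params)
        filtered = filter_low_expressed(counts)
        plain = NBDifferential(filtered, samples, contrast="genotype").fit()
        sv = estimate_surrogates(filtered, samples, ["genotype"], 1)
        adj = NBDifferential(
            filtered, samples, contrast="genotype", covariates=sv
        ).fit()
        diff = np.abs(plain.table["log2fc"] - adj.table["log2fc"])
        assert np.nanmedian(diff) < 0.05

    def test_k_zero_empty(self):
        params = SimParams(n_genes=100, set_size=20, seed=1)
        counts, samples, _ = simulate_experiment(params)
        sv = estimate_surrogates(counts, samples, ["genotype"], 0)
        assert list(sv.columns) == ["sample_id"]

    def test_k_too_large_rejected(self):
        params = SimParams(n_genes=100, set_size=20, n_per_group=2, seed=1)
        counts, samples, _ = simulate_experiment(params)
        with pytest.raises(DataError):
            estimate_surrogates(counts, samples, ["genotype"], 3)

    def test_surrogate_columns_centered_unit_norm(self):
        params = SimParams(n_genes=300, seed=4)
        counts, samples, _ = simulate_experiment(params)
        sv = estimate_surrogates(counts, samples, ["genotype"], 2)
        for col in ("SV1", "SV2"):
            v = sv[col].to_numpy()
            assert abs(v.mean()) < 1e-10
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)


class TestNBWald:
    def test_constant_contrast_rejected(self):
        cm = _cm([[10, 12, 9, 11]])
        samples = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": cm.sample_ids,
                    "genotype": ["WT"] * 4,
                    "treatment": ["VEHICLE"] * 4,
                }
            )
        )
        with pytest.raises(DataError, match="rank"):
            NBDifferential(cm, samples, contrast="genotype")

    def test_wald_stat_is_lfc_over_se(self, small_experiment):
        _, counts, samples, _ = small_experiment
        filtered = filter_low_expressed(counts)
        table = NBDifferential(filtered, samples, contrast="genotype").fit().table
        ok = table["p"].notna()
        assert np.allclose(
            table.loc[ok, "wald_stat"],
            table.loc[ok, "log2fc"] / table.loc[ok, "se"],
            atol=1e-9,
        )

    def test_effect_recovery_single_condition(self):
        """Estimated log2fc lands in [0.5, 1.5] for the vast majority of
        genes planted at log2fc = 1, mean 100, 6 vs 6."""
        params = SimParams(
            n_genes=2000,
            frac_de=0.25,
            set_de_enrichment=1.0,
            lfc_mean=1.0,
            baseline_log_sd=0.0,
            seed=8,
        )
        counts, samples, truth = simulate_experiment(params)
        filtered = filter_low_expressed(counts, 1)
        table = NBDifferential(filtered, samples, contrast="genotype").fit().table
        truth_lfc = dict(zip(truth.gene_ids, truth.true_lfc["genotype"]))
        est = table.set_index("gene_id")["log2fc"]
        ratios = [est[g] / truth_lfc[g] for g in est.index if truth_lfc[g] != 0]
        assert len(ratios) >= 400  # ~500 planted replicates of the effect
        assert np.mean([0.5 <= r <= 1.5 for r in ratios]) >= 0.95

    def test_matches_statsmodels_glm_oracle(self, small_experiment):
        """Coefficients and standard errors agree with statsmodels' NB GLM
        at the same fixed dispersions (independent IRLS implementation)."""
        import statsmodels.api as sm

        _, counts, samples, _ = small_experiment
        filtered = filter_low_expressed(counts)
        model = NBDifferential(filtered, samples, contrast="genotype")
        res = model.fit()
        sf = res.size_factors["size_factor"].to_numpy()
        alpha, _ = model._dispersions(sf)
        X = model.exog
        offset = np.log(sf)
        rng = np.random.default_rng(0)
        pick = rng.choice(filtered.n_genes, size=25, replace=False)
        for g in pick:
            if res.table["p"].iloc[g] != res.table["p"].iloc[g]:
                continue
            ref = sm.GLM(
                filtered.counts[g],
                X,
                family=sm.families.NegativeBinomial(alpha=alpha[g]),
                offset=offset,
            ).fit()
            assert res.table["log2fc"].iloc[g] == pytest.approx(
                ref.params[1] / np.log(2), abs=1e-6
            )
            assert res.table["se"].iloc[g] == pytest.approx(
                ref.bse[1] / np.log(2), rel=1e-4
            )

    def test_matches_pydeseq2_fold_changes(self):
        """Independent whole-pipeline cross-check: MLE log2 fold-changes
        track DESeq2's (pydeseq2) on the same counts."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        params = SimParams(
            n_genes=300,
            frac_de=0.2,
            set_size=50,
            lfc_mean=1.0,
            baseline_log_sd=0.5,
            seed=3,
        )
        counts, samples, _ = simulate_experiment(params)
        filtered = filter_low_expressed(counts)
        mine = (
            NBDifferential(filtered, samples, contrast="genotype")
            .fit()
            .table.set_index("gene_id")
        )
        meta = pd.DataFrame(
            {"genotype": samples.aligned(filtered.sample_ids)["genotype"].values},
            index=filtered.sample_ids,
        )
        dds = DeseqDataSet(
            counts=filtered.to_frame().T, metadata=meta, design="~genotype", quiet=True
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["genotype", "HET", "WT"], quiet=True)
        stat.summary()
        merged = mine.join(stat.results_df[["log2FoldChange"]], how="inner").dropna()
        r = np.corrcoef(merged["log2fc"], merged["log2FoldChange"])[0, 1]
        assert r > 0.99
        assert np.median(np.abs(merged["log2fc"] - merged["log2FoldChange"])) < 0.05


class TestSummarize:
    def test_hand_count(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "padj": [0.05, 0.09, 0.2],
                "log2fc": [1.2, -0.3, 2.0],
            }
        )
        s = summarize_deg(table, fdr=0.1, abs_fc=2)
        assert (s["n_deg"], s["n_up"], s["n_down"], s["n_abs_fc"]) == (2, 1, 1, 1)

    def test_empty_significant_set(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "padj": [0.9], "log2fc": [1.0]}
        )
        s = summarize_deg(table)
        assert s["n_deg"] == s["n_up"] == s["n_down"] == s["n_abs_fc"] == 0

    def test_up_down_partition(self, small_experiment):
        _, counts, samples, _ = small_experiment
        filtered = filter_low_expressed(counts)
        table = NBDifferential(filtered, samples, contrast="genotype").fit().table
        s = summarize_deg(table)
        assert s["n_up"] + s["n_down"] == s["n_deg"]


class TestStratumContrast:
    def test_genotype_stratum_keeps_vehicle_only(self):
        from dysreg.simulate import DRUG_GROUPS

        params = SimParams(n_genes=50, set_size=10, groups=DRUG_GROUPS, seed=0)
        counts, samples, _ = simulate_experiment(params)
        sub_counts, sub_samples = stratum_contrast(counts, samples, "genotype")
        assert set(sub_samples.frame["treatment"]) == {"VEHICLE"}

    def test_treatment_stratum_keeps_het_only(self):
        from dysreg.simulate import DRUG_GROUPS

        params = SimParams(n_genes=50, set_size=10, groups=DRUG_GROUPS, seed=0)
        counts, samples, _ = simulate_experiment(params)
        sub_counts, sub_samples = stratum_contrast(counts, samples, "treatment")
        assert set(sub_samples.frame["genotype"]) == {"HET"}
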