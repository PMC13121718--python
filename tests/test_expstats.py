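"""CPM/TPM normalization, export ratios, detection, CV, overlap, spike-in."""

import numpy as np
import pandas as pd
import pytest

from ntve.expstats import (
    SpikeInConfig,
    cpm_normalize,
    cv_per_gene,
    detection_overlap,
    detection_rate_by_quantile,
    export_ratio_distribution,
    filter_samples_by_reads,
    length_binned_spearman,
    renormalize_tpm,
    spikein_absolute_rna,
    tpm_from_counts,
)
from ntve.io import CountMatrix


def cm(values, meta=None, unit="counts"):
    return CountMatrix(pd.DataFrame(values), meta, unit)


def paired_cm(sn_cols, lys_cols):
    values = {}
    meta_rows = []
    for i, col in enumerate(sn_cols, 1):
        values[f"sn{i}"] = col
        meta_rows.append({"sample_id": f"sn{i}", "compartment": "supernatant", "replicate": i})
    for i, col in enumerate(lys_cols, 1):
        values[f"lys{i}"] = col
        meta_rows.append({"sample_id": f"lys{i}", "compartment": "lysate", "replicate": i})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(pd.DataFrame(values), meta)


class TestNormalization:
    def test_cpm_arithmetic(self):
        out = cpm_normalize(cm({"s1": [1, 1, 2]}))
        assert np.allclose(out.values["s1"], [250000, 250000, 500000])

    def test_cpm_zero_column_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            cpm_normalize(cm({"s1": [0, 0]}))

    def test_cpm_pseudocount_after_scaling(self):
        out = cpm_normalize(cm({"s1": [1, 1, 2]}), pseudocount=1e-3)
        assert np.allclose(out.values["s1"], np.array([250000, 250000, 500000]) + 1e-3)

    def test_tpm_closed_form(self):
        counts = cm({"s1": [100, 100]})
        lengths = pd.Series({0: 1000, 1: 2000})
        out = tpm_from_counts(counts, lengths)
        assert np.allclose(out.values["s1"], [2e6 / 3, 1e6 / 3])

    def test_tpm_columns_sum_to_million(self, rng):
        counts = cm({f"s{i}": rng.integers(0, 1000, 50) + 1 for i in range(3)})
        lengths = pd.Series(rng.integers(200, 5000, 50), index=counts.feature_ids)
        out = tpm_from_counts(counts, lengths)
        assert np.allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_renormalize_subset_sums_to_million(self, rng):
        counts = cm({"s1": rng.integers(1, 1000, 40)})
        lengths = pd.Series(rng.integers(200, 5000, 40), index=counts.feature_ids)
        tpm = tpm_from_counts(counts, lengths)
        sub = tpm.subset_features(list(tpm.feature_ids[:20]))
        out = renormalize_tpm(sub)
        assert np.allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)


class TestExportRatio:
    def test_identity_matrices_mass_at_zero(self, rng):
        vals = rng.uniform(1, 100, (200, 1))
        m = paired_cm([vals[:, 0]], [vals[:, 0]])
        res = export_ratio_distribution(m, bins=70)
        assert all(np.allclose(r, 0.0) for r in res.log10_ratios)

    def test_low_lysate_genes_excluded(self):
        m = paired_cm([[10.0, 10.0]], [[0.5, 5.0]])
        res = export_ratio_distribution(m, min_lysate=1.0)
        assert res.n_genes_per_pair[0] == 1

    def test_recovers_generator_sd(self):
        from ntve.simulate import SimulationConfig, simulate_paired_counts, simulate_transcriptome

        cfg = SimulationConfig(n_genes=5000, export_log10_ratio_sd=0.5, mito_fraction=0.0,
                               dispersion=0.02, mean_library_size=5e6, seed=9)
        _, ann = simulate_transcriptome(cfg)
        counts, _ = simulate_paired_counts(cfg, ann)
        res = export_ratio_distribution(cpm_normalize(counts), min_lysate=1.0)
        assert 0.45 <= res.pooled_sd <= 0.55

    def test_histogram_count_and_ci(self, rng):
        m = paired_cm([rng.uniform(1, 100, 300) for _ in range(3)], [rng.uniform(1, 100, 300) for _ in range(3)])
        res = export_ratio_distribution(m, bins=70)
        assert res.densities.shape == (3, 70)
        assert (res.ci_low <= res.mean_density + 1e-12).all()


class TestDetectionRate:
    def test_no_dropout_is_100_everywhere(self, rng):
        vals = rng.uniform(2, 100, (500, 3))
        src = cm({f"s{i}": vals[:, i] for i in range(3)})
        out = detection_rate_by_quantile(src, src, n_quantiles=50)
        assert np.allclose(out["detection_rate_pct"], 100.0)

    def test_bottom_half_dropout(self, rng):
        n = 500
        expr = np.sort(rng.uniform(1.5, 100, n))[::-1]  # descending
        src = cm({"s1": expr, "s2": expr, "s3": expr})
        tgt_vals = expr.copy()
        tgt_vals[n // 2 :] = 0.0  # genes ranked below median undetected
        tgt = cm({"s1": tgt_vals, "s2": tgt_vals, "s3": tgt_vals})
        out = detection_rate_by_quantile(src, tgt, n_quantiles=10, direction="desc")
        assert np.allclose(out["detection_rate_pct"].iloc[:5], 100.0)
        assert np.allclose(out["detection_rate_pct"].iloc[5:], 0.0)

    def test_desc_and_asc_are_reverses(self, rng):
        n = 500
        src = cm({f"s{i}": rng.uniform(1.5, 100, n) for i in range(3)})
        tgt = cm({f"s{i}": rng.uniform(0, 10, n) for i in range(3)})
        d = detection_rate_by_quantile(src, tgt, n_quantiles=50, direction="desc")
        a = detection_rate_by_quantile(src, tgt, n_quantiles=50, direction="asc")
        assert np.allclose(d["detection_rate_pct"].to_numpy(), a["detection_rate_pct"].to_numpy()[::-1])


class TestLengthBinnedSpearman:
    def _matched(self, rng, n=120):
        """Replicates are monotone transforms of one abundance vector, so
        every SN x lysate replicate pair is perfectly rank-concordant."""
        base = rng.uniform(2, 1000, n)
        sn = cm({f"s{i}": base * (i + 1) for i in range(3)})
        lys = cm({f"l{i}": base + 10 * i for i in range(3)})
        lengths = pd.Series(rng.integers(200, 4000, n), index=sn.feature_ids)
        return sn, lys, lengths

    def test_identity_rho_one_sd_zero(self, rng):
        sn, lys, lengths = self._matched(rng)
        out = length_binned_spearman(sn, lys, lengths, [0, 2000, 4000])
        populated = out[out["n_transcripts"] >= 3]
        assert np.allclose(populated["mean_rho"], 1.0)
        assert np.allclose(populated["sd_rho"], 0.0)

    def test_nine_pairs_for_triplicates(self, rng):
        """3 SN x 3 lysate replicates -> 9 pairwise correlations per bin,
        so anti-monotone columns give mean rho strictly inside (-1, 1)."""
        n = 60
        base = np.sort(np.arange(1, n + 1, dtype=float))
        sn = cm({"s1": base + 1, "s2": base + 2, "s3": base + 3})
        lys = cm({"l1": base[::-1] + 1, "l2": base[::-1] + 2, "l3": base[::-1] + 3})
        lengths = pd.Series(np.full(n, 1000), index=sn.feature_ids)
        out = length_binned_spearman(sn, lys, lengths, [0, 2000])
        assert out.loc[0, "mean_rho"] == pytest.approx(-1.0)

    def test_small_bin_undefined(self, rng):
        sn, lys, lengths = self._matched(rng, n=4)
        out = length_binned_spearman(sn, lys, lengths, [10_000, 20_000])  # empty bin
        assert np.isnan(out.loc[0, "mean_rho"])


class TestCv:
    def test_identical_replicates_zero(self):
        cv, med = cv_per_gene(cm({"a": [10, 5], "b": [10, 5]}))
        assert np.allclose(cv, 0.0) and med == 0.0

    def test_hand_case(self):
        cv, med = cv_per_gene(cm({"a": [10.0], "b": [20.0]}))
        assert med == pytest.approx(np.sqrt(50.0) / 15.0, abs=1e-9)

    def test_mean_zero_gene_excluded(self):
        cv, _ = cv_per_gene(cm({"a": [0, 10], "b": [0, 10]}))
        assert len(cv) == 1 and not cv.isna().any()


class TestOverlap:
    def test_arithmetic(self):
        out = detection_overlap({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert out == {"both": 2, "only_a": 1, "only_b": 1, "iou_pct": 50.0}

    def test_identical_sets(self):
        assert detection_overlap({"a"}, {"a"})["iou_pct"] == 100.0

    def test_disjoint(self):
        assert detection_overlap({"a"}, {"b"})["iou_pct"] == 0.0


class TestSpikeIn:
    def test_ratio_arithmetic(self):
        counts = pd.Series({"spikein_mGL": 100.0, "g1": 9900.0})
        out = spikein_absolute_rna(counts, SpikeInConfig())
        assert out["sample_rna_pg"] == pytest.approx(99.0)

    def test_fifty_percent_spike_symmetry(self):
        counts = pd.Series({"spikein_mGL": 500.0, "g1": 500.0})
        out = spikein_absolute_rna(counts, SpikeInConfig(spike_mass_pg=2.5))
        assert out["sample_rna_pg"] == pytest.approx(2.5)

    def test_monomers_to_particles(self):
        counts = pd.Series({"spikein_mGL": 100.0, "g1": 900.0})
        out = spikein_absolute_rna(counts, SpikeInConfig(), monomer_count=2.5e6)
        assert out["particle_count"] == pytest.approx(1000.0)

    def test_linear_in_mass_and_ratio(self):
        base = pd.Series({"spikein_mGL": 100.0, "g1": 900.0})
        double_ratio = pd.Series({"spikein_mGL": 100.0, "g1": 1800.0})
        a = spikein_absolute_rna(base, SpikeInConfig(spike_mass_pg=1.0))
        b = spikein_absolute_rna(base, SpikeInConfig(spike_mass_pg=3.0))
        c = spikein_absolute_rna(double_ratio, SpikeInConfig(spike_mass_pg=1.0))
        assert b["sample_rna_pg"] == pytest.approx(3 * a["sample_rna_pg"])
        assert c["sample_molecules"] == pytest.approx(2 * a["sample_molecules"])

    def test_cell_days_rule(self):
        counts = pd.Series({"spikein_mGL": 1.0, "g1": 1.0})
        out = spikein_absolute_rna(counts, SpikeInConfig(divisions_during_culture=2), seeded_cells=10.0)
        assert out["cell_days"] == pytest.approx(70.0)  # 10 * (1 + 2 + 4)

    def test_zero_spike_errors(self):
        with pytest.raises(ValueError, match="spike"):
            spikein_absolute_rna(pd.Series({"spikein_mGL": 0.0, "g1": 5.0}), SpikeInConfig())


class TestSampleFilter:
    def test_boundaries(self):
        m = cm({"low": [99_999.0], "ok": [100_000.0]})
        with pytest.warns(UserWarning, match="low"):
            out = filter_samples_by_reads(m, 1e5)
        assert list(out.sample_ids) == ["ok"]

    def test_empty_result_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_samples_by_reads(cm({"a": [1.0]}), 1e5)
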