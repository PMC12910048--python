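import math

import numpy as np
import pandas as pd
import pytest

from hrclassify.exceptions import (
    DegenerateLibraryError,
    EmptyAfterFilterError,
    ExcessiveMissingnessError,
    MissingStatisticsError,
    UnmappedCellError,
    ZeroVarianceError,
)
from hrclassify.io import CountMatrix
from hrclassify.preprocess import (
    TMMParams,
    apply_standardizer,
    filter_low_expression,
    fit_standardizer,
    log2_cpm,
    pseudobulk_counts,
    remove_excluded_genes,
    subset_with_zero_fill,
    tmm_norm_factors,
)


def _matrix(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes, samples, counts)


class TestRemoveExcludedGenes:
    def _annotation(self):
        return pd.DataFrame(
            {
                "gene_id": ["A", "B", "C", "D"],
                "chromosome": ["8", "Y", "8", "M"],
                "arm": ["8q", "", "8q", ""],
                "band": ["8q24.2", "", "8q11", ""],
                "biotype": ["protein_coding", "protein_coding", "lncRNA", "protein_coding"],
            }
        )

    def test_rules(self):
        m = _matrix(np.ones((4, 2), dtype=int), genes=["A", "B", "C", "D"])
        out, report = remove_excluded_genes(m, self._annotation())
        assert out.gene_ids == ["A"]  # chrY coding, chr8 non-coding, chrM all removed
        assert report["chrM_or_chrY"] == 2
        assert report["non_coding"] == 1

    def test_identity_on_clean_matrix(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["A", "B"],
                "chromosome": ["1", "2"],
                "arm": ["1p", "2q"],
                "band": ["1p36", "2q11"],
                "biotype": ["protein_coding", "protein_coding"],
            }
        )
        m = _matrix([[1, 2], [3, 4]], genes=["A", "B"])
        out, _ = remove_excluded_genes(m, ann)
        assert out.gene_ids == m.gene_ids
        assert np.array_equal(out.counts, m.counts)

    def test_empty_after_filter(self):
        m = _matrix([[1, 2]], genes=["B"])
        with pytest.raises(EmptyAfterFilterError):
            remove_excluded_genes(m, self._annotation())


class TestFilterLowExpression:
    def test_brute_force_rule(self):
        # libraries of 1e6 so counts == CPM; groups {2,2} need ceil(0.7*2)=2 samples
        gene = np.array([12, 11, 0, 0])
        m = _matrix(np.vstack([gene, 10**6 - gene]))
        kept = filter_low_expression(m, (2, 2))
        assert "G0" in kept

    def test_threshold_is_inclusive_on_cpm(self):
        # CPM {9,9,9,9} < 10 -> removed; CPM 10 retained
        base = np.full((1, 4), 10**6, dtype=int)
        m = CountMatrix(
            ["low", "ten", "fill"],
            [f"S{j}" for j in range(4)],
            np.vstack([np.full((1, 4), 9), np.full((1, 4), 10), base - 19]),
        )
        kept = filter_low_expression(m, (2, 2))
        assert "low" not in kept and "ten" in kept

    def test_all_zero_gene_removed(self):
        m = _matrix([[0, 0, 0, 0], [100, 100, 100, 100]])
        kept = filter_low_expression(m, (2, 2))
        assert kept == ["G1"]

    def test_monotone_in_threshold(self, small_cohort):
        counts, _ = small_cohort
        kept_lo = set(filter_low_expression(counts, (40, 40), cpm_threshold=5))
        kept_hi = set(filter_low_expression(counts, (40, 40), cpm_threshold=20))
        assert kept_hi <= kept_lo


def _brute_force_tmm(counts, lib, j, ref_idx, logratio_trim=0.3, abs_expr_trim=0.05):
    """Literal doubly trimmed weighted mean of M-values for sample j vs reference."""
    obs, ref = counts[:, j].astype(float), counts[:, ref_idx].astype(float)
    n_o, n_r = lib[j], lib[ref_idx]
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask], ref[mask]
    m = np.log2((o / n_o) / (r / n_r))
    a = 0.5 * (np.log2(o / n_o) + np.log2(r / n_r))
    v = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    from scipy.stats import rankdata

    lo_l, lo_s = math.floor(n * logratio_trim) + 1, math.floor(n * abs_expr_trim) + 1
    keep = (
        (rankdata(m) >= lo_l)
        & (rankdata(m) <= n + 1 - lo_l)
        & (rankdata(a) >= lo_s)
        & (rankdata(a) <= n + 1 - lo_s)
    )
    w = 1.0 / v[keep]
    return 2.0 ** (np.sum(w * m[keep]) / np.sum(w))


class TestTMM:
    def test_identical_libraries(self):
        col = np.array([10, 20, 30, 40, 500])
        m = _matrix(np.column_stack([col, col]))
        assert tmm_norm_factors(m) == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference(self):
        col = np.array([10, 20, 30, 40, 500])
        m = _matrix(np.column_stack([col, 2 * col]))
        assert tmm_norm_factors(m) == pytest.approx([1.0, 1.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 2000, size=(50, 3))
        m = _matrix(counts)
        lib = m.library_sizes()
        q75 = np.quantile(counts / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(q75 - q75.mean())))
        raw = np.array([_brute_force_tmm(counts, lib, j, ref) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert tmm_norm_factors(m) == pytest.approx(expected, abs=1e-8)

    def test_product_one_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 1000, size=(60, 4))
        m = _matrix(counts)
        f = tmm_norm_factors(m)
        assert np.prod(f) == pytest.approx(1.0)
        perm = [2, 0, 3, 1]
        m2 = CountMatrix(m.gene_ids, [m.sample_ids[i] for i in perm], counts[:, perm])
        assert tmm_norm_factors(m2) == pytest.approx(f[perm])

    def test_all_zero_library_rejected(self):
        m = _matrix([[0, 5], [0, 5]])
        with pytest.raises(DegenerateLibraryError):
            tmm_norm_factors(m)


class TestLog2CPM:
    def test_closed_form_at_zero(self):
        m = _matrix([[0], [999_999]])
        norm = log2_cpm(m, prior_count=0.5)
        # count 0, effective library 10^6 - 1 + 2*0.5 = 10^6: log2(0.5) = -1
        assert norm.values[0, 0] == pytest.approx(-1.0)

    def test_scale_invariance_without_prior(self):
        counts = np.array([[10, 20], [30, 40], [5, 7]])
        a = log2_cpm(_matrix(counts), prior_count=0.0).values
        b = log2_cpm(_matrix(2 * counts), prior_count=0.0).values
        assert a == pytest.approx(b)

    def test_formula_oracle(self, toy_counts):
        norm = log2_cpm(toy_counts, prior_count=0.5)
        lib = toy_counts.library_sizes()
        expected = np.log2((toy_counts.counts + 0.5) / (lib + 1.0) * 1e6)
        assert norm.values == pytest.approx(expected)

    def test_monotone_in_count(self):
        m = _matrix([[0, 0], [10, 10], [100, 100]])
        lib = np.array([1000.0, 1000.0])
        vals = log2_cpm(m.counts, lib).values
        assert (np.diff(vals[:, 0]) > 0).all()


class TestStandardizer:
    def test_mean_sd_from_definition(self):
        norm = log2_cpm(np.array([[16, 64]]), np.array([1e6, 1e6]), prior_count=0.0)
        stats = fit_standardizer(norm)
        assert stats.means[0] == pytest.approx(5.0)
        assert stats.sds[0] == pytest.approx(math.sqrt(2))

    def test_self_standardization_is_unit(self, small_cohort):
        counts, _ = small_cohort
        norm = log2_cpm(counts)
        stats = fit_standardizer(norm)
        z = apply_standardizer(norm, stats).to_numpy()
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_constant_gene_rejected(self):
        norm = log2_cpm(np.array([[5, 5], [1, 9]]), np.array([1e6, 1e6]))
        with pytest.raises(ZeroVarianceError):
            fit_standardizer(norm)

    def test_stored_stats_and_order_invariance(self):
        counts = np.array([[16, 64], [2, 8]])
        lib = np.array([1e6, 1e6])
        norm = log2_cpm(counts, lib, prior_count=0.0)
        stats = fit_standardizer(norm)
        flipped = log2_cpm(
            counts[::-1], lib, prior_count=0.0, gene_ids=list(reversed(norm.gene_ids))
        )
        z = apply_standardizer(flipped, stats)
        z_orig = apply_standardizer(norm, stats)
        assert z.loc["g0"].to_numpy() == pytest.approx(z_orig.loc["g0"].to_numpy())

    def test_missing_statistics_error(self):
        norm = log2_cpm(np.array([[16, 64]]), np.array([1e6, 1e6]))
        stats = fit_standardizer(norm)
        other = log2_cpm(np.array([[1, 2]]), np.array([1e6, 1e6]), gene_ids=["unknown"])
        with pytest.raises(MissingStatisticsError):
            apply_standardizer(other, stats)


class TestSubsetWithZeroFill:
    def test_identity_when_all_present(self, toy_counts):
        subset, missing = subset_with_zero_fill(toy_counts, ["G3", "G1"])
        assert missing == []
        assert subset.gene_ids == ["G3", "G1"]
        assert np.array_equal(subset.counts[0], toy_counts.counts[3])

    def test_missing_genes_zero_filled_and_reported(self, toy_counts):
        with pytest.warns(UserWarning, match="missing"):
            subset, missing = subset_with_zero_fill(toy_counts, ["G0", "ABSENT"])
        assert missing == ["ABSENT"]
        assert (subset.counts[1] == 0).all()

    def test_excessive_missingness_refused(self, toy_counts):
        required = ["G0"] + [f"NOPE{i}" for i in range(9)]
        with pytest.raises(ExcessiveMissingnessError):
            subset_with_zero_fill(toy_counts, required)

    def test_max_missing_fraction_configurable(self, toy_counts):
        required = ["G0"] + [f"NOPE{i}" for i in range(9)]
        with pytest.warns(UserWarning):
            _, missing = subset_with_zero_fill(toy_counts, required, max_missing_fraction=0.95)
        assert len(missing) == 9


class TestPseudobulk:
    def test_single_cell_per_group_identity(self, toy_counts):
        grouping = {s: f"grp_{s}" for s in toy_counts.sample_ids}
        out = pseudobulk_counts(toy_counts, grouping)
        assert np.array_equal(out.counts, toy_counts.counts)

    def test_total_conservation(self, toy_counts):
        grouping = {s: "all" for s in toy_counts.sample_ids}
        out = pseudobulk_counts(toy_counts, grouping)
        assert out.counts.sum() == toy_counts.counts.sum()

    def test_additivity_site_then_patient(self, toy_counts):
        by_site = {"S0": "siteA", "S1": "siteA", "S2": "siteB", "S3": "siteB"}
        sites = pseudobulk_counts(toy_counts, by_site)
        patient_via_sites = pseudobulk_counts(sites, {"siteA": "pt", "siteB": "pt"})
        direct = pseudobulk_counts(toy_counts, {s: "pt" for s in toy_counts.sample_ids})
        assert np.array_equal(patient_via_sites.counts, direct.counts)

    def test_unmapped_cell_rejected(self, toy_counts):
        with pytest.raises(UnmappedCellError):
            pseudobulk_counts(toy_counts, {"S0": "a"})
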