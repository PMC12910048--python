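import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hrclassify.diffexp import (
    ModerationPrior,
    arm_enrichment_test,
    bh_adjust,
    estimate_moderation_prior,
    fit_gene_linear_models,
    moderate_statistics,
    pearson_correlation,
    run_differential_expression,
    select_de_genes,
    voom_transform,
)
from hrclassify.exceptions import (
    DegenerateLabelsError,
    EmptySignatureError,
    UndefinedCorrelationError,
)
from hrclassify.io import CountMatrix


def _counts_from(matrix):
    matrix = np.asarray(matrix)
    return CountMatrix(
        [f"G{i}" for i in range(matrix.shape[0])],
        [f"S{j}" for j in range(matrix.shape[1])],
        matrix,
    )


class TestVoom:
    def test_weights_positive_finite(self, small_cohort):
        counts, truth = small_cohort
        fit = voom_transform(counts, truth.labels)
        assert np.isfinite(fit.weights).all()
        assert (fit.weights > 0).all()

    def test_constant_residual_variance_gives_flat_weights(self):
        # log-normal counts with a constant log-scale SD: the mean-variance
        # trend is flat, so precision weights should barely vary
        rng = np.random.default_rng(2)
        n, g = 40, 1000
        mu = rng.uniform(np.log(2_000), np.log(60_000), size=g)
        vals = np.exp(mu[:, None] + 0.25 * rng.normal(size=(g, n)))
        counts = _counts_from(np.round(vals).astype(int))
        y = np.repeat([0, 1], n // 2)
        fit = voom_transform(counts, y)
        spread = (fit.weights.max() - fit.weights.min()) / fit.weights.mean()
        assert spread < 0.10

    def test_poisson_trend_decreasing_at_low_expression(self):
        rng = np.random.default_rng(3)
        n, g = 40, 1000
        mu = np.exp(rng.uniform(np.log(4), np.log(2_000), size=g))
        counts = _counts_from(rng.poisson(mu[:, None], size=(g, n)))
        y = np.repeat([0, 1], n // 2)
        fit = voom_transform(counts, y)
        # sqrt-SD trend should fall with abundance in the Poisson regime
        lo = fit.trend_y[: len(fit.trend_y) // 4].mean()
        hi = fit.trend_y[len(fit.trend_y) // 2 : 3 * len(fit.trend_y) // 4].mean()
        assert lo > hi

    def test_single_class_rejected(self, toy_counts):
        with pytest.raises(DegenerateLabelsError):
            voom_transform(toy_counts, np.ones(4))


class TestGeneLinearModels:
    def _fit_with_weights(self, y_vals, weights, status):
        from hrclassify.diffexp import VoomFit

        g, n = y_vals.shape
        design = np.column_stack([np.ones(n), status])
        return VoomFit(
            [f"G{i}" for i in range(g)],
            [f"S{j}" for j in range(n)],
            y_vals,
            weights,
            design,
            np.array([0.0, 1.0]),
            np.array([1.0, 1.0]),
        )

    def test_unit_weights_give_group_mean_difference(self):
        status = np.array([0, 0, 1, 1])
        y = np.array([[3.0, 3.0, 5.0, 5.0]])
        fit = self._fit_with_weights(y, np.ones_like(y), status)
        table = fit_gene_linear_models(fit)
        assert table["logFC"].iloc[0] == pytest.approx(2.0)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        status = np.repeat([0, 1], 5)
        y = rng.normal(size=(20, 10))
        w = rng.uniform(0.5, 2.0, size=y.shape)
        t1 = fit_gene_linear_models(self._fit_with_weights(y, w, status))
        t2 = fit_gene_linear_models(self._fit_with_weights(y, 10 * w, status))
        assert t1["logFC"].to_numpy() == pytest.approx(t2["logFC"].to_numpy())
        # the t-statistic divisor s * unscaled_sd is also scale-free
        prod1 = t1["s"].to_numpy() * t1["unscaled_sd"].to_numpy()
        prod2 = t2["s"].to_numpy() * t2["unscaled_sd"].to_numpy()
        assert prod1 == pytest.approx(prod2)

    def test_matches_brute_force_wls(self):
        rng = np.random.default_rng(4)
        status = np.repeat([0, 1], 4)
        y = rng.normal(size=(6, 8))
        w = rng.uniform(0.2, 3.0, size=y.shape)
        table = fit_gene_linear_models(self._fit_with_weights(y, w, status))
        X = np.column_stack([np.ones(8), status])
        for g in range(6):
            sw = np.sqrt(w[g])
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y[g] * sw, rcond=None)
            assert table["logFC"].iloc[g] == pytest.approx(beta[1], abs=1e-10)
            resid = y[g] - X @ beta
            s2 = np.sum(w[g] * resid**2) / (8 - 2)
            assert table["s"].iloc[g] ** 2 == pytest.approx(s2, abs=1e-10)


class TestModeration:
    def _toy_fits(self, seed=0, g=50, equal_var=False):
        rng = np.random.default_rng(seed)
        s = np.full(g, 1.3) if equal_var else rng.uniform(0.5, 2.0, size=g)
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(g)],
                "logFC": rng.normal(size=g),
                "s": s,
                "df_resid": 10.0,
                "unscaled_sd": np.full(g, 0.3),
            }
        )

    def test_d0_zero_is_ordinary_t(self):
        fits = self._toy_fits()
        table, _ = moderate_statistics(fits, ModerationPrior(d0=0.0, s0_sq=1.0))
        expected = fits["logFC"] / (fits["s"] * fits["unscaled_sd"])
        assert table["t_mod"].to_numpy() == pytest.approx(expected.to_numpy())
        expected_p = 2 * scipy.stats.t.sf(np.abs(expected), 10.0)
        assert table["p"].to_numpy() == pytest.approx(expected_p)

    def test_equal_variances_fixed_point(self):
        fits = self._toy_fits(equal_var=True)
        with pytest.warns(UserWarning, match="identical"):
            table, prior = moderate_statistics(fits)
        assert prior.s0_sq == pytest.approx(1.3**2)
        ordinary = fits["logFC"] / (fits["s"] * fits["unscaled_sd"])
        assert table["t_mod"].to_numpy() == pytest.approx(ordinary.to_numpy())

    def test_prior_recovery_from_scaled_inv_chisq(self):
        rng = np.random.default_rng(8)
        g, d, d0, s0_sq = 5000, 10.0, 8.0, 1.7
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=g)
        s_sq = sigma_sq * rng.chisquare(d, size=g) / d
        prior = estimate_moderation_prior(s_sq, np.full(g, d), robust=False)
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.2)


class TestBHAdjust:
    @staticmethod
    def _brute_force(p):
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            adj[idx] = min(
                min(p[j] * m / (list(order).index(j) + 1) for j in order[rank - 1 :]), 1.0
            )
        return adj

    def test_worked_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42])) == pytest.approx([0.42])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.random(100)
            assert bh_adjust(p) == pytest.approx(self._brute_force(p), abs=1e-12)

    def test_idempotent_and_dominates_raw(self):
        rng = np.random.default_rng(10)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert bh_adjust(adj) == pytest.approx(self._brute_force(adj), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestSelectDeGenes:
    def test_strict_threshold(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "p_adj": [0.05, 0.049], "direction": ["up", "down"]}
        )
        out = select_de_genes(table)
        assert out["gene_id"].tolist() == ["b"]

    def test_empty_selection_raises(self):
        table = pd.DataFrame({"gene_id": ["a"], "p_adj": [0.9], "direction": ["up"]})
        with pytest.raises(EmptySignatureError):
            select_de_genes(table)


class TestLabelSwapAntisymmetry:
    def test_swap_negates_logfc_keeps_p(self, small_cohort):
        counts, truth = small_cohort
        sub = CountMatrix(counts.gene_ids[:200], counts.sample_ids, counts.counts[:200])
        de_a = run_differential_expression(sub, truth.labels)
        de_b = run_differential_expression(sub, 1 - truth.labels)
        assert de_a["logFC"].to_numpy() == pytest.approx(-de_b["logFC"].to_numpy(), abs=1e-10)
        assert de_a["t_mod"].to_numpy() == pytest.approx(-de_b["t_mod"].to_numpy(), abs=1e-10)
        assert de_a["p"].to_numpy() == pytest.approx(de_b["p"].to_numpy(), abs=1e-12)


def _annotation_for(genes_by_arm):
    rows = []
    for arm, genes in genes_by_arm.items():
        for g in genes:
            rows.append(
                {"gene_id": g, "chromosome": arm[:-1], "arm": arm,
                 "band": f"{arm}11", "biotype": "protein_coding"}
            )
    return pd.DataFrame(rows)


class TestArmEnrichment:
    def test_closed_form_yates(self):
        # arm 1p: 10 up, 0 down; elsewhere: 0 up, 10 down
        selected = pd.DataFrame(
            {
                "gene_id": [f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)],
                "direction": ["up"] * 10 + ["down"] * 10,
            }
        )
        ann = _annotation_for(
            {"1p": [f"u{i}" for i in range(10)], "2q": [f"d{i}" for i in range(10)]}
        )
        out = arm_enrichment_test(selected, ann).set_index("arm")
        assert out.loc["1p", "chi_sq"] == pytest.approx(16.2)
        assert out.loc["1p", "p"] == pytest.approx(scipy.stats.chi2.sf(16.2, 1), rel=1e-6)
        assert out.loc["1p", "p_bonf"] == pytest.approx(
            min(1.0, out.loc["1p", "p"] * len(out))
        )

    def test_no_effect_arm(self):
        # same up:down ratio on the arm as elsewhere -> no signal
        selected = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(40)],
                "direction": (["up", "down"] * 20),
            }
        )
        ann = _annotation_for(
            {"3q": [f"g{i}" for i in range(20)], "4p": [f"g{i}" for i in range(20, 40)]}
        )
        out = arm_enrichment_test(selected, ann).set_index("arm")
        assert out.loc["3q", "chi_sq"] == pytest.approx(0.0, abs=0.2)
        assert out.loc["3q", "p"] > 0.5

    def test_counts_sum_to_signature_totals(self, small_cohort):
        counts, truth = small_cohort
        de = run_differential_expression(counts, truth.labels)
        selected = select_de_genes(de)
        out = arm_enrichment_test(selected, truth.annotation())
        ann = truth.annotation().set_index("gene_id")["arm"]
        mapped = selected[selected["gene_id"].map(ann).notna() & (selected["gene_id"].map(ann) != "")]
        assert out["up_on_arm"].sum() == (mapped["direction"] == "up").sum()
        assert out["down_on_arm"].sum() == (mapped["direction"] == "down").sum()


class TestPearson:
    def test_identity_and_affine(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p = pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
        assert r == pytest.approx(expected, abs=1e-12)
        t = expected * np.sqrt(18 / (1 - expected**2))
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), 18), rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation(np.ones(5), np.arange(5.0))
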