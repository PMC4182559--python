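"""Per-gene linear models, variance moderation, BH adjustment, top tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigresp.diffexpr import (
    bh_adjust,
    fit_gene_linear_models,
    moderate_variances,
    top_table,
)
from sigresp.errors import DesignError
from sigresp.synthetic import CohortConfig, generate_cohort


def _exact_gene_matrix(design):
    treated = design["treated"].to_numpy(dtype=float)
    gf = design["gf"].to_numpy(dtype=float)
    values = np.vstack([treated, 2.0 * gf, treated + 0.5 * gf])
    return pd.DataFrame(values, index=["g_trt", "g_gf", "g_both"], columns=design.index)


class TestLinearModels:
    def test_exact_effects_recovered_with_zero_residual(self, toy_design):
        fit = fit_gene_linear_models(_exact_gene_matrix(toy_design), toy_design)
        assert fit.coef.at["g_trt", "treated"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coef.at["g_trt", "gf"] == pytest.approx(0.0, abs=1e-10)
        assert fit.coef.at["g_gf", "gf"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coef.at["g_gf", "treated"] == pytest.approx(0.0, abs=1e-10)
        assert fit.s2.max() < 1e-20
        assert fit.df_residual == len(toy_design) - 3

    def test_gf_confounding_absorbed_by_gf_column(self, rng, toy_design):
        # a purely GF-responsive noisy gene should show ~zero treatment effect
        gf = toy_design["gf"].to_numpy(dtype=float)
        values = 2.0 * gf + rng.normal(0, 0.05, size=(50, len(toy_design)))
        fit = fit_gene_linear_models(
            pd.DataFrame(values, columns=toy_design.index), toy_design
        )
        assert np.abs(fit.coef["treated"].mean()) < 0.02
        assert fit.coef["gf"].mean() == pytest.approx(2.0, abs=0.02)

    def test_planted_treatment_genes_have_larger_coefficients(self, default_cohort):
        from sigresp.preprocess import adjust_batches_eb

        matrix, design, _, truth = default_cohort
        adjusted, _ = adjust_batches_eb(matrix, design, anchor="control")
        fit = fit_gene_linear_models(adjusted, design)
        planted = fit.coef.loc[truth.treatment_gene_ids, "treated"].abs().mean()
        others = fit.coef.drop(index=truth.treatment_gene_ids)["treated"].abs().mean()
        assert planted > 2 * others

    def test_all_treated_design_rejected(self, rng):
        design = pd.DataFrame(
            {"patient": "A", "treated": True, "gf": [False, True] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        mat = pd.DataFrame(rng.normal(size=(5, 6)), columns=design.index)
        with pytest.raises(DesignError):
            fit_gene_linear_models(mat, design)


class TestModeration:
    def test_prior_parameters_recovered_from_scaled_f_samples(self):
        """Moment matching recovers d0 and s0^2 when gene variances follow
        the generating scaled-F model (d0 = 4)."""
        rng = np.random.default_rng(123)
        n_genes, df, d0, s0_2 = 5000, 69, 4.0, 0.05
        sigma2 = s0_2 * d0 / rng.chisquare(d0, n_genes)
        s2 = sigma2 * rng.chisquare(df, n_genes) / df

        # package the simulated variances into a fit skeleton
        from sigresp.diffexpr import ModeratedFit

        genes = pd.Index([f"g{i}" for i in range(n_genes)])
        fit = ModeratedFit(
            genes=genes,
            coef=pd.DataFrame({"treated": np.zeros(n_genes), "gf": 0.0}, index=genes),
            s2=pd.Series(s2, index=genes),
            df_residual=float(df),
            se_unit=1.0,
        )
        fit = moderate_variances(fit)
        assert 3.0 < fit.d0 < 5.5
        assert abs(fit.s0_2 - s0_2) / s0_2 < 0.15

    def test_identical_variances_collapse_to_pooled(self, toy_design, rng):
        treated = toy_design["treated"].to_numpy(dtype=float)
        # identical residual patterns give identical s2 across genes
        resid = rng.normal(0, 1, size=len(toy_design))
        resid -= np.linalg.lstsq(
            np.column_stack([np.ones_like(treated), treated, toy_design["gf"].astype(float)]),
            resid,
            rcond=None,
        )[0] @ np.column_stack(
            [np.ones_like(treated), treated, toy_design["gf"].astype(float)]
        ).T
        values = np.vstack([k * treated + resid for k in (0.5, 1.0, 2.0)])
        fit = moderate_variances(
            fit_gene_linear_models(
                pd.DataFrame(values, index=["a", "b", "c"], columns=toy_design.index),
                toy_design,
            )
        )
        assert np.isinf(fit.d0)
        pooled = fit.s0_2
        expected = fit.coef["treated"] / (np.sqrt(pooled) * fit.se_unit)
        assert np.allclose(fit.t_mod, expected)

    def test_posterior_variance_between_prior_and_sample(self, default_cohort):
        matrix, design, *_ = default_cohort
        fit = moderate_variances(fit_gene_linear_models(matrix.iloc[:500], design))
        lo = np.minimum(fit.s2, fit.s0_2)
        hi = np.maximum(fit.s2, fit.s0_2)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()

    def test_moderation_is_deterministic(self, small_cohort):
        matrix, design, *_ = small_cohort
        a = moderate_variances(fit_gene_linear_models(matrix, design))
        b = moderate_variances(fit_gene_linear_models(matrix, design))
        pd.testing.assert_series_equal(a.p, b.p)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_equal_inputs_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), [0.2] * 5)
        assert np.allclose(bh_adjust([0.7]), [0.7])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, p, rnd):
        """BH output permutes together with its input."""
        p = np.array(p)
        perm = np.arange(p.size)
        rnd.shuffle(perm)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTopTable:
    def test_recovers_planted_genes_at_strict_fdr(self, default_cohort):
        from sigresp.preprocess import adjust_batches_eb

        matrix, design, _, truth = default_cohort
        adjusted, _ = adjust_batches_eb(matrix, design, anchor="control")
        fit = moderate_variances(fit_gene_linear_models(adjusted, design))
        top = top_table(fit, 300, 0.001)
        assert len(top) <= 300
        assert (fit.fdr.loc[top] < 0.001).all()
        planted_frac = np.mean([g in set(truth.treatment_gene_ids) for g in top])
        assert planted_frac >= 0.9

    def test_zero_fdr_threshold_gives_empty(self, small_cohort):
        matrix, design, *_ = small_cohort
        fit = moderate_variances(fit_gene_linear_models(matrix, design))
        assert top_table(fit, 300, 0.0) == []


def test_global_null_calibration():
    """Without planted effects, ~5% of genes reach p<0.05 and strict-FDR
    discoveries are (almost always) absent."""
    seeds_with_zero_discoveries = 0
    fractions = []
    for seed in range(5):
        cfg = CohortConfig(
            n_patients=12, n_genes=1000, n_treatment_genes=0, n_gf_genes=0,
            n_causal_genes=0, patient_sd=0.0, seed=seed,
        )
        matrix, design, *_ = generate_cohort(cfg)
        fit = moderate_variances(fit_gene_linear_models(matrix, design))
        fractions.append((fit.p < 0.05).mean())
        seeds_with_zero_discoveries += int((fit.fdr < 0.05).sum() == 0)
    assert abs(np.mean(fractions) - 0.05) < 0.01
    assert seeds_with_zero_discoveries >= 4
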