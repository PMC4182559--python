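"""Variance filter and empirical-Bayes batch adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sigresp.errors import DesignError
from sigresp.preprocess import adjust_batches_eb, filter_by_variance


def _toy_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFilterByVariance:
    def test_keeps_highest_variance_genes_in_input_order(self, rng):
        base = rng.normal(size=8)
        mat = _toy_matrix(
            np.vstack([
                1.0 + 0.1 * base,   # var ~ 0.01 * var(base)
                5.0 + 5.0 * base,   # largest
                2.0 + 2.0 * base,   # second
            ])
        )
        out = filter_by_variance(mat, 2)
        assert list(out.index) == ["g1", "g2"]

    def test_k_equal_gene_count_is_identity(self, rng):
        mat = _toy_matrix(rng.normal(size=(5, 6)))
        pd.testing.assert_frame_equal(filter_by_variance(mat, 5), mat)

    def test_ties_broken_by_input_order(self):
        row = np.array([0.0, 1.0, 2.0, 3.0])
        mat = _toy_matrix(np.vstack([row, row, row]))
        out = filter_by_variance(mat, 2)
        assert list(out.index) == ["g0", "g1"]

    @pytest.mark.parametrize("k", [0, 6])
    def test_out_of_range_k_rejected(self, k, rng):
        mat = _toy_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            filter_by_variance(mat, k)


def _two_batch_instance(seed=0, n_genes=400, shift=2.0):
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for b in ("A", "B"):
        for treated in (False, True):
            for gf in (False, True):
                samples.append(f"{b}_{int(treated)}{int(gf)}")
                rows.append((b, treated, gf))
    design = pd.DataFrame(rows, columns=["patient", "treated", "gf"], index=samples)
    base = rng.normal(7, 1, size=(n_genes, 1))
    x = base + rng.normal(0, 0.4, size=(n_genes, 8))
    x[:, 4:] += shift  # batch B shifted on every gene
    return _toy_matrix(x, samples=samples), design


class TestAdjustBatches:
    def test_single_batch_is_identity(self, rng):
        mat = _toy_matrix(rng.normal(7, 1, size=(30, 6)))
        design = pd.DataFrame(
            {"patient": "only", "treated": [False] * 3 + [True] * 3, "gf": False},
            index=mat.columns,
        )
        out, params = adjust_batches_eb(mat, design, preserve_covariates=False)
        assert np.abs(out.to_numpy() - mat.to_numpy()).max() < 1e-8

    def test_planted_mean_shift_removed(self):
        mat, design = _two_batch_instance(seed=1, shift=2.0)
        out, _ = adjust_batches_eb(mat, design)
        means = out.T.groupby(design["patient"]).mean().T
        gap = (means["A"] - means["B"]).abs()
        assert gap.mean() < 0.05

    def test_gamma_star_lies_between_gamma_hat_and_gamma_bar(self, default_cohort):
        matrix, design, *_ = default_cohort
        top = filter_by_variance(matrix, 300)
        _, params = adjust_batches_eb(top, design)
        for b in params.batches:
            g_hat = params.gamma_hat.loc[b].to_numpy()
            g_star = params.gamma_star.loc[b].to_numpy()
            g_bar = params.hyper.at[b, "gamma_bar"]
            lo = np.minimum(g_hat, g_bar) - 1e-8
            hi = np.maximum(g_hat, g_bar) + 1e-8
            assert ((g_star >= lo) & (g_star <= hi)).all()

    def test_second_pass_changes_little(self, small_cohort):
        """A second adjustment pass changes the matrix far less than the
        first (4-sample batches leave re-estimation noise in the scale
        parameters, so exact idempotence is not attainable)."""
        matrix, design, *_ = small_cohort
        once, _ = adjust_batches_eb(matrix, design)
        twice, _ = adjust_batches_eb(once, design)
        first = np.abs(once.to_numpy() - matrix.to_numpy()).mean()
        second = np.abs(twice.to_numpy() - once.to_numpy()).mean()
        assert second < first / 10
        # batch locations are stable after one pass
        _, params2 = adjust_batches_eb(once, design)
        assert np.abs(params2.gamma_hat.to_numpy()).mean() < 0.05

    def test_shrinkage_vanishes_for_heterogeneous_batch_effects(self):
        """With strongly gene-specific batch effects (large tau^2) the
        posterior gamma* stays close to the unshrunken per-gene estimate
        gamma_hat; with homogeneous effects it is pulled to gamma_bar."""
        rng = np.random.default_rng(2)
        samples = [f"{b}{j}" for b in "AB" for j in range(4)]
        design = pd.DataFrame(
            {
                "patient": [s[0] for s in samples],
                "treated": [int(s[1]) >= 2 for s in samples],
                "gf": [int(s[1]) % 2 == 1 for s in samples],
            },
            index=samples,
        )

        def gap(shift_sd):
            x = rng.normal(7, 1, (600, 1)) + rng.normal(0, 0.4, (600, 8))
            x[:, 4:] += rng.normal(0, shift_sd, (600, 1))
            mat = _toy_matrix(x, samples=samples)
            _, params = adjust_batches_eb(mat, design, preserve_covariates=False)
            num = np.abs(params.gamma_star.to_numpy() - params.gamma_hat.to_numpy()).mean()
            den = np.abs(
                params.gamma_hat.to_numpy()
                - params.hyper["gamma_bar"].to_numpy()[:, None]
            ).mean()
            return num / den

        hetero, homo = gap(3.0), gap(0.0)
        assert hetero < 0.1  # nearly no shrinkage when tau^2 is large
        assert homo > 0.5  # strong pull toward gamma_bar when effects agree

    def test_small_batch_rejected(self, rng):
        mat = _toy_matrix(rng.normal(size=(10, 5)))
        design = pd.DataFrame(
            {"patient": ["A"] * 4 + ["B"], "treated": False, "gf": False},
            index=mat.columns,
        )
        with pytest.raises(DesignError):
            adjust_batches_eb(mat, design)

    def test_control_anchor_leaves_untreated_profiles_unlinked(self, default_cohort):
        """Control-anchored adjustment removes patient effects without
        mirroring the treatment response into control profiles."""
        matrix, design, response, truth = default_cohort
        out, _ = adjust_batches_eb(matrix, design, anchor="control")
        causal = truth.causal_gene_ids
        untreated = design[~design["treated"] & design["gf"]].index
        x = out.loc[causal, untreated].mean(axis=0).to_numpy()
        r = np.corrcoef(x, response["proliferation"].to_numpy())[0, 1]
        assert abs(r) < 0.45  # within null sampling range at n=18


def test_matches_reference_combat_implementation(tmp_path):
    """Cross-check against the Bioconductor reference on a seeded instance."""
    rng = np.random.default_rng(42)
    n_genes, n_b, per = 60, 3, 4
    samples = [f"b{i}s{j}" for i in range(n_b) for j in range(per)]
    patient = [f"b{i}" for i in range(n_b) for _ in range(per)]
    treated = [j >= 2 for _ in range(n_b) for j in range(per)]
    gf = [j % 2 == 1 for _ in range(n_b) for j in range(per)]
    base = rng.normal(7, 1, (n_genes, 1))
    shift = np.repeat([0.0, 2.0, -1.0], per)
    scale = np.repeat([1.0, 1.5, 0.7], per)
    x = base + rng.normal(0, 0.5, (n_genes, n_b * per)) * scale + shift
    x += 0.8 * np.array(treated, float) * rng.normal(0, 1, (n_genes, 1))
    mat = _toy_matrix(x, samples=samples)
    design = pd.DataFrame({"patient": patient, "treated": treated, "gf": gf}, index=samples)
    ours, _ = adjust_batches_eb(mat, design, preserve_covariates=True)

    mat.to_csv(tmp_path / "x.tsv", sep="\t")
    pd.DataFrame(
        {"batch": patient, "treated": np.array(treated, int), "gf": np.array(gf, int)},
        index=samples,
    ).to_csv(tmp_path / "d.tsv", sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(sva))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
        d <- read.delim("{tmp_path}/d.tsv", row.names=1)
        mod <- model.matrix(~treated+gf, data=d)
        out <- ComBat(dat=x, batch=d$batch, mod=mod, par.prior=TRUE)
        write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
    """)
    (tmp_path / "combat.R").write_text(script)
    proc = subprocess.run(
        ["Rscript", str(tmp_path / "combat.R")], capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    assert np.abs(ours.to_numpy() - ref.to_numpy()).max() < 1e-3
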