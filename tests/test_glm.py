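import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import agoripseq as aq
from agoripseq.glm import (
    CELL_ORDER,
    build_design_matrix,
    estimate_dispersion,
    fit_nbglm,
    lrt_contrast,
    validate_design,
)
from agoripseq.targets import builtin_contrasts
from oracles import bh_bruteforce


def _design(n_reps=3):
    rows = []
    for cell in CELL_ORDER:
        ip, tr = cell.split(".")
        for r in range(1, n_reps + 1):
            rows.append({"library_id": f"{ip}_{tr}_{r}", "treatment": tr, "ip": ip, "replicate": r})
    return pd.DataFrame(rows)


def _cell_counts(per_cell, n_reps=3):
    """Counts for one gene laid out in CELL_ORDER with n_reps replicates."""
    return np.repeat(np.asarray(per_cell, dtype=float), n_reps)[None, :]


class TestDesignMatrix:
    def test_full_factorial_one_hot(self):
        dm = build_design_matrix(_design())
        assert dm.shape == (18, 6)
        assert (dm.sum(axis=0) == 3).all()
        assert (dm.sum(axis=1) == 1).all()

    def test_single_replicate_is_permutation(self):
        dm = build_design_matrix(_design(1)).to_numpy()
        assert dm.shape == (6, 6)
        assert np.allclose(dm @ dm.T, np.eye(6))

    def test_missing_cell_named(self):
        design = _design()
        design = design[~((design["ip"] == "IgG") & (design["treatment"] == "control"))]
        with pytest.raises(ValueError, match="IgG.control"):
            validate_design(design)

    def test_row_permutation_permutes_matrix_and_leaves_fit_invariant(self, small_sim):
        _, counts, design, _ = small_sim
        counts = counts.head(40)
        perm = np.random.default_rng(0).permutation(len(design))
        design2 = design.iloc[perm].reset_index(drop=True)
        counts2 = counts.loc[:, design2["library_id"]]
        dm1 = build_design_matrix(design)
        dm2 = build_design_matrix(design2)
        assert (dm1.to_numpy()[perm] == dm2.to_numpy()).all()
        o1 = np.log(counts.sum(axis=0).to_numpy(float))
        f1 = fit_nbglm(counts.to_numpy(), dm1.to_numpy(), o1, 0.1)
        f2 = fit_nbglm(counts2.to_numpy(), dm2.to_numpy(), o1[perm], 0.1)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)


class TestFit:
    def test_saturated_cell_mean_is_arithmetic_mean(self):
        """With equal offsets, the one-hot NB MLE of each cell mean is the
        cell's sample mean, independent of the dispersion."""
        y = _cell_counts([10, 10, 10, 20, 30, 40])
        y[0, :3] = [5, 10, 15]  # Ago.miR replicates, mean 10
        dm = build_design_matrix(_design()).to_numpy()
        for phi in (0.0, 0.1, 1.0):
            fit = fit_nbglm(y, dm, np.zeros(18), phi)
            np.testing.assert_allclose(np.exp(fit.beta[0, 0]), 10.0, rtol=1e-6)
            np.testing.assert_allclose(np.exp(fit.beta[0, 3:]), [20, 30, 40], rtol=1e-6)

    def test_poisson_and_nb_agree_on_cell_means(self, rng):
        y = rng.poisson(50, size=(20, 18)).astype(float)
        dm = build_design_matrix(_design()).to_numpy()
        f0 = fit_nbglm(y, dm, np.zeros(18), 0.0)
        f1 = fit_nbglm(y, dm, np.zeros(18), 0.4)
        np.testing.assert_allclose(f0.beta, f1.beta, atol=1e-6)

    def test_matches_statsmodels_glm(self, small_sim):
        """Independent cross-check: per-gene statsmodels NB GLM with the
        same design, offsets and dispersion reproduces coefficients and
        log-likelihood."""
        _, counts, design, _ = small_sim
        y = counts.head(12).to_numpy(float)
        dm = build_design_matrix(design)
        offsets = np.log(counts.sum(axis=0).to_numpy(float))
        phi = 0.1
        ours = fit_nbglm(y, dm.to_numpy(), offsets, phi)
        for g in range(y.shape[0]):
            model = sm.GLM(
                y[g],
                dm.to_numpy(),
                family=sm.families.NegativeBinomial(alpha=phi),
                offset=offsets,
            )
            res = model.fit()
            np.testing.assert_allclose(ours.beta[g], res.params, atol=1e-5)
            np.testing.assert_allclose(ours.loglik[g], res.llf, atol=1e-5)

    def test_beta_recovery_on_simulated_cells(self, rng):
        """ln cell means recovered with small mean absolute error over 500
        NB-simulated genes at 3 replicates, phi = 0.1."""
        true_means = np.array([100.0, 10.0, 50.0, 50.0, 10.0, 50.0])
        mu = np.repeat(true_means, 3)
        r = 1 / 0.1
        y = rng.poisson(rng.gamma(r, mu / r, size=(500, 18)))
        dm = build_design_matrix(_design()).to_numpy()
        fit = fit_nbglm(y.astype(float), dm, np.zeros(18), 0.1)
        mae = np.mean(np.abs(fit.beta - np.log(true_means)))
        assert mae < 0.25

    def test_rank_deficient_design_rejected(self):
        dm = build_design_matrix(_design()).to_numpy()
        dm[:, 1] = dm[:, 0]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nbglm(np.ones((2, 18)), dm, np.zeros(18), 0.1)


class TestDispersion:
    def test_poisson_data_yield_near_zero_common_estimate(self):
        cfg = aq.SimConfig(n_genes=2000, dispersion=0.0, frac_targets=0.0, seed=8)
        counts, design, _ = aq.simulate_ripseq(cfg)
        dm = build_design_matrix(design).to_numpy()
        offs = np.log(counts.sum(axis=0).to_numpy(float))
        phi = estimate_dispersion(counts.to_numpy(), dm, offs, mode="common")
        assert phi[0] <= 1e-3

    def test_common_recovery(self):
        cfg = aq.SimConfig(n_genes=2000, dispersion=0.1, frac_targets=0.0, seed=9)
        counts, design, _ = aq.simulate_ripseq(cfg)
        dm = build_design_matrix(design).to_numpy()
        offs = np.log(counts.sum(axis=0).to_numpy(float))
        phi = estimate_dispersion(counts.to_numpy(), dm, offs, mode="common")
        assert 0.08 <= phi[0] <= 0.12

    def test_identical_genes_identical_genewise_estimates(self, rng):
        y = rng.poisson(40, size=(1, 18)).astype(float)
        y = np.vstack([y, y, rng.poisson(40, size=(1, 18))])
        dm = build_design_matrix(_design()).to_numpy()
        phi = estimate_dispersion(y, dm, np.zeros(18), mode="genewise")
        assert phi[0] == phi[1]

    def test_shrunk_lies_between_genewise_and_common(self):
        cfg = aq.SimConfig(n_genes=300, dispersion=0.1, frac_targets=0.0, seed=10)
        counts, design, _ = aq.simulate_ripseq(cfg)
        dm = build_design_matrix(design).to_numpy()
        offs = np.log(counts.sum(axis=0).to_numpy(float))
        y = counts.to_numpy()
        shrunk = estimate_dispersion(y, dm, offs, mode="shrunk", prior_weight=10.0)
        heavy = estimate_dispersion(y, dm, offs, mode="shrunk", prior_weight=1e6)
        common = estimate_dispersion(y, dm, offs, mode="common")
        # infinite prior collapses onto the common value
        np.testing.assert_allclose(heavy, common[0], rtol=0.05)
        assert shrunk.std() > heavy.std()


class TestLRT:
    def test_flat_gene_has_null_results(self):
        y = _cell_counts([50, 50, 50, 50, 50, 50])
        dm = build_design_matrix(_design()).to_numpy()
        for spec in builtin_contrasts():
            res = lrt_contrast(y, dm, np.zeros(18), 0.1, np.array(spec.coefficients))
            assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-8)
            assert res["lrt_stat"].iloc[0] == pytest.approx(0.0, abs=1e-6)
            assert res["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_worked_cell_mean_example(self):
        """Cell means (400, 50, 200, 100, 50, 200) give an Ago-IP_IgG
        estimate of log2(400/50) - log2(100/50) = 2.0."""
        y = _cell_counts([400, 50, 200, 100, 50, 200])
        dm = build_design_matrix(_design()).to_numpy()
        contrast = np.array(builtin_contrasts()[0].coefficients)
        res = lrt_contrast(y, dm, np.zeros(18), 0.1, contrast)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_full_likelihood_dominates_null(self, small_sim):
        _, counts, design, _ = small_sim
        dm = build_design_matrix(design).to_numpy()
        offs = np.log(counts.sum(axis=0).to_numpy(float))
        y = counts.to_numpy()
        full = fit_nbglm(y, dm, offs, 0.1)
        for spec in builtin_contrasts():
            c = np.array(spec.coefficients)
            res = lrt_contrast(y, dm, offs, 0.1, c, full_fit=full)
            assert (res["lrt_stat"] >= -1e-6).all()

    def test_matches_statsmodels_lrt(self, small_sim):
        """The constrained-refit LRT equals 2(llf - llnull) computed by two
        independent statsmodels fits on full and reduced designs."""
        from scipy.linalg import null_space

        _, counts, design, _ = small_sim
        y = counts.head(8).to_numpy(float)
        dm = build_design_matrix(design).to_numpy()
        offs = np.log(counts.sum(axis=0).to_numpy(float))
        c = np.array(builtin_contrasts()[0].coefficients)
        res = lrt_contrast(y, dm, offs, 0.1, c)
        reduced = dm @ null_space(c[None, :])
        fam = sm.families.NegativeBinomial(alpha=0.1)
        for g in range(y.shape[0]):
            ll_full = sm.GLM(y[g], dm, family=fam, offset=offs).fit().llf
            ll_null = sm.GLM(y[g], reduced, family=fam, offset=offs).fit().llf
            np.testing.assert_allclose(
                res["lrt_stat"].iloc[g], 2 * (ll_full - ll_null), atol=1e-4
            )

    def test_all_zero_contrast_rejected(self):
        y = _cell_counts([1, 2, 3, 4, 5, 6])
        dm = build_design_matrix(_design()).to_numpy()
        with pytest.raises(ValueError, match="all zeros"):
            lrt_contrast(y, dm, np.zeros(18), 0.1, np.zeros(6))

    def test_zero_cell_fold_change_is_finite(self):
        y = _cell_counts([0, 50, 200, 100, 50, 200])
        dm = build_design_matrix(_design()).to_numpy()
        c = np.array(builtin_contrasts()[0].coefficients)
        res = lrt_contrast(y, dm, np.full(18, np.log(1e6)), 0.1, c)
        assert np.isfinite(res["log2fc"].iloc[0])
        assert res["zero_cell"].iloc[0]


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert aq.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(aq.bh_adjust([0.3] * 5), 0.3)

    def test_literal_step_up_example(self):
        p = [0.01, 0.02, 0.03, 0.5]
        np.testing.assert_allclose(aq.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aq.bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_matches_bruteforce_and_dominates_p(self, p):
        adj = aq.bh_adjust(p)
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1])
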