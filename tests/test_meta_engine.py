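"""REML engine: sampling VCV, likelihood optimization, inference, Q test."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from badgemeta import meta_engine as me
from badgemeta.meta_engine import MetaDataset, ModelFit

from oracles import gls_beta, grid_reml_oracle, random_small_instance


class TestSamplingVCV:
    def test_single_effect(self):
        V = me.build_sampling_vcv(np.array([0.2]), ["s1"])
        assert V.tolist() == [[0.2]]

    def test_same_study_covariance(self):
        V = me.build_sampling_vcv(np.array([0.1, 0.4]), ["s1", "s1"], rho=0.5)
        assert V[0, 1] == pytest.approx(0.5 * np.sqrt(0.04))
        assert V[0, 1] == pytest.approx(0.1)

    def test_different_studies_independent(self):
        V = me.build_sampling_vcv(np.array([0.1, 0.4]), ["s1", "s2"], rho=0.5)
        assert V[0, 1] == 0.0

    def test_psd_by_construction(self, rng):
        v = rng.uniform(0.01, 0.5, 30)
        studies = rng.integers(0, 6, 30).astype(str)
        V = me.build_sampling_vcv(v, studies, rho=0.9)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_rho_domain(self):
        with pytest.raises(ValueError):
            me.build_sampling_vcv(np.array([0.1]), ["s1"], rho=1.0)
        with pytest.raises(ValueError):
            me.build_sampling_vcv(np.array([0.0, 0.1]), ["s1", "s2"])


class TestRemlFit:
    def test_fixed_effect_limit_equals_gls(self, small_dataset):
        dataset, _ = small_dataset
        zeros = {name: 0.0 for name in me.LEVELS}
        fit = me.fit_intercept_model(dataset, fixed_sigma2=zeros)
        X = np.ones((dataset.k, 1))
        expected = gls_beta(dataset.y, X, dataset.sampling_vcv)
        assert fit.beta == pytest.approx(expected, rel=1e-10)

    def test_two_equal_variance_effects_average(self):
        y = np.array([0.1, 0.5])
        V = np.diag([0.04, 0.04])
        fit = me.reml_fit(y, np.ones((2, 1)), V, {"unit": np.eye(2)},
                          fixed_sigma2={"unit": 0.0})
        assert fit.beta[0] == pytest.approx(0.3)

    def test_rank_deficient_design_rejected(self, small_dataset):
        dataset, _ = small_dataset
        X = np.ones((dataset.k, 2))
        with pytest.raises(ValueError, match="rank"):
            me.reml_fit(dataset.y, X, dataset.sampling_vcv, dataset.random_design())

    def test_tiny_instance_matches_grid_oracle(self, rng):
        # k = 12, 4 studies, 2-level structure: engine optimum vs brute force
        study = np.repeat(np.arange(4), 3)
        v = rng.uniform(0.02, 0.1, 12)
        V = np.diag(v)
        comps = {"study": (study[:, None] == study[None, :]).astype(float),
                 "unit": np.eye(12)}
        S = V + 0.05 * comps["study"] + 0.08 * comps["unit"]
        y = 0.3 + np.linalg.cholesky(S) @ rng.standard_normal(12)
        X = np.ones((12, 1))
        fit = me.reml_fit(y, X, V, comps, seed=0)
        ll_oracle, s2_oracle = grid_reml_oracle(y, X, V, comps)
        assert fit.loglik_reml >= ll_oracle - 1e-6
        for name in comps:
            assert fit.sigma2[name] == pytest.approx(s2_oracle[name], abs=1e-4)

    def test_permutation_invariance(self, small_dataset):
        dataset, _ = small_dataset
        fit = me.fit_intercept_model(dataset, seed=0)
        rng = np.random.default_rng(11)
        perm = rng.permutation(dataset.k)
        permuted = MetaDataset(
            y=dataset.y[perm], v=dataset.v[perm],
            study_ids=dataset.study_ids[perm], species=dataset.species[perm],
            n_eff=dataset.n_eff[perm],
            sampling_vcv=dataset.sampling_vcv[np.ix_(perm, perm)],
            moderators=dataset.moderators.iloc[perm].reset_index(drop=True),
            phylo_corr=dataset.phylo_corr, rho=dataset.rho,
        )
        fit_p = me.fit_intercept_model(permuted, seed=0)
        assert fit_p.beta[0] == pytest.approx(fit.beta[0], abs=1e-6)
        assert fit_p.loglik_reml == pytest.approx(fit.loglik_reml, abs=1e-6)
        for name in fit.sigma2:
            assert fit_p.sigma2[name] == pytest.approx(fit.sigma2[name], abs=1e-5)

    def test_species_phylo_exchangeable_under_identity_matrix(self, small_dataset):
        # with A = I only the species+phylogeny sum is identified
        dataset, _ = small_dataset
        comps = dataset.random_design()
        comps_identity = dict(comps, phylogeny=np.eye(dataset.k) * 0 +
                              comps["species"])  # A = I at species level
        X = np.ones((dataset.k, 1))
        fit_split = me.reml_fit(dataset.y, X, dataset.sampling_vcv, comps_identity,
                                seed=0)
        comps_merged = {k: v for k, v in comps.items() if k != "phylogeny"}
        fit_merged = me.reml_fit(dataset.y, X, dataset.sampling_vcv, comps_merged,
                                 seed=0)
        split_sum = fit_split.sigma2["species"] + fit_split.sigma2["phylogeny"]
        assert fit_split.loglik_reml == pytest.approx(fit_merged.loglik_reml, abs=1e-5)
        assert split_sum == pytest.approx(fit_merged.sigma2["species"], abs=2e-3)


class TestWaldInference:
    @staticmethod
    def _fit(beta, se, inference="z", k=50, p=1):
        return ModelFit(beta=np.atleast_1d(beta), se=np.atleast_1d(se),
                        vcov_beta=np.diag(np.atleast_1d(se)) ** 2,
                        sigma2={"unit": 0.0}, loglik_reml=0.0, converged=True,
                        k=k, p=p, n_studies=10, n_species=5,
                        coef_names=["intercept"], fitted=np.zeros(k),
                        inference=inference)

    def test_null_coefficient(self):
        table = me.wald_inference(self._fit(0.0, 1.0))
        assert table["ci_lower"][0] == pytest.approx(-1.959964, abs=1e-5)
        assert table["ci_upper"][0] == pytest.approx(1.959964, abs=1e-5)
        assert table["p"][0] == pytest.approx(1.0)

    def test_headline_self_consistency(self):
        # estimate 0.218 with SE 0.0717 gives the 95% CI [0.078, 0.359]
        table = me.wald_inference(self._fit(0.218, 0.0717))
        assert table["ci_lower"][0] == pytest.approx(0.078, abs=1e-3)
        assert table["ci_upper"][0] == pytest.approx(0.359, abs=1e-3)
        assert table["p"][0] == pytest.approx(0.003, abs=1e-3)

    def test_level_monotonicity(self):
        fit = self._fit(0.2, 0.1)
        wide = me.wald_inference(fit, level=0.95)
        narrow = me.wald_inference(fit, level=0.5)
        assert narrow["ci_upper"][0] - narrow["ci_lower"][0] < \
            wide["ci_upper"][0] - wide["ci_lower"][0]

    def test_t_reference_is_wider(self):
        z = me.wald_inference(self._fit(0.2, 0.1, "z", k=10))
        t = me.wald_inference(self._fit(0.2, 0.1, "t", k=10))
        assert t["ci_upper"][0] > z["ci_upper"][0]


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        Q, df, p = me.cochran_q(np.full(5, 0.3), np.full(5, 0.1))
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_effects(self):
        Q, df, p = me.cochran_q(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert Q == pytest.approx(0.5)
        assert df == 1

    def test_scale_equivariance(self, rng):
        y = rng.normal(0, 1, 20)
        v = rng.uniform(0.05, 0.3, 20)
        Q1, *_ = me.cochran_q(y, v)
        Q2, *_ = me.cochran_q(3 * y, 9 * v)
        assert Q1 == pytest.approx(Q2, rel=1e-12)

    def test_too_few_effects(self):
        with pytest.raises(ValueError):
            me.cochran_q(np.array([0.1]), np.array([0.1]))


class TestMetaRegression:
    def test_single_level_moderator_rejected(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(ValueError, match="single level"):
            me.meta_regression(dataset, "origin")

    def test_two_level_recovery(self, small_dataset):
        dataset, _ = small_dataset
        rng = np.random.default_rng(9)
        labels = np.where(rng.random(dataset.k) < 0.5, "a", "b")
        shifted = MetaDataset(
            y=dataset.y + 0.4 * (labels == "b"), v=dataset.v,
            study_ids=dataset.study_ids, species=dataset.species,
            n_eff=dataset.n_eff, sampling_vcv=dataset.sampling_vcv,
            moderators=dataset.moderators.assign(grp=labels),
            phylo_corr=dataset.phylo_corr, rho=dataset.rho,
        )
        fit = me.meta_regression(shifted, "grp", seed=0)
        assert fit.coef_names == ["a", "b"]
        diff = fit.beta[1] - fit.beta[0]
        se_diff = np.sqrt(fit.vcov_beta[0, 0] + fit.vcov_beta[1, 1]
                          - 2 * fit.vcov_beta[0, 1])
        assert diff == pytest.approx(0.4, abs=2 * se_diff)


class TestReferenceImplementationCrossCheck:
    """Dual route: the engine against metafor's rma.mv on the same instance."""

    def test_agrees_with_rma_mv(self, tmp_path, small_dataset):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript not on PATH"
        dataset, _ = small_dataset
        df = pd.DataFrame({
            "r": dataset.y, "study_id": dataset.study_ids,
            "species": dataset.species,
            "effect_id": dataset.moderators["effect_id"],
        })
        df.to_csv(tmp_path / "d.csv", index=False)
        np.savetxt(tmp_path / "V.csv", dataset.sampling_vcv, delimiter=",")
        A = dataset.phylo_corr
        pd.DataFrame(A.matrix, index=A.species_order, columns=A.species_order
                     ).to_csv(tmp_path / "A.csv")
        script = textwrap.dedent("""
            suppressMessages({library(metafor); library(jsonlite)})
            args <- commandArgs(trailingOnly=TRUE)
            d <- read.csv(args[1])
            V <- as.matrix(read.csv(args[2], header=FALSE))
            A <- as.matrix(read.csv(args[3], row.names=1, check.names=FALSE))
            colnames(A) <- rownames(A)
            d$phylo <- d$species
            res <- rma.mv(r, V, random=list(~1|study_id, ~1|species, ~1|phylo,
                                            ~1|effect_id),
                          R=list(phylo=A), data=d, method="REML",
                          control=list(optimizer="optim", optmethod="BFGS"))
            cat(toJSON(list(b=as.numeric(res$b), se=as.numeric(res$se),
                            ll=as.numeric(logLik(res)),
                            sigma2=as.numeric(res$sigma2)), digits=12))
        """)
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            [rscript, str(tmp_path / "fit.R"), str(tmp_path / "d.csv"),
             str(tmp_path / "V.csv"), str(tmp_path / "A.csv")],
            capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        fit = me.fit_intercept_model(dataset, seed=0)
        # metafor's REML loglik carries an extra +0.5*log|X'X| constant
        ll_ours = float(fit.loglik_reml) + 0.5 * np.log(dataset.k)
        assert ll_ours == pytest.approx(ref["ll"][0], abs=1e-4)
        assert float(fit.beta[0]) == pytest.approx(ref["b"][0], abs=1e-4)
        assert float(fit.se[0]) == pytest.approx(ref["se"][0], abs=1e-4)
        assert fit.sigma2_total == pytest.approx(sum(ref["sigma2"]), abs=2e-3)
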