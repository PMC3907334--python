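"""Hierarchical reporter-assay model: design, density, sampler, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskenhancer import (LuciferaseDesign, TrueLuciferaseParams, build_design,
                          contrast_basal, contrast_induction,
                          contrast_induction_ratio, diagnostics, fit_model,
                          log_posterior, simulate_luciferase_dataset)
from riskenhancer.luciferase import (HYPER_PRIOR_MEANS, _grad_logp, _Packed,
                                     cauchy_logpdf, expon_mean_logpdf,
                                     halfnorm_logpdf, initial_params,
                                     norm_logpdf, t_logpdf)


@pytest.fixture(scope="module")
def reduced_fit():
    design = LuciferaseDesign(enhancers=("allele_1", "allele_2"),
                              n_preps=3, n_transfections=2, n_batches=2)
    truth = TrueLuciferaseParams(
        L0=1.0, E={"allele_1": 0.5, "allele_2": 0.2, "PSA_pos": 1.5},
        A={"allele_1": 1.0, "allele_2": 0.8, "PSA_pos": 2.0},
        P={}, T={}, B={}, sigma=0.05)
    data = simulate_luciferase_dataset(design, truth, seed=1)
    post = fit_model(data, chains=2, iterations=1200, warmup=600, seed=5)
    return truth, data, post


class TestLogDensities:
    """Hand-coded densities against their scipy.stats counterparts."""

    def test_against_scipy(self):
        x = np.array([-1.3, 0.2, 2.7])
        assert norm_logpdf(x, 0.7) == pytest.approx(
            stats.norm.logpdf(x, scale=0.7).sum())
        assert t_logpdf(x, 4.5, 1.3) == pytest.approx(
            stats.t.logpdf(x, df=4.5, scale=1.3).sum())
        assert cauchy_logpdf(x, 0.4) == pytest.approx(
            stats.cauchy.logpdf(x, scale=0.4).sum())
        assert expon_mean_logpdf(1.7, 8.0) == pytest.approx(
            stats.expon.logpdf(1.7, scale=8.0))
        xp = np.abs(x)
        assert halfnorm_logpdf(xp, 0.9) == pytest.approx(
            stats.halfnorm.logpdf(xp, scale=0.9).sum())


class TestBuildDesign:
    def test_default_plate_layout(self):
        design = LuciferaseDesign(enhancers=("a", "b"))
        tp = TrueLuciferaseParams(L0=0.0, E={}, A={}, P={}, T={}, B={},
                                  sigma=0.1)
        df = simulate_luciferase_dataset(design, tp, seed=0)
        info = build_design(df)
        per_enh = df[df["enhancer"] == "a"]
        assert per_enh["prep"].nunique() == 6
        assert per_enh.groupby(["prep", "batch"])["transfection"].nunique().eq(4).all()
        assert per_enh.groupby(["transfection", "dht"])["replicate"].count().eq(2).all()
        assert info.warnings == []

    def test_missing_batch_controls_warn_not_fail(self):
        design = LuciferaseDesign(enhancers=("a",), n_preps=1,
                                  n_transfections=1)
        tp = TrueLuciferaseParams(L0=0.0, E={}, A={}, P={}, T={}, B={},
                                  sigma=0.1)
        df = simulate_luciferase_dataset(design, tp, seed=0)
        df = df[df["enhancer"] != "PSA_pos"]
        with pytest.warns(UserWarning, match="PSA_pos"):
            info = build_design(df)
        assert info.warnings

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_design(pd.DataFrame())
        bad = pd.DataFrame({"enhancer": ["neg_ctrl_1", "neg_ctrl_2"],
                            "dht": [0, 0], "prep": ["p", "p"],
                            "transfection": ["t", "t"], "batch": [0, 0],
                            "luminescence": [1.0, -2.0]})
        with pytest.raises(ValueError, match="positive"):
            build_design(bad)

    def test_index_round_trip(self):
        design = LuciferaseDesign(enhancers=("a",), n_preps=2,
                                  n_transfections=2)
        tp = TrueLuciferaseParams(L0=0.0, E={}, A={}, P={}, T={}, B={},
                                  sigma=0.1)
        info = build_design(simulate_luciferase_dataset(design, tp, seed=0))
        assert info.free_levels[info.free_index("a")] == "a"
        with pytest.raises(KeyError):
            info.free_index("neg_ctrl_1")


class TestLogPosterior:
    def make_design(self):
        design = LuciferaseDesign(enhancers=("a",), n_preps=1,
                                  n_transfections=1)
        tp = TrueLuciferaseParams(L0=1.0, E={"a": 0.3}, A={"a": 0.6},
                                  P={}, T={}, B={}, sigma=0.0)
        return build_design(simulate_luciferase_dataset(design, tp, seed=0))

    def zero_params(self, info):
        params = {"E": np.zeros(len(info.free_levels)),
                  "A": np.zeros(len(info.free_levels)),
                  "P": np.zeros(len(info.prep_levels)),
                  "T": np.zeros(len(info.trans_levels)),
                  "B": np.zeros(len(info.batch_levels)),
                  "sigma": np.full(len(info.group_levels), 0.5)}
        params.update({k: np.array(v) for k, v in HYPER_PRIOR_MEANS.items()})
        return params

    def test_scalar_oracle(self):
        """One-observation model checked against hand-computed terms."""
        info = self.make_design()
        params = self.zero_params(info)
        lp = log_posterior(params, info)
        h = HYPER_PRIOR_MEANS
        expected = sum(stats.expon.logpdf(v, scale=v) for v in h.values())
        expected += stats.t.logpdf(params["E"], df=h["nu_E"], scale=h["s_E"]).sum()
        expected += stats.cauchy.logpdf(params["A"], scale=h["s_A"]).sum()
        expected += stats.norm.logpdf(params["P"], scale=h["s_P"]).sum()
        expected += stats.t.logpdf(params["T"], df=h["nu_T"], scale=h["s_T"]).sum()
        expected += stats.norm.logpdf(params["B"], scale=h["s_B"]).sum()
        expected += stats.halfnorm.logpdf(params["sigma"], scale=h["tau"]).sum()
        # all effects zero -> mu = L0 for every observation
        expected += stats.norm.logpdf(info.log_y, loc=info.L0, scale=0.5).sum()
        assert lp == pytest.approx(expected)

    def test_out_of_support_is_minus_inf(self):
        info = self.make_design()
        params = self.zero_params(info)
        params["s_A"] = np.array(-1.0)
        assert log_posterior(params, info) == -np.inf
        params = self.zero_params(info)
        params["sigma"][0] = 0.0
        assert log_posterior(params, info) == -np.inf

    def test_noise_free_data_maximises_likelihood_at_truth(self):
        info = self.make_design()
        params = self.zero_params(info)
        # data were generated with E=0.3, A=0.6 and zero noise
        i_a = info.free_index("a")
        truth = {**params}
        truth["E"] = params["E"].copy(); truth["E"][i_a] = 0.3
        truth["A"] = params["A"].copy(); truth["A"][i_a] = 0.6
        # likelihood at the generative values beats any perturbation
        base = log_posterior(truth, info)
        for delta in (0.05, -0.05):
            worse = {**truth, "E": truth["E"] + delta}
            assert log_posterior(worse, info) < base

    def test_gradient_matches_finite_differences(self):
        info = self.make_design()
        packed = _Packed(info)
        rng = np.random.default_rng(3)
        theta = packed.pack(initial_params(info, rng))
        theta += 0.1 * rng.standard_normal(theta.size)
        lp, grad = _grad_logp(packed, theta)
        eps = 1e-6
        for i in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (packed.logp(up) - packed.logp(dn)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_packed_consistent_with_dict_density(self):
        """Sampling-space density differs from the natural-space one only by
        the change-of-variables terms of the reparameterisation."""
        info = self.make_design()
        packed = _Packed(info)
        rng = np.random.default_rng(4)
        params = initial_params(info, rng)
        theta = packed.pack(params)
        nat = packed.unpack(theta)
        for k, v in params.items():
            np.testing.assert_allclose(np.asarray(nat[k]), np.asarray(v),
                                       atol=1e-12)
        nP, nT = len(info.prep_levels), len(info.trans_levels)
        nB, nG = len(info.batch_levels), len(info.group_levels)
        corr = (nP * math.log(nat["s_P"]) + nT * math.log(nat["s_T"])
                + nB * math.log(nat["s_B"]) + nG * math.log(nat["tau"])
                + sum(math.log(float(nat[h])) for h in HYPER_PRIOR_MEANS)
                + float(np.sum(np.log(nat["sigma"] / nat["tau"]))))
        assert packed.logp(theta) == pytest.approx(
            log_posterior(params, info) + corr)


class TestFitAndContrasts:
    def test_invalid_iteration_requests(self):
        df = pd.DataFrame({"enhancer": ["neg_ctrl_1", "neg_ctrl_2"],
                           "dht": [0, 0], "prep": ["p1", "p2"],
                           "transfection": ["t1", "t2"], "batch": [0, 0],
                           "luminescence": [1.0, 1.1]})
        with pytest.raises(ValueError):
            fit_model(df, iterations=0)
        with pytest.raises(ValueError):
            fit_model(df, iterations=100, warmup=100)

    def test_recovery_on_low_noise_data(self, reduced_fit):
        truth, data, post = reduced_fit
        i1 = post.design.free_index("allele_1")
        i2 = post.design.free_index("allele_2")
        E = post.pooled("E")
        contrast = (E[:, i1] - E[:, i2]).mean()
        assert contrast == pytest.approx(0.3, abs=0.05)

    def test_basal_contrast_fold_scale(self, reduced_fit):
        truth, data, post = reduced_fit
        c = contrast_basal(post, "allele_1", "allele_2")
        assert c.lower <= c.mean <= c.upper
        assert c.lower <= math.exp(0.3) <= c.upper
        same = contrast_basal(post, "allele_1", "allele_1")
        assert (same.mean, same.lower, same.upper) == (1.0, 1.0, 1.0)

    def test_negative_control_contrast_is_defined(self, reduced_fit):
        _, _, post = reduced_fit
        c = contrast_basal(post, "allele_1", "neg_ctrl_1")
        assert c.mean > 1.0           # planted E = 0.5 over a pinned control

    def test_induction_and_ratio(self, reduced_fit):
        truth, data, post = reduced_fit
        ind = contrast_induction(post, "allele_1")
        assert ind.lower <= math.exp(1.0) <= ind.upper
        ratio = contrast_induction_ratio(post, "allele_1", "allele_2")
        assert ratio.lower <= math.exp(0.2) <= ratio.upper
        with pytest.raises(KeyError):
            contrast_induction(post, "unknown")

    def test_same_seed_reproduces_draws(self):
        design = LuciferaseDesign(enhancers=("a",), n_preps=1,
                                  n_transfections=1)
        tp = TrueLuciferaseParams(L0=0.0, E={"a": 0.2}, A={"a": 0.1},
                                  P={}, T={}, B={}, sigma=0.1)
        df = simulate_luciferase_dataset(design, tp, seed=3)
        a = fit_model(df, chains=2, iterations=200, warmup=100, seed=11,
                      compute_diagnostics=False)
        b = fit_model(df, chains=2, iterations=200, warmup=100, seed=11,
                      compute_diagnostics=False)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_two_seeds_overlapping_cis(self, reduced_fit):
        truth, data, post = reduced_fit
        other = fit_model(data, chains=2, iterations=1200, warmup=600, seed=99)
        c1 = contrast_basal(post, "allele_1", "allele_2")
        c2 = contrast_basal(other, "allele_1", "allele_2")
        assert c1.lower < c2.upper and c2.lower < c1.upper


class TestDiagnostics:
    def test_well_mixed_versus_disjoint_chains(self, reduced_fit):
        _, _, post = reduced_fit
        diag = post.diagnostics
        assert set(["parameter", "rhat", "ess"]) <= set(diag.columns)
        assert (diag["ess"] <= 2 * 600 + 1).all()
        # constructed failure: two chains around disjoint means
        import copy
        broken = copy.copy(post)
        draws = {k: v.copy() for k, v in post.draws.items()}
        draws["E"][1] += 50.0
        broken.draws = draws
        bad = diagnostics(broken)
        assert bad.set_index("parameter").filter(like="E", axis=0)["rhat"].max() > 1.5

    def test_single_chain_flagged(self):
        design = LuciferaseDesign(enhancers=("a",), n_preps=1,
                                  n_transfections=1)
        tp = TrueLuciferaseParams(L0=0.0, E={}, A={}, P={}, T={}, B={},
                                  sigma=0.1)
        df = simulate_luciferase_dataset(design, tp, seed=0)
        post = fit_model(df, chains=1, iterations=100, warmup=50, seed=0)
        assert not post.converged
        with pytest.raises(ValueError):
            diagnostics(post)
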