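"""Three-step offset GLM: oracle agreement, dispersion recovery, Wald
inference, and the per-gene driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

import pbulk
from pbulk.aggregate import PseudobulkDataset
from pbulk.glm import bh_fdr, fit_gene, nb_loglik
from pbulk.simulate import SubjectDesign


def _random_instance(rng, n=6):
    """Random two-group subject-level data with positive group totals."""
    x = np.array([0] * (n // 2) + [1] * (n - n // 2), dtype=float)
    s = rng.uniform(0.5, 5.0, n)
    y = rng.poisson(s * np.exp(0.4 + 0.6 * x))
    y[0] += 1
    y[-1] += 1
    return y.astype(float), x, np.log(s), s


def _pb(y, s, x):
    n = len(y)
    return (
        PseudobulkDataset(
            agg_counts=np.asarray(y, dtype=int)[:, None],
            subject_offsets=np.asarray(s, dtype=float),
            subject_ids=np.array([f"s{i}" for i in range(n)]),
            gene_ids=np.array(["g"]),
        ),
        SubjectDesign(np.array([f"s{i}" for i in range(n)]), np.asarray(x, dtype=int)),
    )


class TestPoissonIRLS:
    def test_saturated_two_group_closed_form(self):
        # cases: total Y=20 over total s=10; controls: 10 over 10
        y = np.array([12.0, 8.0, 6.0, 4.0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        s = np.array([6.0, 4.0, 5.0, 5.0])
        fit = pbulk.fit_poisson_irls(y, x, np.log(s))
        assert fit.converged
        assert abs(fit.beta1 - np.log(2.0)) < 1e-10
        assert abs(fit.beta0_prime - 0.0) < 1e-10

    def test_depends_only_on_group_totals(self, rng):
        y, x, lo, s = _random_instance(rng, n=8)
        fit = pbulk.fit_poisson_irls(y, x, lo)
        # swap members within groups: same totals, same fit
        perm = np.array([1, 0, 2, 3, 5, 4, 7, 6])
        fit2 = pbulk.fit_poisson_irls(y[perm], x[perm], lo[perm])
        assert abs(fit.beta1 - fit2.beta1) < 1e-12

    def test_matches_generic_optimizer_and_statsmodels(self, rng):
        import statsmodels.api as sm

        y, x, lo, s = _random_instance(rng)
        fit = pbulk.fit_poisson_irls(y, x, lo)

        def nll(beta):
            mu = np.exp(lo + beta[0] + x * beta[1])
            return -np.sum(y * np.log(mu) - mu)

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 10000, "maxfev": 10000})
        assert abs(fit.beta1 - res.x[1]) < 1e-8

        sm_fit = sm.GLM(y, np.column_stack([np.ones_like(x), x]),
                        family=sm.families.Poisson(), offset=lo).fit()
        assert abs(fit.beta1 - sm_fit.params[1]) < 1e-8
        assert abs(fit.se_beta1 - sm_fit.bse[1]) < 1e-5

    def test_separation_sentinels(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        lo = np.zeros(4)
        f = pbulk.fit_poisson_irls(np.array([0.0, 0, 3, 2]), x, lo)
        assert not f.converged and f.beta1 == -np.inf and f.flag == "cases_zero"
        f = pbulk.fit_poisson_irls(np.array([3.0, 2, 0, 0]), x, lo)
        assert f.beta1 == np.inf and f.flag == "controls_zero"
        assert np.isnan(pbulk.wald_test(f).p_value)

    def test_nonfinite_offset_rejected(self):
        with pytest.raises(ValueError):
            pbulk.fit_poisson_irls(np.ones(4), np.array([0.0, 0, 1, 1]),
                                   np.array([0.0, np.inf, 0, 0]))


class TestClosedForm:
    def test_equal_group_means_give_zero(self):
        pb, design = _pb([5, 5, 5, 5], [1, 1, 1, 1], [0, 0, 1, 1])
        b0, b1 = pbulk.closed_form_two_group(pb, design)
        assert b1[0] == 0.0

    def test_direct_substitution(self):
        pb, design = _pb([12, 8, 6, 4], [6, 4, 5, 5], [1, 1, 0, 0])
        b0, b1 = pbulk.closed_form_two_group(pb, design)
        assert abs(b0[0] - np.log(1.0)) < 1e-14
        assert abs(b1[0] - np.log(2.0)) < 1e-14

    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_with_irls(self, seed):
        rng = np.random.default_rng(seed)
        y, x, lo, s = _random_instance(rng)
        pb, design = _pb(y, s, x)
        b0, b1 = pbulk.closed_form_two_group(pb, design)
        fit = pbulk.fit_poisson_irls(y, x, lo)
        assert fit.converged
        assert abs(fit.beta1 - b1[0]) < 1e-10
        assert abs(fit.beta0_prime - b0[0]) < 1e-10


class TestDispersion:
    def test_poisson_data_clamps_to_zero(self, rng):
        phis = []
        for _ in range(20):
            mu = rng.uniform(2, 20, 200)
            y = rng.poisson(mu)
            phis.append(pbulk.estimate_dispersion(y, mu))
        assert np.median(phis) < 0.05

    def test_recovers_true_dispersion(self, rng):
        phi_true = 0.5
        phis = []
        for _ in range(20):
            mu = rng.uniform(5, 20, 200)
            lam = rng.gamma(1 / phi_true, phi_true * mu)
            y = rng.poisson(lam)
            phis.append(pbulk.estimate_dispersion(y, mu))
        assert abs(np.median(phis) - phi_true) / phi_true < 0.2

    def test_degenerate_inputs(self):
        assert pbulk.estimate_dispersion(np.array([3.0]), np.array([2.0])) == 0.0
        assert pbulk.estimate_dispersion(np.zeros(10), np.full(10, 0.5)) == 0.0

    def test_cox_reid_raises_estimate(self, rng):
        # the adjustment compensates the two fitted coefficients, so the
        # adjusted estimate is no smaller than the plain profile ML one
        mu = rng.uniform(5, 20, 40)
        y = rng.poisson(rng.gamma(2.0, 0.5 * mu))
        x = np.array([0.0, 1.0] * 20)
        plain = pbulk.estimate_dispersion(y, mu, x=x, method="ml", cox_reid=False)
        adj = pbulk.estimate_dispersion(y, mu, x=x, method="ml", cox_reid=True)
        assert adj >= plain

    def test_ml_variant_recovers_true_dispersion(self, rng):
        phi_true = 0.5
        phis = []
        for _ in range(20):
            mu = rng.uniform(5, 20, 200)
            y = rng.poisson(rng.gamma(1 / phi_true, phi_true * mu))
            phis.append(pbulk.estimate_dispersion(y, mu, method="ml"))
        assert abs(np.median(phis) - phi_true) / phi_true < 0.2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pbulk.estimate_dispersion(np.ones(10), np.ones(10), method="nope")


class TestNBRefit:
    def test_phi_zero_equals_poisson(self, rng):
        y, x, lo, s = _random_instance(rng)
        a = pbulk.fit_poisson_irls(y, x, lo)
        b = pbulk.refit_nb(y, x, lo, 0.0)
        assert a.beta1 == b.beta1 and a.se_beta1 == b.se_beta1

    def test_matches_brute_force_nb_mle(self, rng):
        y, x, lo, s = _random_instance(rng, n=10)
        phi = 0.4
        fit = pbulk.refit_nb(y, x, lo, phi)

        def nll(beta):
            mu = np.exp(lo + beta[0] + x * beta[1])
            return -nb_loglik(y, mu, phi)

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        assert abs(fit.beta1 - res.x[1]) < 1e-7

    def test_group_constant_offsets_leave_beta1_at_poisson(self):
        # when offsets are equal within each group the NB score equations
        # reduce to the same group-total conditions as Poisson
        y = np.array([7.0, 12.0, 4.0, 6.0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        lo = np.log(np.array([2.0, 2.0, 3.0, 3.0]))
        a = pbulk.fit_poisson_irls(y, x, lo)
        b = pbulk.refit_nb(y, x, lo, 0.7)
        assert abs(a.beta1 - b.beta1) < 1e-8
        assert b.se_beta1 > a.se_beta1

    def test_se_nondecreasing_in_dispersion(self, rng):
        y, x, lo, s = _random_instance(rng, n=12)
        ses = [pbulk.refit_nb(y, x, lo, phi).se_beta1
               for phi in (0.0, 0.1, 0.3, 0.6, 1.0, 2.0)]
        assert np.all(np.diff(ses) >= -1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            pbulk.refit_nb(np.ones(4), np.array([0.0, 0, 1, 1]), np.zeros(4), -0.1)


class TestWald:
    def test_zero_effect_gives_p_one(self):
        fit = pbulk.GLMFit(0.0, 0.0, 0.5, converged=True)
        assert pbulk.wald_test(fit).p_value == 1.0

    def test_normal_quantile(self):
        fit = pbulk.GLMFit(0.0, 1.959964, 1.0, converged=True)
        assert abs(pbulk.wald_test(fit).p_value - 0.05) < 1e-6

    def test_sign_symmetric(self):
        a = pbulk.wald_test(pbulk.GLMFit(0.0, 0.7, 0.2, converged=True))
        b = pbulk.wald_test(pbulk.GLMFit(0.0, -0.7, 0.2, converged=True))
        assert a.p_value == b.p_value


class TestRunPseudobulk:
    def test_empty_gene_table(self, small_dataset):
        pb = small_dataset["pb"]
        empty = PseudobulkDataset(
            agg_counts=pb.agg_counts[:, :0],
            subject_offsets=pb.subject_offsets,
            subject_ids=pb.subject_ids,
            gene_ids=pb.gene_ids[:0],
        )
        out = pbulk.run_pseudobulk_dge(empty, small_dataset["design"])
        assert len(out) == 0 and "p" in out.columns

    def test_subject_permutation_invariance(self, small_dataset, rng):
        pb, design = small_dataset["pb"], small_dataset["design"]
        res = pbulk.run_pseudobulk_dge(pb, design)
        perm = rng.permutation(design.n_subjects)
        design_p = SubjectDesign(design.subject_ids[perm], design.condition[perm])
        res_p = pbulk.run_pseudobulk_dge(pb, design_p)
        # exchangeability up to float summation order (the dispersion
        # optimizer resolves its argmax to ~1e-5 relative)
        assert (res["gene_id"] == res_p["gene_id"]).all()
        np.testing.assert_allclose(res["beta1"], res_p["beta1"], atol=1e-7)
        np.testing.assert_allclose(res["se"], res_p["se"], rtol=1e-4, atol=1e-7)
        np.testing.assert_allclose(res["p"], res_p["p"], rtol=1e-3, atol=1e-7)
        np.testing.assert_allclose(res["dispersion"], res_p["dispersion"],
                                   rtol=1e-3, atol=1e-5)

    def test_three_step_pipeline_fields(self, small_dataset):
        res = pbulk.run_pseudobulk_dge(small_dataset["pb"], small_dataset["design"])
        conv = res[res["converged"]]
        assert len(conv) > 30
        np.testing.assert_allclose(conv["log2fc"], conv["beta1"] / np.log(2))
        # small-sample Wald reference: t with n_subjects - 2 df
        df = small_dataset["design"].n_subjects - 2
        np.testing.assert_allclose(
            conv["p"], 2 * stats.t.sf(np.abs(conv["z"]), df), atol=1e-12
        )
        assert (conv["dispersion"] >= 0).all()

    def test_poisson_only_flag(self, small_dataset):
        res = pbulk.run_pseudobulk_dge(small_dataset["pb"], small_dataset["design"],
                                       poisson_only=True)
        assert (res.loc[res["converged"], "dispersion"] == 0).all()


def test_bh_fdr_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=50)
    p[5] = np.nan
    ours = bh_fdr(p)
    ok = np.isfinite(p)
    ref = multipletests(p[ok], method="fdr_bh")[1]
    np.testing.assert_allclose(ours[ok], ref)
    assert np.isnan(ours[5])
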