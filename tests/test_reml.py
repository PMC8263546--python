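import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clonalgp as cg
from clonalgp.reml import _WoodburyReml


def dense_restricted_loglik(y, X, Z, kernels, theta):
    """Direct dense evaluation of the restricted log-likelihood (oracle)."""
    *sig, s2e = theta
    n = len(y)
    V = s2e * np.eye(n)
    for s, K in zip(sig, kernels):
        V += s * (Z @ K @ Z.T)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + y @ P @ y)


def _toy_instance(seed=3):
    rng = np.random.default_rng(seed)
    c, n = 6, 14
    K = rng.standard_normal((c, 10))
    K = K @ K.T
    K /= np.trace(K) / c
    idx = rng.integers(0, c, n)
    X = np.ones((n, 1))
    Z = np.zeros((n, c))
    Z[np.arange(n), idx] = 1
    g = rng.multivariate_normal(np.zeros(c), 2.0 * K)
    y = 5.0 + g[idx] + rng.standard_normal(n)
    return y, X, Z, idx, K


class TestRemlAgainstOracle:
    def test_optimum_matches_grid_search(self):
        """The fitted restricted likelihood matches a dense two-stage grid
        search over (sigma2_g, sigma2_e) on a six-clone instance."""
        y, X, Z, idx, K = _toy_instance()
        design = cg.reml.Design(y=y, X=X, columns=["intercept"],
                                clone_index=idx, clone_ids=list("abcdef"))
        kernels = {"G_A": cg.KernelMatrix("G_A", K, list("abcdef"))}
        spec = cg.ModelSpec("A", fixed_factors=())
        fit = cg.reml_fit(design, kernels, spec)
        assert fit.converged

        vy = np.var(y, ddof=1)
        lo, hi = vy * 1e-3, vy * 4
        best = -np.inf
        center = None
        grid = np.geomspace(lo, hi, 40)
        for s2g in grid:
            for s2e in grid:
                ll = dense_restricted_loglik(y, X, Z, [K], (s2g, s2e))
                if ll > best:
                    best, center = ll, (s2g, s2e)
        # zoom around the coarse maximum
        for s2g in np.linspace(center[0] * 0.7, center[0] * 1.4, 60):
            for s2e in np.linspace(center[1] * 0.7, center[1] * 1.4, 60):
                ll = dense_restricted_loglik(y, X, Z, [K], (s2g, s2e))
                best = max(best, ll)
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_woodbury_equals_dense_likelihood(self):
        y, X, Z, idx, K = _toy_instance(seed=9)
        eng = _WoodburyReml(y, X, idx, [K])
        for theta in [(1.0, 1.0), (0.3, 2.5), (4.0, 0.2)]:
            eng.prepare(np.array(theta))
            dense = dense_restricted_loglik(y, X, Z, [K], theta)
            assert eng.loglik == pytest.approx(dense, abs=1e-8)


class TestDesign:
    def test_fixed_design_columns(self, small_sim):
        _, g, ph, _ = small_sim
        sub = ph[ph["region"] == "R1"].copy()
        sub = sub[sub["trial"] == sub["trial"].iloc[0]]
        spec = cg.ModelSpec("A", fixed_factors=("year", "crop", "region"))
        d = cg.build_design(sub, spec, g.clone_ids)
        # single-level region dropped; intercept + year + crop contrasts remain
        n_years = sub["year"].nunique()
        assert len(d.columns) == 1 + (n_years - 1) + 2
        assert not any(c.startswith("region") for c in d.columns)

    def test_het_column_centred(self, small_sim):
        _, g, ph, _ = small_sim
        het = cg.heterozygosity(g)
        spec = cg.ModelSpec("AH")
        d = cg.build_design(ph, spec, g.clone_ids, het, on_aliased="drop")
        j = d.columns.index("het")
        assert abs(d.X[:, j].mean()) < 1e-12

    def test_repeated_records_share_clone_index(self, small_sim):
        _, g, ph, _ = small_sim
        spec = cg.ModelSpec("A")
        d = cg.build_design(ph, spec, g.clone_ids, on_aliased="drop")
        counts = ph.groupby("clone").size()
        clone = counts.idxmax()
        rows = np.where(ph["clone"].to_numpy() == clone)[0]
        assert len(set(d.clone_index[rows])) == 1

    def test_aliased_columns_raise_by_default(self, small_sim):
        _, g, ph, _ = small_sim
        spec = cg.ModelSpec("A")  # trial nested in region x year -> aliased
        with pytest.raises(ValueError, match="aliased"):
            cg.build_design(ph, spec, g.clone_ids)


@pytest.fixture(scope="module")
def fits(small_sim, small_kernels):
    _, g, ph, _ = small_sim
    het = cg.heterozygosity(g)
    out = {}
    for label in ("A", "AD", "ADE"):
        spec = cg.ModelSpec(label)
        d = cg.build_design(ph, spec, g.clone_ids, het, on_aliased="drop")
        out[label] = cg.reml_fit(d, small_kernels, spec)
    return out


class TestRemlFit:

    def test_variances_nonnegative(self, fits):
        for fit in fits.values():
            assert all(est >= 0 for est, _ in fit.var_components.values())

    def test_loglik_nondecreasing_in_nesting(self, fits):
        # pinned boundary components sit at a tiny positive floor, so the
        # larger model can trail the smaller optimum by convergence noise
        assert fits["AD"].loglik >= fits["A"].loglik - 1e-4
        assert fits["ADE"].loglik >= fits["AD"].loglik - 1e-4

    def test_gpcp_is_sum_of_genetic_blups(self, fits):
        fit = fits["ADE"]
        total = sum(fit.blups[k] for k in fit.spec.random_kernels)
        np.testing.assert_allclose(fit.gpcp, total)

    def test_heritability_ordering(self, fits):
        for fit in fits.values():
            h2, H2 = cg.heritabilities(fit)
            assert 0 <= h2 <= H2 <= 1 + 1e-9

    def test_pure_noise_pins_at_boundary(self):
        rng = np.random.default_rng(0)
        c, n = 60, 120
        K = rng.standard_normal((c, 200))
        K = K @ K.T
        K /= np.trace(K) / c
        idx = rng.integers(0, c, n)
        y = rng.standard_normal(n)
        design = cg.reml.Design(y=y, X=np.ones((n, 1)), columns=["intercept"],
                                clone_index=idx, clone_ids=[str(i) for i in range(c)])
        kernels = {"G_A": cg.KernelMatrix("G_A", K, [str(i) for i in range(c)])}
        fit = cg.reml_fit(design, kernels, cg.ModelSpec("A", fixed_factors=()))
        est, _ = fit.var_components["G_A"]
        assert fit.boundary_flags["G_A"] and est <= 2e-6 * np.var(y, ddof=1)
        assert np.isnan(fit.var_components["G_A"][1])  # no SE when pinned

    def test_gebv_invariant_to_clone_permutation(self, small_sim, small_kernels):
        _, g, ph, _ = small_sim
        spec = cg.ModelSpec("A")
        d = cg.build_design(ph, spec, g.clone_ids, on_aliased="drop")
        fit = cg.reml_fit(d, small_kernels, spec)

        rng = np.random.default_rng(5)
        perm = rng.permutation(g.n_clones)
        ids_p = [g.clone_ids[i] for i in perm]
        K = small_kernels["G_A"].values[np.ix_(perm, perm)]
        kernels_p = {"G_A": cg.KernelMatrix("G_A", K, ids_p)}
        d_p = cg.build_design(ph, spec, ids_p, on_aliased="drop")
        fit_p = cg.reml_fit(d_p, kernels_p, spec)
        np.testing.assert_allclose(fit_p.gebv, fit.gebv[perm], atol=1e-4)

    def test_identity_kernels_flag_singular_information(self):
        """Two identical identity-pattern kernels with one record per clone
        are non-identifiable; the fit must fall back and warn, not split
        the variance arbitrarily with bogus SEs."""
        rng = np.random.default_rng(1)
        c = 50
        ids = [str(i) for i in range(c)]
        I = np.eye(c)
        y = rng.standard_normal(c) * 2
        design = cg.reml.Design(y=y, X=np.ones((c, 1)), columns=["intercept"],
                                clone_index=np.arange(c), clone_ids=ids)
        kernels = {"K1": cg.KernelMatrix("K1", I, ids),
                   "K2": cg.KernelMatrix("K2", I, ids)}
        spec = cg.ModelSpec("custom", random_kernels=("K1", "K2"))
        fit = cg.reml_fit(design, kernels, spec)
        assert "singular average-information matrix" in fit.warnings


class TestHeritabilities:
    def test_published_ad_decomposition(self):
        """Printed complex-trait AD components give h2 = 0.41, H2 = 0.70."""
        h2, H2 = cg.heritability_from_components(
            var_a=49.91, var_d=35.84, var_resid=36.08
        )
        assert round(h2, 2) == 0.41
        assert round(H2, 2) == 0.70

    def test_zero_genetic_variance(self):
        assert cg.heritability_from_components(0.0, 0.0, 0.0, 36.0) == (0.0, 0.0)

    def test_no_residual_limit(self):
        h2, H2 = cg.heritability_from_components(50.0, 0.0, 0.0, 0.0)
        assert h2 == pytest.approx(1.0)


class TestLrt:
    def test_published_worked_example(self):
        """Printed model log-likelihoods -45,439.59 (additive) and
        -45,403.70 (additive+dominance) give stat 71.78, significant."""
        res = cg.lrt_from_loglik(-45403.70, -45439.59)
        assert res.stat == pytest.approx(71.78)
        assert res.significant

    def test_identical_fits(self):
        res = cg.lrt_from_loglik(-100.0, -100.0)
        assert res.stat == 0.0 and not res.significant

    def test_chi2_tail_at_four(self):
        res = cg.lrt_from_loglik(-98.0, -100.0)
        assert res.stat == pytest.approx(4.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1))
        assert res.significant

    def test_non_nested_raises(self, small_sim, small_kernels):
        _, g, ph, _ = small_sim
        fits = {}
        for label, ks in (("A", ("G_A",)), ("custom", ("G_D",))):
            spec = cg.ModelSpec(label, random_kernels=ks if label == "custom" else None)
            d = cg.build_design(ph, spec, g.clone_ids, on_aliased="drop")
            fits[label] = cg.reml_fit(d, small_kernels, spec)
        with pytest.raises(ValueError, match="nested"):
            cg.lrt(fits["A"], fits["custom"])
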