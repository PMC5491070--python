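"""Box-Cox, mixed-model fitting, permutation p-values and q-values."""

import math
import warnings

import numpy as np
import pytest
from scipy import optimize, stats

from orofaecal.diff_abundance import (boxcox_fit, boxcox_transform,
                                      diff_abundance_scan, estimate_pi0,
                                      heatmap_support, lme_fit_ml,
                                      otu_permutation_pvalue, storey_qvalue)
from orofaecal.core_tables import prevalence_filter
from orofaecal.synthetic_data import SyntheticSpec, generate_dataset


DESIGN_IND = np.array([f"b{k}" for k in range(8) for _ in range(2)]
                      + [f"s{k}" for k in range(24)])
DESIGN_REG = np.array(["oral", "faecal"] * 8 + ["oral"] * 12 + ["faecal"] * 12)


class TestBoxCox:
    def test_log_branch_and_identity_branch(self):
        assert boxcox_transform(np.array([math.e]), 0.0)[0] == \
            pytest.approx(1.0)
        y = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(boxcox_transform(y, 1.0), y - 1.0)

    def test_transform_monotone_for_any_lambda(self):
        y = np.linspace(0.1, 20, 50)
        for lam in (-2.0, -0.5, 0.0, 0.5, 2.0):
            z = boxcox_transform(y, lam)
            assert np.all(np.diff(z) > 0)

    def test_nonpositive_after_shift_errors(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_fit(np.array([-2.0, 1.0]), shift=1.0)

    def test_lognormal_recovers_lambda_zero(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(0, 1, 500))
        fit = boxcox_fit(y)
        assert abs(fit.lambda_) < 0.2

    def test_gaussian_positive_recovers_lambda_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 5, 500)
        fit = boxcox_fit(y)
        assert abs(fit.lambda_ - 1.0) < 0.2

    def test_matches_scipy_profile_mle(self):
        """Independent cross-check against scipy's Box-Cox lambda."""
        rng = np.random.default_rng(2)
        y = rng.gamma(3.0, 2.0, 300)
        fit = boxcox_fit(y)
        lam_scipy = stats.boxcox_normmax(y, method="mle")
        assert fit.lambda_ == pytest.approx(lam_scipy, abs=1e-3)


def _oracle_deviance(y, X, individual, lam_grid_refine=3):
    """Brute-force ML deviance: 2-D grid over both variance components,
    fixed effects profiled by GLS at each grid point.  Fully independent of
    the package's profiled-likelihood path (builds dense covariance)."""
    y = np.asarray(y, float)
    n = y.size
    _, codes = np.unique(individual, return_inverse=True)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0

    def neg2ll(s2b, s2e):
        V = s2e * np.eye(n) + s2b * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        return (n * math.log(2 * math.pi) + logdet + r @ Vi @ r)

    lo_b, hi_b = 1e-8, 10 * y.var() + 1e-6
    lo_e, hi_e = 1e-6, 10 * y.var() + 1e-6
    best = None
    for _ in range(lam_grid_refine):
        gb = np.linspace(lo_b, hi_b, 40)
        ge = np.linspace(lo_e, hi_e, 40)
        vals = np.array([[neg2ll(b, e) for e in ge] for b in gb])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = vals[i, j]
        span_b = gb[1] - gb[0]
        span_e = ge[1] - ge[0]
        lo_b, hi_b = max(1e-10, gb[i] - span_b), gb[i] + span_b
        lo_e, hi_e = max(1e-10, ge[j] - span_e), ge[j] + span_e
    # final polish with a local optimiser on log-variances
    res = optimize.minimize(
        lambda t: neg2ll(math.exp(t[0]), math.exp(t[1])),
        [math.log(max(gb[i], 1e-8)), math.log(max(ge[j], 1e-8))],
        method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return min(best, res.fun)


class TestLmeFit:
    def test_zero_group_variance_collapses_to_ols(self):
        rng = np.random.default_rng(3)
        n = 24
        ind = np.array([f"i{k % 8}" for k in range(n)])
        reg = np.array(["oral", "faecal"] * (n // 2))
        x = (reg == "oral").astype(float)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)  # no individual effect
        fit = lme_fit_ml(y, region=reg, individual=ind)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if fit.var_individual < 1e-8:
            assert fit.fixed_effects["intercept"] == \
                pytest.approx(beta_ols[0], abs=1e-6)
            assert fit.fixed_effects["region[oral]"] == \
                pytest.approx(beta_ols[1], abs=1e-6)

    def test_single_individual_is_plain_ols(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=10)
        fit = lme_fit_ml(y, individual=np.array(["only"] * 10))
        assert fit.var_individual == pytest.approx(0.0, abs=1e-10)
        assert fit.fixed_effects["intercept"] == pytest.approx(y.mean())
        # ML residual variance (divides by n)
        assert fit.var_residual == pytest.approx(y.var(), rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_deviance_matches_gridsearch_oracle(self, seed):
        """Small balanced design: deviance agrees with the dense-covariance
        2-D variance grid search within 1e-4."""
        rng = np.random.default_rng(seed)
        ind = np.repeat([f"i{k}" for k in range(4)], 2)
        reg = np.array(["oral", "faecal"] * 4)
        b = np.repeat(rng.normal(0, 1.0, 4), 2)
        y = 1.0 + b + rng.normal(0, 0.7, 8)
        fit = lme_fit_ml(y, region=reg, individual=ind)
        X = np.column_stack([np.ones(8), (reg == "oral").astype(float)])
        oracle = _oracle_deviance(y, X, ind)
        assert fit.deviance == pytest.approx(oracle, abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        """Independent cross-check against statsmodels' ML fit."""
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        b = {u: rng.normal(0, 0.8) for u in np.unique(DESIGN_IND)}
        y = (0.4 * (DESIGN_REG == "oral")
             + np.array([b[u] for u in DESIGN_IND])
             + rng.normal(0, 1, DESIGN_IND.size))
        fit = lme_fit_ml(y, region=DESIGN_REG, individual=DESIGN_IND)
        X = np.column_stack([np.ones(y.size),
                             (DESIGN_REG == "oral").astype(float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = sm.MixedLM(y, X, groups=DESIGN_IND).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.fixed_effects["region[oral]"] == \
            pytest.approx(sm_fit.fe_params[1], abs=1e-4)

    def test_offset_moves_to_response(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=16)
        off = rng.normal(size=16)
        ind = np.repeat([f"i{k}" for k in range(8)], 2)
        a = lme_fit_ml(y, individual=ind, offset=off)
        b = lme_fit_ml(y - off, individual=ind)
        assert a.deviance == pytest.approx(b.deviance, abs=1e-10)

    def test_nested_deviance_never_increases(self):
        """Adding the region term can only improve the ML deviance."""
        rng = np.random.default_rng(7)
        for sim in range(200):
            n_ind = int(rng.integers(3, 8))
            reps = int(rng.integers(1, 4))
            ind = np.repeat([f"i{k}" for k in range(n_ind)], reps)
            reg = rng.choice(["oral", "faecal"], size=ind.size)
            if len(set(reg)) < 2:
                reg[0] = "oral" if reg[1] == "faecal" else "faecal"
            y = rng.normal(size=ind.size)
            full = lme_fit_ml(y, region=reg, individual=ind)
            null = lme_fit_ml(y, individual=ind)
            assert null.deviance - full.deviance >= -1e-6


class TestOtuPermutation:
    def test_constant_counts_warn_and_return_null(self):
        counts = np.full(DESIGN_IND.size, 7.0)
        totals = np.full(DESIGN_IND.size, 5000.0)
        with pytest.warns(RuntimeWarning, match="constant"):
            res = otu_permutation_pvalue(counts, totals, DESIGN_REG,
                                         DESIGN_IND, n_perm=49, seed=0)
        assert res.deviance_change == 0.0 and res.p == 1.0

    def test_p_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(8)
        effect = np.where(DESIGN_REG == "oral", 400.0, 5.0)
        counts = rng.poisson(effect)
        totals = np.full(DESIGN_IND.size, 5000.0)
        res = otu_permutation_pvalue(counts, totals, DESIGN_REG, DESIGN_IND,
                                     n_perm=99, seed=1)
        assert res.p == pytest.approx(1 / 100)

    def test_identical_seed_identical_p(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(40, DESIGN_IND.size)
        totals = rng.poisson(5000, DESIGN_IND.size).astype(float)
        a = otu_permutation_pvalue(counts, totals, DESIGN_REG, DESIGN_IND,
                                   n_perm=99, seed=42)
        b = otu_permutation_pvalue(counts, totals, DESIGN_REG, DESIGN_IND,
                                   n_perm=99, seed=42)
        assert a.p == b.p and a.deviance_change == b.deviance_change

    def test_bootstrap_variant_runs(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(40, DESIGN_IND.size)
        totals = rng.poisson(5000, DESIGN_IND.size).astype(float)
        res = otu_permutation_pvalue(counts, totals, DESIGN_REG, DESIGN_IND,
                                     n_perm=49, seed=0, resample="bootstrap")
        assert 0 < res.p <= 1.0


class TestStoreyQvalue:
    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(storey_qvalue(np.ones(4), pi0=1.0), 1.0)

    def test_bh_equivalence_with_pi0_one(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(storey_qvalue(p, pi0=1.0), 0.04)
        # generic BH oracle
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        q = storey_qvalue(p, pi0=1.0)
        m = p.size
        order = np.argsort(p)
        bh = np.minimum.accumulate((p[order] * m
                                    / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(bh, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_pi0_near_one_on_uniform_pvalues(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=1000)
        assert 0.85 <= estimate_pi0(p) <= 1.0

    def test_q_monotone_in_p_and_bounded_by_pi0(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.001, 1.0, 200)
        pi0 = estimate_pi0(p)
        q = storey_qvalue(p, pi0=pi0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= pi0 + 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalue(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            storey_qvalue(np.array([]))


@pytest.fixture(scope="module")
def scanned():
    spec = SyntheticSpec(n_individuals=32, n_paired=8,
                         oral_fraction_unpaired=0.5, n_otus=80,
                         n_differential=8, region_pools=False,
                         concentration_oral=100.0,
                         concentration_faecal=100.0,
                         fraction_chloroplast=0,
                         fraction_unassigned_phylum=0, seed=77)
    ds = generate_dataset(spec)
    prev = prevalence_filter(ds.table, 5)
    scan = diff_abundance_scan(prev, ds.metadata, n_perm=99, seed=1,
                               totals=ds.table.sample_sums().astype(float),
                               tax=ds.taxonomy)
    return ds, prev, scan


class TestScan:
    def test_scan_shape_and_joint_rule(self, scanned):
        _, prev, scan = scanned
        assert len(scan) == prev.n_otus
        ok = scan["p_perm"].notna()
        joint = ok & (scan["p_perm"] < 0.05) & (scan["q"] < 0.05)
        assert (scan["significant"] == joint).all()

    def test_direction_follows_region_contrast_sign(self, scanned):
        _, _, scan = scanned
        ok = scan["p_perm"].notna()
        assert (scan.loc[ok & (scan.region_effect > 0), "direction"]
                == "+oral").all()
        assert (scan.loc[ok & (scan.region_effect <= 0), "direction"]
                == "+faecal").all()

    def test_direction_sign_on_spiked_otus(self, scanned):
        ds, _, scan = scanned
        strong = scan[scan.otu_id.isin(ds.truth.differential_effects)
                      & (scan.p_perm < 0.2)]
        for _, row in strong.iterrows():
            expected = ("+oral" if ds.truth.differential_effects[row.otu_id]
                        > 0 else "+faecal")
            assert row.direction == expected

    def test_scan_invariant_to_otu_order(self, scanned):
        ds, prev, scan = scanned
        rng = np.random.default_rng(0)
        perm = rng.permutation(prev.n_otus)
        shuffled = prev.select_otus([prev.otu_ids[j] for j in perm])
        scan2 = diff_abundance_scan(shuffled, ds.metadata, n_perm=99, seed=1,
                                    totals=ds.table.sample_sums().astype(float))
        merged = scan.set_index("otu_id").join(
            scan2.set_index("otu_id"), rsuffix="_2")
        np.testing.assert_allclose(merged["deviance_change"],
                                   merged["deviance_change_2"], atol=1e-9)
        np.testing.assert_allclose(merged["p_perm"], merged["p_perm_2"])

    def test_heatmap_rows_follow_tree_leaf_order(self, scanned):
        ds, prev, scan = scanned
        forced = scan.copy()
        forced["significant"] = False
        forced.iloc[:6, forced.columns.get_loc("significant")] = True
        frame, newick = heatmap_support(prev, forced, ds.tree)
        assert len(frame) == 6
        sig = set(forced.loc[forced.significant, "otu_id"])
        leaf_order = [n for n in ds.tree.shear(sig).leaf_names()]
        assert list(frame.index) == leaf_order
        assert newick.strip().endswith(";")
        expected = np.log10(prev.select_otus(list(frame.index)).counts.T + 1)
        np.testing.assert_allclose(frame.to_numpy(), expected)
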