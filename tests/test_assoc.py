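import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divsel_gwas.assoc import (
    AssocError,
    LambdaFit,
    apply_genomic_control,
    fit_null_lambda,
    genomic_control,
    qq_data,
    score_markers,
)
from divsel_gwas.genotypes import GenotypeMatrix
from divsel_gwas.pedigree import RelationshipMatrix, build_a_matrix

from conftest import dense_gls_oracle, random_pedigree


def make_gm(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    m = x.shape[1]
    smap = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)], "chrom": "1",
        "pos_bp": np.arange(1, m + 1) * 1000, "allele_counted": "A", "allele_other": "B",
    })
    return GenotypeMatrix([f"i{k}" for k in range(x.shape[0])], smap, x)


def fixed_lambda_fit(a_values, y, lam):
    """LambdaFit at a chosen lambda (bypasses REML) for scoring tests."""
    s, u = np.linalg.eigh(a_values)
    s = np.clip(s, 0, None)
    ids = [f"i{k}" for k in range(len(y))]
    return LambdaFit(lam, 1.0, 0.0, "fixed", False, s, u.T @ y, u.T @ np.ones(len(y)),
                     u.T, ids)


class TestFitNullLambda:
    def test_identity_a_flagged_as_boundary(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=50))
        amat = RelationshipMatrix([str(i) for i in range(50)], np.eye(50))
        fit = fit_null_lambda(y, amat)
        assert fit.boundary

    def test_zero_variance_phenotype_rejected(self):
        amat = RelationshipMatrix([str(i) for i in range(20)], np.eye(20))
        with pytest.raises(AssocError, match="zero variance"):
            fit_null_lambda(pd.Series(np.ones(20)), amat)

    def test_small_n_rejected(self):
        amat = RelationshipMatrix([str(i) for i in range(5)], np.eye(5))
        with pytest.raises(AssocError, match="too small"):
            fit_null_lambda(pd.Series(np.arange(5.0)), amat)

    def test_recovers_variance_ratio_on_deep_pedigree(self):
        """Data simulated with sigma_g^2 / sigma_e^2 = 1: the median REML
        estimate across seeds lands in a factor-of-two band around 1."""
        rng = np.random.default_rng(42)
        ped = random_pedigree(300, rng, n_founders=20)
        amat = build_a_matrix(ped)
        chol = np.linalg.cholesky(amat.values + 1e-9 * np.eye(300))
        lams = []
        for _ in range(12):
            u = chol @ rng.normal(size=300)
            y = pd.Series(u + rng.normal(size=300))
            lams.append(fit_null_lambda(y, amat).lambda_)
        assert 0.6 <= np.median(lams) <= 1.6


class TestScoreMarkers:
    def test_ols_limit_with_identity_a(self):
        rng = np.random.default_rng(1)
        n = 60
        x = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * x + rng.normal(size=n)
        fit = fixed_lambda_fit(np.eye(n), y, 1e-12)
        res = score_markers(pd.Series(y, index=fit.ids), make_gm(x), fit)
        sl = stats.linregress(x, y)
        assert res.beta.iloc[0] == pytest.approx(sl.slope, rel=1e-9)
        assert res.se.iloc[0] == pytest.approx(sl.stderr, rel=1e-9)

    def test_matches_dense_gls_oracle_small(self):
        rng = np.random.default_rng(2)
        n = 12
        ped = random_pedigree(n, rng, n_founders=4)
        amat = build_a_matrix(ped)
        x = rng.binomial(2, 0.5, n).astype(float)
        y = rng.normal(size=n)
        lam = 0.8
        fit = fixed_lambda_fit(amat.values, y, lam)
        res = score_markers(pd.Series(y, index=fit.ids), make_gm(x), fit)
        b, se = dense_gls_oracle(y, x, amat.values, lam)
        assert res.beta.iloc[0] == pytest.approx(b, abs=1e-8)
        assert res.se.iloc[0] == pytest.approx(se, abs=1e-8)

    def test_monomorphic_markers_skipped(self):
        rng = np.random.default_rng(3)
        n = 40
        x = np.column_stack([np.full(n, 2.0), rng.binomial(2, 0.5, n)]).astype(float)
        y = rng.normal(size=n)
        fit = fixed_lambda_fit(np.eye(n), y, 0.5)
        res = score_markers(pd.Series(y, index=fit.ids), make_gm(x), fit)
        assert np.isnan(res.beta.iloc[0]) and np.isfinite(res.beta.iloc[1])

    def test_mean_imputation_of_missing_dosages(self):
        rng = np.random.default_rng(4)
        n = 30
        x = rng.binomial(2, 0.5, n).astype(float)
        xm = x.copy()
        xm[:3] = np.nan
        y = rng.normal(size=n)
        fit = fixed_lambda_fit(np.eye(n), y, 1e-12)
        res = score_markers(pd.Series(y, index=fit.ids), make_gm(xm), fit)
        xf = xm.copy()
        xf[:3] = np.nanmean(xm)
        sl = stats.linregress(xf, y)
        assert res.beta.iloc[0] == pytest.approx(sl.slope, rel=1e-9)

    def test_type_one_error_calibrated_under_null(self):
        """Parametric null draws (y ~ N(0, lam*A + I)) give ~5% rejections."""
        rng = np.random.default_rng(5)
        n = 150
        ped = random_pedigree(n, rng, n_founders=12)
        amat = build_a_matrix(ped)
        lam = 1.0
        s, u = np.linalg.eigh(amat.values)
        s = np.clip(s, 0, None)
        x = rng.binomial(2, 0.4, n).astype(float)
        gm = make_gm(x)
        chol_d = np.sqrt(lam * s + 1.0)
        hits = 0
        n_rep = 2000
        ids = [f"i{k}" for k in range(n)]
        for _ in range(n_rep):
            ystar = chol_d * rng.normal(size=n)
            y = u @ ystar
            fit = LambdaFit(lam, 1.0, 0.0, "fixed", False, s, ystar, u.T @ np.ones(n),
                            u.T, ids)
            res = score_markers(pd.Series(y, index=ids), gm, fit)
            hits += res.p.iloc[0] < 0.05
        rate = hits / n_rep
        assert 0.035 < rate < 0.065  # 99% binomial band around 0.05

    def test_misaligned_ids_rejected(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        fit = fixed_lambda_fit(np.eye(20), y, 0.1)
        with pytest.raises(AssocError, match="ids"):
            score_markers(pd.Series(y, index=[f"z{k}" for k in range(20)]),
                          make_gm(rng.binomial(2, 0.5, 20).astype(float)), fit)


class TestPerMarkerRefit:
    def test_matches_bruteforce_profile_likelihood(self):
        """The rotated per-marker refit equals a dense-V grid/golden
        search over lambda followed by explicit GLS."""
        from scipy import optimize as opt

        rng = np.random.default_rng(9)
        n = 40
        ped = random_pedigree(n, rng, n_founders=6)
        amat = build_a_matrix(ped)
        chol = np.linalg.cholesky(amat.values + 1e-9 * np.eye(n))
        x = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * x + chol @ rng.normal(size=n) + rng.normal(size=n)
        fit = fixed_lambda_fit(amat.values, y, 1.0)
        res = score_markers(pd.Series(y, index=fit.ids), make_gm(x), fit,
                            refit_lambda_per_marker=True)

        xmat = np.column_stack([np.ones(n), x])

        def nll(log_lam):
            v = np.exp(log_lam) * amat.values + np.eye(n)
            vi = np.linalg.inv(v)
            cov = np.linalg.inv(xmat.T @ vi @ xmat)
            b = cov @ xmat.T @ vi @ y
            r = y - xmat @ b
            rss = float(r @ vi @ r)
            sign, logdet = np.linalg.slogdet(v)
            return 0.5 * ((n - 2) * np.log(rss / (n - 2)) + logdet)

        sol = opt.minimize_scalar(nll, bounds=(np.log(1e-5), np.log(1e5)),
                                  method="bounded", options={"xatol": 1e-6})
        b_ref, se_ref = dense_gls_oracle(y, x, amat.values, float(np.exp(sol.x)))
        assert res.beta.iloc[0] == pytest.approx(b_ref, abs=1e-6)
        assert res.se.iloc[0] == pytest.approx(se_ref, abs=1e-6)

    def test_monomorphic_markers_still_skipped(self):
        rng = np.random.default_rng(10)
        n = 30
        y = rng.normal(size=n)
        fit = fixed_lambda_fit(np.eye(n), y, 0.5)
        res = score_markers(pd.Series(y, index=fit.ids),
                            make_gm(np.zeros((n, 1))), fit,
                            refit_lambda_per_marker=True)
        assert np.isnan(res.beta.iloc[0])


class TestOracleEquivalenceAcrossLambdas:
    @pytest.mark.parametrize("lam", [0.01, 0.5, 2.0, 20.0])
    def test_random_instances(self, lam):
        rng = np.random.default_rng(int(lam * 100))
        for _ in range(10):
            n = int(rng.integers(15, 50))
            ped = random_pedigree(n, rng, n_founders=5)
            amat = build_a_matrix(ped)
            x = rng.binomial(2, 0.3, n).astype(float)
            if np.var(x) == 0:
                continue
            y = rng.normal(size=n)
            fit = fixed_lambda_fit(amat.values, y, lam)
            res = score_markers(pd.Series(y, index=fit.ids), make_gm(x), fit)
            b, se = dense_gls_oracle(y, x, amat.values, lam)
            assert res.beta.iloc[0] == pytest.approx(b, abs=1e-8)
            assert res.se.iloc[0] == pytest.approx(se, abs=1e-8)


class TestGenomicControl:
    def test_identity_and_linearity(self):
        m = 500
        q = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
        assert genomic_control(q)[0] == pytest.approx(1.0)
        assert genomic_control(2 * q)[0] == pytest.approx(2.0)

    def test_median_estimator(self):
        m = 1001
        q = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
        factor, _, _ = genomic_control(3 * q, estimator="median")
        assert factor == pytest.approx(3.0, rel=1e-3)

    def test_floor_option(self):
        rng = np.random.default_rng(7)
        draws = 0.5 * rng.chisquare(1, size=2000)
        assert genomic_control(draws)[0] < 1
        assert genomic_control(draws, floor_at_one=True)[0] == 1.0

    def test_corrected_pvalues_recomputed(self):
        rng = np.random.default_rng(8)
        res = pd.DataFrame({"chi2_raw": 2 * rng.chisquare(1, size=300)})
        out, factor = apply_genomic_control(res)
        np.testing.assert_allclose(out["chi2_gc"], res["chi2_raw"] / factor)
        np.testing.assert_allclose(out["p"], stats.chi2.sf(out["chi2_gc"], df=1))

    def test_too_few_markers_rejected(self):
        with pytest.raises(AssocError):
            genomic_control(np.ones(50))


class TestQqData:
    def test_hand_computed_expected_quantiles(self):
        out = qq_data([0.5, 0.1, 0.9, 0.01])
        np.testing.assert_allclose(out["expected"], -np.log10([0.125, 0.375, 0.625, 0.875]))
        np.testing.assert_allclose(out["observed"], -np.log10([0.01, 0.1, 0.5, 0.9]))

    def test_all_ones_give_zero_observed(self):
        out = qq_data(np.ones(10))
        assert (out["observed"] == 0).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(AssocError):
            qq_data([0.0, 0.5])


class TestNullInflationPlausible:
    def test_mean_inflation_in_plausible_range(self):
        """Pure-null runs of the association stage (drift-only scheme,
        polygenic + noise phenotype) give mean inflation factors in a
        plausible band around 1."""
        from divsel_gwas.genotypes import predict_average_genotypes
        from divsel_gwas.simdesign import SimConfig, simulate_experiment

        facs = []
        for s in range(10):
            cfg = SimConfig(
                n_chromosomes=2, n_snps_per_chrom=100, traits=("RFI",),
                founder_maf_range=(0.2, 0.5), sex_effect=0.0, cg_effect_sd=0.0,
                response_counts=(48,) * 9, selection=False, seed=300 + s,
            )
            sim = simulate_experiment(cfg)
            avg = predict_average_genotypes(sim.breeder_genotypes, sim.pedigree)
            ph = sim.phenotypes.set_index("id")["RFI"]
            y = ph.loc[[i for i in avg.ids if i in ph.index]]
            amat = build_a_matrix(sim.pedigree, list(y.index))
            fit = fit_null_lambda(y, amat)
            facs.append(genomic_control(score_markers(y, avg, fit)["chi2_raw"])[0])
        assert 0.9 <= np.mean(facs) <= 1.2
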