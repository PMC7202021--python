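import numpy as np
import pandas as pd
import pytest

from extgen import (
    CovarianceStructure,
    ModelSpec,
    VariancePartition,
    build_model_spec,
    fit_full,
    fit_reduced,
    heritability_from_components,
    lrt,
    lrt_pvalue,
    marginal_methylation_fit,
    restricted_loglik,
    standardize,
)
from extgen.variance_partition import blup, incidence_matrix


def _one_way_spec(k=10, reps=5, sigma2_g=2.0, sigma2_e=1.0, seed=7):
    rng = np.random.default_rng(seed)
    y = np.repeat(rng.normal(0, np.sqrt(sigma2_g), k), reps) + rng.normal(
        0, np.sqrt(sigma2_e), k * reps
    )
    labels = [f"g{i}" for i in range(k)]
    groups = [lab for lab in labels for _ in range(reps)]
    g = CovarianceStructure(np.eye(k), labels)
    z = incidence_matrix(groups, labels)
    return ModelSpec(y=y, plant_ids=[str(i) for i in range(k * reps)], z_g=z, k_g=g)


class TestReducedFit:
    def test_matches_balanced_anova_closed_form(self):
        k, reps = 10, 5
        spec = _one_way_spec(k=k, reps=reps)
        fit = fit_reduced(spec)
        y = spec.y.reshape(k, reps)
        group_means = y.mean(axis=1)
        mse = ((y - group_means[:, None]) ** 2).sum() / (k * (reps - 1))
        msb = reps * ((group_means - y.mean()) ** 2).sum() / (k - 1)
        assert fit.converged
        assert fit.sigma2_e == pytest.approx(mse, rel=1e-6)
        assert fit.sigma2_g == pytest.approx((msb - mse) / reps, rel=1e-6)

    def test_constant_trait_is_degenerate(self):
        spec = _one_way_spec()
        spec.y = np.full_like(spec.y, 3.0)
        fit = fit_reduced(spec)
        assert fit.degenerate
        assert fit.sigma2_g == 0.0 and fit.sigma2_e == 0.0
        assert all(fit.boundary.values())

    def test_scaling_y_scales_components_quadratically(self, small_dataset):
        c = 7.0
        one_way = _one_way_spec()
        f_a = fit_reduced(one_way)
        one_way_scaled = _one_way_spec()
        one_way_scaled.y = one_way.y * c
        f_b = fit_reduced(one_way_scaled)
        assert f_b.sigma2_g == pytest.approx(f_a.sigma2_g * c**2, rel=1e-5)
        assert f_b.sigma2_e == pytest.approx(f_a.sigma2_e * c**2, rel=1e-5)

        ds = small_dataset
        spec = build_model_spec(ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat)
        f1, r1 = fit_full(spec), fit_reduced(spec)
        spec_scaled = build_model_spec(
            ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat
        )
        spec_scaled.y = spec.y * c
        f2, r2 = fit_full(spec_scaled), fit_reduced(spec_scaled)
        s1 = standardize(f1, spec.y_mean, lrt_result=lrt(f1, r1))
        s2 = standardize(f2, spec_scaled.y_mean, lrt_result=lrt(f2, r2))
        assert s2.h2_snp == pytest.approx(s1.h2_snp, abs=1e-4)
        assert s2.lrt_p == pytest.approx(s1.lrt_p, abs=1e-3)


class TestFullFit:
    def test_null_methylation_component_shrinks_to_boundary(self):
        # identity methylation structure on accessions nested in families,
        # simulated with zero methylation variance
        rng = np.random.default_rng(21)
        k_fam, acc_per_fam, reps = 7, 4, 3
        fams = [f"f{i}" for i in range(k_fam)]
        accs = [f"f{i}a{j}" for i in range(k_fam) for j in range(acc_per_fam)]
        fam_of = {a: a.split("a")[0] for a in accs}
        g = CovarianceStructure(np.eye(k_fam), fams)
        m = CovarianceStructure(np.eye(len(accs)), accs, kind="methylation")
        fractions = []
        for _ in range(20):
            fam_eff = dict(zip(fams, rng.normal(0, 1.0, k_fam)))
            rows = []
            for a in accs:
                for r in range(reps):
                    rows.append((a, fam_of[a]))
            y = np.array([fam_eff[f] for _, f in rows]) + rng.normal(0, 1.0, len(rows))
            z_g = incidence_matrix([f for _, f in rows], fams)
            z_m = incidence_matrix([a for a, _ in rows], accs)
            spec = ModelSpec(y=y, plant_ids=[str(i) for i in range(len(rows))],
                             z_g=z_g, k_g=g, z_m=z_m, k_m=m)
            fit = fit_full(spec)
            total = fit.sigma2_g + fit.sigma2_m + fit.sigma2_e
            fractions.append(fit.sigma2_m / total)
        assert np.median(fractions) < 0.05

    def test_zero_methylation_variance_reproduces_reduced_loglik(self, small_dataset):
        ds = small_dataset
        spec = build_model_spec(ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat)
        red = fit_reduced(spec)
        ll_fixed = restricted_loglik(
            spec, sigma2_g=red.sigma2_g, sigma2_m=0.0, sigma2_e=red.sigma2_e
        )
        assert ll_fixed == pytest.approx(red.reml_loglik, abs=1e-6)

    def test_full_loglik_never_below_reduced(self, small_dataset):
        ds = small_dataset
        spec = build_model_spec(ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat)
        full = fit_full(spec)
        red = fit_reduced(spec)
        assert full.reml_loglik >= red.reml_loglik - 1e-6


class TestMarginalFit:
    def test_equals_reduced_fit_on_same_structure(self, small_dataset):
        ds = small_dataset
        spec = build_model_spec(ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat)
        red = fit_reduced(spec)
        # marginal fit against the *genetic* structure: same single-component path
        g_as_m = CovarianceStructure(ds.grm.values, ds.grm.labels, kind="methylation")
        d = ds.phenotypes.data
        spec_m = ModelSpec(
            y=spec.y,
            plant_ids=spec.plant_ids,
            z_m=spec.z_g,
            k_m=g_as_m,
            trait="trait",
        )
        marg = marginal_methylation_fit(spec_m)
        assert marg.sigma2_m == pytest.approx(red.sigma2_g, rel=1e-6, abs=1e-10)
        assert marg.sigma2_e == pytest.approx(red.sigma2_e, rel=1e-6, abs=1e-10)
        assert marg.reml_loglik == pytest.approx(red.reml_loglik, abs=1e-6)

    def test_pure_noise_gives_near_zero_fraction(self):
        rng = np.random.default_rng(31)
        accs = [f"a{i}" for i in range(20)]
        m = CovarianceStructure(np.eye(20), accs, kind="methylation")
        groups = [a for a in accs for _ in range(3)]
        z = incidence_matrix(groups, accs)
        fractions = []
        for _ in range(11):
            y = rng.normal(0, 1, 60)
            spec = ModelSpec(y=y, plant_ids=[str(i) for i in range(60)], z_m=z, k_m=m)
            fractions.append(marginal_methylation_fit(spec).fractions()["methylation"])
        assert np.median(fractions) < 0.1


class TestLrt:
    def _vp(self, loglik):
        return VariancePartition(
            sigma2_g=1.0, sigma2_m=0.1, sigma2_e=1.0, reml_loglik=loglik,
            converged=True, iterations=1,
        )

    @pytest.mark.parametrize(
        "stat,expected_p,places",
        [(7.29, 0.007, 3), (0.0, 1.0, 12)],
    )
    def test_statistic_to_pvalue(self, stat, expected_p, places):
        full, red = self._vp(stat / 2.0), self._vp(0.0)
        got_stat, got_p = lrt(full, red)
        assert got_stat == pytest.approx(stat, abs=1e-12)
        assert round(got_p, places) == expected_p

    def test_large_statistic_below_reporting_threshold(self):
        assert lrt_pvalue(13.14) < 0.001

    def test_reversed_logliks_clip_with_warning(self):
        full, red = self._vp(-1.0), self._vp(0.0)
        with pytest.warns(UserWarning, match="clipped"):
            stat, p = lrt(full, red)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-1.0)


class TestStandardize:
    def test_fraction_arithmetic(self):
        h2_snp, h2_cg = heritability_from_components(4.240, 0.365, 2.494)
        assert round(h2_snp, 3) == 0.597
        h2_snp, _ = heritability_from_components(0.806, 0.308, 3.474)
        assert round(h2_snp, 3) == 0.176

    def test_pure_genetic_fit_has_unit_heritability(self):
        fit = VariancePartition(sigma2_g=2.0, sigma2_m=0.0, sigma2_e=0.0,
                                reml_loglik=0.0, converged=True, iterations=1)
        rep = standardize(fit, y_mean=4.0)
        assert rep.h2_snp == 1.0 and rep.h2_cg == 0.0
        assert rep.i_a == pytest.approx(100 * 2.0 / 16.0)

    def test_zero_mean_rejected(self):
        fit = VariancePartition(sigma2_g=1.0, sigma2_m=None, sigma2_e=1.0,
                                reml_loglik=0.0, converged=True, iterations=1)
        with pytest.raises(ValueError, match="zero trait mean"):
            standardize(fit, y_mean=0.0)

    def test_fractions_sum_to_one(self, small_dataset):
        ds = small_dataset
        spec = build_model_spec(ds.phenotypes, "trait", "spring", grm=ds.grm, methmat=ds.methmat)
        fit = fit_full(spec)
        assert sum(fit.fractions().values()) == pytest.approx(1.0, abs=1e-10)
        rep = standardize(fit, spec.y_mean)
        resid_frac = 1.0 - rep.h2_snp - rep.h2_cg
        assert rep.h2_snp + rep.h2_cg + resid_frac == pytest.approx(1.0, abs=1e-10)


class TestModelSpec:
    def test_missing_trait_values_dropped_per_trait(self, small_dataset):
        ds = small_dataset
        pheno = ds.phenotypes
        data = pheno.data.copy()
        data.loc[data.index[:3], "trait"] = np.nan
        from extgen import PhenotypeTable

        spec = build_model_spec(PhenotypeTable(data), "trait", "spring", grm=ds.grm)
        assert spec.n_obs == len(data) - 3

    def test_unknown_trait_rejected(self, small_dataset):
        with pytest.raises(KeyError, match="not in phenotype table"):
            build_model_spec(small_dataset.phenotypes, "nope", "spring", grm=small_dataset.grm)

    def test_unmapped_group_rejected(self):
        with pytest.raises(KeyError, match="no row"):
            incidence_matrix(["gX"], ["g1", "g2"])


class TestBlup:
    def test_genetic_predictions_track_family_means(self):
        spec = _one_way_spec(k=8, reps=6, sigma2_g=4.0, sigma2_e=0.5, seed=13)
        fit = fit_reduced(spec)
        preds = blup(spec, fit)["genetic"]
        group_means = spec.y.reshape(8, 6).mean(axis=1)
        r = np.corrcoef(preds, group_means - group_means.mean())[0, 1]
        assert r > 0.95
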