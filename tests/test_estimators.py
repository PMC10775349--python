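"""Correction estimators: degenerate equivalences, mixture weights,
model-averaging machinery and MCMC validity against quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doserr.estimators import (
    ESTIMATORS,
    McmcSettings,
    MetaDataset,
    MixtureWeights,
    fit_mcml,
    fit_regression_calibration,
    fit_unadjusted,
    fma,
    quasi_2dmc_bma,
    register_estimator,
)
from doserr.poisson_rr import fit_linear_rr
from doserr.sim_core import GroupedDataset


@pytest.fixture(scope="module")
def zero_error_metadata(zero_error_meta):
    ens, cases = zero_error_meta
    return MetaDataset.from_ensemble(ens, cases)


class TestDegenerateEquivalence:
    def test_all_point_estimators_agree_with_zero_error(self, zero_error_metadata):
        """With all four error SDs zero every dose summary equals the
        central doses, so unadjusted, regression calibration and MCML
        coincide; FMA agrees within its resampling error."""
        meta = zero_error_metadata
        un = fit_unadjusted(meta, form="linear", ci=False)
        rc = fit_regression_calibration(meta, form="linear", ci=False)
        mc = fit_mcml(meta, form="linear", ci=False)
        assert un.alpha_hat == pytest.approx(rc.alpha_hat, rel=1e-6)
        assert mc.alpha_hat == pytest.approx(rc.alpha_hat, rel=1e-4)

        fw = fma(meta, form="linear", k_samples=200, rng_seed=5)
        sd = meta.vectors.dose_vectors.shape[0] * 200
        mc_err = 4 * fw.per_vector["alpha_sd"].iloc[0] / np.sqrt(sd)
        assert np.allclose(fw.aic_weights, fw.aic_weights[0])
        assert fw.central["alpha"] == pytest.approx(rc.alpha_hat, abs=max(mc_err, 0.02))

    def test_bma_posterior_matches_mle_with_degenerate_vectors(self, zero_error_metadata):
        ps = quasi_2dmc_bma(zero_error_metadata, form="linear", rng_seed=6)
        rc = fit_regression_calibration(zero_error_metadata, form="linear", ci=False)
        post_sd = (ps.intervals["alpha"].upper - ps.intervals["alpha"].lower) / 3.92
        assert ps.medians["alpha"] == pytest.approx(rc.alpha_hat, abs=post_sd)

    def test_mcml_single_vector_equals_plain_fit(self, zero_error_metadata):
        data = zero_error_metadata.vectors
        single = GroupedDataset(
            data.cases, data.offsets, data.dose_vectors[0],
            dose_vectors=data.dose_vectors[:1],
        )
        meta = MetaDataset(vectors=single)
        mc = fit_mcml(meta, form="linear")
        plain = fit_linear_rr(data, dose=data.dose_vectors[0], form="linear")
        assert mc.alpha_hat == pytest.approx(plain.alpha_hat, rel=1e-4)
        assert mc.ci_alpha.lower == pytest.approx(plain.ci_alpha.lower, rel=1e-2)
        assert mc.ci_alpha.upper == pytest.approx(plain.ci_alpha.upper, rel=1e-2)


class TestMixtureWeights:
    @settings(max_examples=50, deadline=None)
    @given(
        lam=st.lists(st.floats(-30, 30), min_size=1, max_size=40),
    )
    def test_softmax_matches_brute_force(self, lam):
        """The stable softmax reproduces the reference-category formula
        p_j = e^{l_j} / (1 + sum_k e^{l_k}) exactly."""
        w = MixtureWeights(np.array(lam))
        denom = 1.0 + np.sum(np.exp(lam))
        brute = np.append(np.exp(lam), 1.0) / denom
        assert np.allclose(w.probs, brute, rtol=1e-12, atol=0)
        assert w.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((w.probs > 0) & (w.probs < 1))

    def test_extreme_lambdas_stay_normalised(self):
        w = MixtureWeights(np.array([800.0, -800.0, 0.0]))
        assert w.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestFma:
    def test_aic_weights_sum_to_one(self, zero_error_metadata):
        fw = fma(zero_error_metadata, form="linear", rng_seed=7)
        assert fw.aic_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_sign_downweights_worse_fit(self, zero_error_metadata):
        """exp(-AIC/2) puts more weight on the better-fitting dose
        vector; the sign-flipped variant would invert the ranking."""
        base = zero_error_metadata.vectors
        good = base.dose_vectors[0]
        bad = good * np.array([1.0, 1.0, 1.0, 1.0, 4.0])  # distorted top group
        meta = MetaDataset(vectors=GroupedDataset(
            base.cases, base.offsets, good, dose_vectors=np.vstack([good, bad])
        ))
        fw = fma(meta, form="linear", rng_seed=8)
        aic = fw.per_vector["aic"].to_numpy()
        assert aic[1] > aic[0]  # distorted vector fits worse
        assert fw.aic_weights[0] > fw.aic_weights[1]
        flipped = np.exp(0.5 * (aic - aic.max()))
        flipped /= flipped.sum()
        assert flipped[1] > flipped[0]  # the misprinted sign favours the worse fit

    def test_asymmetric_variant_runs(self, zero_error_metadata):
        fw = fma(zero_error_metadata, form="linear", rng_seed=9, symmetric_sd=False)
        assert np.isfinite(fw.central["alpha"])

    def test_pooled_sample_count(self, zero_error_metadata):
        fw = fma(zero_error_metadata, form="linear", k_samples=50, rng_seed=10)
        m = zero_error_metadata.vectors.dose_vectors.shape[0]
        assert fw.k_samples == 50 and fw.n_dropped == 0
        assert len(fw.aic_weights) == m


class TestBmaSampler:
    def test_posterior_moments_match_dense_quadrature(self):
        """On a tiny two-vector, two-group fixture the MCMC posterior
        moments agree with dense numerical integration of the mixture
        posterior over (kappa, alpha, lambda)."""
        from doserr.cli import make_fixture

        data = make_fixture("two-vector-mixture", rng_seed=3)
        meta = MetaDataset(vectors=data)
        prior_sd = 3.0
        settings_ = McmcSettings(n_burnin=2000, n_keep=5000, prior_sd=prior_sd)
        ps = quasi_2dmc_bma(meta, form="linear", settings=settings_, rng_seed=11)

        # --- quadrature oracle ---------------------------------------
        y = data.cases.astype(float)
        py = data.offsets
        d = data.dose_vectors  # (2, 2)
        anchor = fit_linear_rr(data, dose=d.mean(axis=0), form="linear", ci=False)
        kg = np.linspace(anchor.kappa_hat - 2.0, anchor.kappa_hat + 2.0, 161)
        a_min = -1.0 / d.max()
        ag = np.linspace(max(a_min + 1e-6, anchor.alpha_hat - 6), anchor.alpha_hat + 8, 281)
        lg = np.linspace(-12, 12, 97)

        K, A = np.meshgrid(kg, ag, indexing="ij")
        def ll_vec(dv):
            rr1 = 1 + A * dv[0]
            rr2 = 1 + A * dv[1]
            ok = (rr1 > 0) & (rr2 > 0)
            out = np.full(K.shape, -np.inf)
            mu1 = np.exp(K) * py[0] * rr1
            mu2 = np.exp(K) * py[1] * rr2
            with np.errstate(invalid="ignore", divide="ignore"):
                val = y[0] * np.log(mu1) + y[1] * np.log(mu2) - mu1 - mu2
            out[ok] = val[ok]
            return out

        ll1, ll2 = ll_vec(d[0]), ll_vec(d[1])
        shift = max(ll1.max(), ll2.max())
        L1, L2 = np.exp(ll1 - shift), np.exp(ll2 - shift)
        prior_ka = np.exp(-(K**2 + A**2) / (2 * prior_sd**2))
        e_a = e_k = e_a2 = z = 0.0
        for lam in lg:
            p1 = 1.0 / (1.0 + np.exp(-lam))
            w = (p1 * L1 + (1 - p1) * L2) * prior_ka * np.exp(-lam**2 / (2 * prior_sd**2))
            s = w.sum()
            z += s
            e_a += (w * A).sum()
            e_k += (w * K).sum()
            e_a2 += (w * A * A).sum()
        e_a, e_k, e_a2 = e_a / z, e_k / z, e_a2 / z
        sd_a = np.sqrt(e_a2 - e_a**2)

        # --- MCMC standard errors via per-chain batch means -----------
        chains = ps.chains  # (2, n_keep, 2) -> kappa, alpha
        def mcse(ix):
            bm = []
            for c in chains:
                for b in np.array_split(c[:, ix], 25):
                    bm.append(b.mean())
            return np.std(bm, ddof=1) / np.sqrt(len(bm))

        assert ps.means["alpha"] == pytest.approx(e_a, abs=3 * mcse(1) + 0.02 * sd_a)
        assert ps.means["kappa"] == pytest.approx(e_k, abs=3 * mcse(0) + 0.02)
        post_sd_alpha = np.std(np.concatenate([c[:, 1] for c in chains]))
        assert post_sd_alpha == pytest.approx(sd_a, rel=0.15)

    def test_two_chains_required(self):
        with pytest.raises(ValueError, match="two chains"):
            McmcSettings(n_chains=1)

    def test_bgr_and_acceptance_reported(self, zero_error_metadata):
        ps = quasi_2dmc_bma(zero_error_metadata, form="linear", rng_seed=12)
        assert set(ps.bgr) == {"kappa", "alpha"}
        assert all(v >= 1.0 - 1e-9 or np.isnan(v) for v in ps.bgr.values())
        assert 0 < ps.acceptance_rates["alpha"] < 1
        assert ps.intervals["alpha"].lower <= ps.medians["alpha"] <= ps.intervals["alpha"].upper


class TestRegistry:
    def test_known_estimators_present(self):
        assert {"unadjusted", "regression_calibration", "mcml",
                "quasi_2dmc_bma", "fma"} <= set(ESTIMATORS)

    def test_plugin_slot(self):
        def erc_stub(meta, form, **kw):
            raise NotImplementedError

        register_estimator("extended_regression_calibration_stub", erc_stub)
        try:
            with pytest.raises(ValueError, match="already registered"):
                register_estimator("extended_regression_calibration_stub", erc_stub)
        finally:
            ESTIMATORS.pop("extended_regression_calibration_stub")
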