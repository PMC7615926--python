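"""EM fitting, posterior classification and eligibility assessment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from leakytx.gmm import (
    EmError,
    GmmFit,
    PosteriorCall,
    assess_eligibility,
    classify_by_posterior,
    fit_two_component_gmm,
    gmm_classify_dataset,
    posterior_active,
)
from leakytx.io import ExpressionDataset, GeneUniverse

from .conftest import make_gmm_fit


def bayes_oracle(fit: GmmFit, x: float) -> float:
    """Directly coded Bayes formula in plain probability space."""
    num = fit.w_active * norm.pdf(x, fit.mu_active, fit.sigma_active)
    den = num + fit.w_leaky * norm.pdf(x, fit.mu_leaky, fit.sigma_leaky)
    return num / den


class TestPosterior:
    def test_symmetric_fit_midpoint_is_half(self):
        fit = make_gmm_fit(-4.0, 4.0, 1.0, 1.0, 0.5, 0.5)
        assert posterior_active(fit, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_deep_in_leaky_component(self):
        fit = make_gmm_fit(-4.0, 4.0, 1.0, 1.0, 0.5, 0.5)
        expected = math.exp(-32) / (1 + math.exp(-32))  # closed-form Bayes
        assert posterior_active(fit, -4.0) == pytest.approx(expected, rel=1e-10)

    def test_tail_dominance(self):
        fit = make_gmm_fit(-3.0, 3.0, 1.0, 2.0, 0.5, 0.5)
        assert posterior_active(fit, 60.0) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        mu_gap=st.floats(0.5, 10),
        mu_leaky=st.floats(-8, 2),
        sigma_leaky=st.floats(0.2, 3),
        sigma_active=st.floats(0.2, 3),
        w_leaky=st.floats(0.05, 0.95),
        t=st.floats(-1, 1),
    )
    def test_matches_direct_bayes_formula(
        self, mu_gap, mu_leaky, sigma_leaky, sigma_active, w_leaky, t
    ):
        fit = make_gmm_fit(
            mu_leaky, mu_leaky + mu_gap, sigma_leaky, sigma_active,
            w_leaky, 1 - w_leaky,
        )
        span = mu_gap + 4 * max(sigma_leaky, sigma_active)
        x = mu_leaky + 0.5 * mu_gap + t * span
        assert posterior_active(fit, x) == pytest.approx(
            bayes_oracle(fit, x), abs=1e-10
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        sigma_leaky=st.floats(0.3, 2),
        extra=st.floats(0, 2),
        w_leaky=st.floats(0.05, 0.95),
    )
    def test_monotone_when_active_wider(self, sigma_leaky, extra, w_leaky):
        """P(active) is non-decreasing above the leaky mean when
        sigma_active >= sigma_leaky.

        The log-odds of the active component is quadratic in x with
        non-negative leading coefficient, and its vertex always lies below
        mu_leaky, so the posterior is monotone on [mu_leaky, inf); below
        the leaky mean the wider active component can dominate again in the
        far tail (a region with essentially no data).
        """
        fit = make_gmm_fit(
            -3.0, 3.0, sigma_leaky, sigma_leaky + extra, w_leaky, 1 - w_leaky
        )
        xs = np.linspace(fit.mu_leaky, 15, 301)
        p = posterior_active(fit, xs)
        assert np.all(np.diff(p) >= -1e-12)

    def test_complement_sums_to_one(self):
        fit = make_gmm_fit()
        for x in (-6.0, -1.0, 0.4, 3.3, 9.0):
            pa = posterior_active(fit, x)
            PosteriorCall("g", x, pa, 1.0 - pa, classify_by_posterior(pa))


class TestClassifyByPosterior:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.70, "active"),
            (0.30, "leaky"),
            (0.67, "undetermined"),  # strict inequality at the boundary
            (0.33, "undetermined"),
            (0.5, "undetermined"),
            (1.0, "active"),
            (0.0, "leaky"),
        ],
    )
    def test_threshold_labels(self, p, expected):
        assert classify_by_posterior(p) == expected

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            classify_by_posterior(1.2)
        with pytest.raises(ValueError):
            classify_by_posterior(-0.1)


class TestFit:
    def test_recovers_generating_parameters(self, spec_mixture_sample):
        fit = fit_two_component_gmm(spec_mixture_sample, seed=1)
        assert fit.converged
        assert fit.w_leaky == pytest.approx(0.25, abs=0.1)
        assert fit.mu_leaky == pytest.approx(-3.5, abs=0.1)
        assert fit.sigma_leaky == pytest.approx(1.2, abs=0.1)
        assert fit.mu_active == pytest.approx(3.0, abs=0.1)
        assert fit.sigma_active == pytest.approx(1.8, abs=0.1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_agrees_with_independent_mixture_fitter(self, spec_mixture_sample):
        """Cross-check against a generic EM implementation (scikit-learn)."""
        sklearn_gm = pytest.importorskip("sklearn.mixture").GaussianMixture
        ref = sklearn_gm(2, n_init=3, random_state=0, tol=1e-6).fit(
            spec_mixture_sample[:, None]
        )
        order = np.argsort(ref.means_.ravel())
        ref_means = ref.means_.ravel()[order]
        ref_sds = np.sqrt(ref.covariances_.ravel()[order])
        ref_w = ref.weights_[order]
        fit = fit_two_component_gmm(spec_mixture_sample, seed=1)
        assert fit.mu_leaky == pytest.approx(ref_means[0], abs=0.05)
        assert fit.mu_active == pytest.approx(ref_means[1], abs=0.05)
        assert fit.sigma_leaky == pytest.approx(ref_sds[0], abs=0.05)
        assert fit.sigma_active == pytest.approx(ref_sds[1], abs=0.05)
        assert fit.w_leaky == pytest.approx(ref_w[0], abs=0.02)

    def test_two_tight_clusters(self):
        """Well-separated point clusters: moments match brute-force cluster stats."""
        rng = np.random.default_rng(3)
        lo = rng.normal(-4.0, 0.05, 60)
        hi = rng.normal(4.0, 0.05, 140)
        x = np.concatenate([lo, hi])
        fit = fit_two_component_gmm(x, seed=0)
        assert fit.mu_leaky == pytest.approx(lo.mean(), abs=0.02)
        assert fit.mu_active == pytest.approx(hi.mean(), abs=0.02)
        assert fit.w_leaky == pytest.approx(0.3, abs=0.02)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="zero spread"):
            fit_two_component_gmm(np.ones(100), seed=0)
        with pytest.raises(ValueError, match="at least 50"):
            fit_two_component_gmm(np.arange(10.0), seed=0)
        with pytest.raises(ValueError, match="finite"):
            fit_two_component_gmm(
                np.r_[np.full(60, np.nan), np.ones(40)], seed=0
            )

    def test_component_order_invariant(self, spec_mixture_sample):
        fit = fit_two_component_gmm(spec_mixture_sample, seed=5)
        assert fit.mu_active > fit.mu_leaky
        assert fit.w_leaky + fit.w_active == pytest.approx(1.0, abs=1e-12)


class TestEligibility:
    def test_bimodal_two_component(self):
        rng = np.random.default_rng(11)
        x = np.concatenate(
            [rng.normal(-4, 1, 2000), rng.normal(3, 2, 8000)]
        )
        assert assess_eligibility(x, seed=0) == "two_component"

    def test_single_gaussian_unimodal(self):
        rng = np.random.default_rng(12)
        assert assess_eligibility(rng.normal(2, 2, 10_000), seed=0) == "unimodal"

    def test_three_separated_components(self):
        rng = np.random.default_rng(13)
        x = np.concatenate(
            [rng.normal(-6, 1, 3000), rng.normal(0, 1, 3000), rng.normal(6, 1, 4000)]
        )
        assert assess_eligibility(x, seed=0) == "three_component"

    def test_close_means_fail_separation_check(self):
        """Two components closer than one s.d. show no left shoulder."""
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(0, 1.5, 5000), rng.normal(1.2, 1.5, 5000)])
        assert assess_eligibility(x, seed=0) == "unimodal"

    @pytest.mark.parametrize("case", ["bimodal", "unimodal", "trimodal"])
    def test_agrees_with_independent_bic_enumeration(self, case):
        """The k chosen by BIC matches scikit-learn's BIC over k = 1..3."""
        sklearn_gm = pytest.importorskip("sklearn.mixture").GaussianMixture
        rng = np.random.default_rng(15)
        x = {
            "bimodal": np.concatenate(
                [rng.normal(-4, 1, 2000), rng.normal(3, 2, 8000)]
            ),
            "unimodal": rng.normal(2, 2, 10_000),
            "trimodal": np.concatenate(
                [rng.normal(-6, 1, 3000), rng.normal(0, 1, 3000),
                 rng.normal(6, 1, 4000)]
            ),
        }[case]
        bics = [
            sklearn_gm(k, n_init=3, random_state=0).fit(x[:, None]).bic(x[:, None])
            for k in (1, 2, 3)
        ]
        ref_k = int(np.argmin(bics)) + 1
        verdict = assess_eligibility(x, seed=0)
        expected = {1: "unimodal", 2: "two_component", 3: "three_component"}[ref_k]
        assert verdict == expected


class TestClassifyDataset:
    def _dataset(self, rng, n=1500):
        """Bimodal dataset with planted truth, well separated components."""
        active = rng.random(n) < 0.75
        values = np.where(
            active, rng.normal(3.5, 1.5, n), rng.normal(-4.5, 1.0, n)
        )
        tpm = {f"G{i:04d}": float(2.0 ** values[i]) for i in range(n)}
        tpm["ZERO"] = 0.0
        ds = ExpressionDataset("d1", "g", "Hs", tpm)
        uni = GeneUniverse(frozenset(tpm))
        return ds, uni, active, values

    def test_planted_labels_recovered(self):
        rng = np.random.default_rng(21)
        ds, uni, active, values = self._dataset(rng)
        result = gmm_classify_dataset(ds, uni, seed=0)
        assert result.eligibility == "two_component"
        calls = result.call_map
        # score only unambiguous genes: within 1 s.d. of their own component
        checked = correct = 0
        for i in range(len(values)):
            z_own = (values[i] - 3.5) / 1.5 if active[i] else (values[i] + 4.5) / 1.0
            if abs(z_own) >= 1:
                continue
            label = calls[f"G{i:04d}"].label
            if label == "undetermined":
                continue
            checked += 1
            correct += label == ("active" if active[i] else "leaky")
        assert checked > 500
        assert correct / checked >= 0.95

    def test_zero_tpm_gene_gets_no_call(self):
        rng = np.random.default_rng(22)
        ds, uni, _, _ = self._dataset(rng)
        result = gmm_classify_dataset(ds, uni, seed=0)
        assert "ZERO" not in result.call_map

    def test_label_exhaustiveness(self):
        """Every coding gene is active, leaky, undetermined or not detected."""
        rng = np.random.default_rng(23)
        ds, uni, _, _ = self._dataset(rng)
        result = gmm_classify_dataset(ds, uni, seed=0)
        n_detected = sum(1 for t in ds.tpm.values() if t > 0)
        labels = [c.label for c in result.calls]
        assert set(labels) <= {"active", "leaky", "undetermined"}
        assert len(labels) == n_detected
        assert len(labels) + 1 == len(uni)  # the one ZERO gene is not detected

    def test_unimodal_dataset_excluded_with_no_calls(self):
        rng = np.random.default_rng(24)
        values = rng.normal(3, 2, 2000)
        tpm = {f"G{i:04d}": float(2.0 ** v) for i, v in enumerate(values)}
        ds = ExpressionDataset("d1", "g", "Hs", tpm)
        uni = GeneUniverse(frozenset(tpm))
        result = gmm_classify_dataset(ds, uni, seed=0)
        assert result.eligibility == "unimodal"
        assert result.fit is None and result.calls == []

    def test_eligibility_override_forces_classification(self):
        rng = np.random.default_rng(25)
        values = rng.normal(3, 2, 2000)
        tpm = {f"G{i:04d}": float(2.0 ** v) for i, v in enumerate(values)}
        ds = ExpressionDataset("d1", "g", "Hs", tpm)
        uni = GeneUniverse(frozenset(tpm))
        result = gmm_classify_dataset(ds, uni, seed=0, eligibility="two_component")
        assert result.fit is not None and len(result.calls) == 2000
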