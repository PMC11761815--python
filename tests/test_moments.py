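"""Closed-form mixture moments of g against quadrature oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

from mixturemeta import (
    DesignSet,
    NormalLatent,
    central_moment,
    conditional_pdf_g,
    conditional_variance_g,
    marginal_pdf_g,
    mean_meta,
    skewness_fixed,
    skewness_meta,
    third_moment_fixed,
    variance_fixed,
    variance_meta,
)
from mixturemeta.effect_size import degrees_of_freedom, effective_size
from mixturemeta.exceptions import MomentUndefinedError, VarianceUndefinedError
from mixturemeta.moments import moments_fixed, moments_meta, third_moment_meta
from mixturemeta.simulation import PAPER_SIZE_PAIRS

GRID = [
    (mu, tau2, n1, n2)
    for mu in (0.0, 0.5, 1.0)
    for tau2 in (0.0, 0.1, 0.5)
    for (n1, n2) in ((15, 15), (5, 15))
]


def _quad_moment(r, latent, m, nt):
    """Oracle: E[(g - mu)^r] by adaptive quadrature of the marginal pdf."""
    mu = latent.mu_delta
    spread = math.sqrt(float(variance_fixed(mu, latent.tau2, m, nt)))
    val, _ = integrate.quad(
        lambda g: (g - mu) ** r * float(marginal_pdf_g(g, latent, m, nt)),
        mu - 20 * spread,
        mu + 20 * spread,
        limit=400,
        epsabs=1e-13,
        epsrel=1e-11,
        points=[mu - spread, mu, mu + spread],
    )
    return val


class TestConditionalPdf:
    def test_central_symmetry(self):
        assert float(conditional_pdf_g(0.7, 0.0, 28, 7.5)) == pytest.approx(
            float(conditional_pdf_g(-0.7, 0.0, 28, 7.5)), rel=1e-12
        )

    def test_normalization_and_mean(self):
        total, _ = integrate.quad(
            lambda g: float(conditional_pdf_g(g, 0.5, 28, 7.5)), -6, 8, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)
        mean, _ = integrate.quad(
            lambda g: g * float(conditional_pdf_g(g, 0.5, 28, 7.5)), -6, 8, limit=200
        )
        assert mean == pytest.approx(0.5, abs=1e-6)  # E(g | delta) = delta


class TestMarginalPdf:
    def test_degenerate_mixture_equals_conditional(self):
        lat = NormalLatent(0.5, 0.0)
        gs = np.linspace(-2, 3, 25)
        np.testing.assert_allclose(
            marginal_pdf_g(gs, lat, 28, 7.5),
            conditional_pdf_g(gs, 0.5, 28, 7.5),
            atol=1e-8,
        )

    @pytest.mark.parametrize("mu, tau2", [(0.0, 0.1), (0.5, 0.1), (1.0, 0.5)])
    @pytest.mark.parametrize("pair", [(15, 15), (5, 15)])
    def test_normalization(self, mu, tau2, pair):
        lat = NormalLatent(mu, tau2)
        m = float(degrees_of_freedom(*pair))
        nt = float(effective_size(*pair))
        total, _ = integrate.quad(
            lambda g: float(marginal_pdf_g(g, lat, m, nt)), mu - 12, mu + 12, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_non_normal_family_without_pdf_rejected(self):
        class MomentsOnly:
            mu_delta, tau2 = 0.5, 0.1

            def raw_moment(self, r):
                return 1.0

        with pytest.raises(NotImplementedError):
            marginal_pdf_g(0.0, MomentsOnly(), 28, 7.5)


class TestGeneralCentralMoment:
    @pytest.mark.parametrize("mu, tau2, n1, n2", GRID)
    def test_first_moment_cancels(self, mu, tau2, n1, n2):
        lat = NormalLatent(mu, tau2)
        m, nt = float(degrees_of_freedom(n1, n2)), float(effective_size(n1, n2))
        assert abs(central_moment(1, lat, m, nt)) < 1e-12

    @pytest.mark.parametrize("mu, tau2, n1, n2", GRID)
    def test_second_moment_equals_variance_formula(self, mu, tau2, n1, n2):
        lat = NormalLatent(mu, tau2)
        m, nt = float(degrees_of_freedom(n1, n2)), float(effective_size(n1, n2))
        assert central_moment(2, lat, m, nt) == pytest.approx(
            float(variance_fixed(mu, tau2, m, nt)), abs=1e-12, rel=1e-12
        )

    @pytest.mark.parametrize("mu, tau2, n1, n2", GRID)
    def test_third_moment_equals_closed_form(self, mu, tau2, n1, n2):
        lat = NormalLatent(mu, tau2)
        m, nt = float(degrees_of_freedom(n1, n2)), float(effective_size(n1, n2))
        assert central_moment(3, lat, m, nt) == pytest.approx(
            third_moment_fixed(lat, m, nt), abs=1e-12, rel=1e-12
        )

    @pytest.mark.parametrize(
        "r, mu, tau2, pair",
        [
            (1, 0.5, 0.1, (15, 15)),
            (2, 0.5, 0.1, (15, 15)),
            (3, 0.5, 0.1, (15, 15)),
            (2, 1.0, 0.5, (5, 15)),
            (3, 0.0, 0.1, (5, 15)),
            (3, 1.0, 0.5, (15, 15)),
        ],
    )
    def test_matches_quadrature_oracle(self, r, mu, tau2, pair):
        lat = NormalLatent(mu, tau2)
        m, nt = float(degrees_of_freedom(*pair)), float(effective_size(*pair))
        closed = central_moment(r, lat, m, nt)
        oracle = _quad_moment(r, lat, m, nt)
        if abs(oracle) < 1e-9:
            assert abs(closed) < 1e-9
        else:
            assert closed == pytest.approx(oracle, rel=1e-6)

    def test_order_exceeding_df_rejected(self):
        lat = NormalLatent(0.5, 0.1)
        with pytest.raises(MomentUndefinedError):
            central_moment(3, lat, 3, 1.5)
        with pytest.raises(MomentUndefinedError):
            third_moment_fixed(lat, 3, 1.5)
        with pytest.raises(VarianceUndefinedError):
            variance_fixed(0.5, 0.1, 2, 1.0)


class TestStudyLevelMoments:
    def test_reference_condition_values(self, latent):
        """Closed forms at mu=0.5, tau2=0.1, N1=N2=15 (printed reference)."""
        assert float(variance_fixed(0.5, 0.1, 28, 7.5)) == pytest.approx(
            0.24272, abs=5e-6
        )
        assert skewness_fixed(latent, 28, 7.5) == pytest.approx(0.12139, abs=5e-6)

    def test_tau2_zero_collapses_to_conditional_variance(self):
        for delta, pair in [(0.5, (15, 15)), (1.0, (5, 15))]:
            m, nt = float(degrees_of_freedom(*pair)), float(effective_size(*pair))
            assert float(variance_fixed(delta, 0.0, m, nt)) == pytest.approx(
                float(conditional_variance_g(delta, m, nt)), rel=1e-14
            )

    def test_large_sample_limits(self, latent):
        m = float(degrees_of_freedom(100_000, 100_000))
        nt = float(effective_size(100_000, 100_000))
        assert float(variance_fixed(0.5, 0.1, m, nt)) == pytest.approx(0.1, abs=1e-3)
        m4 = float(degrees_of_freedom(10_000, 10_000))
        nt4 = float(effective_size(10_000, 10_000))
        assert abs(skewness_fixed(latent, m4, nt4)) < 0.01

    def test_symmetric_latent_zero_mean_unskewed(self):
        lat = NormalLatent(0.0, 0.1)
        assert abs(third_moment_fixed(lat, 28, 7.5)) < 1e-12

    def test_skewness_monotone_in_parameters(self):
        """Skewness grows with mu_delta, shrinks with tau2 and with N."""
        skews_mu = [
            skewness_fixed(NormalLatent(mu, 0.1), 28, 7.5) for mu in (0.2, 0.5, 0.8)
        ]
        assert skews_mu == sorted(skews_mu)
        skews_t2 = [
            skewness_fixed(NormalLatent(0.5, t2), 28, 7.5) for t2 in (0.05, 0.1, 0.3)
        ]
        assert skews_t2 == sorted(skews_t2, reverse=True)
        skews_n = [
            skewness_fixed(
                NormalLatent(0.5, 0.1),
                float(degrees_of_freedom(n, n)),
                float(effective_size(n, n)),
            )
            for n in (10, 20, 40)
        ]
        assert skews_n == sorted(skews_n, reverse=True)


class TestMetaLevelMoments:
    def test_mean_is_design_free(self, latent, design_pairs):
        design = DesignSet(design_pairs)
        assert mean_meta(latent, design) == 0.5
        shuffled = DesignSet(design_pairs[::-1] + design_pairs[:1])
        assert mean_meta(latent, shuffled) == 0.5

    def test_reference_condition_values(self, latent, design_pairs):
        design = DesignSet(design_pairs)
        assert variance_meta(latent, design) == pytest.approx(0.30380, abs=5e-6)
        assert skewness_meta(latent, design) == pytest.approx(0.22161, abs=5e-6)

    def test_single_pair_collapse(self, latent):
        design = DesignSet([(15, 15)])
        assert variance_meta(latent, design) == pytest.approx(
            float(variance_fixed(0.5, 0.1, 28, 7.5)), rel=1e-14
        )
        assert skewness_meta(latent, design) == pytest.approx(
            skewness_fixed(latent, 28, 7.5), rel=1e-14
        )

    def test_variance_is_mean_of_per_pair_variances(self, latent, design_pairs):
        design = DesignSet(design_pairs)
        per_pair = [
            float(
                variance_fixed(
                    0.5,
                    0.1,
                    float(degrees_of_freedom(n1, n2)),
                    float(effective_size(n1, n2)),
                )
            )
            for n1, n2 in design_pairs
        ]
        assert variance_meta(latent, design) == pytest.approx(
            float(np.mean(per_pair)), abs=1e-12
        )
        per_mu3 = [
            third_moment_fixed(
                latent, float(degrees_of_freedom(n1, n2)), float(effective_size(n1, n2))
            )
            for n1, n2 in design_pairs
        ]
        assert third_moment_meta(latent, design) == pytest.approx(
            float(np.mean(per_mu3)), abs=1e-12
        )

    def test_moment_sets(self, latent, design_pairs):
        ms = moments_fixed(latent, 15, 15)
        assert (ms.mean, ms.variance) == (0.5, pytest.approx(0.24272, abs=5e-6))
        mm = moments_meta(latent, DesignSet(design_pairs))
        assert mm.skewness == pytest.approx(0.22161, abs=5e-6)


class TestNormalLatent:
    def test_raw_moments(self):
        lat = NormalLatent(0.5, 0.1)
        assert lat.raw_moment(0) == 1.0
        assert lat.raw_moment(1) == 0.5
        assert lat.raw_moment(2) == pytest.approx(0.35)
        assert lat.raw_moment(3) == pytest.approx(0.5**3 + 3 * 0.5 * 0.1)
        # higher order against the scipy normal distribution
        from scipy import stats

        assert lat.raw_moment(6) == pytest.approx(
            stats.norm(0.5, math.sqrt(0.1)).moment(6), rel=1e-12
        )

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            NormalLatent(0.5, -0.1)
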