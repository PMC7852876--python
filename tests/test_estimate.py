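"""Least-squares rate estimator: objective, golden-section search vs the
analytic minimiser, bootstrap CI behaviour, and diversity checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sibline.equilibrium import REFERENCE_RATE, build_markov_model, expected_sfs_counts_at
from sibline.errors import EstimationError
from sibline.estimate import (
    BootstrapSpec,
    bootstrap_ci,
    bootstrap_rates,
    closed_form_rate,
    effective_size_from_theta,
    estimate_rate,
    expected_variant_count,
    golden_section_minimize,
    objective_d,
)
from sibline.sfs import ELEMENTS, SFSVector

U_FLAT = SFSVector(np.array([1.0, 1, 1, 1, 1, 1, 1]))


def vec(*vals):
    return SFSVector(np.array(vals, dtype=float))


class TestObjective:
    def test_zero_rate_gives_sum_of_squares(self):
        v = vec(1, 2, 99, 3, 4, 5, 6)  # RARA excluded by default
        assert objective_d(0.0, U_FLAT, v) == pytest.approx(1 + 4 + 9 + 16 + 25 + 36)

    def test_proportional_spectra_have_zero_objective(self):
        u = vec(2, 2, 5, 1, 1, 1, 1)
        v = SFSVector(3 * u.counts)
        assert objective_d(3.0, u, v) == pytest.approx(0.0, abs=1e-20)

    def test_hand_worked_example(self):
        u = vec(2, 2, 0, 1, 1, 1, 1)
        v = SFSVector(2 * u.counts)
        assert objective_d(2.0, u, v) == pytest.approx(0.0)
        assert objective_d(1.0, u, v) == pytest.approx(12.0)  # sum u_i^2 = 4+4+1+1+1+1

    def test_all_elements_excluded_is_error(self):
        with pytest.raises(ValueError):
            objective_d(1.0, U_FLAT, U_FLAT, excluded=set(ELEMENTS))


class TestClosedForm:
    def test_proportional_recovers_constant(self):
        u = vec(5, 4, 3, 2, 1, 2, 3)
        v = SFSVector(2.5 * u.counts)
        assert closed_form_rate(u, v) == pytest.approx(2.5, rel=1e-12)

    def test_hand_worked_example(self):
        u = vec(1, 1, 0, 1, 1, 1, 1)
        v = vec(2, 0, 0, 0, 0, 0, 0)
        assert closed_form_rate(u, v) == pytest.approx(2 / 6)

    def test_orthogonal_observation_gives_zero(self):
        u = vec(1, 0, 0, 0, 0, 0, 0)
        v = vec(0, 5, 0, 5, 5, 5, 5)
        assert closed_form_rate(u, v) == 0.0

    def test_zero_u_is_error(self):
        with pytest.raises(EstimationError):
            closed_form_rate(SFSVector.zeros(), U_FLAT)


class TestGoldenSection:
    def test_proportional_spectrum_recovers_scale_exactly(self):
        u = vec(10, 10, 7, 2, 2, 3, 3)
        v = SFSVector(3.0 * u.counts)
        est = golden_section_minimize(u, v)
        assert est.mu_hat == pytest.approx(3.0, abs=1e-3)
        assert est.mu_hat_absolute == pytest.approx(3.0 * REFERENCE_RATE, rel=1e-3)
        # residual at 3-significant-digit convergence: (err*sum u^2)^... ~ 1e-5
        assert est.d_min < 1e-4

    def test_zero_observation_gives_zero_rate(self):
        est = golden_section_minimize(U_FLAT, SFSVector.zeros())
        assert est.mu_hat == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_closed_form_over_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            u = SFSVector(rng.uniform(0.05, 20.0, 7))
            v = SFSVector(rng.uniform(0.0, 60.0, 7))
            cf = closed_form_rate(u, v)
            gs = golden_section_minimize(u, v).mu_hat
            assert abs(gs - cf) <= 1e-3 * max(abs(cf), 1e-6)

    def test_bracket_expansion_when_optimum_beyond_default(self):
        u = vec(1, 1, 1, 1, 1, 1, 1)
        v = SFSVector(150.0 * u.counts)  # optimum beyond the supplied bracket
        est = golden_section_minimize(u, v, bracket=(0.0, 100.0))
        assert est.mu_hat == pytest.approx(150.0, rel=5e-3)

    def test_invalid_bracket_rejected(self):
        with pytest.raises(ValueError):
            golden_section_minimize(U_FLAT, U_FLAT, bracket=(5.0, 1.0))

    @given(st.integers(min_value=1, max_value=9))
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(23)
        u = SFSVector(rng.uniform(0.5, 5.0, 7))
        v = SFSVector(rng.integers(0, 40, 7).astype(float))
        base = closed_form_rate(u, v)
        scaled = closed_form_rate(u, SFSVector(k * v.counts))
        assert scaled == pytest.approx(k * base, rel=1e-12)
        gs = golden_section_minimize(u, SFSVector(k * v.counts)).mu_hat
        assert gs == pytest.approx(k * base, rel=2e-3, abs=1e-6)


class TestBootstrap:
    def test_degenerate_spectrum_has_point_mass_ci(self):
        v = vec(40, 0, 0, 0, 0, 0, 0)
        u = vec(2, 1, 1, 1, 1, 1, 1)
        lo, hi = bootstrap_ci(u, v, spec=BootstrapSpec(replicates=200, seed=1))
        est = golden_section_minimize(u, v)
        assert lo == pytest.approx(hi, rel=1e-9)
        # every resample is identical, so the CI collapses onto... the
        # re-estimated rate from the (identical) resampled spectrum
        assert lo == pytest.approx(est.mu_hat_absolute, rel=1e-3)

    def test_empty_observation_is_error(self):
        with pytest.raises(EstimationError):
            bootstrap_ci(U_FLAT, SFSVector.zeros())

    def test_ci_width_shrinks_with_total_count(self):
        model = build_markov_model("wf_selfing")
        u = expected_sfs_counts_at(model, 1e-8, 10**6)
        props = u.counts / u.total
        rng = np.random.default_rng(3)
        v100 = SFSVector(rng.multinomial(100, props).astype(float))
        v400 = SFSVector(rng.multinomial(400, props).astype(float))
        w100 = np.subtract(*bootstrap_ci(u, v100, spec=BootstrapSpec(2000, 5))[::-1])
        w400 = np.subtract(*bootstrap_ci(u, v400, spec=BootstrapSpec(2000, 6))[::-1])
        rel100 = w100 / golden_section_minimize(u, v100).mu_hat_absolute
        rel400 = w400 / golden_section_minimize(u, v400).mu_hat_absolute
        # binomial scaling of the relative width ~ sqrt(4) = 2
        assert rel100 / rel400 == pytest.approx(2.0, abs=0.6)

    def test_nominal_coverage_at_fixed_total(self):
        """Drawing v multinomially at fixed segregating total (the sampling
        regime the fixed-total bootstrap models), the 95% CI covers the true
        rate in ~95% of trials."""
        model = build_markov_model("wf_selfing")
        u = expected_sfs_counts_at(model, 1e-8, 10**6)
        ui, kept = u.drop({"RARA"})
        mu_true = 1000.0  # reference units
        lam = ui * mu_true
        n = int(round(lam.sum()))
        rng = np.random.default_rng(29)
        hits = 0
        trials = 200
        for _ in range(trials):
            draw = rng.multinomial(n, lam / lam.sum()).astype(float)
            v = SFSVector.from_dict(dict(zip(kept, draw)))
            lo, hi = bootstrap_ci(u, v, spec=BootstrapSpec(300, int(rng.integers(2**31))))
            hits += lo <= mu_true * REFERENCE_RATE <= hi
        assert 0.90 <= hits / trials <= 0.99

    def test_estimate_rate_reports_ci_containing_point(self):
        model = build_markov_model("wf_selfing")
        u = expected_sfs_counts_at(model, 1e-8, 10**6)
        rng = np.random.default_rng(101)
        v = SFSVector(rng.poisson(u.counts * 500).astype(float))
        est = estimate_rate(u, v, bootstrap=BootstrapSpec(500, 2))
        assert est.ci_low <= est.mu_hat_absolute <= est.ci_high
        assert est.bootstrap_se > 0


class TestContaminationDirection:
    def test_double_het_excess_inflates_only_the_all_element_fit(self):
        """Paralog leakage lands in RARA; excluding it protects the fit."""
        model = build_markov_model("wf_selfing")
        u = expected_sfs_counts_at(model, 1e-8, 10**6)
        true_mu = 300.0
        v = SFSVector(true_mu * u.counts)
        contaminated = v.counts.copy()
        contaminated[ELEMENTS.index("RARA")] *= 8  # misaligned-paralog excess
        vc = SFSVector(contaminated)
        with_rara = closed_form_rate(u, vc, excluded=set())
        without = closed_form_rate(u, vc, excluded={"RARA"})
        assert without == pytest.approx(true_mu, rel=1e-9)
        assert with_rara > without


class TestDiversityChecks:
    @pytest.mark.parametrize(
        "mu,ne,L,expected",
        [(1e-8, 2.6, 2_725_521_370, 283.5), (0.0, 2.6, 2_725_521_370, 0.0)],
    )
    def test_expected_variant_count(self, mu, ne, L, expected):
        assert expected_variant_count(mu, ne, L) == pytest.approx(expected, abs=0.06)

    def test_effective_size_inverts_diversity(self):
        mu, L = 1e-8, 2_725_521_370
        assert effective_size_from_theta(4 * mu * L, mu, L) == pytest.approx(1.0)
        assert effective_size_from_theta(283.5, mu, L) == pytest.approx(2.6, abs=0.01)
        assert effective_size_from_theta(0.0, mu, L) == 0.0

    def test_effective_size_needs_positive_rate(self):
        with pytest.raises(EstimationError):
            effective_size_from_theta(10.0, 0.0, 1e9)
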