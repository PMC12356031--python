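"""Clonogenic statistics: LQ fits, MID, RBE/SER ratios, line fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import letrbe as L
from letrbe.survival import DoseResponse, MIDResult


def _lq_response(alpha, beta, doses):
    doses = np.asarray(doses, dtype=float)
    sf = np.exp(-(alpha * doses + beta * doses**2))
    return DoseResponse(doses=doses, sf_mean=sf)


class TestFitLQ:
    def test_noiseless_recovery(self):
        data = _lq_response(0.3, 0.03, [0, 1, 2, 4, 6, 8])
        fit = L.fit_lq(data)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.300, abs=1e-6)
        assert fit.beta == pytest.approx(0.030, abs=1e-6)

    def test_pure_exponential_hits_beta_boundary(self):
        data = _lq_response(0.5, 0.0, [0, 1, 2, 4, 6])
        fit = L.fit_lq(data)
        assert fit.beta == pytest.approx(0.0, abs=1e-4)
        assert fit.alpha == pytest.approx(0.5, abs=1e-4)

    def test_too_few_points(self):
        data = _lq_response(0.3, 0.03, [0, 2])
        with pytest.raises(ValueError):
            L.fit_lq(data)

    def test_recovery_coverage_on_replicated_counts(self):
        """Binomial colony noise, 3 replicates: alpha within 2 SE >= 90%."""
        alpha, beta, pe = 0.5, 0.05, 0.5
        doses = np.array([0.0, 1, 2, 4, 6, 8])
        seeded = np.array([300, 500, 1000, 4000, 10000, 20000])
        hits = 0
        n_rep = 100
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            counts = np.array([
                np.maximum(
                    rng.binomial(seeded, pe * np.exp(-(alpha * doses + beta * doses**2))), 1
                )
                for _r in range(3)
            ])
            sf_reps = counts / seeded / (counts[:, 0:1] / seeded[0])
            data = DoseResponse(
                doses=doses, sf_mean=np.exp(np.log(sf_reps).mean(axis=0)),
                replicates=[sf_reps[:, i] for i in range(len(doses))],
                colony_counts=[counts[:, i] for i in range(len(doses))],
            )
            fit = L.fit_lq(data)
            hits += abs(fit.alpha - alpha) <= 2 * fit.alpha_se
        assert hits / n_rep >= 0.90


class TestComputeMid:
    def test_pure_exponential(self):
        doses = np.arange(0, 20.01, 0.05)
        data = DoseResponse(doses=doses, sf_mean=np.exp(-0.5 * doses))
        res = L.compute_mid(data)
        assert res.mid == pytest.approx(2.0, rel=0.005)

    def test_lq_against_closed_form(self):
        doses = np.arange(0, 12.01, 0.1)
        data = _lq_response(0.3, 0.03, doses)
        res = L.compute_mid(data)
        exact = L.lq_mid_closed_form(0.3, 0.03)
        assert exact == pytest.approx(2.39, abs=0.005)
        assert res.mid == pytest.approx(exact, rel=0.01)

    def test_flat_segment_limit(self):
        data = DoseResponse(doses=np.array([0.0, 2.0]), sf_mean=np.array([1.0, 1.0]))
        res = L.compute_mid(data)
        assert res.mid == pytest.approx(2.0)
        assert res.tail_fraction == 0.0

    def test_tail_warning_when_range_too_short(self):
        doses = np.array([0.0, 0.5, 1.0])
        data = _lq_response(0.2, 0.0, doses)
        with pytest.warns(UserWarning, match="tail"):
            L.compute_mid(data)

    def test_monotone_in_survival(self, rng):
        doses = np.arange(0, 10.01, 0.25)
        hi = _lq_response(0.3, 0.03, doses)
        lo = _lq_response(0.4, 0.04, doses)  # pointwise lower survival
        assert L.compute_mid(lo).mid < L.compute_mid(hi).mid

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        alpha=st.floats(0.05, 0.8),
        beta=st.floats(0.005, 0.1),
    )
    def test_oracle_equivalence_dense_lq(self, alpha, beta):
        """Exponential interpolation matches both the closed form and dense
        trapezoidal quadrature on any dense LQ sampling."""
        d_max = 25.0 / (alpha + beta * 10)  # deep enough for a tiny tail
        doses = np.linspace(0, d_max, 400)
        sf = np.exp(-(alpha * doses + beta * doses**2))
        data = DoseResponse(doses=doses, sf_mean=sf)
        mid = L.compute_mid(data).mid
        assert mid == pytest.approx(L.lq_mid_closed_form(alpha, beta), rel=0.01)
        assert mid == pytest.approx(np.trapezoid(sf, doses), rel=0.01)


class TestRatios:
    def _mid(self, value, se=None):
        return MIDResult(mid=value, method="exponential_interpolation",
                         tail_fraction=0.0, se=se)

    def test_rbe_basic_and_identity(self):
        assert L.compute_rbe(self._mid(2.0), self._mid(1.0)).value == 2.0
        assert L.compute_rbe(self._mid(1.37), self._mid(1.37)).value == 1.0

    def test_ser_basic_and_identity(self):
        assert L.compute_ser(self._mid(2.0), self._mid(1.0)).value == 2.0
        assert L.compute_ser(self._mid(0.8), self._mid(0.8)).value == 1.0

    def test_rescaling_invariance(self):
        base = L.compute_rbe(self._mid(2.4), self._mid(0.9)).value
        scaled = L.compute_rbe(self._mid(2.4 * 3.7), self._mid(0.9 * 3.7)).value
        assert abs(base - scaled) < 1e-12

    def test_se_propagation(self):
        res = L.compute_rbe(self._mid(2.0, se=0.1), self._mid(1.0, se=0.05))
        expected = 2.0 * np.hypot(0.1 / 2.0, 0.05 / 1.0)
        assert res.se == pytest.approx(expected)

    def test_invalid_mid(self):
        with pytest.raises(ValueError):
            MIDResult(mid=-1.0, method="exponential_interpolation", tail_fraction=0.0)

    def test_rbe_falls_with_reference_radioresistance(self):
        """At equal beta, a larger reference alpha lowers RBE_MID: more
        radioresistant cells see greater RBEs (closed-form property)."""
        test_mid = self._mid(L.lq_mid_closed_form(1.2, 0.02))
        rbes = [
            L.compute_rbe(self._mid(L.lq_mid_closed_form(a, 0.05)), test_mid).value
            for a in (0.1, 0.3, 0.6, 0.9)
        ]
        assert all(a > b for a, b in zip(rbes, rbes[1:]))


class TestMylarCorrection:
    def test_canonical_direction(self):
        assert L.apply_mylar_correction(2.0) == pytest.approx(2.44)

    def test_identity_and_zero(self):
        assert L.apply_mylar_correction(3.0, factor=1.0) == 3.0
        assert L.apply_mylar_correction(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            L.apply_mylar_correction(-1.0)
        with pytest.raises(ValueError):
            L.apply_mylar_correction(1.0, factor=0.0)


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = L.fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = L.fit_linear([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_degenerate_x(self):
        with pytest.raises(ValueError):
            L.fit_linear([2, 2, 2], [1, 2, 3])

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(31)
        x = np.linspace(0, 130, 20)
        y = 0.04 * x + rng.normal(0, 0.1, 20)
        fit = L.fit_linear(x, y)
        assert abs(fit.slope - 0.04) <= 2 * fit.slope_se


class TestDoseResponseValidation:
    def test_requires_zero_start(self):
        with pytest.raises(ValueError):
            DoseResponse(doses=np.array([1.0, 2.0]), sf_mean=np.array([1.0, 0.5]))

    def test_rejects_non_monotone_doses(self):
        with pytest.raises(ValueError):
            DoseResponse(doses=np.array([0.0, 2.0, 1.0]),
                         sf_mean=np.array([1.0, 0.5, 0.7]))

    def test_rejects_non_positive_sf(self):
        with pytest.raises(ValueError):
            DoseResponse(doses=np.array([0.0, 1.0]), sf_mean=np.array([1.0, 0.0]))
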