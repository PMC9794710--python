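"""Enzyme-kinetics: velocity models, IC50 and inhibition fitting, reversibility."""

import numpy as np
import pytest

from chalqsar.errors import DesignError, DomainError, ResidualActivityError, SchemaError
from chalqsar.kinetics import (
    DoseResponsePoint,
    InhibitionMode,
    ReversibilityRecord,
    cheng_prusoff,
    fit_ic50,
    fit_inhibition,
    reversibility_call,
    velocity,
)
from chalqsar.simulate import KineticSimSpec, gen_dose_response, gen_kinetics


class TestVelocity:
    def test_no_inhibitor_michaelis_menten(self):
        assert velocity(100.0, 0.29, S=0.29, I=0.0, ki=0.03) == pytest.approx(50.0)

    def test_competitive_hand_value(self):
        # Vmax=1, Km=0.3, S=0.3, I=Ki -> 0.3/(0.6+0.3) = 1/3
        v = velocity(1.0, 0.3, S=0.3, I=0.03, ki=0.03, mode="competitive")
        assert v == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_competitive_vmax_asymptote(self):
        v = velocity(1.0, 0.3, S=1e9, I=0.03, ki=0.03, mode="competitive")
        assert v == pytest.approx(1.0, rel=1e-6)

    def test_uncompetitive_lowers_apparent_vmax(self):
        v = velocity(1.0, 0.3, S=1e9, I=0.03, ki=0.03, mode="uncompetitive")
        assert v == pytest.approx(0.5, rel=1e-6)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            velocity(1.0, 0.3, 0.3, mode="sideways")

    def test_invalid_parameters(self):
        with pytest.raises(DomainError):
            velocity(-1.0, 0.3, 0.3)


class TestFitIC50:
    def test_noiseless_recovery(self):
        points = gen_dose_response(ic50=0.067, hill=1.0, top=100.0, bottom=0.0)
        fit = fit_ic50(points)
        assert fit.ic50 == pytest.approx(0.067, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-4)
        assert fit.top == pytest.approx(100.0, abs=1e-3)
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)

    def test_screening_rule_refusal(self):
        points = [DoseResponsePoint(c, a) for c, a in
                  [(0.01, 98.0), (0.1, 95.0), (1.0, 88.0), (10.0, 85.0)]]
        with pytest.raises(ResidualActivityError):
            fit_ic50(points)

    def test_scale_equivariance(self):
        base = gen_dose_response(ic50=0.5, hill=1.2)
        doubled = [DoseResponsePoint(2 * p.inhibitor_conc, p.activity) for p in base]
        assert fit_ic50(doubled).ic50 == pytest.approx(2 * fit_ic50(base).ic50, rel=1e-4)

    def test_activity_at_ic50_is_midpoint(self):
        points = gen_dose_response(ic50=0.067, conc_grid=(0.001, 0.01, 0.067, 0.5, 10.0))
        mid = [p.activity for p in points if p.inhibitor_conc == 0.067][0]
        assert mid == pytest.approx(50.0, abs=1e-9)

    def test_noisy_recovery_bias(self):
        fitted = []
        for seed in range(200):
            points = gen_dose_response(ic50=0.067, noise_sd=5.0, seed=seed)
            try:
                fitted.append(fit_ic50(points).ic50)
            except ResidualActivityError:
                continue
        assert len(fitted) > 150
        assert abs(np.mean(fitted) - 0.067) / 0.067 < 0.10


class TestFitInhibition:
    def test_noiseless_competitive_round_trip(self):
        data = gen_kinetics(KineticSimSpec(noise_cv=0.0))
        fit = fit_inhibition(data)
        assert fit.mode is InhibitionMode.COMPETITIVE
        assert fit.vmax == pytest.approx(100.0, rel=1e-6)
        assert fit.km == pytest.approx(0.29, rel=1e-6)
        assert fit.ki == pytest.approx(0.030, rel=1e-6)

    def test_lineweaver_burk_common_intercept(self):
        data = gen_kinetics(KineticSimSpec(noise_cv=0.0))
        fit = fit_inhibition(data)
        intercepts = [line.intercept for line in fit.lb_lines]
        assert np.ptp(intercepts) < 1e-8
        assert intercepts[0] == pytest.approx(1.0 / 100.0, abs=1e-10)

    def test_secondary_plot_ki(self):
        data = gen_kinetics(KineticSimSpec(noise_cv=0.0))
        fit = fit_inhibition(data)
        assert fit.ki_lineweaver_burk == pytest.approx(0.030, rel=1e-8)

    @pytest.mark.parametrize("mode", [InhibitionMode.COMPETITIVE, InhibitionMode.UNCOMPETITIVE, InhibitionMode.MIXED])
    def test_mode_classification_noiseless(self, mode):
        data = gen_kinetics(KineticSimSpec(mode=mode, alpha=3.0 if mode is InhibitionMode.MIXED else 1.0))
        assert fit_inhibition(data).mode is mode

    def test_requires_zero_inhibitor_level(self):
        data = gen_kinetics(KineticSimSpec(inhibitor_levels=(0.015, 0.030, 0.060)))
        with pytest.raises(DesignError):
            fit_inhibition(data)

    def test_nonlinear_and_linearized_ki_agree_under_noise(self):
        rel_diff = []
        for seed in range(50):
            data = gen_kinetics(KineticSimSpec(noise_cv=0.05, seed=seed))
            fit = fit_inhibition(data)
            if fit.mode is InhibitionMode.COMPETITIVE and np.isfinite(fit.ki_lineweaver_burk):
                rel_diff.append(abs(fit.ki - fit.ki_lineweaver_burk) / fit.ki)
        assert np.median(rel_diff) < 0.25


class TestChengPrusoff:
    def test_hand_values(self):
        assert cheng_prusoff(0.030, 0.3, 0.29) == pytest.approx(0.0610, abs=5e-5)
        assert cheng_prusoff(0.033, 0.3, 0.25) == pytest.approx(0.0726, abs=5e-5)

    def test_zero_substrate_limit(self):
        assert cheng_prusoff(0.030, 0.0, 0.29) == pytest.approx(0.030)

    def test_invalid(self):
        with pytest.raises(DomainError):
            cheng_prusoff(-1.0, 0.3, 0.29)


REFS = dict(ref_reversible=(45.13, 80.78), ref_irreversible=(45.26, 43.96))


class TestReversibility:
    def test_recovered_sample_is_reversible(self):
        record = ReversibilityRecord(44.29, 77.53, **REFS)
        assert reversibility_call(record) == "reversible"

    def test_flat_sample_is_irreversible(self):
        record = ReversibilityRecord(45.26, 43.96, **REFS)
        assert reversibility_call(record) == "irreversible"

    def test_zero_recovery_is_irreversible(self):
        record = ReversibilityRecord(50.0, 50.0, **REFS)
        assert reversibility_call(record) == "irreversible"

    def test_partial_recovery_indeterminate(self):
        record = ReversibilityRecord(45.0, 53.0, **REFS)
        assert reversibility_call(record) == "indeterminate"

    def test_bad_reference(self):
        record = ReversibilityRecord(45.0, 60.0, ref_reversible=(50.0, 50.0), ref_irreversible=(45.26, 43.96))
        with pytest.raises(DomainError):
            reversibility_call(record)
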