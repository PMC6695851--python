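"""Unit and property tests for the optics + transmission-line model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avfppg import hemodynamics as hd
from avfppg.errors import DomainError

OC = hd.OpticalConstants(eps_HbO=1.2, eps_Hb=0.8, tissue_exponent=0.5, I0=1.0)
BP = hd.BloodProperties(eta=0.035, rho=1.056, spo2=0.97)


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------


class TestReceivedIntensity:
    def test_no_absorber_identity(self):
        oc = hd.OpticalConstants(tissue_exponent=0.0)
        assert hd.received_intensity(oc, eps_b_c_b=1.0, s_b=0.0) == oc.I0

    def test_doubling_path_squares_blood_factor(self):
        oc = hd.OpticalConstants(tissue_exponent=0.0, I0=1.0)
        r1 = hd.received_intensity(oc, 0.7, 1.0)
        r2 = hd.received_intensity(oc, 0.7, 2.0)
        assert r2 == pytest.approx(r1**2, rel=1e-12)

    def test_scalar_oracle(self):
        # I0=1, tissue exponent 0.5, blood exponent 0.1 -> e^-0.6
        got = hd.received_intensity(OC, eps_b_c_b=0.2, s_b=0.5)
        assert got == pytest.approx(0.5488116360940264, rel=1e-12)

    def test_negative_path_rejected(self):
        with pytest.raises(DomainError):
            hd.received_intensity(OC, 1.0, -0.1)


class TestEffectiveAbsorption:
    @pytest.mark.parametrize(
        "spo2,expected", [(1.0, 1.2), (0.0, 0.8), (0.5, 1.0)]
    )
    def test_endpoints_and_midpoint(self, spo2, expected):
        assert hd.effective_absorption(spo2, OC) == pytest.approx(expected)

    @pytest.mark.parametrize("spo2", [-0.01, 1.01])
    def test_out_of_range(self, spo2):
        with pytest.raises(DomainError):
            hd.effective_absorption(spo2, OC)


class TestPerfusionIndex:
    def test_zero_path_zero_pi(self):
        assert hd.pi_from_path(0.0, 0.97, OC) == 0.0

    @given(s_b=st.floats(1e-6, 10.0), spo2=st.floats(0.0, 1.0))
    def test_round_trip(self, s_b, spo2):
        pi = hd.pi_from_path(s_b, spo2, OC)
        assert hd.path_from_pi(pi, spo2, OC) == pytest.approx(s_b, rel=1e-12)

    def test_linearity(self):
        assert hd.pi_from_path(2.0, 0.97, OC) == pytest.approx(
            2 * hd.pi_from_path(1.0, 0.97, OC), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Womersley and line parameters
# ---------------------------------------------------------------------------


class TestWomersley:
    def test_small_omega_limit(self):
        assert hd.womersley(0.5, 1e-12, BP) == pytest.approx(0.0, abs=1e-5)

    def test_linear_in_d0(self):
        w1 = hd.womersley(0.25, 7.5, BP)
        w2 = hd.womersley(0.50, 7.5, BP)
        assert w2 == pytest.approx(2 * w1, rel=1e-12)

    def test_scalar_oracle(self):
        omega = 2 * math.pi * 72 / 60
        assert hd.womersley(0.5, omega, BP) == pytest.approx(3.77, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            hd.womersley(0.0, 7.5, BP)
        with pytest.raises(DomainError):
            hd.womersley(0.5, 0.0, BP)


class TestWomersleyCoeffs:
    @pytest.mark.parametrize(
        "W,c1,c2",
        [(0.0, 0.45, 1.39), (1.0, 0.63, 1.372), (10.0, 2.25, 1.21)],
    )
    def test_affine(self, W, c1, c2):
        got = hd.womersley_coeffs(W)
        assert got[0] == pytest.approx(c1, rel=1e-12)
        assert got[1] == pytest.approx(c2, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            hd.womersley_coeffs(-0.1)


def _fixture_vessel(p):
    spread = 0.02
    return hd.VesselState(
        D=p["d0"] + spread,
        d=p["d0"],
        d0=p["d0"],
        h1=p["h"],
        h2=0.0,
        E=p["E"],
        sigma_p=p["sigma_p"],
        d_max=p["d0"] + spread,
        d_min=p["d0"] - spread,
    )


class TestLineParams:
    def test_regression_fixture(self, fixture_vessel_params):
        """Frozen values from independent scalar evaluation of the formulas."""
        p = fixture_vessel_params
        vessel = _fixture_vessel(p)
        hemo = hd.Hemodynamics(sbp=p["sbp"], dbp=p["dbp"], hr_bpm=p["hr_bpm"])
        lp = hd.line_params(vessel, hemo, BP)
        assert lp.W == pytest.approx(3.7706698015400892, rel=1e-10)
        assert lp.c1 == pytest.approx(1.128720564277216, rel=1e-10)
        assert lp.c2 == pytest.approx(1.3221279435722784, rel=1e-10)
        assert lp.R == pytest.approx(25.753399300492212, rel=1e-10)
        assert lp.L == pytest.approx(7.110620693956474, rel=1e-10)
        assert lp.C == pytest.approx(3.7301504022857565e-07, rel=1e-10)
        assert lp.G == 0.0
        assert lp.alpha == pytest.approx(0.002871776270862224, rel=1e-9)
        assert lp.beta == pytest.approx(0.012610764654195285, rel=1e-9)
        assert lp.Z0.real == pytest.approx(4483.879813652753, rel=1e-9)
        assert lp.Z0.imag == pytest.approx(-1021.0879358502935, rel=1e-9)

    def test_r_power_law_in_d0(self, fixture_vessel_params):
        p = dict(fixture_vessel_params)
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        lp1 = hd.line_params(_fixture_vessel(p), hemo, BP)
        p2 = dict(p, d0=p["d0"] / 2)
        lp2 = hd.line_params(_fixture_vessel(p2), hemo, BP)
        # holding c1 fixed, R scales as d0^-4
        assert (lp2.R / lp2.c1) == pytest.approx(16 * lp1.R / lp1.c1, rel=1e-12)

    def test_c_functional_form(self, fixture_vessel_params):
        p = fixture_vessel_params
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        lp = hd.line_params(_fixture_vessel(p), hemo, BP)
        expected = (
            (1 - p["sigma_p"] ** 2)
            * math.pi
            * p["d0"] ** 3
            / (4 * p["h"] * p["E"])
        )
        assert lp.C == pytest.approx(expected, rel=1e-12)

    def test_poiseuille_pi_switch(self, fixture_vessel_params):
        p = fixture_vessel_params
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        lp_std = hd.line_params(_fixture_vessel(p), hemo, BP, poiseuille_pi=True)
        lp_raw = hd.line_params(_fixture_vessel(p), hemo, BP, poiseuille_pi=False)
        assert lp_raw.R == pytest.approx(lp_std.R * math.pi, rel=1e-12)


class TestPropagationConstants:
    def test_lossless_limit(self):
        lp = hd.LineParams(R=0.0, L=2.0, G=0.0, C=0.5, W=1.0, c1=0.63, c2=1.372)
        alpha, beta = hd.propagation_constants(lp, omega=3.0)
        assert alpha == pytest.approx(0.0, abs=1e-12)
        assert beta == pytest.approx(3.0 * math.sqrt(2.0 * 0.5), rel=1e-12)

    def test_alpha_nondecreasing_in_r(self):
        alphas = []
        for R in np.linspace(0.0, 100.0, 21):
            lp = hd.LineParams(R=R, L=2.0, G=0.0, C=0.5, W=1.0, c1=0.6, c2=1.3)
            alphas.append(hd.propagation_constants(lp, omega=5.0)[0])
        assert np.all(np.diff(alphas) >= -1e-12)

    @given(
        R=st.floats(0.0, 1e3),
        L=st.floats(1e-3, 1e2),
        C=st.floats(1e-9, 1e-1),
        omega=st.floats(0.1, 50.0),
    )
    @settings(max_examples=50)
    def test_gamma_squared_identity(self, R, L, C, omega):
        lp = hd.LineParams(R=R, L=L, G=0.0, C=C, W=1.0, c1=0.6, c2=1.3)
        alpha, beta = hd.propagation_constants(lp, omega)
        gamma = complex(alpha, beta)
        target = (R + 1j * omega * L) * (1j * omega * C)
        assert gamma**2 == pytest.approx(target, rel=1e-9)


class TestCharacteristicImpedance:
    def test_lossless_real(self):
        lp = hd.LineParams(R=0.0, L=2.0, G=0.0, C=0.5, W=1.0, c1=0.6, c2=1.3)
        z0 = hd.characteristic_impedance(lp, omega=3.0)
        assert z0.imag == pytest.approx(0.0, abs=1e-12)
        assert z0.real == pytest.approx(math.sqrt(2.0 / 0.5), rel=1e-12)

    @given(
        R=st.floats(0.0, 1e3),
        L=st.floats(1e-3, 1e2),
        C=st.floats(1e-9, 1e-1),
        omega=st.floats(0.1, 50.0),
    )
    @settings(max_examples=50)
    def test_magnitude_identity(self, R, L, C, omega):
        lp = hd.LineParams(R=R, L=L, G=0.0, C=C, W=1.0, c1=0.6, c2=1.3)
        z0 = hd.characteristic_impedance(lp, omega)
        assert abs(z0) ** 2 * abs(1j * omega * C) == pytest.approx(
            abs(R + 1j * omega * L), rel=1e-9
        )

    def test_zero_frequency_rejected(self):
        lp = hd.LineParams(R=1.0, L=2.0, G=0.0, C=0.5, W=1.0, c1=0.6, c2=1.3)
        with pytest.raises(DomainError):
            hd.characteristic_impedance(lp, omega=0.0)


# ---------------------------------------------------------------------------
# pressures, compliance, thickness
# ---------------------------------------------------------------------------


class TestMeanBp:
    @pytest.mark.parametrize("sbp,dbp,expected", [(120, 80, 93.3333333333), (90, 60, 70.0)])
    def test_values(self, sbp, dbp, expected):
        assert hd.mean_bp(sbp, dbp) == pytest.approx(expected, rel=1e-9)

    @given(dbp=st.floats(40, 119), pulse=st.floats(1, 100))
    def test_between_dbp_and_sbp(self, dbp, pulse):
        sbp = dbp + pulse
        mbp = hd.mean_bp(sbp, dbp)
        assert dbp < mbp < sbp

    def test_equal_pressures_rejected(self):
        with pytest.raises(DomainError):
            hd.mean_bp(80, 80)


class TestVesselCompliance:
    def test_no_pulsation_zero(self):
        assert hd.vessel_compliance(0.5, 0.5, 120, 80) == 0.0

    def test_halves_with_double_pulse_pressure(self):
        c1 = hd.vessel_compliance(0.6, 0.5, 120, 80)
        c2 = hd.vessel_compliance(0.6, 0.5, 160, 80)
        assert c2 == pytest.approx(c1 / 2, rel=1e-12)

    def test_circular_cross_section_oracle(self):
        d_max, d_min = 0.52, 0.48
        a_max, a_min = math.pi * d_max**2 / 4, math.pi * d_min**2 / 4
        got = hd.vessel_compliance(a_max, a_min, 120, 80)
        expected = (a_max - a_min) / (40 * 1333.22)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_pulse_pressure_rejected(self):
        with pytest.raises(DomainError):
            hd.vessel_compliance(0.6, 0.5, 100, 100)


class TestVesselThickness:
    def _vessel(self, d_max, d_min, E=4e6, sigma_p=0.49):
        d0 = 0.5 * (d_max + d_min)
        return hd.VesselState(
            D=d_max, d=d0, d0=d0, h1=0.03, h2=0.0, E=E, sigma_p=sigma_p,
            d_max=d_max, d_min=d_min,
        )

    def test_inverse_in_e(self):
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        h1 = hd.vessel_thickness(self._vessel(0.52, 0.48, E=4e6), hemo)
        h2 = hd.vessel_thickness(self._vessel(0.52, 0.48, E=8e6), hemo)
        assert h2 == pytest.approx(h1 / 2, rel=1e-12)

    def test_doubles_with_pulse_pressure(self):
        v = self._vessel(0.52, 0.48)
        h1 = hd.vessel_thickness(v, hd.Hemodynamics(120, 80, 72))
        h2 = hd.vessel_thickness(v, hd.Hemodynamics(160, 80, 72))
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_compliance_round_trip_up_to_convention(self):
        """Thickness -> line compliance reproduces the pressure-strain
        compliance up to the documented constant factor (pi)."""
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        d_max, d_min = 0.53, 0.47
        v = self._vessel(d_max, d_min)
        h = hd.vessel_thickness(v, hemo)
        v2 = hd.VesselState(
            D=d_max, d=v.d0, d0=v.d0, h1=h, h2=0.0, E=v.E, sigma_p=v.sigma_p,
            d_max=d_max, d_min=d_min,
        )
        lp = hd.line_params(v2, hemo, BP)
        a_max, a_min = math.pi * d_max**2 / 4, math.pi * d_min**2 / 4
        c_strain = hd.vessel_compliance(a_max, a_min, 120, 80)
        assert c_strain == pytest.approx(
            hd.COMPLIANCE_CONVENTION_FACTOR * lp.C, rel=1e-9
        )

    def test_no_pulsation_rejected(self):
        with pytest.raises(DomainError):
            hd.vessel_thickness(self._vessel(0.5, 0.5), hd.Hemodynamics(120, 80, 72))


# ---------------------------------------------------------------------------
# DOS
# ---------------------------------------------------------------------------


class TestDos:
    def test_no_stenosis(self):
        assert hd.dos_from_geometry(0.5, 0.5) == 0.0

    def test_seventy_percent_diameter(self):
        assert hd.dos_from_geometry(0.7, 1.0) == pytest.approx(51.0, rel=1e-12)

    def test_strictly_decreasing_in_d(self):
        ds = np.linspace(0.1, 0.6, 30)
        vals = [hd.dos_from_geometry(d, 0.6) for d in ds]
        assert np.all(np.diff(vals) < 0)

    def test_d_above_D_rejected(self):
        with pytest.raises(DomainError):
            hd.dos_from_geometry(0.7, 0.6)

    def test_thickness_no_hyperplasia(self):
        assert hd.dos_from_thickness(0.3, 0.05, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_thickness_oracle(self):
        assert hd.dos_from_thickness(0.3, 0.1, 0.05) == pytest.approx(43.75, rel=1e-12)

    @given(
        d=st.floats(0.1, 1.0),
        h1=st.floats(0.0, 0.1),
        h2=st.floats(0.0, 0.3),
    )
    @settings(max_examples=100)
    def test_identity_with_geometry_form(self, d, h1, h2):
        h = h1 + h2
        got = hd.dos_from_thickness(d, h, h1)
        expected = hd.dos_from_geometry(d, d + 2 * h2)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_h_below_h1_rejected(self):
        with pytest.raises(DomainError):
            hd.dos_from_thickness(0.3, 0.04, 0.05)


# ---------------------------------------------------------------------------
# BFV
# ---------------------------------------------------------------------------


class TestAverageBfv:
    def test_linear_in_mbp(self):
        v = _fixture_vessel({"d0": 0.5, "h": 0.05, "E": 4e6, "sigma_p": 0.49})
        q1 = hd.average_bfv(v, hd.Hemodynamics(120, 80, 72), BP)
        # MBP doubles: (240, 160) vs (120, 80)
        q2 = hd.average_bfv(v, hd.Hemodynamics(240, 160, 72), BP)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_monotone_in_d0(self):
        hemo = hd.Hemodynamics(120, 80, 72)
        qs = []
        for d0 in np.linspace(0.1, 0.8, 15):
            v = _fixture_vessel({"d0": d0, "h": 0.05, "E": 4e6, "sigma_p": 0.49})
            qs.append(hd.average_bfv(v, hemo, BP))
        assert np.all(np.diff(qs) > 0)

    def test_lossless_limit(self):
        """With R = 0 the flow magnitude is MBP * sqrt(C/L) * 60.

        (The Womersley-corrected R cannot reach 0 through the viscosity,
        so the limit is checked on the line parameters directly.)
        """
        omega = 2 * math.pi * 72 / 60
        L, C = 7.11, 3.73e-7
        lp = hd.LineParams(R=0.0, L=L, G=0.0, C=C, W=1.0, c1=0.63, c2=1.372)
        z0 = hd.characteristic_impedance(lp, omega)
        mbp_cgs = hd.mean_bp(120, 80) * hd.MMHG_TO_DYN_CM2
        assert abs(mbp_cgs / z0) * 60 == pytest.approx(
            mbp_cgs * math.sqrt(C / L) * 60, rel=1e-9
        )

    def test_healthy_fixture_physiological_range(self):
        """Order-of-magnitude guard for a healthy mid-forearm fistula."""
        v = hd.VesselState(
            D=0.62, d=0.6, d0=0.6, h1=0.03, h2=0.0, E=2e7, sigma_p=0.49,
            d_max=0.62, d_min=0.58,
        )
        q = hd.average_bfv(v, hd.Hemodynamics(120, 80, 72), BP)
        assert 200 <= q <= 2000

    def test_dos_monotonicity(self, calibration):
        """Flow is nonincreasing in stenosis at fixed D, E, MBP, HR."""
        hemo = hd.Hemodynamics(120, 80, 72)
        qs = []
        for dos in np.linspace(0, 90, 19):
            feats = hd.features_from_vessel(
                dos, 0.6 * math.sqrt(1 - dos / 100), hemo, 0.97, calibration
            )
            qs.append(feats["bfv_ml_min"])
        assert np.all(np.diff(qs) <= 1e-9)


# ---------------------------------------------------------------------------
# feature-space inverse maps and closure
# ---------------------------------------------------------------------------


class TestFeatureInverses:
    def test_zero_pulsatility_rejected(self, calibration):
        with pytest.raises(DomainError):
            hd.dos_from_features(0.02, 0.02, 0.97, 120, 80, calibration)

    def test_dos_closure(self, calibration):
        hemo = hd.Hemodynamics(sbp=125, dbp=82, hr_bpm=68)
        feats = hd.features_from_vessel(40.0, 0.5, hemo, 0.96, calibration)
        got = hd.dos_from_features(
            feats["pi_max"], feats["pi_min"], feats["spo2"],
            feats["sbp"], feats["dbp"], calibration,
        )
        assert got == pytest.approx(40.0, rel=1e-6)

    def test_bfv_closure(self, calibration):
        hemo = hd.Hemodynamics(sbp=125, dbp=82, hr_bpm=68)
        feats = hd.features_from_vessel(40.0, 0.5, hemo, 0.96, calibration)
        got = hd.bfv_from_features(
            feats["pi_max"], feats["pi_min"], feats["spo2"],
            feats["sbp"], feats["dbp"], feats["hr"], calibration,
        )
        assert got == pytest.approx(feats["bfv_ml_min"], rel=1e-6)

    @given(
        dos=st.floats(0.0, 80.0),
        d=st.floats(0.3, 0.7),
        spo2=st.floats(0.9, 1.0),
    )
    @settings(max_examples=60)
    def test_closure_property(self, dos, d, spo2):
        cal = hd.CalibrationConstants()
        hemo = hd.Hemodynamics(sbp=130, dbp=85, hr_bpm=75)
        feats = hd.features_from_vessel(dos, d, hemo, spo2, cal)
        got_dos = hd.dos_from_features(
            feats["pi_max"], feats["pi_min"], spo2, 130, 85, cal
        )
        got_bfv = hd.bfv_from_features(
            feats["pi_max"], feats["pi_min"], spo2, 130, 85, 75, cal
        )
        assert got_dos == pytest.approx(dos, rel=1e-6, abs=1e-6)
        assert got_bfv == pytest.approx(feats["bfv_ml_min"], rel=1e-6)

    def test_scale_invariance(self, calibration):
        """(PI, kappa) -> (c PI, kappa / c) leaves DOS unchanged."""
        from dataclasses import replace

        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        feats = hd.features_from_vessel(35.0, 0.5, hemo, 0.97, calibration)
        base = hd.dos_from_features(
            feats["pi_max"], feats["pi_min"], 0.97, 120, 80, calibration
        )
        c = 3.7
        cal2 = replace(calibration, kappa=calibration.kappa / c)
        scaled = hd.dos_from_features(
            c * feats["pi_max"], c * feats["pi_min"], 0.97, 120, 80, cal2
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_bfv_increases_with_mbp_at_fixed_pulse_pressure(self, calibration):
        """Raising SBP and DBP together (pulse pressure fixed) raises the
        flow estimate linearly through MBP.  Raising SBP alone also raises
        the inferred wall thickness, so monotonicity only holds at fixed
        pulse pressure."""
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        feats = hd.features_from_vessel(20.0, 0.55, hemo, 0.97, calibration)
        args = (feats["pi_max"], feats["pi_min"], 0.97)
        q1 = hd.bfv_from_features(*args, 120, 80, 72, calibration)
        q2 = hd.bfv_from_features(*args, 140, 100, 72, calibration)
        assert q2 > q1
        assert q2 == pytest.approx(
            q1 * hd.mean_bp(140, 100) / hd.mean_bp(120, 80), rel=1e-9
        )

    def test_bfv_decreases_with_shrinking_pi(self, calibration):
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=72)
        feats = hd.features_from_vessel(20.0, 0.55, hemo, 0.97, calibration)
        qs = []
        for c in np.linspace(1.0, 0.5, 8):
            qs.append(
                hd.bfv_from_features(
                    c * feats["pi_max"], c * feats["pi_min"], 0.97, 120, 80, 72,
                    calibration,
                )
            )
        assert np.all(np.diff(qs) < 0)


class TestTypeInvariants:
    def test_vessel_state_invariants(self):
        with pytest.raises(DomainError):
            hd.VesselState(D=0.5, d=0.6, d0=0.55, h1=0.03, h2=0.0, E=4e6,
                           sigma_p=0.49, d_max=0.6, d_min=0.5)
        with pytest.raises(DomainError):
            hd.VesselState(D=0.6, d=0.5, d0=0.5, h1=0.03, h2=0.0, E=4e6,
                           sigma_p=0.5, d_max=0.52, d_min=0.48)

    def test_hemodynamics_omega(self):
        hemo = hd.Hemodynamics(sbp=120, dbp=80, hr_bpm=60)
        assert hemo.omega == pytest.approx(2 * math.pi, rel=1e-12)

    def test_optical_constants_reject_equal_eps(self):
        with pytest.raises(DomainError):
            hd.OpticalConstants(eps_HbO=1.0, eps_Hb=1.0)

    def test_line_params_reject_nonzero_g(self):
        with pytest.raises(DomainError):
            hd.LineParams(R=1, L=1, G=0.1, C=1, W=1, c1=0.6, c2=1.3)
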