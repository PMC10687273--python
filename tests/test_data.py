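"""Data model, conversions, and the built-in dataset."""

import io
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scsol as s


class TestAssayConversion:
    def test_back_solved_vial_concentration_reproduces_measured_mole_fraction(self):
        # 0.010808 g/L in the 5 mL vial after discharging 600 uL of
        # saturated fluid at 769 g/L corresponds to the measured 1.297e-5
        y2 = s.mole_fraction_from_assay(0.010808, s.AssayGeometry(), 769.0)
        assert y2 == pytest.approx(1.297e-5, rel=1e-3)

    def test_zero_solute_limit(self):
        assert s.mole_fraction_from_assay(0.0, s.AssayGeometry(), 769.0) == 0.0

    def test_dilute_scaling_halves_mole_fraction(self):
        # doubling both loop volume and density quadruples n_CO2 against a
        # fixed vial load; for y2 << 1 that halves y2 when C_s also doubles
        g1 = s.AssayGeometry(loop_volume=6e-4, vial_volume=5e-3)
        g2 = s.AssayGeometry(loop_volume=12e-4, vial_volume=5e-3)
        y1 = s.mole_fraction_from_assay(0.01, g1, 769.0)
        y2 = s.mole_fraction_from_assay(0.02, g2, 2 * 769.0)
        assert y2 == pytest.approx(y1 / 2, rel=1e-4)

    def test_invalid_inputs_raise(self):
        with pytest.raises(s.DomainError):
            s.mole_fraction_from_assay(-1.0, s.AssayGeometry(), 769.0)
        with pytest.raises(s.DomainError):
            s.mole_fraction_from_assay(0.01, s.AssayGeometry(), -769.0)
        with pytest.raises(s.DomainError):
            s.AssayGeometry(loop_volume=0.0)

    def test_assay_path_consistent_with_density_ratio_path(self, codeine):
        # for every record: back-solve C_s from y2, then S = C_s Vs/V1
        # must equal rho (Ms/MCO2) y2/(1-y2) to near machine precision
        geom = s.AssayGeometry()
        for r in codeine:
            n_co2 = geom.loop_volume * r.solvent_density / s.CO2.molar_mass
            n_drug = r.mole_fraction / (1 - r.mole_fraction) * n_co2
            c_s = n_drug * s.CODEINE_PHOSPHATE.molar_mass / geom.vial_volume
            s_assay = c_s * geom.vial_volume / geom.loop_volume
            s_direct = s.solubility_gL_from_mole_fraction(
                r.mole_fraction, r.solvent_density
            )
            assert abs(s_assay - s_direct) / s_direct < 1e-10


class TestSolubilityConversion:
    @pytest.mark.parametrize(
        "y2, rho, expected",
        [(1.297e-5, 769.0, 0.090), (6.502e-5, 783.0, 0.459)],
    )
    def test_printed_equilibrium_solubility(self, y2, rho, expected):
        assert s.solubility_gL_from_mole_fraction(y2, rho) == pytest.approx(
            expected, rel=5e-3
        )

    def test_zero_and_domain(self):
        assert s.solubility_gL_from_mole_fraction(0.0, 769.0) == 0.0
        assert s.mole_fraction_from_solubility_gL(0.0, 769.0) == 0.0
        with pytest.raises(s.DomainError):
            s.solubility_gL_from_mole_fraction(1.0, 769.0)
        with pytest.raises(s.DomainError):
            s.mole_fraction_from_solubility_gL(-0.1, 769.0)

    def test_inverse_example(self):
        assert s.mole_fraction_from_solubility_gL(0.09007, 769.0) == pytest.approx(
            1.297e-5, rel=1e-3
        )

    def test_round_trip_identity_on_every_record(self, codeine):
        y = codeine.mole_fraction
        back = s.mole_fraction_from_solubility_gL(
            s.solubility_gL_from_mole_fraction(y, codeine.solvent_density),
            codeine.solvent_density,
        )
        assert np.max(np.abs(back - y) / y) < 1e-12

    @given(
        y2=st.floats(1e-8, 0.5),
        y2b=st.floats(1e-8, 0.5),
        rho=st.floats(100.0, 1200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_conversion_strictly_monotone(self, y2, y2b, rho):
        s1 = s.solubility_gL_from_mole_fraction(y2, rho)
        s2 = s.solubility_gL_from_mole_fraction(y2b, rho)
        assert (s1 < s2) == (y2 < y2b) or y2 == y2b


class TestBuiltinDataset:
    def test_shape_and_grid(self, codeine):
        assert len(codeine) == 24
        assert set(codeine.temperatures) == {308.0, 318.0, 328.0, 338.0}
        assert set(np.unique(codeine.pressure)) == {12.0, 15.0, 18.0, 21.0, 24.0, 27.0}

    def test_anchor_record_and_extremes(self, codeine):
        rec = next(r for r in codeine if r.temperature == 308 and r.pressure == 12)
        assert rec.solvent_density == 769.0
        assert rec.mole_fraction == pytest.approx(1.297e-5)
        assert codeine.mole_fraction.min() == pytest.approx(1.297e-5)
        assert codeine.mole_fraction.max() == pytest.approx(6.502e-5)

    def test_printed_solubility_column_consistent_with_mole_fractions(self, codeine):
        # printed S and printed y2 satisfy the density-ratio relation
        # within the rounding of the printed values
        for r in codeine:
            s_calc = s.solubility_gL_from_mole_fraction(
                r.mole_fraction, r.solvent_density
            )
            assert abs(s_calc - r.equilibrium_solubility) / r.equilibrium_solubility < 0.01

    def test_records_sorted_by_temperature_then_pressure(self, codeine):
        keys = [(r.temperature, r.pressure) for r in codeine]
        assert keys == sorted(keys)

    def test_record_validation(self):
        with pytest.raises(s.DomainError):
            s.SolubilityRecord(-300, 12, 769, 1e-5)
        with pytest.raises(s.DomainError):
            s.SolubilityRecord(300, 12, 769, 1.5)
        with pytest.raises(s.DomainError):
            s.SolubilityDataset([])


class TestSampleStd:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1.0, 1.0, 1.0], 0.0),
            ([1.0, 2.0, 3.0], 1.0),
            ([1.29e-5, 1.30e-5, 1.31e-5], 1.0e-7),
        ],
    )
    def test_bessel_corrected_values(self, values, expected):
        assert s.sample_std(values) == pytest.approx(expected, abs=1e-12)

    def test_requires_two_replicates(self):
        with pytest.raises(s.DomainError):
            s.sample_std([1.0])


class TestIO:
    def test_csv_round_trip(self, codeine, tmp_path):
        path = tmp_path / "codeine.csv"
        codeine.to_csv(path)
        back = s.SolubilityDataset.from_csv(path)
        assert len(back) == 24
        np.testing.assert_allclose(back.mole_fraction, codeine.mole_fraction, rtol=1e-11)
        np.testing.assert_allclose(
            [r.std_dev for r in back], [r.std_dev for r in codeine], rtol=1e-11
        )

    def test_csv_comment_lines_ignored(self):
        text = (
            "# generated dataset\n"
            "temperature_K,pressure_MPa,density_kg_m3,mole_fraction\n"
            "308,12,769,1.297e-05\n"
        )
        ds = s.SolubilityDataset.from_csv(io.StringIO(text))
        assert len(ds) == 1 and ds[0].solvent_density == 769.0

    def test_substance_config_json_and_yaml(self, tmp_path):
        d = {"name": "test solute", "molar_mass": 397.42, "melting_temperature": 428.15}
        jpath = tmp_path / "solute.json"
        jpath.write_text(json.dumps(d))
        assert s.load_substance(jpath).molar_mass == 397.42
        ypath = tmp_path / "solute.yaml"
        ypath.write_text("name: test solute\nmolar_mass: 397.42\n")
        assert s.load_substance(ypath).name == "test solute"

    def test_substance_requirements(self):
        bare = s.SubstanceProperties(name="x", molar_mass=100.0)
        with pytest.raises(s.ConfigurationError):
            bare.require_fusion()
        with pytest.raises(s.ConfigurationError):
            bare.require_critical()
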