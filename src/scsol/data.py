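"""Data model for isothermal solubility measurements in supercritical CO2.

Unit conventions, fixed throughout the package: temperature in K, pressure
in MPa, solvent density in kg/m3 (numerically identical to g/L), solubility
either as mole fraction ``y2`` or equilibrium solubility ``S`` in g/L.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Gas constant, J/(mol K), the value used in every correlation here.
R = 8.314

CSV_COLUMNS = [
    "temperature_K",
    "pressure_MPa",
    "density_kg_m3",
    "mole_fraction",
    "solubility_g_L",
    "std",
    "expanded_U",
]


class DomainError(ValueError):
    """An input violates a physical-domain precondition."""


class ConfigurationError(ValueError):
    """A required substance constant or setting is missing."""


@dataclass(frozen=True)
class SubstanceProperties:
    """Physical constants of a solute or solvent.

    Parameters
    ----------
    molar_mass : float
        g/mol.
    enthalpy_of_fusion : float, optional
        J/mol; required for expanded-liquid models.
    melting_temperature : float, optional
        K; required for expanded-liquid models.
    critical_temperature, critical_pressure, acentric_factor : float, optional
        K, MPa, dimensionless; required for cubic-EoS use of the substance.
    """

    name: str
    molar_mass: float
    enthalpy_of_fusion: float | None = None
    melting_temperature: float | None = None
    critical_temperature: float | None = None
    critical_pressure: float | None = None
    acentric_factor: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise DomainError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.melting_temperature is not None and self.melting_temperature <= 0:
            raise DomainError("melting_temperature must be > 0")

    def require_fusion(self) -> tuple[float, float]:
        if self.enthalpy_of_fusion is None or self.melting_temperature is None:
            raise ConfigurationError(
                f"{self.name}: enthalpy_of_fusion and melting_temperature are "
                "required for solid-liquid equilibrium models"
            )
        return self.enthalpy_of_fusion, self.melting_temperature

    def require_critical(self) -> tuple[float, float, float]:
        if (
            self.critical_temperature is None
            or self.critical_pressure is None
            or self.acentric_factor is None
        ):
            raise ConfigurationError(
                f"{self.name}: critical_temperature, critical_pressure and "
                "acentric_factor are required for equation-of-state use"
            )
        return self.critical_temperature, self.critical_pressure, self.acentric_factor

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "SubstanceProperties":
        return cls(**d)


def load_substance(path: str | Path) -> SubstanceProperties:
    """Read substance constants from a JSON or YAML config file."""
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        return SubstanceProperties.from_dict(yaml.safe_load(text))
    return SubstanceProperties.from_dict(json.loads(text))


#: CO2 solvent constants. Critical point and acentric factor are the standard
#: literature values; they feed the Peng-Robinson solvent branch and reduced
#: coordinates, and are overridable per dataset.
CO2 = SubstanceProperties(
    name="carbon dioxide",
    molar_mass=44.01,
    critical_temperature=304.13,
    critical_pressure=7.377,
    acentric_factor=0.225,
)

#: Codeine phosphate solute constants: molar mass of the phosphate salt and
#: calorimetric fusion data (18.86 cal/g at a 155 degC melting point).
CODEINE_PHOSPHATE = SubstanceProperties(
    name="codeine phosphate",
    molar_mass=397.42,
    enthalpy_of_fusion=31358.83,
    melting_temperature=428.15,
)


@dataclass(frozen=True)
class AssayGeometry:
    """Sampling-loop and collection-vial volumes of the saturation assay (L)."""

    loop_volume: float = 6e-4
    vial_volume: float = 5e-3

    def __post_init__(self) -> None:
        if self.loop_volume <= 0 or self.vial_volume <= 0:
            raise DomainError("assay volumes must be > 0")


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium observation: (T, P, solvent density, mole fraction).

    ``std_dev`` and ``expanded_uncertainty`` are on the same absolute scale
    as ``mole_fraction`` (not premultiplied by 1e5).
    """

    temperature: float
    pressure: float
    solvent_density: float
    mole_fraction: float
    equilibrium_solubility: float | None = None
    std_dev: float | None = None
    expanded_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0, got {self.temperature}")
        if self.pressure <= 0:
            raise DomainError(f"pressure must be > 0, got {self.pressure}")
        if self.solvent_density <= 0:
            raise DomainError(f"solvent_density must be > 0, got {self.solvent_density}")
        if not 0 < self.mole_fraction < 1:
            raise DomainError(
                f"mole_fraction must lie in (0, 1), got {self.mole_fraction}"
            )


class SolubilityDataset:
    """Ordered collection of solubility records for one solute/solvent pair.

    Records are kept sorted by (temperature, pressure). Column views are
    exposed as numpy arrays for the model evaluators.
    """

    def __init__(
        self,
        records: Iterable[SolubilityRecord],
        solute: SubstanceProperties = CODEINE_PHOSPHATE,
        solvent: SubstanceProperties = CO2,
    ) -> None:
        recs = sorted(records, key=lambda r: (r.temperature, r.pressure))
        if not recs:
            raise DomainError("dataset must contain at least one record")
        self.records: tuple[SolubilityRecord, ...] = tuple(recs)
        self.solute = solute
        self.solvent = solvent

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def temperature(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records])

    @property
    def pressure(self) -> np.ndarray:
        return np.array([r.pressure for r in self.records])

    @property
    def solvent_density(self) -> np.ndarray:
        return np.array([r.solvent_density for r in self.records])

    @property
    def mole_fraction(self) -> np.ndarray:
        return np.array([r.mole_fraction for r in self.records])

    @property
    def temperatures(self) -> np.ndarray:
        """Distinct temperatures, ascending."""
        return np.unique(self.temperature)

    def with_density_scaled(self, factor: float) -> "SolubilityDataset":
        """Copy with solvent densities multiplied by ``factor`` (unit change)."""
        return SolubilityDataset(
            [
                SolubilityRecord(
                    r.temperature,
                    r.pressure,
                    r.solvent_density * factor,
                    r.mole_fraction,
                    r.equilibrium_solubility,
                    r.std_dev,
                    r.expanded_uncertainty,
                )
                for r in self.records
            ],
            self.solute,
            self.solvent,
        )

    def with_pressure_scaled(self, factor: float) -> "SolubilityDataset":
        """Copy with pressures multiplied by ``factor`` (unit change)."""
        return SolubilityDataset(
            [
                SolubilityRecord(
                    r.temperature,
                    r.pressure * factor,
                    r.solvent_density,
                    r.mole_fraction,
                    r.equilibrium_solubility,
                    r.std_dev,
                    r.expanded_uncertainty,
                )
                for r in self.records
            ],
            self.solute,
            self.solvent,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "temperature_K": r.temperature,
                    "pressure_MPa": r.pressure,
                    "density_kg_m3": r.solvent_density,
                    "mole_fraction": r.mole_fraction,
                    "solubility_g_L": r.equilibrium_solubility,
                    "std": r.std_dev,
                    "expanded_U": r.expanded_uncertainty,
                }
            )
        df = pd.DataFrame(rows)
        return df.dropna(axis=1, how="all")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        solute: SubstanceProperties = CODEINE_PHOSPHATE,
        solvent: SubstanceProperties = CO2,
    ) -> "SolubilityDataset":
        def opt(row, col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        records = [
            SolubilityRecord(
                temperature=float(row["temperature_K"]),
                pressure=float(row["pressure_MPa"]),
                solvent_density=float(row["density_kg_m3"]),
                mole_fraction=float(row["mole_fraction"]),
                equilibrium_solubility=opt(row, "solubility_g_L"),
                std_dev=opt(row, "std"),
                expanded_uncertainty=opt(row, "expanded_U"),
            )
            for _, row in df.iterrows()
        ]
        return cls(records, solute, solvent)

    def to_csv(self, path_or_buf) -> None:
        df = self.to_dataframe()
        df.to_csv(path_or_buf, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls,
        path_or_buf,
        solute: SubstanceProperties = CODEINE_PHOSPHATE,
        solvent: SubstanceProperties = CO2,
    ) -> "SolubilityDataset":
        df = pd.read_csv(path_or_buf, comment="#")
        return cls.from_dataframe(df, solute, solvent)


# ---------------------------------------------------------------------------
# Conversions between assay concentration, mole fraction, and g/L solubility
# ---------------------------------------------------------------------------

def mole_fraction_from_assay(
    concentration_gL: float,
    geometry: AssayGeometry,
    solvent_density: float,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    solvent: SubstanceProperties = CO2,
) -> float:
    """Mole fraction from the measured vial concentration ``C_s`` (g/L).

    ``n_drug = C_s V_s / M_s`` moles of solute in the vial and
    ``n_CO2 = V_1 rho / M_CO2`` moles of solvent discharged through the
    sampling loop; ``y2 = n_drug / (n_drug + n_CO2)``.
    """
    if concentration_gL < 0:
        raise DomainError("assay concentration must be >= 0")
    if solvent_density <= 0:
        raise DomainError("solvent_density must be > 0")
    n_drug = concentration_gL * geometry.vial_volume / solute.molar_mass
    n_co2 = geometry.loop_volume * solvent_density / solvent.molar_mass
    return n_drug / (n_drug + n_co2)


def solubility_gL_from_mole_fraction(
    y2,
    solvent_density,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    solvent: SubstanceProperties = CO2,
):
    """Equilibrium solubility S (g/L): ``S = rho (M_s/M_CO2) y2/(1-y2)``."""
    y2 = np.asarray(y2, dtype=float)
    if np.any(y2 < 0) or np.any(y2 >= 1):
        raise DomainError("mole fraction must lie in [0, 1)")
    S = solvent_density * (solute.molar_mass / solvent.molar_mass) * y2 / (1.0 - y2)
    return S if S.ndim else float(S)


def mole_fraction_from_solubility_gL(
    S,
    solvent_density,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    solvent: SubstanceProperties = CO2,
):
    """Exact algebraic inverse of :func:`solubility_gL_from_mole_fraction`."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DomainError("solubility must be >= 0")
    ratio = S * solvent.molar_mass / (solvent_density * solute.molar_mass)
    y2 = ratio / (1.0 + ratio)
    return y2 if y2.ndim else float(y2)


def sample_std(replicates: Sequence[float]) -> float:
    """Experimental standard deviation with the n-1 (Bessel) denominator."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise DomainError("sample_std requires at least two replicates")
    return float(np.std(x, ddof=1))


# ---------------------------------------------------------------------------
# Built-in crystalline codeine phosphate / SC-CO2 dataset
# ---------------------------------------------------------------------------
# 4 isotherms x 6 pressures. Columns: T (K), P (MPa), rho1 (kg/m3),
# y2 x 1e5, experimental std x 1e5, S (g/L), expanded uncertainty x 1e5.
# Mole fractions carry the precision they were reported at.
_CODEINE_TABLE = (
    (308, 12, 769, 1.297, 0.021, 0.090, 0.072),
    (308, 15, 817, 1.615, 0.014, 0.119, 0.078),
    (308, 18, 849, 1.702, 0.022, 0.131, 0.086),
    (308, 21, 875, 1.754, 0.083, 0.138, 0.113),
    (308, 24, 896, 1.897, 0.031, 0.153, 0.104),
    (308, 27, 914, 1.991, 0.055, 0.164, 0.103),
    (318, 12, 661, 1.387, 0.038, 0.083, 0.099),
    (318, 15, 744, 2.614, 0.091, 0.176, 0.041),
    (318, 18, 791, 2.742, 0.021, 0.196, 0.130),
    (318, 21, 824, 3.158, 0.077, 0.235, 0.108),
    (318, 24, 851, 3.422, 0.093, 0.263, 0.109),
    (318, 27, 872, 3.817, 0.040, 0.300, 0.106),
    (328, 12, 509, 1.891, 0.082, 0.087, 0.115),
    (328, 15, 656, 3.594, 0.011, 0.213, 0.124),
    (328, 18, 725, 3.949, 0.088, 0.259, 0.150),
    (328, 21, 769, 4.284, 0.062, 0.298, 0.127),
    (328, 24, 802, 4.521, 0.095, 0.327, 0.176),
    (328, 27, 829, 5.441, 0.063, 0.407, 0.171),
    (338, 12, 388, 2.294, 0.071, 0.080, 0.178),
    (338, 15, 557, 3.959, 0.081, 0.199, 0.142),
    (338, 18, 652, 4.395, 0.033, 0.259, 0.108),
    (338, 21, 710, 4.927, 0.128, 0.316, 0.137),
    (338, 24, 751, 5.521, 0.141, 0.375, 0.173),
    (338, 27, 783, 6.502, 0.065, 0.459, 0.115),
)


def builtin_codeine_dataset() -> SolubilityDataset:
    """The 24-point crystalline codeine phosphate / SC-CO2 dataset.

    Four isotherms (308-338 K) at 12-27 MPa; NIST solvent densities;
    triplicate-assay mole fractions with their standard deviations and
    k=2 expanded uncertainties.
    """
    records = [
        SolubilityRecord(
            temperature=float(T),
            pressure=float(P),
            solvent_density=float(rho),
            mole_fraction=y * 1e-5,
            equilibrium_solubility=S,
            std_dev=std * 1e-5,
            expanded_uncertainty=U * 1e-5,
        )
        for (T, P, rho, y, std, S, U) in _CODEINE_TABLE
    ]
    return SolubilityDataset(records, CODEINE_PHOSPHATE, CO2)
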