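"""Semi-empirical density-based solubility correlations.

Five forward evaluators plus their Model classes: the Chrastil association
model, the Mendez-Santiago/Teja (MT) single-line consistency model, the
Bartle et al. reference-state model, the six-term Sodeifian et al. form,
and the reduced-coordinate Reddy-Garlapati polynomial.

Unit conventions: T in K, P in MPa, solvent density rho1 in kg/m3. Each
correlation absorbs any change of density or pressure unit into its own
constants, so the fitted AARD is unit-invariant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._util import safe_exp
from .base import SolubilityModel
from .data import CO2, CODEINE_PHOSPHATE, ConfigurationError, SubstanceProperties


class _ParamsBase:
    """JSON (de)serialization keyed by symbol name, and array conversion."""

    _fit_fields: tuple[str, ...] | None = None  # None -> all fields

    @classmethod
    def fit_fields(cls) -> tuple[str, ...]:
        if cls._fit_fields is not None:
            return cls._fit_fields
        return tuple(f.name for f in dataclasses.fields(cls))

    def as_array(self) -> np.ndarray:
        return np.array([float(getattr(self, k)) for k in self.fit_fields()])

    @classmethod
    def from_array(cls, theta, **fixed):
        theta = np.asarray(theta, dtype=float).ravel()
        names = cls.fit_fields()
        if theta.size != len(names):
            raise ValueError(f"{cls.__name__} expects {len(names)} values")
        return cls(**dict(zip(names, theta)), **fixed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict):
        return cls(**d)


@dataclass(frozen=True)
class ChrastilParams(_ParamsBase):
    """kappa: association number; A1 dimensionless; B1 in K."""

    kappa: float
    A1: float
    B1: float


@dataclass(frozen=True)
class MTParams(_ParamsBase):
    """A2 in K; B2 in K m3/kg; C2 dimensionless."""

    A2: float
    B2: float
    C2: float


@dataclass(frozen=True)
class BartleParams(_ParamsBase):
    """A3 dimensionless; B3 in K; C3 in m3/kg; fixed reference state
    0.1 MPa / 700 kg m-3 unless overridden."""

    A3: float
    B3: float
    C3: float
    ref_pressure: float = 0.1
    ref_density: float = 700.0

    _fit_fields = ("A3", "B3", "C3")


@dataclass(frozen=True)
class SodeifianParams(_ParamsBase):
    A4: float
    B4: float
    C4: float
    D4: float
    E4: float
    F4: float


@dataclass(frozen=True)
class RGParams(_ParamsBase):
    """Six dimensionless constants plus the solvent critical point used to
    form reduced coordinates."""

    A5: float
    B5: float
    C5: float
    D5: float
    E5: float
    F5: float
    critical_temperature: float | None = None
    critical_pressure: float | None = None

    _fit_fields = ("A5", "B5", "C5", "D5", "E5", "F5")


# ---------------------------------------------------------------------------
# Forward evaluators
# ---------------------------------------------------------------------------

def chrastil_y2(
    params: ChrastilParams,
    T,
    rho1,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    solvent: SubstanceProperties = CO2,
):
    """Chrastil solubility as mole fraction.

    The solvate-complex law ``c = rho1^kappa exp(A1 + B1/T)`` is recast as a
    mole ratio ``(M_solvent/M_solute) rho1^(kappa-1) exp(A1 + B1/T)`` and
    mapped to a fraction via ``ratio / (1 + ratio)``.
    """
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    arg = (
        np.log(solvent.molar_mass / solute.molar_mass)
        + (params.kappa - 1.0) * np.log(rho1)
        + params.A1
        + params.B1 / T
    )
    ratio = safe_exp(arg, "Chrastil (kappa, A1, B1)")
    out = ratio / (1.0 + ratio)
    return out if np.ndim(out) else float(out)


def mt_y2(params: MTParams, T, P, rho1):
    """MT model: ``T ln(y2 P) = A2 + B2 rho1 + C2 T`` solved for y2."""
    T = np.asarray(T, dtype=float)
    out = safe_exp(
        (params.A2 + params.B2 * np.asarray(rho1, float) + params.C2 * T) / T,
        "MT (A2, B2, C2)",
    ) / np.asarray(P, dtype=float)
    return out if np.ndim(out) else float(out)


def bartle_y2(params: BartleParams, T, P, rho1):
    """Bartle et al.: ``ln(y2 P / Pref) = A3 + B3/T + C3 (rho1 - rho_ref)``."""
    T = np.asarray(T, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    out = (
        params.ref_pressure
        / np.asarray(P, dtype=float)
        * safe_exp(
            params.A3 + params.B3 / T + params.C3 * (rho1 - params.ref_density),
            "Bartle (A3, B3, C3)",
        )
    )
    return out if np.ndim(out) else float(out)


def sodeifian_y2(params: SodeifianParams, T, P, rho1):
    """Six-term Sodeifian et al. correlation,

        ln y2 = A4 + B4 P^2/T + C4 ln(rho1 T) + D4 rho1 ln(rho1)
                + E4 P ln(T) + F4 ln(rho1)/T,

    linear in its parameters on the log scale and therefore always
    positive.
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    out = safe_exp(
        params.A4
        + params.B4 * P**2 / T
        + params.C4 * np.log(rho1 * T)
        + params.D4 * rho1 * np.log(rho1)
        + params.E4 * P * np.log(T)
        + params.F4 * np.log(rho1) / T,
        "Sodeifian (A4..F4)",
    )
    return out if np.ndim(out) else float(out)


def reddy_garlapati_y2(params: RGParams, T, P):
    """Reddy-Garlapati: quadratic in reduced pressure, bilinear in reduced T."""
    if params.critical_temperature is None or params.critical_pressure is None:
        raise ConfigurationError(
            "Reddy-Garlapati model needs the solvent critical temperature and pressure"
        )
    Tr = np.asarray(T, dtype=float) / params.critical_temperature
    Pr = np.asarray(P, dtype=float) / params.critical_pressure
    out = (params.A5 + params.B5 * Pr + params.C5 * Pr**2) * Tr + (
        params.D5 + params.E5 * Pr + params.F5 * Pr**2
    )
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

def _lstsq(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return coef


class Chrastil(SolubilityModel):
    """Chrastil association model bound to a dataset.

    The starting point for the nonlinear AARD regression comes from
    ordinary least squares on the exactly linearized form
    ``ln(ratio) = ln(M1/M2) + (kappa-1) ln rho1 + A1 + B1/T``.
    """

    name = "chrastil"
    param_names = ("kappa", "A1", "B1")
    params_cls = ChrastilParams

    def _predict(self, theta, T, P, rho):
        return chrastil_y2(
            ChrastilParams(*theta), T, rho, self.data.solute, self.data.solvent
        )

    def start_params(self) -> np.ndarray:
        y = self.y_exp
        z = np.log(y / (1.0 - y)) - np.log(
            self.data.solvent.molar_mass / self.data.solute.molar_mass
        )
        design = np.column_stack([np.log(self.rho), np.ones_like(z), 1.0 / self.T])
        km1, a1, b1 = _lstsq(design, z)
        return np.array([km1 + 1.0, a1, b1])


class MendezSantiagoTeja(SolubilityModel):
    """MT model; also the basis of the single-line consistency diagnostic."""

    name = "mt"
    param_names = ("A2", "B2", "C2")
    params_cls = MTParams

    def _predict(self, theta, T, P, rho):
        return mt_y2(MTParams(*theta), T, P, rho)

    def start_params(self) -> np.ndarray:
        target = self.T * np.log(self.y_exp * self.P)
        design = np.column_stack([np.ones_like(self.T), self.rho, self.T])
        return _lstsq(design, target)


class Bartle(SolubilityModel):
    """Bartle et al. reference-state model; B3 carries the sublimation
    enthalpy through the van 't Hoff reading ``dH_sub = -B3 R``."""

    name = "bartle"
    param_names = ("A3", "B3", "C3")
    params_cls = BartleParams

    def __init__(self, dataset, ref_pressure: float = 0.1, ref_density: float = 700.0):
        self.ref_pressure = ref_pressure
        self.ref_density = ref_density
        super().__init__(dataset)

    def _params_obj(self, theta) -> BartleParams:
        return BartleParams(
            *theta, ref_pressure=self.ref_pressure, ref_density=self.ref_density
        )

    def _predict(self, theta, T, P, rho):
        return bartle_y2(self._params_obj(theta), T, P, rho)

    def start_params(self) -> np.ndarray:
        target = np.log(self.y_exp * self.P / self.ref_pressure)
        design = np.column_stack(
            [np.ones_like(self.T), 1.0 / self.T, self.rho - self.ref_density]
        )
        return _lstsq(design, target)


class Sodeifian(SolubilityModel):
    """Sodeifian et al. six-term correlation (log-linear in parameters)."""

    name = "sodeifian"
    param_names = ("A4", "B4", "C4", "D4", "E4", "F4")
    params_cls = SodeifianParams

    def _predict(self, theta, T, P, rho):
        return sodeifian_y2(SodeifianParams(*theta), T, P, rho)

    def _design(self) -> np.ndarray:
        T, P, rho = self.T, self.P, self.rho
        return np.column_stack(
            [
                np.ones_like(T),
                P**2 / T,
                np.log(rho * T),
                rho * np.log(rho),
                P * np.log(T),
                np.log(rho) / T,
            ]
        )

    def start_params(self) -> np.ndarray:
        return _lstsq(self._design(), np.log(self.y_exp))


class ReddyGarlapati(SolubilityModel):
    """Reddy-Garlapati reduced-coordinate polynomial."""

    name = "reddy-garlapati"
    param_names = ("A5", "B5", "C5", "D5", "E5", "F5")
    params_cls = RGParams

    def _setup(self) -> None:
        tc, pc, _ = self.data.solvent.require_critical()
        self.critical_temperature = tc
        self.critical_pressure = pc

    def _params_obj(self, theta) -> RGParams:
        return RGParams(
            *theta,
            critical_temperature=self.critical_temperature,
            critical_pressure=self.critical_pressure,
        )

    def _predict(self, theta, T, P, rho):
        return reddy_garlapati_y2(self._params_obj(theta), T, P)

    def start_params(self) -> np.ndarray:
        Tr = self.T / self.critical_temperature
        Pr = self.P / self.critical_pressure
        design = np.column_stack(
            [Tr, Pr * Tr, Pr**2 * Tr, np.ones_like(Tr), Pr, Pr**2]
        )
        return _lstsq(design, self.y_exp)
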