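"""Peng-Robinson equation-of-state solubility model for a dilute solid
solute in supercritical CO2.

The solid-fluid equilibrium closure is

    y2 = P_sub * phi2_sat / (P * phi2_hat) * exp((P - P_sub) v2 / (R T)),

with the solid saturation fugacity coefficient ``phi2_sat`` taken as 1
(negligible sublimation pressure), the fluid-phase fugacity coefficient
``phi2_hat`` from the PR EoS in the infinite-dilution limit, the solute
molar volume ``v2`` correlated quadratically in solvent density, and the
sublimation pressure parameterized in temperature. Adjustable parameters:
a2, b2 (solute PR constants), beta, gamma, dsub_delta (sublimation
pressure), K1, K2, K3 (molar volume).

Internally the cubic and the fugacity expression work in SI (Pa); the
public surface keeps pressure in MPa. The sublimation-pressure unit is
absorbed into ``beta`` during fitting; only the enthalpy read-out
``dH_sub = (-gamma + dsub_delta T) R`` is unit-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import EvaluationError, safe_exp
from .base import SolubilityModel
from .data import R, DomainError, SubstanceProperties
from .density import _ParamsBase

#: PR universal constants.
_OMEGA_A = 0.45724
_OMEGA_B = 0.07780
_SQRT8 = 2.0 * np.sqrt(2.0)


class EoSRootError(EvaluationError):
    """The PR cubic produced no physical root at the requested state."""


@dataclass(frozen=True)
class PREoSParams(_ParamsBase):
    """The eight adjustable constants of the PR solubility model.

    a2 in Pa m6/mol2, b2 in m3/mol, beta/gamma/dsub_delta in the
    sublimation-pressure expression's J/(mol K) family, K1..K3 in
    m3/mol, m6/(mol kg), m9/(mol kg2).
    """

    a2: float
    b2: float
    beta: float
    gamma: float
    dsub_delta: float
    K1: float
    K2: float
    K3: float


@dataclass(frozen=True)
class SolventEoSState:
    """Pure-solvent PR state at one (T, P): compressibility and molar volume."""

    Z1: float
    V1: float
    a1: float
    b1: float


def pr_ab_from_critical(solvent: SubstanceProperties, T) -> tuple[float, float]:
    """Pure-component PR constants from critical point and acentric factor.

    ``b = 0.07780 R Tc / Pc`` and ``a = 0.45724 R^2 Tc^2 / Pc * alpha(T)``
    with the Soave-type alpha and kappa(omega) polynomial.
    """
    tc, pc_mpa, omega = solvent.require_critical()
    pc = pc_mpa * 1e6
    b = _OMEGA_B * R * tc / pc
    kappa = 0.37464 + 1.54226 * omega - 0.26992 * omega**2
    alpha = (1.0 + kappa * (1.0 - np.sqrt(np.asarray(T, float) / tc))) ** 2
    a = _OMEGA_A * R**2 * tc**2 / pc * alpha
    return (float(a) if np.ndim(a) == 0 else a), b


def pr_pure_solve(T: float, P: float, a1: float, b1: float, phase: str = "dense") -> SolventEoSState:
    """Solve the PR cubic for the pure solvent at (T in K, P in MPa).

    Returns the phase-appropriate root: the smallest real Z > B for the
    dense/liquid-like branch, the largest for vapor. Above the critical
    point exactly one physical root exists.
    """
    if T <= 0 or P <= 0:
        raise DomainError("T and P must be > 0")
    p_pa = P * 1e6
    A = a1 * p_pa / (R**2 * T**2)
    B = b1 * p_pa / (R * T)
    coeffs = [1.0, -(1.0 - B), A - 3.0 * B**2 - 2.0 * B, -(A * B - B**2 - B**3)]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    physical = np.sort(real[real > B * (1 + 1e-12)])
    if physical.size == 0:
        raise EoSRootError(
            f"no physical PR root at T={T} K, P={P} MPa (A={A:.4g}, B={B:.4g}, "
            f"roots={roots})"
        )
    Z = physical[0] if phase == "dense" else physical[-1]
    V = Z * R * T / p_pa
    return SolventEoSState(Z1=float(Z), V1=float(V), a1=float(a1), b1=float(b1))


def fugacity_coeff_dilute(
    state: SolventEoSState, T: float, P, a2: float, b2: float, k12: float = 0.0
):
    """Infinite-dilution solute fugacity coefficient in the PR fluid.

    The full two-component PR expression collapsed at y2 -> 0 (z -> Z1,
    a -> a1, b -> b1), with the van der Waals cross term
    ``a12 = (1 - k12) sqrt(a1 a2)``:

        ln phi2 = b2/b1 (Z1 - 1) - ln(P (V1 - b1)/(R T))
                  - a1/(2 sqrt2 R T b1) (2 a12/a1 - b2/b1)
                    ln((V1 + 2.414 b1)/(V1 - 0.414 b1))
    """
    if a2 < 0:
        raise DomainError("a2 must be >= 0 for the sqrt combining rule")
    V1, b1, a1, Z1 = state.V1, state.b1, state.a1, state.Z1
    if V1 <= 0.414 * b1:
        raise DomainError(f"molar volume {V1:.4g} at/below the 0.414 b1 singularity")
    p_pa = np.asarray(P, dtype=float) * 1e6
    a12 = (1.0 - k12) * np.sqrt(a1 * a2)
    ln_phi = (
        b2 / b1 * (Z1 - 1.0)
        - np.log(p_pa * (V1 - b1) / (R * T))
        - a1
        / (_SQRT8 * R * T * b1)
        * (2.0 * a12 / a1 - b2 / b1)
        * np.log((V1 + (1.0 + np.sqrt(2.0)) * b1) / (V1 - (np.sqrt(2.0) - 1.0) * b1))
    )
    return safe_exp(ln_phi, "PR fugacity coefficient (a2, b2)")


def solute_molar_volume(rho1, K1: float, K2: float, K3: float):
    """Solute molar volume correlation ``v2 = K1 + K2 rho1 + K3 rho1^2``.

    Negative values are not clipped here; the regression objective rejects
    them by penalty.
    """
    rho1 = np.asarray(rho1, dtype=float)
    out = K1 + K2 * rho1 + K3 * rho1**2
    return out if out.ndim else float(out)


def sublimation_pressure(T, beta: float, gamma: float, dsub_delta: float):
    """Sublimation pressure (MPa by internal convention) from
    ``R ln P_sub = beta + gamma/T + dsub_delta ln(T/298.15)``."""
    T = np.asarray(T, dtype=float)
    return safe_exp(
        (beta + gamma / T + dsub_delta * np.log(T / 298.15)) / R,
        "sublimation pressure (beta, gamma, dsub_delta)",
    )


def sublimation_enthalpy(T, gamma: float, dsub_delta: float):
    """Sublimation enthalpy in J/mol: ``dH_sub = (-gamma + dsub_delta T) R``."""
    T = np.asarray(T, dtype=float)
    out = (-gamma + dsub_delta * T) * R
    return out if out.ndim else float(out)


def eos_solubility(
    params: PREoSParams,
    solvent: SubstanceProperties,
    T,
    P,
    rho1,
    states: list[SolventEoSState] | None = None,
    k12: float = 0.0,
):
    """Compose the PR closures into the solid-fluid equilibrium mole fraction.

    Explicit in y2 under the dilute-solute assumption (no self-consistency
    loop). ``states`` may carry precomputed solvent states aligned with the
    inputs; otherwise they are solved from the critical constants.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    P = np.atleast_1d(np.asarray(P, dtype=float))
    rho1 = np.atleast_1d(np.asarray(rho1, dtype=float))
    if states is None:
        states = []
        for Ti, Pi in zip(T, P):
            a1, b1 = pr_ab_from_critical(solvent, Ti)
            states.append(pr_pure_solve(Ti, Pi, a1, b1))
    p_sub = np.atleast_1d(
        sublimation_pressure(T, params.beta, params.gamma, params.dsub_delta)
    )
    v2 = solute_molar_volume(rho1, params.K1, params.K2, params.K3)
    phi2 = np.array(
        [
            fugacity_coeff_dilute(st, Ti, Pi, params.a2, params.b2, k12)
            for st, Ti, Pi in zip(states, T, P)
        ]
    )
    poynting = safe_exp((P - p_sub) * 1e6 * v2 / (R * T), "Poynting factor (K1..K3)")
    y2 = p_sub / (P * phi2) * poynting
    return y2 if y2.size > 1 else float(y2[0])


class PengRobinson(SolubilityModel):
    """PR EoS solubility model bound to a dataset.

    ``solvent_ab="critical"`` (default) computes a1, b1 from the solvent's
    critical constants with the T-dependent alpha; ``solvent_ab="fixed"``
    takes the numeric pair in ``fixed_ab`` instead. Solvent states are
    solved once per dataset, so objective evaluations during fitting are
    pure arithmetic.
    """

    name = "pr-eos"
    param_names = ("a2", "b2", "beta", "gamma", "dsub_delta", "K1", "K2", "K3")
    params_cls = PREoSParams

    def __init__(
        self,
        dataset,
        solvent_ab: str = "critical",
        fixed_ab: tuple[float, float] | None = None,
        k12: float = 0.0,
    ):
        if solvent_ab not in ("critical", "fixed"):
            raise DomainError("solvent_ab must be 'critical' or 'fixed'")
        if solvent_ab == "fixed" and fixed_ab is None:
            raise DomainError("solvent_ab='fixed' requires fixed_ab=(a1, b1)")
        self.solvent_ab = solvent_ab
        self.fixed_ab = fixed_ab
        self.k12 = k12
        super().__init__(dataset)

    def _solve_states(self, T, P) -> list[SolventEoSState]:
        states = []
        for Ti, Pi in zip(np.atleast_1d(T), np.atleast_1d(P)):
            if self.solvent_ab == "critical":
                a1, b1 = pr_ab_from_critical(self.data.solvent, Ti)
            else:
                a1, b1 = self.fixed_ab
            states.append(pr_pure_solve(float(Ti), float(Pi), a1, b1))
        return states

    def _setup(self) -> None:
        self._states = self._solve_states(self.T, self.P)

    def _predict(self, theta, T, P, rho):
        if (
            T.shape == self.T.shape
            and np.array_equal(T, self.T)
            and np.array_equal(P, self.P)
        ):
            states = self._states
        else:
            states = self._solve_states(T, P)
        return eos_solubility(
            PREoSParams(*theta), self.data.solvent, T, P, rho, states=states, k12=self.k12
        )

    def default_bounds(self):
        inf = np.inf
        return [
            (0.0, inf),   # a2: sqrt combining rule
            (0.0, inf),   # b2: covolume
            (-inf, inf),
            (-inf, inf),
            (-inf, inf),
            (-inf, inf),
            (-inf, inf),
            (-inf, inf),
        ]

    def start_params(self) -> np.ndarray:
        """Least-squares start from the exact log-linearization.

        With s = sqrt(a2) and the sublimation pressure dropped against P
        (it is orders of magnitude smaller), ln y2 is linear in
        (s, b2, beta, gamma, dsub_delta, K1, K2, K3); ordinary least
        squares on that form seeds the nonlinear AARD regression. Falls
        back to a fixed magnitude template if the design is degenerate.
        """
        template = np.array([1.0, 3e-4, 20.0, -9000.0, -6.0, 7e-4, 0.0, 0.0])
        try:
            T, P, rho = self.T, self.P, self.rho
            p_pa = P * 1e6
            Z1 = np.array([st.Z1 for st in self._states])
            V1 = np.array([st.V1 for st in self._states])
            a1 = np.array([st.a1 for st in self._states])
            b1 = np.array([st.b1 for st in self._states])
            ln_vr = np.log(
                (V1 + (1 + np.sqrt(2.0)) * b1) / (V1 - (np.sqrt(2.0) - 1) * b1)
            )
            c_s = np.sqrt(a1) * ln_vr / (np.sqrt(2.0) * R * T * b1)
            c_b = (Z1 - 1.0) / b1 + a1 * ln_vr / (_SQRT8 * R * T * b1**2)
            design = np.column_stack(
                [
                    c_s,                       # sqrt(a2)
                    -c_b,                      # b2
                    np.full_like(T, 1.0 / R),  # beta
                    1.0 / (R * T),             # gamma
                    np.log(T / 298.15) / R,    # dsub_delta
                    p_pa / (R * T),            # K1
                    p_pa * rho / (R * T),      # K2
                    p_pa * rho**2 / (R * T),   # K3
                ]
            )
            target = np.log(self.y_exp) + np.log(P) - np.log(p_pa * (V1 - b1) / (R * T))
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            s, b2 = max(coef[0], 0.0), max(coef[1], 0.0)
            theta = np.array([s**2, b2, *coef[2:]])
            if np.all(np.isfinite(theta)):
                return theta
        except (np.linalg.LinAlgError, FloatingPointError):
            pass
        return template
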