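"""Expanded-liquid (solid-liquid equilibrium) solubility models.

The supercritical phase is treated as an expanded liquid; solubility is
the ideal-fusion fugacity ratio divided by the solute's infinite-dilution
activity coefficient,

    y2 = (f2_S / f2_L) / gamma2_inf,

with ``gamma2_inf = exp(l1 + l2 x + l3 x^2)``, ``x = P/(R T)`` (P in MPa,
R = 8.314). Three closures for the solid/liquid heat-capacity difference
dCp inside the fugacity-ratio integral:

* case 1: dCp = 0 (3 parameters: l1, l2, l3)
* case 2: dCp = D constant (4 parameters)
* case 3: dCp = beta1 + beta2 T + beta3 T^2 (6 parameters), with the
  exact closed form of the double integral.

All three are explicit in composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import safe_exp
from .base import SolubilityModel
from .data import CODEINE_PHOSPHATE, R, DomainError, SubstanceProperties
from .density import _ParamsBase, _lstsq


@dataclass(frozen=True)
class ELMParams(_ParamsBase):
    """Parameters of one expanded-liquid case.

    ``case_id`` selects the dCp closure; ``D`` is required exactly for
    case 2 and ``beta1..beta3`` exactly for case 3.
    """

    case_id: int
    l1: float
    l2: float
    l3: float
    D: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    beta3: float | None = None

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3):
            raise DomainError(f"case_id must be 1, 2 or 3, got {self.case_id}")
        need_d = self.case_id == 2
        need_b = self.case_id == 3
        if need_d != (self.D is not None):
            raise DomainError("D must be given exactly for case 2")
        betas_given = all(b is not None for b in (self.beta1, self.beta2, self.beta3))
        betas_absent = all(b is None for b in (self.beta1, self.beta2, self.beta3))
        if need_b and not betas_given:
            raise DomainError("beta1, beta2, beta3 must all be given for case 3")
        if not need_b and not betas_absent:
            raise DomainError("beta1..beta3 are only allowed for case 3")

    @classmethod
    def case_fields(cls, case_id: int) -> tuple[str, ...]:
        return {
            1: ("l1", "l2", "l3"),
            2: ("l1", "l2", "l3", "D"),
            3: ("l1", "l2", "l3", "beta1", "beta2", "beta3"),
        }[case_id]

    def as_array(self) -> np.ndarray:
        return np.array(
            [float(getattr(self, k)) for k in self.case_fields(self.case_id)]
        )

    @classmethod
    def from_array(cls, case_id: int, theta) -> "ELMParams":
        names = cls.case_fields(case_id)
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != len(names):
            raise DomainError(f"case {case_id} expects {len(names)} parameters")
        return cls(case_id=case_id, **dict(zip(names, theta)))


def activity_coeff_inf(T, P, l1: float, l2: float, l3: float):
    """Infinite-dilution activity coefficient, pressure-polynomial form."""
    x = np.asarray(P, dtype=float) / (R * np.asarray(T, dtype=float))
    return safe_exp(l1 + l2 * x + l3 * x**2, "activity coefficient (l1, l2, l3)")


def _dcp_brackets(T: np.ndarray, t_m: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three temperature brackets of the closed-form dCp double integral."""
    inv = 1.0 / t_m - 1.0 / T
    br1 = np.log(T / t_m) - t_m * inv
    br2 = (T - t_m) - t_m**2 * inv
    br3 = (T**2 - t_m**2) / 2.0 - t_m**3 * inv
    return br1, br2, br3


def log_fugacity_ratio(
    T,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    case_id: int = 1,
    D: float | None = None,
    betas: tuple[float, float, float] | None = None,
):
    """ln(f2_S/f2_L): ideal fusion term minus the dCp double integral.

    The quadratic closure is the exact antiderivative of
    ``int_Tm^T 1/(R t^2) int_Tm^t dCp dT' dt``.
    """
    dh_m, t_m = solute.require_fusion()
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be > 0")
    out = dh_m / (R * T) * (T / t_m - 1.0)
    if case_id == 1:
        return out
    br1, br2, br3 = _dcp_brackets(T, t_m)
    if case_id == 2:
        if D is None:
            raise DomainError("case 2 requires the constant dCp value D")
        return out - D / R * br1
    if case_id == 3:
        if betas is None:
            raise DomainError("case 3 requires (beta1, beta2, beta3)")
        b1, b2, b3 = betas
        return out - b1 / R * br1 - b2 / (2.0 * R) * br2 - b3 / (3.0 * R) * br3
    raise DomainError(f"case_id must be 1, 2 or 3, got {case_id}")


def fugacity_ratio(
    T,
    solute: SubstanceProperties = CODEINE_PHOSPHATE,
    case_id: int = 1,
    D: float | None = None,
    betas: tuple[float, float, float] | None = None,
):
    """f2_S/f2_L for the selected dCp closure; equals 1 at T = Tm."""
    out = safe_exp(
        log_fugacity_ratio(T, solute, case_id, D, betas),
        "fugacity ratio (dCp closure)",
    )
    return out if np.ndim(out) else float(out)


def elm_y2(params: ELMParams, solute: SubstanceProperties, T, P):
    """Expanded-liquid solubility: fugacity ratio over activity coefficient."""
    betas = None
    if params.case_id == 3:
        betas = (params.beta1, params.beta2, params.beta3)
    fr = fugacity_ratio(T, solute, params.case_id, params.D, betas)
    gamma = activity_coeff_inf(T, P, params.l1, params.l2, params.l3)
    out = fr / gamma
    return out if np.ndim(out) else float(out)


class ExpandedLiquid(SolubilityModel):
    """Expanded-liquid model bound to a dataset; ``case`` selects the
    dCp closure (1, 2 or 3).

    Every case is exactly linear in its parameters on the log scale:
    ``ln y2 = ideal(T) - [dCp brackets] @ (D or betas) - (l1 + l2 x + l3 x^2)``,
    so ordinary least squares on ``ln y2 - ideal(T)`` supplies the start
    for the nonlinear AARD regression. The dCp brackets are nearly
    collinear over a narrow temperature window, which is why fitted
    beta magnitudes can be large with little effect on the fit.
    """

    params_cls = ELMParams

    def __init__(self, dataset, case: int = 1):
        if case not in (1, 2, 3):
            raise DomainError(f"case must be 1, 2 or 3, got {case}")
        self.case = case
        self.name = f"elm{case}"
        self.param_names = ELMParams.case_fields(case)
        super().__init__(dataset)
        self.data.solute.require_fusion()

    def _params_obj(self, theta) -> ELMParams:
        return ELMParams.from_array(self.case, theta)

    def _predict(self, theta, T, P, rho):
        return elm_y2(self._params_obj(theta), self.data.solute, T, P)

    def start_params(self) -> np.ndarray:
        # target: ln y2 - ideal fusion term = -(l-polynomial) - dCp brackets
        _, t_m = self.data.solute.require_fusion()
        target = np.log(self.y_exp) - log_fugacity_ratio(self.T, self.data.solute, 1)
        x = self.P / (R * self.T)
        l_cols = [-np.ones_like(x), -x, -(x**2)]
        br1, br2, br3 = _dcp_brackets(self.T, t_m)
        dcp_cols = {
            1: [],
            2: [-br1 / R],
            3: [-br1 / R, -br2 / (2.0 * R), -br3 / (3.0 * R)],
        }[self.case]
        design = np.column_stack(l_cols + dcp_cols)
        return _lstsq(design, target)
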