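"""Information-criterion model ranking, enthalpy decomposition, and the
MT single-line consistency diagnostic."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import R, DomainError, SolubilityDataset


def aic_aicc(sse: float, n: int, q: int) -> tuple[float, float]:
    """Akaike information criterion and its small-sample correction.

    ``AIC = N ln(SSE/N) + 2Q`` (natural log; Q counts only fitted
    parameters) and ``AICc = AIC + 2Q(Q+1)/(N-Q-1)``.
    """
    if sse <= 0:
        raise DomainError("SSE must be > 0")
    if n <= q + 1:
        raise DomainError(f"need N > Q+1 (N={n}, Q={q})")
    aic = n * np.log(sse / n) + 2 * q
    aicc = aic + 2 * q * (q + 1) / (n - q - 1)
    return float(aic), float(aicc)


@dataclass(frozen=True)
class RankedModel:
    model_name: str
    aard_percent: float
    aic: float
    aicc: float
    n_params: int


@dataclass(frozen=True)
class ModelRanking:
    """Fit results ordered by AICc (ascending); ties broken by fewer
    parameters, then by name."""

    entries: tuple[RankedModel, ...]

    @property
    def best(self) -> str:
        return self.entries[0].model_name

    def to_text(self) -> str:
        header = f"{'model':<16}{'AARD%':>8}{'AIC':>10}{'AICc':>10}{'Q':>4}"
        lines = [header, "-" * len(header)]
        for e in self.entries:
            lines.append(
                f"{e.model_name:<16}{e.aard_percent:>8.2f}{e.aic:>10.2f}"
                f"{e.aicc:>10.2f}{e.n_params:>4d}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "ranking": [
                {
                    "model": e.model_name,
                    "aard_percent": e.aard_percent,
                    "aic": e.aic,
                    "aicc": e.aicc,
                    "n_params": e.n_params,
                }
                for e in self.entries
            ],
        }


def rank_models(results: Sequence) -> ModelRanking:
    """Rank fitted results from one dataset by AICc."""
    if len(results) < 2:
        raise DomainError("ranking needs at least two fit results")
    ref = results[0].y_exp
    for r in results[1:]:
        if r.y_exp.shape != ref.shape or not np.allclose(r.y_exp, ref):
            raise DomainError(
                f"fit result for {r.model_name!r} comes from a different dataset"
            )
    entries = sorted(
        (
            RankedModel(r.model_name, r.aard_percent, r.aic, r.aicc, r.n_params)
            for r in results
        ),
        key=lambda e: (e.aicc, e.n_params, e.model_name),
    )
    return ModelRanking(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Enthalpy decomposition
# ---------------------------------------------------------------------------

def total_enthalpy_from_chrastil(B1: float) -> float:
    """Total dissolution enthalpy (kJ/mol) from the Chrastil B1/T term,
    read as a van 't Hoff slope: ``dH_total = -B1 R``."""
    return -B1 * R / 1000.0


def sublimation_enthalpy_from_bartle(B3: float) -> float:
    """Sublimation enthalpy (kJ/mol) from the Bartle B3/T term:
    ``dH_sub = -B3 R``."""
    return -B3 * R / 1000.0


def solvation_enthalpy(total: float, sublimation: float) -> float:
    """Solvation enthalpy (kJ/mol): total minus sublimation."""
    return total - sublimation


@dataclass(frozen=True)
class EnthalpyReport:
    """Dissolution-enthalpy decomposition with component provenance.

    The identity ``solvation = total - sublimation`` holds exactly by
    construction.
    """

    total_enthalpy: float
    sublimation_enthalpy: float
    solvation_enthalpy: float
    source_labels: dict = field(default_factory=dict)

    @classmethod
    def from_components(
        cls, total: float, sublimation: float, total_source: str, sublimation_source: str
    ) -> "EnthalpyReport":
        return cls(
            total_enthalpy=total,
            sublimation_enthalpy=sublimation,
            solvation_enthalpy=solvation_enthalpy(total, sublimation),
            source_labels={
                "total": total_source,
                "sublimation": sublimation_source,
                "solvation": "total - sublimation",
            },
        )

    def to_dict(self) -> dict:
        return {
            "total_enthalpy_kJ_mol": self.total_enthalpy,
            "sublimation_enthalpy_kJ_mol": self.sublimation_enthalpy,
            "solvation_enthalpy_kJ_mol": self.solvation_enthalpy,
            "source_labels": dict(self.source_labels),
        }

    def to_text(self) -> str:
        s = self.source_labels
        return "\n".join(
            [
                f"{'Total enthalpy:':<26}{self.total_enthalpy:>9.2f} kJ/mol   [{s.get('total', '')}]",
                f"{'Sublimation enthalpy:':<26}{self.sublimation_enthalpy:>9.2f} kJ/mol   [{s.get('sublimation', '')}]",
                f"{'Solvation enthalpy:':<26}{self.solvation_enthalpy:>9.2f} kJ/mol   [{s.get('solvation', '')}]",
            ]
        )


def enthalpy_report(chrastil_results, bartle_results) -> EnthalpyReport:
    """Decomposition from fitted Chrastil (total) and Bartle (sublimation)."""
    total = total_enthalpy_from_chrastil(chrastil_results.params_dict["B1"])
    sub = sublimation_enthalpy_from_bartle(bartle_results.params_dict["B3"])
    return EnthalpyReport.from_components(
        total, sub, "Chrastil -B1*R", "Bartle -B3*R"
    )


# ---------------------------------------------------------------------------
# MT consistency diagnostic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MTConsistency:
    """The MT collapse: ``T ln(y2 P) - C2 T`` against solvent density,
    with the least-squares line and its R^2.

    Thermodynamically consistent data fall around a single straight line
    for the fitted C2.
    """

    rho1: np.ndarray
    transformed: np.ndarray
    slope: float
    intercept: float
    r2: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"density_kg_m3": self.rho1, "T_ln_y2P_minus_C2T": self.transformed}
        )


def mt_consistency_transform(dataset: SolubilityDataset, C2: float) -> MTConsistency:
    """Collapse all isotherms onto the MT line for a given C2."""
    T = dataset.temperature
    P = dataset.pressure
    rho = dataset.solvent_density
    y = dataset.mole_fraction
    transformed = T * np.log(y * P) - C2 * T
    slope, intercept = np.polyfit(rho, transformed, 1)
    fitted = slope * rho + intercept
    ss_res = float(np.sum((transformed - fitted) ** 2))
    ss_tot = float(np.sum((transformed - transformed.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MTConsistency(
        rho1=rho, transformed=transformed, slope=float(slope),
        intercept=float(intercept), r2=float(r2),
    )
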