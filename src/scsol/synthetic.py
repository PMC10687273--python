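"""Synthetic solubility datasets with the study's statistical structure.

A generating model evaluated on a temperature x pressure grid gives the
true mole fractions; observations are the truth times mean-one-ish
multiplicative lognormal noise, matching the relative-error structure of
triplicate saturation assays (and of the AARD objective). The default
grid mirrors the measured design: 4 isotherms x 6 pressures with the
measured NIST densities, so synthetic and real datasets are drop-in
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CO2,
    CODEINE_PHOSPHATE,
    DomainError,
    SolubilityDataset,
    SolubilityRecord,
    SubstanceProperties,
    builtin_codeine_dataset,
)
from .fitting import FitConfig, FitError
from .registry import make_model


class GenerationError(RuntimeError):
    """The generating model produced an unusable mole fraction."""


def _default_density_table() -> dict[tuple[float, float], float]:
    return {
        (r.temperature, r.pressure): r.solvent_density
        for r in builtin_codeine_dataset()
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    ``density_rule`` maps (T, P) to solvent density: a table keyed by
    (T, P) or a callable; by default the measured-grid densities.
    ``noise_cv`` is the relative standard deviation of the multiplicative
    lognormal noise (default 0.05, the scale of the triplicate-assay
    standard deviations).
    """

    model: str = "chrastil"
    params: Mapping | object = field(
        default_factory=lambda: {"kappa": 2.8403, "A1": -4.0221, "B1": -5284.7}
    )
    temperatures: Sequence[float] = (308.0, 318.0, 328.0, 338.0)
    pressures: Sequence[float] = (12.0, 15.0, 18.0, 21.0, 24.0, 27.0)
    density_rule: Mapping | Callable | None = None
    noise_cv: float = 0.05
    seed: int = 0
    solute: SubstanceProperties = CODEINE_PHOSPHATE
    solvent: SubstanceProperties = CO2

    def __post_init__(self) -> None:
        if not len(self.temperatures) or not len(self.pressures):
            raise DomainError("temperature and pressure grids must be nonempty")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")

    def density_at(self, T: float, P: float) -> float:
        rule = self.density_rule
        if rule is None:
            rule = _default_density_table()
        if callable(rule):
            return float(rule(T, P))
        try:
            return float(rule[(T, P)])
        except KeyError:
            raise DomainError(f"density_rule has no entry for (T={T}, P={P})") from None


def generate_dataset(spec: GeneratorSpec) -> tuple[SolubilityDataset, pd.DataFrame]:
    """Draw one dataset; returns (observed dataset, hidden truth table).

    Observed y2 = true y2 * exp(eps) with eps ~ N(0, sqrt(ln(1+cv^2))),
    seeded from ``spec.seed``.
    """
    grid = [(float(T), float(P)) for T in spec.temperatures for P in spec.pressures]
    rho = np.array([spec.density_at(T, P) for T, P in grid])
    T = np.array([t for t, _ in grid])
    P = np.array([p for _, p in grid])

    skeleton = SolubilityDataset(
        [
            SolubilityRecord(t, p, r, 0.5)
            for (t, p), r in zip(grid, rho)
        ],
        spec.solute,
        spec.solvent,
    )
    model = make_model(spec.model, skeleton)
    theta = model._as_array(spec.params)
    # skeleton is sorted by (T, P); evaluate on its own grid ordering
    y_true = np.asarray(
        model.predict_y2(theta, skeleton.temperature, skeleton.pressure,
                         skeleton.solvent_density)
    )
    bad = ~np.isfinite(y_true) | (y_true <= 0) | (y_true >= 1)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GenerationError(
            f"generating model {spec.model!r} gave y2={y_true[i]!r} at "
            f"T={skeleton.temperature[i]} K, P={skeleton.pressure[i]} MPa"
        )

    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    eps = rng.normal(0.0, sigma, y_true.size) if spec.noise_cv > 0 else np.zeros(y_true.size)
    y_obs = y_true * np.exp(eps)

    records = [
        SolubilityRecord(t, p, r, y)
        for t, p, r, y in zip(
            skeleton.temperature, skeleton.pressure, skeleton.solvent_density, y_obs
        )
    ]
    dataset = SolubilityDataset(records, spec.solute, spec.solvent)
    truth = pd.DataFrame(
        {
            "temperature_K": skeleton.temperature,
            "pressure_MPa": skeleton.pressure,
            "density_kg_m3": skeleton.solvent_density,
            "mole_fraction_true": y_true,
        }
    )
    return dataset, truth


@dataclass(frozen=True)
class RecoverySummary:
    """Parameter-recovery Monte Carlo summary."""

    model: str
    param_names: tuple[str, ...]
    truth: np.ndarray
    estimates: np.ndarray  # (n_ok, n_params)
    aard_percents: np.ndarray
    n_replicates: int
    n_failed: int

    @property
    def bias(self) -> np.ndarray:
        return self.estimates.mean(axis=0) - self.truth

    @property
    def rmse(self) -> np.ndarray:
        return np.sqrt(np.mean((self.estimates - self.truth) ** 2, axis=0))

    def fraction_within(self, rel_tol: float, param: str | None = None) -> float:
        """Fraction of replicates whose estimate is within ``rel_tol`` of
        truth (one parameter, or all parameters jointly)."""
        rel_err = np.abs(self.estimates - self.truth) / np.abs(self.truth)
        if param is not None:
            j = self.param_names.index(param)
            ok = rel_err[:, j] <= rel_tol
        else:
            ok = np.all(rel_err <= rel_tol, axis=1)
        return float(np.mean(ok))

    def aard_quantiles(self, qs=(0.25, 0.5, 0.75)) -> dict[float, float]:
        return {q: float(np.quantile(self.aard_percents, q)) for q in qs}


def recovery_experiment(
    spec: GeneratorSpec,
    fit_config: FitConfig | None = None,
    n_replicates: int = 50,
) -> RecoverySummary:
    """Generate-and-refit Monte Carlo: per-parameter bias/RMSE and the
    refit AARD distribution over seeded replicates.

    Replicate seeds derive deterministically from ``spec.seed``. Fit
    failures are counted, not fatal.
    """
    if n_replicates < 2:
        raise DomainError("n_replicates must be >= 2")
    if fit_config is None:
        fit_config = FitConfig(n_starts=8, seed=spec.seed)
    rep_seeds = np.random.default_rng(spec.seed).integers(0, 2**31 - 1, n_replicates)

    estimates, aards = [], []
    n_failed = 0
    truth = None
    names = None
    for s in rep_seeds:
        dataset, _ = generate_dataset(replace(spec, seed=int(s)))
        model = make_model(spec.model, dataset)
        if truth is None:
            truth = model._as_array(spec.params)
            names = model.param_names
        try:
            res = model.fit(fit_config)
        except FitError:
            n_failed += 1
            continue
        estimates.append(res.params)
        aards.append(res.aard_percent)

    if not estimates:
        raise FitError("every recovery replicate failed to fit")
    return RecoverySummary(
        model=spec.model,
        param_names=tuple(names),
        truth=truth,
        estimates=np.array(estimates),
        aard_percents=np.array(aards),
        n_replicates=n_replicates,
        n_failed=n_failed,
    )
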