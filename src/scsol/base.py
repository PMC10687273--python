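"""Model/Results base classes.

Every solubility correlation is a :class:`SolubilityModel` built from a
:class:`~scsol.data.SolubilityDataset`; ``fit()`` runs the multi-start
Nelder-Mead regression on the sum-of-relative-deviations objective and
returns a :class:`SolubilityResults` carrying the fitted parameters,
goodness-of-fit statistics and convergence metadata.
"""

from __future__ import annotations

import abc
import json
from typing import Mapping, Sequence

import numpy as np

from ._util import EvaluationError
from .data import DomainError, SolubilityDataset
from .fitting import (
    PENALTY,
    FitConfig,
    aard_percent,
    fit_stats,
    multistart_minimize,
    penalized_objective,
)


class SolubilityModel(abc.ABC):
    """Abstract base: a solubility correlation bound to one dataset.

    Subclasses declare ``name`` and ``param_names`` and implement
    ``_predict`` (vectorized over the dataset's records) plus a
    data-informed ``start_params``.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, dataset: SolubilityDataset) -> None:
        self.data = dataset
        self.T = dataset.temperature
        self.P = dataset.pressure
        self.rho = dataset.solvent_density
        self.y_exp = dataset.mole_fraction
        self._setup()

    def _setup(self) -> None:
        """Hook for per-dataset precomputation (e.g. EoS solvent states)."""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def nobs(self) -> int:
        return len(self.data)

    # -- parameter plumbing -------------------------------------------------
    def _as_array(self, params) -> np.ndarray:
        """Accept an array, a mapping keyed by symbol, or a params object."""
        if isinstance(params, Mapping):
            try:
                return np.array([float(params[k]) for k in self.param_names])
            except KeyError as exc:
                raise DomainError(
                    f"{self.name}: missing parameter {exc.args[0]!r}; "
                    f"expected keys {self.param_names}"
                ) from None
        if hasattr(params, "as_array"):
            return np.asarray(params.as_array(), dtype=float)
        arr = np.asarray(params, dtype=float).ravel()
        if arr.size != self.n_params:
            raise DomainError(
                f"{self.name} expects {self.n_params} parameters, got {arr.size}"
            )
        return arr

    def params_dict(self, theta) -> dict[str, float]:
        theta = self._as_array(theta)
        return {k: float(v) for k, v in zip(self.param_names, theta)}

    # -- prediction and objective -------------------------------------------
    @abc.abstractmethod
    def _predict(self, theta: np.ndarray, T, P, rho) -> np.ndarray:
        """Predicted mole fractions at the given conditions."""

    def predict_y2(self, params, T=None, P=None, rho=None) -> np.ndarray:
        """Predicted mole fractions; defaults to the model's own dataset grid."""
        theta = self._as_array(params)
        if T is None:
            T, P, rho = self.T, self.P, self.rho
        return np.asarray(
            self._predict(theta, np.asarray(T, float), np.asarray(P, float), np.asarray(rho, float))
        )

    def loss(self, theta) -> float:
        """Penalized sum of absolute relative deviations at ``theta``."""
        theta = np.asarray(theta, dtype=float)
        try:
            y_calc = self._predict(theta, self.T, self.P, self.rho)
        except (EvaluationError, FloatingPointError):
            return 2.0 * PENALTY * self.nobs
        return penalized_objective(self.y_exp, np.asarray(y_calc, float))

    # -- starting points ----------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Data-informed starting point; subclasses override."""
        raise NotImplementedError

    def default_bounds(self) -> Sequence[tuple[float, float]] | None:
        return None

    # -- fitting -------------------------------------------------------------
    def fit(self, config: FitConfig | None = None, **kwargs) -> "SolubilityResults":
        """Multi-start Nelder-Mead regression; returns the best fit found.

        ``kwargs`` override individual :class:`FitConfig` fields.
        """
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise DomainError("pass either a FitConfig or keyword overrides, not both")
        if config.bounds is None and self.default_bounds() is not None:
            config = FitConfig(
                n_starts=config.n_starts,
                seed=config.seed,
                max_iterations=config.max_iterations,
                x_tolerance=config.x_tolerance,
                f_tolerance=config.f_tolerance,
                bounds=self.default_bounds(),
                start_jitter=config.start_jitter,
            )
        x0 = self.start_params()
        theta, of_value, best_start, diagnostics = multistart_minimize(
            self.loss, x0, config
        )
        return SolubilityResults(self, theta, of_value, best_start, diagnostics, config)


class SolubilityResults:
    """Fitted-model results: parameters, fit statistics, diagnostics.

    Attributes
    ----------
    params : ndarray
        Fitted parameter vector, ordered as ``model.param_names``.
    aard_percent : float
        Average absolute relative deviation of mole fractions, percent.
    r2, r2_adj, rmse, sse : float
        Goodness of fit on the mole-fraction scale.
    aic, aicc : float
        Information criteria from SSE (natural log, Q = fitted parameters).
    """

    def __init__(self, model, theta, of_value, best_start_index, diagnostics, config):
        from .selection import aic_aicc  # late import; selection ranks results

        self.model = model
        self.model_name = model.name
        self.params = np.asarray(theta, dtype=float)
        self.objective_value = float(of_value)
        self.best_start_index = int(best_start_index)
        self.start_diagnostics = diagnostics
        self.config = config
        self.converged = bool(diagnostics[best_start_index].converged)

        self.y_exp = model.y_exp
        self.fittedvalues = model.predict_y2(self.params)
        self.nobs = model.nobs
        self.n_params = model.n_params
        self.aard_percent = aard_percent(self.y_exp, self.fittedvalues)
        self.r2, self.r2_adj, self.rmse, self.sse = fit_stats(
            self.y_exp, self.fittedvalues, self.n_params
        )
        self.aic, self.aicc = aic_aicc(self.sse, self.nobs, self.n_params)

    @property
    def params_dict(self) -> dict[str, float]:
        return self.model.params_dict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.y_exp - self.fittedvalues

    def predict(self, T=None, P=None, rho=None) -> np.ndarray:
        return self.model.predict_y2(self.params, T, P, rho)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "parameters": self.params_dict,
            "aard_percent": self.aard_percent,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "rmse": self.rmse,
            "sse": self.sse,
            "aic": self.aic,
            "aicc": self.aicc,
            "n_points": self.nobs,
            "n_params": self.n_params,
            "converged": self.converged,
            "best_start_index": self.best_start_index,
            "seed": self.config.seed,
            "n_starts": self.config.n_starts,
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        """Human-readable fit report (fixed-width table)."""
        lines = [
            f"{'Model:':<22}{self.model_name}",
            f"{'No. observations:':<22}{self.nobs}",
            f"{'No. parameters:':<22}{self.n_params}",
            f"{'Converged:':<22}{self.converged} (start {self.best_start_index} "
            f"of {self.config.n_starts}, seed {self.config.seed})",
            "-" * 46,
        ]
        for name, value in self.params_dict.items():
            lines.append(f"  {name:<12}{value: .6g}")
        lines += [
            "-" * 46,
            f"{'AARD%:':<22}{self.aard_percent:.4g}",
            f"{'R2:':<22}{self.r2:.4g}",
            f"{'R2 (adjusted):':<22}{self.r2_adj:.4g}",
            f"{'RMSE:':<22}{self.rmse:.4g}",
            f"{'SSE:':<22}{self.sse:.4g}",
            f"{'AIC:':<22}{self.aic:.4g}",
            f"{'AICc:':<22}{self.aicc:.4g}",
        ]
        return "\n".join(lines)

    def plot_isotherms(self, ax=None, against: str = "pressure"):
        """Measured vs fitted solubility isotherms (one line per temperature)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x_all = self.model.P if against == "pressure" else self.model.rho
        xlabel = "P (MPa)" if against == "pressure" else r"$\rho_1$ (kg/m$^3$)"
        for T in np.unique(self.model.T):
            m = self.model.T == T
            order = np.argsort(x_all[m])
            ax.plot(x_all[m][order], self.y_exp[m][order], "o", label=f"{T:.0f} K")
            ax.plot(x_all[m][order], self.fittedvalues[m][order], "-",
                    color=ax.lines[-1].get_color())
        ax.set_xlabel(xlabel)
        ax.set_ylabel(r"$y_2$")
        ax.set_title(f"{self.model_name}: AARD {self.aard_percent:.2f}%")
        ax.legend()
        return ax
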