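"""AARD objective, goodness-of-fit statistics, and the multi-start
Nelder-Mead driver shared by every solubility model."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import DomainError

#: Per-point penalty assigned to a non-positive or non-finite prediction
#: inside the regression objective. Large against any attainable relative
#: deviation, but finite and (for negative predictions) increasing in the
#: violation, so the simplex is pushed back into the feasible region.
PENALTY = 1e4


class FitError(RuntimeError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def objective(y_exp, y_calc) -> float:
    """Sum of absolute relative deviations, ``sum |ye - yc| / ye``.

    The raw regression objective (no 1/N). Invariant under a common
    rescaling of both vectors.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.shape != y_calc.shape:
        raise DomainError("experimental and calculated vectors differ in length")
    if np.any(y_exp <= 0):
        raise DomainError("experimental mole fractions must be > 0")
    return float(np.sum(np.abs(y_exp - y_calc) / y_exp))


def penalized_objective(y_exp: np.ndarray, y_calc: np.ndarray) -> float:
    """Objective with invalid predictions replaced by a finite penalty."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    bad = ~np.isfinite(y_calc) | (y_calc <= 0.0)
    if not np.any(bad):
        return float(np.sum(np.abs(y_exp - y_calc) / y_exp))
    total = float(np.sum(np.abs(y_exp[~bad] - y_calc[~bad]) / y_exp[~bad]))
    overshoot = np.where(
        np.isfinite(y_calc[bad]), np.abs(y_calc[bad]) / y_exp[bad], 1.0
    )
    total += float(np.sum(PENALTY * (1.0 + np.minimum(overshoot, 1e6))))
    return total


def aard_percent(y_exp, y_calc) -> float:
    """Average absolute relative deviation in percent, ``100/N * objective``."""
    y_exp = np.asarray(y_exp, dtype=float)
    return 100.0 / y_exp.size * objective(y_exp, y_calc)


def fit_stats(y_exp, y_calc, q: int) -> tuple[float, float, float, float]:
    """(R2, adjusted R2, RMSE, SSE) of predictions against data.

    ``q`` is the number of fitted parameters; adjusted R2 uses
    ``1 - (1-R2)(N-1)/(N-q-1)`` and requires ``N > q + 1``.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    n = y_exp.size
    if n <= q + 1:
        raise DomainError(f"need N > Q+1 data points (N={n}, Q={q})")
    sse = float(np.sum((y_exp - y_calc) ** 2))
    rmse = float(np.sqrt(sse / n))
    sst = float(np.sum((y_exp - np.mean(y_exp)) ** 2))
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    return r2, r2_adj, rmse, sse


@dataclass
class FitConfig:
    """Settings for the multi-start Nelder-Mead regression.

    ``n_starts`` seeded simplex starts are launched: the first from the
    model's data-informed template, the rest jittered by up to
    ``start_jitter`` in log-magnitude. The best terminal point wins.
    """

    n_starts: int = 32
    seed: int = 0
    max_iterations: int = 50_000
    x_tolerance: float = 1e-8
    f_tolerance: float = 1e-10
    bounds: Sequence[tuple[float, float]] | None = None
    start_jitter: float = 0.5

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")
        if self.x_tolerance <= 0 or self.f_tolerance <= 0:
            raise DomainError("tolerances must be > 0")


@dataclass
class StartDiagnostic:
    start_index: int
    x0: np.ndarray
    fun: float
    n_iterations: int
    converged: bool
    message: str


def _jitter_start(x0: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Randomize a start: multiply each nonzero entry by exp(U(-s, s));
    zero entries get a small symmetric perturbation."""
    x = x0.copy()
    nonzero = x != 0.0
    x[nonzero] *= np.exp(rng.uniform(-scale, scale, nonzero.sum()))
    if np.any(~nonzero):
        ref = np.max(np.abs(x0)) if np.any(nonzero) else 1.0
        x[~nonzero] = rng.uniform(-scale, scale, (~nonzero).sum()) * 0.01 * ref
    return x


def multistart_minimize(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, float, int, list[StartDiagnostic]]:
    """Run Nelder-Mead from ``config.n_starts`` seeded points.

    Returns (best x, best objective, index of the winning start,
    per-start diagnostics). Fully deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    x0 = np.asarray(x0, dtype=float)
    starts = [x0]
    for _ in range(config.n_starts - 1):
        starts.append(_jitter_start(x0, rng, config.start_jitter))

    diagnostics: list[StartDiagnostic] = []
    best = None
    for i, xi in enumerate(starts):
        try:
            res = minimize(
                fun,
                xi,
                method="Nelder-Mead",
                bounds=config.bounds,
                options={
                    "maxiter": config.max_iterations,
                    "maxfev": config.max_iterations,
                    "xatol": config.x_tolerance,
                    "fatol": config.f_tolerance,
                    "adaptive": x0.size > 4,
                },
            )
        except (FloatingPointError, OverflowError, ValueError) as exc:
            diagnostics.append(
                StartDiagnostic(i, xi, np.inf, 0, False, f"raised {exc!r}")
            )
            continue
        diagnostics.append(
            StartDiagnostic(i, xi, float(res.fun), int(res.nit), bool(res.success), res.message)
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[1]):
            best = (np.asarray(res.x, dtype=float), float(res.fun), i)

    if best is None:
        raise FitError("all optimizer starts failed", diagnostics)
    return best[0], best[1], best[2], diagnostics
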