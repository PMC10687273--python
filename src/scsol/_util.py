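"""Small numeric helpers shared across model evaluators."""

from __future__ import annotations

import numpy as np

#: Largest exponent handed to np.exp before we call it an overflow.
_EXP_MAX = 700.0


class EvaluationError(ArithmeticError):
    """A model evaluation left the representable range."""


def safe_exp(x, context: str):
    """np.exp with an informative overflow error naming the offending term."""
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x > _EXP_MAX):
        raise EvaluationError(
            f"exponent overflow in {context}: max argument "
            f"{np.max(x[np.isfinite(x)]) if np.any(np.isfinite(x)) else np.nan:.3g}"
        )
    out = np.exp(x)
    return out if out.ndim else float(out)
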