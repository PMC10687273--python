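"""Independent reference implementations used only as test oracles."""

import numpy as np

from scsol import R


def lnphi2_full_mixture(T, P_mpa, y2, a1, b1, a2, b2, k12=0.0):
    """Solute fugacity coefficient from the full two-component PR EoS with
    van der Waals mixing, at finite composition y2.

    Independent of the package's dilute-limit expression: mixes a and b at
    the given composition, re-solves the mixture cubic, and evaluates the
    complete two-component formula.
    """
    p = P_mpa * 1e6
    y1 = 1.0 - y2
    a12 = (1.0 - k12) * np.sqrt(a1 * a2)
    a = y1 * y1 * a1 + 2.0 * y1 * y2 * a12 + y2 * y2 * a2
    b = y1 * b1 + y2 * b2
    A = a * p / (R * T) ** 2
    B = b * p / (R * T)
    roots = np.roots([1.0, -(1.0 - B), A - 3.0 * B * B - 2.0 * B, -(A * B - B * B - B**3)])
    real = roots[np.abs(roots.imag) < 1e-9].real
    Z = np.sort(real[real > B])[0]
    V = Z * R * T / p
    return (
        b2 / b * (Z - 1.0)
        - np.log(p * (V - b) / (R * T))
        - a
        / (2.0 * np.sqrt(2.0) * R * T * b)
        * (2.0 * (a12 * y1 + a2 * y2) / a - b2 / b)
        * np.log((V + (1.0 + np.sqrt(2.0)) * b) / (V - (np.sqrt(2.0) - 1.0) * b))
    )


def dcp_double_integral(T, t_m, betas):
    """Adaptive double quadrature of the heat-capacity correction term
    ``int_Tm^T 1/(R t^2) [int_Tm^t dCp dT'] dt`` for quadratic dCp."""
    from scipy.integrate import quad

    b1, b2, b3 = betas

    def inner(t):
        return (
            b1 * (t - t_m)
            + b2 * (t * t - t_m * t_m) / 2.0
            + b3 * (t**3 - t_m**3) / 3.0
        )

    val, _ = quad(lambda t: inner(t) / (R * t * t), t_m, T, limit=200)
    return val
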