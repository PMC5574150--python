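"""Cytokine feedback operators and the asymmetric self-renewal bookkeeping.

Cytokines are not modelled as explicit species; their abundance is assumed
proportional to the concentration ``C`` of the cell state that secretes them,
entering the rate laws through Michaelis-Menten saturation factors.
"""

from __future__ import annotations

import numpy as np


def negative_feedback(k: float, C) :
    """Inhibition factor ``k / (k + C)``.

    ``k`` is the Michaelis-Menten constant (cells/uL) and ``C`` the regulator
    concentration; the factor is 1 with no regulator and decays toward 0 as the
    regulator accumulates.
    """
    if k <= 0:
        raise ValueError(f"Michaelis constant k={k} must be > 0")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("regulator concentration must be >= 0")
    out = k / (k + C)
    return float(out) if out.ndim == 0 else out


def positive_feedback(k: float, C):
    """Activation factor ``C / (k + C)``; complements :func:`negative_feedback`."""
    if k <= 0:
        raise ValueError(f"Michaelis constant k={k} must be > 0")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("regulator concentration must be >= 0")
    out = C / (k + C)
    return float(out) if out.ndim == 0 else out


def self_renewal_fluxes(a: float, mr: float, X: float,
                        inhibition: float = 1.0) -> tuple[float, float]:
    """Net self-renewal flux and differentiation outflux of asymmetric division.

    A dividing pool ``X`` with mitosis rate ``mr`` and effective self-renewal
    probability ``a_eff = a * inhibition`` gains ``(2*a_eff - 1) * mr * X``
    cells/uL/day net and exports ``2 * (1 - a_eff) * mr * X`` to the next
    maturation stage; the two always sum to the total production ``mr * X``.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"self-renewal fraction a={a} outside [0, 1]")
    if mr < 0 or X < 0:
        raise ValueError("mitosis rate and concentration must be >= 0")
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError(f"inhibition factor {inhibition} outside [0, 1]")
    a_eff = a * inhibition
    net = (2.0 * a_eff - 1.0) * mr * X
    out = 2.0 * (1.0 - a_eff) * mr * X
    return net, out
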