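"""Central-difference numerical Hessian of a scalar function.

Used for the Gaussian curvature approximation behind the reported standard
errors.  Steps are absolute (the packed parameters are log magnitudes, all of
order 1-10), with the classic O(h^2) central-difference stencils.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["hessian"]


def hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
            step: float = 1e-4) -> np.ndarray:
    """Symmetric numerical Hessian of ``f`` at ``x``.

    Diagonal: (f(x+h e_i) - 2 f(x) + f(x-h e_i)) / h^2.
    Off-diagonal: four-point cross stencil / (4 h^2).
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H
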