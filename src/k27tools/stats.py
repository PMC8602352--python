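"""Small shared statistical primitives: FDR adjustment and discrete tail probabilities.

These are deliberately thin wrappers over scipy with strict input validation,
so that every module in the package applies exactly the same conventions
(upper tails are inclusive, ``P(X >= k)``; BH is the standard step-up).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["bh_adjust", "poisson_tail", "hypergeom_tail"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Parameters
    ----------
    p : array-like of float in [0, 1]

    Returns
    -------
    ndarray of q-values, order-preserving and never smaller than ``p``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return _st.false_discovery_control(p, method="bh")


def poisson_tail(k, lam) -> np.ndarray | float:
    """Inclusive Poisson upper tail ``P(X >= k)`` for rate ``lam``."""
    k = np.asarray(k)
    return _st.poisson.sf(k - 1, lam)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Inclusive hypergeometric upper tail ``P(X >= k)``.

    ``N`` population size, ``K`` marked in population, ``n`` draws, ``k`` marked drawn.
    """
    return float(_st.hypergeom.sf(k - 1, N, K, n))
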