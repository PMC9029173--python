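"""Beta divergences.

The beta divergence is a one-parameter family of dissimilarities between
non-negative arrays which, in the parameterization used throughout this
package, interpolates three classical measures:

* ``beta = 1``   half squared Euclidean distance,
* ``beta = 0``   generalized Kullback-Leibler divergence,
* ``beta = -1``  Itakura-Saito divergence.

For any other beta the element-wise divergence is

    d(p, q) = p^(1+b) / (b (1+b))  -  p q^b / b  +  q^(1+b) / (1+b)

with ``b = beta``.  Each special case is the continuous limit of this
expression.  The family's appeal for stain separation is robustness: the
influence of large residuals (tissue-processing artifacts, specular spots)
varies smoothly with beta, and the multiplicative NMF updates built on it
keep factors non-negative by construction.

The divergence is asymmetric; by convention the observed data is the first
argument and the model/centroid the second.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .errors import DimensionError, DomainError

__all__ = ["beta_divergence"]

#: floor applied to the second argument before evaluation, so the model
#: side of a ratio or logarithm can never be exactly zero
Q_FLOOR = 1e-12


def beta_divergence(p, q, beta: float) -> float:
    """Sum of element-wise beta divergences ``D_B(p || q)``.

    Parameters
    ----------
    p, q
        Non-negative arrays of identical shape.  ``p`` is the data, ``q``
        the approximation; entries of ``q`` are floored at ``1e-12``
        internally.
    beta
        Shape parameter.  ``1`` gives half the squared Euclidean distance,
        ``0`` the Kullback-Leibler divergence, ``-1`` the Itakura-Saito
        divergence; any other value uses the generic expression.

    Returns
    -------
    float
        Non-negative scalar; zero iff ``p == q`` element-wise.

    Notes
    -----
    For ``beta <= -1`` (and for the Itakura-Saito branch) zeros in ``p``
    make the divergence infinite; callers working in that regime floor
    their data first.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise DimensionError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.size and (p.min() < 0 or q.min() < 0):
        raise DomainError("beta divergence requires non-negative entries")
    qf = np.maximum(q, Q_FLOOR)

    if beta == 1:
        return float(0.5 * np.sum((p - qf) ** 2))
    if beta == 0:
        # xlogy handles p = 0 (0 * log 0 -> 0)
        return float(np.sum(special.xlogy(p, p) - special.xlogy(p, qf) - p + qf))
    if beta == -1:
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(qf) - np.log(p) + p / qf - 1.0))
    b = float(beta)
    with np.errstate(divide="ignore"):
        term_p = np.sum(p ** (1.0 + b)) / (b * (1.0 + b))
        term_pq = np.sum(p * qf**b) / b
        term_q = np.sum(qf ** (1.0 + b)) / (1.0 + b)
    return float(term_p - term_pq + term_q)
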