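"""The rank-based inverse normal transformation (INT).

The INT maps a vector of observations to standard-normal quantiles of
their (offset) ranks::

    RN(v_i) = Phi^{-1}((rank(v_i) - c) / n),   c in (0, 1/2]

where ``rank`` is the 1-based ascending rank among the ``n`` values and
``c`` is a rank offset.  With the conventional offset ``c = 1/2`` the
probabilities lie in ``[1/(2n), 1 - 1/(2n)]``, so the transform is always
finite.  ``c = 0`` would map the largest observation to ``Phi^{-1}(1)``
and is rejected rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = ["RankNormalizeConfig", "rank_inverse_normal"]

_TIE_RULES = ("average", "min", "max", "random")
_DENOMINATORS = ("n", "blom")


@dataclass(frozen=True)
class RankNormalizeConfig:
    """Configuration of the rank-based inverse normal transformation.

    Parameters
    ----------
    offset
        The rank offset ``c``; must lie in ``(0, 1/2]``.  ``c = 1/2`` is
        the conventional choice.
    tie_rule
        How tied observations are ranked: ``"average"`` (default; tied
        inputs receive identical outputs), ``"min"``, ``"max"``, or
        ``"random"`` (ties broken uniformly at random; requires an ``rng``
        argument to :func:`rank_inverse_normal`).
    denominator
        ``"n"`` (default) uses probabilities ``(rank - c)/n``; ``"blom"``
        uses the Blom-style ``(rank - c)/(n - 2c + 1)``, provided for
        comparison with other normalization conventions.
    """

    offset: float = 0.5
    tie_rule: str = "average"
    denominator: str = "n"

    def __post_init__(self) -> None:
        if not (0.0 <= self.offset <= 0.5):
            raise ValueError(f"offset c must lie in [0, 1/2]; got {self.offset}")
        if self.offset == 0.0:
            raise ValueError(
                "offset c = 0 maps the largest rank to a degenerate probability 1"
            )
        if self.tie_rule not in _TIE_RULES:
            raise ValueError(f"tie_rule must be one of {_TIE_RULES}; got {self.tie_rule!r}")
        if self.denominator not in _DENOMINATORS:
            raise ValueError(
                f"denominator must be one of {_DENOMINATORS}; got {self.denominator!r}"
            )


_DEFAULT_CONFIG = RankNormalizeConfig()


def rank_inverse_normal(
    values,
    config: RankNormalizeConfig = _DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the rank-based inverse normal transformation to ``values``.

    Parameters
    ----------
    values
        One-dimensional array-like of finite numbers, length >= 1.
    config
        Offset and tie-handling configuration.
    rng
        Random generator, required only for ``tie_rule="random"``.

    Returns
    -------
    numpy.ndarray
        Vector of the same length with entries
        ``Phi^{-1}((rank - c)/n)``; order-preserving, and under the
        default average-rank rule tied inputs map to identical outputs.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"expected a 1-d vector, got shape {v.shape}")
    if v.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("input contains non-finite values")

    n = v.size
    if config.tie_rule == "random":
        if rng is None:
            raise ValueError("tie_rule='random' requires an rng")
        # shuffle then ordinal ranking breaks ties uniformly at random
        perm = rng.permutation(n)
        ranks = np.empty(n)
        ranks[perm] = rankdata(v[perm], method="ordinal")
    else:
        ranks = rankdata(v, method=config.tie_rule)

    c = config.offset
    denom = n if config.denominator == "n" else n - 2.0 * c + 1.0
    return ndtri((ranks - c) / denom)
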