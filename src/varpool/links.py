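"""Link functions mapping a linear predictor to an infection probability.

A link here is the *mean* function g: R -> (0,1) together with its
derivative and inverse. The default throughout the package is the
logistic link g(u) = 1/(1+exp(-u)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats

__all__ = ["LinkFunction", "LOGIT", "PROBIT", "get_link"]


@dataclass(frozen=True)
class LinkFunction:
    """A strictly increasing, differentiable map from R onto (0, 1).

    Attributes
    ----------
    name : str
        Identifier used in config files ("logit", "probit", ...).
    evaluate : callable
        g(u), vectorised, returning probabilities in (0, 1).
    derivative : callable
        g'(u) > 0, vectorised.
    inverse : callable
        g^{-1}(p) for p in (0, 1).
    """

    name: str
    evaluate: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    derivative: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    inverse: Callable[[np.ndarray], np.ndarray] = field(repr=False)


def _logit_derivative(u):
    p = special.expit(u)
    return p * (1.0 - p)


LOGIT = LinkFunction(
    name="logit",
    evaluate=special.expit,
    derivative=_logit_derivative,
    inverse=special.logit,
)

PROBIT = LinkFunction(
    name="probit",
    evaluate=stats.norm.cdf,
    derivative=stats.norm.pdf,
    inverse=stats.norm.ppf,
)

_REGISTRY = {link.name: link for link in (LOGIT, PROBIT)}


def get_link(name: str) -> LinkFunction:
    """Look up a link function by name; raises KeyError for unknown names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown link {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
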