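"""Beta likelihood with logit link: log-density, derivatives and the
boundary-squeezing transform for proportion responses."""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln, polygamma


def squeeze_response(y: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Pull proportions off the {0, 1} boundary: y' = (y (n - 1) + 0.5) / n.

    ``n`` is the effective count behind each proportion (e.g. respondents per
    cluster).  The result is strictly inside (0, 1) and monotone in y.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("effective count must exceed 1")
    return (y * (n - 1.0) + 0.5) / n


def inv_logit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def beta_loglik(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """Pointwise log-density of Beta(mu*phi, (1-mu)*phi), logit(mu) = eta."""
    mu = inv_logit(eta)
    a, b = mu * phi, (1.0 - mu) * phi
    return (gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))


def beta_score_eta(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """d loglik / d eta."""
    mu = inv_logit(eta)
    ystar = np.log(y) - np.log1p(-y)
    mustar = digamma(mu * phi) - digamma((1.0 - mu) * phi)
    return phi * mu * (1.0 - mu) * (ystar - mustar)


def beta_fisher_eta(eta: np.ndarray, phi: float) -> np.ndarray:
    """Expected information wrt eta (always positive; used for scoring steps)."""
    mu = inv_logit(eta)
    w = mu * (1.0 - mu)
    return phi ** 2 * w ** 2 * (polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi))
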