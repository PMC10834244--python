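"""Shared beta-binomial parameterization.

Repo-wide convention: the beta-binomial is parameterized by a mean
``mu`` in (0, 1) and an overdispersion ``phi`` in [0, 1), with shape
parameters

    alpha = mu * (1 - phi) / phi
    beta  = (1 - mu) * (1 - phi) / phi

so that ``phi -> 0`` degenerates to the binomial and ``phi`` equals the
correlation between the underlying Bernoulli draws.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

# below this, treat the distribution as an exact binomial: the shape
# parameters exceed ~1e6 where betabinom.logpmf loses precision, while the
# pmf difference from the binomial is O(n^2 * phi)
_PHI_BINOMIAL = 1e-6


def ab_from_mean_overdispersion(mu, phi):
    """Map (mean, overdispersion) to beta shape parameters (alpha, beta)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    scale = (1.0 - phi) / phi
    return mu * scale, (1.0 - mu) * scale


def betabinom_logpmf(k, n, mu, phi):
    """Log-pmf of the (mu, phi) beta-binomial; binomial at phi ~ 0."""
    k = np.asarray(k)
    n = np.asarray(n)
    if np.all(np.asarray(phi) < _PHI_BINOMIAL):
        return stats.binom.logpmf(k, n, mu)
    a, b = ab_from_mean_overdispersion(mu, phi)
    return stats.betabinom.logpmf(k, n, a, b)


def betabinom_rvs(n, mu, phi, rng):
    """Draw beta-binomial counts with the shared parameterization."""
    n = np.asarray(n)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), n.shape)
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), n.shape)
    out = np.empty(n.shape, dtype=np.int64)
    binom_mask = phi_arr < _PHI_BINOMIAL
    if binom_mask.any():
        out[binom_mask] = rng.binomial(n[binom_mask], mu_arr[binom_mask])
    if (~binom_mask).any():
        a, b = ab_from_mean_overdispersion(mu_arr[~binom_mask], phi_arr[~binom_mask])
        p = rng.beta(a, b)
        out[~binom_mask] = rng.binomial(n[~binom_mask], p)
    return out
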