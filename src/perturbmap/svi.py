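"""Minimal stochastic variational inference toolkit.

Building blocks shared by the genotype count model and the
genotype-to-phenotype GLMs:

* an Adam optimizer over dictionaries of named parameter arrays;
* log-normal mean-field guides for positive-valued latents, with analytic
  entropy and analytic expectations of Gamma/Exponential log-priors, so only
  the likelihood term needs Monte-Carlo estimation (pathwise gradients via the
  reparameterisation ``z = exp(loc + scale * eps)``);
* Dirichlet guides with analytic KL against a Dirichlet prior and implicit
  reparameterisation gradients for the likelihood term (the derivative of a
  Gamma variate with respect to its shape is obtained from the inverse-CDF
  identity ``dz/da = -(dP(z;a)/da) / pdf(z;a)``, with the CDF derivative
  computed by central finite differences of the regularised incomplete gamma
  function).

The estimator corresponds to the common "analytic KL + reparameterised
likelihood" ELBO: unbiased and low-variance for the guide families used here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammainc, gammaln, polygamma

LOG_2PI_E = np.log(2.0 * np.pi * np.e)


class Adam:
    """Adam on a dict of named arrays; ``maximize=True`` performs ascent."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             maximize: bool = True) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if not maximize:
                g = -g
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] += self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# log-normal guides
# ---------------------------------------------------------------------------


def lognormal_sample(rng: np.random.Generator, loc: np.ndarray,
                     log_scale: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Draw z = exp(loc + scale*eps); returns (z, eps)."""
    eps = rng.standard_normal(loc.shape)
    z = np.exp(loc + np.exp(log_scale) * eps)
    return z, eps


def lognormal_entropy(loc: np.ndarray, log_scale: np.ndarray) -> float:
    """Sum of entropies; d/dloc = 1 and d/dlog_scale = 1 per element."""
    return float(np.sum(loc + log_scale + 0.5 * LOG_2PI_E))


def gamma_prior_expectation(
    loc: np.ndarray, log_scale: np.ndarray, shape: float, rate: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """E_q[log Gamma(z; shape, rate)] under a log-normal q, with gradients.

    Uses E[log z] = loc and E[z] = exp(loc + scale^2/2).  An Exponential(rate)
    prior is the special case shape = 1.
    """
    s2 = np.exp(2.0 * log_scale)
    m1 = np.exp(loc + 0.5 * s2)
    value = float(
        np.sum((shape - 1.0) * loc - rate * m1)
        + loc.size * (shape * np.log(rate) - gammaln(shape))
    )
    d_loc = (shape - 1.0) - rate * m1
    d_log_scale = -rate * m1 * s2
    return value, d_loc, d_log_scale


# ---------------------------------------------------------------------------
# Dirichlet guides
# ---------------------------------------------------------------------------


def dirichlet_kl(alpha: np.ndarray, prior_conc: float) -> tuple[float, np.ndarray]:
    """KL(Dirichlet(alpha) || Dirichlet(prior_conc)) summed over leading axes.

    ``alpha`` has the simplex on its last axis; returns (value, d/dalpha).
    """
    K = alpha.shape[-1]
    S = alpha.sum(axis=-1, keepdims=True)
    value = (
        gammaln(S[..., 0])
        - gammaln(alpha).sum(axis=-1)
        - (gammaln(K * prior_conc) - K * gammaln(prior_conc))
        + ((alpha - prior_conc) * (digamma(alpha) - digamma(S))).sum(axis=-1)
    )
    grad = (alpha - prior_conc) * polygamma(1, alpha) - (
        S - K * prior_conc
    ) * polygamma(1, S)
    return float(value.sum()), grad


def sample_dirichlet(
    rng: np.random.Generator, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample Dirichlet via normalised Gammas; returns (simplex sample, gammas)."""
    gam = rng.standard_gamma(alpha)
    total = gam.sum(axis=-1, keepdims=True)
    total = np.where(total <= 0, 1e-300, total)
    return gam / total, gam


def gamma_implicit_grad(gam: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """d gamma / d alpha for a Gamma(alpha, 1) variate, implicit reparameterisation.

    dz/da = -(dP(z;a)/da) / pdf(z;a); the CDF derivative uses central finite
    differences of the regularised lower incomplete gamma function.
    """
    g = np.clip(gam, 1e-100, None)
    h = 1e-5 * np.maximum(alpha, 1e-2)
    with np.errstate(all="ignore"):
        dP = (gammainc(alpha + h, g) - gammainc(alpha - h, g)) / (2.0 * h)
        log_pdf = (alpha - 1.0) * np.log(g) - g - gammaln(alpha)
        out = -dP * np.exp(-log_pdf)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def dirichlet_chain_grad(
    dL_dF: np.ndarray, F: np.ndarray, gam: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Chain dL/dF through the normalised-Gamma construction to dL/dalpha."""
    total = gam.sum(axis=-1, keepdims=True)
    total = np.where(total <= 0, 1e-300, total)
    dL_dgam = (dL_dF - (dL_dF * F).sum(axis=-1, keepdims=True)) / total
    return dL_dgam * gamma_implicit_grad(gam, alpha)


# ---------------------------------------------------------------------------
# Gaussian (real-valued) guides, used by the GLMs
# ---------------------------------------------------------------------------


def normal_sample(rng: np.random.Generator, mean: np.ndarray,
                  log_sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eps = rng.standard_normal(mean.shape)
    return mean + np.exp(log_sd) * eps, eps


def normal_entropy(log_sd: np.ndarray) -> float:
    """Sum of entropies; d/dlog_sd = 1 per element."""
    return float(np.sum(log_sd + 0.5 * LOG_2PI_E))


def laplace_logpdf_grad(z: np.ndarray, scale) -> tuple[np.ndarray, np.ndarray]:
    """log Laplace(0, scale) density and its derivative wrt z."""
    scale = np.asarray(scale, dtype=float)
    return -np.abs(z) / scale - np.log(2.0 * scale), -np.sign(z) / scale
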