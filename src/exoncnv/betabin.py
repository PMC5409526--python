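"""Beta-binomial model of per-target read proportions.

Given a test sample and an aggregated reference, the count of test reads at a
target, out of the total test+reference reads there, is modelled as
beta-binomial with mean ``mu`` (the expected test proportion at normal copy
number) and intraclass-correlation overdispersion ``phi``:

    alpha = mu * (1 - phi) / phi,   beta = (1 - mu) * (1 - phi) / phi

``phi = 0`` recovers the binomial; a single global ``phi`` is fitted per test
sample by maximum likelihood over all informative targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln

__all__ = ["BetaBinFit", "betabin_logpmf", "fit_betabin"]

# Below this phi the beta-binomial is numerically indistinguishable from the
# binomial (and the gammaln form loses precision), so switch to the exact
# binomial log-pmf.
_PHI_BINOMIAL = 1e-8


@dataclass
class BetaBinFit:
    """Fitted beta-binomial parameters for one test sample.

    ``converged`` is False when the optimiser failed and the moment/default
    fallback (initial mu, phi = 1e-4) was used.
    """

    mu: float
    phi: float
    converged: bool = True
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0) or not math.isfinite(self.mu):
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.phi < 0.0 or not math.isfinite(self.phi):
            raise ValueError(f"phi must be finite and >= 0, got {self.phi}")

    def logpmf(self, x, n) -> np.ndarray:
        return betabin_logpmf(x, n, self.mu, self.phi)


def betabin_logpmf(x, n, mu: float, phi: float) -> np.ndarray:
    """Log-pmf of the beta-binomial in (mu, phi) parameterisation.

    Vectorised over ``x`` and ``n``.  Requires ``0 <= x <= n`` elementwise,
    ``0 < mu < 1`` and ``0 <= phi < 1``.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if ((x < 0) | (x > n)).any():
        raise ValueError("x must satisfy 0 <= x <= n")
    lchoose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    if phi < _PHI_BINOMIAL:
        out = lchoose + x * math.log(mu) + (n - x) * math.log1p(-mu)
    else:
        s = (1.0 - phi) / phi
        a = mu * s
        b = (1.0 - mu) * s
        out = lchoose + betaln(x + a, n - x + b) - betaln(a, b)
    return out


def _loglik_continuous(x, n, mu: float, phi: float) -> np.ndarray:
    """Beta-binomial log-density continuously extended to real ``x``.

    Used for quadrature; skips the domain validation of
    :func:`betabin_logpmf` and assumes ``0 < x < n`` elementwise.
    """
    lchoose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    if phi < _PHI_BINOMIAL:
        return lchoose + x * math.log(mu) + (n - x) * math.log1p(-mu)
    s = (1.0 - phi) / phi
    a = mu * s
    b = (1.0 - mu) * s
    return lchoose + betaln(x + a, n - x + b) - betaln(a, b)


def _nll_and_grad(theta, x, n):
    """Negative log-likelihood and gradient wrt (logit mu, log phi).

    The transformed parameterisation keeps the gradient well conditioned
    across the whole box (phi spans many orders of magnitude).
    """
    mu = 1.0 / (1.0 + math.exp(-theta[0]))
    phi = math.exp(theta[1])
    s = (1.0 - phi) / phi
    a = mu * s
    b = (1.0 - mu) * s
    ll_terms = (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + gammaln(x + a)
        + gammaln(n - x + b)
        - gammaln(n + s)
        - gammaln(a)
        - gammaln(b)
        + gammaln(s)
    )
    d_a = digamma(x + a) - digamma(n + s) - digamma(a) + digamma(s)
    d_b = digamma(n - x + b) - digamma(n + s) - digamma(b) + digamma(s)
    dll_dmu = s * (d_a.sum() - d_b.sum())
    ds_dphi = -1.0 / phi**2
    dll_dphi = ds_dphi * (mu * d_a.sum() + (1.0 - mu) * d_b.sum())
    grad = np.array([dll_dmu * mu * (1.0 - mu), dll_dphi * phi])
    return -ll_terms.sum(), -grad


def _mle(x, n, mu0: float, max_phi: float) -> BetaBinFit:
    logit_mu0 = math.log(mu0 / (1.0 - mu0))
    bounds = [
        # phi floor 1e-6: below it the likelihood is flat to rounding
        # error (gammaln cancellation at s ~ 1/phi) and the line search
        # stalls; at panel depths it inflates the variance by < 1%.
        (math.log(1e-6 / (1 - 1e-6)), math.log((1 - 1e-6) / 1e-6)),
        (math.log(1e-6), math.log(max_phi)),
    ]
    res = None
    for phi0 in (0.01, 1e-4):  # second start rescues rare line-search stalls
        res = minimize(
            _nll_and_grad,
            x0=np.array([logit_mu0, math.log(phi0)]),
            args=(x, n),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.success:
            break
    if not res.success or not np.isfinite(res.fun):
        warnings.warn(
            f"beta-binomial fit did not converge ({res.message}); "
            "falling back to pooled mu with phi = 1e-4"
        )
        ll, _ = _nll_and_grad(np.array([logit_mu0, math.log(1e-4)]), x, n)
        return BetaBinFit(mu=mu0, phi=1e-4, converged=False, loglik=-ll)
    mu = 1.0 / (1.0 + math.exp(-float(res.x[0])))
    phi = math.exp(float(res.x[1]))
    return BetaBinFit(mu=mu, phi=phi, converged=True, loglik=-float(res.fun))


# A target is trimmed from the dispersion refit when a copy-number-altered
# mean explains its count this much better (in nats) than the normal-copy
# mean — the same order as the HMM's prior cost of opening a CNV.
_TRIM_LOGLIK = math.log(98.0)


def fit_betabin(
    test_counts,
    ref_counts,
    max_phi: float = 0.5,
    trim_outliers: bool = True,
) -> BetaBinFit:
    """Maximum-likelihood (mu, phi) for test counts given test+reference totals.

    Targets with zero total count are uninformative and excluded; at least 5
    informative targets are required.  ``mu`` is initialised at the pooled
    proportion sum(test) / (sum(test) + sum(ref)).  On optimiser failure the
    fit falls back to (initial mu, phi = 1e-4) with ``converged = False`` and
    a warning.

    The (mu, phi) pair describes targets at *normal* copy number, but the
    test sample may carry the very CNV the caller is looking for; on a small
    panel a single genuinely altered exon can inflate the dispersion estimate
    enough to mask the variant.  With ``trim_outliers`` (default) the MLE is
    therefore re-run once after excluding targets whose count is explained
    markedly better (log-likelihood margin ~ the caller's prior cost of
    opening a CNV) by a halved or 1.5x mean than by the fitted normal-copy
    model.  On copy-neutral data the trim is a no-op at the calling false
    positive rate.
    """
    t = np.asarray(test_counts, dtype=float)
    r = np.asarray(ref_counts, dtype=float)
    if t.shape != r.shape:
        raise ValueError("test and reference count vectors differ in length")
    n_all = t + r
    keep = n_all > 0
    if keep.sum() < 5:
        raise ValueError(
            f"need >=5 informative targets (test+ref > 0), got {int(keep.sum())}"
        )
    if t.sum() == 0:
        raise ValueError("all test counts are zero; nothing to fit")
    if r.sum() == 0:
        raise ValueError("all reference counts are zero; nothing to fit")
    x, n = t[keep], n_all[keep]
    mu0 = float(t.sum() / (t.sum() + r.sum()))
    mu0 = min(max(mu0, 1e-6), 1 - 1e-6)
    fit = _mle(x, n, mu0, max_phi)
    if not trim_outliers or not fit.converged:
        return fit
    # Odds-scaled means for copy numbers 1 and 3 (c*mu / (c*mu + 2*(1-mu))).
    mu_del = fit.mu / (2.0 - fit.mu)
    mu_dup = 3.0 * fit.mu / (3.0 * fit.mu + 2.0 * (1.0 - fit.mu))
    ll2 = betabin_logpmf(x, n, fit.mu, fit.phi)
    ll_alt = np.maximum(
        betabin_logpmf(x, n, mu_del, fit.phi),
        betabin_logpmf(x, n, mu_dup, fit.phi),
    )
    inlier = ll_alt - ll2 < _TRIM_LOGLIK
    if inlier.all() or inlier.sum() < 5:
        return fit
    refit = _mle(x[inlier], n[inlier], mu0, max_phi)
    if not refit.converged:
        return fit
    return refit
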