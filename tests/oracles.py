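"""Independent numeric oracles shared by the tests.

These deliberately avoid the package's closed forms: they integrate the
hierarchical densities numerically.
"""

import numpy as np
from scipy import integrate, stats


def gg_marginal_quadrature(beta, alpha, alpha0, nu):
    """Log of ∫ prod_j Gamma(beta_j; alpha, lam) Gamma(lam; alpha0, nu) dlam
    by adaptive quadrature, offset at the integrand's mode so the magnitude
    stays well scaled for any J'."""
    beta = np.asarray(beta, dtype=float)
    jp = beta.size

    def log_integrand(lam):
        return (stats.gamma.logpdf(beta, alpha, scale=1.0 / lam).sum()
                + stats.gamma.logpdf(lam, alpha0, scale=1.0 / nu))

    mode = max((jp * alpha + alpha0 - 1) / (beta.sum() + nu), 1e-8)
    offset = log_integrand(mode)
    val, _ = integrate.quad(
        lambda lam: np.exp(log_integrand(lam) - offset),
        0, np.inf, limit=400, epsabs=1e-300, epsrel=1e-10)
    return offset + np.log(val)
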