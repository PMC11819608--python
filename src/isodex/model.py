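"""Model densities and conditional-posterior parameter formulas.

Two-layer hierarchy per isoform t of gene g:

Within-sample (Poisson-Lognormal) layer.  The count in exon region i of
sample j attributed to isoform t is Poisson with mean

    gamma[t, i, j] = x[i, j] * beta[t, j] * exp(U[t, i]),

where ``x = L_i * N_j / 1e9`` is the region length weighted by library size
(so beta is on the FPKM scale), and U[t, i] is a positional dispersion term
with a Normal(0, 1/tau) prior constrained to sum to zero over the regions
the isoform includes.  tau ~ Gamma(a, b) controls the overall degree of
within-sample variability.

Between-sample (Gamma-Gamma) layer.  Abundances across samples follow
beta[t, j] ~ Gamma(alpha, lambda_group); when the latent differential state
d = 0 both phenotype groups share one rate lambda ~ Gamma(alpha0, nu), when
d = 1 each group has its own rate drawn from the same Gamma(alpha0, nu)
prior, and nu ~ Gamma(a0, b0).

All Gamma distributions use the shape-RATE parameterization
(mean = shape / rate) — forced by the additive rate update of the tau
conditional.  All likelihood computations are in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class SampleDesign:
    """Two-group sample layout: group label (1 or 2) per sample column."""

    groups: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(g not in (1, 2) for g in self.groups):
            raise ValueError("group labels must be 1 or 2")
        if self.j1 < 1 or self.j2 < 1:
            raise ValueError("each phenotype group needs at least one sample")

    @classmethod
    def from_sizes(cls, j1: int, j2: int) -> "SampleDesign":
        return cls(tuple([1] * j1 + [2] * j2))

    @property
    def j1(self) -> int:
        return sum(1 for g in self.groups if g == 1)

    @property
    def j2(self) -> int:
        return sum(1 for g in self.groups if g == 2)

    @property
    def n_samples(self) -> int:
        return len(self.groups)

    @cached_property
    def group1_idx(self) -> np.ndarray:
        return np.array([k for k, g in enumerate(self.groups) if g == 1])

    @cached_property
    def group2_idx(self) -> np.ndarray:
        return np.array([k for k, g in enumerate(self.groups) if g == 2])


def poisson_rates(
    x: np.ndarray,
    beta: np.ndarray,
    U: np.ndarray,
    s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-isoform Poisson means and their per-region totals for one sample.

    Parameters
    ----------
    x : (I,) positive region weights for the sample.
    beta : (T,) positive isoform abundances.
    U : (T, I) positional dispersions (zero where ``s == 0``).
    s : (T, I) binary inclusion matrix.

    Returns
    -------
    gamma : (T, I) array, ``gamma[t, i] = x[i] * beta[t] * exp(U[t, i]) * s[t, i]``.
    exon_totals : (I,) array, observed-scale Poisson mean per region.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(x <= 0):
        raise ValueError("region weights x must be strictly positive")
    if np.any(beta <= 0):
        raise ValueError("abundances beta must be strictly positive")
    gamma = s * np.exp(U) * beta[:, None] * x[None, :]
    return gamma, gamma.sum(axis=0)


def log_conditional_U(
    u: float,
    t: int,
    y_i: np.ndarray,
    x_i: np.ndarray,
    beta: np.ndarray,
    U_i: np.ndarray,
    s_i: np.ndarray,
    tau: float,
) -> float:
    """Log unnormalized conditional density of one dispersion entry U[t, i].

    The target is the product over samples of the Poisson likelihood of the
    observed region total (whose mean sums the contributions of every isoform
    including region i) times the Normal(0, 1/tau) prior:

        sum_j [ y_ij * log(R_ij) - R_ij ] - tau * u^2 / 2,
        R_ij = sum_t' s[t', i] * beta[t', j] * x[i, j] * exp(U[t', i])

    with U[t, i] replaced by the candidate value ``u``.

    Parameters
    ----------
    u : candidate value for U[t, i].
    t : isoform row being updated.
    y_i : (J,) observed counts at region i.
    x_i : (J,) region weights at region i.
    beta : (T, J) abundances.
    U_i : (T,) current dispersions at region i (entry t is ignored).
    s_i : (T,) inclusion column at region i.
    tau : precision of the Normal prior, > 0.
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    eU = np.where(s_i > 0, np.exp(U_i), 0.0)
    eU[t] = np.exp(u) * s_i[t]
    rates = x_i * (eU @ beta)  # (J,)
    y_i = np.asarray(y_i, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = np.where(
            y_i > 0,
            y_i * np.log(rates) - rates,
            -rates,
        )
    return float(loglik.sum() - 0.5 * tau * u * u)


def tau_conditional_params(
    a: float,
    b: float,
    U_row: np.ndarray,
    s_row: np.ndarray,
) -> tuple[float, float]:
    """Conjugate Gamma posterior parameters of the precision tau.

    shape = a + (number of included regions) / 2,
    rate  = b + (sum of squared U over included regions) / 2.
    """
    if a <= 0 or b <= 0:
        raise ValueError("hyperparameters a, b must be strictly positive")
    s_row = np.asarray(s_row)
    U_row = np.asarray(U_row, dtype=float)
    shape = a + float(s_row.sum()) / 2.0
    rate = b + float((s_row * U_row**2).sum()) / 2.0
    return shape, rate


def gg_log_marginal(
    beta_vec: np.ndarray,
    alpha: float,
    alpha0: float,
    nu: float,
) -> float:
    """Log marginal density of abundances with the group rate integrated out.

    m(beta) = ∫ prod_j Gamma(beta_j; alpha, lam) * Gamma(lam; alpha0, nu) dlam
            = nu^alpha0 * Gamma(alpha0 + J'*alpha)
              / (Gamma(alpha0) * Gamma(alpha)^J')
              * (prod beta_j)^(alpha - 1) / (nu + sum beta_j)^(alpha0 + J'*alpha)

    An empty vector returns 0 (empty-product convention).
    """
    beta_vec = np.asarray(beta_vec, dtype=float)
    if beta_vec.size == 0:
        return 0.0
    if np.any(beta_vec <= 0) or min(alpha, alpha0, nu) <= 0:
        raise ValueError("abundances and parameters must be strictly positive")
    jp = beta_vec.size
    return float(
        alpha0 * np.log(nu)
        + gammaln(alpha0 + jp * alpha)
        - gammaln(alpha0)
        - jp * gammaln(alpha)
        + (alpha - 1.0) * np.log(beta_vec).sum()
        - (alpha0 + jp * alpha) * np.log(nu + beta_vec.sum())
    )


def gg_log_marginal_rows(
    B: np.ndarray,
    alpha: float,
    alpha0: float,
    nu: float,
) -> np.ndarray:
    """Vectorized :func:`gg_log_marginal` over the rows of ``B`` (T, J')."""
    B = np.asarray(B, dtype=float)
    jp = B.shape[1]
    if jp == 0:
        return np.zeros(B.shape[0])
    return (
        alpha0 * np.log(nu)
        + gammaln(alpha0 + jp * alpha)
        - gammaln(alpha0)
        - jp * gammaln(alpha)
        + (alpha - 1.0) * np.log(B).sum(axis=1)
        - (alpha0 + jp * alpha) * np.log(nu + B.sum(axis=1))
    )


def snr_db(values1: np.ndarray, values2: np.ndarray) -> float:
    """Signal-to-noise ratio of the between-group separation, in decibels.

    SNR_dB = 10 * log10( (mean1 - mean2)^2 / (var1 + var2) ) with unbiased
    sample variances.  Equal means return ``-inf`` as a sentinel; a zero
    variance sum is a degenerate input and raises.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size < 2 or v2.size < 2:
        raise ValueError("each group needs at least two values")
    noise = v1.var(ddof=1) + v2.var(ddof=1)
    if noise == 0:
        raise ValueError("zero variance in both groups: SNR undefined")
    signal = (v1.mean() - v2.mean()) ** 2
    if signal == 0:
        return float("-inf")
    return float(10.0 * np.log10(signal / noise))
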