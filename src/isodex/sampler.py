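"""Metropolis-Hastings-within-Gibbs sampler for the joint isoform model.

Per iteration and per gene the chain updates, in a fixed order:

1. latent per-isoform counts (multinomial split of each observed region
   count among the isoforms covering it — Poisson superposition
   augmentation, which makes the abundance update conjugate);
2. abundances ``beta`` (conjugate Gamma);
3. positional dispersions ``U`` (pairwise-transfer Metropolis random walk
   that preserves the sum-to-zero constraint exactly);
4. precisions ``tau`` (conjugate Gamma);
5. differential states ``d`` (exact collapsed Bernoulli conditional with the
   group rate integrated out analytically);
6. group rates ``lambda`` (conjugate Gamma, regenerated under the new ``d``);

followed by global updates of the shapes ``alpha`` and ``alpha0``
(log-scale Metropolis random walks with Gamma(0.01, 0.01) priors) and the
rate ``nu`` (conjugate Gamma).  The posterior probability of differential
expression is the post-burn-in mean of the sampled ``d``.

A single seeded ``numpy.random.Generator`` drives every draw; the kernels
are invoked in the documented order with vectorized draws, so a fixed seed
reproduces the chain bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .model import SampleDesign, gg_log_marginal, gg_log_marginal_rows, snr_db, tau_conditional_params


@dataclass
class GeneData:
    """Observed data for one gene: inclusion matrix, counts and weights."""

    gene_id: str
    transcript_ids: list[str]
    s: np.ndarray  # (T, I) binary
    y: np.ndarray  # (I, J) non-negative int
    x: np.ndarray  # (I, J) positive float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.int8)
        self.y = np.asarray(self.y)
        self.x = np.asarray(self.x, dtype=float)
        T, I = self.s.shape
        if self.y.shape[0] != I or self.x.shape != self.y.shape:
            raise ValueError(f"{self.gene_id}: inconsistent array shapes")
        if len(self.transcript_ids) != T:
            raise ValueError(f"{self.gene_id}: transcript id count != T")
        if np.any(self.x <= 0):
            raise ValueError(f"{self.gene_id}: weights must be positive")


@dataclass
class MCMCConfig:
    """Chain length, proposal scales, hyperparameters and the seed.

    ``a, b`` parameterize the Gamma prior on the precision ``tau``;
    ``a0, b0`` the Gamma prior on the rate ``nu``; ``prior_shape`` and
    ``prior_rate`` the diffuse Gamma priors on the shapes ``alpha`` and
    ``alpha0``; ``pi1`` is the prior probability that an isoform is
    differentially expressed.
    """

    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 1
    sigma_u: float = 0.2
    sigma_log_alpha: float = 0.3
    sigma_log_alpha0: float = 0.3
    seed: int = 0
    a: float = 1.0
    b: float = 1.0
    a0: float = 1.0
    b0: float = 1.0
    pi1: float = 0.5
    prior_shape: float = 0.01
    prior_rate: float = 0.01
    keep_traces: bool = False
    check_invariants: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= B < N")
        if min(self.sigma_u, self.sigma_log_alpha, self.sigma_log_alpha0) <= 0:
            raise ValueError("proposal scales must be positive")
        if not 0 < self.pi1 < 1:
            raise ValueError("pi1 must lie in (0, 1)")
        if min(self.a, self.b, self.a0, self.b0,
               self.prior_shape, self.prior_rate) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class PosteriorSummary:
    """Posterior means and diagnostics from one chain."""

    gene_ids: list[str]
    transcript_ids: dict[str, list[str]]
    p: dict[str, np.ndarray]
    beta_hat: dict[str, np.ndarray]
    U_hat: dict[str, np.ndarray]
    tau_hat: dict[str, np.ndarray]
    alpha_hat: float
    alpha0_hat: float
    nu_hat: float
    acceptance_rates: dict[str, float]
    not_estimable: dict[str, np.ndarray]
    design: SampleDesign
    truth_snr: dict[str, np.ndarray] | None = None
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """One row per isoform: posterior P(d=1), group means, SNR."""
        g1 = self.design.group1_idx
        g2 = self.design.group2_idx
        rows = []
        for gid in self.gene_ids:
            B = self.beta_hat[gid]
            for t, tid in enumerate(self.transcript_ids[gid]):
                b1, b2 = B[t, g1], B[t, g2]
                try:
                    snr = snr_db(b1, b2)
                except ValueError:
                    snr = float("nan")
                rows.append((
                    gid, tid, float(self.p[gid][t]),
                    float(b1.mean()), float(b2.mean()), snr,
                    bool(self.not_estimable[gid][t]),
                ))
        return pd.DataFrame(rows, columns=[
            "gene_id", "transcript_id", "prob_differential",
            "mean_group1", "mean_group2", "snr_db", "not_estimable",
        ])


# -- individual kernels ------------------------------------------------------

def allocate_latent_counts(
    y_ij: int,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Split one observed region count among isoforms by Poisson thinning.

    Conditional on the total, the per-isoform counts are multinomial with
    probabilities proportional to the per-isoform Poisson rates.
    """
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if y_ij < 0:
        raise ValueError("observed count must be non-negative")
    if y_ij == 0:
        return np.zeros(rates.size, dtype=np.int64)
    if total <= 0:
        raise ValueError("positive count with all rates zero: inconsistent model")
    return rng.multinomial(int(y_ij), rates / total)


def gibbs_beta(
    latent_total: np.ndarray,
    weight_total: np.ndarray,
    alpha: float,
    lam: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate abundance draw: Gamma(alpha + reads, lambda + exposure).

    ``latent_total`` is the isoform's latent read count summed over its
    regions; ``weight_total`` the matching sum of ``x * exp(U)`` (the Poisson
    exposure per unit abundance).  Broadcasts over arrays.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be strictly positive")
    shape = alpha + np.asarray(latent_total, dtype=float)
    rate = lam + np.asarray(weight_total, dtype=float)
    return rng.gamma(shape, 1.0 / rate)


def gibbs_tau(
    U_row: np.ndarray,
    s_row: np.ndarray,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> float:
    """Conjugate precision draw from the tau conditional."""
    shape, rate = tau_conditional_params(a, b, U_row, s_row)
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_lambda(
    beta_t: np.ndarray,
    design: SampleDesign,
    alpha: float,
    alpha0: float,
    nu: float,
    d: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Conjugate group-rate draw(s) for one isoform.

    Returns ``(lam1, lam2)``; equal (one shared draw) when ``d == 0``.
    """
    b1 = np.asarray(beta_t, dtype=float)[design.group1_idx]
    b2 = np.asarray(beta_t, dtype=float)[design.group2_idx]
    if d == 0:
        lam = float(rng.gamma(alpha0 + design.n_samples * alpha,
                              1.0 / (nu + b1.sum() + b2.sum())))
        return lam, lam
    lam1 = float(rng.gamma(alpha0 + design.j1 * alpha, 1.0 / (nu + b1.sum())))
    lam2 = float(rng.gamma(alpha0 + design.j2 * alpha, 1.0 / (nu + b2.sum())))
    return lam1, lam2


def gibbs_nu(
    lams: np.ndarray,
    alpha0: float,
    a0: float,
    b0: float,
    rng: np.random.Generator,
) -> float:
    """Conjugate draw of the top-level rate nu given all active group rates."""
    lams = np.asarray(lams, dtype=float)
    return float(rng.gamma(a0 + lams.size * alpha0, 1.0 / (b0 + lams.sum())))


def sample_d(
    beta1: np.ndarray,
    beta2: np.ndarray,
    alpha: float,
    alpha0: float,
    nu: float,
    pi1: float,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Exact collapsed Bernoulli draw of the differential state.

    With the group rates integrated out analytically,

        P(d=1 | beta) = pi1 * m(beta1) * m(beta2)
                        / [pi1 * m(beta1) * m(beta2) + (1 - pi1) * m(beta_all)]

    where ``m`` is the closed-form Gamma-Gamma marginal; computed in log
    space.  Returns the draw and its conditional probability.
    """
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.size == 0 or beta2.size == 0:
        raise ValueError("both groups must be non-empty")
    l1 = (np.log(pi1)
          + gg_log_marginal(beta1, alpha, alpha0, nu)
          + gg_log_marginal(beta2, alpha, alpha0, nu))
    l0 = (np.log1p(-pi1)
          + gg_log_marginal(np.concatenate([beta1, beta2]), alpha, alpha0, nu))
    prob = float(expit(l1 - l0))
    return int(rng.random() < prob), prob


def mh_update_U(
    U_row: np.ndarray,
    s_row: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    beta_t: np.ndarray,
    tau: float,
    sigma_u: float,
    rng: np.random.Generator,
    other_rates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One sweep of pairwise-transfer Metropolis proposals on a U row.

    Each included region i is paired with a random other included region i2
    and a transfer ``(U_i + delta, U_i2 - delta)`` with
    ``delta ~ Normal(0, sigma_u^2)`` is proposed, so the sum over included
    regions is conserved to machine precision by construction.  The
    acceptance ratio uses the Poisson likelihood of the observed totals at
    the two touched regions plus the Normal(0, 1/tau) prior terms.

    ``other_rates`` (I, J) carries the Poisson-mean contributions of the
    gene's *other* isoforms at each region; zero when the isoform is alone.
    Fewer than two included regions is a no-op (U stays identically zero).

    Returns the new row and a boolean acceptance flag per proposal.
    """
    s_row = np.asarray(s_row)
    inc = np.flatnonzero(s_row)
    if inc.size < 2:
        return np.zeros_like(np.asarray(U_row, dtype=float)), np.zeros(0, bool)
    U = np.asarray(U_row, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    beta_t = np.asarray(beta_t, dtype=float)
    other = np.zeros_like(x) if other_rates is None else np.asarray(other_rates, float)

    accepted = np.zeros(inc.size, dtype=bool)
    xb = x[inc] * beta_t[None, :]      # (n_inc, J), x * beta per region
    other_inc = other[inc]
    y_inc = y[inc]
    eu = np.exp(U[inc])
    u = U[inc]
    deltas = rng.normal(0.0, sigma_u, size=inc.size)
    partners = rng.integers(0, inc.size - 1, size=inc.size)
    log_accept = np.log(rng.random(size=inc.size))
    for k in range(inc.size):
        k2 = int(partners[k])
        if k2 >= k:  # uniform over the other included regions
            k2 += 1
        delta = deltas[k]
        ed = np.exp(delta)
        c_k, c_k2 = xb[k] * eu[k], xb[k2] * eu[k2]
        r_k, r_k2 = other_inc[k] + c_k, other_inc[k2] + c_k2
        rn_k, rn_k2 = other_inc[k] + c_k * ed, other_inc[k2] + c_k2 / ed
        u_k, u_k2 = u[k] + delta, u[k2] - delta
        dlog = (
            y_inc[k] @ np.log(rn_k / r_k) - (rn_k - r_k).sum()
            + y_inc[k2] @ np.log(rn_k2 / r_k2) - (rn_k2 - r_k2).sum()
            - 0.5 * tau * (u_k**2 - u[k]**2 + u_k2**2 - u[k2]**2)
        )
        if log_accept[k] < dlog:
            u[k], u[k2] = u_k, u_k2
            eu[k] *= ed
            eu[k2] /= ed
            accepted[k] = True
    U[inc] = u
    return U, accepted


def mh_update_shape(
    current: float,
    log_target: Callable[[float], float],
    sigma_log: float,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Log-scale Metropolis random walk for a positive shape parameter.

    Proposes ``current * exp(eps)`` with ``eps ~ Normal(0, sigma_log^2)``;
    the acceptance ratio includes the Jacobian ``proposal / current`` of the
    log-scale walk.
    """
    if current <= 0:
        raise ValueError("current value must be strictly positive")
    lt_cur = log_target(current)
    if not np.isfinite(lt_cur):
        raise ValueError("non-finite log-target at current state")
    proposal = current * float(np.exp(rng.normal(0.0, sigma_log)))
    dlog = log_target(proposal) - lt_cur + np.log(proposal / current)
    if np.log(rng.random()) < dlog:
        return proposal, True
    return current, False


# -- orchestration -----------------------------------------------------------

class _GeneState:
    """Mutable chain state for one gene."""

    __slots__ = ("beta", "U", "tau", "lam1", "lam2", "d",
                 "p_sum", "beta_sum", "U_sum", "tau_sum", "zero")

    def __init__(self, gd: GeneData, design: SampleDesign):
        T, I = gd.s.shape
        J = design.n_samples
        num = gd.s @ gd.y.astype(float)     # (T, J) reads compatible with t
        den = gd.s @ gd.x                   # (T, J) exposure
        self.beta = np.maximum(num / den, 1e-3)
        self.U = np.zeros((T, I))
        self.tau = np.ones(T)
        self.lam1 = np.ones(T)
        self.lam2 = np.ones(T)
        self.d = np.zeros(T, dtype=np.int8)
        self.p_sum = np.zeros(T)
        self.beta_sum = np.zeros((T, J))
        self.U_sum = np.zeros((T, I))
        self.tau_sum = np.zeros(T)
        self.zero = bool(gd.y.sum() == 0)


def _update_gene(
    gd: GeneData,
    st: _GeneState,
    design: SampleDesign,
    cfg: MCMCConfig,
    alpha: float,
    alpha0: float,
    nu: float,
    rng: np.random.Generator,
    u_stats: list[int],
) -> None:
    s = gd.s
    T, I = s.shape
    y = gd.y
    x = gd.x
    g1, g2 = design.group1_idx, design.group2_idx

    eU = np.exp(st.U) * s  # (T, I), zero where excluded

    # 1. latent allocation: the weight x[i, j] is common to all isoforms at a
    # region, so allocation probabilities reduce to beta * exp(U) * s.
    J = design.n_samples
    pv = eU.T[:, None, :] * st.beta.T[None, :, :]   # (I, J, T)
    pv /= pv.sum(axis=2, keepdims=True)
    ylat = rng.multinomial(
        y.reshape(-1), pv.reshape(I * J, T)).reshape(I, J, T)
    if cfg.check_invariants:
        recon = ylat.sum(axis=2)
        if not np.array_equal(recon, y):
            raise AssertionError(f"{gd.gene_id}: latent counts do not sum to y")
        if np.any(ylat * (1 - s.T[:, None, :])):
            raise AssertionError(f"{gd.gene_id}: latent counts on excluded regions")

    # 2. beta | latent counts (conjugate)
    latent_tot = ylat.sum(axis=0).T.astype(float)   # (T, J)
    weight_tot = eU @ x                              # (T, J)
    lam_cols = np.empty((T, design.n_samples))
    lam_cols[:, g1] = st.lam1[:, None]
    lam_cols[:, g2] = st.lam2[:, None]
    st.beta = rng.gamma(alpha + latent_tot, 1.0 / (lam_cols + weight_tot))

    # 3. U sweeps (pairwise transfer M-H), with the other isoforms'
    # contributions held fixed in the observed-total likelihood
    contrib = eU[:, :, None] * st.beta[:, None, :] * x[None, :, :]  # (T, I, J)
    total = contrib.sum(axis=0)
    for t in range(T):
        new_row, acc = mh_update_U(
            st.U[t], s[t], y, x, st.beta[t], float(st.tau[t]),
            cfg.sigma_u, rng, other_rates=total - contrib[t])
        if acc.size:
            u_stats[0] += acc.size
            u_stats[1] += int(acc.sum())
        if acc.any():
            st.U[t] = new_row
            new_contrib = (np.exp(new_row) * s[t])[:, None] * st.beta[t][None, :] * x
            total += new_contrib - contrib[t]
            contrib[t] = new_contrib
        if cfg.check_invariants:
            resid = abs(float((s[t] * st.U[t]).sum()))
            if resid >= 1e-10:
                raise AssertionError(
                    f"{gd.gene_id}: sum-to-zero violated ({resid:.2e})")

    # 4. tau (conjugate, vectorized over isoforms)
    shape = cfg.a + s.sum(axis=1) / 2.0
    rate = cfg.b + (s * st.U**2).sum(axis=1) / 2.0
    st.tau = rng.gamma(shape, 1.0 / rate)

    # 5. d (collapsed Bernoulli, vectorized over isoforms)
    B1, B2 = st.beta[:, g1], st.beta[:, g2]
    l1 = (np.log(cfg.pi1)
          + gg_log_marginal_rows(B1, alpha, alpha0, nu)
          + gg_log_marginal_rows(B2, alpha, alpha0, nu))
    l0 = np.log1p(-cfg.pi1) + gg_log_marginal_rows(st.beta, alpha, alpha0, nu)
    prob = expit(l1 - l0)
    st.d = (rng.random(T) < prob).astype(np.int8)

    # 6. lambda | d (conjugate; shared draw when d=0)
    sum1, sum2 = B1.sum(axis=1), B2.sum(axis=1)
    j1, j2 = design.j1, design.j2
    null = st.d == 0
    lam1 = np.empty(T)
    lam2 = np.empty(T)
    if null.any():
        shared = rng.gamma(alpha0 + (j1 + j2) * alpha,
                           1.0 / (nu + sum1[null] + sum2[null]))
        lam1[null] = lam2[null] = shared
    alt = ~null
    if alt.any():
        lam1[alt] = rng.gamma(alpha0 + j1 * alpha, 1.0 / (nu + sum1[alt]))
        lam2[alt] = rng.gamma(alpha0 + j2 * alpha, 1.0 / (nu + sum2[alt]))
    st.lam1, st.lam2 = lam1, lam2


def run_mcmc(
    genes: list[GeneData],
    design: SampleDesign,
    config: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Run the full chain and return posterior summaries.

    Genes with zero total counts in every sample are flagged: their
    differential probability is reported as the prior ``pi1`` with a
    ``not_estimable`` marker and they do not enter the global updates.
    """
    cfg = config or MCMCConfig()
    rng = np.random.default_rng(cfg.seed)
    j1, j2 = design.j1, design.j2
    for gd in genes:
        if gd.y.shape[1] != design.n_samples:
            raise ValueError(f"{gd.gene_id}: sample dimension != design")

    states = [_GeneState(gd, design) for gd in genes]
    active = [k for k, st in enumerate(states) if not st.zero]
    alpha = alpha0 = nu = 1.0

    n_kept = 0
    alpha_sum = alpha0_sum = nu_sum = 0.0
    u_stats = [0, 0]
    shape_stats = {"alpha": [0, 0], "alpha0": [0, 0]}
    traces: dict[str, list[float]] = {"alpha": [], "alpha0": [], "nu": []}

    pa, pb = cfg.prior_shape, cfg.prior_rate

    for it in range(cfg.n_iter):
        s_loglam_beta = 0.0
        s_logbeta = 0.0
        n_terms = 0
        lam_values: list[np.ndarray] = []
        for k in active:
            _update_gene(genes[k], states[k], design, cfg,
                         alpha, alpha0, nu, rng, u_stats)
            st = states[k]
            s_loglam_beta += float(j1 * np.log(st.lam1).sum()
                                   + j2 * np.log(st.lam2).sum())
            s_logbeta += float(np.log(st.beta).sum())
            n_terms += st.beta.size
            alt = st.d == 1
            lam_values.append(st.lam1)
            if alt.any():
                lam_values.append(st.lam2[alt])

        if n_terms:
            lams = np.concatenate(lam_values)
            m = lams.size
            s_loglam = float(np.log(lams).sum())

            def alpha_target(a: float) -> float:
                return (a * s_loglam_beta + (a - 1.0) * s_logbeta
                        - n_terms * gammaln(a) + (pa - 1.0) * np.log(a) - pb * a)

            alpha, acc = mh_update_shape(alpha, alpha_target,
                                         cfg.sigma_log_alpha, rng)
            shape_stats["alpha"][0] += 1
            shape_stats["alpha"][1] += int(acc)

            def alpha0_target(a0: float) -> float:
                return (m * a0 * np.log(nu) + (a0 - 1.0) * s_loglam
                        - m * gammaln(a0) + (pa - 1.0) * np.log(a0) - pb * a0)

            alpha0, acc = mh_update_shape(alpha0, alpha0_target,
                                          cfg.sigma_log_alpha0, rng)
            shape_stats["alpha0"][0] += 1
            shape_stats["alpha0"][1] += int(acc)

            nu = gibbs_nu(lams, alpha0, cfg.a0, cfg.b0, rng)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_kept += 1
            alpha_sum += alpha
            alpha0_sum += alpha0
            nu_sum += nu
            for k in active:
                st = states[k]
                st.p_sum += st.d
                st.beta_sum += st.beta
                st.U_sum += st.U
                st.tau_sum += st.tau
            if cfg.keep_traces:
                traces["alpha"].append(alpha)
                traces["alpha0"].append(alpha0)
                traces["nu"].append(nu)

    p = {}
    beta_hat = {}
    U_hat = {}
    tau_hat = {}
    not_est = {}
    for gd, st in zip(genes, states):
        T = gd.s.shape[0]
        if st.zero:
            p[gd.gene_id] = np.full(T, cfg.pi1)
            beta_hat[gd.gene_id] = st.beta.copy()
            U_hat[gd.gene_id] = np.zeros_like(st.U)
            tau_hat[gd.gene_id] = np.ones(T)
            not_est[gd.gene_id] = np.ones(T, dtype=bool)
        else:
            p[gd.gene_id] = st.p_sum / n_kept
            beta_hat[gd.gene_id] = st.beta_sum / n_kept
            U_hat[gd.gene_id] = st.U_sum / n_kept
            tau_hat[gd.gene_id] = st.tau_sum / n_kept
            not_est[gd.gene_id] = np.zeros(T, dtype=bool)

    rates = {
        "U": u_stats[1] / u_stats[0] if u_stats[0] else float("nan"),
        "alpha": (shape_stats["alpha"][1] / shape_stats["alpha"][0]
                  if shape_stats["alpha"][0] else float("nan")),
        "alpha0": (shape_stats["alpha0"][1] / shape_stats["alpha0"][0]
                   if shape_stats["alpha0"][0] else float("nan")),
    }
    return PosteriorSummary(
        gene_ids=[gd.gene_id for gd in genes],
        transcript_ids={gd.gene_id: list(gd.transcript_ids) for gd in genes},
        p=p, beta_hat=beta_hat, U_hat=U_hat, tau_hat=tau_hat,
        alpha_hat=alpha_sum / n_kept, alpha0_hat=alpha0_sum / n_kept,
        nu_hat=nu_sum / n_kept, acceptance_rates=rates,
        not_estimable=not_est, design=design,
        traces={k: np.array(v) for k, v in traces.items()} if cfg.keep_traces else {},
    )
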