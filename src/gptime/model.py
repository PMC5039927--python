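"""Log joint density of the pseudotime model.

Each gene's expression profile is a Gaussian process over latent pseudotime
with a constant gene-specific mean ``phi_g`` (estimated from the data as the
gene's mean expression), shared Matern 3/2 temporal correlation, per-gene
amplitude ``psi_g`` and noise ``omega_g``.  Pseudotimes get independent
normal priors centred on each cell's capture time; ``psi_g`` and ``omega_g``
get log-normal priors.

The marginal likelihood of each gene is a multivariate normal whose
covariance depends on the pseudotimes, so the log joint is

    sum_g log N(x_g; phi_g 1, psi_g K(tau) + omega_g I)
    + sum_c log N(tau_c; k_c, sigma_tau)
    + sum_g [log LogNormal(psi_g) + log LogNormal(omega_g)]

A deterministic-training-conditional (projected-process) sparse
approximation through ``M`` inducing pseudotimes replaces the exact
per-gene marginal when ``n_inducing`` is set, at cost O(C M^2) per gene,
and is exact when the inducing set coincides with the pseudotimes.

Analytic gradients with respect to ``tau``, ``log psi`` and ``log omega``
are provided for both the exact and the sparse likelihood; they drive the
Hamiltonian Monte Carlo and variational engines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CellMetadata, ExpressionMatrix
from .kernels import (
    GeneParams,
    KernelConfig,
    _correlation_and_grad,
    correlation_matrix,
)

__all__ = [
    "Hyperparameters",
    "ModelState",
    "gene_marginal_loglik",
    "sparse_gene_marginal_loglik",
    "choose_inducing_points",
    "log_prior",
    "log_joint",
    "make_log_density",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Hyperparameters:
    """Model hyperparameters.

    ``mu_psi, sigma_psi`` and ``mu_omega, sigma_omega`` parameterize the
    log-normal priors on per-gene amplitude and noise variances (typically
    set by empirical Bayes).  ``length_scale`` and ``sigma_tau`` are supplied
    by the user in capture-time units.  ``period`` turns on the periodic
    kernel; ``n_inducing`` turns on the sparse likelihood.
    """

    mu_psi: float
    sigma_psi: float
    mu_omega: float
    sigma_omega: float
    length_scale: float
    sigma_tau: float
    period: float | None = None
    n_inducing: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_psi", "sigma_omega", "length_scale", "sigma_tau"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.period is not None and self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if self.n_inducing is not None and self.n_inducing < 2:
            raise ValueError(f"n_inducing must be >= 2, got {self.n_inducing}")

    def kernel_config(self, jitter: float | None = None) -> KernelConfig:
        return KernelConfig(length_scale=self.length_scale, period=self.period, jitter=jitter)


@dataclass
class ModelState:
    """One point in parameter space: pseudotimes plus per-gene variances."""

    tau: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("tau must be finite")
        if np.any(self.psi <= 0) or np.any(self.omega <= 0):
            raise ValueError("psi and omega must be strictly positive")


# ---------------------------------------------------------------------------
# Exact marginal likelihood, batched over genes
# ---------------------------------------------------------------------------


def _batched_cholesky(sig: np.ndarray, base_jitter: np.ndarray, gene_label=None):
    """Cholesky of stacked covariances with x10 jitter escalation (3 tries)."""
    try:
        return np.linalg.cholesky(sig), base_jitter
    except np.linalg.LinAlgError:
        pass
    G = sig.shape[0]
    L = np.empty_like(sig)
    used = base_jitter.copy()
    eye = np.eye(sig.shape[-1])
    for g in range(G):
        extra = 0.0
        for attempt in range(4):
            try:
                L[g] = np.linalg.cholesky(sig[g] + extra * eye)
                used[g] = base_jitter[g] + extra
                break
            except np.linalg.LinAlgError:
                if attempt == 3:
                    label = gene_label(g) if gene_label else str(g)
                    raise np.linalg.LinAlgError(
                        f"covariance for gene {label} is not positive definite "
                        "even after jitter escalation"
                    ) from None
                extra = base_jitter[g] * 10 ** (attempt + 1)
    return L, used


def _exact_loglik(X, phi, tau, psi, omega, cfg: KernelConfig, want_grad=False, gene_label=None):
    """Stacked GP marginal log-likelihoods (and gradients) for all genes.

    Returns ``(ll, grads)`` with ``ll`` shape (G,); ``grads`` is ``None`` or a
    tuple ``(dtau, dlogpsi, dlogomega)`` where ``dtau`` is summed over genes.
    """
    G, C = X.shape
    if want_grad:
        K, D = _correlation_and_grad(tau, tau, cfg)
    else:
        K = correlation_matrix(tau, tau, cfg)
        D = None
    jit = np.array([cfg.effective_jitter(psi[g], omega[g]) for g in range(G)])
    sig = psi[:, None, None] * K[None, :, :]
    idx = np.arange(C)
    sig[:, idx, idx] = (psi + omega + jit)[:, None]
    L, jit_used = _batched_cholesky(sig, jit, gene_label)
    Y = X - phi[:, None]
    z = np.linalg.solve(L, Y[:, :, None])[:, :, 0]
    logdet = 2.0 * np.sum(np.log(np.einsum("gii->gi", L)), axis=1)
    quad = np.sum(z * z, axis=1)
    ll = -0.5 * (C * _LOG2PI + logdet + quad)
    if not want_grad:
        return ll, None
    # E_g = alpha alpha^T - Sigma^{-1}; dL/dtheta = 0.5 tr(E dSigma/dtheta)
    Linv = np.linalg.solve(L, np.broadcast_to(np.eye(C), (G, C, C)).copy())
    Sinv = np.einsum("gki,gkj->gij", Linv, Linv)
    alpha = np.einsum("gij,gj->gi", Sinv, Y)
    E = np.einsum("gi,gj->gij", alpha, alpha) - Sinv
    trE = np.einsum("gii->g", E)
    # relative-jitter coupling: with jitter = rel*(psi+omega) the diagonal
    # moves with psi and omega; absolute jitter contributes nothing
    jrel = jit_used / (psi + omega) if cfg.jitter is None else np.zeros(G)
    # K has unit diagonal, so dSigma/dpsi = K plus the jitter coupling on the
    # diagonal (jitter = jrel*(psi+omega))
    trEK = np.einsum("gij,ij->g", E, K)
    dlogpsi = 0.5 * psi * (trEK + jrel * trE)
    dlogomega = 0.5 * omega * (1.0 + jrel) * trE
    dtau = np.einsum("g,gij,ij->i", psi, E, D)
    return ll, (dtau, dlogpsi, dlogomega)


def gene_marginal_loglik(x_g, tau, params: GeneParams, cfg: KernelConfig) -> float:
    """Exact GP marginal ``log N(x_g; phi_g 1, psi_g K(tau) + omega_g I)``."""
    x_g = np.asarray(x_g, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if x_g.shape != tau.shape:
        raise ValueError("expression vector and pseudotimes must have equal length")
    ll, _ = _exact_loglik(
        x_g[None, :],
        np.array([params.phi]),
        tau,
        np.array([max(params.psi, 0.0)]),
        np.array([params.omega]),
        cfg,
    )
    return float(ll[0])


# ---------------------------------------------------------------------------
# Sparse (deterministic training conditional) marginal likelihood
# ---------------------------------------------------------------------------

_INDUCING_JITTER = 1e-12  # in correlation units; scales with psi in covariance units


def _sparse_shared(tau, u, cfg: KernelConfig, want_grad: bool):
    """Gene-independent pieces of the sparse likelihood (all O(C M^2))."""
    M = u.size
    if want_grad:
        Cfu, Dfu = _correlation_and_grad(tau, u, cfg)
    else:
        Cfu = correlation_matrix(tau, u, cfg)
        Dfu = None
    Cuu_base = correlation_matrix(u, u, cfg)
    ju = _INDUCING_JITTER
    for attempt in range(4):
        Cuu = Cuu_base + ju * np.eye(M)
        try:
            Luu = np.linalg.cholesky(Cuu)
            break
        except np.linalg.LinAlgError:
            if attempt == 3:
                raise np.linalg.LinAlgError(
                    "inducing-point correlation matrix is rank deficient; "
                    "choose fewer or better-separated inducing points"
                ) from None
            ju *= 100.0
    logdet_cuu = 2.0 * np.sum(np.log(np.diag(Luu)))
    A = np.linalg.solve(Cuu, Cfu.T)  # (M, C)
    W = Cfu.T @ Cfu  # (M, M)
    H = A @ Cfu  # (M, M) = Cuu^{-1} W
    return Cfu, Dfu, Cuu, logdet_cuu, A, W, H


def _sparse_loglik(X, phi, tau, psi, omega, cfg: KernelConfig, u, want_grad=False):
    """Sparse marginal log-likelihoods (and gradients), never forming C x C."""
    G, C = X.shape
    u = np.asarray(u, dtype=float)
    Cfu, Dfu, Cuu, logdet_cuu, A, W, H = _sparse_shared(tau, u, cfg, want_grad)
    M = u.size
    jit = np.array([cfg.effective_jitter(psi[g], omega[g]) for g in range(G)])
    beta = omega + jit
    rho = psi / beta
    B = Cuu[None, :, :] + rho[:, None, None] * W[None, :, :]
    LB = np.linalg.cholesky(B)
    logdet_B = 2.0 * np.sum(np.log(np.einsum("gii->gi", LB)), axis=1)
    Y = X - phi[:, None]
    Cy = Y @ Cfu  # (G, M)
    Binv_cy = np.linalg.solve(B, Cy[:, :, None])[:, :, 0]
    quad = np.sum(Y * Y, axis=1) / beta - (psi / beta**2) * np.sum(Cy * Binv_cy, axis=1)
    logdet = C * np.log(beta) + logdet_B - logdet_cuu
    ll = -0.5 * (C * _LOG2PI + logdet + quad)
    if not want_grad:
        return ll, None
    # alpha = Sigma^{-1} y via Woodbury; Mt = (psi/beta^2) B^{-1} so that
    # Sigma^{-1} = I/beta - Cfu Mt Cuf
    alpha = Y / beta[:, None] - (psi / beta**2)[:, None] * (Binv_cy @ Cfu.T)
    Binv = np.linalg.solve(B, np.broadcast_to(np.eye(M), (G, M, M)).copy())
    Mt = (psi / beta**2)[:, None, None] * Binv
    trMtW = np.einsum("gij,ji->g", Mt, W)
    tr_sinv = C / beta - trMtW
    trE = np.sum(alpha * alpha, axis=1) - tr_sinv
    jrel = jit / (psi + omega) if cfg.jitter is None else np.zeros(G)
    # d/dlogpsi: Q = psi Cfu A is linear in psi
    ca = alpha @ Cfu  # (G, M) = Cuf alpha
    v = np.linalg.solve(Cuu, ca.T).T  # A alpha = Cuu^{-1} Cuf alpha  (G, M)
    aQa = np.sum(ca * v, axis=1)
    trSinvQ = np.trace(H) / beta - np.einsum("gij,jk,ki->g", Mt, W, H)
    dlogpsi = 0.5 * psi * (aQa - trSinvQ) + 0.5 * jrel * psi * trE
    dlogomega = 0.5 * omega * (1.0 + jrel) * trE
    # d/dtau_i = psi [ alpha_i (Dfu_i . v) - beta^{-1} Dfu_i . A_:i
    #                  + Dfu_i . (H Mt Cfu_i) ]
    term1 = alpha * np.einsum("im,gm->gi", Dfu, v)
    diagDA = np.einsum("im,mi->i", Dfu, A)
    HMt = np.einsum("ij,gjk->gik", H, Mt)
    term3 = np.einsum("im,gmn,in->gi", Dfu, HMt, Cfu)
    dtau = np.einsum("g,gi->i", psi, term1 + term3) - np.sum(psi / beta) * diagDA
    return ll, (dtau, dlogpsi, dlogomega)


def sparse_gene_marginal_loglik(x_g, tau, params: GeneParams, cfg: KernelConfig, inducing) -> float:
    """Low-rank approximation to :func:`gene_marginal_loglik` through the
    inducing pseudotimes ``inducing``; exact when ``inducing == tau``."""
    x_g = np.asarray(x_g, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if x_g.shape != tau.shape:
        raise ValueError("expression vector and pseudotimes must have equal length")
    ll, _ = _sparse_loglik(
        x_g[None, :],
        np.array([params.phi]),
        tau,
        np.array([max(params.psi, 0.0)]),
        np.array([params.omega]),
        cfg,
        np.asarray(inducing, dtype=float),
    )
    return float(ll[0])


def choose_inducing_points(meta: CellMetadata, hyper: Hyperparameters) -> np.ndarray:
    """Evenly spaced inducing pseudotimes covering the capture-time range
    widened by three prior standard deviations on each side."""
    if hyper.n_inducing is None or hyper.n_inducing < 2:
        raise ValueError("n_inducing must be set and >= 2")
    levels = meta.capture_levels
    lo = levels[0] - 3.0 * hyper.sigma_tau
    hi = levels[-1] + 3.0 * hyper.sigma_tau
    return np.linspace(lo, hi, hyper.n_inducing)


# ---------------------------------------------------------------------------
# Priors and the joint
# ---------------------------------------------------------------------------


def log_prior(state: ModelState, meta: CellMetadata, hyper: Hyperparameters) -> float:
    """Capture-time-anchored normal prior on pseudotimes plus log-normal
    priors on the per-gene variances."""
    if state.tau.size != len(meta.cell_ids):
        raise ValueError("state and metadata disagree on the number of cells")
    lp = np.sum(stats.norm.logpdf(state.tau, loc=meta.capture_time, scale=hyper.sigma_tau))
    lp += np.sum(stats.lognorm.logpdf(state.psi, s=hyper.sigma_psi, scale=np.exp(hyper.mu_psi)))
    lp += np.sum(
        stats.lognorm.logpdf(state.omega, s=hyper.sigma_omega, scale=np.exp(hyper.mu_omega))
    )
    return float(lp)


def _likelihood(state: ModelState, x: ExpressionMatrix, meta: CellMetadata,
                hyper: Hyperparameters, phi=None, want_grad=False):
    cfg = hyper.kernel_config()
    if phi is None:
        phi = x.values.mean(axis=1)
    label = lambda g: x.gene_ids[g]  # noqa: E731
    if hyper.n_inducing is not None:
        u = choose_inducing_points(meta, hyper)
        return _sparse_loglik(x.values, phi, state.tau, state.psi, state.omega,
                              cfg, u, want_grad)
    return _exact_loglik(x.values, phi, state.tau, state.psi, state.omega,
                         cfg, want_grad, gene_label=label)


def log_joint(state: ModelState, x: ExpressionMatrix, meta: CellMetadata,
              hyper: Hyperparameters, likelihood_weight: float = 1.0) -> float:
    """Log prior plus (optionally down-weighted) summed gene marginals.

    ``phi_g`` is fixed at each gene's mean expression.  The likelihood
    weight exists for prior-only runs in calibration tests.
    """
    if x.n_cells != state.tau.size or x.n_genes != state.psi.size:
        raise ValueError("dimensions of state and expression matrix disagree")
    lp = log_prior(state, meta, hyper)
    if likelihood_weight != 0.0:
        ll, _ = _likelihood(state, x, meta, hyper)
        lp += likelihood_weight * float(np.sum(ll))
    return lp


def make_log_density(x: ExpressionMatrix, meta: CellMetadata, hyper: Hyperparameters,
                     likelihood_weight: float = 1.0):
    """Build the unconstrained target ``theta -> (logp, grad)`` for samplers.

    ``theta`` packs ``[tau (C), log psi (G), log omega (G)]``.  On this scale
    the log-normal priors are normal, and the Jacobian of the log transform
    is absorbed into the density, so the returned value is the correct
    (unnormalized) posterior log-density for HMC/VI.  The constrained log
    joint of a draw is ``logp - sum(log psi) - sum(log omega)``.
    """
    meta = meta.reindex(x.cell_ids)
    C, G = x.n_cells, x.n_genes
    k = meta.capture_time
    phi = x.values.mean(axis=1)
    cfg = hyper.kernel_config()
    u = choose_inducing_points(meta, hyper) if hyper.n_inducing is not None else None

    def logp_and_grad(theta: np.ndarray):
        tau = theta[:C]
        lpsi = theta[C:C + G]
        lomega = theta[C + G:]
        psi = np.exp(np.clip(lpsi, -300, 300))
        omega = np.exp(np.clip(lomega, -300, 300))
        grad = np.empty_like(theta)
        # normal priors on tau and on the log-variances
        lp = -0.5 * np.sum((tau - k) ** 2) / hyper.sigma_tau**2 \
            - C * np.log(hyper.sigma_tau) - 0.5 * C * _LOG2PI
        lp += -0.5 * np.sum((lpsi - hyper.mu_psi) ** 2) / hyper.sigma_psi**2 \
            - G * np.log(hyper.sigma_psi) - 0.5 * G * _LOG2PI
        lp += -0.5 * np.sum((lomega - hyper.mu_omega) ** 2) / hyper.sigma_omega**2 \
            - G * np.log(hyper.sigma_omega) - 0.5 * G * _LOG2PI
        grad[:C] = -(tau - k) / hyper.sigma_tau**2
        grad[C:C + G] = -(lpsi - hyper.mu_psi) / hyper.sigma_psi**2
        grad[C + G:] = -(lomega - hyper.mu_omega) / hyper.sigma_omega**2
        if likelihood_weight != 0.0:
            if u is not None:
                ll, (dtau, dlp, dlo) = _sparse_loglik(
                    x.values, phi, tau, psi, omega, cfg, u, want_grad=True)
            else:
                ll, (dtau, dlp, dlo) = _exact_loglik(
                    x.values, phi, tau, psi, omega, cfg, want_grad=True)
            w = likelihood_weight
            lp += w * float(np.sum(ll))
            grad[:C] += w * dtau
            grad[C:C + G] += w * dlp
            grad[C + G:] += w * dlo
        return lp, grad

    return logp_and_grad, phi
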