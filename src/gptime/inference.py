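"""Model fitting: empirical Bayes, chain initialization, NUTS / ADVI drivers,
convergence diagnostics and point-estimate selection.

The posterior over pseudotime orderings is typically multimodal (cells must
pass each other in pseudotime to reorder), so chains are started from
order-diverse heuristics and the draw with the highest log joint serves as
the default point estimate alongside the full draws and split-R-hat
diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._engine import advi_fit, nuts_sample
from .io import CellMetadata, ExpressionMatrix
from .model import Hyperparameters, ModelState, make_log_density

__all__ = [
    "FitResult",
    "PosteriorSample",
    "VARIANCE_FLOOR",
    "empirical_bayes_hyperparams",
    "initialize_states",
    "fit_mcmc",
    "fit_vi",
    "rhat",
    "best_sample",
]

logger = logging.getLogger(__name__)

#: floor for empirical-Bayes per-gene variance estimates (log-expression scale)
VARIANCE_FLOOR = 1e-6


@dataclass
class PosteriorSample:
    """A single posterior draw: pseudotimes, gene variances, log joint."""

    tau: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    phi: np.ndarray
    log_joint: float
    chain: int = 0
    draw: int = 0


@dataclass
class FitResult:
    """Posterior draws from MCMC chains or a variational approximation.

    Arrays are indexed ``(chain, draw, ...)``; VI output uses one "chain".
    ``log_joint`` is the constrained-scale log joint of each draw (the
    quantity maximized by :func:`best_sample`).
    """

    tau: np.ndarray  # (n_chains, n_draws, C)
    log_psi: np.ndarray  # (n_chains, n_draws, G)
    log_omega: np.ndarray  # (n_chains, n_draws, G)
    log_joint: np.ndarray  # (n_chains, n_draws)
    phi: np.ndarray  # (G,)
    method: str = "nuts"
    seed: int = 0
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    hyper: Hyperparameters | None = None
    capture_time: np.ndarray | None = None
    divergences: np.ndarray | None = None
    warnings_: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.tau.shape[0]

    @property
    def n_draws(self) -> int:
        return self.tau.shape[1]

    def sample(self, chain: int, draw: int) -> PosteriorSample:
        return PosteriorSample(
            tau=self.tau[chain, draw].copy(),
            psi=np.exp(self.log_psi[chain, draw]),
            omega=np.exp(self.log_omega[chain, draw]),
            phi=self.phi.copy(),
            log_joint=float(self.log_joint[chain, draw]),
            chain=chain,
            draw=draw,
        )

    def posterior_mean_tau(self) -> np.ndarray:
        return self.tau.reshape(-1, self.tau.shape[-1]).mean(axis=0)

    def to_dict(self) -> dict:
        hyper = None
        if self.hyper is not None:
            hyper = {
                "mu_psi": self.hyper.mu_psi,
                "sigma_psi": self.hyper.sigma_psi,
                "mu_omega": self.hyper.mu_omega,
                "sigma_omega": self.hyper.sigma_omega,
                "length_scale": self.hyper.length_scale,
                "sigma_tau": self.hyper.sigma_tau,
                "period": self.hyper.period,
                "n_inducing": self.hyper.n_inducing,
            }
        return {
            "tau": self.tau,
            "log_psi": self.log_psi,
            "log_omega": self.log_omega,
            "log_joint": self.log_joint,
            "phi": self.phi,
            "method": self.method,
            "seed": self.seed,
            "gene_ids": list(self.gene_ids),
            "cell_ids": list(self.cell_ids),
            "hyper": hyper,
            "capture_time": self.capture_time,
            "divergences": self.divergences,
            "warnings_": list(self.warnings_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        hyper = d.get("hyper")
        if hyper is not None:
            hyper = Hyperparameters(**hyper)
        div = d.get("divergences")
        cap = d.get("capture_time")
        return cls(
            tau=np.asarray(d["tau"], dtype=float),
            log_psi=np.asarray(d["log_psi"], dtype=float),
            log_omega=np.asarray(d["log_omega"], dtype=float),
            log_joint=np.asarray(d["log_joint"], dtype=float),
            phi=np.asarray(d["phi"], dtype=float),
            method=d.get("method", "nuts"),
            seed=int(d.get("seed", 0)),
            gene_ids=list(d.get("gene_ids", [])),
            cell_ids=list(d.get("cell_ids", [])),
            hyper=hyper,
            capture_time=None if cap is None else np.asarray(cap, dtype=float),
            divergences=None if div is None else np.asarray(div),
            warnings_=list(d.get("warnings_", [])),
        )


# ---------------------------------------------------------------------------
# Empirical Bayes
# ---------------------------------------------------------------------------


def empirical_bayes_hyperparams(
    x: ExpressionMatrix,
    meta: CellMetadata,
    length_scale: float | None = None,
    sigma_tau: float | None = None,
    **extra,
) -> Hyperparameters:
    """Estimate the log-normal prior hyperparameters from the data.

    Per gene, the mean within-capture-time variance estimates the noise
    ``omega_g`` and the variance of the capture-time group means estimates
    the temporal amplitude ``psi_g``; the log-normal priors are then moment-
    matched to the per-gene estimates.  ``length_scale`` and ``sigma_tau``
    are user choices and must be supplied (here or afterwards).
    """
    meta = meta.reindex(x.cell_ids)
    levels = meta.capture_levels
    if levels.size < 2:
        raise ValueError(
            "empirical Bayes needs at least two capture times; supply "
            "hyperparameters manually for single-time data"
        )
    groups = [np.flatnonzero(meta.capture_time == lev) for lev in levels]
    small = [lev for lev, g in zip(levels, groups) if g.size < 2]
    if small:
        raise ValueError(
            f"capture times {small} have fewer than 2 cells; within-group "
            "variances are undefined"
        )
    within = np.stack([x.values[:, g].var(axis=1, ddof=1) for g in groups], axis=1)
    omega_hat = within.mean(axis=1)
    group_means = np.stack([x.values[:, g].mean(axis=1) for g in groups], axis=1)
    psi_hat = group_means.var(axis=1, ddof=1)
    floored = (omega_hat < VARIANCE_FLOOR) | (psi_hat < VARIANCE_FLOOR)
    if np.any(floored):
        for g in np.flatnonzero(floored):
            logger.warning(
                "gene %s has a near-zero variance estimate; flooring at %g",
                x.gene_ids[g], VARIANCE_FLOOR,
            )
    omega_hat = np.maximum(omega_hat, VARIANCE_FLOOR)
    psi_hat = np.maximum(psi_hat, VARIANCE_FLOOR)
    log_psi = np.log(psi_hat)
    log_omega = np.log(omega_hat)
    if length_scale is None:
        length_scale = float(levels[-1] - levels[0]) / 2.0 or 1.0
    if sigma_tau is None:
        sigma_tau = float(np.min(np.diff(levels))) / 2.0
    return Hyperparameters(
        mu_psi=float(log_psi.mean()),
        sigma_psi=float(max(log_psi.std(ddof=1), 0.1)) if x.n_genes > 1 else 1.0,
        mu_omega=float(log_omega.mean()),
        sigma_omega=float(max(log_omega.std(ddof=1), 0.1)) if x.n_genes > 1 else 1.0,
        length_scale=float(length_scale),
        sigma_tau=float(sigma_tau),
        **extra,
    )


# ---------------------------------------------------------------------------
# Initialization heuristics
# ---------------------------------------------------------------------------


def initialize_states(
    x: ExpressionMatrix,
    meta: CellMetadata,
    hyper: Hyperparameters,
    n_chains: int,
    seed: int,
    jitter: float = 1.0,
) -> list[ModelState]:
    """Order-diverse chain starting points.

    Chain 1 starts every pseudotime at its capture time (plus a small
    jittered perturbation).  Later chains order cells within each capture
    time by their projection on the leading principal axis of the expression
    matrix (sign-aligned with capture time, alternating direction between
    chains so that reflected orderings are also covered) and spread them
    evenly across ``[k_c - sigma_tau, k_c + sigma_tau]``.  Gene variances
    start at their prior medians.  Deterministic given the seed.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    meta = meta.reindex(x.cell_ids)
    rng = np.random.default_rng(seed)
    C = x.n_cells
    G = x.n_genes
    k = meta.capture_time
    psi0 = np.full(G, np.exp(hyper.mu_psi))
    omega0 = np.full(G, np.exp(hyper.mu_omega))

    # leading principal axis of cells in gene space, aligned with capture time
    centered = (x.values - x.values.mean(axis=1, keepdims=True)).T  # (C, G)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    corr = np.corrcoef(proj, k)[0, 1] if np.std(proj) > 0 else 0.0
    if corr < 0:
        proj = -proj

    states = []
    for chain in range(n_chains):
        if chain == 0:
            tau = k + jitter * rng.normal(0.0, hyper.sigma_tau / 4.0, size=C)
        else:
            tau = np.empty(C)
            p = proj if chain % 2 == 1 else -proj
            for lev in meta.capture_levels:
                idx = np.flatnonzero(k == lev)
                order = idx[np.argsort(p[idx])]
                if idx.size == 1:
                    spread = np.array([lev])
                else:
                    spread = np.linspace(lev - hyper.sigma_tau, lev + hyper.sigma_tau,
                                         idx.size)
                tau[order] = spread
            tau = tau + jitter * rng.normal(0.0, hyper.sigma_tau / 10.0, size=C)
        states.append(ModelState(tau=tau, psi=psi0.copy(), omega=omega0.copy()))
    return states


# ---------------------------------------------------------------------------
# Fit drivers
# ---------------------------------------------------------------------------


def _pack(state: ModelState) -> np.ndarray:
    return np.concatenate([state.tau, np.log(state.psi), np.log(state.omega)])


def fit_mcmc(
    x: ExpressionMatrix,
    meta: CellMetadata,
    hyper: Hyperparameters,
    n_chains: int = 2,
    n_iter: int = 500,
    warmup: int | None = None,
    seed: int = 0,
    likelihood_weight: float = 1.0,
    max_treedepth: int = 8,
) -> FitResult:
    """Sample the posterior with the No-U-Turn sampler.

    Returns ``n_iter`` post-warmup draws per chain; warmup defaults to
    ``n_iter``.  A warning is recorded when more than 25% of a chain's
    draws diverge.
    """
    meta = meta.reindex(x.cell_ids)
    if warmup is None:
        warmup = n_iter
    logp_and_grad, phi = make_log_density(x, meta, hyper, likelihood_weight)
    states = initialize_states(x, meta, hyper, n_chains, seed)
    C, G = x.n_cells, x.n_genes
    tau = np.empty((n_chains, n_iter, C))
    log_psi = np.empty((n_chains, n_iter, G))
    log_omega = np.empty((n_chains, n_iter, G))
    log_joint = np.empty((n_chains, n_iter))
    divergences = np.zeros(n_chains, dtype=int)
    warn_list: list[str] = []
    for chain, state in enumerate(states):
        res = nuts_sample(
            logp_and_grad,
            _pack(state),
            n_warmup=warmup,
            n_draws=n_iter,
            seed=seed + 1000 * (chain + 1),
            max_treedepth=max_treedepth,
        )
        tau[chain] = res.draws[:, :C]
        log_psi[chain] = res.draws[:, C:C + G]
        log_omega[chain] = res.draws[:, C + G:]
        # constrained-scale log joint: subtract the log-transform Jacobian
        log_joint[chain] = res.logps - res.draws[:, C:].sum(axis=1)
        divergences[chain] = res.n_divergent
        if res.n_divergent > 0.25 * n_iter:
            msg = (f"chain {chain}: {res.n_divergent}/{n_iter} divergent "
                   "transitions; results may be unreliable")
            warn_list.append(msg)
            warnings.warn(msg)
    return FitResult(
        tau=tau, log_psi=log_psi, log_omega=log_omega, log_joint=log_joint,
        phi=phi, method="nuts", seed=seed, gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids), hyper=hyper,
        capture_time=meta.capture_time.copy(), divergences=divergences,
        warnings_=warn_list,
    )


def fit_vi(
    x: ExpressionMatrix,
    meta: CellMetadata,
    hyper: Hyperparameters,
    n_draws: int = 500,
    seed: int = 0,
    likelihood_weight: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 4000,
    init_chain: int = 1,
) -> FitResult:
    """Mean-field Gaussian variational fit (ADVI) on the unconstrained scale.

    The approximation is optimized to convergence of a smoothed ELBO, then
    ``n_draws`` samples are drawn from it and returned in the same form as
    MCMC draws (a single "chain").  ``init_chain`` selects which
    initialization heuristic seeds the optimization (0 = capture times,
    1 = principal-axis ordering).
    """
    meta = meta.reindex(x.cell_ids)
    logp_and_grad, phi = make_log_density(x, meta, hyper, likelihood_weight)
    states = initialize_states(x, meta, hyper, max(init_chain + 1, 1), seed)
    theta0 = _pack(states[min(init_chain, len(states) - 1)])
    res = advi_fit(logp_and_grad, theta0, seed=seed, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed + 99991)
    D = theta0.size
    C, G = x.n_cells, x.n_genes
    sd = np.exp(res.log_sd)
    draws = res.mean[None, :] + sd[None, :] * rng.standard_normal((n_draws, D))
    logps = np.array([logp_and_grad(d)[0] for d in draws])
    log_joint = logps - draws[:, C:].sum(axis=1)
    warn_list = [] if res.converged else [
        f"ADVI stopped at max_iter={max_iter} before meeting tol={tol}"]
    return FitResult(
        tau=draws[None, :, :C], log_psi=draws[None, :, C:C + G],
        log_omega=draws[None, :, C + G:], log_joint=log_joint[None, :],
        phi=phi, method="vi", seed=seed, gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids), hyper=hyper,
        capture_time=meta.capture_time.copy(), divergences=None,
        warnings_=warn_list,
    )


# ---------------------------------------------------------------------------
# Diagnostics and point estimates
# ---------------------------------------------------------------------------


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter from draws shaped (chain, draw)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    B = n * chain_means.var(ddof=1)
    W = chain_vars.mean()
    var_plus = (n - 1) / n * W + B / n
    if W <= 0:
        return np.inf if B > 0 else 1.0
    return float(np.sqrt(var_plus / W))


def rhat(fit: FitResult) -> dict[str, np.ndarray]:
    """Split-R-hat for every scalar parameter (each tau_c, log psi_g,
    log omega_g).  Requires at least two chains and four draws."""
    if fit.n_chains < 2:
        raise ValueError("R-hat needs >= 2 chains; run more chains")
    if fit.n_draws < 4:
        raise ValueError("R-hat needs >= 4 draws per chain")
    out = {}
    for name, arr in (("tau", fit.tau), ("log_psi", fit.log_psi),
                      ("log_omega", fit.log_omega)):
        out[name] = np.array([_split_rhat(arr[:, :, j]) for j in range(arr.shape[2])])
    return out


def best_sample(fit: FitResult) -> PosteriorSample:
    """The draw with the highest log joint (first occurrence on ties)."""
    if fit.log_joint.size == 0:
        raise ValueError("empty fit")
    flat = int(np.argmax(fit.log_joint))
    chain, draw = np.unravel_index(flat, fit.log_joint.shape)
    return fit.sample(int(chain), int(draw))
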