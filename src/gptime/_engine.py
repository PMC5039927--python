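"""Gradient-based samplers: a No-U-Turn HMC sampler and mean-field ADVI.

Both operate on an unconstrained parameter vector through a single callable
``logp_and_grad(theta) -> (float, ndarray)``.  The NUTS implementation
follows the efficient slice-sampling formulation with dual-averaging step
size adaptation and a single diagonal mass-matrix adaptation window during
warmup.  ADVI optimizes a fully factorized Gaussian with reparameterized
stochastic gradients and Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts_sample", "NutsResult", "advi_fit", "AdviResult"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, D)
    logps: np.ndarray  # (n_draws,)
    n_divergent: int
    step_size: float
    mass_diag: np.ndarray
    accept_rate: float


def _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    lp, grad = logp_and_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


def _kinetic(r, inv_mass):
    return 0.5 * np.sum(r * r * inv_mass)


def _find_reasonable_epsilon(logp_and_grad, theta, rng, inv_mass):
    eps = 1.0
    lp, grad = logp_and_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(r, inv_mass)
    t1, r1, lp1, _ = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        t1, r1, lp1, _ = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """Recursive NUTS tree builder (Hoffman & Gelman, efficient variant)."""

    def __init__(self, logp_and_grad, rng, inv_mass, eps, log_u, h0):
        self.f = logp_and_grad
        self.rng = rng
        self.inv_mass = inv_mass
        self.eps = eps
        self.log_u = log_u
        self.h0 = h0
        self.divergent = False
        self.sum_accept = 0.0
        self.n_accept = 0

    def build(self, theta, r, grad, direction, depth):
        if depth == 0:
            t1, r1, lp1, g1 = _leapfrog(self.f, theta, r, grad, direction * self.eps,
                                        self.inv_mass)
            h1 = lp1 - _kinetic(r1, self.inv_mass) if np.isfinite(lp1) else -np.inf
            n_valid = 1 if self.log_u <= h1 else 0
            stop = (h1 - self.log_u) < -_MAX_ENERGY_ERROR
            if stop:
                self.divergent = True
            self.sum_accept += min(1.0, np.exp(min(0.0, h1 - self.h0)))
            self.n_accept += 1
            return t1, r1, g1, t1, r1, g1, t1, lp1, g1, n_valid, stop
        # build left and right subtrees
        (tm, rm, gm, tp, rp, gp, tprop, lpprop, gprop, n1, stop) = self.build(
            theta, r, grad, direction, depth - 1)
        if not stop:
            if direction == -1:
                (tm, rm, gm, _, _, _, tprop2, lpprop2, gprop2, n2, stop2) = self.build(
                    tm, rm, gm, direction, depth - 1)
            else:
                (_, _, _, tp, rp, gp, tprop2, lpprop2, gprop2, n2, stop2) = self.build(
                    tp, rp, gp, direction, depth - 1)
            if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
                tprop, lpprop, gprop = tprop2, lpprop2, gprop2
            span = tp - tm
            stop = stop2 or (np.dot(span, self.inv_mass * rm) < 0) or (
                np.dot(span, self.inv_mass * rp) < 0)
            n1 += n2
        return tm, rm, gm, tp, rp, gp, tprop, lpprop, gprop, n1, stop


def nuts_sample(logp_and_grad, theta0, n_warmup, n_draws, seed,
                target_accept=0.8, max_treedepth=8) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws.

    Step size is tuned by dual averaging toward ``target_accept``; a diagonal
    mass matrix is estimated once from the middle half of warmup.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, dtype=float).copy()
    D = theta.size
    inv_mass = np.ones(D)
    lp, grad = logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial state")

    eps = _find_reasonable_epsilon(logp_and_grad, theta, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    mass_lo, mass_hi = n_warmup // 4, max(n_warmup // 4 + 2, (3 * n_warmup) // 4)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(D), np.zeros(D)

    draws = np.empty((n_draws, D))
    logps = np.empty(n_draws)
    n_divergent = 0
    accept_sum, accept_n = 0.0, 0

    for it in range(n_warmup + n_draws):
        r0 = rng.standard_normal(D) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(r0, inv_mass)
        log_u = h0 + np.log(rng.uniform())
        tree = _Tree(logp_and_grad, rng, inv_mass, eps, log_u, h0)
        tm, rm, gm = theta, r0, grad
        tp, rp, gp = theta, r0, grad
        n_valid, depth, stop = 1, 0, False
        while not stop and depth < max_treedepth:
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                (tm, rm, gm, _, _, _, tprop, lpprop, gprop, n2, stop2) = tree.build(
                    tm, rm, gm, direction, depth)
            else:
                (_, _, _, tp, rp, gp, tprop, lpprop, gprop, n2, stop2) = tree.build(
                    tp, rp, gp, direction, depth)
            if not stop2 and n_valid + n2 > 0 and rng.uniform() < n2 / n_valid:
                theta, lp, grad = tprop, lpprop, gprop
            n_valid += n2
            span = tp - tm
            stop = stop2 or (np.dot(span, inv_mass * rm) < 0) or (
                np.dot(span, inv_mass * rp) < 0)
            depth += 1

        accept_stat = tree.sum_accept / max(tree.n_accept, 1)
        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if mass_lo <= it < mass_hi:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if it == mass_hi - 1 and welford_n >= 5:
                var = welford_m2 / (welford_n - 1)
                inv_mass = var + 1e-6
                eps = _find_reasonable_epsilon(logp_and_grad, theta, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if tree.divergent:
                n_divergent += 1
            accept_sum += accept_stat
            accept_n += 1
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = lp

    return NutsResult(
        draws=draws,
        logps=logps,
        n_divergent=n_divergent,
        step_size=eps,
        mass_diag=1.0 / inv_mass,
        accept_rate=accept_sum / max(accept_n, 1),
    )


@dataclass
class AdviResult:
    mean: np.ndarray
    log_sd: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int


def advi_fit(logp_and_grad, theta0, seed, n_mc=2, max_iter=4000, learning_rate=0.05,
             tol=1e-4, check_every=25, window=8, init_log_sd=-2.0) -> AdviResult:
    """Fit a fully factorized Gaussian ``q(theta) = N(mu, diag(sd^2))``.

    Maximizes the ELBO with reparameterized gradients (``n_mc`` samples per
    step) and Adam.  Convergence is declared when the relative change of a
    smoothed ELBO over successive check windows falls below ``tol``; if the
    objective diverges the last trace is raised inside the error.
    """
    rng = np.random.default_rng(seed)
    D = np.asarray(theta0).size
    mu = np.asarray(theta0, dtype=float).copy()
    log_sd = np.full(D, float(init_log_sd))
    params = np.concatenate([mu, log_sd])
    m_adam = np.zeros(2 * D)
    v_adam = np.zeros(2 * D)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    elbos = []
    smoothed = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu, log_sd = params[:D], params[D:]
        sd = np.exp(np.clip(log_sd, -30, 30))
        g_mu = np.zeros(D)
        g_lsd = np.zeros(D)
        elbo = 0.0
        for _ in range(n_mc):
            epsilon = rng.standard_normal(D)
            theta = mu + sd * epsilon
            lp, grad = logp_and_grad(theta)
            elbo += lp / n_mc
            g_mu += grad / n_mc
            g_lsd += grad * sd * epsilon / n_mc
        entropy = np.sum(log_sd) + 0.5 * D * (1.0 + np.log(2 * np.pi))
        elbo += entropy
        g_lsd += 1.0  # d entropy / d log_sd
        g = np.concatenate([g_mu, g_lsd])
        if not np.all(np.isfinite(g)) or not np.isfinite(elbo):
            raise FloatingPointError(
                f"ADVI objective diverged at iteration {it}; "
                f"last ELBO values: {elbos[-5:]}"
            )
        elbos.append(elbo)
        m_adam = b1 * m_adam + (1 - b1) * g
        v_adam = b2 * v_adam + (1 - b2) * g * g
        mhat = m_adam / (1 - b1**it)
        vhat = v_adam / (1 - b2**it)
        params = params + learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
        if it % check_every == 0:
            smoothed.append(float(np.mean(elbos[-check_every:])))
            if len(smoothed) > window:
                prev = np.mean(smoothed[-2 * window:-window])
                curr = np.mean(smoothed[-window:])
                denom = max(abs(prev), 1.0)
                if abs(curr - prev) / denom < tol:
                    converged = True
                    break
    mu, log_sd = params[:D], params[D:]
    return AdviResult(mean=mu, log_sd=log_sd, elbo_trace=np.asarray(elbos),
                      converged=converged, n_iter=it)
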