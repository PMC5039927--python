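"""Covariance functions over pseudotime.

The temporal covariance shared by all genes is a Matern 3/2 kernel on the
(optionally period-folded) separation between two pseudotimes.  Each gene's
covariance is an affine combination of that shared correlation structure:

    Sigma_g(tau_i, tau_j) = psi_g * K(tau_i, tau_j) + omega_g * delta_{ij}

where ``psi_g`` is the gene's temporal-variance amplitude, ``omega_g`` its
observation-noise variance, and the Kronecker delta is on *cell index*: two
distinct cells at the same pseudotime share signal but not noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelConfig",
    "GeneParams",
    "scaled_distance",
    "matern32",
    "periodic_distance",
    "correlation_matrix",
    "gene_covariance",
    "cross_covariance",
]

_SQRT3 = np.sqrt(3.0)

#: relative jitter applied to covariance diagonals when no absolute jitter is set
DEFAULT_JITTER_REL = 1e-6


@dataclass(frozen=True)
class KernelConfig:
    """Shared kernel hyperparameters.

    Parameters
    ----------
    length_scale
        Matern 3/2 length-scale ``l`` in pseudotime units; shared across genes.
    period
        If set, the kernel is made periodic with this period by folding the
        pseudotime separation through a sine warp before scaling by ``l``.
    jitter
        Absolute diagonal jitter for Cholesky stability.  ``None`` (default)
        means a relative jitter of ``1e-6 * (psi + omega)`` per gene.
    """

    length_scale: float
    period: float | None = None
    jitter: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.length_scale) or self.length_scale <= 0:
            raise ValueError(f"length_scale must be positive, got {self.length_scale}")
        if self.period is not None and self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if self.jitter is not None and self.jitter < 0:
            raise ValueError(f"jitter must be nonnegative, got {self.jitter}")

    def effective_jitter(self, psi: float, omega: float) -> float:
        if self.jitter is not None:
            return self.jitter
        return DEFAULT_JITTER_REL * (psi + omega)


@dataclass(frozen=True)
class GeneParams:
    """Per-gene covariance parameters: amplitude ``psi``, noise ``omega``,
    constant profile mean ``phi``."""

    psi: float
    omega: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError(f"psi must be nonnegative, got {self.psi}")
        if self.omega < 0:
            raise ValueError(f"omega must be nonnegative, got {self.omega}")


def scaled_distance(tau1, tau2, length_scale: float):
    """``|tau1 - tau2| / l`` — the dimensionless separation fed to the Matern.

    Symmetric in its arguments and vectorized over array inputs.
    """
    if length_scale <= 0:
        raise ValueError(f"length_scale must be positive, got {length_scale}")
    return np.abs(np.asarray(tau1, dtype=float) - np.asarray(tau2, dtype=float)) / length_scale


def matern32(r):
    """Matern 3/2 correlation ``(1 + sqrt(3) r) exp(-sqrt(3) r)`` for ``r >= 0``.

    Equals 1 iff ``r == 0`` and decreases strictly to 0 as ``r`` grows.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("scaled distance r must be nonnegative")
    a = _SQRT3 * r
    return (1.0 + a) * np.exp(-a)


def _matern32_deriv(d, length_scale: float):
    """d/dd of matern32(d / l) at raw separation d >= 0."""
    r = np.asarray(d, dtype=float) / length_scale
    return -(3.0 * r / length_scale) * np.exp(-_SQRT3 * r)


def periodic_distance(r, period: float):
    """Sine-warped separation ``(period/2) * |sin(pi r / period)|``.

    Periodic in ``r`` with period ``period`` and zero at integer multiples of
    it, so a kernel evaluated on the warped separation is exactly periodic.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    r = np.asarray(r, dtype=float)
    return (period / 2.0) * np.abs(np.sin(np.pi * r / period))


def _periodic_distance_deriv(d, period: float):
    """d/dd of periodic_distance(d, period)."""
    d = np.asarray(d, dtype=float)
    s = np.sin(np.pi * d / period)
    return (np.pi / 2.0) * np.cos(np.pi * d / period) * np.sign(s)


def correlation_matrix(tau1, tau2, cfg: KernelConfig) -> np.ndarray:
    """Shared temporal correlation ``K(tau1_i, tau2_j)`` (unit diagonal when
    ``tau1 is tau2``): period-fold the raw separation if configured, scale by
    the length-scale, apply the Matern 3/2."""
    tau1 = np.atleast_1d(np.asarray(tau1, dtype=float))
    tau2 = np.atleast_1d(np.asarray(tau2, dtype=float))
    if not (np.all(np.isfinite(tau1)) and np.all(np.isfinite(tau2))):
        raise ValueError("pseudotimes must be finite")
    d = np.abs(tau1[:, None] - tau2[None, :])
    if cfg.period is not None:
        d = periodic_distance(d, cfg.period)
    return matern32(d / cfg.length_scale)


def _correlation_and_grad(tau1, tau2, cfg: KernelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and its elementwise derivative w.r.t. ``tau1_i``.

    Returns ``(K, D)`` with ``D[i, j] = d K(tau1_i, tau2_j) / d tau1_i``.
    """
    tau1 = np.atleast_1d(np.asarray(tau1, dtype=float))
    tau2 = np.atleast_1d(np.asarray(tau2, dtype=float))
    delta = tau1[:, None] - tau2[None, :]
    d = np.abs(delta)
    sgn = np.sign(delta)
    if cfg.period is not None:
        dfold = periodic_distance(d, cfg.period)
        chain = _periodic_distance_deriv(d, cfg.period) * sgn
        K = matern32(dfold / cfg.length_scale)
        D = _matern32_deriv(dfold, cfg.length_scale) * chain
    else:
        K = matern32(d / cfg.length_scale)
        D = _matern32_deriv(d, cfg.length_scale) * sgn
    return K, D


def gene_covariance(tau, params: GeneParams, cfg: KernelConfig) -> np.ndarray:
    """Per-gene covariance over cells at pseudotimes ``tau``.

    Off-diagonal entries are ``psi * K(tau_i, tau_j)`` even for numerically
    identical pseudotimes (noise attaches to cells, not locations); the
    diagonal is ``psi + omega + jitter``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if not np.all(np.isfinite(tau)):
        raise ValueError("pseudotimes must be finite")
    K = correlation_matrix(tau, tau, cfg)
    cov = params.psi * K
    jit = cfg.effective_jitter(params.psi, params.omega)
    idx = np.arange(tau.size)
    cov[idx, idx] = params.psi + params.omega + jit
    return cov


def cross_covariance(tau_star, tau, params: GeneParams, cfg: KernelConfig) -> np.ndarray:
    """Noise-free covariance ``psi * K(tau_star_i, tau_j)`` between prediction
    grid points and observed cells."""
    return params.psi * correlation_matrix(tau_star, tau, cfg)
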