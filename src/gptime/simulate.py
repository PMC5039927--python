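"""Synthetic datasets drawn from the model's own generative process.

Cells are assigned round-robin to ``T`` equally spaced capture times; true
pseudotimes are normal around the capture times; per-gene amplitudes and
noise variances are log-normal; profiles are GP draws over the true
pseudotimes (optionally periodic); observations add Gaussian (optionally
heavier-tailed) noise.  The stored truth is sufficient to recompute the
exact log joint at the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellMetadata, ExpressionMatrix
from .kernels import correlation_matrix
from .model import Hyperparameters

__all__ = ["SyntheticDataset", "simulate_dataset", "simulate_precocious", "heldout_split"]


@dataclass
class SyntheticDataset:
    """A simulated expression matrix plus the generating truth."""

    expression: ExpressionMatrix
    meta: CellMetadata
    tau: np.ndarray  # true pseudotimes (C,)
    psi: np.ndarray  # true amplitudes (G,)
    omega: np.ndarray  # true noise variances (G,)
    phi: np.ndarray  # true profile means (G,)
    config: dict = field(default_factory=dict)
    precocious: np.ndarray | None = None  # boolean mask over cells
    latent_grid: np.ndarray | None = None  # (Q,) grid of latent evaluations
    latent_values: np.ndarray | None = None  # (G, Q) noise-free profiles on grid
    phases: np.ndarray | None = None  # (G,) true peak phases (sinusoid profiles)

    def true_peak_times(self) -> np.ndarray:
        """Per-gene pseudotime of the noise-free profile maximum: the exact
        phase for sinusoid profiles, the grid argmax otherwise."""
        if self.phases is not None:
            return self.phases.copy()
        if self.latent_grid is None or self.latent_values is None:
            raise ValueError("dataset was simulated without a latent grid")
        return self.latent_grid[np.argmax(self.latent_values, axis=1)]

    def to_files(self, prefix: str) -> tuple[str, str, str]:
        """Write expression, metadata and truth tables next to ``prefix``."""
        import pandas as pd

        from .io import write_cell_meta, write_expression

        expr_path = f"{prefix}.expression.csv"
        meta_path = f"{prefix}.cells.csv"
        truth_path = f"{prefix}.truth.csv"
        write_expression(self.expression, expr_path)
        write_cell_meta(self.meta, meta_path)
        truth = pd.DataFrame({
            "cell": self.expression.cell_ids,
            "tau": self.tau,
            "precocious": (self.precocious if self.precocious is not None
                           else np.zeros(self.tau.size, dtype=bool)),
        })
        truth.to_csv(truth_path, index=False, float_format="%.17g")
        return expr_path, meta_path, truth_path


def _simulate(n_genes, n_cells, n_times, capture_spacing, hyper, rng,
              tau_override=None, noise_df=None, latent_grid=None,
              profile="gp", phases=None):
    if n_cells < n_times:
        raise ValueError("need at least one cell per capture time")
    levels = capture_spacing * np.arange(1, n_times + 1, dtype=float)
    k = levels[np.arange(n_cells) % n_times]
    tau = rng.normal(k, hyper.sigma_tau) if hyper.sigma_tau > 0 else k.copy()
    if tau_override is not None:
        mask, values = tau_override
        tau = tau.copy()
        tau[mask] = values
    psi = np.exp(rng.normal(hyper.mu_psi, hyper.sigma_psi, size=n_genes))
    omega = np.exp(rng.normal(hyper.mu_omega, hyper.sigma_omega, size=n_genes))
    phi = rng.normal(0.0, 1.0, size=n_genes)
    cfg = hyper.kernel_config()
    points = tau if latent_grid is None else np.concatenate([tau, latent_grid])
    if profile == "gp":
        K = correlation_matrix(points, points, cfg)
        K[np.diag_indices_from(K)] += 1e-9
        L = np.linalg.cholesky(K)
        latent = phi[:, None] + np.sqrt(psi)[:, None] * (
            rng.standard_normal((n_genes, points.size)) @ L.T)
    elif profile == "sinusoid":
        # single-peaked periodic profiles with explicit phases; the amplitude
        # sqrt(2 psi) makes the temporal variance over a period equal psi
        if hyper.period is None:
            raise ValueError("sinusoid profiles require a period")
        if phases is None:
            phases = rng.uniform(0.0, hyper.period, size=n_genes)
        phases = np.asarray(phases, dtype=float)
        amp = np.sqrt(2.0 * psi)
        latent = phi[:, None] + amp[:, None] * np.cos(
            2.0 * np.pi * (points[None, :] - phases[:, None]) / hyper.period)
    else:
        raise ValueError(f"unknown profile kind {profile!r}")
    y = latent[:, :n_cells]
    if noise_df is None:
        noise = rng.standard_normal((n_genes, n_cells))
    else:
        noise = rng.standard_t(noise_df, size=(n_genes, n_cells))
    x = y + np.sqrt(omega)[:, None] * noise
    expr = ExpressionMatrix(
        [f"G{g + 1}" for g in range(n_genes)],
        [f"C{c + 1}" for c in range(n_cells)],
        x,
    )
    meta = CellMetadata(list(expr.cell_ids), k)
    latent_values = None if latent_grid is None else latent[:, n_cells:]
    return expr, meta, tau, psi, omega, phi, latent_values, (
        None if profile != "sinusoid" else phases)


def simulate_dataset(
    n_genes: int,
    n_cells: int,
    n_times: int,
    capture_spacing: float,
    hyper: Hyperparameters,
    seed: int,
    noise_df: float | None = None,
    latent_grid=None,
    profile: str = "gp",
    phases=None,
) -> SyntheticDataset:
    """Draw a dataset from the generative model; deterministic given ``seed``.

    ``noise_df`` switches the observation noise to a Student-t and
    ``profile="sinusoid"`` replaces GP draws with single-peaked cosines at
    known ``phases`` (misspecification knobs, off by default).
    ``latent_grid`` additionally records the noise-free profiles at the
    given pseudotime grid points, jointly drawn with the values at the cells.
    """
    rng = np.random.default_rng(seed)
    if latent_grid is not None:
        latent_grid = np.asarray(latent_grid, dtype=float)
    expr, meta, tau, psi, omega, phi, latent_values, phases_out = _simulate(
        n_genes, n_cells, n_times, capture_spacing, hyper, rng,
        noise_df=noise_df, latent_grid=latent_grid, profile=profile,
        phases=phases)
    return SyntheticDataset(
        expression=expr, meta=meta, tau=tau, psi=psi, omega=omega, phi=phi,
        config=dict(n_genes=n_genes, n_cells=n_cells, n_times=n_times,
                    capture_spacing=capture_spacing, seed=seed,
                    sigma_tau=hyper.sigma_tau, length_scale=hyper.length_scale,
                    period=hyper.period, profile=profile),
        latent_grid=latent_grid, latent_values=latent_values,
        phases=phases_out,
    )


def simulate_precocious(
    n_genes: int,
    n_cells: int,
    n_times: int,
    capture_spacing: float,
    hyper: Hyperparameters,
    n_precocious: int,
    displacement: float,
    seed: int,
) -> SyntheticDataset:
    """A dataset in which some first-capture cells are biologically ahead.

    ``n_precocious`` cells labelled with the first capture time get true
    pseudotimes ``kappa_1 + displacement`` (near the second capture time for
    ``displacement ~ capture_spacing``) while keeping their first-capture
    label.  With ``displacement=0`` this reduces to :func:`simulate_dataset`.
    """
    if displacement < 0:
        raise ValueError("displacement must be nonnegative")
    rng = np.random.default_rng(seed)
    levels = capture_spacing * np.arange(1, n_times + 1, dtype=float)
    first_capture = np.flatnonzero(np.arange(n_cells) % n_times == 0)
    if n_precocious >= first_capture.size:
        raise ValueError(
            f"n_precocious={n_precocious} must be smaller than the "
            f"{first_capture.size} cells at the first capture time"
        )
    chosen = first_capture[:n_precocious]
    mask = np.zeros(n_cells, dtype=bool)
    mask[chosen] = True
    override = None
    if displacement > 0:
        override = (mask, levels[0] + displacement)
    expr, meta, tau, psi, omega, phi, _, _ = _simulate(
        n_genes, n_cells, n_times, capture_spacing, hyper, rng,
        tau_override=override)
    ds = SyntheticDataset(
        expression=expr, meta=meta, tau=tau, psi=psi, omega=omega, phi=phi,
        config=dict(n_genes=n_genes, n_cells=n_cells, n_times=n_times,
                    capture_spacing=capture_spacing, seed=seed,
                    n_precocious=n_precocious, displacement=displacement),
        precocious=mask,
    )
    return ds


def heldout_split(x: ExpressionMatrix, n_held: int, seed: int):
    """Random disjoint, exhaustive gene partition into (fit, held-out)."""
    if n_held <= 0:
        raise ValueError("n_held must be positive")
    if n_held >= x.n_genes:
        raise ValueError(f"n_held={n_held} must be smaller than G={x.n_genes}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(x.n_genes)
    held = sorted(perm[:n_held].tolist())
    fit = sorted(perm[n_held:].tolist())
    fit_x = ExpressionMatrix([x.gene_ids[i] for i in fit], list(x.cell_ids),
                             x.values[fit])
    held_x = ExpressionMatrix([x.gene_ids[i] for i in held], list(x.cell_ids),
                              x.values[held])
    return fit_x, held_x
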