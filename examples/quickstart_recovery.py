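"""Quickstart: recover pseudotimes from a simulated cross-sectional series.

Simulates 20 genes x 50 cells captured at 5 time points, where each cell's
true pseudotime scatters around its capture time, then fits the model with
variational inference and compares the inferred ordering with the truth.
"""

import numpy as np
from scipy.stats import spearmanr

from gptime import (
    Hyperparameters,
    best_sample,
    empirical_bayes_hyperparams,
    fit_vi,
    simulate_dataset,
)

generating = Hyperparameters(
    mu_psi=0.0, sigma_psi=0.5,      # per-gene temporal variance ~ lognormal, median 1
    mu_omega=-2.3, sigma_omega=0.5,  # per-gene noise variance, median ~0.1
    length_scale=1.0,                # profile smoothness in capture-time units
    sigma_tau=0.5,                   # pseudotime scatter around capture times
)

ds = simulate_dataset(n_genes=20, n_cells=50, n_times=5, capture_spacing=1.0,
                      hyper=generating, seed=11)

# the user supplies length-scale and sigma_tau; the gene-level priors are
# estimated from the data by empirical Bayes
hyper = empirical_bayes_hyperparams(ds.expression, ds.meta,
                                    length_scale=1.0, sigma_tau=0.5)
fit = fit_vi(ds.expression, ds.meta, hyper, n_draws=500, seed=1)
bs = best_sample(fit)

rho_best = spearmanr(ds.tau, bs.tau).statistic
rho_mean = spearmanr(ds.tau, fit.posterior_mean_tau()).statistic
err = np.abs(bs.tau - ds.tau)

print(f"Spearman(best-sample tau, true tau)     = {rho_best:.3f}")
print(f"Spearman(posterior-mean tau, true tau)  = {rho_mean:.3f}")
print(f"median |tau_hat - tau_true|             = {np.median(err):.3f} "
      f"(prior sd was {generating.sigma_tau})")
# A Spearman correlation near 1 means the latent cell ordering is recovered
# almost perfectly; the median absolute error shows the fit localizes each
# cell well below the prior's own uncertainty.
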