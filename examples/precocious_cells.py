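"""Detecting precocious cells with the sparse model.

Some cells progress faster than their capture-time cohort (e.g. an
antiviral program already active at 1 h).  The capture-time prior is soft,
so the likelihood can pull such cells to later pseudotimes.  We displace
two first-capture cells by one capture interval in truth, fit with NUTS
using the low-rank inducing-point likelihood (M=12), and check where the
displaced cells land.  Runs in well under a minute.
"""

import numpy as np

from gptime import (
    Hyperparameters,
    best_sample,
    empirical_bayes_hyperparams,
    fit_mcmc,
    simulate_precocious,
)

# tight cohort scatter (0.25) makes the one-interval displacement clear-cut
generating = Hyperparameters(mu_psi=0.0, sigma_psi=0.5, mu_omega=-3.0,
                             sigma_omega=0.5, length_scale=1.0, sigma_tau=0.25)
ds = simulate_precocious(n_genes=20, n_cells=40, n_times=4, capture_spacing=1.0,
                         hyper=generating, n_precocious=2, displacement=1.0,
                         seed=4)

# fit with a softer prior so the likelihood can move the displaced cells
hyper = empirical_bayes_hyperparams(ds.expression, ds.meta, length_scale=1.0,
                                    sigma_tau=0.5, n_inducing=12)
fit = fit_mcmc(ds.expression, ds.meta, hyper, n_chains=2, n_iter=200,
               warmup=200, seed=5, max_treedepth=7)
bs = best_sample(fit)

first = ds.meta.capture_time == ds.meta.capture_levels[0]
prec = ds.precocious
print(f"fitted tau of displaced first-capture cells: "
      f"{np.round(bs.tau[prec], 2)}")
print(f"fitted tau range of other first-capture cells: "
      f"[{bs.tau[first & ~prec].min():.2f}, {bs.tau[first & ~prec].max():.2f}]")
n_later = int(np.sum(bs.tau[prec] > bs.tau[first & ~prec].max()))
print(f"displaced cells placed later than every peer: {n_later}/2")
# Both displaced cells should sit near pseudotime 2 -- with the second-capture
# cohort -- while their label said capture time 1.
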