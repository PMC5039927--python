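"""Periodic profiles: estimate cell-cycle peak times.

Cyclic processes (cell cycle, circadian rhythm) are modelled by folding the
pseudotime separation through a sine warp, which restricts the GP prior to
periodic functions.  Cells labelled with three phases map to capture times
1, 2, 3 under a period of 3.  We simulate single-peaked profiles with known
phases, fit with NUTS, and compare estimated peak times against the truth
on the circle.  Runs in about a minute.
"""

from gptime import (
    Hyperparameters,
    best_sample,
    circular_rmse,
    empirical_bayes_hyperparams,
    estimate_peak_times,
    fit_mcmc,
    predict_profiles,
    simulate_dataset,
)

PERIOD = 3.0
generating = Hyperparameters(mu_psi=0.0, sigma_psi=0.5, mu_omega=-3.0,
                             sigma_omega=0.5, length_scale=1.0, sigma_tau=0.5,
                             period=PERIOD)
ds = simulate_dataset(n_genes=20, n_cells=40, n_times=3, capture_spacing=1.0,
                      hyper=generating, seed=2, profile="sinusoid")

hyper = empirical_bayes_hyperparams(ds.expression, ds.meta, length_scale=1.0,
                                    sigma_tau=0.5, period=PERIOD)
fit = fit_mcmc(ds.expression, ds.meta, hyper, n_chains=3, n_iter=250,
               warmup=250, seed=3, max_treedepth=7)
bs = best_sample(fit)

pred = predict_profiles(bs, ds.expression, hyper.kernel_config(), grid_size=150)
peaks, defined = estimate_peak_times(pred)
rmse = circular_rmse(peaks[defined], ds.true_peak_times()[defined], PERIOD)

print(f"genes with a defined peak: {int(defined.sum())}/{ds.expression.n_genes}")
for g in range(5):
    print(f"  {ds.expression.gene_ids[g]}: estimated peak {peaks[g]:.2f}, "
          f"true phase {ds.true_peak_times()[g]:.2f}")
print(f"circular peak-time RMSE: {rmse:.3f} (period {PERIOD})")
# An RMSE well below 10% of the period means the fitted profiles place each
# gene's expression maximum at nearly the right point of the cycle.
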