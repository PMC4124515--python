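"""Certify and then measure exponential relaxation in a weak-coupling regime.

A short refractory period (sigma = 0.3) with a Lipschitz ramp rate and
the proportional reset psi(u) = u/2 satisfies the smallness condition
B* < 1.  The dual weight P (positive, increasing past the threshold)
then certifies decay of the weighted norm of the cumulative difference
M(s,t) = int_0^s (n - A); the simulator realizes at least that rate.
"""

import numpy as np

import neurofrag as nf

rate = nf.FiringRate(family="regularized", threshold=0.3, pM=1.0, smoothing_width=0.2)
kern = nf.FragmentationKernel.point_map_linear(0.5)
grid = nf.steady_grid(rate, ds=0.01)

steady = nf.nonlinear_fixed_point(rate, kern, grid)
b_star = nf.compute_B_star(rate, kern, steady.A_star)
report = nf.check_assumptions(rate, kern, steady.A_star)
print(f"stationary activity A*  = {steady.A_star:.4f}")
print(f"smallness quantity B*   = {b_star:.4f}  (< 1: certificate applies)")
print(f"exponential-moment mu   = {report.mu_star:.4f}")
print(
    f"direct-decay rate nu_B1 = {report.nu_B1:.4f}"
    "  (negative: the unweighted certificate is not granted here,\n"
    "   because the rate vanishes inside the refractory zone --\n"
    "   exactly the case the weighted machinery exists for)"
)

p_star = nf.firing_rate_eval(grid.nodes, steady.A_star, rate)
cert = nf.find_lambda(
    p_star, kern, grid, b_star, sigma_star=float(rate.sigma(steady.A_star))
)
print(f"certified eigenvalue    = {cert.lam:.4f}  (admissible: {cert.admissible})")

snaps = list(np.arange(0.0, 16.5, 0.5))
traj = nf.run(nf.initial_data("exp_decay", grid), rate, kern, T=16.0, snapshot_times=snaps)
fit = nf.estimate_decay_rate(
    traj,
    A_values=steady.A_values,
    P_values=cert.P_values,
    functional="weighted_L1_M",
    window=(1.0, 15.0),
)
print(f"empirical decay rate    = {fit.nu_hat:.4f}  (r^2 = {fit.r_squared:.4f})")
print()
print(
    "The measured rate of ds*sum P|M| meets or beats the certified |lambda|:\n"
    "the spectral machinery is conservative, as it should be."
)
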