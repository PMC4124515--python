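"""Simulate the elapsed-time population model and watch desynchronization.

Builds the alpha = 2 network with the proportional reset psi(u) = u/2
(a neuron that fires after elapsed time u restarts at u/2), integrates
from the memoryless profile e^{-s}, and prints how the total activity
N(t) settles.
"""

import neurofrag as nf

rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=2.0))
kernel = nf.FragmentationKernel.point_map_linear(0.5)
grid = nf.default_grid(rate, ds=0.01)

traj = nf.run(nf.initial_data("exp_decay", grid), rate, kernel, T=60.0)

report = nf.oscillation_analysis(traj)
print(f"initial activity N(0)      = {traj.N_values[0]:.6f}")
print(f"late-time regime           = {report.regime}")
print(f"activity plateau           = {report.plateau:.6f}")
print(f"late-window amplitude      = {report.amplitude:.2e}")
print(f"max mass drift along run   = {traj.max_mass_drift:.2e}")
print()
print(
    "The plateau is the self-consistent stationary activity: the network\n"
    "desynchronizes (neurons fire incoherently) because the partial reset\n"
    "smears the refractory cohort.  Mass drift at machine precision shows\n"
    "the scheme conserves the probability density exactly."
)
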