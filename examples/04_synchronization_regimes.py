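"""Full reset versus proportional reset: synchronization and its smoothing.

With a strong threshold nonlinearity (alpha = 4) the full-reset kernel
delta_{s=0} sustains periodic network activity whose orbit depends on
the initial data; the proportional reset delta_{s=u/2} smooths the
dynamics, and at alpha = 3 every initial profile locks onto the same
periodic orbit.
"""

import numpy as np

import neurofrag as nf


def compare(alpha: float, slope: float, T: float):
    rate = nf.FiringRate(family="step", threshold=nf.ThresholdRule(alpha=alpha))
    grid = nf.default_grid(rate, ds=0.01)
    kd = nf.discretize_kernel(nf.FragmentationKernel.point_map_linear(slope), grid)
    t1 = nf.run(nf.initial_data("exp_decay", grid), rate, kd, T=T)
    t2 = nf.run(
        nf.initial_data("multi_bump", grid, centers=(1.0, 3.0), widths=0.2),
        rate, kd, T=T,
    )
    r1, r2 = nf.oscillation_analysis(t1), nf.oscillation_analysis(t2)
    a, b = t1.N_values[-3000:], t2.N_values[-3000:]
    disc = min(
        float(np.max(np.abs(a[s:][: len(b) - s] - b[: len(b) - s])))
        for s in range(0, 400)
    ) / float(a.mean())
    return r1, r2, disc


r1, r2, disc = compare(4.0, 0.0, 100.0)
print("alpha = 4, full reset delta_0:")
print(f"  exp data   : {r1.regime}, period {r1.period:.2f}")
print(f"  bump data  : {r2.regime}, period {r2.period:.2f}")
print(f"  orbit discrepancy across data = {disc:.2f}  (distinct orbits)")

r1, r2, disc = compare(3.0, 0.5, 200.0)
print("alpha = 3, proportional reset delta_{u/2}:")
print(f"  exp data   : {r1.regime}, period {r1.period:.2f}")
print(f"  bump data  : {r2.regime}, period {r2.period:.2f}")
print(f"  orbit discrepancy across data = {disc:.4f}  (same orbit)")
print()
print(
    "The full reset synchronizes neurons into initial-data-dependent\n"
    "periodic orbits; the partial reset erases the memory of the initial\n"
    "profile and selects a single orbit."
)
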