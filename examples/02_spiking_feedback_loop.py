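"""Closed-loop spiking network: feedback turns weak correlation into synchrony.

Two 40 Hz mitral phase oscillators drive one noisy LIF granule cell; granule
spikes raise the shared inhibitory kick rate lambda.  With the coupling off
the phase-difference histogram is nearly flat; with coupling on, lambda rises
and a sharp peak appears at zero lag.
"""
import numpy as np
from stochsync import SpikingConfig, Topology, phase_difference_histogram, run_spiking

topo = Topology.pair_single_granule()
for g in (0.0, 2.0):
    res = run_spiking(topo, SpikingConfig(g_coupling=g), t_total=120.0, dt=1e-4, rng_seed=1)
    h = phase_difference_histogram(res.phase_differences(), 24)
    n = len(h.rho)
    peak = h.rho[n // 2 - 1 : n // 2 + 1].mean()
    print(
        f"coupling g={g}: mean lambda={res.lam.mean():7.2f}/s, "
        f"zero-lag density={peak:.3f} (uniform would be {1/(2*np.pi):.3f})"
    )
print("\nFeedback raises the shared rate and sharpens the zero-lag peak.")
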