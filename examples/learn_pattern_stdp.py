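"""Unsupervised learning of a repeating spike pattern with STDP.

One frozen 100-ms pattern over 10^4 Poisson afferents (3.2 Hz) is replayed
every 400 ms with +-3.2 ms jitter, 500 times.  The LIF (theta = 370,
homeostatic LTD w_out = -3.5e-3) starts with uniform weights and learns
without supervision; the run is then classified against the SNR-optimal
23-ms Strategy-#1 window.
"""

import numpy as np

from spikepattern import PatternConfig, STDPConfig, generate_pattern, run_stdp

cfg = PatternConfig(N=10_000, f=3.2, L=0.1, T=0.0032, interval=0.4,
                    n_presentations=500, seed=6)
pattern = generate_pattern(cfg)
out = run_stdp(pattern, cfg, STDPConfig(theta=370.0, w_out=-3.5e-3), dt_opt=0.023)

w = out.final_weights
print(f"postsynaptic spikes: {out.post_spike_times.size} "
      f"({out.spikes_per_presentation:.2f} per presentation at the end)")
print(f"weights at 1: {(w >= 0.95).sum()},  at 0: {(w <= 0.05).sum()},  "
      f"between: {((w > 0.05) & (w < 0.95)).sum()}")
print(f"converged (>=95% binarized): {out.converged}")
if out.matched_window:
    t0, dur = out.matched_window
    print(f"learned window: starts {t0 * 1e3:.1f} ms into the pattern, "
          f"duration {dur * 1e3:.1f} ms (optimal dt = 23 ms)")
print(f"optimal detector: {out.optimal}")
print()
print("STDP concentrates the weights on afferents firing in a short window")
print("near the pattern start; whether the window duration lands within 10%")
print("of the optimal 23 ms varies from pattern to pattern (~half do).")
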