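"""Check the closed-form SNR against clock-based LIF simulation.

Small protocol: frozen 20-ms patterns over 10^4 afferents at 5 Hz, detector
wired by Strategies #1 and #2 with dt = L, each pattern replayed 150 times
per jitter value.  Prints simulated vs theoretical SNR.
"""

from spikepattern import validate_theory

df = validate_theory(
    f=5.0, N=10_000, L=0.02, strategies=(1, 2), T_grid=(0.0, 0.002, 0.004),
    n_patterns=5, n_presentations=150, seed=7,
)
print(df[["strategy", "T", "snr_sim_mean", "snr_sim_sd", "snr_theory"]]
      .to_string(index=False))
print()
print("Each row: simulated SNR (mean +- sd over 5 random patterns) against")
print("the closed form.  Agreement within ~1 sd across jitters and both")
print("strategies validates the trapezoid/peak-response derivation.")
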