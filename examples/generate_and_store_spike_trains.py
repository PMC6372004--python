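"""Generate a jittered presentation session and round-trip it through text.

Builds a small session (frozen pattern + Poisson background), writes it as
two-column CSV (afferent, time_s) and reads it back bit-exactly.
"""

import tempfile
from pathlib import Path

import numpy as np

from spikepattern import PatternConfig, build_session, generate_pattern
from spikepattern.io import read_spike_trains, write_spike_trains

cfg = PatternConfig(N=200, f=3.2, L=0.05, T=0.002, interval=0.2,
                    n_presentations=5, seed=42)
pattern = generate_pattern(cfg)
session, onsets = build_session(pattern, cfg)

print(f"pattern: {pattern.n_spikes} spikes over {cfg.N} afferents, L = {cfg.L * 1e3:.0f} ms")
print(f"session: {session.n_spikes} spikes over {session.duration:.1f} s; "
      f"onsets at {np.round(onsets, 3).tolist()} s")

path = Path(tempfile.mkdtemp()) / "session.csv"
write_spike_trains(path, session)
back = read_spike_trains(path)
exact = np.array_equal(back.times, session.times) and np.array_equal(
    back.afferents, session.afferents
)
print(f"wrote {path} ({path.stat().st_size} bytes); bit-exact round-trip: {exact}")
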