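"""Session-level performance metrics and the whisk rate.

Computes percent correct, d-prime (inverse-normal transform of hit and
false-alarm rates with 1/(2N) clipping) and the error rate on the trained
G5-vs-G0 pair, plus the session-inclusion rule (d' > 1 or > 70% correct on
no-laser trials), and counts whisks on a synthetic whisker-angle trace.
"""

import numpy as np

import texdisc as td

observer = td.ObserverParams(g=0.15, l=0.10, u=2.0, v=1.0)
session = td.simulate_session(observer, td.SessionDesign(n_trials=400, seed=7))

for laser in ("none", "sensory"):
    m = td.session_metrics(session, laser=laser)
    print(f"{laser:8s} hit={m.hit_rate:.3f} fa={m.fa_rate:.3f} "
          f"pc={m.percent_correct:.1f}% d'={m.dprime:.2f} err={m.error_rate:.3f}")
print("session included:", td.session_included(session))

# whisk rate: a 25-deg, 8 Hz whisking bout over the 3.84 s sensory period
fs = 122.0
t = np.arange(int(3.84 * fs)) / fs
angle = -12.5 * np.cos(2 * np.pi * 8.0 * t)
print(f"whisk rate: {td.whisk_rate(angle, fs):.2f} Hz "
      "(protraction sweeps per second of the sensory window)")
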