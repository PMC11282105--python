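"""Simulate a go/no-go texture-discrimination session.

Builds the default session design (six textures G0-G5, the smooth no-go G0 on
30% of trials, never more than two identical textures in a row, 50% laser
trials) and an observer defined by the 4-parameter psychometric curve, then
draws a session and summarizes its composition.
"""

import texdisc as td

observer = td.ObserverParams(g=0.15, l=0.10, u=2.0, v=1.0)
design = td.SessionDesign(n_trials=400, seed=7)
session = td.simulate_session(observer, design)

print("trials:", len(session))
print("level composition:")
print(session["stimulus_level"].value_counts(normalize=True).round(3).to_string())
print("laser trials:", (session["laser"] == "sensory").mean().round(3))
print("outcomes:", session["outcome"].value_counts().to_dict())

# The G0 fraction sits near the designed 0.30; outcomes follow from the
# observer's lick curve (guess rate 0.15 sets the asymptotic FA rate).
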