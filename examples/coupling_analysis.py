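"""Theta-gamma phase-amplitude coupling with surrogate significance.

Builds sessions whose slow-gamma amplitude is modulated by theta phase at
increasing coupling depth, and shows that the Tort modulation index (18
phase bins) rises with it while the 200-surrogate trial-shuffling test
separates real coupling from none.  MI = 0 means the gamma envelope is
flat over theta phase; larger values mean stronger concentration at the
preferred phase.
"""

import numpy as np

from laminarlfp import coupling as cpl
from laminarlfp import synth

FS = 500.0

for kc in (0.0, 0.3, 0.6, 0.9):
    src = synth.SourceSpec(
        "nonreversing_superficial",
        band_powers={"slow_gamma": 1.0},
        coupling_depth={"slow_gamma": kc},
        preferred_phase_deg=90.0,
    )
    ref = synth.SourceSpec(
        "linear_volume_conducted", band_powers={"theta": 1.0}, theta_coherent=True
    )
    ev = synth.make_events(n_trials=24, interval_s=2.0, seed=0)
    s, _ = synth.make_timecourses([src, ref], ev, FS, ev.pull_onsets[-1] + 1.5, seed=0)
    phase = cpl.analytic_phase_amp(cpl.bandpass(s[1], FS, cpl.THETA_BAND))[0]
    env = cpl.analytic_phase_amp(cpl.bandpass(s[0], FS, cpl.SLOW_GAMMA))[1]
    phs, envs = [], []
    for onset in ev.pull_onsets:
        a, b = int((onset - 1.0) * FS), int((onset + 0.5) * FS)
        phs.append(phase[a:b])
        envs.append(env[a:b])
    res = cpl.surrogate_mi(phs, envs, n_surrogates=200, seed=1)
    print(
        f"coupling depth {kc:.1f}: MI = {res.mi:.4f}, "
        f"preferred phase = {res.preferred_phase_deg:.0f} deg, "
        f"p = {res.p_empirical:.3f}, significant = {res.significant}"
    )
print(
    "MI grows with the generated coupling depth; at this trial count only "
    "the stronger couplings clear the surrogate threshold"
)
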