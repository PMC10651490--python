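"""Rectified-integrated nerve activity, per heartbeat, vs baseline.

Simulates cardiac-locked baroreceptor-nerve bursts whose amplitude rises
by 50% from beat 20 on, processes the raw trace (DC removal, band-pass,
rectification, 3 ms leaky integration), subtracts the post-mortem noise
floor and expresses every beat relative to the 10 pre-event beats.
"""

import numpy as np

import ifshear as ifs

fs = 3000.0
beats = np.arange(0.5, 40, 0.8)

# base bursts on every beat, plus an extra half-amplitude burst from beat
# 20 on; carrier-locked bursts superpose exactly into a 1.5x step
base, _ = ifs.generate_nerve_signal(fs, beats, burst_amp=1.0,
                                    noise_sd=0.05, dc_offset=0.4, seed=5)
step, _ = ifs.generate_nerve_signal(fs, beats[20:], burst_amp=0.5,
                                    noise_sd=0.0, dc_offset=0.0, seed=6)
samples = base.samples.copy()
samples[-step.samples.size:] += step.samples
raw = ifs.NerveSignal(samples=samples, rate=fs, beat_times=beats)

trace = ifs.integrate_nerve_signal(raw)  # 50-10,000 Hz band, tau = 3 ms

bg_sig, _ = ifs.generate_nerve_signal(fs, beats[:5], burst_amp=0.0,
                                      noise_sd=0.05, dc_offset=0.4, seed=7)
background = float(ifs.integrate_nerve_signal(bg_sig).mean())

rel = ifs.beat_average_relative(trace, fs, beats, background=background,
                                event_time=beats[20])
print(f"noise floor (post-mortem integrated level): {background:.4f} a.u.")
print(f"baseline beats (last 5 of 10): {np.round(rel[15:20], 1)} %")
print(f"post-event beats (first 5)   : {np.round(rel[20:25], 1)} %")
print(f"mean post/pre response       : {rel[20:-1].mean():.0f} %")
print("\nValues are % of the 10-beat pre-event baseline after noise-floor")
print("subtraction; a ~150% plateau matches the planted amplitude step.")
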