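"""Simulate a continuous BP recording and delineate its beats.

Builds a 60-second, 100 Hz arterial-pressure waveform with a dicrotic-notch
pulse morphology, then recovers systolic peaks and diastolic troughs and
compares them with the generator's ground truth.
"""

import numpy as np

import pulsevar as pv

config = pv.WaveformSimConfig(duration=60.0, notch_depth=0.3, seed=42)
beats = pv.simulate_beat_sequence(config)
waveform = pv.render_waveform(beats, config)

series = pv.delineate(waveform, pv.DetectionParams(refractory_ms=400.0))

true_times = np.array([b.peak_time for b in beats])
timing_err_ms = 1000 * np.abs(series.peak_times - true_times).max()

print(f"simulated beats:        {len(beats)}")
print(f"detected beats:         {series.n_beats}")
print(f"worst peak timing error: {timing_err_ms:.1f} ms")
print(f"excluded fraction:      {series.excluded_fraction:.3f} (accepted={series.accepted})")
print(f"heart rate:             {pv.compute_hr(series):.1f} bpm")

# A 40 ms refractory lets the dicrotic notch through as a spurious peak.
short = pv.delineate(waveform, pv.DetectionParams(refractory_ms=40.0))
print(f"with 40 ms refractory:  {short.n_beats} peaks "
      f"(dicrotic notches misdetected)")

# Interpretation: with the 400 ms refractory every true beat is recovered
# within one sample; halving the separation to 40 ms roughly doubles the
# peak count because each pulse's dicrotic notch is picked up as a beat.
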