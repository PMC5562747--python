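"""Quantify beating in a synthetic organoid video.

Generates a 30 s clip of a contracting organoid at a known 60 BPM (with
pixel noise), converts it to a moving-pixel motion trace, detects beat
peaks and prints the recovered kinetics.  The recovered BPM should sit
within ~2 of the ground truth, with near-zero inter-beat variability.
"""

from organchip import analyze_video
from organchip.synth import VideoTruth, generate_beating_video

truth = VideoTruth(bpm_trajectory=60.0, noise_sd=2.0, seed=42)
seq, truth = generate_beating_video(truth)
trace, series, metrics = analyze_video(seq)

print(f"ground truth          : {truth.bpm_trajectory:.0f} BPM, "
      f"{truth.n_pulses} contraction pulses")
print(f"motion threshold used : {trace.tau_used:.1f} intensity units")
print(f"recovered beat rate   : {metrics.bpm:.2f} BPM from {metrics.n_peaks} peaks")
print(f"inter-beat interval   : {metrics.ibi_mean_s:.3f} s "
      f"(CV {metrics.ibi_cv:.3f}; a healthy regular rhythm is near 0)")
print(f"ceased                : {metrics.ceased}")
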