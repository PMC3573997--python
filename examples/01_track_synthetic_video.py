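"""Track a synthetic spinning embryo and compare against ground truth.

Renders a textured disc rotating clockwise at 0.035 rad/frame inside a
capsule ring, runs the sparse optic-flow pipeline, and prints the
recovered mean rotation next to the known spin rate.
"""

import numpy as np

from embryoflow import VideoSpec, analyze_sequence, synth_embryo_video

seq, truth = synth_embryo_video(
    VideoSpec(n_frames=60, spin_profile=0.035, fps=7.5, seed=42))
record = analyze_sequence(seq)

print(f"frames tracked:            {len(seq)} ({seq.duration_s:.1f} s at {seq.fps} Hz)")
print(f"true spin:                 {truth.pos_angle.mean():.4f} rad/frame clockwise")
print(f"recovered pos_angle mean:  {record.pos_angle.mean():.4f} rad/frame")
print(f"recovered neg_angle mean:  {record.neg_angle.mean():.4f} rad/frame")
print(f"centroid drift per frame:  {record.com_rho.mean():.4f} px")
rel = abs(record.pos_angle.mean() - 0.035) / 0.035
print(f"relative error:            {rel:.1%}")
print()
print("pos_angle is the mean clockwise angular step of tracked corners about")
print("their centroid; for a rigidly spinning body it estimates the spin rate,")
print("while neg_angle (anti-clockwise) and the centroid step stay near zero.")
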