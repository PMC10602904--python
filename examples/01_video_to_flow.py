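"""Render a synthetic stimulus video and extract its optical-flow series.

A bright ellipse (stand-in for a moving articulator) follows a band-limited
trajectory; dense Horn–Schunck flow is estimated between adjacent frames
and summed per frame into the global motion-energy timeseries the
entrainment analysis uses as its stimulus-side signal.
"""

import numpy as np

from entrainflow.flow import extract_flow
from entrainflow.synth import SynthSpec, make_video

spec = SynthSpec(seed=7)
frames, truth = make_video(spec, np.random.default_rng(7))
frames = frames[:45]  # 1.5 s is plenty for a demonstration
flow = extract_flow(frames, spec.frame_rate_hz, source_id="demo")

print(f"frames: {frames.shape[0]} of {frames.shape[1]}x{frames.shape[2]} px")
print(f"flow series: {len(flow.values)} samples at "
      f"{flow.frame_rate_hz:.0f} Hz")
print(f"mean global flow magnitude: {flow.values.mean():.1f} px/frame "
      "(summed over pixels)")
r = np.corrcoef(flow.values, truth[:len(flow.values)])[0, 1]
print(f"correlation with ground-truth centroid speed: r = {r:.2f}")
print("A high r means the extracted motion-energy series tracks how fast "
      "the articulator actually moved.")
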