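"""Embed a known entrainment effect and recover it from the coherence
spectrum.

EEG is synthesised with the left-hemisphere channels tracking the stimulus
optical flow at 1.0 Hz with a 200 ms delay; the frequency-resolved lagged
correlation should then peak at (or next to) the 1.0 Hz bin over the left
region.
"""

import numpy as np

from entrainflow.entrainment import (coherence_spectrum, default_grid,
                                     localize_cells)
from entrainflow.features import region_average
from entrainflow.synth import (EntrainmentCell, SynthSpec, make_eeg,
                               make_flow_series)

cell = EntrainmentCell("a", "left", 1.0, 200.0, 8.0)
spec = SynthSpec(entrainment_cells=[cell], seed=5)
flow = make_flow_series(spec, 0)
rec = make_eeg(spec, flow, "a01", "direct")

onset = rec.events[0][0]
keep = [i for i, c in enumerate(rec.channel_labels)
        if c not in ("M1", "M2", "HEOG", "VEOG")]
trial = rec.data[keep, onset:onset + 2500]
labels = [rec.channel_labels[i] for i in keep]

cs = coherence_spectrum(flow, trial, rec.rate_hz, labels)
rs = region_average(cs)
grid = default_grid()
left = rs.amplitude[2]  # regions ordered anterior, posterior, left, right
j = int(np.argmax(left))
print(f"embedded cell: left region, {cell.frequency_hz} Hz, "
      f"{cell.lag_ms:.0f} ms, snr {cell.snr}")
print(f"left-region argmax: {grid.centers[j]:.1f} Hz bin, "
      f"peak amplitude {left[j]:.3f}")

f_hat, lag_hat, r = localize_cells(flow, [trial], rec.rate_hz, labels,
                                   channels=list(spec.region_map["left"]))
print(f"pooled-channel localization: {f_hat:.1f} Hz at {lag_hat:.0f} ms "
      f"(pooled r = {r:.3f})")
print("Pooling the correlation curves over the region's five channels "
      "suppresses the spurious peaks that single narrowband channels show "
      "under a free lag search; the recovered bin should be the embedded "
      "one (or its immediate neighbour — 5 s of data has 0.2 Hz "
      "resolution) and the lag should be in the right few-hundred-ms "
      "range.")
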