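"""Synthetic stimuli and EEG with known embedded entrainment.

Every downstream stage of the analysis (flow extraction, preprocessing,
coherence, feature ranking, classification) is verified by parameter
recovery against data this module generates:

* videos: a bright soft-edged ellipse (stand-in for a moving articulator)
  whose centroid follows a band-limited trajectory; the per-frame centroid
  displacement magnitude is returned as ground-truth motion;
* optical-flow series: positive, band-limited (≤ ~12 Hz) stochastic
  signals with a 1/f-like spectrum, shared across participants the way real
  stimulus videos are;
* EEG: per-channel 1/f background noise plus, for each *entrainment cell*
  ``(group, region, frequency_hz, lag_ms, snr)``, an snr-scaled, lag-delayed,
  narrowband-filtered copy of the stimulus flow (0.2 Hz bandwidth at the
  cell frequency) added to every channel of the target region.  The delay
  is circular — a pure shift of a stationary segment — so no onset
  transient is introduced (sub-Hz filtering rings for ~1/bandwidth = 5 s
  and would otherwise smear a hard onset across the whole trial).
  ``snr`` is the in-band amplitude ratio between the injected component
  and the channel's background noise.

Two synthetic populations (a: 24 participants, b: 20) differ in which
region × frequency cells carry entrainment and at what lag.  For the
reversed condition each group's cells are attenuated by a configurable
factor (group a strongly — its entrainment is comprehension-dependent;
group b mildly), which is what the classifiers must detect.

All outputs are deterministic functions of ``SynthSpec.seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .entrainment import narrowband, resample_flow
from .features import REGION_ORDER, RegionMap
from .flow import FlowTimeseries
from .preproc import EEGRecording

__all__ = [
    "EntrainmentCell",
    "SynthSpec",
    "Cohort",
    "Instance",
    "default_cells",
    "one_over_f_noise",
    "make_video",
    "make_flow_series",
    "make_eeg",
    "make_cohort",
]

#: 26 scalp electrodes of the 10/20 montage used for acquisition.
SCALP_26 = ("Fz", "Cz", "Pz", "Oz", "F3", "F4", "F7", "F8", "FC1", "FC2",
            "FC5", "FC6", "T7", "T8", "C3", "C4", "CP1", "CP2", "CP5",
            "CP6", "P3", "P7", "P4", "P8", "O1", "O2")
AUX_CHANNELS = ("M1", "M2", "HEOG", "VEOG")


@dataclass(frozen=True)
class EntrainmentCell:
    """One embedded stimulus-tracking effect.

    All channels of ``region`` in participants of ``group`` receive a copy
    of the stimulus flow, narrowband-filtered at ``frequency_hz`` (0.2 Hz
    bandwidth), delayed by ``lag_ms``, scaled to ``snr`` times the channel's
    in-band noise amplitude.
    """

    group: str
    region: str
    frequency_hz: float
    lag_ms: float
    snr: float


def default_cells() -> list[EntrainmentCell]:
    """Default effect structure of the two synthetic populations.

    Group a entrains at ~1 Hz with a left-weighted, distributed topography;
    group b shares the posterior/anterior cells but is right-weighted.
    Lags sit in the 100–300 ms window where visual tracking peaks.
    """
    return [
        EntrainmentCell("a", "posterior", 1.0, 200.0, 6.0),
        EntrainmentCell("a", "left", 1.0, 150.0, 6.0),
        EntrainmentCell("a", "anterior", 1.0, 250.0, 5.0),
        EntrainmentCell("a", "right", 1.2, 200.0, 4.0),
        EntrainmentCell("b", "posterior", 1.0, 200.0, 6.0),
        EntrainmentCell("b", "anterior", 1.0, 250.0, 5.0),
        EntrainmentCell("b", "right", 1.2, 150.0, 6.0),
        EntrainmentCell("b", "left", 1.0, 200.0, 3.0),
    ]


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study design: 24 + 20 participants, two conditions
    (direct and time-reversed stimuli), 5 s videos, 500 Hz 26-channel EEG.
    ``reversed_snr_factor`` attenuates each group's entrainment in the
    reversed condition (group a strongly: its entrainment models
    comprehension; group b mildly: its entrainment models biological-motion
    tracking that still weakens for atypical motion).
    """

    n_group_a: int = 24
    n_group_b: int = 20
    n_videos_per_condition: int = 2
    video_duration_s: float = 5.0
    frame_rate_hz: float = 30.0
    eeg_rate_hz: float = 500.0
    channel_labels: tuple[str, ...] = SCALP_26 + AUX_CHANNELS
    entrainment_cells: list[EntrainmentCell] = field(
        default_factory=default_cells)
    noise_exponent: float = 1.0
    noise_std_uv: float = 8.0
    reversed_snr_factor: dict[str, float] = field(
        default_factory=lambda: {"a": 0.3, "b": 0.6})
    eog_amplitude_uv: float = 15.0
    pre_stim_s: float = 0.5
    post_stim_s: float = 0.2
    region_map: RegionMap = field(default_factory=RegionMap)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_videos_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 5.0 <= self.video_duration_s <= 7.0:
            raise ValueError("video_duration_s must lie in [5, 7] s")
        cells = [EntrainmentCell(*c) if not isinstance(c, EntrainmentCell)
                 else c for c in self.entrainment_cells]
        for c in cells:
            if not 0.2 <= c.frequency_hz <= 12.4:
                raise ValueError(
                    f"cell frequency {c.frequency_hz} Hz outside [0.2, 12.4]")
            if c.region not in REGION_ORDER:
                raise ValueError(f"unknown region {c.region!r}")
            if c.snr < 0:
                raise ValueError("cell snr must be >= 0")
        self.entrainment_cells = cells

    def participant_ids(self) -> list[str]:
        return ([f"a{i + 1:02d}" for i in range(self.n_group_a)]
                + [f"b{i + 1:02d}" for i in range(self.n_group_b)])


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Independent deterministic stream for (seed, tokens)."""
    digest = hashlib.sha256(("|".join(map(str, tokens))).encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng([seed & 0x7FFFFFFF, *words.tolist()])


def one_over_f_noise(rng: np.random.Generator, n: int, exponent: float = 1.0,
                     rate_hz: float = 500.0,
                     f_floor_hz: float = 0.1) -> np.ndarray:
    """Gaussian noise with power spectrum S(f) ∝ f^(−exponent), unit SD.

    Shaped in the frequency domain; frequencies below ``f_floor_hz`` are
    flattened so the variance stays finite for steep exponents.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = np.empty_like(freqs)
    shape[0] = 0.0  # no DC
    f = np.maximum(freqs[1:], f_floor_hz)
    shape[1:] = f ** (-exponent / 2.0)
    spec = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _soft_ellipse(h: int, w: int, cy: float, cx: float,
                  ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2))


def make_video(spec: SynthSpec, rng: np.random.Generator | None = None,
               *, shape: tuple[int, int] = (64, 64),
               trajectory: np.ndarray | None = None,
               axes_px: tuple[float, float] = (5.0, 8.0),
               trajectory_cutoff_hz: float = 3.0,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Render a moving soft-edged ellipse.

    Returns ``(frames, displacement)``: frames of shape (n_frames, H, W) in
    [0, 1], and the ground-truth per-transition centroid displacement
    magnitude (pixels/frame, length n_frames − 1).

    ``trajectory`` overrides the default band-limited random walk with an
    explicit (n_frames, 2) array of (row, col) centroid positions.
    """
    n_frames = int(round(spec.video_duration_s * spec.frame_rate_hz))
    if n_frames < 1:
        raise ValueError("zero frames requested")
    h, w = shape
    if trajectory is None:
        if rng is None:
            rng = _rng(spec.seed, "video")
        # low-pass filtered white noise per axis, scaled to stay in-frame
        raw = rng.standard_normal((2, n_frames + 60))
        sos = signal.butter(4, trajectory_cutoff_hz / (spec.frame_rate_hz / 2),
                            "lowpass", output="sos")
        smooth = signal.sosfiltfilt(sos, raw, axis=-1)[:, 30:30 + n_frames]
        smooth = smooth / (np.abs(smooth).max() + 1e-12)
        margin_y, margin_x = axes_px[0] * 1.5, axes_px[1] * 1.5
        trajectory = np.stack([
            h / 2 + smooth[0] * (h / 2 - margin_y),
            w / 2 + smooth[1] * (w / 2 - margin_x)], axis=1)
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != (n_frames, 2):
        raise ValueError(f"trajectory must be ({n_frames}, 2)")
    frames = np.stack([_soft_ellipse(h, w, cy, cx, *axes_px)
                       for cy, cx in trajectory])
    displacement = np.linalg.norm(np.diff(trajectory, axis=0), axis=1)
    return frames, displacement


def make_flow_series(spec: SynthSpec, video_index: int,
                     flow_exponent: float = 1.0) -> FlowTimeseries:
    """Synthesise the optical-flow magnitude series of one stimulus video.

    A positive band-limited stochastic signal: 1/f-shaped noise low-passed
    at 12.5 Hz (so it has power across the whole 0.2–12.4 Hz analysis band,
    concentrated at low frequencies like real articulator motion), offset to
    be non-negative.  Length is n_frames − 1, matching extracted flow.
    """
    n_frames = int(round(spec.video_duration_s * spec.frame_rate_hz))
    rng = _rng(spec.seed, "flow", video_index)
    x = one_over_f_noise(rng, n_frames - 1, exponent=flow_exponent,
                         rate_hz=spec.frame_rate_hz, f_floor_hz=0.15)
    if spec.frame_rate_hz / 2 > 12.5:
        sos = signal.butter(6, 12.5 / (spec.frame_rate_hz / 2), "lowpass",
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
        x = x / (x.std() + 1e-12)
    values = x - x.min() + 0.1
    return FlowTimeseries(values, spec.frame_rate_hz,
                          source_id=f"video{video_index:03d}")


def _region_of(label: str, region_map: RegionMap) -> str | None:
    for region, members in region_map.items():
        if label in members:
            return region
    return None


def make_eeg(spec: SynthSpec, flow: FlowTimeseries, participant_id: str,
             condition: str) -> EEGRecording:
    """One participant's EEG response to one stimulus presentation.

    The recording spans a short pre-stimulus baseline, the stimulus window
    and a post-stimulus tail, with the onset event marked.  Channels carry
    1/f background noise; channels of regions targeted by the participant's
    group receive the delayed narrowband flow copies described in the module
    docstring.  For ``condition == "reversed"`` pass the *reversed* flow
    series (the stimulus actually shown) — cell snr is further attenuated by
    the group's ``reversed_snr_factor``.
    """
    if condition not in ("direct", "reversed"):
        raise ValueError("condition must be 'direct' or 'reversed'")
    group = participant_id[0]
    fs = spec.eeg_rate_hz
    if flow.duration_s < spec.video_duration_s - 1.5 / flow.frame_rate_hz:
        raise ValueError("flow series does not cover the video duration")
    flow_rs = resample_flow(flow, fs).values
    onset = int(round(spec.pre_stim_s * fs))
    n = onset + len(flow_rs) + int(round(spec.post_stim_s * fs))

    rng = _rng(spec.seed, "eeg", participant_id, condition, flow.source_id)
    data = np.empty((len(spec.channel_labels), n))
    for i, label in enumerate(spec.channel_labels):
        scale = spec.noise_std_uv * (0.5 if label in ("M1", "M2") else 1.0)
        data[i] = scale * one_over_f_noise(rng, n, spec.noise_exponent,
                                           rate_hz=fs)
    # EOG: slow sinusoid + noise pair (for exercising ocular correction);
    # zero propagation to scalp by default.
    t = np.arange(n) / fs
    for label, f_eog, phase in (("HEOG", 0.23, 0.0), ("VEOG", 0.31, 1.1)):
        i = spec.channel_labels.index(label)
        data[i] += spec.eog_amplitude_uv * np.sin(2 * np.pi * f_eog * t
                                                  + phase)

    cells = [c for c in spec.entrainment_cells if c.group == group]
    factor = (spec.reversed_snr_factor.get(group, 1.0)
              if condition == "reversed" else 1.0)
    targeted = {c.region for c in cells}
    region_channels = {r: spec.region_map[r] for r in targeted}
    for region, members in region_channels.items():
        for ch in members:
            if ch not in spec.channel_labels:
                raise ValueError(
                    f"cell targets region {region!r} but channel {ch!r} "
                    "is not in the montage")
    for cell in cells:
        eff_snr = cell.snr * factor
        if eff_snr == 0:
            continue
        # Narrowband copy at the cell frequency (0.2 Hz bandwidth, the same
        # resonator the analysis uses) with a circular delay: a pure shift
        # of a stationary segment, avoiding an onset transient that sub-Hz
        # filtering (ring time ~ 1/bandwidth = 5 s) would smear across the
        # whole trial.
        comp = narrowband(flow_rs - flow_rs.mean(), cell.frequency_hz,
                          0.2, fs)
        lag = int(round(cell.lag_ms / 1000.0 * fs))
        delayed = np.roll(comp, lag)
        band_rms = np.sqrt(np.mean(
            narrowband(delayed, cell.frequency_hz, 0.2, fs) ** 2))
        if band_rms <= 0:
            continue
        for ch in spec.region_map[cell.region]:
            i = spec.channel_labels.index(ch)
            seg = data[i, onset:onset + len(comp)]
            noise_band = narrowband(seg, cell.frequency_hz, 0.2, fs)
            noise_rms = np.sqrt(np.mean(noise_band ** 2))
            amp = eff_snr * noise_rms / band_rms
            data[i, onset:onset + len(comp)] += amp * delayed

    code = int(flow.source_id.replace("-reversed", "")[-3:]) + 1 \
        if flow.source_id[-3:].isdigit() else 1
    meta = {"participant": participant_id, "group": group,
            "condition": condition, "video_id": flow.source_id}
    return EEGRecording(data, fs, list(spec.channel_labels),
                        events=[(onset, code)], meta=meta)


@dataclass
class Instance:
    """One participant × condition cell of the cohort design."""

    participant: str
    group: str
    condition: str
    trials: list[tuple[FlowTimeseries, EEGRecording]]


@dataclass
class Cohort:
    spec: SynthSpec
    flows: list[FlowTimeseries]          # direct-condition stimulus flows
    instances: list[Instance]

    def __len__(self) -> int:
        return len(self.instances)


def make_cohort(spec: SynthSpec) -> Cohort:
    """Full synthetic study: every participant × condition × video.

    The same ``n_videos_per_condition`` stimulus flows are shown to every
    participant (as in the real design); the reversed condition uses the
    time-reversed flow series of the same videos.
    """
    flows = [make_flow_series(spec, v)
             for v in range(spec.n_videos_per_condition)]
    instances = []
    for pid in spec.participant_ids():
        for condition in ("direct", "reversed"):
            trials = []
            for fl in flows:
                stim = fl if condition == "direct" else fl.reversed()
                rec = make_eeg(spec, stim, pid, condition)
                trials.append((stim, rec))
            instances.append(Instance(pid, pid[0], condition, trials))
    return Cohort(spec, flows, instances)
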