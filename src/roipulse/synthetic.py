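"""Synthetic pulse-modulated study data with known ground truth.

The generator emulates the statistical structure the evaluation pipeline
assumes about facial video: per-ROI mean-RGB traces whose pulsatile
amplitude differs by region, a quasi-periodic pulse waveform with a first
harmonic and a slowly drifting rate, white sensor noise, illumination drift
common to all channels, and sporadic motion-artifact bursts.  Ground-truth
contact-PPG and HR series are sampled at their own (higher) rate to exercise
the alignment step.

The pulse enters the color channels through a green-dominant gain vector,
reflecting that the green channel carries the strongest cardiac signal in
reflectance video.  The default per-ROI amplitudes grade the 28 regions so
that the glabella, forehead, malar and upper-nasal-dorsum regions carry the
strongest pulse; amplitudes are in mean-intensity units (a value of 1 swings
the green channel by about +/-1 of 255), matching the sub-percent pulsatile
contrast of real skin.

A small frame renderer paints every ROI polygon with its generating trace
color on a synthetic face layout, producing frame sequences plus matching
landmark records for end-to-end tests of the raw-signal-extraction phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError
from .hr_estimation import HRSeries
from .roi_scheme import N_LANDMARKS, FaceMeshFrame, RGBTrace, load_roi_table, polygon_mask

HR_MIN_BPM, HR_MAX_BPM = 48.0, 180.0

#: activity noise presets: low-motion cognitive-task recording vs a
#: motion-heavy recording with stronger drift and frequent artifact bursts
ACTIVITY_PRESETS: dict[str, dict[str, float]] = {
    "cognitive": dict(white_sigma=0.4, drift_amplitude=1.0, drift_period=30.0,
                      burst_rate=0.05, burst_amplitude=3.0),
    "motion": dict(white_sigma=0.8, drift_amplitude=2.0, drift_period=15.0,
                   burst_rate=0.2, burst_amplitude=6.0),
}

_STRONG = {4: 3.0, 1: 2.6, 2: 2.5, 3: 2.4, 22: 2.3, 23: 2.2, 5: 2.1}


def default_roi_amplitudes() -> dict[int, float]:
    """Graded pulsatile amplitudes: seven strong regions (glabella first),
    the remaining 21 fading from 1.4 down to 0.2 in index order."""
    amps = dict(_STRONG)
    weak = [r.index_k for r in load_roi_table() if r.index_k not in _STRONG]
    for k, a in zip(weak, np.linspace(1.4, 0.2, len(weak))):
        amps[k] = float(a)
    return amps


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording (pure function of ``seed``)."""

    seed: int = 0
    fps: float = 30.0
    duration: float = 30.0
    hr_trajectory: tuple[tuple[float, float], ...] = ((0.0, 72.0), (30.0, 72.0))
    harmonic_ratio: float = 0.3
    roi_amplitudes: Mapping[int, float] | None = None
    baseline: tuple[float, float, float] = (160.0, 120.0, 95.0)
    pulse_gains: tuple[float, float, float] = (0.4, 1.0, 0.6)
    white_sigma: float = 0.4
    drift_amplitude: float = 1.0
    drift_period: float = 30.0
    burst_rate: float = 0.05
    burst_amplitude: float = 3.0
    gt_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.fps <= 8:
            raise ConfigError("fps must exceed 8 Hz")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.gt_rate <= 0:
            raise ConfigError("gt_rate must be positive")
        traj = np.asarray(self.hr_trajectory, dtype=float)
        if traj.ndim != 2 or traj.shape[1] != 2 or traj.shape[0] < 1:
            raise ConfigError("hr_trajectory must be a sequence of (time, BPM) pairs")
        if np.any(np.diff(traj[:, 0]) < 0):
            raise ConfigError("hr_trajectory times must be non-decreasing")
        if np.any(traj[:, 1] < HR_MIN_BPM) or np.any(traj[:, 1] > HR_MAX_BPM):
            raise ConfigError(
                f"hr_trajectory outside {HR_MIN_BPM}-{HR_MAX_BPM} BPM"
            )
        for name in ("harmonic_ratio", "white_sigma", "drift_amplitude",
                     "burst_rate", "burst_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.roi_amplitudes is not None:
            if any(a < 0 for a in self.roi_amplitudes.values()):
                raise ConfigError("roi_amplitudes must be non-negative")

    @property
    def amplitudes(self) -> dict[int, float]:
        if self.roi_amplitudes is None:
            return default_roi_amplitudes()
        return dict(self.roi_amplitudes)


@dataclass
class TimeSeries:
    """A plain sampled waveform (used for the contact-PPG ground truth)."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def _hr_at(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    traj = np.asarray(config.hr_trajectory, dtype=float)
    return np.interp(t, traj[:, 0], traj[:, 1])


def _phase(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    hr = _hr_at(config, t)
    return cumulative_trapezoid(2.0 * np.pi * hr / 60.0, t, initial=0.0)


def _waveform(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    phi = _phase(config, t)
    return np.sin(phi) + config.harmonic_ratio * np.sin(2.0 * phi)


def simulate_pulse(config: SimulationConfig) -> tuple[TimeSeries, HRSeries]:
    """Ground-truth contact-PPG waveform and HR series at ``gt_rate``."""
    t = np.arange(0.0, config.duration, 1.0 / config.gt_rate)
    cppg = TimeSeries(t, _waveform(config, t))
    hr = HRSeries(t, _hr_at(config, t))
    return cppg, hr


def simulate_traces(
    config: SimulationConfig,
) -> tuple[dict[int, RGBTrace], TimeSeries, HRSeries]:
    """Per-ROI mean-RGB traces plus the matching ground truth.

    ROI ``k``'s trace is ``baseline + amplitude(k) * p(t) * gains`` plus
    white noise (independent per ROI and channel), illumination drift
    (shared by all ROIs and channels) and motion bursts (correlated
    transients at Poisson event times, shared across ROIs), clipped to the
    0-255 intensity scale.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration, 1.0 / config.fps)
    n = t.size
    pulse = _waveform(config, t)
    amps = config.amplitudes
    rois = load_roi_table()

    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = config.drift_amplitude * np.sin(
        2 * np.pi * t / config.drift_period + drift_phase
    )

    burst = np.zeros(n)
    n_events = rng.poisson(config.burst_rate * config.duration)
    event_times = np.sort(rng.uniform(0, config.duration, n_events))
    signs = rng.choice([-1.0, 1.0], n_events)
    for t0, s in zip(event_times, signs):
        after = t >= t0
        burst[after] += s * np.exp(-(t[after] - t0) / 0.25)
    burst *= config.burst_amplitude

    gains = np.asarray(config.pulse_gains)
    base = np.asarray(config.baseline)
    traces: dict[int, RGBTrace] = {}
    for roi in rois:
        amp = amps.get(roi.index_k, 0.0)
        clean = base + amp * pulse[:, None] * gains
        noisy = (
            clean
            + rng.normal(0.0, config.white_sigma, (n, 3))
            + drift[:, None]
            + burst[:, None]
        )
        traces[roi.index_k] = RGBTrace(
            config.fps, np.clip(noisy, 0.0, 255.0), np.ones(n, dtype=bool)
        )
    cppg, hr = simulate_pulse(config)
    return traces, cppg, hr


@dataclass
class StudyUnit:
    """One participant x activity recording."""

    participant: str
    activity: str
    config: SimulationConfig
    traces: dict[int, RGBTrace]
    cppg: TimeSeries
    hr: HRSeries


@dataclass
class SyntheticStudy:
    seed: int
    units: list[StudyUnit]

    @property
    def participants(self) -> list[str]:
        return sorted({u.participant for u in self.units})

    @property
    def activities(self) -> list[str]:
        return sorted({u.activity for u in self.units})


def make_study(
    seed: int,
    n_participants: int = 6,
    activities: Mapping[str, Mapping[str, float]] | None = None,
    base_config: SimulationConfig | None = None,
) -> SyntheticStudy:
    """Simulate a multi-participant, multi-activity study.

    Each participant gets their own slowly drifting HR trajectory; each
    activity applies its noise preset on top of the shared base
    configuration.  Deterministic given ``seed``.
    """
    if activities is None:
        activities = ACTIVITY_PRESETS
    base = base_config if base_config is not None else SimulationConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants * (len(activities) + 1))
    units: list[StudyUnit] = []
    i = 0
    for p in range(n_participants):
        rng = np.random.default_rng(children[i]); i += 1
        start = rng.uniform(60.0, 100.0)
        end = float(np.clip(start + rng.uniform(-12.0, 12.0), 50.0, 170.0))
        traj = ((0.0, float(start)), (base.duration, end))
        for act, preset in activities.items():
            unit_seed = int(children[i].generate_state(1)[0] % (2**31)); i += 1
            cfg = replace(base, seed=unit_seed, hr_trajectory=traj, **preset)
            traces, cppg, hr = simulate_traces(cfg)
            units.append(StudyUnit(f"p{p + 1:02d}", act, cfg, traces, cppg, hr))
    return SyntheticStudy(seed, units)


# ---------------------------------------------------------------------------
# frame rendering


@dataclass(frozen=True)
class LandmarkTemplate:
    """Static 468-point landmark layout used by the frame renderer."""

    height: int
    width: int
    points: np.ndarray  # (468, 2)


def load_landmark_template() -> LandmarkTemplate:
    """The synthetic face-layout template shipped with the package."""
    with resources.files("roipulse.data").joinpath(
        "synthetic_face_template.json"
    ).open() as fh:
        raw = json.load(fh)
    pts = np.asarray(raw["points"], dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ConfigError("template must provide 468 (x, y) points")
    return LandmarkTemplate(int(raw["height"]), int(raw["width"]), pts)


def render_frames(
    config: SimulationConfig,
    template: LandmarkTemplate | None = None,
    jitter_px: float = 0.0,
    occluded_frames: Sequence[int] = (),
) -> tuple[np.ndarray, list[FaceMeshFrame], dict[int, RGBTrace], TimeSeries, HRSeries]:
    """Paint each ROI polygon with its generating trace color, frame by frame.

    Returns ``(frames, mesh_frames, traces, cppg, hr)`` where ``frames`` is
    a ``(n, H, W, 3)`` uint8 array and ``mesh_frames`` the matching landmark
    records.  ``jitter_px`` adds a bounded random-walk rigid shift of the
    whole landmark set (polygons are painted at the shifted positions, so
    the landmarks stay consistent with the pixels).  Frames listed in
    ``occluded_frames`` have their landmarks pushed far off-frame, emulating
    a lost face detection.
    """
    if template is None:
        template = load_landmark_template()
    rois = load_roi_table()
    for roi in rois:
        m = polygon_mask(FaceMeshFrame(0, template.points), roi,
                         template.height, template.width)
        if m.pixel_count == 0:
            raise ConfigError(f"template polygon {roi.index_k} has zero area")
    traces, cppg, hr = simulate_traces(config)
    n = next(iter(traces.values())).n_frames
    rng = np.random.default_rng(config.seed + 1)
    background = rng.integers(0, 256, (template.height, template.width, 3),
                              dtype=np.uint8)
    if jitter_px > 0:
        steps = rng.normal(0.0, jitter_px / 3.0, (n, 2))
        offsets = np.clip(np.cumsum(steps, axis=0), -jitter_px, jitter_px)
    else:
        offsets = np.zeros((n, 2))
    occluded = set(int(i) for i in occluded_frames)

    frames = np.empty((n, template.height, template.width, 3), dtype=np.uint8)
    mesh_frames: list[FaceMeshFrame] = []
    for i in range(n):
        pts = template.points + offsets[i]
        if i in occluded:
            pts = pts + 4.0 * max(template.width, template.height)
        mesh = FaceMeshFrame(i, pts)
        mesh_frames.append(mesh)
        img = background.copy()
        for roi in rois:
            m = polygon_mask(mesh, roi, template.height, template.width)
            if m.pixel_count:
                color = np.clip(np.round(traces[roi.index_k].samples[i]), 0, 255)
                img[m.mask] = color.astype(np.uint8)
        frames[i] = img
    return frames, mesh_frames, traces, cppg, hr
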