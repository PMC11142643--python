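"""Seeded generators for synthetic calcium sessions, optogenetic sessions,
swim trajectories, and neuron-blob image stacks with known ground truth.

The generators emulate the statistical structure the analysis assumes:

* Shock-paradigm calcium sessions at 5.2 Hz with two neuronal archetypes.
  ``quiet_sustained`` neurons show sparse spontaneous transients and a
  long-lasting evoked response to the shock; ``oscillatory_brief`` neurons
  superimpose a slow (tens of seconds) suprathreshold oscillation on their
  spontaneous activity and respond to the shock only briefly.
* Optogenetic stimulation sessions at 2.6 Hz: 200 baseline frames, 20
  stimulation frames in which the mean signal is ``gain`` times the
  baseline mean, 150 post frames; the two laser-switch boundary frames can
  be marked missing to emulate configuration-switch latency.
* 60-fps bout-structured swim trajectories in a 6-cm arena: alternating
  movement phases and immobile gaps of at least 1 s, an optional
  post-shock hyperactivity epoch, and an "ablated" profile with longer
  phases and wider heading jitter at an unchanged phase count.

Every generator takes an explicit seed and returns a
:class:`~larvaquant.types.GroundTruthLog` consistent with its output by
construction. There is no global random state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    FluorescenceTrace,
    GroundTruthLog,
    ImageStack,
    LarvaQuantError,
    Trajectory,
)

__all__ = [
    "SyntheticCalciumSpec",
    "SyntheticTrajectorySpec",
    "SyntheticStackSpec",
    "generate_calcium_traces",
    "generate_reachr_session",
    "generate_trajectory",
    "generate_image_stack",
    "transient_kernel",
]

CALCIUM_ARCHETYPES = ("quiet_sustained", "oscillatory_brief")
TRAJECTORY_PROFILES = ("control", "ablated_rln3a_NI", "post_shock")

# Archetype-dependent defaults, calibrated to reproduce the qualitative
# ordering between the two populations: the oscillatory archetype has more
# suprathreshold fluctuations per recording and a much shorter evoked decay.
_ARCHETYPE_DEFAULTS = {
    "quiet_sustained": dict(
        spont_event_rate=0.5,  # events/min
        evoked_decay_tau_s=20.0,
        oscillation_amplitude=0.0,
    ),
    "oscillatory_brief": dict(
        spont_event_rate=1.5,
        evoked_decay_tau_s=4.0,
        oscillation_amplitude=20.0,
    ),
}

# Profile-dependent trajectory defaults. Phase counts and lengths are set to
# the observed baseline-behaviour calibration (about 7.7 phases of 7.4 s per
# 115 s for controls; longer phases, wider heading jitter and a faster swim
# for the NI-ablated hyperactive profile at the same phase count).
_PROFILE_DEFAULTS = {
    "control": dict(
        n_phases_mean=7.74,
        phase_len_mean_s=7.35,
        speed_cm_s=0.35,
        heading_change_sd_deg=20.0,
    ),
    "ablated_rln3a_NI": dict(
        n_phases_mean=7.74,
        phase_len_mean_s=10.38,
        speed_cm_s=0.53,
        heading_change_sd_deg=35.0,
    ),
    "post_shock": dict(
        n_phases_mean=7.74,
        phase_len_mean_s=7.35,
        speed_cm_s=0.35,
        heading_change_sd_deg=20.0,
    ),
}


@dataclass
class SyntheticCalciumSpec:
    """Parameters of a synthetic shock-paradigm calcium session.

    Archetype-dependent fields (``spont_event_rate``,
    ``evoked_decay_tau_s``, ``oscillation_amplitude``) default to the
    archetype calibration when left as None.
    """

    archetype: str
    seed: int
    n_neurons: int = 10
    rate_hz: float = 5.2
    n_frames: int = 2000
    shock_frame: int | None = 600
    spont_event_rate: float | None = None  # events per minute
    event_amplitude: float = 30.0  # a.u.
    rise_tau_s: float = 1.0
    decay_tau_s: float = 5.0
    evoked_amplitude: float = 50.0
    evoked_decay_tau_s: float | None = None
    baseline_level: float = 100.0
    noise_sd: float = 2.0
    oscillation_amplitude: float | None = None
    oscillation_period_s: float = 30.0
    # four decay constants so consecutive transients resolve as distinct peaks
    min_event_separation_s: float = 12.0

    def __post_init__(self) -> None:
        if self.archetype not in CALCIUM_ARCHETYPES:
            raise LarvaQuantError(
                f"archetype must be one of {CALCIUM_ARCHETYPES}, "
                f"got {self.archetype!r}"
            )
        defaults = _ARCHETYPE_DEFAULTS[self.archetype]
        for name, value in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, value)
        if self.rate_hz <= 0:
            raise LarvaQuantError("rate_hz must be > 0")
        if self.n_frames < 1 or self.n_neurons < 1:
            raise LarvaQuantError("n_frames and n_neurons must be >= 1")
        for name in ("rise_tau_s", "decay_tau_s", "evoked_decay_tau_s",
                     "oscillation_period_s"):
            if getattr(self, name) <= 0:
                raise LarvaQuantError(f"{name} must be > 0")
        if self.spont_event_rate < 0:
            raise LarvaQuantError("spont_event_rate must be >= 0")
        if self.event_amplitude <= 0 or self.baseline_level <= 0:
            raise LarvaQuantError(
                "event_amplitude and baseline_level must be > 0"
            )
        if self.evoked_amplitude < 0 or self.noise_sd < 0:
            raise LarvaQuantError("evoked_amplitude and noise_sd must be >= 0")
        if self.shock_frame is not None and not (
            0 <= self.shock_frame < self.n_frames
        ):
            raise LarvaQuantError(
                f"shock_frame {self.shock_frame} outside [0, {self.n_frames})"
            )


@dataclass
class SyntheticTrajectorySpec:
    """Parameters of a synthetic bout-structured swim trajectory.

    ``n_phases_mean`` is the expected phase count per 115-s analysis
    window; profile-dependent fields default to the profile calibration
    when left as None. Only the ``post_shock`` profile inserts a
    hyperactive epoch after the stimulus frame.
    """

    profile: str
    seed: int
    duration_s: int = 240
    fps: int = 60
    n_phases_mean: float | None = None
    phase_len_mean_s: float | None = None
    speed_cm_s: float | None = None
    heading_change_sd_deg: float | None = None
    gap_min_s: int = 1
    arena_cm: float = 6.0
    shock_s: int | None = 120
    hyper_speed_cm_s: float = 1.2
    hyper_duration_s: int = 5

    def __post_init__(self) -> None:
        if self.profile not in TRAJECTORY_PROFILES:
            raise LarvaQuantError(
                f"profile must be one of {TRAJECTORY_PROFILES}, "
                f"got {self.profile!r}"
            )
        defaults = _PROFILE_DEFAULTS[self.profile]
        for name, value in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, value)
        if self.fps <= 0:
            raise LarvaQuantError("fps must be > 0")
        if self.duration_s < 1:
            raise LarvaQuantError("duration_s must be >= 1")
        if self.gap_min_s < 1:
            raise LarvaQuantError(
                "gap_min_s must be >= 1 so inter-phase gaps register as "
                "immobile seconds after per-second binning"
            )
        if self.n_phases_mean < 0 or self.phase_len_mean_s <= 0:
            raise LarvaQuantError("invalid phase parameters")
        if self.n_phases_mean > 0 and self.duration_s < self.phase_len_mean_s:
            raise LarvaQuantError("duration too short for one phase")
        if self.arena_cm <= 0 or self.speed_cm_s < 0:
            raise LarvaQuantError("invalid arena or speed")
        if self.shock_s is not None and not (
            0 <= self.shock_s < self.duration_s
        ):
            raise LarvaQuantError("shock_s outside the recording")


@dataclass
class SyntheticStackSpec:
    """Parameters of a synthetic neuron-blob image stack."""

    n_frames: int
    height_px: int
    width_px: int
    neuron_centers: list
    blob_sigma_px: float
    traces: list
    background_level: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.height_px < 1 or self.width_px < 1:
            raise LarvaQuantError("stack dimensions must be >= 1")
        if self.blob_sigma_px <= 0:
            raise LarvaQuantError("blob_sigma_px must be > 0")
        if len(self.traces) != len(self.neuron_centers):
            raise LarvaQuantError("need exactly one trace per neuron center")
        for r, c in self.neuron_centers:
            if not (0 <= r < self.height_px and 0 <= c < self.width_px):
                raise LarvaQuantError(f"center ({r}, {c}) outside the frame")
        for t in self.traces:
            if len(t) != self.n_frames:
                raise LarvaQuantError("trace length must equal n_frames")
        if self.background_level < 0 or self.noise_sd < 0:
            raise LarvaQuantError("background_level and noise_sd must be >= 0")


def transient_kernel(
    rise_tau_s: float, decay_tau_s: float, rate_hz: float
) -> np.ndarray:
    """Unit-peak calcium transient kernel (1 - e^(-t/rise)) e^(-t/decay).

    The standard GCaMP-like difference-of-exponentials shape, sampled at the
    acquisition rate over ~8 decay constants and scaled to unit peak.
    """
    n = max(2, int(np.ceil((8 * decay_tau_s + 5 * rise_tau_s) * rate_hz)))
    t = np.arange(n) / rate_hz
    k = (1 - np.exp(-t / rise_tau_s)) * np.exp(-t / decay_tau_s)
    return k / k.max()


def _add_transient(
    trace: np.ndarray, frame: int, amplitude: float, kernel: np.ndarray
) -> None:
    end = min(len(trace), frame + len(kernel))
    if end > frame:
        trace[frame:end] += amplitude * kernel[: end - frame]


def _spaced_event_frames(
    rng: np.random.Generator,
    n_events: int,
    n_frames: int,
    min_sep: int,
    end_margin: int = 0,
) -> np.ndarray:
    """Uniformly placed event frames with a refractory minimum separation.

    Placement is exact: with n events of minimum separation m in
    [0, L - end_margin), draw n sorted uniforms over the remaining slack and
    add back i*m. ``end_margin`` keeps events away from the recording end so
    each transient has room to rise. If the recording cannot fit n events,
    the count saturates at the maximum that fits.
    """
    if n_events == 0:
        return np.empty(0, dtype=int)
    usable = max(1, n_frames - end_margin)
    min_sep = max(min_sep, 1)
    n_events = min(n_events, (usable - 1) // min_sep + 1)
    slack = usable - 1 - (n_events - 1) * min_sep
    offsets = np.sort(rng.uniform(0, slack + 1, size=n_events))
    frames = (offsets + np.arange(n_events) * min_sep).astype(int)
    return frames


def generate_calcium_traces(
    spec: SyntheticCalciumSpec,
) -> tuple[list[FluorescenceTrace], GroundTruthLog]:
    """Simulate a cohort of single-neuron calcium traces for one session.

    Each trace is the baseline level plus Poisson-timed spontaneous
    double-exponential transients, an evoked transient at the shock frame,
    an optional slow sinusoidal modulation (oscillatory archetype), and
    Gaussian noise. The truth log records every spontaneous/evoked event
    frame, oscillation crest frames, and the noiseless traces.
    """
    rng = np.random.default_rng(spec.seed)
    duration_min = spec.n_frames / spec.rate_hz / 60.0
    spont_kernel = transient_kernel(
        spec.rise_tau_s, spec.decay_tau_s, spec.rate_hz
    )
    evoked_kernel = transient_kernel(
        spec.rise_tau_s, spec.evoked_decay_tau_s, spec.rate_hz
    )
    min_sep = int(round(spec.min_event_separation_s * spec.rate_hz))
    period_frames = spec.oscillation_period_s * spec.rate_hz

    traces: list[FluorescenceTrace] = []
    truth = GroundTruthLog()
    for j in range(spec.n_neurons):
        roi_id = f"neuron{j:03d}"
        clean = np.full(spec.n_frames, spec.baseline_level, dtype=float)
        n_events = rng.poisson(spec.spont_event_rate * duration_min)
        # keep events clear of the recording end so each transient can rise
        # to a measurable peak
        end_margin = int(
            np.ceil((3 * spec.rise_tau_s + spec.decay_tau_s) * spec.rate_hz)
        )
        event_frames = _spaced_event_frames(
            rng, int(n_events), spec.n_frames, min_sep, end_margin
        )
        for f in event_frames:
            _add_transient(clean, int(f), spec.event_amplitude, spont_kernel)
        all_events = list(event_frames)
        if spec.shock_frame is not None and spec.evoked_amplitude > 0:
            _add_transient(
                clean, spec.shock_frame, spec.evoked_amplitude, evoked_kernel
            )
            all_events.append(spec.shock_frame)
        crests = np.empty(0, dtype=int)
        if spec.oscillation_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            frames = np.arange(spec.n_frames)
            clean += spec.oscillation_amplitude * np.sin(
                2 * np.pi * frames / period_frames + phase
            )
            # crest frames: sin argument congruent to pi/2
            first = (np.pi / 2 - phase) / (2 * np.pi) * period_frames
            first %= period_frames
            crests = np.arange(first, spec.n_frames, period_frames)
            crests = np.round(crests).astype(int)
            crests = crests[(crests >= 0) & (crests < spec.n_frames)]
        noisy = clean + rng.normal(0, spec.noise_sd, size=spec.n_frames)
        traces.append(
            FluorescenceTrace(roi_id=roi_id, rate_hz=spec.rate_hz, values=noisy)
        )
        truth.event_frames[roi_id] = np.array(sorted(all_events), dtype=int)
        truth.oscillation_crest_frames[roi_id] = crests
        truth.true_traces[roi_id] = clean
    return traces, truth


def generate_reachr_session(
    spec: SyntheticCalciumSpec,
    gain: float,
    n_baseline: int = 200,
    n_stim: int = 20,
    n_post: int = 150,
    mark_gaps: bool = True,
) -> tuple[FluorescenceTrace, GroundTruthLog]:
    """Simulate one optogenetic-stimulation session.

    The session has ``n_baseline`` frames of spontaneous signal, ``n_stim``
    frames during which the mean signal is ``gain`` times the baseline mean,
    and ``n_post`` recovery frames (370 frames total at the defaults, 142.3 s
    at 2.6 Hz). With ``mark_gaps`` the frames at the two laser-switch
    boundaries are set missing, emulating switch latency.
    """
    if gain < 0:
        raise LarvaQuantError(f"gain must be >= 0, got {gain}")
    rng = np.random.default_rng(spec.seed)
    n_total = n_baseline + n_stim + n_post
    clean = np.full(n_total, spec.baseline_level, dtype=float)
    stim = (n_baseline, n_baseline + n_stim)
    clean[stim[0] : stim[1]] = gain * spec.baseline_level
    noisy = clean + rng.normal(0, spec.noise_sd, size=n_total)
    if mark_gaps:
        noisy[stim[0]] = np.nan  # laser-on switch
        noisy[stim[1] - 1] = np.nan  # laser-off switch
    trace = FluorescenceTrace(
        roi_id="session", rate_hz=spec.rate_hz, values=noisy
    )
    truth = GroundTruthLog(stim_window=stim, true_traces={"session": clean})
    return trace, truth


def _phase_layout(
    rng: np.random.Generator, spec: SyntheticTrajectorySpec
) -> list[tuple[int, int]]:
    """Alternating-renewal layout of integer-second movement phases.

    Phase lengths are Poisson around the mean (>= 1 s); gaps are
    ``gap_min_s`` plus a Poisson remainder whose mean makes the expected
    phase count per 115 s equal ``n_phases_mean``.
    """
    if spec.n_phases_mean == 0:
        return []
    cycle_mean = 115.0 / spec.n_phases_mean
    gap_mean = max(float(spec.gap_min_s), cycle_mean - spec.phase_len_mean_s)
    intervals: list[tuple[int, int]] = []
    t = int(rng.poisson(gap_mean))
    while t < spec.duration_s:
        length = max(1, int(rng.poisson(spec.phase_len_mean_s)))
        end = min(t + length, spec.duration_s)
        intervals.append((t, end))
        t = end + spec.gap_min_s + int(
            rng.poisson(max(0.0, gap_mean - spec.gap_min_s))
        )
    return intervals


def _fold(p: np.ndarray, limit: float) -> np.ndarray:
    """Reflect unbounded coordinates into [0, limit] (mirror boundaries)."""
    return limit - np.abs(np.mod(p, 2 * limit) - limit)


def generate_trajectory(
    spec: SyntheticTrajectorySpec,
    phase_intervals: list[tuple[int, int]] | None = None,
) -> tuple[Trajectory, GroundTruthLog]:
    """Simulate a bout-structured swim trajectory.

    Movement seconds advance the larva at ``speed_cm_s`` with per-frame
    Gaussian heading jitter; immobile seconds hold the position exactly.
    Positions are reflected at the arena walls. An explicit
    ``phase_intervals`` list of integer-second (start, end) pairs overrides
    the random layout (used to program exact phase structures). The
    ``post_shock`` profile forces a hyperactive epoch of
    ``hyper_duration_s`` seconds at ``hyper_speed_cm_s`` after the shock.
    """
    rng = np.random.default_rng(spec.seed)
    if phase_intervals is None:
        intervals = _phase_layout(rng, spec)
    else:
        intervals = [(int(s), int(e)) for s, e in phase_intervals]
        for (s, e) in intervals:
            if not (0 <= s < e <= spec.duration_s):
                raise LarvaQuantError(f"phase ({s}, {e}) outside the recording")

    fps = int(spec.fps)
    n_sec = spec.duration_s
    moving = np.zeros(n_sec, dtype=bool)
    for s, e in intervals:
        moving[s:e] = True
    speed = np.where(moving, spec.speed_cm_s, 0.0).astype(float)

    if spec.profile == "post_shock" and spec.shock_s is not None:
        h0 = spec.shock_s
        h1 = min(n_sec, h0 + spec.hyper_duration_s)
        moving[h0:h1] = True
        speed[h0:h1] = spec.hyper_speed_cm_s

    n_steps = n_sec * fps
    step_len = np.repeat(speed / fps, fps)
    jitter = rng.normal(0, spec.heading_change_sd_deg, size=n_steps)
    heading = np.cumsum(np.radians(jitter)) + rng.uniform(0, 2 * np.pi)
    dx = np.where(step_len > 0, step_len * np.cos(heading), 0.0)
    dy = np.where(step_len > 0, step_len * np.sin(heading), 0.0)
    x0 = rng.uniform(0.25, 0.75) * spec.arena_cm
    y0 = rng.uniform(0.25, 0.75) * spec.arena_cm
    x = _fold(x0 + np.concatenate(([0.0], np.cumsum(dx))), spec.arena_cm)
    y = _fold(y0 + np.concatenate(([0.0], np.cumsum(dy))), spec.arena_cm)

    shock_frame = (
        spec.shock_s * fps if spec.shock_s is not None else None
    )
    traj = Trajectory(fps=float(fps), x=x, y=y, shock_frame=shock_frame)
    # report the realized per-second movement runs (hyper epoch may merge
    # with adjacent programmed phases)
    padded = np.concatenate(([False], moving, [False])).astype(int)
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    truth = GroundTruthLog(
        phase_intervals=[(int(s), int(e)) for s, e in zip(starts, ends)],
        headings_deg=np.degrees(heading),
    )
    return traj, truth


def generate_image_stack(
    spec: SyntheticStackSpec,
) -> tuple[ImageStack, GroundTruthLog]:
    """Render per-neuron traces as Gaussian blobs on a noisy background.

    Each frame is ``background_level`` plus each neuron's trace value scaled
    by a unit-peak Gaussian blob at its center, plus Gaussian noise, clipped
    at zero. The truth log holds the true traces and disc ROI masks of
    radius two blob sigmas around each center.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    rr, cc = np.mgrid[0:h, 0:w]
    stack = np.full((spec.n_frames, h, w), spec.background_level, dtype=float)
    truth = GroundTruthLog()
    for center, trace in zip(spec.neuron_centers, spec.traces):
        r0, c0 = center
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        blob = np.exp(-d2 / (2 * spec.blob_sigma_px**2))
        stack += trace.values[:, None, None] * blob[None, :, :]
        truth.true_traces[trace.roi_id] = trace.values.copy()
        truth.roi_masks[trace.roi_id] = d2 <= (2 * spec.blob_sigma_px) ** 2
    if spec.noise_sd > 0:
        stack += rng.normal(0, spec.noise_sd, size=stack.shape)
    np.clip(stack, 0, None, out=stack)
    rate = spec.traces[0].rate_hz if spec.traces else 5.2
    return ImageStack(intensities=stack, rate_hz=rate), truth
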