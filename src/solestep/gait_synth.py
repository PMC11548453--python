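"""Synthetic multi-activity foot-IMU gait generator.

Emulates trials in which a participant wearing a sole-embedded 6-axis IMU
(200 Hz, ±16 g, ±2000 °/s) completes a scripted multi-activity track —
stair descent, walking at three speeds, running, stomping, high knees,
butt kicks — interleaved with standing rests, after a three-heel-strike
clock-synchronization prelude.

The signal model is deliberately phenomenological: each step is a swing
burst (half-sine angular-rate burst with a random 3-D axis, gravity tilt
and motion acceleration, a short heel-strike transient) followed by a
quiescent foot-flat interval (gyro ≈ 0, acceleration norm ≈ 1 g), plus
Gaussian sensor noise.  It reproduces the label/feature statistical
structure of real sole-IMU recordings (channel-to-label correlations,
class balance, cadence range, subject heterogeneity) without claiming
biomechanical fidelity.

Ground truth is exact by construction: per-step foot-flat onsets, flat
intervals, a sole pitch-angle trace, and per-sample activity codes.  A
frame-rate annotation table (60 fps, foot status 0/1/2) emulates manual
video labeling, including contiguous "undetermined" runs where the foot
would be occluded on camera.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording_io import (
    ACC_RANGE_G,
    GYRO_RANGE_DPS,
    AnnotationTable,
    ImuRecording,
    compute_norms,
)

__all__ = [
    "ActivitySpec",
    "SubjectSpec",
    "TrackScript",
    "GroundTruth",
    "ACTIVITIES",
    "default_track_script",
    "simulate_subject",
    "simulate_cohort",
    "foot_angle_to_status",
    "inject_undetermined",
]

#: video annotation frame rate (fps)
ANNOTATION_FPS = 60.0
#: default IMU sampling rate (Hz)
DEFAULT_FS = 200.0
#: sole-angle threshold separating foot-flat from transition (degrees)
FLAT_ANGLE_THRESHOLD_DEG = 3.0
#: default fraction of annotation frames relabeled "undetermined";
#: ratio of undetermined to total labeled video frames in a typical
#: lateral-camera protocol (43,943 / 454,596)
DEFAULT_UNDETERMINED_FRACTION = 0.097


@dataclass(frozen=True)
class ActivitySpec:
    """One scripted activity segment.

    cadence is the stepping rate of the *instrumented* foot (steps/min),
    i.e. half the whole-body cadence.  flat_fraction is the fraction of
    each per-step period during which the sole is flat on the ground.
    """

    category_id: int
    name: str
    cadence: float = 0.0           # steps/min, instrumented foot
    flat_fraction: float = 0.0     # of the per-step period
    gyro_swing_amp: float = 0.0    # °/s peak during swing
    acc_impact_amp: float = 0.0    # g peak heel-strike transient
    n_steps: int = 0
    duration_s: float = 0.0        # used when n_steps == 0 (standing)
    swing_angle_deg: float = 30.0  # peak sole pitch during swing
    acc_swing_amp: float | None = None  # g; default 0.4 × impact amp

    def __post_init__(self) -> None:
        if self.n_steps > 0:
            if not (0.0 < self.flat_fraction < 1.0):
                raise ValueError(
                    f"{self.name}: flat_fraction must lie in (0, 1) for "
                    f"stepping activities, got {self.flat_fraction}"
                )
            if self.cadence <= 0:
                raise ValueError(f"{self.name}: cadence must be > 0 when n_steps > 0")

    @property
    def period_s(self) -> float:
        """Per-step period in seconds (instrumented foot)."""
        return 60.0 / self.cadence if self.cadence > 0 else 0.0

    @property
    def segment_duration_s(self) -> float:
        return self.n_steps * self.period_s if self.n_steps > 0 else self.duration_s


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject heterogeneity: cadence/amplitude scaling and noise floors."""

    subject_id: int
    cadence_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0
    noise_sd_acc: float = 0.035   # g
    noise_sd_gyro: float = 7.0    # °/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_multiplier <= 0 or self.amplitude_multiplier <= 0:
            raise ValueError("subject multipliers must be > 0")


@dataclass(frozen=True)
class TrackScript:
    """Ordered activity segments preceded by a 3-heel-strike sync prelude."""

    segments: tuple[ActivitySpec, ...]
    prelude_duration_s: float = 4.0
    prelude_strike_times: tuple[float, ...] = (1.0, 1.75, 2.5)

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("TrackScript needs at least one segment")
        if len(self.prelude_strike_times) != 3:
            raise ValueError("sync prelude must contain exactly 3 heel strikes")

    @property
    def total_steps(self) -> int:
        return sum(seg.n_steps for seg in self.segments)


@dataclass
class GroundTruth:
    """Exact per-sample and per-event truth on the trial clock (t=0 at sync)."""

    fs: float
    time: np.ndarray                      # s, trial clock
    foot_angle_deg: np.ndarray            # sole pitch angle
    status: np.ndarray                    # 1 foot-flat/stationary, 0 moving
    activity: np.ndarray                  # per-sample category code
    step_event_times: np.ndarray          # s, flat onset per step
    flat_intervals: list[tuple[float, float]]  # per-step [start, end)


# Per-activity defaults.  Cadences are per instrumented foot; amplitudes are
# pre-subject-multiplier peaks; flat fractions follow the stance sub-phase
# shrinking as locomotion speeds up.
ACTIVITIES: dict[str, ActivitySpec] = {
    "standing": ActivitySpec(0, "standing", duration_s=1.0),
    "slow_walk": ActivitySpec(1, "slow_walk", 40.0, 0.45, 250.0, 1.2,
                              swing_angle_deg=27.5),
    "moderate_walk": ActivitySpec(2, "moderate_walk", 50.0, 0.40, 350.0, 1.6,
                                  swing_angle_deg=33.0),
    "fast_walk": ActivitySpec(3, "fast_walk", 60.0, 0.34, 450.0, 2.0,
                              swing_angle_deg=38.5),
    "run": ActivitySpec(4, "run", 80.0, 0.16, 700.0, 3.5,
                        swing_angle_deg=49.5),
    "stomping": ActivitySpec(5, "stomping", 60.0, 0.30, 400.0, 2.5,
                             swing_angle_deg=35.0),
    "high_knees": ActivitySpec(6, "high_knees", 80.0, 0.16, 600.0, 2.0,
                               swing_angle_deg=49.5),
    "butt_kicks": ActivitySpec(7, "butt_kicks", 80.0, 0.16, 650.0, 1.6,
                               swing_angle_deg=55.0),
    "stair_descent": ActivitySpec(8, "stair_descent", 50.0, 0.30, 300.0, 1.8,
                                  swing_angle_deg=31.0),
}


def _steps(name: str, n: int) -> ActivitySpec:
    return replace(ACTIVITIES[name], n_steps=n)


def _stand(duration_s: float) -> ActivitySpec:
    return replace(ACTIVITIES["standing"], duration_s=duration_s)


def default_track_script() -> TrackScript:
    """The default multi-activity track: 191 steps for the instrumented foot.

    40 walking steps (slow/moderate/fast), 40 running steps, 30 each of
    stomping / high knees / butt kicks, 11 stair-descent steps and a
    10-step transition walk, separated by standing rests.  Stairs come
    first, directly after the synchronization prelude.
    """
    segments = (
        _steps("stair_descent", 11),
        _stand(5.0),
        _steps("slow_walk", 14),
        _steps("moderate_walk", 13),
        _steps("fast_walk", 13),
        _stand(6.0),
        _steps("run", 40),
        _stand(8.0),
        _steps("stomping", 30),
        _stand(6.0),
        _steps("high_knees", 30),
        _stand(6.0),
        _steps("butt_kicks", 30),
        _stand(6.0),
        _steps("moderate_walk", 10),  # transition walk back to start
    )
    return TrackScript(segments)


def foot_angle_to_status(angle_deg: np.ndarray,
                         threshold_deg: float = FLAT_ANGLE_THRESHOLD_DEG) -> np.ndarray:
    """Threshold a sole-angle trace into a binary foot-flat status.

    Returns 1 where ``|angle| < threshold`` (foot flat / stationary) and 0
    otherwise; an angle of exactly the threshold counts as a transition (0).
    """
    angle = np.asarray(angle_deg, dtype=float)
    if angle.size == 0:
        return np.zeros(0, dtype=np.int8)
    if not np.all(np.isfinite(angle)):
        raise ValueError("foot angle trace contains non-finite values")
    return (np.abs(angle) < threshold_deg).astype(np.int8)


def inject_undetermined(status: np.ndarray,
                        fraction: float = DEFAULT_UNDETERMINED_FRACTION,
                        seed: int | np.random.Generator = 0,
                        mean_run_s: float = 0.25,
                        fps: float = ANNOTATION_FPS) -> np.ndarray:
    """Relabel contiguous runs of a status vector as undetermined (2).

    Emulates video occlusion: runs with geometric length (mean
    ``mean_run_s`` seconds at ``fps``) are placed uniformly until about
    ``fraction`` of the samples carry label 2.  Runs, not i.i.d. samples,
    because occlusion is temporally contiguous.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    status = np.asarray(status)
    out = status.copy()
    n = out.size
    if fraction == 0.0 or n == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_run = max(1.0, mean_run_s * fps)
    target = int(round(fraction * n))
    n_undet = 0
    # cap attempts: overlapping runs make progress slow near the target
    for _ in range(50 * max(1, target)):
        if n_undet >= target:
            break
        start = int(rng.integers(0, n))
        length = 1 + int(rng.geometric(1.0 / mean_run))
        stop = min(n, start + length)
        newly = int(np.count_nonzero(out[start:stop] != 2))
        if n_undet + newly > target + mean_run:  # would overshoot badly
            continue
        out[start:stop] = 2
        n_undet += newly
    return out


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

#: heel-strike transient duration (s)
_IMPACT_DURATION_S = 0.03
#: fraction of the swing occupied by the angular-rate burst
_GYRO_BURST_FRACTION = 0.85
#: half-sine gain of the burst, clipped to a plateau at the activity peak
_GYRO_PLATEAU_GAIN = 0.6
#: log-sd of per-step amplitude jitter (step-to-step variability)
_STEP_AMP_JITTER_SD = 0.4
#: default motion-acceleration amplitude as a fraction of the impact peak
_ACC_SWING_RATIO = 0.20


def _random_unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=dim)
    norm = float(np.linalg.norm(v))
    return v / norm if norm > 1e-12 else np.eye(dim)[0]


def _synthesize_trial(subject: SubjectSpec, script: TrackScript, fs: float,
                      rng: np.random.Generator):
    """Build noiseless per-sample kinematics + IMU channels on the trial clock."""
    amp = subject.amplitude_multiplier
    cad = subject.cadence_multiplier

    # segment/step boundaries in continuous time, then rasterized
    total_s = sum(
        (seg.n_steps * seg.period_s / cad) if seg.n_steps > 0 else seg.duration_s
        for seg in script.segments
    )
    n = int(round(total_s * fs))
    time = np.arange(n) / fs
    angle = np.zeros(n)
    status = np.ones(n, dtype=np.int8)   # default: stationary
    activity = np.zeros(n, dtype=np.int16)
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0                      # gravity along +z when flat
    gyro = np.zeros((n, 3))

    step_event_times: list[float] = []
    flat_intervals: list[tuple[float, float]] = []

    t_cursor = 0.0
    for seg in script.segments:
        if seg.n_steps == 0:
            if seg.duration_s <= 0:
                raise ValueError(f"{seg.name}: standing segments need duration_s > 0")
            i0, i1 = int(round(t_cursor * fs)), int(round((t_cursor + seg.duration_s) * fs))
            activity[i0:i1] = seg.category_id
            t_cursor += seg.duration_s
            continue

        period = seg.period_s / cad
        swing_s = (1.0 - seg.flat_fraction) * period
        flat_s = seg.flat_fraction * period
        gyro_peak = seg.gyro_swing_amp * amp
        imp_peak = seg.acc_impact_amp * amp
        acc_swing = (seg.acc_swing_amp if seg.acc_swing_amp is not None
                     else _ACC_SWING_RATIO * seg.acc_impact_amp) * amp

        for _ in range(seg.n_steps):
            # step-to-step amplitude variability
            step_gain = float(np.exp(rng.normal(0.0, _STEP_AMP_JITTER_SD)))
            # ---- swing phase -------------------------------------------------
            i0 = int(round(t_cursor * fs))
            i1 = int(round((t_cursor + swing_s) * fs))
            i1 = max(i1, i0 + 1)
            m = i1 - i0
            s = (np.arange(m) + 0.5) / m
            activity[i0:i1] = seg.category_id
            status[i0:i1] = 0
            # steep lift-off/landing: the sole leaves the ±3° flat band
            # within about one sample at 200 Hz
            theta = seg.swing_angle_deg * np.sqrt(np.sin(np.pi * s))
            angle[i0:i1] = theta

            # angular-rate burst along a random per-step axis; the norm can
            # never fall below the pitch rate implied by the emitted sole
            # angle, so the steep lift-off/landing edges carry large rates
            burst = np.zeros(m)
            core = (s > (1 - _GYRO_BURST_FRACTION) / 2) & (s < 1 - (1 - _GYRO_BURST_FRACTION) / 2)
            sb = (s[core] - (1 - _GYRO_BURST_FRACTION) / 2) / _GYRO_BURST_FRACTION
            burst[core] = gyro_peak * step_gain * np.clip(
                _GYRO_PLATEAU_GAIN * np.sin(np.pi * sb), 0.0, 1.0)
            pitch_rate = np.abs(np.gradient(theta)) * fs
            np.maximum(burst, np.minimum(pitch_rate, gyro_peak * step_gain),
                       out=burst)
            d = _random_unit_vector(rng, 3)
            gyro[i0:i1] += burst[:, None] * d[None, :]

            # gravity tilt + motion acceleration; horizontal direction random
            # per step so individual axes carry little label information
            th_rad = np.deg2rad(theta)
            az = np.cos(th_rad) + 0.5 * acc_swing * step_gain * np.sin(2 * np.pi * s)
            ah = np.sin(th_rad) + acc_swing * step_gain * np.sin(np.pi * s)
            e = _random_unit_vector(rng, 2)
            acc[i0:i1, 0] = ah * e[0]
            acc[i0:i1, 1] = ah * e[1]
            acc[i0:i1, 2] = az

            # heel-strike transient at the very end of the swing
            mi = max(1, int(round(_IMPACT_DURATION_S * fs)))
            j0 = max(i0, i1 - mi)
            si = (np.arange(i1 - j0) + 0.5) / (i1 - j0)
            spike = imp_peak * np.sin(np.pi * si)
            acc[j0:i1, 2] += spike
            eh = _random_unit_vector(rng, 2)
            acc[j0:i1, 0] += 0.35 * spike * eh[0]
            acc[j0:i1, 1] += 0.35 * spike * eh[1]

            # ---- foot-flat phase --------------------------------------------
            f0 = t_cursor + swing_s
            f1 = t_cursor + swing_s + flat_s
            k0, k1 = int(round(f0 * fs)), int(round(f1 * fs))
            activity[k0:k1] = seg.category_id
            step_event_times.append(f0)
            flat_intervals.append((f0, f1))
            t_cursor += period

    return time, angle, status, activity, acc, gyro, step_event_times, flat_intervals


def _synthesize_prelude(script: TrackScript, subject: SubjectSpec, fs: float,
                        rng: np.random.Generator):
    """Pre-trial segment containing the 3 synchronization heel strikes."""
    n = int(round(script.prelude_duration_s * fs))
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0
    gyro = np.zeros((n, 3))
    mi = max(2, int(round(_IMPACT_DURATION_S * fs)))
    for t_strike in script.prelude_strike_times:
        i0 = int(round(t_strike * fs)) - mi // 2
        si = (np.arange(mi) + 0.5) / mi
        spike = 5.0 * subject.amplitude_multiplier * np.sin(np.pi * si)
        acc[i0:i0 + mi, 2] += spike
        # small leg movement around each strike
        gyro[i0 - mi:i0 + 2 * mi, :] += rng.normal(0.0, 15.0, (3 * mi, 3))
    return acc, gyro


def simulate_subject(subject: SubjectSpec, script: TrackScript | None = None,
                     fs: float = DEFAULT_FS) -> tuple[ImuRecording, GroundTruth]:
    """Simulate one subject completing the track.

    Returns the IMU recording on the device clock (t=0 at recording start,
    sync prelude included) and the exact ground truth on the trial clock
    (t=0 at the third sync heel strike).
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be > 0, got {fs}")
    if script is None:
        script = default_track_script()
    rng = np.random.default_rng(subject.seed)

    (time, angle, status, activity, acc, gyro,
     step_times, flat_intervals) = _synthesize_trial(subject, script, fs, rng)
    pre_acc, pre_gyro = _synthesize_prelude(script, subject, fs, rng)

    acc_all = np.vstack([pre_acc, acc])
    gyro_all = np.vstack([pre_gyro, gyro])
    n_all = acc_all.shape[0]
    acc_all = acc_all + rng.normal(0.0, subject.noise_sd_acc, (n_all, 3))
    gyro_all = gyro_all + rng.normal(0.0, subject.noise_sd_gyro, (n_all, 3))
    np.clip(acc_all, -ACC_RANGE_G, ACC_RANGE_G, out=acc_all)
    np.clip(gyro_all, -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=gyro_all)

    frame = pd.DataFrame({
        "time_s": np.arange(n_all) / fs,
        "acc_x": acc_all[:, 0], "acc_y": acc_all[:, 1], "acc_z": acc_all[:, 2],
        "gyro_x": gyro_all[:, 0], "gyro_y": gyro_all[:, 1], "gyro_z": gyro_all[:, 2],
    })
    rec = compute_norms(ImuRecording(frame, fs=fs))

    # trial clock: t=0 at the third sync strike, so the trial (which starts
    # when the prelude ends) begins at prelude_duration - last strike time
    off = script.prelude_duration_s - script.prelude_strike_times[-1]
    truth = GroundTruth(
        fs=fs,
        time=time + off,
        foot_angle_deg=angle,
        status=status,
        activity=activity,
        step_event_times=np.asarray(step_times) + off,
        flat_intervals=[(a + off, b + off) for a, b in flat_intervals],
    )
    return rec, truth


def make_annotation(truth: GroundTruth,
                    undetermined_fraction: float = DEFAULT_UNDETERMINED_FRACTION,
                    seed: int | np.random.Generator = 0,
                    fps: float = ANNOTATION_FPS) -> AnnotationTable:
    """Emulate frame-by-frame video labeling of a simulated trial.

    Samples the sole-angle trace at the video frame rate, thresholds it
    into foot status, and relabels contiguous occluded runs undetermined.
    """
    t_start = float(truth.time[0])
    t_end = float(truth.time[-1])
    frame_times = t_start + np.arange(int(np.floor((t_end - t_start) * fps)) + 1) / fps
    idx = np.clip(np.round((frame_times - t_start) * truth.fs).astype(int),
                  0, truth.time.size - 1)
    status = foot_angle_to_status(truth.foot_angle_deg[idx])
    status = inject_undetermined(status, undetermined_fraction, seed, fps=fps)
    frame = pd.DataFrame({
        "time_s": frame_times,
        "foot_status": status.astype(np.int8),
        "activity": truth.activity[idx].astype(np.int16),
    })
    return AnnotationTable(frame)


def draw_subject_spec(subject_id: int, rng: np.random.Generator) -> SubjectSpec:
    """Draw one subject's heterogeneity parameters from the cohort distributions."""
    return SubjectSpec(
        subject_id=subject_id,
        cadence_multiplier=float(np.clip(rng.normal(1.0, 0.08), 0.8, 1.25)),
        amplitude_multiplier=float(np.clip(rng.normal(1.0, 0.3), 0.5, 1.7)),
        noise_sd_acc=float(rng.uniform(0.025, 0.05)),
        noise_sd_gyro=float(rng.uniform(5.0, 10.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_cohort(n_subjects: int = 21, seed: int = 0,
                    script: TrackScript | None = None, fs: float = DEFAULT_FS,
                    undetermined_fraction: float = DEFAULT_UNDETERMINED_FRACTION,
                    ) -> list[tuple[ImuRecording, AnnotationTable, GroundTruth]]:
    """Simulate a cohort of subjects completing the default (or given) track."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if script is None:
        script = default_track_script()
    root = np.random.default_rng(seed)
    out = []
    for sid in range(n_subjects):
        spec = draw_subject_spec(sid, root)
        rec, truth = simulate_subject(spec, script, fs)
        ann = make_annotation(truth, undetermined_fraction,
                              seed=int(root.integers(0, 2**31 - 1)))
        out.append((rec, ann, truth))
    return out
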