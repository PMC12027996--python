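"""Synthetic binocular gaze recordings with known ground truth.

Emulates the study design used throughout this package: three viewing
paradigms (fixation on a static target, tracking a target that hops along
straight/curved legs, and smooth pursuit of an S-shaped path), each run
under a dichoptic rivalry condition (R-G: opposing colors to the two eyes)
and two fusion control conditions (R-R, G-G), three repetitions per
condition, for a cohort of subjects.

The perceptual state shifts oculomotor behaviour: in static fixation,
rivalry lowers saccade amplitude and shortens blinks; in the hopping task,
rivalry raises saccade amplitude (and, through the main sequence, saccade
velocities); in smooth pursuit, rivalry lowers saccade amplitude.  Effect
sizes are expressed in units of the pooled (36 fusion + 18 rivalry)
standard deviation — the z-score scale on which the downstream range
analysis operates — and converted to physical shifts internally.

Saccades follow a raised-cosine velocity profile whose peak velocity obeys
the main sequence (peak = slope x amplitude, bounded); blinks zero the
pupil and invalidate gaze for their duration.  Generation is fully
deterministic given (meta, params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .events import GazeEvent, SampleStream
from .geometry import DEFAULT_GEOMETRY, DisplayGeometry, deg_to_px

PARADIGMS = ("gaze_stability", "straight_curve", "smooth_pursuit")
GROUPS = ("RG", "RR", "GG")
STATES = ("fusion", "rivalry")

#: study-scale trial durations, seconds
DEFAULT_DURATIONS = {"gaze_stability": 130.0, "straight_curve": 100.0,
                     "smooth_pursuit": 80.0}
DEFAULT_SACCADE_RATES = {"gaze_stability": 1.0, "straight_curve": 1.5,
                         "smooth_pursuit": 1.0}
#: fusion-state baseline mean saccade amplitude, degrees
DEFAULT_AMPLITUDE_MEANS = {"gaze_stability": 2.2, "straight_curve": 1.5,
                           "smooth_pursuit": 2.2}
#: rivalry-vs-fusion amplitude effect, z-pool SD units
DEFAULT_AMPLITUDE_EFFECTS = {"gaze_stability": -1.5, "straight_curve": 1.0,
                             "smooth_pursuit": -1.5}
#: rivalry-vs-fusion blink-duration effect, z-pool SD units
DEFAULT_BLINK_EFFECTS = {"gaze_stability": -1.0, "straight_curve": 0.0,
                         "smooth_pursuit": 0.0}

# hopping target speed: 4.5 degrees per 1.2 s
HOP_SPEED = 4.5 / 1.2
HOP_STRAIGHT_S = 38.0
HOP_LEGS = 14
HOP_CURVE_RADIUS = 6.0
PURSUIT_SWEEP_S = 40.0
PURSUIT_RADIUS = 5.0


def state_of_group(group: str) -> str:
    """Perceptual state is a pure function of the viewing group."""
    if group == "RG":
        return "rivalry"
    if group in ("RR", "GG"):
        return "fusion"
    raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class TrialMeta:
    subject_id: str
    paradigm: str
    group: str
    repetition: int
    seed: int

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.repetition not in (1, 2, 3):
            raise ValueError("repetition must be in {1, 2, 3}")
        state_of_group(self.group)  # validates

    @property
    def state(self) -> str:
        return state_of_group(self.group)

    @property
    def trial_id(self) -> str:
        return (f"{self.subject_id}_{self.paradigm}_{self.group}"
                f"_r{self.repetition}")


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable generator settings (``None`` -> per-paradigm default).

    ``subject_*`` fields are per-trial overrides used by the cohort
    generator to inject between-subject variability while keeping
    :func:`generate_trial` a pure function of (meta, params).
    """

    sampling_rate: float = 500.0
    trial_duration: float | None = None            # s
    saccade_rate: float | None = None              # events/s
    amplitude_mean: float | None = None            # deg, fusion baseline
    amplitude_between_sd: float = 0.35             # deg, between subjects
    amplitude_cv: float = 0.25                     # per-saccade SD / mean
    amplitude_cv_sd: float = 0.05                  # between-subject CV SD
    amplitude_min: float = 0.8                     # deg, per-saccade floor
    amplitude_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_EFFECTS))
    blink_rate: float = 0.2                        # events/s
    blink_duration_mean: float = 250.0             # ms, fusion baseline
    blink_between_sd: float = 25.0                 # ms, between subjects
    blink_duration_sd: float = 40.0                # ms, within subject
    blink_duration_min: float = 80.0               # ms
    blink_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLINK_EFFECTS))
    main_sequence_slope: float = 50.0              # (deg/s)/deg
    peak_velocity_cap: float = 700.0               # deg/s
    fixation_noise_sd: float = 0.03                # deg, per eye per axis
    pupil_baseline: float = 1000.0                 # a.u.
    pupil_noise_sd: float = 5.0
    subject_amplitude_offset: float = 0.0          # deg
    subject_blink_offset: float = 0.0              # ms
    subject_cv: float | None = None

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "amplitude_between_sd", "amplitude_cv",
                     "amplitude_cv_sd", "blink_rate", "blink_between_sd",
                     "blink_duration_sd", "fixation_noise_sd",
                     "pupil_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trial_duration is not None and self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.saccade_rate is not None and self.saccade_rate < 0:
            raise ValueError("saccade_rate must be >= 0")
        if self.amplitude_mean is not None and self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")
        if self.main_sequence_slope <= 0:
            raise ValueError("main_sequence_slope must be positive")

    # -- per-paradigm / per-state resolution -------------------------------

    def duration(self, paradigm: str) -> float:
        return self.trial_duration if self.trial_duration is not None \
            else DEFAULT_DURATIONS[paradigm]

    def rate(self, paradigm: str) -> float:
        return self.saccade_rate if self.saccade_rate is not None \
            else DEFAULT_SACCADE_RATES[paradigm]

    def state_amplitude_mean(self, paradigm: str, state: str) -> float:
        base = self.amplitude_mean if self.amplitude_mean is not None \
            else DEFAULT_AMPLITUDE_MEANS[paradigm]
        if state == "rivalry":
            base += effect_shift(self.amplitude_effect.get(paradigm, 0.0),
                                 self.amplitude_between_sd)
        return base

    def state_blink_mean(self, paradigm: str, state: str) -> float:
        base = self.blink_duration_mean
        if state == "rivalry":
            base += effect_shift(self.blink_effect.get(paradigm, 0.0),
                                 self.blink_between_sd)
        return base


def effect_shift(effect_z: float, between_sd: float,
                 fusion_frac: float = 2.0 / 3.0) -> float:
    """Physical shift realising a state gap of ``effect_z`` z-pool SDs.

    The z-pool mixes fusion and rivalry units (weights 2/3 and 1/3 in the
    study design), so its SD depends on the gap itself:
    ``pool_sd^2 = sd^2 + w(1-w) gap^2``.  Solving ``gap = e * pool_sd``
    gives ``gap = e * sd / sqrt(1 - w(1-w) e^2)``, clamped for very large
    effects.
    """
    w = fusion_frac * (1.0 - fusion_frac)
    denom = np.sqrt(max(1.0 - w * effect_z ** 2, 0.02))
    return effect_z * between_sd / denom


@dataclass
class GroundTruth:
    """True event list for one generated trial (sorted, non-overlapping)."""

    events: list[GazeEvent]

    @property
    def saccades(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == "saccade"]

    @property
    def blinks(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == "blink"]


# ---------------------------------------------------------------------------
# Target trajectories (degrees from screen centre; x rightward, y downward)

def target_trajectory(paradigm: str, time_s, params: GeneratorParams
                      = GeneratorParams()) -> np.ndarray:
    """Stimulus-target position at ``time_s`` (scalar or array) -> (n, 2) deg.

    * ``gaze_stability``: fixed at the screen centre.
    * ``straight_curve``: 38 s of back-and-forth straight legs advancing
      4.5 degrees per 1.2 s (14 legs), then a curved (circular-arc) path at
      the same speed until 100 s.
    * ``smooth_pursuit``: S-shaped path (two semicircular arcs) traversed
      in 40 s, then retraced in reverse.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    t = np.atleast_1d(np.asarray(time_s, dtype=float))
    duration = params.duration(paradigm)
    if np.any(t < 0) or np.any(t > duration + 1e-9):
        raise ValueError("time outside trial duration")
    if paradigm == "gaze_stability":
        out = np.zeros((t.size, 2))
    elif paradigm == "straight_curve":
        out = _hopping_path(t)
    elif paradigm == "smooth_pursuit":
        out = _pursuit_path(t)
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return out if np.ndim(time_s) else out[0]


def _hopping_path(t: np.ndarray) -> np.ndarray:
    leg_len = HOP_SPEED * HOP_STRAIGHT_S / HOP_LEGS
    out = np.zeros((t.size, 2))
    straight = t < HOP_STRAIGHT_S
    s = HOP_SPEED * t[straight]
    leg = np.floor_divide(s, leg_len).astype(int)
    frac = s - leg * leg_len
    x = np.where(leg % 2 == 0, frac, leg_len - frac) - leg_len / 2.0
    out[straight, 0] = x
    # curved phase: circular arcs at the same tangential speed, joined
    # continuously to the straight-phase endpoint (point A)
    curved = ~straight
    if np.any(curved):
        r = HOP_CURVE_RADIUS
        start = np.array([-leg_len / 2.0, 0.0])
        center = start + np.array([r, 0.0])
        theta = np.pi + HOP_SPEED * (t[curved] - HOP_STRAIGHT_S) / r
        out[curved, 0] = center[0] + r * np.cos(theta)
        out[curved, 1] = center[1] + r * np.sin(theta)
    return out


def _pursuit_path(t: np.ndarray) -> np.ndarray:
    r = PURSUIT_RADIUS
    sweep = PURSUIT_SWEEP_S
    # position along one sweep, u in [0, 1]; reverse on the second sweep
    cycle = np.mod(t, 2 * sweep)
    u = np.where(cycle <= sweep, cycle / sweep, 2.0 - cycle / sweep)
    u = np.clip(u, 0.0, 1.0)
    out = np.empty((t.size, 2))
    first = u <= 0.5
    # arc 1: from (0, -2r) around (0, -r) to the centre
    phi = -np.pi / 2 + 2 * np.pi * u[first]
    out[first, 0] = r * np.cos(phi)
    out[first, 1] = -r + r * np.sin(phi)
    # arc 2: from the centre around (0, r) to (0, 2r), opposite curvature
    phi = -np.pi / 2 - 2 * np.pi * (u[~first] - 0.5)
    out[~first, 0] = r * np.cos(phi)
    out[~first, 1] = r + r * np.sin(phi)
    return out


# ---------------------------------------------------------------------------
# Trial generation

def _raised_cosine_ramp(n_samp: int) -> np.ndarray:
    """Displacement fraction of a raised-cosine velocity profile."""
    u = np.arange(n_samp + 1) / n_samp
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def generate_trial(meta: TrialMeta, params: GeneratorParams = GeneratorParams(),
                   geometry: DisplayGeometry = DEFAULT_GEOMETRY,
                   ) -> tuple[SampleStream, GroundTruth]:
    """Generate one binocular trial and its ground-truth event list.

    Deterministic given ``(meta, params)``: all randomness flows from
    ``meta.seed``.  Ground-truth saccade amplitudes and peak velocities are
    measured on the noiseless gaze trace, so they are exact for the
    detector-recovery oracles.
    """
    rng = np.random.default_rng(meta.seed)
    srate = params.sampling_rate
    duration = params.duration(meta.paradigm)
    if duration <= 0 or srate <= 0:
        raise ValueError("non-positive duration or sampling rate")
    n = int(round(duration * srate))
    step_ms = 1000.0 / srate
    t_ms = np.arange(n) * step_ms
    t_s = t_ms / 1000.0

    base = target_trajectory(meta.paradigm, t_s, params)

    # floor at the per-saccade minimum so extreme effects saturate rather
    # than producing negative parameter means
    amp_mu = max(params.state_amplitude_mean(meta.paradigm, meta.state)
                 + params.subject_amplitude_offset, params.amplitude_min)
    cv = params.subject_cv if params.subject_cv is not None \
        else params.amplitude_cv
    blink_mu = max(params.state_blink_mean(meta.paradigm, meta.state)
                   + params.subject_blink_offset,
                   params.blink_duration_min)

    # --- saccade schedule -------------------------------------------------
    sacc_rate = params.rate(meta.paradigm)
    sacc_windows: list[tuple[int, int]] = []
    offsets = np.zeros((n, 2))
    s_current = np.zeros(2)        # saccadic offset relative to target
    cursor = 0.4
    leash = 1.5 * max(amp_mu, 0.5)
    while sacc_rate > 0:
        cursor += max(rng.exponential(1.0 / sacc_rate), 0.12)
        amp = rng.normal(amp_mu, cv * amp_mu)
        amp = float(np.clip(amp, params.amplitude_min, 15.0))
        vp = min(params.main_sequence_slope * amp, params.peak_velocity_cap)
        dur_s = 2.0 * amp / vp
        if cursor + dur_s > duration - 0.3:
            break
        # heading: uniform near the leash origin, re-centering beyond it
        if np.hypot(*s_current) > leash:
            heading = np.arctan2(-s_current[1], -s_current[0]) \
                + rng.normal(0.0, 0.5)
        else:
            heading = rng.uniform(0.0, 2 * np.pi)
        disp = amp * np.array([np.cos(heading), np.sin(heading)])
        i_on = int(round(cursor * srate))
        n_samp = max(2, int(round(dur_s * srate)))
        i_off = i_on + n_samp
        if i_off >= n:
            break
        ramp = _raised_cosine_ramp(n_samp)
        offsets[i_on:i_off + 1] = s_current + disp * ramp[:, None]
        offsets[i_off + 1:] = s_current + disp
        s_current = s_current + disp
        sacc_windows.append((i_on, i_off))
        cursor += dur_s

    pos = base + offsets           # noiseless gaze, degrees

    # --- blink schedule (kept clear of saccades and trial edges) ----------
    blink_windows: list[tuple[int, int]] = []
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * duration)
        onsets = np.sort(rng.uniform(0.4, max(duration - 0.6, 0.4), n_blinks))
        durs = rng.normal(blink_mu, params.blink_duration_sd, n_blinks)
        durs = np.clip(durs, params.blink_duration_min, 2000.0) / 1000.0
        margin = int(round(0.08 * srate))
        for onset, dur in zip(onsets, durs):
            i_on = int(round(onset * srate))
            i_off = i_on + max(1, int(round(dur * srate)))
            if i_off >= n - margin:
                continue
            clash = any(i_on - margin < so_off and i_off + margin > so_on
                        for so_on, so_off in sacc_windows)
            clash |= any(i_on - margin < bo_off and i_off + margin > bo_on
                         for bo_on, bo_off in blink_windows)
            if not clash:
                blink_windows.append((i_on, i_off))
    blink_windows.sort()

    # --- ground truth from the noiseless trace ----------------------------
    speed = np.hypot(np.gradient(pos[:, 0], 1.0 / srate),
                     np.gradient(pos[:, 1], 1.0 / srate))
    truth_events = []
    for i_on, i_off in sacc_windows:
        disp = pos[i_off] - pos[i_on]
        amp = float(np.hypot(disp[0], disp[1]))
        dur_ms = (i_off - i_on) * step_ms
        truth_events.append(GazeEvent(
            "saccade", "both", onset_ms=i_on * step_ms,
            offset_ms=i_on * step_ms + dur_ms, amplitude_deg=amp,
            avg_velocity=amp / (dur_ms / 1000.0),
            peak_velocity=float(speed[i_on:i_off + 1].max())))
    for i_on, i_off in blink_windows:
        truth_events.append(GazeEvent(
            "blink", "both", onset_ms=i_on * step_ms,
            offset_ms=i_off * step_ms))
    truth_events.sort(key=lambda e: e.onset_ms)

    # --- per-eye streams with noise, blinks, pixel conversion -------------
    channels = {}
    pupils = {}
    for prefix in ("l", "r"):
        eye_pos = pos + rng.normal(0.0, params.fixation_noise_sd, (n, 2))
        pupil = params.pupil_baseline \
            + rng.normal(0.0, params.pupil_noise_sd, n)
        for i_on, i_off in blink_windows:
            eye_pos[i_on:i_off] = np.nan
            pupil[i_on:i_off] = 0.0
        channels[prefix + "x"] = deg_to_px(eye_pos[:, 0], geometry, "x")
        channels[prefix + "y"] = deg_to_px(eye_pos[:, 1], geometry, "y")
        pupils[prefix + "pupil"] = pupil

    stream = SampleStream(time_ms=t_ms, lx=channels["lx"], ly=channels["ly"],
                          rx=channels["rx"], ry=channels["ry"],
                          lpupil=pupils["lpupil"], rpupil=pupils["rpupil"])
    return stream, GroundTruth(truth_events)


# ---------------------------------------------------------------------------
# Cohort generation

@dataclass
class CohortTrial:
    meta: TrialMeta
    stream: SampleStream
    truth: GroundTruth


def iter_cohort(n_subjects: int, params: GeneratorParams = GeneratorParams(),
                master_seed: int = 0,
                paradigms: Sequence[str] = PARADIGMS,
                groups: Sequence[str] = GROUPS,
                repetitions: int = 3,
                geometry: DisplayGeometry = DEFAULT_GEOMETRY,
                ) -> Iterator[CohortTrial]:
    """Yield cohort trials one at a time (memory-friendly).

    Subjects carry per-paradigm random trait offsets (amplitude mean, blink
    duration mean, amplitude CV) drawn from the stated between-subject SDs;
    traits are shared across that subject's groups and repetitions.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(master_seed)
    for si in range(n_subjects):
        subject_id = f"S{si + 1:02d}"
        for paradigm in paradigms:
            amp_off = rng.normal(0.0, 1.0) * params.amplitude_between_sd
            blink_off = rng.normal(0.0, 1.0) * params.blink_between_sd
            cv = max(rng.normal(params.amplitude_cv, params.amplitude_cv_sd),
                     0.05)
            trial_params = replace(params, subject_amplitude_offset=amp_off,
                                   subject_blink_offset=blink_off,
                                   subject_cv=cv)
            for group in groups:
                for rep in range(1, repetitions + 1):
                    seed = int(rng.integers(0, 2 ** 31))
                    meta = TrialMeta(subject_id, paradigm, group, rep, seed)
                    stream, truth = generate_trial(meta, trial_params,
                                                   geometry)
                    yield CohortTrial(meta, stream, truth)


def generate_cohort(n_subjects: int,
                    params: GeneratorParams = GeneratorParams(),
                    master_seed: int = 0, **kwargs) -> list[CohortTrial]:
    """Materialised cohort: n_subjects x paradigms x groups x repetitions."""
    return list(iter_cohort(n_subjects, params, master_seed, **kwargs))


# ---------------------------------------------------------------------------
# On-disk format: one delimited file per trial + JSON sidecar + manifest

def write_trial(trial: CohortTrial, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = trial.meta.trial_id
    sample_path = directory / f"{stem}.csv"
    s = trial.stream
    header = "time_ms, lx, ly, rx, ry, lpupil, rpupil"
    data = np.column_stack([s.time_ms, s.lx, s.ly, s.rx, s.ry,
                            s.lpupil, s.rpupil])
    np.savetxt(sample_path, data, fmt="%.4f", delimiter=", ",
               header=header, comments="")
    sidecar = {
        "meta": {"subject_id": trial.meta.subject_id,
                 "paradigm": trial.meta.paradigm,
                 "group": trial.meta.group,
                 "repetition": trial.meta.repetition,
                 "state": trial.meta.state,
                 "seed": trial.meta.seed},
        "events": [{"kind": e.kind, "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "amplitude_deg": e.amplitude_deg,
                    "avg_velocity": e.avg_velocity,
                    "peak_velocity": e.peak_velocity}
                   for e in trial.truth.events],
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return sample_path


def write_cohort(trials: Sequence[CohortTrial], directory: str | Path) -> Path:
    """Write all trials plus a tab-separated cohort manifest."""
    directory = Path(directory)
    rows = []
    for trial in trials:
        path = write_trial(trial, directory)
        m = trial.meta
        rows.append((m.subject_id, m.paradigm, m.group, m.repetition,
                     m.state, m.seed, path.name))
    manifest = directory / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tparadigm\tgroup\trepetition\tstate\tseed"
                 "\tsample_file\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return manifest
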