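"""Synthetic participants, pupil traces, screens, and game telemetry.

No public recordings exist for this kind of study, so the package ships a
generator that emulates the statistical structure the analysis assumes:

* individual tonic pupil diameters and light-reflex gains;
* a steady-state pupillary light response driven by an *effective luminance*
  that blends the global mean intensity of the viewed image with a penalty
  for coarse spatial structure (retinal adaptation to local contrast) — this
  is a phenomenological model whose purpose is to make the ordering of
  baseline-image filters emerge, not to model retinal physiology;
* task-evoked pupillary responses during play: a sustained effort shift plus
  gamma-shaped phasic events whose amplitude grows with level difficulty;
* blink dropouts, isolated tracker spikes, and measurement noise;
* difficulty-dependent telemetry (errors and completion time) with
  difficulty-independent position changes and attempts.

Every generator is a pure function of (config, seed).  One global seed fans
out to per-participant / per-trial seeds through ``numpy``'s splittable
``SeedSequence`` spawn keys, so adding a participant never perturbs the data
of earlier ones.

Calibration constants in :class:`SimConfig` are chosen so that a default
20-participant cohort reproduces the qualitative outcomes the analysis is
designed to detect (difficulty signal in errors, completion time, mean
diameter change, and peak dilation; none in the remaining features) with
high power; see the methods note for the reasoning behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import PupilTrace, SessionLog
from .scramble import ScrambleSpec, grid_edges, make_baseline_image

__all__ = [
    "SimConfig",
    "ParticipantProfile",
    "KernelSpec",
    "TrialTruth",
    "TrialTraces",
    "Exp1Record",
    "Exp2Trial",
    "Exp2Participant",
    "Cohort",
    "EXP1_CONDITIONS",
    "synth_game_frame",
    "effective_luminance",
    "simulate_participant",
    "luminance_response",
    "simulate_trial_trace",
    "simulate_gamer_telemetry",
    "simulate_experiment1_cohort",
    "simulate_experiment2_cohort",
    "simulate_cohort",
]

EXP1_CONDITIONS = (
    "white", "black", "scramble", "grid_8x6", "grid_10x10", "grid_20x20"
)

_CONDITION_SPECS = {
    "white": ("white", 1, 1),
    "black": ("black", 1, 1),
    "scramble": ("scramble", 1, 1),
    "grid_8x6": ("grid_scramble", 8, 6),
    "grid_10x10": ("grid_scramble", 10, 10),
    "grid_20x20": ("grid_scramble", 20, 20),
}

WORLDS = ("A", "B")
WORLD_LEVELS = {"A": ("L1a", "L2a"), "B": ("L3b", "L4b")}


@dataclass(frozen=True)
class KernelSpec:
    """Gamma-shaped task-evoked response kernel, normalised to unit peak.

    Onset latency 300 ms and a peak roughly 1 s after event onset reflect
    the sluggish iris musculature; the response decays below 5% of its peak
    within 4 s, consistent with responses that subside quickly once
    processing ends.
    """

    onset_ms: float = 300.0
    shape: float = 2.0
    scale_ms: float = 550.0

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        u = (np.asarray(t_ms, dtype=float) - self.onset_ms) / self.scale_ms
        u0 = self.shape - 1.0
        out = np.zeros_like(u)
        pos = u > 0
        out[pos] = (u[pos] / u0) ** u0 * np.exp(u0 - u[pos])
        return out

    @property
    def peak_time_ms(self) -> float:
        return self.onset_ms + (self.shape - 1.0) * self.scale_ms

    @property
    def area_ms(self) -> float:
        """Integral of the unit-peak kernel over time (ms)."""
        from scipy.special import gamma as _gamma

        u0 = self.shape - 1.0
        return float(self.scale_ms * _gamma(self.shape) * np.exp(u0) / u0**u0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions and calibration constants for the generator."""

    # cohort sizes (as in the two experiments)
    n_participants: int = 20
    n_participants_exp1: int = 14
    rate_hz: float = 60.0
    observation_s: float = 8.0

    # individual differences
    d0_mean_px: float = 30.0
    d0_sd_px: float = 3.0
    light_gain_mean: float = -0.022  # px per effective-luminance unit
    light_gain_sd: float = 0.005
    tepr_gain_sigma: float = 0.15  # lognormal sigma of the TEPR multiplier

    # effective-luminance model
    structure_weight: float = 1.3
    structure_cell_px: int = 16

    # screen
    frame_width: int = 288
    frame_height: int = 192
    frame_seed: int = 20210111
    baseline_grid: tuple[int, int] = (8, 6)

    # task-evoked response
    kernel: KernelSpec = field(default_factory=KernelSpec)
    tonic_effort_px: dict = field(
        default_factory=lambda: {"A": 1.5, "B": 2.0}
    )
    phasic_amp_px: dict = field(
        default_factory=lambda: {"A": 4.0, "B": 15.0}
    )
    phasic_amp_cv: float = 0.45
    phasic_events_mean: dict = field(
        default_factory=lambda: {"A": 5.0, "B": 3.5}
    )
    # phasic effort is concentrated in the initial analysis phase of a level:
    # event times are exponential at this scale, capped at a fixed horizon so
    # peak latency carries no difficulty information
    event_time_scale_ms: float = 10000.0
    event_horizon_ms: float = 25000.0

    # session tonic drift before the second world (arousal carry-over);
    # calibrated so divisive features carry no net difficulty signal
    baseline_drift_frac: float = 0.30

    # noise and artifacts
    noise_sd_px: float = 0.25
    channel_noise_sd_px: float = 0.10
    interval_jitter_sd_px: float = 0.30
    blink_rate_hz: float = 0.10
    blink_duration_ms: float = 150.0
    spike_rate_hz: float = 0.05
    spike_magnitude_px: float = 5.0

    # telemetry
    te_mean: dict = field(default_factory=lambda: {"A": 0.5, "B": 2.5})
    tc_median_ms: dict = field(
        default_factory=lambda: {"A": 43486.0, "B": 83970.0}
    )
    tc_sigma: float = 0.25
    skill_te_slope: float = 0.8
    skill_tc_slope: float = 0.5
    cp_mean: float = 1.0
    extra_attempts_mean: float = 0.5
    places_mean: float = 8.0

    seed: int = 0


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent per-participant parameters."""

    participant_id: str
    d0: float  # tonic pupil diameter, px
    light_gain: float  # px per effective-luminance unit, <= 0
    tepr_gain: float  # multiplier on TEPR amplitudes, > 0
    skill: float  # latent gamer ability in [0, 1]

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.light_gain > 0:
            raise ValueError("light_gain must be <= 0 (constriction with light)")
        if self.tepr_gain <= 0:
            raise ValueError("tepr_gain must be positive")


@dataclass
class TrialTruth:
    """Generating parameters of one trial, for recovery tests."""

    tonic_baseline: float
    tonic_measurement: float
    event_times_ms: np.ndarray
    amplitudes: np.ndarray
    kernel: KernelSpec
    baseline_shift: float
    jitter_baseline: float
    jitter_measurement: float


@dataclass
class TrialTraces:
    baseline: PupilTrace
    measurement: PupilTrace
    truth: TrialTruth


@dataclass
class Exp1Record:
    participant_id: str
    condition: str
    traces: TrialTraces


@dataclass
class Exp2Trial:
    level_id: str
    world: str
    log: SessionLog
    measurement: PupilTrace
    truth: TrialTruth


@dataclass
class Exp2Participant:
    profile: ParticipantProfile
    baselines: dict  # world -> PupilTrace (raw baseline-image viewing)
    trials: list  # of Exp2Trial


@dataclass
class Cohort:
    config: SimConfig
    frame: np.ndarray
    experiment1: list | None = None  # of Exp1Record
    experiment2: list | None = None  # of Exp2Participant


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def synth_game_frame(width: int = 288, height: int = 192,
                     seed: int = 20210111) -> np.ndarray:
    """A synthetic stand-in for a representative in-game frame.

    Emulates the coarse luminance layout of a puzzle screen: a dark play
    field with a horizontal brightness gradient, a bright tool panel, and a
    handful of bright rectangular elements, plus mild pixel noise.  The
    result has strong structure at the scale of a few dozen pixels, which is
    what distinguishes grid scrambling from whole-image scrambling.
    """
    rng = np.random.default_rng(seed)
    xx = np.linspace(0.0, 1.0, width)[None, :]
    img = 80.0 + 50.0 * xx * np.ones((height, 1))
    # bright tool panel on the right, as in many puzzle layouts
    img[:, int(width * 0.8):] = 230.0
    for _ in range(12):
        w = int(rng.uniform(0.10, 0.30) * width)
        h = int(rng.uniform(0.10, 0.30) * height)
        x0 = rng.integers(0, max(width - w, 1))
        y0 = rng.integers(0, max(height - h, 1))
        img[y0:y0 + h, x0:x0 + w] = rng.uniform(170.0, 250.0)
    img += rng.normal(0.0, 8.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def effective_luminance(image: np.ndarray, structure_weight: float = 1.3,
                        cell_px: int = 16) -> float:
    """Global mean intensity minus a weighted coarse-structure contrast.

    The structure term is the standard deviation of cell means over a grid
    of roughly ``cell_px``-pixel cells: retinal adaptation to spatial
    contrast lowers the effective drive of a structured scene relative to a
    uniform field of the same mean.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:  # typical case: memoise on the raw bytes
        return _effective_luminance_cached(
            img.tobytes(), img.shape, structure_weight, cell_px)
    return _effective_luminance_impl(img, structure_weight, cell_px)


@lru_cache(maxsize=256)
def _effective_luminance_cached(data: bytes, shape: tuple,
                                structure_weight: float, cell_px: int) -> float:
    img = np.frombuffer(data, dtype=np.uint8).reshape(shape)
    return _effective_luminance_impl(img, structure_weight, cell_px)


def _effective_luminance_impl(image: np.ndarray, structure_weight: float,
                              cell_px: int) -> float:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.2126, 0.7152, 0.0722])
    h, w = img.shape
    ny = max(h // cell_px, 1)
    nx = max(w // cell_px, 1)
    ye = grid_edges(h, ny)
    xe = grid_edges(w, nx)
    # cell means via cumulative sums (exact, fast)
    cs = np.zeros((h + 1, w + 1))
    cs[1:, 1:] = img.cumsum(0).cumsum(1)
    sums = (cs[ye[1:], :][:, xe[1:]] - cs[ye[:-1], :][:, xe[1:]]
            - cs[ye[1:], :][:, xe[:-1]] + cs[ye[:-1], :][:, xe[:-1]])
    areas = np.outer(np.diff(ye), np.diff(xe))
    cell_means = sums / areas
    structure = float(cell_means.std())
    return float(img.mean() - structure_weight * structure)


def luminance_response(profile: ParticipantProfile, image: np.ndarray,
                       reference: np.ndarray,
                       config: SimConfig = SimConfig()) -> float:
    """Steady-state diameter shift (px) while viewing ``image``.

    Zero by construction when the image is the reference in-test frame;
    brighter-than-reference screens constrict (negative shift), darker ones
    dilate.
    """
    el_img = effective_luminance(image, config.structure_weight,
                                 config.structure_cell_px)
    el_ref = effective_luminance(reference, config.structure_weight,
                                 config.structure_cell_px)
    return float(profile.light_gain * (el_img - el_ref))


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

def _seed_for(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def simulate_participant(seed, config: SimConfig = SimConfig(),
                         participant_id: str = "p0") -> ParticipantProfile:
    """Draw one participant profile; deterministic for a given seed."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    d0 = max(rng.normal(config.d0_mean_px, config.d0_sd_px), 5.0)
    gain = -abs(rng.normal(config.light_gain_mean, config.light_gain_sd))
    tepr_gain = float(np.exp(rng.normal(0.0, config.tepr_gain_sigma)))
    skill = float(rng.uniform(0.0, 1.0))
    return ParticipantProfile(participant_id, float(d0), float(gain),
                              tepr_gain, skill)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def _noisy_channels(rng, t, d_det, config: SimConfig):
    """Add sample noise, artifacts, and split into two eye channels."""
    n = t.size
    d = d_det + rng.normal(0.0, config.noise_sd_px, size=n)
    # isolated tracker spikes (to be removed by the Hampel stage)
    n_spikes = rng.poisson(config.spike_rate_hz * (n / config.rate_hz))
    spike_idx = rng.integers(0, n, size=n_spikes)
    d[spike_idx] += rng.choice([-1.0, 1.0], size=n_spikes) * \
        rng.uniform(0.6, 1.4, size=n_spikes) * config.spike_magnitude_px
    d_left = d + rng.normal(0.0, config.channel_noise_sd_px, size=n)
    d_right = d + rng.normal(0.0, config.channel_noise_sd_px, size=n)
    # blink dropouts: both channels lost for a short run
    n_blinks = rng.poisson(config.blink_rate_hz * (n / config.rate_hz))
    dt = 1000.0 / config.rate_hz
    for _ in range(n_blinks):
        start = rng.integers(0, n)
        length = max(int(rng.normal(config.blink_duration_ms, 30.0) / dt), 1)
        d_left[start:start + length] = np.nan
        d_right[start:start + length] = np.nan
    d_left = np.where(np.isfinite(d_left), np.maximum(d_left, 1.0), np.nan)
    d_right = np.where(np.isfinite(d_right), np.maximum(d_right, 1.0), np.nan)
    return d_left, d_right


def _time_grid(duration_ms: float, rate_hz: float) -> np.ndarray:
    n = max(int(round(duration_ms / 1000.0 * rate_hz)), 2)
    return np.arange(n) * (1000.0 / rate_hz)


def _phasic_sum(t_ms, event_times, amplitudes, kernel: KernelSpec):
    out = np.zeros_like(t_ms, dtype=float)
    for t_k, a_k in zip(event_times, amplitudes):
        out += a_k * kernel(t_ms - t_k)
    return out


def _truncated_exp(rng, n, scale_ms, upper_ms):
    if upper_ms <= 0:
        return np.zeros(0)
    u = rng.uniform(size=n)
    return -scale_ms * np.log1p(-u * (1.0 - np.exp(-upper_ms / scale_ms)))


def simulate_trial_trace(
    profile: ParticipantProfile,
    baseline_image: np.ndarray,
    difficulty: str | None,
    duration_ms: float,
    seed,
    config: SimConfig = SimConfig(),
    reference: np.ndarray | None = None,
    tonic_offset: float = 0.0,
    participant_id: str | None = None,
) -> TrialTraces:
    """One baseline-viewing trace plus one measurement trace.

    The baseline segment is an 8 s fixation on ``baseline_image``; the
    measurement segment lasts ``duration_ms`` while the participant views a
    screen luminance-equivalent to the reference frame.  With
    ``difficulty`` in ``{"A", "B"}`` the measurement carries a sustained
    effort shift plus Poisson-placed phasic task-evoked responses; with
    ``difficulty=None`` it is passive viewing (the baseline-image
    comparison setting).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if reference is None:
        reference = synth_game_frame(config.frame_width, config.frame_height,
                                     config.frame_seed)
    pid = participant_id if participant_id is not None else profile.participant_id
    shift = luminance_response(profile, baseline_image, reference, config)
    jitter_b = rng.normal(0.0, config.interval_jitter_sd_px)
    jitter_m = rng.normal(0.0, config.interval_jitter_sd_px)
    tonic_b = profile.d0 + tonic_offset + shift + jitter_b

    if difficulty is None:
        tonic_m = profile.d0 + tonic_offset + jitter_m
        event_times = np.zeros(0)
        amplitudes = np.zeros(0)
    else:
        if difficulty not in WORLDS:
            raise ValueError(f"difficulty must be one of {WORLDS} or None")
        tonic_m = (profile.d0 + tonic_offset + jitter_m
                   + config.tonic_effort_px[difficulty])
        n_events = rng.poisson(config.phasic_events_mean[difficulty])
        upper = max(min(duration_ms - 2000.0, config.event_horizon_ms), 1.0)
        event_times = np.sort(
            _truncated_exp(rng, n_events, config.event_time_scale_ms, upper)
        )
        amp_mean = config.phasic_amp_px[difficulty] * profile.tepr_gain
        amplitudes = np.maximum(
            rng.normal(amp_mean, config.phasic_amp_cv * amp_mean,
                       size=n_events),
            0.1,
        )

    t_b = _time_grid(config.observation_s * 1000.0, config.rate_hz)
    det_b = np.full(t_b.size, tonic_b)
    bl, br = _noisy_channels(rng, t_b, det_b, config)
    baseline = PupilTrace(t_b, bl, br, config.rate_hz, pid, "baseline")

    t_m = _time_grid(duration_ms, config.rate_hz)
    det_m = tonic_m + _phasic_sum(t_m, event_times, amplitudes, config.kernel)
    ml, mr = _noisy_channels(rng, t_m, det_m, config)
    measurement = PupilTrace(t_m, ml, mr, config.rate_hz, pid, "measurement")

    truth = TrialTruth(
        tonic_baseline=float(tonic_b),
        tonic_measurement=float(tonic_m),
        event_times_ms=event_times,
        amplitudes=amplitudes,
        kernel=config.kernel,
        baseline_shift=float(shift),
        jitter_baseline=float(jitter_b),
        jitter_measurement=float(jitter_m),
    )
    return TrialTraces(baseline, measurement, truth)


# ---------------------------------------------------------------------------
# Telemetry
# ---------------------------------------------------------------------------

def simulate_gamer_telemetry(
    profile: ParticipantProfile,
    difficulty: str,
    seed,
    config: SimConfig = SimConfig(),
    level_id: str | None = None,
) -> SessionLog:
    """Session log for one level: errors and completion time scale with
    difficulty and (inversely) with skill; position changes and attempts
    carry no difficulty signal."""
    if difficulty not in WORLDS:
        raise ValueError(f"difficulty must be one of {WORLDS}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if level_id is None:
        level_id = WORLD_LEVELS[difficulty][0]
    skill_c = 0.5 - profile.skill
    te = rng.poisson(config.te_mean[difficulty] * np.exp(config.skill_te_slope * skill_c))
    mu = np.log(config.tc_median_ms[difficulty]) + config.skill_tc_slope * skill_c
    tc = float(np.exp(rng.normal(mu, config.tc_sigma)))
    cp = rng.poisson(config.cp_mean)
    extra_attempts = rng.poisson(config.extra_attempts_mean)
    places = 1 + rng.poisson(config.places_mean)

    events: list[tuple[float, str]] = [(0.0, "attempt_start")]
    interior = rng.uniform(1.0, tc - 1.0, size=extra_attempts)
    events += [(float(t), "attempt_start") for t in interior]
    events += [(float(t), "error")
               for t in rng.uniform(1.0, tc - 1.0, size=te)]
    events += [(float(t), "move") for t in rng.uniform(1.0, tc - 1.0, size=cp)]
    events += [(float(t), "place") for t in rng.uniform(0.0, tc, size=places)]
    events.append((tc, "level_complete"))
    events.sort(key=lambda e: e[0])
    return SessionLog(profile.participant_id, level_id, events)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _baseline_images(frame: np.ndarray, rng) -> dict[str, np.ndarray]:
    images = {}
    for cond, (method, n, m) in _CONDITION_SPECS.items():
        spec = ScrambleSpec(method, n, m, seed=int(rng.integers(2**31)))
        images[cond] = make_baseline_image(frame, spec)
    return images


def simulate_experiment1_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Baseline-image comparison: every participant views all six baseline
    images (8 s each) followed by the in-test frame (8 s)."""
    frame = synth_game_frame(config.frame_width, config.frame_height,
                             config.frame_seed)
    images = _baseline_images(frame, _seed_for(config, 0))
    records = []
    for i in range(config.n_participants_exp1):
        pid = f"e1p{i:02d}"
        profile = simulate_participant(_seed_for(config, 1, i), config, pid)
        for j, cond in enumerate(EXP1_CONDITIONS):
            traces = simulate_trial_trace(
                profile, images[cond], None,
                config.observation_s * 1000.0,
                _seed_for(config, 2, i, j), config, frame,
            )
            records.append(Exp1Record(pid, cond, traces))
    return Cohort(config=config, frame=frame, experiment1=records)


def simulate_experiment2_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Difficulty cohort: per participant, a world-A baseline viewing, the
    two world-A levels, a world-B baseline viewing, then the two world-B
    levels.  The session tonic drifts upward before world B (arousal
    carry-over), which leaves the subtractive features untouched but makes
    the divisive one uninformative."""
    frame = synth_game_frame(config.frame_width, config.frame_height,
                             config.frame_seed)
    n, m = config.baseline_grid
    participants = []
    for i in range(config.n_participants):
        pid = f"p{i:02d}"
        profile = simulate_participant(_seed_for(config, 1, i), config, pid)
        rng_img = _seed_for(config, 3, i)
        baselines: dict[str, PupilTrace] = {}
        trials: list[Exp2Trial] = []
        for wi, world in enumerate(WORLDS):
            drift = config.baseline_drift_frac * profile.d0 if world == "B" else 0.0
            baseline_image = make_baseline_image(
                frame, ScrambleSpec("grid_scramble", n, m,
                                    seed=int(rng_img.integers(2**31)))
            )
            for li, level_id in enumerate(WORLD_LEVELS[world]):
                rng = _seed_for(config, 4, i, wi, li)
                log = simulate_gamer_telemetry(profile, world, rng, config,
                                               level_id)
                tc = next(t for t, k in log.events if k == "level_complete")
                traces = simulate_trial_trace(
                    profile, baseline_image, world, tc, rng, config, frame,
                    tonic_offset=drift,
                )
                if li == 0:
                    baselines[world] = traces.baseline
                trials.append(Exp2Trial(level_id, world, log,
                                        traces.measurement, traces.truth))
        participants.append(Exp2Participant(profile, baselines, trials))
    return Cohort(config=config, frame=frame, experiment2=participants)


def simulate_cohort(config: SimConfig = SimConfig(),
                    experiments: tuple[str, ...] = ("exp1", "exp2")) -> Cohort:
    """Full synthetic study: both experimental cohorts under one seed."""
    frame = synth_game_frame(config.frame_width, config.frame_height,
                             config.frame_seed)
    cohort = Cohort(config=config, frame=frame)
    if "exp1" in experiments:
        cohort.experiment1 = simulate_experiment1_cohort(config).experiment1
    if "exp2" in experiments:
        cohort.experiment2 = simulate_experiment2_cohort(config).experiment2
    return cohort
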