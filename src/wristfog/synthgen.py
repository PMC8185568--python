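"""Synthetic single-wrist IMU cohorts with annotated freezing episodes.

Real wrist recordings of Parkinson's-disease walking sessions with
clinician-annotated freezing-of-gait (FoG) episodes are scarce and
typically shared only on request, so this module generates stylized
cohorts with the same structure: per subject, a continuous 6-channel
recording (tri-axial accelerometer + gyroscope at 128 Hz) tiled by
WALK / STOP / FOG intervals.

The signal model is deliberately simple — a test harness for the
pipeline, not a biomechanical simulation:

* **walk** — gravity offset on one accelerometer axis, an arm-swing
  fundamental at the subject's gait frequency (~1 Hz) with a second
  harmonic, matching angular-rate swing on the gyroscope plus periodic
  yaw bursts emulating 180°/360° turns, and white noise;
* **FoG** — the locomotor component attenuated, plus a trembling tone
  with an episode-specific centre frequency in the 3–8 Hz freeze band
  and band-limited freeze-band noise (so the freeze index, the power
  ratio freeze-band/locomotor-band, exceeds 1 inside an episode);
* **stop** — gravity plus the noise floor only.

Episode durations follow a lognormal law quantile-matched to published
clinical statistics for FoG episodes (about half last under 3 s,
~65% under 5 s, full range 0.11–98.8 s), truncated to that range by
rejection.  A class-separation knob γ ∈ [0, 1] scales every
class-distinguishing component; at γ=0 the three classes are
statistically identical (the null cohort), at γ=1 the defaults apply.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import AnnotationTrack, ImuRecording

logger = logging.getLogger(__name__)

#: Truncation bounds of the episode-duration law, in seconds.
DURATION_RANGE = (0.11, 98.8)

#: Lognormal parameters solved so that P(d < 3 s) = 0.508 and
#: P(d < 5 s) = 0.647 under the untruncated law.
DURATION_MU = 1.0699
DURATION_SIGMA = 1.4302


@dataclass
class GeneratorConfig:
    """Cohort-level generation settings (defaults = the study conditions)."""

    fs: float = 128.0
    n_subjects: int = 11
    session_s: float = 600.0
    # per-subject gait
    gait_freq_mean: float = 1.0           # Hz
    gait_freq_sd: float = 0.1
    swing_amp: float = 0.25               # g, arm-swing fundamental on accel
    harmonic_frac: float = 0.35           # 2nd-harmonic amplitude fraction
    gravity_g: float = 1.0                # offset on the az axis
    gyro_swing_amp: float = 60.0          # deg/s
    turn_rate: float = 80.0               # deg/s peak yaw rate during turns
    turn_period_s: float = 20.0
    turn_duration_s: float = 3.0
    # FoG trembling
    fog_center_range: tuple[float, float] = (4.0, 7.0)   # Hz
    fog_tremble_amp: float = 0.18         # g
    fog_gyro_tremble_amp: float = 40.0    # deg/s
    fog_band: tuple[float, float] = (3.0, 8.0)
    fog_band_noise_amp: float = 0.06      # g
    locomotor_attenuation: float = 0.25   # FoG keeps this fraction of the swing
    # noise floors
    accel_noise_sd: float = 0.02          # g, all classes
    gyro_noise_sd: float = 2.0            # deg/s
    # session structure
    walk_block_range: tuple[float, float] = (25.0, 50.0)  # s
    stop_block_range: tuple[float, float] = (5.0, 15.0)   # s
    episode_buffer_s: float = 2.0         # min walk margin around an episode
    episodes_per_min: float = 3.8         # nominal candidate rate (pre-thinning)
    # episode-duration law
    duration_mu: float = DURATION_MU
    duration_sigma: float = DURATION_SIGMA
    duration_range: tuple[float, float] = DURATION_RANGE
    # separation knob
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.episodes_per_min < 0:
            raise ValueError("episode rate must be nonnegative")


@dataclass
class SubjectParams:
    """Per-subject idiosyncrasies, drawn once per subject."""

    gait_freq: float
    swing_amp: float
    harmonic_frac: float
    axis_weights: np.ndarray      # how the swing projects on ax, ay, az
    gyro_weights: np.ndarray      # gx, gy, gz
    tremble_amp: float


@dataclass
class SyntheticCohort:
    """Generated recordings + annotation tracks with a provenance manifest."""

    recordings: list[ImuRecording]
    tracks: list[AnnotationTrack]
    manifest: dict


def sample_episode_duration(rng: np.random.Generator,
                            config: GeneratorConfig) -> float:
    """One FoG episode duration (s): truncated lognormal by rejection."""
    lo, hi = config.duration_range
    while True:
        d = rng.lognormal(config.duration_mu, config.duration_sigma)
        if lo <= d <= hi:
            return d


def _draw_subject_params(rng: np.random.Generator,
                         cfg: GeneratorConfig) -> SubjectParams:
    aw = np.array([1.0, 0.5, 0.3]) * rng.uniform(0.85, 1.15, 3)
    gw = np.array([0.4, 1.0, 0.6]) * rng.uniform(0.85, 1.15, 3)
    return SubjectParams(
        gait_freq=float(rng.normal(cfg.gait_freq_mean, cfg.gait_freq_sd)),
        swing_amp=float(cfg.swing_amp * rng.uniform(0.85, 1.15)),
        harmonic_frac=float(cfg.harmonic_frac * rng.uniform(0.7, 1.3)),
        axis_weights=aw,
        gyro_weights=gw,
        tremble_amp=float(cfg.fog_tremble_amp * rng.uniform(0.85, 1.15)),
    )


def _band_limited_noise(n: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def make_walk_segment(duration_s: float, sp: SubjectParams,
                      rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """n×6 walking-with-turns signal (n = round(duration·fs))."""
    n = max(1, int(round(duration_s * cfg.fs)))
    t = np.arange(n) / cfg.fs
    phase = rng.uniform(0, 2 * np.pi)
    g = cfg.gamma
    fund = np.sin(2 * np.pi * sp.gait_freq * t + phase)
    harm = sp.harmonic_frac * np.sin(4 * np.pi * sp.gait_freq * t + 2 * phase)
    swing = sp.swing_amp * (fund + harm)
    accel = np.zeros((n, 3))
    accel[:, 2] = cfg.gravity_g
    accel += g * swing[:, None] * sp.axis_weights
    accel += rng.standard_normal((n, 3)) * cfg.accel_noise_sd

    gyro_swing = cfg.gyro_swing_amp * np.cos(2 * np.pi * sp.gait_freq * t + phase)
    gyro = g * gyro_swing[:, None] * sp.gyro_weights
    # periodic yaw bursts emulating 180/360-degree turns
    turn = np.zeros(n)
    start = rng.uniform(0, cfg.turn_period_s)
    while start + cfg.turn_duration_s < duration_s:
        i0 = int(start * cfg.fs)
        i1 = min(n, i0 + int(cfg.turn_duration_s * cfg.fs))
        envelope = np.sin(np.pi * np.arange(i1 - i0) / max(1, i1 - i0)) ** 2
        turn[i0:i1] += rng.choice((-1.0, 1.0)) * cfg.turn_rate * envelope
        start += cfg.turn_period_s
    gyro[:, 2] += g * turn
    gyro += rng.standard_normal((n, 3)) * cfg.gyro_noise_sd
    return np.hstack([accel, gyro])


def make_fog_segment(duration_s: float, sp: SubjectParams,
                     rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """n×6 freezing signal: attenuated locomotion + freeze-band trembling."""
    n = max(1, int(round(duration_s * cfg.fs)))
    t = np.arange(n) / cfg.fs
    g = cfg.gamma
    phase = rng.uniform(0, 2 * np.pi)
    fund = np.sin(2 * np.pi * sp.gait_freq * t + phase)
    residual_swing = cfg.locomotor_attenuation * sp.swing_amp * fund

    fc = rng.uniform(*cfg.fog_center_range)
    tremble = sp.tremble_amp * np.sin(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    if n >= 8:
        tremble = tremble + cfg.fog_band_noise_amp * _band_limited_noise(
            n, cfg.fs, cfg.fog_band, rng
        )

    accel = np.zeros((n, 3))
    accel[:, 2] = cfg.gravity_g
    accel += g * (residual_swing + tremble)[:, None] * sp.axis_weights
    accel += rng.standard_normal((n, 3)) * cfg.accel_noise_sd

    gyro_tremble = cfg.fog_gyro_tremble_amp * np.sin(
        2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi)
    )
    gyro_resid = cfg.locomotor_attenuation * cfg.gyro_swing_amp * np.cos(
        2 * np.pi * sp.gait_freq * t + phase
    )
    gyro = g * (gyro_resid + gyro_tremble)[:, None] * sp.gyro_weights
    gyro += rng.standard_normal((n, 3)) * cfg.gyro_noise_sd
    return np.hstack([accel, gyro])


def make_stop_segment(duration_s: float, sp: SubjectParams,
                      rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """n×6 standing-still signal: gravity plus the sensor noise floor."""
    n = max(1, int(round(duration_s * cfg.fs)))
    accel = rng.standard_normal((n, 3)) * cfg.accel_noise_sd
    accel[:, 2] += cfg.gravity_g
    gyro = rng.standard_normal((n, 3)) * cfg.gyro_noise_sd
    return np.hstack([accel, gyro])


_SEGMENT_MAKERS = {
    "WALK": make_walk_segment,
    "FOG": make_fog_segment,
    "STOP": make_stop_segment,
}


def _tile_blocks(total_n: int, rng: np.random.Generator,
                 cfg: GeneratorConfig) -> list[tuple[int, int, str]]:
    """Alternate WALK/STOP blocks tiling [0, total_n) in samples."""
    blocks, pos, label = [], 0, "WALK"
    while pos < total_n:
        lo, hi = cfg.walk_block_range if label == "WALK" else cfg.stop_block_range
        n = min(total_n - pos, int(round(rng.uniform(lo, hi) * cfg.fs)))
        n = max(1, n)
        blocks.append((pos, pos + n, label))
        pos += n
        label = "STOP" if label == "WALK" else "WALK"
    return blocks


def _place_episodes(blocks, total_n: int, rng: np.random.Generator,
                    cfg: GeneratorConfig) -> list[tuple[int, int]]:
    """Poisson candidate starts thinned to fit disjointly inside WALK blocks."""
    if cfg.episodes_per_min == 0:
        return []
    mean_dur = _truncated_lognormal_mean(cfg)
    walk_n = sum(e - s for s, e, lab in blocks if lab == "WALK")
    demand = (cfg.episodes_per_min / 60.0) * (
        mean_dur + 2 * cfg.episode_buffer_s
    ) * (total_n / cfg.fs)
    if demand > 1.2 * walk_n / cfg.fs:
        raise ValueError(
            "episode rate too high: episodes cannot be placed disjointly "
            f"(expected demand {demand:.0f}s vs {walk_n / cfg.fs:.0f}s of walking)"
        )
    n_candidates = rng.poisson(cfg.episodes_per_min * total_n / cfg.fs / 60.0)
    starts = np.sort(rng.uniform(0, total_n / cfg.fs, n_candidates))
    buf = int(round(cfg.episode_buffer_s * cfg.fs))
    walk_blocks = [(s, e) for s, e, lab in blocks if lab == "WALK"]
    accepted: list[tuple[int, int]] = []
    for start_s in starts:
        dur = sample_episode_duration(rng, cfg)
        i0 = int(round(start_s * cfg.fs))
        i1 = i0 + max(1, int(round(dur * cfg.fs)))
        host = next((b for b in walk_blocks if b[0] + buf <= i0 and i1 <= b[1] - buf),
                    None)
        if host is None:
            continue
        if any(i0 < e + buf and i1 > s - buf for s, e in accepted):
            continue
        accepted.append((i0, i1))
    return sorted(accepted)


def _truncated_lognormal_mean(cfg: GeneratorConfig) -> float:
    """Analytic mean of the truncated episode-duration law, in seconds."""
    from scipy.stats import norm

    mu, s = cfg.duration_mu, cfg.duration_sigma
    lo, hi = cfg.duration_range
    a, b = (np.log(lo) - mu) / s, (np.log(hi) - mu) / s
    z = norm.cdf(b) - norm.cdf(a)
    return float(np.exp(mu + s ** 2 / 2)
                 * (norm.cdf(b - s) - norm.cdf(a - s)) / z)


def synthesize_session(subject_id: str, config: GeneratorConfig,
                       rng: np.random.Generator,
                       params: SubjectParams | None = None):
    """One subject's (recording, track): WALK/STOP tiling with FoG inserts."""
    sp = params or _draw_subject_params(rng, config)
    total_n = int(round(config.session_s * config.fs))
    blocks = _tile_blocks(total_n, rng, config)
    episodes = _place_episodes(blocks, total_n, rng, config)

    # carve episodes out of their host walk blocks
    intervals: list[tuple[int, int, str]] = []
    for s, e, lab in blocks:
        if lab != "WALK":
            intervals.append((s, e, lab))
            continue
        pos = s
        for i0, i1 in episodes:
            if i0 >= s and i1 <= e:
                if i0 > pos:
                    intervals.append((pos, i0, "WALK"))
                intervals.append((i0, i1, "FOG"))
                pos = i1
        if pos < e:
            intervals.append((pos, e, "WALK"))
    intervals.sort()

    pieces = [
        _SEGMENT_MAKERS[lab]((e - s) / config.fs, sp, rng, config)
        for s, e, lab in intervals
    ]
    samples = np.vstack(pieces)
    assert samples.shape[0] == total_n
    track = AnnotationTrack(
        subject_id,
        [(s / config.fs, e / config.fs, lab) for s, e, lab in intervals],
    )
    recording = ImuRecording(subject_id, samples, fs=config.fs)
    durations = [(i1 - i0) / config.fs for i0, i1 in episodes]
    return recording, track, durations


def synthesize_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Full cohort: one session per subject, seeded per-subject streams."""
    config = config or GeneratorConfig()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    recordings, tracks, per_subject = [], [], {}
    for i, ss in enumerate(streams):
        sid = f"S{i + 1:02d}"
        rng = np.random.default_rng(ss)
        rec, track, durations = synthesize_session(sid, config, rng)
        recordings.append(rec)
        tracks.append(track)
        per_subject[sid] = {
            "n_episodes": len(durations),
            "episode_durations_s": [round(d, 4) for d in durations],
        }
    total = sum(v["n_episodes"] for v in per_subject.values())
    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "subjects": per_subject,
        "total_episodes": total,
    }
    logger.info("synthesized cohort: %d subjects, %d FoG episodes",
                config.n_subjects, total)
    return SyntheticCohort(recordings, tracks, manifest)


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write per-subject recording + annotation CSVs and manifest.json."""
    from .io import write_annotations, write_recording

    os.makedirs(outdir, exist_ok=True)
    for rec, track in zip(cohort.recordings, cohort.tracks):
        write_recording(rec, os.path.join(outdir, f"{rec.subject_id}.csv"))
        write_annotations(
            track, os.path.join(outdir, f"{rec.subject_id}_annotations.csv")
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(cohort.manifest, fh, indent=2)


def load_cohort(indir) -> SyntheticCohort:
    from .io import read_annotations, read_recording

    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    fs = manifest["config"]["fs"]
    recordings, tracks = [], []
    for sid in sorted(manifest["subjects"]):
        recordings.append(
            read_recording(os.path.join(indir, f"{sid}.csv"), fs=fs, subject_id=sid)
        )
        tracks.append(
            read_annotations(
                os.path.join(indir, f"{sid}_annotations.csv"), subject_id=sid
            )
        )
    return SyntheticCohort(recordings, tracks, manifest)
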