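"""Synthetic accelerometer data: frame pools, virtual experiments, sit-stand-walk.

Because the benchmark recordings behind the seven-activity study are not
redistributable, this module generates stand-in signals with the same
statistical structure the pipeline needs:

* per-activity *frame pools* — each activity emits frames built from a
  per-channel DC baseline (gravity projection), sinusoidal harmonics with
  random phase (gait periodicity), and cross-correlated Gaussian noise;
* *virtual experiments* — a state path sampled from an observable Markov
  model emits frames drawn with replacement from the matching pool, with
  "garbage" frames from an unmodeled-activity pool interspersed at random
  positions (default 1 garbage per 3 genuine frames);
* a continuous *sit-stand-walk* recording (default 15 s at 250 Hz) with
  annotated transition zones between the three phases.

All generators are bit-reproducible under a fixed seed. The emission specs
are declared synthetic stand-ins: they make the seven activities separable
with deliberate overlap between stair-climbing and walking, but make no
claim of biomechanical realism.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chmm import LabeledSequence
from .features import extract_features
from .io_windowing import Recording, TRANSITION_LABEL
from .markov import ObservableMarkovModel, TABLE1_STATES, sample_chain

__all__ = [
    "ActivityEmissionSpec",
    "FramePool",
    "VirtualExperiment",
    "GARBAGE_LABEL",
    "default_activity_specs",
    "garbage_spec",
    "generate_frame_pool",
    "virtual_experiment",
    "generate_sit_stand_walk",
    "make_virtual_dataset",
]

GARBAGE_LABEL = "garbage"


@dataclass
class ActivityEmissionSpec:
    """Signal recipe for one activity.

    dc : per-channel baseline (g); harmonics : per-channel list of
    (frequency Hz, amplitude g) pairs; noise_sd : Gaussian noise SD (g);
    cross_channel_corr : common pairwise correlation of the noise.
    """

    name: str
    dc: tuple[float, ...]
    harmonics: tuple[tuple[tuple[float, float], ...], ...] = ()
    noise_sd: float = 0.05
    cross_channel_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.harmonics and len(self.harmonics) != len(self.dc):
            raise ValueError("need one harmonics list per channel")
        if not 0 <= self.cross_channel_corr < 1:
            raise ValueError("cross_channel_corr must be in [0, 1)")

    @property
    def n_channels(self) -> int:
        return len(self.dc)


@dataclass
class FramePool:
    """Frames available for one activity of one (virtual) subject."""

    activity: str
    frames: np.ndarray  # (N, n_channels, width)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (N, ch, width) array")

    @property
    def size(self) -> int:
        return self.frames.shape[0]


@dataclass
class VirtualExperiment:
    """One simulated activity sequence with garbage contamination."""

    frames: np.ndarray  # (n_total, ch, width)
    labels: np.ndarray  # activity names, GARBAGE_LABEL for spurious frames
    spurious: np.ndarray  # bool flags, True for garbage frames
    state_path: np.ndarray  # genuine-frame state indices (length T)
    subject_id: str | None = None


# Per-activity templates for a 3-channel thigh-worn sensor (g units). For
# other channel counts the patterns are tiled. Stairs deliberately overlaps
# walking (close DC and harmonics) so confusion concentrates there.
_TEMPLATES = {
    "lying": dict(dc=(1.0, 0.05, 0.05), harm=(), noise=0.03, corr=0.2),
    "cycling": dict(dc=(0.30, 0.50, 0.60), harm=((1.5, 0.25),), noise=0.08, corr=0.4),
    "stairs": dict(
        dc=(0.12, 0.22, 0.90), harm=((1.8, 0.35), (3.6, 0.12)), noise=0.14, corr=0.3
    ),
    "walking": dict(
        dc=(0.10, 0.20, 0.95), harm=((2.0, 0.40), (4.0, 0.15)), noise=0.12, corr=0.3
    ),
    "running": dict(
        dc=(0.05, 0.25, 0.85), harm=((2.8, 0.90), (5.6, 0.30)), noise=0.25, corr=0.35
    ),
    "sitting": dict(dc=(0.60, 0.60, 0.20), harm=(), noise=0.03, corr=0.2),
    "standing": dict(dc=(0.15, 0.20, 0.95), harm=(), noise=0.04, corr=0.2),
    GARBAGE_LABEL: dict(
        dc=(0.45, 0.10, 0.50), harm=((0.7, 0.30), (3.3, 0.25)), noise=0.18, corr=0.1
    ),
}


def _spec_from_template(name: str, tpl: dict, n_channels: int) -> ActivityEmissionSpec:
    dc = tuple(tpl["dc"][c % len(tpl["dc"])] for c in range(n_channels))
    # amplitude tapers across channels so channels are informative but distinct
    harmonics = tuple(
        tuple((f, a * (1.0 - 0.15 * (c % 3))) for f, a in tpl["harm"])
        for c in range(n_channels)
    )
    return ActivityEmissionSpec(name, dc, harmonics, tpl["noise"], tpl["corr"])


def default_activity_specs(n_channels: int = 3) -> dict[str, ActivityEmissionSpec]:
    """Emission specs for the seven benchmark activities."""
    return {
        name: _spec_from_template(name, _TEMPLATES[name], n_channels)
        for name in TABLE1_STATES
    }


def garbage_spec(n_channels: int = 3) -> ActivityEmissionSpec:
    """Spec for unmodeled-activity (garbage) frames."""
    return _spec_from_template(GARBAGE_LABEL, _TEMPLATES[GARBAGE_LABEL], n_channels)


def generate_frame_pool(
    spec: ActivityEmissionSpec,
    N: int,
    width: int = 512,
    fs: float = 76.25,
    rng_seed: int | np.random.Generator = 0,
    subject_id: str | None = None,
    dc_scale: float = 1.0,
    amp_scale: float = 1.0,
) -> FramePool:
    """Draw N frames from an activity spec.

    Each frame is dc + sum of harmonics with random phase + correlated
    Gaussian noise. ``dc_scale``/``amp_scale`` impose per-subject style
    (between-subject variability). Frequencies at or above Nyquist raise.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ch = spec.n_channels
    for ch_harm in spec.harmonics:
        for f, _ in ch_harm:
            if f >= fs / 2:
                raise ValueError(f"harmonic at {f} Hz >= Nyquist ({fs / 2} Hz)")
    t = np.arange(width) / fs
    frames = np.empty((N, ch, width))
    dc = np.asarray(spec.dc) * dc_scale
    cov = spec.noise_sd**2 * (
        (1 - spec.cross_channel_corr) * np.eye(ch)
        + spec.cross_channel_corr * np.ones((ch, ch))
    )
    L = np.linalg.cholesky(cov) if spec.noise_sd > 0 else np.zeros((ch, ch))
    for n in range(N):
        sig = np.tile(dc[:, None], (1, width))
        for c in range(ch):
            harmonics = spec.harmonics[c] if spec.harmonics else ()
            for f, a in harmonics:
                phase = rng.uniform(0, 2 * np.pi)
                sig[c] += a * amp_scale * np.sin(2 * np.pi * f * t + phase)
        noise = L @ rng.standard_normal((ch, width))
        frames[n] = sig + noise
    return FramePool(spec.name, frames, subject_id)


def virtual_experiment(
    omm: ObservableMarkovModel,
    pools: dict[str, FramePool],
    T: int = 300,
    garbage_pool: FramePool | None = None,
    garbage_ratio: float = 1.0 / 3.0,
    garbage_mode: str = "per-genuine",
    rng_seed: int | np.random.Generator = 0,
    subject_id: str | None = None,
) -> VirtualExperiment:
    """Simulate one activity sequence from the chain.

    A length-T state path is sampled from the OMM; each state emits a frame
    drawn with replacement from its pool. Garbage frames from
    ``garbage_pool`` are then interspersed at uniformly random positions:
    ``garbage_mode="per-genuine"`` (default) inserts round(T*garbage_ratio)
    frames (ratio 1/3 -> 1 garbage per 3 genuine, 25% of the total);
    ``"of-total"`` makes garbage the given fraction of the final sequence.
    """
    rng = np.random.default_rng(rng_seed)
    missing = [s for s in omm.state_names if s not in pools]
    if missing:
        raise ValueError(f"missing frame pools for states: {missing}")
    path = sample_chain(omm, T, rng)
    genuine_frames = np.stack(
        [
            pools[omm.state_names[s]].frames[
                rng.integers(pools[omm.state_names[s]].size)
            ]
            for s in path
        ]
    )
    genuine_labels = np.array([omm.state_names[s] for s in path], dtype=object)
    if garbage_ratio > 0:
        if garbage_pool is None:
            raise ValueError("garbage_ratio > 0 requires a garbage_pool")
        if garbage_mode == "per-genuine":
            n_garbage = int(round(T * garbage_ratio))
        elif garbage_mode == "of-total":
            n_garbage = int(round(T * garbage_ratio / (1.0 - garbage_ratio)))
        else:
            raise ValueError(f"unknown garbage_mode {garbage_mode!r}")
    else:
        n_garbage = 0
    n_total = T + n_garbage
    spurious = np.zeros(n_total, dtype=bool)
    if n_garbage:
        pos = rng.choice(n_total, size=n_garbage, replace=False)
        spurious[pos] = True
    ch, width = genuine_frames.shape[1:]
    frames = np.empty((n_total, ch, width))
    labels = np.empty(n_total, dtype=object)
    frames[~spurious] = genuine_frames
    labels[~spurious] = genuine_labels
    if n_garbage:
        picks = rng.integers(garbage_pool.size, size=n_garbage)
        frames[spurious] = garbage_pool.frames[picks]
        labels[spurious] = GARBAGE_LABEL
    return VirtualExperiment(frames, labels, spurious, path, subject_id)


def generate_sit_stand_walk(
    durations: tuple[float, float, float] = (5.0, 4.0, 6.0),
    transition_duration: float = 0.8,
    transition_sd: float = 0.1,
    fs: float = 250.0,
    rng_seed: int | np.random.Generator = 0,
    noise_sd: float = 0.03,
    subject_id: str | None = None,
) -> Recording:
    """Continuous 3-channel sit -> stand -> walk recording with annotations.

    The gravity projection rotates smoothly (logistic sigmoid) from the
    sitting to the standing orientation across the first transition; walking
    adds gait harmonics on top of the standing posture. Annotation label
    order is sit, transition, stand, transition, walk. Defaults give 15 s
    at 250 Hz (3750 samples).
    """
    if len(durations) != 3 or any(d <= 0 for d in durations):
        raise ValueError("three positive phase durations required")
    rng = np.random.default_rng(rng_seed)
    n = int(round(sum(durations) * fs))
    t = np.arange(n) / fs
    g_sit = np.array([0.75, 0.60, 0.20])
    g_stand = np.array([0.10, 0.15, 0.98])
    t1 = durations[0]
    t2 = durations[0] + durations[1]
    w1 = max(0.05, transition_duration + rng.normal(0.0, transition_sd))
    w2 = max(0.05, transition_duration + rng.normal(0.0, transition_sd))
    # sigmoid blend of the gravity projections across the sit->stand transition
    blend = 1.0 / (1.0 + np.exp(-(t - t1) / (w1 / 8.0)))
    signal = g_sit[:, None] * (1 - blend) + g_stand[:, None] * blend
    walk_ramp = 1.0 / (1.0 + np.exp(-(t - t2) / (w2 / 8.0)))
    for c, (f, a) in enumerate(((2.0, 0.40), (2.0, 0.30), (4.0, 0.18))):
        phase = rng.uniform(0, 2 * np.pi)
        signal[c] += walk_ramp * a * np.sin(2 * np.pi * f * t + phase)
    signal += noise_sd * rng.standard_normal(signal.shape)
    labels = np.full(n, "sit", dtype=object)
    labels[t >= t1 - w1 / 2] = TRANSITION_LABEL
    labels[t >= t1 + w1 / 2] = "stand"
    labels[t >= t2 - w2 / 2] = TRANSITION_LABEL
    labels[t >= t2 + w2 / 2] = "walk"
    return Recording(signal, fs, labels, subject_id)


def make_virtual_dataset(
    n_subjects: int = 5,
    experiments_per_subject: int = 20,
    T: int = 300,
    garbage_ratio: float = 1.0 / 3.0,
    width: int = 512,
    fs: float = 76.25,
    n_channels: int = 3,
    omm: ObservableMarkovModel | None = None,
    rng_seed: int = 0,
    families=("dc", "energy", "entropy", "correlation"),
) -> dict[str, list[LabeledSequence]]:
    """Full study-style dataset: per-subject pools -> virtual experiments -> features.

    Each virtual subject gets its own frame pools (pool sizes uniform in
    [18, 58], subject-specific DC/amplitude style factors), from which
    ``experiments_per_subject`` contaminated sequences are generated and
    featurized. Returns {subject_id: [LabeledSequence, ...]}.
    """
    from .markov import seven_activity_tpm

    if omm is None:
        omm = seven_activity_tpm()
    rng = np.random.default_rng(rng_seed)
    specs = default_activity_specs(n_channels)
    g_spec = garbage_spec(n_channels)
    dataset: dict[str, list[LabeledSequence]] = {}
    for s in range(n_subjects):
        sid = f"subj{s + 1}"
        dc_scale = 1.0 + rng.normal(0.0, 0.05)
        amp_scale = 1.0 + rng.normal(0.0, 0.08)
        pools = {
            name: generate_frame_pool(
                specs[name],
                int(rng.integers(18, 59)),
                width,
                fs,
                rng,
                sid,
                dc_scale,
                amp_scale,
            )
            for name in omm.state_names
        }
        g_pool = generate_frame_pool(
            g_spec, int(rng.integers(18, 59)), width, fs, rng, sid, dc_scale, amp_scale
        )
        seqs = []
        for _ in range(experiments_per_subject):
            exp = virtual_experiment(
                omm, pools, T, g_pool, garbage_ratio, rng_seed=rng, subject_id=sid
            )
            X = extract_features(exp.frames, families=families).to_numpy()
            seqs.append(LabeledSequence(X, exp.labels, sid, exp.spurious))
        dataset[sid] = seqs
    return dataset
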