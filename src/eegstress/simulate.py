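"""Synthetic EEG / anxiety-score cohort generation.

Emulates a music-intervention stress study: 14-channel scalp EEG sampled at
256 Hz, one 2-minute baseline segment plus four 2-minute music-intervention
(MI) segments per subject, for two groups of subjects ("male" / "female"),
together with pre/post State-Trait Anxiety (STA) questionnaire scores.

Each channel is a sum of five band-limited Gaussian-noise carriers (delta,
theta, alpha, beta, gamma) with configurable per-(group, condition, band) RMS
amplitudes, a 1/f background, and a 50-Hz powerline sinusoid.  Everything is
deterministic given the configuration seed: each (subject, condition, channel)
draws from its own counter-derived random stream, so regenerating any single
recording reproduces it bit-for-bit regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "BAND_NAMES",
    "SYNTH_BAND_EDGES",
    "CHANNELS_1020",
    "CONDITIONS",
    "GROUPS",
    "SimulationConfig",
    "Recording",
    "STARecord",
    "default_band_amplitudes",
    "make_band_signal",
    "one_over_f_noise",
    "simulate_recording",
    "simulate_cohort",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Band edges used for *synthesis* (Hz).  The wavelet decomposition in
#: :mod:`eegstress.signals` uses its own dyadic edges (alpha 8-16, beta 16-32,
#: gamma 32-64); both conventions are common and are documented separately.
SYNTH_BAND_EDGES = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 32.0),
    "gamma": (32.0, 60.0),
}

#: 10-20 montage: central, frontal, parietal and temporal electrodes.
CHANNELS_1020 = (
    "C3", "C4",
    "F3", "F4", "F7", "F8", "FP1", "FP2",
    "P3", "P4",
    "T3", "T4", "T5", "T6",
)

CONDITIONS = ("baseline", "MI-1", "MI-2", "MI-3", "MI-4")
GROUPS = ("male", "female")

#: Typical resting scalp-EEG RMS amplitudes per band (microvolt).
_BASE_AMPLITUDES = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 15.0,
    "beta": 8.0,
    "gamma": 4.0,
}


def default_band_amplitudes(
    groups=GROUPS,
    conditions=CONDITIONS,
    base=None,
    ratios=None,
):
    """Build the (group, condition) -> {band: RMS uV} amplitude map.

    ``ratios`` optionally scales selected cells, e.g.
    ``{("male", "MI-1", "delta"): 4.0}`` multiplies the male MI-1 delta RMS
    by 4 while leaving every other cell at the shared base amplitude.
    """
    base = dict(_BASE_AMPLITUDES if base is None else base)
    amps = {
        (g, c): dict(base) for g in groups for c in conditions
    }
    if ratios:
        for (g, c, b), r in ratios.items():
            amps[(g, c)][b] = amps[(g, c)][b] * r
    return amps


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults mirror the study protocol: 9 subjects per group, 256 Hz,
    2-minute segments, a baseline plus four music interventions, the
    14-electrode 10-20 montage, and STA pre-score ranges / paired
    pre-minus-post reduction distributions matching the reported group
    summaries (reduction SD 7.12 for males, 6.38 for females).
    """

    n_per_group: int = 9
    fs: float = 256.0
    segment_duration: float = 120.0
    conditions: tuple = CONDITIONS
    channel_names: tuple = CHANNELS_1020
    band_amplitude: dict = None  # (group, condition) -> {band: RMS uV}
    noise_exponent: float = 1.0
    noise_rms: float = 5.0
    powerline_amplitude: float = 2.0
    sta_pre_range: dict = field(
        default_factory=lambda: {"male": (45.0, 63.0), "female": (41.0, 59.0)}
    )
    sta_reduction_mean: dict = field(
        default_factory=lambda: {"male": 10.0, "female": 5.5}
    )
    sta_reduction_sd: dict = field(
        default_factory=lambda: {"male": 7.12, "female": 6.38}
    )
    seed: int = 0
    pure_tone_bands: bool = False  # sinusoidal carriers, for oracle tests

    def __post_init__(self):
        if self.band_amplitude is None:
            object.__setattr__(
                self,
                "band_amplitude",
                default_band_amplitudes(GROUPS, self.conditions),
            )
        self.validate()

    def validate(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.fs <= 2 * SYNTH_BAND_EDGES["gamma"][1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge "
                f"({SYNTH_BAND_EDGES['gamma'][1]} Hz)"
            )
        for key, bands in self.band_amplitude.items():
            for band, a in bands.items():
                if a < 0:
                    raise ValueError(f"negative amplitude for {key}/{band}")
        if self.powerline_amplitude < 0 or self.noise_rms < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_duration))

    def with_band_ratio(self, band: str, ratio: float, group: str = "male",
                        conditions=None) -> "SimulationConfig":
        """Return a config with one group's band RMS scaled by ``ratio``
        during the given conditions (default: every non-baseline condition).
        """
        if conditions is None:
            conditions = [c for c in self.conditions if c != "baseline"]
        ratios = {(group, c, band): ratio for c in conditions}
        amps = default_band_amplitudes(GROUPS, self.conditions, ratios=ratios)
        return replace(self, band_amplitude=amps)


@dataclass
class Recording:
    """One subject/condition multichannel EEG segment (microvolt)."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: tuple
    subject_id: str
    group: str
    condition: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must match channel_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class STARecord:
    """Pre (sta1) / post (sta2) State-Trait Anxiety scores, scale 20-80."""

    subject_id: str
    group: str
    sta1: float
    sta2: float

    def __post_init__(self):
        for v in (self.sta1, self.sta2):
            if not 20.0 <= v <= 80.0:
                raise ValueError(f"STA score {v} outside [20, 80]")


def _stream(*keys) -> np.random.Generator:
    """Independent RNG stream keyed on a tuple of ints/strings."""
    entropy = [
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def make_band_signal(band, duration, fs, rms, rng, pure_tone=False):
    """Band-limited carrier of the requested RMS amplitude.

    White Gaussian noise band-pass filtered to the band's synthesis edges
    (delta is a low-pass; gamma is capped at 60 Hz), then rescaled so its
    sample standard deviation equals ``rms``.  With ``pure_tone`` a sinusoid
    at the band's geometric centre frequency is returned instead — useful as
    a closed-form oracle for downstream feature tests.
    """
    if band not in SYNTH_BAND_EDGES:
        raise ValueError(
            f"unknown band {band!r}; valid bands: {', '.join(BAND_NAMES)}"
        )
    if rms < 0:
        raise ValueError("rms must be >= 0")
    n = int(round(duration * fs))
    if rms == 0:
        return np.zeros(n)
    lo, hi = SYNTH_BAND_EDGES[band]
    if pure_tone:
        f0 = np.sqrt(max(lo, 1.0) * hi)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        return rms * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase)
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    if lo <= 0:
        sos = sps.butter(4, hi / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    if sd > 0:
        x = x * (rms / sd)
    return x


def one_over_f_noise(n, fs, exponent, rms, rng):
    """1/f^exponent background noise scaled to the requested RMS (uV)."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x = x * (rms / sd)
    return x


def simulate_recording(config, subject_id, group, condition):
    """Generate one subject/condition :class:`Recording`.

    Deterministic given (config.seed, subject_id, condition, channel): each
    channel's carriers, background and powerline phase come from a dedicated
    stream, so the same call always yields the identical matrix.
    """
    key = (group, condition)
    if key not in config.band_amplitude:
        raise ValueError(
            f"no amplitudes configured for group={group!r}, "
            f"condition={condition!r}"
        )
    amps = config.band_amplitude[key]
    n = config.n_samples
    t = np.arange(n) / config.fs
    data = np.empty((len(config.channel_names), n))
    for ci, ch in enumerate(config.channel_names):
        rng = _stream(config.seed, subject_id, condition, ch)
        x = np.zeros(n)
        for band in BAND_NAMES:
            x += make_band_signal(
                band, config.segment_duration, config.fs,
                amps.get(band, 0.0), rng, pure_tone=config.pure_tone_bands,
            )
        x += one_over_f_noise(n, config.fs, config.noise_exponent,
                              config.noise_rms, rng)
        if config.powerline_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += config.powerline_amplitude * np.sin(
                2 * np.pi * 50.0 * t + phase
            )
        data[ci] = x
    return Recording(
        data=data, fs=config.fs, channel_names=tuple(config.channel_names),
        subject_id=subject_id, group=group, condition=condition,
    )


def _subject_ids(config):
    width = max(2, len(str(config.n_per_group)))
    out = []
    for group, prefix in (("male", "m"), ("female", "f")):
        for i in range(1, config.n_per_group + 1):
            out.append((f"{prefix}{i:0{width}d}", group))
    return out


def simulate_sta_record(config, subject_id, group):
    """Draw one subject's pre/post STA pair from the group's distributions."""
    rng = _stream(config.seed, subject_id, "sta")
    lo, hi = config.sta_pre_range[group]
    sta1 = float(np.clip(rng.uniform(lo, hi), 20.0, 80.0))
    reduction = rng.normal(
        config.sta_reduction_mean[group], config.sta_reduction_sd[group]
    )
    sta2 = float(np.clip(sta1 - reduction, 20.0, 80.0))
    return STARecord(subject_id=subject_id, group=group, sta1=sta1, sta2=sta2)


def simulate_cohort(config):
    """Full cohort: one Recording per (subject x condition) plus one
    STARecord per subject.

    Returns ``(recordings, sta_records)``.  With the default configuration
    that is 18 x 5 = 90 recordings and 18 STA records.
    """
    recordings = []
    sta_records = []
    for subject_id, group in _subject_ids(config):
        for condition in config.conditions:
            recordings.append(
                simulate_recording(config, subject_id, group, condition)
            )
        sta_records.append(simulate_sta_record(config, subject_id, group))
    return recordings, sta_records


def iter_cohort_recordings(config):
    """Lazily yield the cohort's recordings (memory-friendly ordering
    identical to :func:`simulate_cohort`)."""
    for subject_id, group in _subject_ids(config):
        for condition in config.conditions:
            yield simulate_recording(config, subject_id, group, condition)


def simulate_sta_cohort(config):
    """STA records only (no EEG), e.g. for large-n parameter-recovery runs."""
    return [
        simulate_sta_record(config, sid, grp) for sid, grp in _subject_ids(config)
    ]
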