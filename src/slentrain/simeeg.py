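"""Synthetic multichannel EEG for stream familiarisation and test phases.

The simulator emulates the phenomena the analysis pipeline is built to
measure: a steady-state response at the 4 Hz syllable rate, a duplet-rate
(2 Hz) response whose amplitude grows during structured exposure with a
saturating-exponential learning curve, condition-dependent ERP deflections
400-1500 ms after isolated test duplets, 1/f background noise, and
motion-artifact segments with a ground-truth mask. It makes no claim of
biophysical realism (no head model, no sleep dynamics, no ocular/cardiac
morphology); it provides controllable ground truth for recovery and
calibration tests.

Timing: at 250 Hz a 0.25 s syllable is 62.5 samples, so individual token
onsets fall between samples; events are placed at the nearest sample and
the 7.5 s analysis epoch (1875 samples, exactly 15 duplets) is the
alignment unit, matching the epoching the statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import montage as mon
from .streamgen import Stream, TestItem, test_block_events

SYLLABLE_HZ = 4.0
DUPLET_HZ = 2.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-EEG generator.

    Amplitudes are in arbitrary units relative to a unit-SD pink-noise
    background; ``learn_tau_s`` is the time constant (s) of the saturating
    duplet-response growth a_dup(t) = a_dup_max * (1 - exp(-t/tau)) with t
    the time spent in structured streams.
    """

    n_channels: int = 128
    srate_hz: float = 250.0
    a_syll: float = 0.7
    a_dup_max: float = 0.7
    learn_tau_s: float = 60.0
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    phase_jitter_sd: float = 0.3  # radians at the duplet rate, per 7.5 s block
    erp_gain: float = 0.5  # generic auditory response to any test duplet
    erp_effect: float = 0.4  # Word minus Part-word dipolar component
    artifact_rate_per_min: float = 2.0
    seed: int = 0
    positions: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    topo_syll: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    topo_dup: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    topo_erp: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if min(self.a_syll, self.a_dup_max, self.noise_sd, self.erp_gain) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.positions is None:
            self.positions = mon.make_montage(self.n_channels)
        if len(self.positions) != self.n_channels:
            raise ValueError("positions must match n_channels")
        p = self.positions
        r = mon.HEAD_RADIUS_CM
        if self.topo_syll is None:
            # broad central response
            self.topo_syll = mon.gaussian_topography(p, [0, 0, r], fwhm_cm=12)
        if self.topo_dup is None:
            # occipital + left-central, where duplet-rate entrainment is expected
            self.topo_dup = mon.gaussian_topography(
                p, [0, -0.8 * r, 0.3 * r], fwhm_cm=9
            ) + 0.7 * mon.gaussian_topography(p, [-0.6 * r, 0, 0.7 * r], fwhm_cm=7)
        if self.topo_erp is None:
            # frontal-right positive / left-temporal negative dipole
            self.topo_erp = mon.gaussian_topography(
                p, [0.4 * r, 0.7 * r, 0.5 * r], fwhm_cm=8
            ) - mon.gaussian_topography(p, [-0.9 * r, 0, 0.2 * r], fwhm_cm=8)


@dataclass
class EEGRecording:
    """Continuous channels x samples EEG with events and artifact flags."""

    data: np.ndarray
    srate_hz: float
    channel_positions: np.ndarray
    events: pd.DataFrame
    artifact_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape, dtype=bool)
        if self.artifact_mask.shape != self.data.shape:
            raise ValueError("artifact mask must match data shape")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate_hz


def pink_noise(
    n_channels: int, n_samples: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^exponent noise, unit SD per channel, via spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _raised_cosine(duration_s: float, srate: float) -> np.ndarray:
    """One-cycle raised-cosine bump, unit peak."""
    n = int(round(duration_s * srate))
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2 * np.pi * t))


def _evoked(
    n_samples: int,
    onsets_s: np.ndarray,
    amplitudes: np.ndarray,
    kernel: np.ndarray,
    srate: float,
) -> np.ndarray:
    """Sum of amplitude-scaled kernels placed at the nearest sample to each onset."""
    sig = np.zeros(n_samples)
    for t0, a in zip(onsets_s, amplitudes):
        i = int(round(t0 * srate))
        if i >= n_samples or i + len(kernel) <= 0:
            continue
        k0 = max(0, -i)
        j = min(n_samples, i + len(kernel))
        sig[i + k0 : j] += a * kernel[k0 : k0 + (j - i - k0)]
    return sig


def simulate_stream_eeg(
    stream: Stream,
    config: SimulationConfig,
    structured_time_offset_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Synthesise EEG for one familiarisation stream.

    The signal is pink noise plus a syllable-rate evoked train on
    ``topo_syll`` and, for structured streams, a duplet-rate train on
    ``topo_dup`` whose amplitude follows the learning curve
    ``a_dup_max * (1 - exp(-t/learn_tau_s))`` where t counts time already
    spent listening to structured material (``structured_time_offset_s``
    carries it across successive streams). Per-7.5-s-block phase jitter is
    applied as a common latency shift of the evoked components.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    srate = config.srate_hz
    if np.any(stream.onsets_s >= stream.duration_s):
        raise ValueError("stream onsets exceed its duration")
    n_samples = int(round(stream.duration_s * srate))
    nch = config.n_channels

    syll_kernel = _raised_cosine(1.0 / SYLLABLE_HZ, srate)
    dup_kernel = _raised_cosine(1.0 / DUPLET_HZ, srate)

    onsets = np.asarray(stream.onsets_s, dtype=float)
    dup_onsets = onsets[::2]
    structured = stream.condition.value.startswith("structured")
    if structured:
        t_struct = structured_time_offset_s + dup_onsets
        a_dup = config.a_dup_max * (1.0 - np.exp(-t_struct / config.learn_tau_s))
    else:
        a_dup = np.zeros_like(dup_onsets)

    # per-block latency jitter, shared by both rates within a block
    block_len = 7.5
    n_blocks = int(np.ceil(stream.duration_s / block_len))
    jitter_s = (
        rng.normal(0.0, config.phase_jitter_sd, size=n_blocks)
        / (2 * np.pi * DUPLET_HZ)
    )
    block_of = lambda t: np.minimum((t / block_len).astype(int), n_blocks - 1)

    syll_sig = _evoked(
        n_samples,
        onsets + jitter_s[block_of(onsets)],
        np.full(len(onsets), config.a_syll),
        syll_kernel,
        srate,
    )
    dup_sig = _evoked(
        n_samples, dup_onsets + jitter_s[block_of(dup_onsets)], a_dup, dup_kernel, srate
    )

    data = config.noise_sd * pink_noise(nch, n_samples, config.noise_exponent, rng)
    data += config.topo_syll[:, None] * syll_sig[None, :]
    data += config.topo_dup[:, None] * dup_sig[None, :]

    events = stream.to_events()
    return EEGRecording(data, srate, config.positions, events)


def simulate_test_eeg(
    test_blocks: list[list[TestItem]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    block_gap_s: float = 2.5,
) -> EEGRecording:
    """Synthesise EEG for the recognition phase (isolated duplets).

    Every item elicits a generic auditory response (raised-cosine bump,
    0.1-0.6 s, on the syllable topography); Words additionally carry the
    dipolar ``erp_effect`` component on ``topo_erp`` over 400-1500 ms,
    which is what the Word vs Part-word contrasts are built to recover.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    srate = config.srate_hz
    tables = []
    t = 1.0  # lead-in before the first item
    for items in test_blocks:
        tab = test_block_events(items, start_s=t)
        t = tab["onset"].iloc[-1] + items[-1].soa_s + block_gap_s
        tables.append(tab)
    events = pd.concat(tables, ignore_index=True)
    n_samples = int(round((t + 2.5) * srate))

    aud_kernel = _raised_cosine(0.5, srate)
    erp_len = int(round(1.1 * srate))  # 400-1500 ms window
    erp_kernel = _raised_cosine(1.1, srate)[:erp_len]

    aud = np.zeros(n_samples)
    word_comp = np.zeros(n_samples)
    for _, row in events.iterrows():
        i = int(round((row["onset"] + 0.1) * srate))
        j = min(n_samples, i + len(aud_kernel))
        aud[i:j] += config.erp_gain * aud_kernel[: j - i]
        if row["item_type"] == "word" and config.erp_effect != 0:
            i2 = int(round((row["onset"] + 0.4) * srate))
            j2 = min(n_samples, i2 + erp_len)
            word_comp[i2:j2] += config.erp_effect * erp_kernel[: j2 - i2]

    data = config.noise_sd * pink_noise(
        config.n_channels, n_samples, config.noise_exponent, rng
    )
    data += config.topo_syll[:, None] * aud[None, :]
    data += config.topo_erp[:, None] * word_comp[None, :]
    return EEGRecording(data, srate, config.positions, events)


def inject_artifacts(
    recording: EEGRecording,
    rate_per_min: float,
    seed: int | np.random.Generator,
    min_dur_s: float = 0.3,
    max_dur_s: float = 1.5,
    channel_frac_range: tuple[float, float] = (0.1, 0.6),
    amplitude_mult: float = 10.0,
) -> EEGRecording:
    """Add high-amplitude motion-like segments and flag them in the mask.

    Each event corrupts a random contiguous time span on a random channel
    subset with noise of ``amplitude_mult`` times the background SD. The
    returned mask is ground truth for the rejection-rule tests: segments
    may or may not exceed the 30 %-of-channels rejection threshold
    depending on the drawn channel fraction.
    """
    if rate_per_min < 0:
        raise ValueError("artifact rate must be >= 0")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    data = recording.data.copy()
    mask = recording.artifact_mask.copy()
    srate = recording.srate_hz
    n_events = rng.poisson(rate_per_min * recording.duration_s / 60.0)
    sd = data.std()
    nch = recording.n_channels
    for _ in range(n_events):
        dur = rng.uniform(min_dur_s, max_dur_s)
        n = int(round(dur * srate))
        start = int(rng.integers(0, max(1, recording.n_samples - n)))
        frac = rng.uniform(*channel_frac_range)
        chans = rng.choice(nch, size=max(1, int(round(frac * nch))), replace=False)
        burst = amplitude_mult * sd * rng.standard_normal((len(chans), n))
        data[chans, start : start + n] += burst
        mask[chans, start : start + n] = True
    return replace(recording, data=data, artifact_mask=mask)


def concatenate_recordings(recs: list[EEGRecording]) -> EEGRecording:
    """Join recordings end to end, shifting event onsets accordingly."""
    if not recs:
        raise ValueError("nothing to concatenate")
    datas, masks, events = [], [], []
    offset = 0.0
    for r in recs:
        datas.append(r.data)
        masks.append(r.artifact_mask)
        ev = r.events.copy()
        ev["onset"] = ev["onset"] + offset
        events.append(ev)
        offset += r.duration_s
    return EEGRecording(
        np.concatenate(datas, axis=1),
        recs[0].srate_hz,
        recs[0].channel_positions,
        pd.concat(events, ignore_index=True),
        np.concatenate(masks, axis=1),
    )
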