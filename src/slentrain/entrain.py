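"""Inter-trial coherence, neighbour-bin SNR and electrode-wise permutation stats.

With 7.5 s epochs the DFT bin spacing is 1/7.5 = 0.1333... Hz, so the
4 Hz syllable rate and 2 Hz duplet rate fall exactly on bins 30 and 15.
ITC(f) is the modulus of the mean unit phase vector over epochs — a pure
phase statistic, invariant to per-epoch amplitude scaling, ranging from 0
(desynchronised) to 1 (perfectly phase-locked). SNR z-scores the ITC at a
bin against the twelve adjacent bins (six per side, spanning 0.8 Hz),
which also cancels the ITC's epoch-count bias (E[ITC] ~ sqrt(pi/(4N))
under uniform phases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .permutation import (
    PermTestResult,
    paired_signflip_test,
    unpaired_permutation_test,
)
from .preproc import EpochSet

SYLLABLE_HZ = 4.0
DUPLET_HZ = 2.0
N_NEIGHBOURS_PER_SIDE = 6


@dataclass
class SpectralResult:
    """Per-electrode ITC and SNR spectra for one condition."""

    itc: np.ndarray  # electrodes x bins, in [0, 1]
    snr: np.ndarray  # electrodes x bins (z-like); NaN where neighbours are missing
    freqs_hz: np.ndarray
    n_epochs: int
    condition: str = ""

    def bin_of(self, freq_hz: float) -> int:
        i = int(np.argmin(np.abs(self.freqs_hz - freq_hz)))
        if not np.isclose(self.freqs_hz[i], freq_hz, atol=1e-9):
            raise ValueError(f"{freq_hz} Hz is not on a DFT bin")
        return i


def epoch_phases(epochs: np.ndarray) -> np.ndarray:
    """DFT phases per epoch/channel/bin (rectangular window, mean removed)."""
    x = epochs - epochs.mean(axis=-1, keepdims=True)
    return np.angle(np.fft.rfft(x, axis=-1))


def compute_itc(epochs: EpochSet | np.ndarray, condition: str = "") -> SpectralResult:
    """ITC per electrode and frequency bin over the valid epochs."""
    if isinstance(epochs, EpochSet):
        arr = epochs.epochs[epochs.valid]
        srate = epochs.srate_hz
    else:
        arr = np.asarray(epochs)
        srate = 250.0
    if arr.shape[0] < 2:
        raise ValueError("ITC needs at least 2 epochs")
    phases = epoch_phases(arr)
    itc = np.abs(np.exp(1j * phases).mean(axis=0))
    freqs = np.fft.rfftfreq(arr.shape[-1], d=1.0 / srate)
    snr = snr_spectrum(itc)
    return SpectralResult(itc, snr, freqs, arr.shape[0], condition)


def snr_spectrum(itc: np.ndarray, n_side: int = N_NEIGHBOURS_PER_SIDE) -> np.ndarray:
    """SNR at every bin: (ITC - mean of 12 neighbours) / SD of neighbours.

    Bins without a full neighbour set on both sides are NaN. A zero
    neighbour SD gives 0 when the target equals the neighbour mean (a
    flat spectrum carries no excess synchronisation) and NaN otherwise
    (undefined z-score; ``compute_snr`` raises on it).
    """
    itc = np.asarray(itc)
    nbins = itc.shape[-1]
    snr = np.full_like(itc, np.nan, dtype=float)
    for b in range(n_side, nbins - n_side):
        neigh = np.concatenate(
            [itc[..., b - n_side : b], itc[..., b + 1 : b + 1 + n_side]], axis=-1
        )
        mu = neigh.mean(axis=-1)
        sd = neigh.std(axis=-1, ddof=1)
        diff = itc[..., b] - mu
        # identical neighbour values can leave round-off residue in mean/SD
        tiny = 1e-12
        sd = np.where(sd > tiny, sd, 0.0)
        diff = np.where(np.abs(diff) > tiny, diff, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr[..., b] = np.where(
                sd > 0, diff / sd, np.where(diff == 0, 0.0, np.nan)
            )
    return snr


def compute_snr(spectral: SpectralResult, target_hz: float) -> np.ndarray:
    """Per-electrode SNR at an on-bin target frequency."""
    b = spectral.bin_of(target_hz)
    if b < N_NEIGHBOURS_PER_SIDE or b + N_NEIGHBOURS_PER_SIDE >= len(spectral.freqs_hz):
        raise ValueError("not enough neighbour bins around target")
    out = spectral.snr[:, b]
    if np.any(np.isnan(out)):
        raise ZeroDivisionError(f"zero neighbour SD around {target_hz} Hz")
    return out


def neighbour_average_snr(spectral: SpectralResult, target_hz: float) -> np.ndarray:
    """Mean SNR over the 12 bins adjacent to the target, per electrode."""
    b = spectral.bin_of(target_hz)
    lo, hi = b - N_NEIGHBOURS_PER_SIDE, b + N_NEIGHBOURS_PER_SIDE
    if lo - N_NEIGHBOURS_PER_SIDE < 0 or hi + N_NEIGHBOURS_PER_SIDE >= len(
        spectral.freqs_hz
    ):
        raise ValueError("not enough bins to evaluate neighbour SNRs")
    idx = np.r_[lo:b, b + 1 : hi + 1]
    return spectral.snr[:, idx].mean(axis=1)


def test_target_vs_neighbours(
    target_snr: np.ndarray,
    neighbour_snr: np.ndarray,
    tail: str = "greater",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> PermTestResult:
    """One-tailed paired permutation test: SNR at target vs neighbour average.

    Inputs are (n_subjects, n_electrodes); the null sign-flips each
    subject's difference map. p-values are BH-FDR corrected across
    electrodes.
    """
    diffs = np.asarray(target_snr) - np.asarray(neighbour_snr)
    return paired_signflip_test(
        diffs, tail=tail, n_perm=n_perm, seed=seed, kind="paired-vs-neighbours"
    )


def test_structured_vs_random(
    structured_snr: np.ndarray,
    random_snr: np.ndarray,
    tail: str = "greater",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> PermTestResult:
    """One-tailed paired permutation test of the condition difference."""
    diffs = np.asarray(structured_snr) - np.asarray(random_snr)
    return paired_signflip_test(
        diffs, tail=tail, n_perm=n_perm, seed=seed, kind="paired-between-conditions"
    )


def test_interaction(
    group_a_diffs: np.ndarray,
    group_b_diffs: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> PermTestResult:
    """Two-sided unpaired permutation test of Structured-Random between groups."""
    return unpaired_permutation_test(
        group_a_diffs,
        group_b_diffs,
        tail="two-sided",
        n_perm=n_perm,
        seed=seed,
        kind="unpaired-between-groups",
    )
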