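"""Spectral-frequency fingerprinting of motion-parameter series.

Each of the four motion series is mean-centred and passed through the
Discrete Fourier Transform; coefficient energies are summed into an
ordered set of oscillation-period bins (seconds) and the four binned
vectors are concatenated into one feature vector per individual,
optionally log(x+1)-transformed.  Binning by absolute period, using each
record's own length and sampling rate, keeps vectors comparable across
acquisition rates (7.5 vs 15 fps designs).

Energy convention: for a series of length N sampled at ``fps`` Hz, the
non-DC coefficients k = 1..floor(N/2) carry period N/(k*fps) seconds and
energy (2/N^2)|X_k|^2, so a unit-amplitude on-grid sinusoid contributes
energy 0.5 at its period (the Nyquist term of an even-length series is
not doubled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MotionRecord

__all__ = [
    "FrequencyBinSet",
    "Spectrum",
    "SpectralFeatureVector",
    "preset",
    "PRESET_NAMES",
    "dft_energy_spectrum",
    "bin_energies",
    "assemble_features",
    "feature_names",
]

#: Canonical ordering of the four motion series in every feature vector.
SERIES_ORDER = ("pos_angle", "neg_angle", "com_rho", "com_theta")


@dataclass(frozen=True)
class FrequencyBinSet:
    """An ordered list of inclusive period ranges, longest periods first."""

    name: str
    bins: tuple[tuple[float, float], ...]  # (period_hi_s, period_lo_s)

    def __post_init__(self) -> None:
        prev_hi = prev_lo = np.inf
        for hi, lo in self.bins:
            if not (hi > lo > 0):
                raise ValueError(f"{self.name}: bad bin ({hi}, {lo}); need hi > lo > 0")
            if hi >= prev_hi or lo >= prev_lo:
                raise ValueError(
                    f"{self.name}: bins must be sorted by strictly decreasing "
                    f"period; ({hi}, {lo}) is out of order"
                )
            prev_hi, prev_lo = hi, lo

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class Spectrum:
    """Non-DC DFT energies of one series, indexed by oscillation period."""

    periods_s: np.ndarray
    energies: np.ndarray
    n_samples: int
    fps: float

    def __post_init__(self) -> None:
        self.periods_s = np.asarray(self.periods_s, dtype=np.float64)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if len(self.periods_s) != len(self.energies):
            raise ValueError("periods and energies must have equal length")

    @property
    def max_frequency_hz(self) -> float:
        """Highest resolvable oscillation frequency (shortest period)."""
        return 1.0 / self.periods_s[-1]

    @property
    def max_period_s(self) -> float:
        """Longest resolvable oscillation period (fundamental)."""
        return float(self.periods_s[0])


@dataclass
class SpectralFeatureVector:
    """Binned log-energies for one individual, all four series concatenated."""

    individual_id: str
    values: np.ndarray
    binset_name: str
    log_transformed: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)


# Period-range presets (seconds, hi..lo inclusive), longest period first.
# DANIO_XENOPUS_18 is the 18-bin set for zebrafish/Xenopus recordings at
# 15 fps; RADIX_STAGE_18 the 18-bin set for pond-snail developmental-stage
# comparisons and RADIX_STRESSOR_30 the 30-bin set for its environmental
# stressor comparisons, both at 7.5 fps.
_PRESETS: dict[str, tuple[tuple[float, float], ...]] = {
    "DANIO_XENOPUS_18": (
        (598, 298), (200, 149), (120, 99), (85, 54), (49, 33), (29, 20.5),
        (21, 17), (16, 15), (14, 13), (12, 11), (10, 5), (4.9, 3.5),
        (3.3, 2.5), (2.4, 1.7), (1.6, 1), (0.9, 0.33), (0.3, 0.25),
        (0.24, 0.1),
    ),
    "RADIX_STAGE_18": (
        (598, 299), (291, 145), (120, 100), (85, 75), (66, 60), (54, 50),
        (46, 43), (40, 37), (35, 30), (29, 24), (20, 17), (15, 12.5),
        (12.2, 10), (9.5, 5), (2, 1.1), (1, 0.68), (0.66, 0.5), (0.3, 0.26),
    ),
    "RADIX_STRESSOR_30": (
        (300, 150), (100, 75), (60, 50), (43, 37.5), (33.5, 30), (27.5, 25),
        (23, 21.5), (20, 19), (17.5, 16.5), (16, 14.5), (13.5, 12.5),
        (12, 11), (10.5, 9.5), (9, 6.5), (6.3, 5), (4.9, 3.5), (3.3, 2.5),
        (2.4, 2), (1.9, 1.5), (1.4, 1), (0.9, 0.8), (0.7, 0.65), (0.6, 0.5),
        (0.49, 0.4), (0.39, 0.34), (0.33, 0.28), (0.27, 0.22), (0.21, 0.18),
        (0.17, 0.15), (0.14, 0.13),
    ),
}

PRESET_NAMES = tuple(_PRESETS)

# NOTE: DANIO_XENOPUS_18 bins 6 (29-20.5 s) and 7 (21-17 s) overlap on
# [20.5, 21] as published; a coefficient landing there is assigned to the
# longer-period bin only (see bin_energies).


def preset(name: str) -> FrequencyBinSet:
    """Return one of the built-in frequency-bin presets by name."""
    try:
        bins = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return FrequencyBinSet(name=name, bins=bins)


def custom_binset(name: str, bins: list[list[float]] | list[tuple[float, float]]) -> FrequencyBinSet:
    """Build a user binset from [period_hi_s, period_lo_s] pairs."""
    return FrequencyBinSet(name=name, bins=tuple((float(h), float(l)) for h, l in bins))


def dft_energy_spectrum(series: np.ndarray, fps: float) -> Spectrum:
    """Mean-centred DFT energy spectrum of one motion-parameter series.

    Raises
    ------
    ValueError
        If the series has fewer than 4 samples.
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 samples for a spectrum, got {n}")
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    coef = np.fft.rfft(x - x.mean())
    k = np.arange(1, n // 2 + 1)
    energies = (2.0 / n**2) * np.abs(coef[1 : n // 2 + 1]) ** 2
    if n % 2 == 0:
        energies[-1] *= 0.5  # the Nyquist coefficient is not doubled
    periods = n / (k * fps)
    return Spectrum(periods_s=periods, energies=energies, n_samples=n, fps=fps)


def bin_energies(spectrum: Spectrum, binset: FrequencyBinSet) -> np.ndarray:
    """Sum spectral energies into the binset's period ranges.

    Both range ends are inclusive; a coefficient falling in a gap between
    bins contributes nowhere, and one landing exactly on a boundary shared
    by two bins goes to the longer-period bin.
    """
    p = spectrum.periods_s
    e = spectrum.energies
    out = np.zeros(len(binset))
    claimed = np.zeros(len(p), dtype=bool)
    for i, (hi, lo) in enumerate(binset.bins):  # longest periods first
        inside = (p >= lo) & (p <= hi) & ~claimed
        out[i] = e[inside].sum()
        claimed |= inside
    return out


def assemble_features(record: MotionRecord, binset: FrequencyBinSet,
                      log_transform: bool = True) -> SpectralFeatureVector:
    """Build one individual's spectral feature vector.

    The four series are each transformed and binned, then concatenated in
    the fixed order (pos_angle, neg_angle, com_rho, com_theta); with an
    18-bin preset this yields 72 features.  ``log_transform`` maps each
    value x -> ln(x + 1).
    """
    parts = []
    for name in SERIES_ORDER:
        spec = dft_energy_spectrum(record.series[name], record.fps)
        parts.append(bin_energies(spec, binset))
    values = np.concatenate(parts)
    if log_transform:
        values = np.log1p(values)
    return SpectralFeatureVector(
        individual_id=record.source_id,
        values=values,
        binset_name=binset.name,
        log_transformed=log_transform,
    )


def feature_names(binset: FrequencyBinSet) -> list[str]:
    """Column names for a feature matrix, e.g. ``pos_angle.bin01``."""
    return [
        f"{series}.bin{i + 1:02d}"
        for series in SERIES_ORDER
        for i in range(len(binset))
    ]
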