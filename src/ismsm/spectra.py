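"""Informational spectra, cross-spectra, peak extraction and S/N.

The informational spectrum of an EIIP series x(1..N) is the amplitude of its
discrete Fourier transform,

    X(n) = sum_m x(m) exp(-i 2 pi n (m-1) / L),   n = 1 .. L/2,

reported on normalized frequencies f_n = n/L in (0, 0.5]. Series are
mean-centered (EIIP series carry large DC offsets) and zero-padded to a
common even grid length L so spectra of different-length molecules share
bins; the cross-spectrum is then the bin-wise product of member amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eiip import EncodedSequence

__all__ = [
    "InformationalSpectrum",
    "CrossSpectrum",
    "PeakReport",
    "default_grid_length",
    "dft_spectrum",
    "cross_spectrum",
    "signal_to_noise",
    "find_peaks",
    "match_frequency",
]

DEFAULT_GRID = 512


@dataclass(frozen=True)
class InformationalSpectrum:
    source_id: str
    grid_length: int
    amplitudes: np.ndarray  # |X(n)| for n = 1..L/2, non-negative

    def __post_init__(self) -> None:
        if self.grid_length % 2:
            raise ValueError("grid_length must be even")
        if len(self.amplitudes) != self.grid_length // 2:
            raise ValueError("amplitudes length must equal grid_length/2")

    @property
    def frequencies(self) -> np.ndarray:
        """f_n = n/L for n = 1..L/2, strictly increasing in (0, 0.5]."""
        L = self.grid_length
        return np.arange(1, L // 2 + 1) / L


@dataclass(frozen=True)
class CrossSpectrum:
    member_ids: tuple[str, ...]
    grid_length: int
    amplitudes: np.ndarray  # C(j) = prod_i S(i,j)

    @property
    def frequencies(self) -> np.ndarray:
        L = self.grid_length
        return np.arange(1, L // 2 + 1) / L


@dataclass(frozen=True)
class PeakReport:
    frequency: float  # bin/L, in (0, 0.5]
    bin: int  # 1-based DFT bin index
    amplitude: float
    snr: float

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("S/N must be non-negative")


Spectrum = InformationalSpectrum | CrossSpectrum


def default_grid_length(max_sequence_length: int, minimum: int = DEFAULT_GRID) -> int:
    """Next power of two >= max sequence length (at least ``minimum``).

    E.g. the 758-residue human tau sequence needs L = 1024.
    """
    L = minimum
    while L < max_sequence_length:
        L *= 2
    return L


def dft_spectrum(seq: EncodedSequence, grid_length: int = DEFAULT_GRID) -> InformationalSpectrum:
    """Amplitude spectrum of the mean-centered, zero-padded EIIP series."""
    n = len(seq.values)
    if grid_length < n:
        raise ValueError(
            f"grid_length {grid_length} < sequence length {n} for {seq.id!r}"
        )
    if grid_length % 2:
        raise ValueError("grid_length must be even")
    x = np.asarray(seq.values, dtype=float)
    x = x - x.mean()
    padded = np.zeros(grid_length)
    padded[:n] = x
    # rfft bin k equals X(k); keep n = 1..L/2 (drop DC, keep Nyquist).
    amps = np.abs(np.fft.rfft(padded))[1 : grid_length // 2 + 1]
    return InformationalSpectrum(
        source_id=seq.id, grid_length=grid_length, amplitudes=amps
    )


def cross_spectrum(spectra: Sequence[Spectrum]) -> CrossSpectrum:
    """Bin-wise product C(j) = prod_i S(i,j) over member spectra."""
    if not spectra:
        raise ValueError("cross_spectrum requires at least one spectrum")
    grids = {s.grid_length for s in spectra}
    if len(grids) > 1:
        ids = [getattr(s, "source_id", None) or ",".join(s.member_ids) for s in spectra]
        raise ValueError(f"mismatched grid lengths {sorted(grids)} among members {ids}")
    member_ids: list[str] = []
    for s in spectra:
        if isinstance(s, CrossSpectrum):
            member_ids.extend(s.member_ids)
        else:
            member_ids.append(s.source_id)
    product = np.ones_like(spectra[0].amplitudes)
    for s in spectra:
        product = product * s.amplitudes
    return CrossSpectrum(
        member_ids=tuple(member_ids),
        grid_length=spectra[0].grid_length,
        amplitudes=product,
    )


def _nearest_bin(frequency: float, grid_length: int) -> int:
    """1-based bin index nearest to a normalized frequency in (0, 0.5]."""
    if not 0.0 < frequency <= 0.5:
        raise ValueError(f"frequency {frequency} outside (0, 0.5]")
    return int(np.clip(round(frequency * grid_length), 1, grid_length // 2))


def signal_to_noise(spectrum: Spectrum, frequency: float) -> float:
    """Amplitude at the bin nearest ``frequency`` over the spectrum mean."""
    amps = spectrum.amplitudes
    mean = float(amps.mean())
    if mean == 0.0:
        raise ValueError("S/N undefined for an all-zero spectrum")
    return float(amps[_nearest_bin(frequency, spectrum.grid_length) - 1] / mean)


def match_frequency(
    f: float, grid_length: int, tolerance_bins: int = 1
) -> tuple[int, bool]:
    """Nearest bin for a normalized frequency; also whether it is within
    ``tolerance_bins`` of the exact value (for matching peaks across grids)."""
    b = _nearest_bin(f, grid_length)
    within = abs(f - b / grid_length) <= tolerance_bins / grid_length
    return b, within


def find_peaks(
    spectrum: Spectrum, k: int = 5, min_separation_bins: int = 1
) -> list[PeakReport]:
    """Top-k local maxima by amplitude, >= min_separation_bins apart.

    Boundary bins count as maxima when they exceed their single inner
    neighbor. Sorted by amplitude descending; ties broken toward the lower
    frequency. May return fewer than k. An all-zero spectrum yields [].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    amps = spectrum.amplitudes
    B = len(amps)
    if not np.any(amps > 0):
        return []
    mean = float(amps.mean())

    left = np.empty(B)
    right = np.empty(B)
    left[0] = -np.inf
    left[1:] = amps[:-1]
    right[-1] = -np.inf
    right[:-1] = amps[1:]
    is_max = (amps >= left) & (amps >= right) & (amps > 0)
    candidates = np.flatnonzero(is_max)
    # amplitude desc, then lower frequency: stable sort on (-amp, index)
    order = sorted(candidates, key=lambda i: (-amps[i], i))
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation_bins for j in chosen):
            chosen.append(i)
        if len(chosen) == k:
            break
    return [
        PeakReport(
            frequency=float((i + 1) / spectrum.grid_length),
            bin=int(i + 1),
            amplitude=float(amps[i]),
            snr=float(amps[i] / mean),
        )
        for i in chosen
    ]
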