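"""Localization of protein regions contributing to an ISM frequency.

Two complementary views:

* sliding-window spectra — each window of the EIIP series is mean-centered,
  zero-padded to the analysis grid and transformed; the amplitude at the
  target frequency's bin traces which part of the sequence carries the
  periodicity, and a thresholded contiguous run of windows is called as the
  contributing domain;

* continuous wavelet transform — a Morlet CWT over a scale ladder bracketing
  the scale equivalent of the target frequency gives residue-by-scale
  coefficients, quantile-binned into five bands; top-band cells at the
  matched scale are merged into "hotspot" residue intervals.

Residue coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve

from .eiip import EncodedSequence
from .spectra import dft_spectrum, match_frequency, default_grid_length

__all__ = [
    "WindowProfile",
    "DomainAnnotation",
    "WaveletMap",
    "HotspotSet",
    "sliding_window_profile",
    "call_domain",
    "morlet_center_frequency",
    "cwt_map",
    "call_hotspots",
]

MORLET_OMEGA0 = 6.0  # standard admissibility-safe center frequency


@dataclass(frozen=True)
class WindowProfile:
    protein_id: str
    frequency: float
    window_length: int
    step: int
    positions: np.ndarray  # window-center residue indices, 1-based
    responses: np.ndarray  # amplitude at the target bin per window

    @property
    def window_starts(self) -> np.ndarray:
        return self.positions - (self.window_length - 1) // 2


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    frequency: float
    peak_response: float
    threshold_used: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid domain interval")

    def to_bed(self) -> tuple[str, int, int]:
        """(chrom-like id, 0-based start, half-open end)."""
        return self.protein_id, self.start - 1, self.end


@dataclass(frozen=True)
class WaveletMap:
    protein_id: str
    frequency: float
    scales: np.ndarray  # ordered, increasing
    coefficients: np.ndarray  # |CWT|, shape (n_scales, n_residues)
    quantile_bands: np.ndarray  # int 1..5 per cell; band 5 = top quintile
    coi_mask: np.ndarray  # True where inside the cone of influence (valid)

    @property
    def n_residues(self) -> int:
        return self.coefficients.shape[1]


@dataclass(frozen=True)
class HotspotSet:
    protein_id: str
    intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    scale: float
    frequency: float
    band_threshold: int
    edge_flagged: tuple[tuple[int, int], ...] = ()  # intervals touching the COI


def sliding_window_profile(
    seq: EncodedSequence,
    frequency: float,
    window_length: int = 64,
    step: int = 1,
    grid_length: int | None = None,
) -> WindowProfile:
    """Amplitude at ``frequency`` for each sliding window of the EIIP series."""
    x = np.asarray(seq.values, dtype=float)
    n = len(x)
    if window_length > n:
        raise ValueError(
            f"window length {window_length} exceeds sequence length {n}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    if grid_length is None:
        grid_length = default_grid_length(window_length)
    target_bin, _ = match_frequency(frequency, grid_length)

    starts = np.arange(0, n - window_length + 1, step)
    responses = np.empty(len(starts))
    for i, s in enumerate(starts):
        w = x[s : s + window_length]
        w = w - w.mean()
        padded = np.zeros(grid_length)
        padded[:window_length] = w
        responses[i] = np.abs(np.fft.rfft(padded)[target_bin])
    centers = starts + 1 + (window_length - 1) // 2  # 1-based window centers
    return WindowProfile(
        protein_id=seq.id,
        frequency=frequency,
        window_length=window_length,
        step=step,
        positions=centers,
        responses=responses,
    )


def call_domain(profile: WindowProfile, threshold_fraction: float = 0.7) -> DomainAnnotation:
    """Maximal contiguous supra-threshold run of windows, as a residue interval.

    Threshold is ``threshold_fraction`` x max response. Among equal-length
    runs the earlier one wins. The interval spans the first window's start to
    the last window's end.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    resp = profile.responses
    if len(resp) == 0:
        raise ValueError("empty window profile")
    peak = float(resp.max())
    if peak == 0.0:
        raise ValueError("all-zero profile: no domain to call")
    above = resp >= threshold_fraction * peak

    best: tuple[int, int] | None = None  # (start_idx, end_idx) inclusive
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    assert best is not None
    starts = profile.window_starts
    first_start = int(starts[best[0]])
    last_end = int(starts[best[1]]) + profile.window_length - 1
    return DomainAnnotation(
        protein_id=profile.protein_id,
        start=first_start,
        end=last_end,
        frequency=profile.frequency,
        peak_response=peak,
        threshold_used=threshold_fraction * peak,
    )


def morlet_center_frequency(omega0: float = MORLET_OMEGA0) -> float:
    """Center frequency (cycles/sample at scale 1) of the Morlet wavelet."""
    return omega0 / (2.0 * np.pi)


def _morlet(t: np.ndarray, omega0: float) -> np.ndarray:
    return np.pi ** (-0.25) * np.exp(1j * omega0 * t) * np.exp(-0.5 * t * t)


def cwt_map(
    seq: EncodedSequence,
    frequency: float,
    n_scales: int = 25,
    omega0: float = MORLET_OMEGA0,
    scale_span: float = 4.0,
) -> WaveletMap:
    """Morlet CWT of the mean-centered EIIP series.

    The scale ladder is geometric over [s0/scale_span, s0*scale_span] where
    s0 = (omega0 / 2pi) / frequency is the scale whose pseudo-frequency
    matches the target. Absolute coefficients are binned into five quantile
    bands; cone-of-influence cells (within sqrt(2)*scale of either edge) are
    excluded from the quantile computation and marked invalid.
    """
    x = np.asarray(seq.values, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("sequence too short for CWT (need >= 16 residues)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) series: CWT undefined")
    if not 0.0 < frequency <= 0.5:
        raise ValueError(f"frequency {frequency} outside (0, 0.5]")
    x = x - x.mean()

    s0 = morlet_center_frequency(omega0) / frequency
    scales = np.geomspace(s0 / scale_span, s0 * scale_span, n_scales)

    coeffs = np.empty((n_scales, n))
    for i, a in enumerate(scales):
        half = int(np.ceil(6.0 * a))  # envelope support; exp(-18) ~ 1e-8 truncation
        t = np.arange(-half, half + 1) / a
        psi = _morlet(t, omega0) / np.sqrt(a)
        # scipy's "same" keeps the first argument's length even when the
        # wavelet support exceeds the sequence (large scales)
        coeffs[i] = np.abs(convolve(x, np.conj(psi)[::-1], mode="same"))

    # Cone of influence: e-folding distance sqrt(2)*a from each edge.
    positions = np.arange(n)
    coi = np.sqrt(2.0) * scales[:, None]
    valid = (positions[None, :] >= coi) & (positions[None, :] <= n - 1 - coi)

    bands = np.ones_like(coeffs, dtype=int)
    inside = coeffs[valid]
    if inside.size:
        edges = np.quantile(inside, [0.2, 0.4, 0.6, 0.8])
        bands = np.digitize(coeffs, edges) + 1  # 1..5
    return WaveletMap(
        protein_id=seq.id,
        frequency=frequency,
        scales=scales,
        coefficients=coeffs,
        quantile_bands=bands,
        coi_mask=valid,
    )


def call_hotspots(
    wmap: WaveletMap,
    band_threshold: int = 4,
) -> HotspotSet:
    """Residue intervals whose band at the frequency-matched scale meets the
    threshold. Scale selection is nearest-to-frequency; intervals touching
    the cone of influence are flagged separately."""
    if not 1 <= band_threshold <= 5:
        raise ValueError("band_threshold must be in 1..5")
    target_scale = morlet_center_frequency() / wmap.frequency
    row = int(np.argmin(np.abs(wmap.scales - target_scale)))
    hot = wmap.quantile_bands[row] >= band_threshold
    valid = wmap.coi_mask[row]

    intervals: list[tuple[int, int]] = []
    flagged: list[tuple[int, int]] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            iv = (i + 1, j + 1)  # 1-based inclusive
            intervals.append(iv)
            if not (valid[i] and valid[j]):
                flagged.append(iv)
            i = j + 1
        else:
            i += 1
    return HotspotSet(
        protein_id=wmap.protein_id,
        intervals=tuple(intervals),
        scale=float(wmap.scales[row]),
        frequency=wmap.frequency,
        band_threshold=band_threshold,
        edge_flagged=tuple(flagged),
    )
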