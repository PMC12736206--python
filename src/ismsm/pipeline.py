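"""End-to-end spectral screening.

Workflow mirroring a ligand-based ISM campaign against one protein target:

1. derive candidate frequencies — cross-spectra of the target with each
   known ligand, a joint cross-spectrum over all ligands, and a
   conservation cross-spectrum over an ortholog family;
2. scan a compound library — per compound, the (protein, compound)
   cross-spectrum is read at every target frequency;
3. rank — by Total Score when descriptors are available, else by best S/N;
   deterministic compound-id tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eiip import EncodedSequence, EncodingError, encode_smiles
from .scoring import DescriptorRecord, drug_score, total_score
from .spectra import (
    CrossSpectrum,
    cross_spectrum,
    default_grid_length,
    dft_spectrum,
    find_peaks,
    signal_to_noise,
)

__all__ = [
    "FrequencyEntry",
    "FrequencySet",
    "ScreeningHit",
    "derive_ligand_frequencies",
    "derive_joint_frequency",
    "derive_ortholog_frequency",
    "screen_library",
]

logger = logging.getLogger("ismsm")

DEFAULT_SNR_CUTOFF = 20.0  # configurable; mid-range of strong-specificity S/N


@dataclass(frozen=True)
class FrequencyEntry:
    frequency: float
    provenance: str  # ligand-CS | joint-CS | ortholog-CS
    supporting_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.supporting_ids:
            raise ValueError("frequency entry needs at least one supporting id")


@dataclass(frozen=True)
class FrequencySet:
    entries: tuple[FrequencyEntry, ...]
    grid_length: int
    tolerance_bins: int = 1

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(e.frequency for e in self.entries)

    def merged_with(self, other: "FrequencySet") -> "FrequencySet":
        if other.grid_length != self.grid_length:
            raise ValueError("cannot merge frequency sets on different grids")
        merged = list(self.entries)
        for e in other.entries:
            merged = _dedupe_add(merged, e, self.grid_length, self.tolerance_bins)
        return FrequencySet(tuple(merged), self.grid_length, self.tolerance_bins)


def _dedupe_add(
    entries: list[FrequencyEntry],
    new: FrequencyEntry,
    grid_length: int,
    tolerance_bins: int,
) -> list[FrequencyEntry]:
    """Merge ``new`` into an existing entry within the bin tolerance, pooling
    supporting ids; otherwise append."""
    tol = tolerance_bins / grid_length
    for i, e in enumerate(entries):
        if abs(e.frequency - new.frequency) <= tol:
            ids = tuple(dict.fromkeys(e.supporting_ids + new.supporting_ids))
            entries[i] = FrequencyEntry(e.frequency, e.provenance, ids)
            return entries
    return entries + [new]


@dataclass(frozen=True)
class ScreeningHit:
    compound_id: str
    per_frequency: Mapping[float, tuple[float, float]]  # f -> (amplitude, snr)
    best_frequency: float
    best_snr: float
    dS: float | None = None
    total_score: float | None = None
    rank: int | None = None
    is_hit: bool = False


def _analysis_grid(sequences: Sequence[EncodedSequence], grid_length: int | None) -> int:
    longest = max(len(s) for s in sequences)
    if grid_length is None:
        return default_grid_length(longest)
    if grid_length < longest:
        raise ValueError(
            f"grid_length {grid_length} shorter than longest sequence ({longest})"
        )
    return grid_length


def derive_ligand_frequencies(
    protein: EncodedSequence,
    ligands: Sequence[EncodedSequence],
    top_k: int = 1,
    grid_length: int | None = None,
    tolerance_bins: int = 1,
) -> FrequencySet:
    """Per-ligand (protein, ligand) cross-spectrum peaks, deduplicated."""
    if not ligands:
        raise ValueError("need at least one ligand")
    L = _analysis_grid([protein, *ligands], grid_length)
    prot_spec = dft_spectrum(protein, L)
    entries: list[FrequencyEntry] = []
    for lig in ligands:
        cs = cross_spectrum([prot_spec, dft_spectrum(lig, L)])
        for peak in find_peaks(cs, k=top_k):
            entries = _dedupe_add(
                entries,
                FrequencyEntry(peak.frequency, "ligand-CS", (protein.id, lig.id)),
                L,
                tolerance_bins,
            )
    return FrequencySet(tuple(entries), L, tolerance_bins)


def derive_joint_frequency(
    protein: EncodedSequence,
    ligands: Sequence[EncodedSequence],
    top_k: int = 1,
    grid_length: int | None = None,
) -> FrequencySet:
    """Top peak(s) of the cross-spectrum over the protein plus all ligands."""
    if len(ligands) < 2:
        raise ValueError("joint cross-spectrum needs at least two ligands")
    L = _analysis_grid([protein, *ligands], grid_length)
    cs = cross_spectrum([dft_spectrum(s, L) for s in (protein, *ligands)])
    entries = tuple(
        FrequencyEntry(
            p.frequency, "joint-CS", (protein.id, *(l.id for l in ligands))
        )
        for p in find_peaks(cs, k=top_k)
    )
    return FrequencySet(entries, L)


def derive_ortholog_frequency(
    orthologs: Sequence[EncodedSequence],
    top_k: int = 1,
    grid_length: int | None = None,
) -> FrequencySet:
    """Top peak(s) of the conservation cross-spectrum over an ortholog family."""
    if len(orthologs) < 2:
        raise ValueError("ortholog analysis needs at least two sequences")
    L = _analysis_grid(orthologs, grid_length)
    cs = cross_spectrum([dft_spectrum(s, L) for s in orthologs])
    entries = tuple(
        FrequencyEntry(p.frequency, "ortholog-CS", tuple(s.id for s in orthologs))
        for p in find_peaks(cs, k=top_k)
    )
    return FrequencySet(entries, L)


def screen_library(
    protein: EncodedSequence,
    library: Sequence[tuple[str, str]],
    freqs: FrequencySet,
    descriptors: Sequence[DescriptorRecord] | None = None,
    *,
    snr_cutoff: float = DEFAULT_SNR_CUTOFF,
    encoding_mode: str = "per-group",
    grid_length: int | None = None,
) -> list[ScreeningHit]:
    """Scan a SMILES library at the target frequencies and rank.

    Per compound the (protein, compound) cross-spectrum is computed and read
    at each frequency; a compound qualifies as a hit through its best
    frequency (S/N >= ``snr_cutoff``). Ranking is by Total Score when
    descriptors are supplied, else by best S/N; ties break on compound id.
    Unparseable SMILES are logged and skipped (all skipped is an error).
    Results are independent of library input order.
    """
    if not library:
        raise ValueError("empty compound library")
    if not freqs.entries:
        raise ValueError("empty frequency set: nothing to scan")
    L = freqs.grid_length
    if grid_length is not None and grid_length != L:
        raise ValueError("grid_length disagrees with the FrequencySet grid")
    prot_spec = dft_spectrum(protein, L)
    desc_by_id = {d.compound_id: d for d in descriptors} if descriptors else {}

    hits: list[ScreeningHit] = []
    skipped = 0
    for compound_id, smiles in sorted(library):  # order-independence
        try:
            seq = encode_smiles(smiles, mode=encoding_mode, id=compound_id)
        except EncodingError as exc:
            logger.warning("skipping %s: %s", compound_id, exc)
            skipped += 1
            continue
        if len(seq) > L:
            logger.warning("skipping %s: series longer than grid", compound_id)
            skipped += 1
            continue
        cs = cross_spectrum([prot_spec, dft_spectrum(seq, L)])
        mean_amp = float(cs.amplitudes.mean())
        per_freq: dict[float, tuple[float, float]] = {}
        for f in freqs.frequencies:
            b = int(np.clip(round(f * L), 1, L // 2))
            amp = float(cs.amplitudes[b - 1])
            # constant EIIP series (e.g. a pure alkane) gives an all-zero
            # spectrum: no shared information, S/N 0 rather than undefined
            snr = amp / mean_amp if mean_amp > 0 else 0.0
            per_freq[f] = (amp, snr)
        best_f = max(per_freq, key=lambda f: (per_freq[f][1], -f))
        best_snr = per_freq[best_f][1]
        dS = ts = None
        if compound_id in desc_by_id:
            dS = drug_score(desc_by_id[compound_id])
            ts = total_score(dS, best_snr)
        hits.append(
            ScreeningHit(
                compound_id=compound_id,
                per_frequency=per_freq,
                best_frequency=best_f,
                best_snr=best_snr,
                dS=dS,
                total_score=ts,
                is_hit=best_snr >= snr_cutoff,
            )
        )
    if not hits:
        raise ValueError(f"all {skipped} library compounds failed to encode")
    if skipped:
        logger.info("skipped %d unencodable compounds", skipped)

    if descriptors:
        key = lambda h: (-(h.total_score if h.total_score is not None else -np.inf), h.compound_id)
    else:
        key = lambda h: (-h.best_snr, h.compound_id)
    hits.sort(key=key)
    return [
        ScreeningHit(
            compound_id=h.compound_id,
            per_frequency=h.per_frequency,
            best_frequency=h.best_frequency,
            best_snr=h.best_snr,
            dS=h.dS,
            total_score=h.total_score,
            rank=i + 1,
            is_hit=h.is_hit,
        )
        for i, h in enumerate(hits)
    ]
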